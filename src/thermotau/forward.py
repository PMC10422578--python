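"""Multi-exponential forward model for temperature-rise curves.

A thermal system's step response after removal of a cooling excitation is
modelled as a Foster ladder of R-C cells: each cell contributes one rising
exponential, so the surface temperature rise is

    T(t) = sum_i  T_i * (1 - exp(-t / tau_i))

with time constants ``tau_i`` and steady-state amplitudes ``T_i``.  The
curve's asymptote is the sum of the amplitudes.  This module holds the
forward model, the non-uniform (log-spaced) sampling grid that represents a
curve by 1024 points dense at early times, the canonical component ordering,
and the normalized <-> physical unit scaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "N_COMPONENTS",
    "ExponentialSpectrum",
    "TimeGrid",
    "TemperatureCurve",
    "ScalingTransform",
    "evaluate_curve",
    "make_time_grid",
    "sort_components",
    "normalize_spectrum",
    "rescale_spectrum",
]

#: Model order used throughout the pipeline (four R-C cells).
N_COMPONENTS = 4

#: Number of samples representing one curve (the network input width).
N_SAMPLES = 1024


@dataclass(frozen=True)
class ExponentialSpectrum:
    """A discrete time-constant spectrum: paired (tau_i, T_i) components.

    Components are stored sorted by ``tau`` ascending; the constructor
    canonicalizes the order, resolving the label-permutation symmetry of the
    sum of exponentials.

    Parameters
    ----------
    tau : array-like
        Time constants, strictly positive.  Seconds, or dimensionless when
        ``normalized`` is set.
    amp : array-like
        Amplitudes, non-negative, same length as ``tau``.  Degrees Celsius,
        or dimensionless when ``normalized`` is set.
    normalized : bool
        Whether both blocks live on the [0, 1] training scale.
    """

    tau: np.ndarray
    amp: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        amp = np.atleast_1d(np.asarray(self.amp, dtype=float))
        if tau.ndim != 1 or amp.ndim != 1 or tau.size != amp.size or tau.size < 1:
            raise ValueError(
                f"tau and amp must be 1-D of equal length >= 1, got {tau.shape} and {amp.shape}"
            )
        if not np.all(np.isfinite(tau)) or not np.all(np.isfinite(amp)):
            raise ValueError("tau and amp must be finite")
        if np.any(tau <= 0):
            raise ValueError(f"all time constants must be strictly positive, got {tau}")
        if np.any(amp < 0):
            raise ValueError(f"all amplitudes must be non-negative, got {amp}")
        order = np.argsort(tau, kind="stable")
        tau = tau[order]
        amp = amp[order]
        if self.normalized and (tau.max() > 1.0 or amp.max() > 1.0):
            warnings.warn(
                "normalized spectrum has components outside [0, 1]; "
                "the value lies outside the trained parameter range",
                stacklevel=2,
            )
        tau.setflags(write=False)
        amp.setflags(write=False)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "amp", amp)

    @property
    def n_components(self) -> int:
        return self.tau.size

    @property
    def asymptote(self) -> float:
        """Steady-state temperature rise: sum of the amplitudes."""
        return float(self.amp.sum())

    def to_vector(self) -> np.ndarray:
        """Flatten to the regression target layout [tau_1..tau_n, T_1..T_n]."""
        return np.concatenate([self.tau, self.amp])

    @classmethod
    def from_vector(cls, vec: np.ndarray, normalized: bool = True) -> "ExponentialSpectrum":
        vec = np.asarray(vec, dtype=float)
        if vec.ndim != 1 or vec.size % 2:
            raise ValueError(f"expected a flat even-length vector, got shape {vec.shape}")
        half = vec.size // 2
        return cls(tau=vec[:half], amp=vec[half:], normalized=normalized)

    def to_dict(self) -> dict:
        return {
            "tau": self.tau.tolist(),
            "amp": self.amp.tolist(),
            "units": {
                "time": "norm" if self.normalized else "s",
                "temp": "norm" if self.normalized else "C",
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExponentialSpectrum":
        normalized = d.get("units", {}).get("time", "s") == "norm"
        return cls(tau=np.asarray(d["tau"]), amp=np.asarray(d["amp"]), normalized=normalized)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ExponentialSpectrum":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TimeGrid:
    """An ordered set of strictly positive sample times ending at ``t_end``."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a time grid needs at least two samples")
        if samples[0] <= 0:
            raise ValueError("first sample must be strictly positive")
        if np.any(np.diff(samples) <= 0):
            raise ValueError("grid samples must be strictly increasing")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def t_end(self) -> float:
        return float(self.samples[-1])

    def scaled(self, t_scale: float) -> "TimeGrid":
        """Return the grid with every sample multiplied by ``t_scale``."""
        if t_scale <= 0:
            raise ValueError("t_scale must be strictly positive")
        return TimeGrid(self.samples * t_scale)


@dataclass(frozen=True)
class TemperatureCurve:
    """A sampled temperature-rise signal on a :class:`TimeGrid`."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.samples.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid shape {self.grid.samples.shape}"
            )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def to_csv(self, path: str | Path) -> None:
        """Write the curve as two-column CSV (time, value) with a header."""
        arr = np.column_stack([self.grid.samples, self.values])
        np.savetxt(path, arr, delimiter=",", header="time,temperature_rise", comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TemperatureCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(grid=TimeGrid(arr[:, 0]), values=arr[:, 1])


@dataclass(frozen=True)
class ScalingTransform:
    """Multiplicative factors mapping normalized units to physical units.

    ``t_scale`` is seconds per normalized time unit (the recording duration
    used to squeeze the time axis into [0, 1]); ``temp_scale`` is degrees
    Celsius per normalized temperature unit (the recording's temperature-rise
    span).
    """

    t_scale: float
    temp_scale: float

    def __post_init__(self) -> None:
        if self.t_scale <= 0 or self.temp_scale <= 0:
            raise ValueError("scaling factors must be strictly positive")

    @classmethod
    def identity(cls) -> "ScalingTransform":
        return cls(t_scale=1.0, temp_scale=1.0)


def make_time_grid(n: int = N_SAMPLES, t_end: float = 1.0, density: float = 3.0) -> TimeGrid:
    """Build the non-uniform sampling grid, dense at early times.

    Samples follow a log-spaced law

        t_k = t_end * (10**(k/(n-1) * d) - 1) / (10**d - 1),   k = 1..n-1,

    prepended with a first point at half of t_1 so that all samples are
    strictly positive.  With the default density exponent ``d = 3`` more than
    half of the 1024 samples fall in the first 10% of the interval, matching
    the fast transient / quasi-steady-state structure of exponential
    recovery curves.

    Parameters
    ----------
    n : int
        Number of samples (>= 2).
    t_end : float
        Last sample time (> 0).
    density : float
        Log-density exponent ``d``; larger values pack more samples into the
        early part of the interval.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got n={n}")
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    k = np.arange(1, n, dtype=float)
    tail = t_end * (10.0 ** (k / (n - 1) * density) - 1.0) / (10.0**density - 1.0)
    samples = np.concatenate([[tail[0] / 2.0], tail])
    return TimeGrid(samples)


def evaluate_curve(spectrum: ExponentialSpectrum, grid: TimeGrid) -> TemperatureCurve:
    """Evaluate the multi-exponential rise on a grid.

    The value at each sample time t is  sum_i T_i * (1 - exp(-t / tau_i)).
    At t = 0 the model is exactly 0 (grids start strictly after 0).
    """
    t = grid.samples[:, None]
    values = np.sum(spectrum.amp * (1.0 - np.exp(-t / spectrum.tau)), axis=1)
    return TemperatureCurve(grid=grid, values=values)


def evaluate_curves(targets: np.ndarray, grid: TimeGrid, chunk: int = 1024) -> np.ndarray:
    """Vectorized forward model for a batch of target vectors.

    ``targets`` has rows [tau_1..tau_m, T_1..T_m]; returns an (N, grid.n)
    matrix of curve values.  Evaluation is chunked to bound peak memory.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 2 or targets.shape[1] % 2:
        raise ValueError(f"targets must be (N, 2m), got {targets.shape}")
    m = targets.shape[1] // 2
    if np.any(targets[:, :m] <= 0):
        raise ValueError("all time constants must be strictly positive")
    t = grid.samples
    out = np.empty((targets.shape[0], t.size))
    for lo in range(0, targets.shape[0], chunk):
        hi = min(lo + chunk, targets.shape[0])
        tau = targets[lo:hi, None, :m]
        amp = targets[lo:hi, None, m:]
        out[lo:hi] = np.sum(amp * (1.0 - np.exp(-t[None, :, None] / tau)), axis=2)
    return out


def sort_components(spectrum: ExponentialSpectrum) -> ExponentialSpectrum:
    """Return the canonical tau-ascending representative of a spectrum.

    The sum of exponentials is invariant under component permutation; the
    constructor already canonicalizes, so this is idempotent.
    """
    return ExponentialSpectrum(tau=spectrum.tau, amp=spectrum.amp, normalized=spectrum.normalized)


def normalize_spectrum(
    spectrum: ExponentialSpectrum, transform: ScalingTransform
) -> ExponentialSpectrum:
    """Map a physical-unit spectrum onto the [0, 1] training scale.

    Divides tau by ``t_scale`` and amplitudes by ``temp_scale``.  Values that
    land outside [0, 1] trigger a warning (the spectrum falls outside the
    trained range) but are not rejected.
    """
    return ExponentialSpectrum(
        tau=spectrum.tau / transform.t_scale,
        amp=spectrum.amp / transform.temp_scale,
        normalized=True,
    )


def rescale_spectrum(
    spectrum: ExponentialSpectrum, transform: ScalingTransform
) -> ExponentialSpectrum:
    """Map a normalized spectrum back to physical units (inverse of
    :func:`normalize_spectrum` for the same transform)."""
    return ExponentialSpectrum(
        tau=spectrum.tau * transform.t_scale,
        amp=spectrum.amp * transform.temp_scale,
        normalized=False,
    )
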