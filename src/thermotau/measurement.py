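"""Measured-signal ingestion and preprocessing for the inversion pipeline.

A dynamic-thermography recording is a temperature-time series of the skin
surface re-warming after contact cooling (ROI-averaged IR-camera signal,
typically ~50 Hz for ~6 minutes, ~18,000 samples).  Before inversion the
recording is reduced to the network's input representation:

1. the rise onset is located at the global temperature minimum (the
   post-cooling trough) and time is re-zeroed there;
2. the baseline (minimum temperature) is subtracted, so the curve starts
   at 0 and measures temperature *rise*;
3. time is divided by the remaining duration and temperature by the rise
   span (max - min), mapping the curve into the unit square;
4. the result is linearly interpolated onto the 1024-point non-uniform
   grid.

The two divisors are kept as a :class:`ScalingTransform` so normalized
predictions can be mapped back to seconds and degrees Celsius.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forward import (
    ScalingTransform,
    TemperatureCurve,
    evaluate_curves,
    make_time_grid,
    rescale_spectrum,
)

__all__ = [
    "RawMeasurement",
    "PreprocessedCurve",
    "read_measurement",
    "preprocess_measurement",
    "analyze_measurement",
]

_MIN_SAMPLES = 16


@dataclass(frozen=True)
class RawMeasurement:
    """A raw temperature-time recording in physical units."""

    times: np.ndarray  # seconds, strictly increasing
    temps: np.ndarray  # degrees Celsius, absolute readings
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        if times.shape != temps.shape or times.ndim != 1:
            raise ValueError("times and temps must be 1-D of equal length")
        if times.size < _MIN_SAMPLES:
            raise ValueError(f"need at least {_MIN_SAMPLES} samples, got {times.size}")
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            raise ValueError(f"times must be strictly increasing; violation at row {bad[0] + 1}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)


@dataclass(frozen=True)
class PreprocessedCurve:
    """A measurement mapped onto the normalized training representation."""

    curve: TemperatureCurve
    transform: ScalingTransform
    label: str = ""


def read_measurement(path: str | Path, label: str = "") -> RawMeasurement:
    """Parse a two-column text file (time s, temperature degC).

    Comma and whitespace delimiters are auto-detected; a non-numeric first
    line is treated as a header.  Malformed rows raise with the offending
    row number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    times, temps = [], []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s;]+", line)
        if len(parts) < 2:
            raise ValueError(f"{path.name}: row {lineno}: expected two columns, got {line!r}")
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 and not times:  # header line
                continue
            raise ValueError(f"{path.name}: row {lineno}: non-numeric data {line!r}") from None
        times.append(t)
        temps.append(v)
    if len(times) < _MIN_SAMPLES:
        raise ValueError(f"{path.name}: only {len(times)} data rows, need >= {_MIN_SAMPLES}")
    arr_t = np.asarray(times)
    bad = np.nonzero(np.diff(arr_t) <= 0)[0]
    if bad.size:
        # Map back to 1-based file rows, accounting for any header.
        raise ValueError(
            f"{path.name}: time not strictly increasing at data row {bad[0] + 2}"
        )
    return RawMeasurement(times=arr_t, temps=np.asarray(temps), label=label or path.stem)


def preprocess_measurement(
    raw: RawMeasurement, n_samples: int = 1024, density: float = 3.0
) -> PreprocessedCurve:
    """Reduce a raw recording to the normalized 1024-point representation.

    See the module docstring for the four steps.  Raises if the recording
    has zero temperature span (flat signal, nothing to fit).
    """
    onset = int(np.argmin(raw.temps))
    if onset >= raw.times.size - _MIN_SAMPLES // 2:
        raise ValueError("temperature minimum sits at the end of the recording; no rise phase")
    times = raw.times[onset:] - raw.times[onset]
    temps = raw.temps[onset:] - raw.temps[onset]
    span = float(temps.max())
    duration = float(times[-1])
    if span <= 0:
        raise ValueError("zero temperature span: flat signal, nothing to fit")
    t_norm = times / duration
    v_norm = temps / span
    grid = make_time_grid(n_samples, t_end=1.0, density=density)
    values = np.interp(grid.samples, t_norm, v_norm)
    transform = ScalingTransform(t_scale=duration, temp_scale=span)
    return PreprocessedCurve(
        curve=TemperatureCurve(grid=grid, values=values),
        transform=transform,
        label=raw.label,
    )


def analyze_measurement(raw: RawMeasurement, results) -> tuple:
    """Full inversion of a measured recording.

    Preprocess, predict with the trained network, rescale the normalized
    spectrum by the recorded transform, and report the normalized-scale MSE
    between the input curve and the curve regenerated from the prediction.

    Returns
    -------
    (spectrum, reconstruction_mse) : (ExponentialSpectrum, float)
        Spectrum in physical units (seconds, degrees Celsius).
    """
    pre = preprocess_measurement(raw, n_samples=results.config.n_input)
    spectrum_norm = results.predict_spectrum(pre.curve)
    spectrum_phys = rescale_spectrum(spectrum_norm, pre.transform)
    recon = evaluate_curves(spectrum_norm.to_vector()[None, :], pre.curve.grid)[0]
    mse = float(np.mean((recon - pre.curve.values) ** 2))
    return spectrum_phys, mse
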