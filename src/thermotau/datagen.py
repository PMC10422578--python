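"""Synthetic corpus generation and the Gaussian-noise protocol.

Training, validation and test curves are drawn from the forward model with
time constants and amplitudes sampled uniformly on the normalized [0, 1]
scale: four tau uniform on [TAU_MIN, 1] (the lower cut excludes components
whose transient dies between the first grid samples) and four amplitudes
uniform on [0, 1].  Targets are stored tau-sorted, so the regression problem
is well defined despite the permutation symmetry of the model.

Noise robustness is probed by adding zero-mean i.i.d. Gaussian noise (on the
normalized temperature scale) to the *inputs* of an already generated clean
dataset; targets are never touched and the training corpus stays clean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .forward import (
    N_COMPONENTS,
    ExponentialSpectrum,
    TimeGrid,
    evaluate_curves,
    make_time_grid,
)

__all__ = ["TAU_MIN", "NoiseSpec", "CurveDataset", "sample_spectrum", "build_dataset", "add_noise"]

#: Lower bound for sampled time constants on the normalized scale.
TAU_MIN = 1e-3


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian corruption: N(0, variance) per curve sample."""

    variance: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"noise variance must be non-negative, got {self.variance}")


@dataclass(frozen=True)
class CurveDataset:
    """Matched curves (N x 1024) and regression targets (N x 8).

    Target rows are [tau_1..tau_4 ascending, T_1..T_4 co-sorted], all on the
    normalized [0, 1] scale.  ``meta`` records the generation seed, the
    injected noise variance (0 for clean data) and N.
    """

    curves: np.ndarray
    targets: np.ndarray
    grid: TimeGrid
    meta: dict

    def __post_init__(self) -> None:
        if self.curves.shape[0] != self.targets.shape[0]:
            raise ValueError("curves and targets must have equal row counts")
        if self.curves.shape[1] != self.grid.n:
            raise ValueError("curve width must match the grid length")

    @property
    def n(self) -> int:
        return self.curves.shape[0]

    def spectrum(self, i: int) -> ExponentialSpectrum:
        """The generating spectrum of row ``i``."""
        return ExponentialSpectrum.from_vector(self.targets[i], normalized=True)

    def save(self, path: str | Path) -> None:
        """Write the dataset container (.npz) plus a JSON meta sidecar."""
        path = Path(path)
        np.savez_compressed(
            path, curves=self.curves, targets=self.targets, grid=self.grid.samples
        )
        sidecar = path.with_suffix(path.suffix + ".json" if path.suffix != ".npz" else ".json")
        sidecar.write_text(json.dumps(self.meta, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CurveDataset":
        path = Path(path)
        with np.load(path) as z:
            curves, targets, grid = z["curves"], z["targets"], z["grid"]
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(curves=curves, targets=targets, grid=TimeGrid(grid), meta=meta)


def sample_spectrum(rng: np.random.Generator, tau_min: float = TAU_MIN) -> ExponentialSpectrum:
    """Draw one normalized spectrum: tau ~ U[tau_min, 1], amp ~ U[0, 1]."""
    tau = rng.uniform(tau_min, 1.0, size=N_COMPONENTS)
    amp = rng.uniform(0.0, 1.0, size=N_COMPONENTS)
    return ExponentialSpectrum(tau=tau, amp=amp, normalized=True)


def build_dataset(
    n: int,
    grid: TimeGrid | None = None,
    seed: int = 0,
    tau_min: float = TAU_MIN,
) -> CurveDataset:
    """Generate ``n`` clean (curve, target) pairs, deterministically in
    (n, grid, seed).

    The per-draw random stream matches :func:`sample_spectrum`: row i of the
    targets equals the i-th spectrum drawn from ``default_rng(seed)``.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if grid is None:
        grid = make_time_grid()
    rng = np.random.default_rng(seed)
    # Interleaved (tau, amp) draws per row, identical to repeated sample_spectrum calls.
    targets = np.empty((n, 2 * N_COMPONENTS))
    for i in range(n):
        tau = rng.uniform(tau_min, 1.0, size=N_COMPONENTS)
        amp = rng.uniform(0.0, 1.0, size=N_COMPONENTS)
        order = np.argsort(tau, kind="stable")
        targets[i, :N_COMPONENTS] = tau[order]
        targets[i, N_COMPONENTS:] = amp[order]
    curves = evaluate_curves(targets, grid)
    meta = {"seed": int(seed), "variance": 0.0, "n": int(n), "tau_min": float(tau_min)}
    return CurveDataset(curves=curves, targets=targets, grid=grid, meta=meta)


def add_noise(dataset: CurveDataset, noise: NoiseSpec) -> CurveDataset:
    """Corrupt every curve sample with an independent N(0, variance) draw.

    Targets are untouched; ``meta['variance']`` records the injected level.
    Deterministic in ``noise.seed``; variance 0 returns the data unchanged.
    """
    if noise.variance == 0.0:
        return replace(dataset, meta={**dataset.meta, "variance": 0.0})
    rng = np.random.default_rng(noise.seed)
    noisy = dataset.curves + rng.normal(0.0, np.sqrt(noise.variance), size=dataset.curves.shape)
    meta = {**dataset.meta, "variance": float(noise.variance), "noise_seed": int(noise.seed)}
    return CurveDataset(curves=noisy, targets=dataset.targets, grid=dataset.grid, meta=meta)
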