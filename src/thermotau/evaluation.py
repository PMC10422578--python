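"""Error metrics and noise-robustness reports for the inversion pipeline.

Recovery quality is quantified by per-component mean squared errors of the
time constants and amplitudes (components paired by their canonical
tau-ascending index on both sides) and by the MSE between the input curve
and the curve regenerated from the predicted spectrum, all on the
normalized [0, 1] scale and on the network's non-uniform 1024-point grid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import CurveDataset, NoiseSpec, add_noise
from .forward import TimeGrid, evaluate_curves

__all__ = [
    "DEFAULT_VARIANCES",
    "EvaluationReport",
    "component_mse",
    "curve_mse",
    "evaluate_model",
    "noise_sweep",
    "render_report",
]

#: Noise-sweep protocol: variances of the added zero-mean Gaussian noise.
DEFAULT_VARIANCES = (0.0001, 0.0005, 0.001, 0.0015, 0.0025, 0.005)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-component and mean MSEs for one evaluated condition."""

    tau_mse: np.ndarray  # (4,) per-component time-constant MSE
    amp_mse: np.ndarray  # (4,) per-component amplitude MSE
    curve_mse: float  # reconstructed-vs-input temperature MSE
    variance: float  # injected noise variance (0 for clean data)
    n_test: int

    @property
    def mean_tau_mse(self) -> float:
        return float(self.tau_mse.mean())

    @property
    def mean_amp_mse(self) -> float:
        return float(self.amp_mse.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variance": self.variance,
                "component": i + 1,
                "tau_mse": float(self.tau_mse[i]),
                "amp_mse": float(self.amp_mse[i]),
                "curve_mse": self.curve_mse if i == 0 else np.nan,
            }
            for i in range(self.tau_mse.size)
        ]
        rows.append(
            {
                "variance": self.variance,
                "component": "mean",
                "tau_mse": self.mean_tau_mse,
                "amp_mse": self.mean_amp_mse,
                "curve_mse": np.nan,
            }
        )
        return pd.DataFrame(rows)


def component_mse(
    predicted: np.ndarray, true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component MSEs of a batch of (tau, amplitude) target vectors.

    Both batches are (N, 2m) with canonically tau-sorted rows; returns
    (tau MSE per component, amplitude MSE per component), each length m.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    true = np.atleast_2d(np.asarray(true, dtype=float))
    if predicted.shape != true.shape or predicted.shape[1] % 2:
        raise ValueError(f"need matching (N, 2m) batches, got {predicted.shape} vs {true.shape}")
    m = predicted.shape[1] // 2
    sq = (predicted - true) ** 2
    return sq[:, :m].mean(axis=0), sq[:, m:].mean(axis=0)


def curve_mse(
    predicted_targets: np.ndarray, input_curves: np.ndarray, grid: TimeGrid
) -> float:
    """MSE between input curves and curves regenerated from predictions.

    Each predicted target vector is pushed through the forward model on
    ``grid``; the squared error is averaged over all samples and the batch.
    """
    predicted_targets = np.atleast_2d(np.asarray(predicted_targets, dtype=float))
    input_curves = np.atleast_2d(np.asarray(input_curves, dtype=float))
    if predicted_targets.shape[0] != input_curves.shape[0]:
        raise ValueError("batch lengths differ")
    if input_curves.shape[1] != grid.n:
        raise ValueError(f"curve width {input_curves.shape[1]} != grid length {grid.n}")
    recon = evaluate_curves(predicted_targets, grid)
    return float(np.mean((recon - input_curves) ** 2))


def evaluate_model(results, dataset: CurveDataset) -> EvaluationReport:
    """Evaluate trained-model predictions against a dataset's ground truth."""
    pred = results.predict(dataset.curves)
    tau_mse, amp_mse = component_mse(pred, dataset.targets)
    c_mse = curve_mse(pred, dataset.curves, dataset.grid)
    return EvaluationReport(
        tau_mse=tau_mse,
        amp_mse=amp_mse,
        curve_mse=c_mse,
        variance=float(dataset.meta.get("variance", 0.0)),
        n_test=dataset.n,
    )


def noise_sweep(
    results,
    clean_test: CurveDataset,
    variances=DEFAULT_VARIANCES,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Evaluate one trained model across noise levels.

    Each variance gets an independently seeded injection on the *same* clean
    curves; the seed for level i derives deterministically from
    ``(seed, i)``.  Variance 0 reproduces the clean-data protocol exactly.
    """
    if float(clean_test.meta.get("variance", 0.0)) != 0.0:
        raise ValueError("noise_sweep requires a clean test set")
    reports = []
    for i, var in enumerate(variances):
        level_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        noisy = add_noise(clean_test, NoiseSpec(variance=float(var), seed=level_seed))
        reports.append(evaluate_model(results, noisy))
    return reports


def render_report(reports: list[EvaluationReport] | EvaluationReport) -> str:
    """Human-readable table: component rows 1-4 plus a mean row per variance."""
    if isinstance(reports, EvaluationReport):
        reports = [reports]
    if not reports:
        raise ValueError("need at least one report")
    frame = reports_to_frame(reports)
    out = io.StringIO()
    out.write(f"{'variance':>10} {'component':>10} {'tau':>10} {'T':>10} {'T(t)':>10}\n")
    for _, row in frame.iterrows():
        tt = "" if pd.isna(row["curve_mse"]) else f"{row['curve_mse']:.5f}"
        out.write(
            f"{row['variance']:>10g} {str(row['component']):>10} "
            f"{row['tau_mse']:>10.5f} {row['amp_mse']:>10.5f} {tt:>10}\n"
        )
    return out.getvalue()


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Concatenate reports into one tidy DataFrame (CSV-serializable)."""
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)
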