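# thermotau

Thermal time-constant spectrometry of temperature-rise curves with a
regression CNN trained on synthetic data, plus a constrained nonlinear
least-squares baseline.

## The problem

In active (dynamic) infrared thermography, skin is briefly cooled by
contact and the surface temperature is recorded while the tissue re-warms
(ROI-averaged camera signal, typically 50 Hz for ~6 minutes). Modelling the
tissue as a Foster ladder of thermal R-C cells, the recovery curve is a sum
of rising exponentials

    T(t) = Σ_{i=1..4} T_i · (1 − e^(−t/τ_i))

and the discrete spectrum {(τ_i, T_i)} characterizes the tissue's thermal
dynamics: inflamed (e.g., psoriatic) skin responds with slower time
constants than healthy skin, so the spectrum is a diagnostic feature.
Recovering the spectrum from a noisy sampled curve is an ill-conditioned
inverse problem (non-orthogonal exponential basis).

`thermotau` solves the inversion with a 9-layer regression CNN — dense(1024)
→ six conv(32, 3×3, sigmoid) → conv(1, 3×3) → dense(8, sigmoid) — trained
purely on synthetically generated curves with the weighted loss
`0.2·mse(τ) + 0.8·mse(T)` and stochastic gradient descent. The sigmoid
output makes negative time constants impossible by construction. A
box-constrained trust-region least-squares fitter provides the classical
baseline and the ground-truth oracle in the well-separated regime.
The neural network is implemented in a self-contained NumPy engine
(exact reverse-mode gradients, finite-difference-validated); no deep
learning framework is required.

Intended users: researchers in biomedical thermography and, more broadly,
anyone inverting multi-exponential step responses (thermal impedance
spectrometry, R-C network identification).

## Worked example

```python
import numpy as np
from thermotau import (build_dataset, NetworkConfig, ThermalCNN,
                       fit_least_squares, evaluate_curve,
                       ExponentialSpectrum, make_time_grid)
from thermotau.evaluation import evaluate_model

# 1. synthetic corpora on the 1024-point log-dense grid
train = build_dataset(1500, seed=11)
val   = build_dataset(200,  seed=12)
test  = build_dataset(1000, seed=13)

# 2. train the CNN (desk-scale run, ~15 min on one CPU; the reference
#    protocol is 10,000 curves x 5,000 epochs)
model  = ThermalCNN(train, val, NetworkConfig(seed=11, epochs=34))
fitted = model.fit(verbose=False)

# 3. clean-data recovery on 1,000 held-out curves
report = evaluate_model(fitted, test)
print(f"mean tau MSE {report.mean_tau_mse:.4f}  "
      f"mean T MSE {report.mean_amp_mse:.4f}  "
      f"curve MSE {report.curve_mse:.4f}")
# -> mean tau MSE 0.0190  mean T MSE 0.0595  curve MSE 0.0041

# 4. classical oracle on one well-separated spectrum
s = ExponentialSpectrum(tau=[0.01, 0.05, 0.2, 0.8],
                        amp=[0.3, 0.5, 0.7, 0.4], normalized=True)
fit = fit_least_squares(evaluate_curve(s, make_time_grid()))
print(np.round(fit.spectrum.tau, 6))   # -> [0.01 0.05 0.2  0.8 ]
```

The evaluation numbers are mean squared errors on the normalized [0, 1]
scale: `mean tau MSE` is the average squared error of the four sorted time
constants (values near 0.01 mean ~1% squared-error recovery), `mean T MSE`
the same for amplitudes (always worse than tau — amplitudes of slow
components are weakly constrained by a finite window), and `curve MSE`
measures how closely the curve regenerated from the predicted spectrum
reproduces the input. The least-squares fit recovers a noiseless
well-separated spectrum to ~1e-6.

A measured recording (two-column text: time s, temperature °C) goes through
the same machinery end-to-end:

    thermotau analyze --model MODEL_DIR --input recording.csv

which re-zeroes time at the post-cooling trough, normalizes to the unit
box, predicts the normalized spectrum, and rescales to seconds/°C with the
recorded duration and temperature span. CLI verbs: `generate`, `train`,
`evaluate`, `predict`, `fit`, `analyze` (all take `--seed`).

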