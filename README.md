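# dcepk

Pharmacokinetic (PK) parameter estimation from dynamic contrast-enhanced
MRI (DCE-MRI) concentration curves with stacked LSTM/GRU regressors and
Monte Carlo dropout (MCD) uncertainty, alongside a constrained nonlinear
least-squares (NLSQ) baseline.

## Who this is for

Quantitative-imaging researchers who want voxel-wise maps of the extended
Tofts parameters — and a per-voxel measure of how much to trust them —
from brain-tumor DCE-MRI, plus the simulation machinery to train and
stress-test such estimators under controlled conditions (noise level,
bolus-arrival delay, arterial-input dispersion, injection-dose variation).

## The model

Tissue concentration follows the extended Tofts model

C_t(t) = k_ep · v_e · ∫₀ᵗ C_p(τ − τ_BAT) e^(−k_ep (t−τ)) dτ + v_p · C_p(t − τ_BAT)

with k_ep the efflux rate constant from the extravascular extracellular
space (EES) to plasma (1/min), v_e the EES volume fraction, v_p the plasma
volume fraction, τ_BAT the bolus arrival time (s), and the volume transfer
constant derived as Kᵗʳᵃⁿˢ = k_ep · v_e.  The plasma input C_p(t) is a
population-averaged arterial input function (bi-Gaussian plus
sigmoid-modulated exponential) converted to plasma concentration by
1/(1 − Hct), scaled by an injection factor SF and optionally dispersed by
an exponential kernel with time constant τ_d.

A stack of four recurrent layers (LSTM or GRU) reads the two-channel
sequence (reference C_p, measured C_t; 65 frames at 4.8 s) and regresses
(k_ep, v_e, v_p, τ_BAT).  Keeping dropout active at inference and
repeating the forward pass n times yields a predictive distribution: its
mean is the estimate and its standard deviation the uncertainty.
Accuracy is quantified by Lin's concordance correlation coefficient (CCC)
and range-normalized RMSE (NRMSE, %); uncertainty by the predictive SD
normalized by the ground-truth range (σ_uc, %).

The recurrent networks, batch normalization, dropout, Adam optimizer and
backpropagation through time are implemented directly in NumPy, so the
package has no deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from dcepk import (SimConfig, generate_dataset, ModelConfig, TrainConfig,
                   build_model, train_model, mcd_predict, evaluate_run)

train = generate_dataset(SimConfig(n_samples=10_000, seed=11))
model = build_model(ModelConfig(cell_type="gru", n_layers=4,
                                hidden_units=64, dropout_rate=0.25), seed=0)
train_model(model, train, TrainConfig(epochs=10, seed=0))

test = generate_dataset(SimConfig(n_samples=1000, seed=999))
pred = mcd_predict(model, test.inputs, n_mc=100, seed=5)
res = evaluate_run(pred, test.targets)
print(f"CCC(Ktrans)   = {res.ccc['ktrans']:.3f}")
print(f"NRMSE(Ktrans) = {res.nrmse['ktrans']:.1f} %")
print(f"sigma_uc(Ktrans) = {res.sigma_uc['ktrans']:.1f} %")
```

Output from the run above:

```
CCC(Ktrans)   = 0.869
NRMSE(Ktrans) = 10.1 %
sigma_uc(Ktrans) = 11.6 %
```

CCC close to 1 means the predicted Kᵗʳᵃⁿˢ values sit on the identity line
against the ground truth; NRMSE is the residual scatter as a share of the
simulated Kᵗʳᵃⁿˢ range; σ_uc is the average MC-dropout spread on the same
scale.  (This is a deliberately small training run — a few minutes on one
CPU; accuracy rises further with more samples, units and epochs.)

The same estimator runs on clinical images through the signal chain in
`dcepk.clinical` (variable-flip-angle T1 mapping → spoiled-GRE signal
inversion → venous-output-function calibration → pixel-wise maps), exposed
on the command line as `dcepk clinical-map`; `dcepk simulate`, `train`,
`predict`, `fit-nlsq`, `evaluate` and `run-experiment` drive the
simulation studies.

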