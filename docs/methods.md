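# Methods

## Scope and model

The package estimates extended Tofts parameters from DCE-MRI concentration
curves.  Tissue concentration is

C_t(t) = k_ep · v_e · ∫₀ᵗ C_p(τ − τ_BAT) e^(−k_ep (t−τ)) dτ + v_p · C_p(t − τ_BAT),

with the plasma input derived from the arterial blood concentration C_b(t)
by C_p(t) = SF/(1 − Hct) · (C_b ⊛ (1/τ_d) e^(−t/τ_d))(t).  The model assumes
well-mixed compartments, a spatially uniform arterial input known up to the
scale factor SF, an exponential dispersion kernel, and C_p(t) = 0 for
t ≤ τ_BAT, which makes the integral's lower limit immaterial (starting it at
0 or at τ_BAT is equivalent, and that is the behaviour implemented).

The arterial input is the population-averaged form — two Gaussians (first
and second pass) plus a sigmoid-modulated exponential washout — with its
published constants kept in a module-level dictionary so alternates can be
substituted.  The closed form carries a small (~0.08 mM, about 1% of peak)
pre-bolus Gaussian tail at t = 0; the implementation truncates values at
t ≤ 0 to zero so the curve is causal.  Only the t = 0 sample is affected on
the default grid.

## Numerical choices

- **Oversampled convolution.** Dispersion constants (0.1–4 s) sit far below
  the 4.8 s frame spacing, so all convolutions run on an internally refined
  grid (default 0.1 s, `TimeGrid.oversample = 48`) and are then sampled at
  frame times.  The exponential kernels are applied by an exact first-order
  recursion (the input treated as piecewise linear between fine samples),
  which is stable for any rate, including kernels as narrow as the fine
  step and the k_ep → 0 limit, where a series expansion avoids
  cancellation.  Against a 0.01 s brute-force trapezoidal quadrature the
  frame-sampled curves agree to a few parts in 10⁴ (relative to the curve
  peak) across the full parameter ranges.
- **Bolus delay.** τ_BAT is drawn continuously, so the delay is applied by
  linear interpolation on the fine grid, with values forced to zero for
  t ≤ τ_BAT, rather than by frame rounding.
- **Units.** k_ep is carried in 1/min while grids are in seconds; the
  single conversion k_ep/60 happens inside the forward model's exponential
  rate, nowhere else.

## Synthetic data = study conditions

`SimConfig` defaults encode the simulated brain-tumor study: 65 frames at
4.8 s; k_ep ~ U(0.00025, 0.33) 1/min, v_e ~ U(0.04, 0.6),
v_p ~ U(0.005, 0.1), τ_BAT ~ U(40, 50) s, SF ~ U(0.7, 1.3),
τ_d ~ U(0.1, 4) s, Hct = 0.45; frame-wise Gaussian noise with
SD = max(C_t)/PSNR, training PSNR spanning 20–30 as a geometric
progression (test conditions of PSNR 10 or 15 use a degenerate range).
Channel 1 of every sample is the reference plasma curve with no delay, no
dispersion and SF = 1 — what an analyst using a population input would
assume — and channel 2 is the noisy tissue curve, so the network must
absorb the SF/τ_d/τ_BAT mismatch.

Two design points the conditions do not pin down: the geometric PSNR
schedule is randomly permuted across samples (a `shuffle_psnr` flag
restores index order), because tying noise level to sample index would
correlate it with nothing physical; and parameter draws and noise draws
come from two independently spawned streams of the dataset seed, so the
mismatch experiments can vary one factor holding the other fixed.

The generator emulates concentration-space statistics only: it does not
model Rician signal noise, spatial correlation, motion, B1 inhomogeneity
or patient-specific arterial inputs.  Tests passing on synthetic data
therefore demonstrate correctness of the estimator under the stated
generative model, not clinical accuracy.

## Network and training

Stack of `n_layers` (default 4) LSTM or GRU layers; all but the last
return full sequences and are followed by batch normalization; the last
returns its final hidden state; a dense layer maps to the four outputs.
Dropout follows each recurrent block (after its batch norm), with one mask
per sample and feature shared across time steps within a pass — the
simplest placement consistent with standard MC-dropout practice; recurrent-
state dropout variants can be swapped in behind the same configuration.
Targets are affinely scaled to [0, 1] by their sampling ranges before the
MSE loss; otherwise τ_BAT (~45) would dominate v_p (~0.01) by six orders
of magnitude in squared error.  Training uses Adam (initial learning rate
10⁻³) with inverse-time decay lr₀/(1 + 0.1·epoch) — the reading of a
"decay constant" in the legacy optimizer sense — batch size 128, and a
0.9/0.1 train/validation split.  Validation losses are computed with
dropout off and batch norm on running statistics.

Everything (forward, backward-through-time, Adam, batch-norm and dropout
semantics) is implemented in NumPy with per-time-step batched matrix
products; the analytic gradients are checked against central finite
differences in the test suite, and the training loop is deterministic for
fixed seeds in single-threaded BLAS.

At inference, `mcd_predict` keeps dropout active and repeats the forward
pass n_mc times (default 100), with batch norm on stored statistics; the
per-parameter mean is the prediction and the SD the uncertainty, with
Kᵗʳᵃⁿˢ = k_ep·v_e derived within each pass before aggregation.  With
dropout 0 the ensemble collapses and the SD is exactly zero by
construction.

## NLSQ baseline

Trust-region-reflective bounded least squares (finite-difference Jacobian)
over (k_ep, v_e, v_p, τ_BAT), initialised at (0.15 1/min, 0.3, 0.03, 45 s)
with bounds [10⁻⁶, 0.5], [10⁻⁸, 1], [10⁻⁸, 0.1], [10⁻³, 60].  The fit
assumes SF = 1 and no dispersion and uses uniform residual weighting (the
noise is homoscedastic per curve by construction).  The model curve inside
the fit reuses the forward model's oversampled convolution, so simulator
and fitter share one discretization and noiseless recovery is exact to
optimizer tolerance.  Explicit `x_scale` entries match the disparate
parameter magnitudes.

One structural caveat: for k_ep below roughly 0.01 1/min the residue
kernel e^(−k_ep t/60) is flat over the 312 s acquisition, so k_ep and v_e
are only jointly identifiable through Kᵗʳᵃⁿˢ — any (k_ep, v_e) pair with
the right product reproduces the curve to numerical precision.  Recovery
tests therefore assert per-parameter accuracy only above that floor, and
the identifiable combinations (Kᵗʳᵃⁿˢ, v_p, τ_BAT) at the degenerate
corner.

## Evaluation statistics

CCC uses population variances (Lin's original definition).  NRMSE and the
normalized uncertainty σ_uc share one denominator convention: the
ground-truth range over the evaluated collection — for Kᵗʳᵃⁿˢ the range of
the derived per-sample k_ep·v_e values, not the product of the sampling
endpoints.  (A config switch on `normalized_uncertainty` callers could use
sampling-range endpoints instead; the collection range is the
implementation because the error formulas define their denominators from
the observed ground-truth values.)  NLSQ results carry no σ_uc — reported
absent, not zero.  Parameters pinned to a constant by a design (τ_BAT in a
no-delay group) have undefined range-normalized metrics and are reported
as NaN.  Repeat-level aggregation (mean ± SD over independently seeded
repeats) is handled by the experiment drivers; significance testing is
left to standard statistics routines.

## Clinical chain

The VFA fit linearizes S/sin α against S/tan α for initial (K, T10), then
refines with bounded least squares on the spoiled-GRE equation; S0 at the
dynamic settings follows from the same equation.  The signal inversion
uses 1/T1(t) = −(1/TR)·ln[(1−B)/(1−B cos α)] with
B = A(t)(1−E0)/(1−E0 cos α), the algebraic inverse of the SPGR signal
ratio A(t) = S(t)/S0; frames with a non-positive log argument (signal
above the model's ceiling) are flagged and excluded rather than clipped.
Concentration follows from C = (1/r1)(1/T1(t) − 1/T10) and is scaled by
CF = AUC(AIF)/AUC(VOF) (trapezoidal AUC on each curve's native grid) to
correct venous partial-volume underestimation.  Brain masking replaces a
manual binarize-and-correct step with fractional thresholding of S0 plus
largest-connected-component selection, with a user-supplied mask override;
tumor ROIs are always user-supplied.  S0 comes from the VFA fit directly
rather than from averaging pre-contrast baseline frames.  Clinical
uncertainty maps are raw MC SDs in parameter units (not range-normalized,
as no ground-truth range exists).

## Problem sizes in the shipped tests and script

The test suite and the acceptance script run desk-scale versions of the
experiments: the training-sanity check uses a 4-layer GRU with 64 hidden
units, 10⁴ training samples and 10 epochs evaluated on 10³ fresh samples
(CCC(Kᵗʳᵃⁿˢ) ≈ 0.87); the dropout-behaviour and mismatch checks use
2-layer, 48–64-unit models on 1.5–6·10³ samples.  These sizes are the
package's chosen trade-off for a single-CPU NumPy implementation; accuracy
at these scales is far from the ceiling reachable with 10⁵ samples, 256
units and 50 epochs, which the configuration objects support unchanged.
Directional findings (dropout shrinking the early train/validation gap,
higher dropout raising GRU uncertainty, bolus-delay mismatch inflating
NRMSE and delay-aware retraining restoring it) are asserted as directions,
not magnitudes.

## Known limitations

- Patient-individual AIF extraction, alternative kinetic models (2CXM,
  Patlak), Rician noise, DICOM ingestion, motion/B1 correction and tumor
  segmentation are out of scope.
- The dispersion time constant is not an output; strong dispersion
  mismatch is only partially correctable by training (and the experiments
  show it).
- Variable-length sequences are structurally supported (the recurrences
  are length-agnostic) but untested; trained models expect their
  configured frame count.
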