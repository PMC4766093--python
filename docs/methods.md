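# Methods

`littdce` quantifies how strongly a hyperthermic ablation (laser
interstitial thermal therapy, LITT) opens the blood–brain barrier in
the tissue ring around the ablated lesion, and how that opening evolves
over the following ten weeks.  Three measurements are combined per
subject: the DCE-MRI transfer constant K^trans in an enhancing-rim ROI,
serum brain-specific enolase (BSE), and the maximal-slice area of the
FLAIR abnormality.  This note records the models, the numerical
choices, and what the synthetic test bed does and does not establish.

## Tracer-kinetic models

Tissue concentration is modelled as a linear time-invariant response to
the arterial plasma input C_a(t).  Four standard models are
implemented:

* **Standard Tofts** — C_t(t) = K^trans ∫₀ᵗ C_a(τ) e^{−(K^trans/v_e)(t−τ)} dτ,
  parameters K^trans (1/min) and v_e (interstitial volume fraction).
* **Extended Tofts** — adds v_p·C_a(t).
* **Compartment tissue uptake (CTU)** — plasma flow F_p
  (mL/min/mL), irreversible extraction PS (1/min), plasma fraction
  v_p; impulse response F_p[(1−E)e^{−t/T_p} + E] with
  T_p = v_p/(F_p+PS), E = PS/(F_p+PS).
* **Two-compartment exchange (2CXM)** — bidirectional exchange; the
  impulse response is the bi-exponential obtained from the eigen-system
  of the coupled mass balance.  The eigen-rate discriminant
  (a−c)² + 4bc is strictly positive whenever F_p > 0, so the
  decomposition never degenerates; a floor on the rate gap guards
  against floating-point cancellation near-degeneracy.

All four reduce to weighted exponential convolutions with the input.
The convolution kernel is the per-interval closed form that is exact
for a piecewise-linear input, accumulated recursively (carry factor
e^{−rΔt} ≤ 1, so it is unconditionally stable).  Small rΔt uses series
branches of (1−e^{−x})/r to avoid cancellation.  At the 10 s frame
spacing of the acquisition a naive trapezoid convolution is visibly
inaccurate; the exact kernel agrees with a dense ODE integration of
each model to better than 1e−8 relative.

Time is in minutes internally; acquisition timestamps (seconds) are
converted at the signal-model boundary.  Bolus-arrival delay is assumed
to be encoded in the measured input function — no onset parameter is
fitted (limitation).

## Signal model

The dynamic series is a 3D spoiled gradient echo (TR/TE 4.8/2.4 ms, one
volume per 10 s, 36 post-injection volumes, voxel 1.5×1.5×4 mm at
1.5 T).  Signal and concentration are linked by the SPGR steady state
S = M0 sinα (1−E1)/(1−cosα E1), E1 = e^{−TR(1/T10 + r1 C)}.  M0 is
estimated from the mean of the pre-contrast baseline frames (default
3) with the known pre-contrast T10, and the equation is inverted per
frame; frames whose signal is not invertible are clamped to 0 mM by
default (configurable: NaN flag or raise).  T2*-weighting at
TE = 2.4 ms is neglected.

Constants not fixed by the acquisition are configuration, not code:
flip angle 25° (typical for 3D SPGR DCE at 1.5 T), r1 = 6.3
L·mmol⁻¹·s⁻¹ and T10 blood/tissue = 1.4/1.0 s (literature values for
gadobenate at 1.5 T), hematocrit 0.45 (applied to the arterial input
only).  The arterial input is taken from a single voxel centred in the
middle cerebral artery and scaled to plasma concentration by
1/(1−hematocrit).

## Bayesian fitting and model comparison

The noise model is i.i.d. Gaussian on concentrations; σ is a nuisance
parameter under a log-uniform prior on [1e−4, 1] mM.  Kinetic
parameters have uniform priors: K^trans ∈ [0, 6] 1/min and v_e ∈ [0, 1]
(the study's stated physiological ranges), v_p ∈ [0, 1], F_p ∈ (0, 10]
mL/min/mL, PS ∈ [0, 6] 1/min — all configurable.  Sampling uses the
affine-invariant ensemble sampler (emcee) with walkers initialised
from the prior; a short exploration phase is followed by collapsing
the ensemble into a tight ball around the best position found, which
prevents single walkers stalling in diffuse corners of the box.
Convergence requires split-chain R̂ < 1.05 on every parameter; a
failing fit is re-run once with 4× the steps and otherwise returned
flagged, never silently.  The point estimate is the posterior median —
robust to the right-skew of the K^trans posterior.  Defaults: 24
walkers, 900 steps, first third discarded.

Model evidence (marginal likelihood) is computed with σ integrated out
analytically — under the log-uniform prior the σ integral is an
incomplete-gamma expression, evaluated in log space with asymptotic
tails — so every estimator works on the kinetic parameters only.
Three estimators are provided:

* **Thermodynamic integration** (default of `model_evidence`): a
  power-law ladder β = u⁵.  Each rung runs parallel independence-
  Metropolis chains whose proposal is a fixed 50/50 mixture of the
  uniform prior box and a multivariate Student-t matched to the
  β-tempered Laplace approximation (full-covariance finite-difference
  Hessian at the MAP, covariance/β, df 5).  Because the proposal
  tracks the tempered target's width at every temperature the chains
  decorrelate within a step or two; affine-ensemble moves on the same
  rungs carry autocorrelation an order of magnitude higher and were
  the dominant error of earlier estimates.  The integral
  ∫ E_β[log L] dβ is evaluated in the ladder variable u with Simpson's
  rule; in β itself the trapezoid rule carries a systematic positive
  bias at affordable ladder sizes.  At 49 rungs × 1200 steps the
  estimate agrees with grid quadrature to ±0.03 on the two-parameter
  model across seeds; the 33 × 400 default is a few seconds per curve
  at ±0.05.
* **Graded-grid quadrature** (reference for ≤ 2 kinetic parameters):
  the posterior peak occupies a ~1e−4 fraction of the prior box, so a
  uniform grid cannot resolve it; a coarse global mesh is merged with a
  fine mesh spanning ±12 Laplace length scales of the MAP and
  integrated with the nested trapezoid rule on the non-uniform axes.
* **Importance sampling** (default of `compare_models`): a short MCMC
  run supplies moments for a multivariate Student-t proposal (df 7,
  scale inflated 1.2×); the evidence is the importance-weighted mean of
  likelihood/proposal.  It has no ladder-discretisation error and is an
  order of magnitude cheaper per model, which matters when four models
  are compared over many curves; the tempered ladder at comparable cost
  is noticeably biased along the exchange model's high-flow ridge.  It
  assumes a unimodal posterior, which holds for these models on
  enhancing-tissue curves.  A BIC approximation is available as a
  clearly labelled fast fallback.

Model probabilities are normalised evidences under equal model priors.
The pipeline default fits the standard Tofts model everywhere and
exposes the four-model comparison as a per-dataset diagnostic,
mirroring a selection step performed once on the first subjects.

## Per-visit fitting and uncertainty

`fit_visit` composes: ROI-mean signal → concentration → Tofts posterior
→ posterior-median K^trans.  Visits whose peak tissue concentration
does not exceed an absolute floor (0.02 mM) and 5× the baseline noise
are flagged "no measurement" (no visible enhancement) and propagate as
missing values downstream.

The raw posterior interval is conditional on two calibration
quantities the i.i.d. noise model cannot see, and the reported
K^trans interval therefore folds in two delta-method terms:

* **Baseline M0 of the tissue curve.**  M0 from a few baseline frames
  carries a common-mode, approximately multiplicative concentration
  error, amplified by the SPGR inversion.  With a large ROI the i.i.d.
  component averages away while this term does not; ignoring it makes
  nominal 95% intervals cover far below nominal.
* **The arterial input.**  A single arterial voxel carries the full
  per-frame image noise: an i.i.d. term propagated through the
  convolution operator (linearised around the fitted rate), and the
  vessel's own baseline-M0 calibration, which acts as a multiplicative
  error of the whole input and hence (by linearity of the tissue model
  in its input) one-to-one on K^trans.  Per-frame noise scales are
  estimated robustly from median absolute second differences, which
  are insensitive to the smooth washout trend and to the few
  bolus-rise frames.

On the default digital phantom this restores empirical interval
coverage to nominal (16/16 visits in spot checks; ≥ 90% asserted across
the full cohort in the test suite) with interval widths consistent
with, and modestly conservative relative to, the realised errors.  The
propagation is first-order; it does not capture v_e co-adaptation or
input-function dispersion.

## Longitudinal analysis

Per-subject series (K^trans per imaging visit, BSE weekly, FLAIR area
per imaging visit) are interpolated with shape-preserving piecewise
cubic Hermite polynomials (PCHIP) onto a daily grid over the
overlapping span of each pair, then correlated (Pearson).  Missing
visits are dropped before interpolation; extrapolation is refused.
Cohort aggregation is the raw across-subject mean and sample standard
deviation of per-subject r (no Fisher-z transform) and the mean ± SEM
of the interpolated K^trans curves on the common day span.  The daily
grid step and the interpolate-both-series pairing (rather than
subsampling the denser series) are package choices; both series are
smooth on the scale of days, so the pairing choice is second-order.

## Synthetic cohort

The generator emulates the study design: 14 subjects; DCE visits at
days −1, +1, 14, 28, 42, 70; serum sampling at days −1, +1 and weekly
to day 42 plus day 70; 36 dynamic frames at 10 s after 3 pre-contrast
frames.  Per subject:

* K^trans trajectory: baseline 0.22 1/min (the cohort pre-treatment
  mean) plus an excess A·e^{−(d−1)/τ} from the first post-ablation
  visit; defaults A = 0.5 1/min, τ = 10 d put the day-28 value within
  20% of baseline.
* BSE trajectory: baseline 8 ng/mL plus a log-normal-in-time bump
  (amplitude 12 ng/mL, peak day 14, width 0.35), optionally preceded by
  a small immediate dip in half the cohort.  The width is capped per
  subject so the bump at day 42 has decayed below 8% of baseline,
  guaranteeing the return-to-baseline structure for every draw.
* FLAIR area: the same bump form peaking near day 14 (baseline
  500 mm², amplitude 800 mm²).
* Heterogeneity: log-normal multiplicative jitter on amplitudes,
  baselines and timescales, clipped so every truth stays strictly
  inside the fitting priors (peak day within [7.5, 20], τ within
  [6, 11] d, K^trans never above 2.1 1/min).

The digital phantom is a 32×32×16 grid at the study voxel size with an
ablation-cavity ellipsoid, an enhancing-rim shell within 1 cm of the
cavity margin carrying the SPGR signal of the Tofts curve, one
arterial voxel carrying the blood signal of a gamma-variate-plus-
washout population input (plasma peak 6 mM ~0.85 min after start), and
i.i.d. Gaussian noise with sd 2% of the peak rim signal.  Serum and
FLAIR measurements get 5% and 3% multiplicative noise.  Seeding is
hierarchical via `numpy.random.SeedSequence((master, subject, visit))`,
so adding subjects never reshuffles existing ones.

What the phantom does **not** emulate: anatomy, motion, partial-volume
mixing, registration error, input-function dispersion/delay, B1
inhomogeneity, or T2* effects.  Passing tests therefore establish the
correctness and calibration of the computational pipeline under its
own assumptions, not robustness to those physical effects.

## Problem sizes in the test suite

The suite fits the full default cohort (84 visits) once, runs 100
parameter-recovery replicates and 50 model-selection replicates at the
protocol frame count, and validates the evidence estimators on single
curves; these sizes keep the whole suite under a half hour on one core
while leaving the statistical assertions (coverage ≥ 90%, selection
rate ≥ 80%) well away from their thresholds under the default
conditions.
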