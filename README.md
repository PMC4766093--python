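# littdce

Quantitative measurement of blood–brain-barrier (BBB) disruption
induced by hyperthermic ablation (laser interstitial thermal therapy,
LITT), from dynamic contrast-enhanced MRI and serum biomarkers.

After LITT of a brain tumour, the BBB in the peritumoral rim opens
transiently.  This package implements the analysis pipeline that
quantifies that window:

* **Tracer kinetics** — the transfer constant K^trans (1/min) of the
  enhancing rim is estimated by fitting the standard Tofts model

  C_t(t) = K^trans ∫₀ᵗ C_a(τ) e^{−(K^trans/v_e)(t−τ)} dτ

  to the ROI-mean dynamic curve, with the arterial input C_a taken
  from a single voxel of the middle cerebral artery.  The extended
  Tofts, compartment tissue-uptake, and two-compartment exchange
  models are implemented alongside for Bayesian model selection.
* **Bayesian inference** — MCMC with uniform priors (K^trans ∈ [0, 6]
  1/min, v_e ∈ [0, 1]), a jointly sampled Gaussian noise scale, and
  marginal-likelihood model comparison (thermodynamic integration,
  grid quadrature, importance sampling, BIC).
* **Signal conversion** — spoiled-gradient-echo signal ↔ gadolinium
  concentration (TR/TE 4.8/2.4 ms, one volume per 10 s, 36 dynamic
  volumes).
* **Longitudinal analysis** — per-subject time courses of K^trans,
  serum brain-specific enolase (BSE), and FLAIR-abnormality area are
  PCHIP-interpolated to a daily grid and correlated (Pearson), and
  summarised as cohort mean ± SEM curves.
* **Synthetic cohort** — a seeded generator produces a 14-subject
  digital cohort (phantom 4D NIfTI images, serum and FLAIR tables,
  ground-truth tables) with the study's temporal structure: K^trans
  peaks immediately after ablation and decays over ~4 weeks, BSE peaks
  at 1–3 weeks and returns to baseline by week 6, FLAIR area peaks
  near week 2.  Every pipeline stage is testable without patient data.

See `docs/methods.md` for the models, priors, numerical choices and
limitations.

## Worked example

```sh
littdce simulate --seed 0 --out cohort/ --n-subjects 14
littdce fit      --seed 0 --manifest cohort/manifest.csv --out estimates.csv
littdce analyze  --estimates estimates.csv \
                 --longitudinal cohort/longitudinal.csv --out analysis/ --plots
```

or from Python:

```python
import numpy as np
from littdce import (AcquisitionProtocol, ToftsParams, tofts_forward,
                     fit_visit, population_aif)
from littdce.curves import SignalCurve
from littdce.signal_model import spgr_signal

proto = AcquisitionProtocol()                       # study acquisition
aif = population_aif(proto.frame_times() / 60.0)    # plasma input, mM vs min
truth = ToftsParams(ktrans=0.22, ve=0.3)            # pre-treatment mean
tissue = tofts_forward(truth, aif)
signal = SignalCurve(proto.frame_times(),
                     spgr_signal(tissue.values, proto, m0=600.0))
fit = fit_visit(signal, aif, proto, seed=0)
print(f"ktrans = {fit.ktrans:.4f} 1/min, 95% CI "
      f"[{fit.ktrans_ci95[0]:.4f}, {fit.ktrans_ci95[1]:.4f}]")
```

prints

```
ktrans = 0.2200 1/min, 95% CI [0.2197, 0.2203]
```

— the noise-free visit recovers the generating transfer constant; with
noise the interval widens to include the baseline-calibration and
arterial-input uncertainty (see the methods note).

The cohort pipeline writes `analysis/cohort_summary.csv` (day,
cohort-mean K^trans, SEM) and `analysis/subject_correlations.csv`
(per-subject Pearson r between K^trans, BSE, and FLAIR area).  On the
default synthetic cohort the mean K^trans curve peaks at the first
post-ablation visit (day +1) and sheds more than half of its excess
over baseline by day 28, and every subject's serum BSE peaks between
days 7 and 21 — the temporal signature of a transient, roughly
month-long permeability window.

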