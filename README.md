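# corrddm

Evidence accumulation with **correlated observations**: simulation, ideal-observer
analysis, drift-diffusion modeling, and model comparison for perceptual
decisions about pairwise-correlated Gaussian evidence.

## The problem

In sequential-sampling accounts of decision-making, noisy observations are
weighed by their reliability and accumulated to a bound. When observations
arrive in *correlated* pairs, the normative weight of evidence — the
log-likelihood ratio (logLR) — must be rescaled: for a pair `(x1, x2)` drawn
from a bivariate Gaussian with means `±mu_g`, SD `sigma_g`, and correlation
`rho`,

```
logLR(x1, x2) = 2 mu_g / (sigma_g^2 (1 + rho)) * (x1 + x2)
```

so that positive correlations (redundant samples) down-weight the evidence by
`1/(1+rho)` and negative correlations (synergistic samples) up-weight it.
The expected logLR per pair (the *evidence strength*) is
`4 mu_g^2 / (sigma_g^2 (1 + rho))`, which a star-pair psychophysics task
equates across correlation conditions by calibrating the generative mean as
`mu_rho = mu_0 sqrt(1 + rho)`.

`corrddm` packages everything needed to study whether decision makers apply
this correlation-dependent weighing:

- **`corrddm.evidence`** — ideal-observer logLR, evidence-strength equating,
  scale factors, Fisher-z utilities, empirical correlation estimator.
- **`corrddm.task`** — the star-pair task: bivariate stimulus streams
  (clipped at ±0.7 window-height units, new pair every 0.2 s), the
  4 × 192-trial blocked design with 12 crossed conditions, a 3-down-1-up
  staircase targeting 79.4% accuracy, and full synthetic sessions simulated
  from DDM observers with known parameters.
- **`corrddm.ddm`** — six DDM variants whose drift rate
  `k0 mu_0 sqrt(1+rho) / sqrt(1+rho_hat_SD)` and collapsing bound
  `scale(rho_hat) * (B0 - tB t)` implement different hypotheses about how a
  *subjective* correlation estimate `rho_hat` enters encoding and evidence
  weighing; first-passage densities from a Crank-Nicolson Fokker-Planck
  solver with moving absorbing bounds, cross-validated by a Brownian-bridge
  corrected path sampler.
- **`corrddm.fitting`** — scikit-learn style estimators: maximum-likelihood
  fits of full choice/RT distributions by differential evolution
  (`DriftDiffusionEstimator`), lapse-bounded logistic psychometric fits
  (`PsychometricEstimator`), RT exclusions, split-half fits.
- **`corrddm.model_selection`** — AIC and random-effects Bayesian model
  selection with protected exceedance probabilities (PEP).
- **`corrddm.pipeline`** — end-to-end synthetic cohorts (staircase →
  session → fits → BMS → summaries) and the reference analyses: RT
  difference curves under unscaled / naive / true / underestimated evidence
  weighing, and ideal-versus-naive performance projections.

## Worked example

```python
import numpy as np
from corrddm import correlation_scale_factor, calibrated_mean, \
    expected_evidence_strength, GenerativeSpec
from corrddm.ddm import DDMSpec, condition_params, solve_first_passage

for rho in (-0.6, 0.0, 0.6):
    mu = calibrated_mean(0.05, rho)
    E = expected_evidence_strength(GenerativeSpec(mu, 0.1, rho))
    print(f"rho={rho:+.1f}  scale={correlation_scale_factor(rho):.3f}  "
          f"mu_rho={mu:.4f}  E[logLR]={E:.3f}")
```

```
rho=-0.6  scale=2.500  mu_rho=0.0316  E[logLR]=1.000
rho=+0.0  scale=1.000  mu_rho=0.0500  E[logLR]=1.000
rho=+0.6  scale=0.625  mu_rho=0.0632  E[logLR]=1.000
```

The calibration makes the objective evidence strength identical across
correlation conditions — an ideal observer is equally fast and accurate in
all of them. An observer who *underestimates* the correlation
(`rho_hat = ±0.42` when `rho = ±0.6`) is predicted to keep constant accuracy
but show correlation-dependent response times:

```python
spec = DDMSpec(variant="full_rho", k0=8, B0=1.2, tB=0.05, ndt=0.35,
               lapse=0.02, rho_hat_minus=-0.42, rho_hat_plus=0.42,
               mu_0={"low": 0.0548, "high": 0.1371})
for rho in (-0.6, 0.0, 0.6):
    sol = solve_first_passage(condition_params(spec, rho, "high"))
    g = sol.density_correct + sol.density_error
    rt = float((sol.t * g).sum() * sol.dt / (g.sum() * sol.dt)) + spec.ndt
    print(f"rho={rho:+.1f}  P(correct)={sol.p_correct:.3f}  mean RT={rt:.3f} s")
```

```
rho=-0.6  P(correct)=0.924  mean RT=1.628 s
rho=+0.0  P(correct)=0.927  mean RT=1.253 s
rho=+0.6  P(correct)=0.927  mean RT=1.157 s
```

Accuracy is essentially flat (the `rho_hat` terms cancel in the drift × bound
product) while decisions are ~0.5 s slower in the negative- than in the
positive-correlation condition — the behavioral signature of correlation
underestimation that the fitting machinery recovers from simulated cohorts.

## Command line

```
corrddm simulate --config task.yaml --seed 3 --out artifacts/
corrddm fit --data artifacts/cohort.csv --model full_rho --seed 0 --out fits.json
corrddm compare --fits fits_base.json --fits fits_full.json --out bms.json
corrddm report --artifacts artifacts/ --out report/
```

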