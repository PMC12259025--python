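# Methods

This note documents the models, numerical schemes, and design choices behind
`corrddm`, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic-data tests do and do not establish.

## Generative task

Each trial presents a stream of observation pairs `(x1, x2)` drawn i.i.d.
every `0.2 s` from a bivariate Gaussian with equal means `±mu_rho` (sign set
by the generative source, left or right), per-coordinate SD `sigma_g = 0.1`
(window-height units), and pairwise correlation `rho ∈ {-|rho|, 0, +|rho|}`.
Draws are clipped at `±0.7` window-height units, a display constraint
(78.8% of the center-to-edge distance on a 16:9 screen). Clipping is
implemented as value truncation, not resampling; at task-scale means
(`mu < 0.15`, `sigma = 0.1`) the clip probability is ≈ 2e-8 per coordinate,
so the ideal-observer analysis ignores it.

A session is 4 blocks × 192 trials; each block is divided into 16 sets that
present the 12 crossed conditions (2 sources × 2 evidence levels × 3
correlation conditions) once in seeded random order, giving 64 repetitions
per condition. Scoring (+1/−2 points, cumulative total floored at zero) is
attached as annotation only and never feeds back into simulated behavior.

### Staircase calibration

Evidence strengths are calibrated per participant with a 3-down-1-up
staircase run at a fixed 1.4 s viewing duration in the zero-correlation
condition. The rule's drift-balance point is the accuracy `p` solving
`p^3 = 0.5`, i.e. 79.4%. Implementation details (the procedure's free
constants, chosen once):

- initial mean 0.2 window-height units; multiplicative steps of `10^0.05`,
  shrinking to `10^0.02` after 4 reversals;
- an initial 1-down-1-up descent phase until the first error. Without it
  the recorded reversals sample the approach transient from the easy start
  level and the threshold estimate lands near 84% accuracy; with it the
  reversal-mean estimator is unbiased (verified against long-run stationary
  simulations);
- stop after 12 reversals; threshold = mean of reversals 3-12;
- non-convergence is reported when the mean crosses a floor (`1e-5`) or
  ceiling (`0.7`, the clip limit — reached only by observers at or below
  chance) or when `max_trials` elapse.

Measured calibration accuracy with an ideal fixed-duration responder:
79.4% ± ~5.5pp per run (SD across staircases), mean within 2pp of target.

The low/high evidence levels are defined as 0.4× and 2.5× the threshold
*evidence strength* (expected logLR, quadratic in the mean), so the
generative means scale by `sqrt(0.4)` and `sqrt(2.5)`. A config switch
(`multiplier_applies_to="mean"`) exposes the alternative reading in which
the multipliers act on the generative mean directly.

## Ideal observer

For equal-and-opposite sources the logLR of a pair reduces to
`2 mu_g / (sigma_g^2 (1+rho)) (x1 + x2)`: the pair sum is sufficient, and
the correlation enters only through the scale factor `1/(1+rho)`.
Expected evidence strength is `4 mu_g^2 / (sigma_g^2 (1+rho))`; equating it
across correlation conditions requires `mu_rho = mu_0 sqrt(1+rho)`.
Natural logarithms are used throughout. The empirical correlation estimator
is the plain sample Pearson coefficient; on 5-pair streams its signed
expectation is biased toward zero (E[r] ≈ 0.55 at rho = 0.6) although its
magnitude is not (noise folds into |r|). Temporal (across-frame)
correlations are out of scope.

## DDM variants

All variants share five parameters: drift sensitivity `k0`, initial bound
`B0`, linear collapse rate `tB`, non-decision time `ndt`, and lapse rate
`lapse`. The diffusion coefficient is fixed at 1 (the zero-correlation
generative noise is absorbed into `k0` and `B0`). The drift rate is
`k0 mu_0 sqrt(1+rho) / sqrt(1+rho_hat_SD)` — the `sqrt(1+rho)` factor comes
from the task's mean calibration, and `rho_hat_SD` is the correlation
reflected in the observer's internal observation distribution. The
instantaneous bound is `scale × (B0 − tB t)` with variant-specific `scale`
(see `corrddm.ddm.specs` for the table). Subjective correlations are fit
separately for the negative and positive conditions; variants without an
encoding parameter set `rho_hat_SD = rho`.

Two notable consequences, used as test oracles:

- `full_rho` with `rho_hat = rho` cancels exactly: drift and bound are
  identical across correlation conditions.
- With a *fixed* bound, choice probability depends only on the product
  drift × bound, which is `rho`-free in `full_rho` for any `rho_hat`
  (choice invariance under misestimation). With a collapsing bound this
  invariance is only approximate (observed spread ~6e-3 in `p_correct` at
  `tB = 0.05`); the exact statements are tested at `tB = 0`.

The general bound expression `(1+rho_hat_B)/(sqrt(1+rho) sqrt(1+rho_hat_SD))`
is used for the `scaled_rho` variant; the `bound_rho` and `full_rho`
variants use the square-root special-case forms
(`sqrt(1+rho_hat_B)/sqrt(1+rho)` and `sqrt(1+rho_hat)/sqrt(1+rho)`), so
`scaled_rho` does not nest `bound_rho` exactly at `rho_hat_SD = rho`.

## First-passage solver

The Fokker-Planck equation for the survivor density is integrated with
Crank-Nicolson on a fixed spatial grid spanning `[-b(0), +b(0)]`, with the
collapsing bound handled by shrinking the active window (mass of newly
excluded cells is credited to the adjacent bound) and Dirichlet absorption
at the window edges. Probability flux through each edge is recovered from
the exact discrete mass balance of the implicit step, so
`p_correct + p_error + survival = 1` to round-off. A Rannacher start (4
backward-Euler steps) suppresses Crank-Nicolson oscillations from the delta
initial condition. The bound is floored one cell above zero; once the
nominal bound reaches the floor, remaining mass is absorbed by the sign of
the decision variable.

Grid defaults: `dt = 5 ms`, `dx = 5e-3` evidence units, horizon 15 s
(matching the RT exclusion ceiling). Accuracy against constant-bound closed
forms (`p = 1/(1+exp(-2 m B))`, `E[T] = (B/m) tanh(m B)`): choice
probability to ~2e-6, mean decision time to ~0.3% at the default grid and
~0.7% at the coarse fitting grid (`dt = dx = 0.01`). The path sampler is
Euler-Maruyama at 1 ms steps with Brownian-bridge crossing corrections;
sampler and solver agree to KS distance < 0.01 at 1e5 paths.

Predicted RT distributions shift the decision-time density by `ndt` and mix
with a lapse component, uniform on `[0, horizon]` and split evenly between
choices: `density = (1-lapse) g(t-ndt) + lapse/(2 × horizon)`. Lapse RTs do
not receive the `ndt` shift.

## Fitting

`DriftDiffusionEstimator` minimizes the negative log predicted defective
density over trials, with one solver run per (correlation, evidence-level)
condition per objective evaluation. Likelihood evaluation truncates the
solve at the latest observed RT (plus margin); the lapse support stays the
full 15 s horizon. Densities are floored at 1e-10 /s. Optimization is
differential evolution (scipy; latin-hypercube init, `updating="immediate"`,
L-BFGS-B polish), deterministic given the seed. Default box constraints:
`k0, k± ∈ [0.5, 50]`, `B0 ∈ [0.05, 10]`, `tB ∈ [0, 2]`, `ndt ∈ [0, 1] s`,
`lapse ∈ [0, 0.1]`, `rho_hat ∈ (-0.95, 0.95)`.

Budgets are configurable; the package's interactive defaults (popsize
multiplier 8, 40 generations, coarse `dt = dx = 0.01` grid) fit one
7-parameter variant to a 768-trial session in ~20-30 s. At that budget,
recovery of `rho_hat±` from simulated `full_rho` observers (768 trials) has
median absolute error ≈ 0.03 (negative condition) and ≈ 0.11 (positive
condition) — the positive-condition estimate is intrinsically noisier, as
its performance consequences are weaker. RT boundaries at 0.3 and 15 s are
treated as inclusive on retention.

The psychometric model is a lapse-bounded logistic in the signed expected
logLR, `P(R) = lam + (1-2 lam)/(1+exp(-(b0 + be E)))`, fit by L-BFGS-B from
multiple starts with `lam ∈ [0, 0.5)`; the joint mode shares 3 parameters
across correlation conditions, the separate mode fits 9.

## Model selection

Log model evidence is approximated as `-AIC/2`. The random-effects scheme
places a uniform Dirichlet prior on population model frequencies and
iterates mean-field updates for per-participant assignments and the
Dirichlet posterior. Exceedance probabilities are Monte-Carlo estimates
(1e5 Dirichlet draws, seeded); the Bayes omnibus risk compares the
variational free energy against the equal-frequency null, and
`PEP = BOR/M + (1-BOR) EP`. On instances with decisive per-participant
evidence the variational EP matches a brute-force Gibbs sampler to < 0.02;
at soft evidence the mean-field EP is systematically sharper than the exact
posterior — a known property of the approximation, shared by standard
implementations of this scheme, and documented rather than corrected.

## Synthetic cohorts

`run_cohort` draws observer parameters from a population
(`ObserverPopulation`): `k0 ~ N(8, 1.5)`, `B0 ~ N(1.2, 0.15)`,
`tB ~ N(0.05, 0.02)`, `ndt ~ N(0.35, 0.05)` (all clipped to plausible
ranges), `lapse ~ U(0, 0.03)`, and subjective correlations attenuated
toward zero, `rho_hat = tanh(atanh(attenuation × rho) + N(0, 0.1))` with
attenuation 0.7 by default — emulating observers who underestimate the
objective correlation. These population settings are the package's own
synthetic choices: they produce staircase-calibrated cohorts with ~70-90%
accuracy and ~1-1.5 s mean RTs, but they are not estimates from any real
dataset. Each participant is staircase-calibrated, simulated for a full
session, RT-excluded, fit with the configured variants, and entered into
the AIC matrix for BMS (overall and per correlation-magnitude group).

Summary analyses mirror the standard descriptive battery: per-group RT
versus correlation; the per-participant RT(rho+) − RT(rho−) difference with
solver reference curves for a fixed bound on unscaled evidence
(bound scale `(1+rho)^{-1/2}`), correlation-blind "naive" logLR
(`(1+rho)^{-1}`), true logLR (flat), and a slight underestimate of the
scale factor (`(1+0.9 rho)/(1+rho)`); Fisher-z regression of fitted
subjective on objective correlations (slope < 1 under attenuation), with
negative-condition deviations sign-flipped before averaging so under- and
overestimates share a sign; and ideal-versus-naive performance projections
holding non-correlation parameters at fitted values. In those projections,
under the model equations a naive observer (`rho_hat_B = 0`) is slower but
*more* accurate than ideal in negative-correlation conditions (its
unadjusted bound is effectively raised) and faster but less accurate in
positive ones; the net cost of ignoring correlations is a speed-accuracy
distortion, not a uniform accuracy deficit.

Default cohort profiles are desk-scale (one group, 8 participants,
192-trial sessions, reduced optimizer budget) so that a full run remains
interactive; study-scale settings (4 groups × 25 participants × 768 trials,
all six variants) are plain configuration values.

## What the synthetic tests do and do not show

The generator produces exactly the stimulus statistics, design balance, and
observer families the models assume: recovery results certify that the
estimation machinery is consistent and identifiable *under the model*, not
that real participants satisfy its assumptions (stationary parameters,
diffusion-limit accumulation of discretely updated stimuli, uniform
lapses). Sequential effects, learning across blocks, non-stationary
criteria, and temporal stimulus correlations are all absent from the
generator and untested. Split-half fitting is provided for stability
analyses but its statistical power at desk-scale budgets is limited.

## Numerical edge cases

- Bound collapsing faster than one grid cell per step raises a resolution
  error; during optimization such corners are excluded with a large
  objective penalty.
- Trials with RTs beyond the solver horizon fall into the survival deficit
  and contribute the density floor (with a warning).
- Degenerate staircase observers (always correct, at/below chance) raise
  explicit non-convergence errors rather than returning thresholds.
- Complete separation in psychometric fits stays bounded through the lapse
  parameter and slope box constraints.
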