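"""AIC-based model comparison and random-effects Bayesian model selection.

The random-effects analysis treats the model identity of each participant
as drawn from an unknown population frequency vector ``r`` with a uniform
Dirichlet prior.  A variational scheme (mean-field over per-participant
model assignments and ``r``) yields a Dirichlet posterior over ``r``; the
exceedance probability (EP) of a model is the posterior probability that
its frequency is the largest, estimated by Monte Carlo over that
Dirichlet.  The protected exceedance probability (PEP) discounts EP by the
Bayes omnibus risk (BOR) — the posterior probability that all models are
equally frequent, from a free-energy comparison of the null and
alternative hypotheses::

    PEP_k = BOR / M + (1 - BOR) * EP_k

Per-participant log model evidence is approximated as ``-AIC / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp


__all__ = ["aic", "BMSResult", "random_effects_bms", "evidence_from_aic"]


def aic(log_likelihood: float, n_params: int) -> float:
    """Akaike information criterion: ``2 k - 2 logL``."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return 2.0 * n_params - 2.0 * log_likelihood


def evidence_from_aic(aics: np.ndarray) -> np.ndarray:
    """Approximate log model evidence from AIC values (``-AIC / 2``)."""
    return -0.5 * np.asarray(aics, dtype=float)


@dataclass
class BMSResult:
    models: list[str]
    expected_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    protected_exceedance_prob: np.ndarray
    bor: float
    alpha: np.ndarray  # Dirichlet posterior counts
    assignment_prob: np.ndarray  # participants x models responsibilities

    def best_model(self) -> str:
        return self.models[int(np.argmax(self.protected_exceedance_prob))]


def _variational_dirichlet(lme: np.ndarray, alpha0: np.ndarray, max_iter=200, tol=1e-8):
    """Mean-field updates for the random-effects model; returns (alpha, z, F)."""
    n, m = lme.shape
    alpha = alpha0.copy()
    z = np.full((n, m), 1.0 / m)
    for _ in range(max_iter):
        logu = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        z_new = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + z_new.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha, z = alpha_new, z_new
            break
        alpha, z = alpha_new, z_new
    # variational free energy (lower bound on log p(y | alternative))
    zs = np.where(z > 0, z, 1.0)
    F = (
        float(np.sum(z * lme))
        - float(np.sum(z * np.log(zs)))
        + gammaln(alpha0.sum())
        - float(np.sum(gammaln(alpha0)))
        - gammaln(alpha.sum())
        + float(np.sum(gammaln(alpha)))
    )
    return alpha, z, F


def random_effects_bms(
    evidence: np.ndarray,
    rng: np.random.Generator | int | None = None,
    models: list[str] | None = None,
    n_draws: int = 100_000,
) -> BMSResult:
    """Random-effects Bayesian model selection over a cohort.

    Parameters
    ----------
    evidence : array, shape (n_participants, n_models)
        Approximate log model evidence per participant and model
        (e.g. ``-AIC / 2``).  Only within-row differences matter.
    rng : Generator or int
        Seeds the Monte-Carlo EP estimate.
    n_draws : int
        Dirichlet draws for the EP estimate.
    """
    lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be 2-D with at least two model columns")
    if lme.shape[0] < 2:
        raise ValueError("random-effects analysis needs at least two participants")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence entries must be finite")
    n, m = lme.shape
    if models is None:
        models = [f"model_{j}" for j in range(m)]
    rng = np.random.default_rng(rng)

    # center rows for numerical stability (invariant to row constants)
    lme = lme - lme.max(axis=1, keepdims=True)

    alpha0 = np.ones(m)
    alpha, z, F1 = _variational_dirichlet(lme, alpha0)

    # null hypothesis: all models equally frequent
    F0 = float(np.sum(logsumexp(lme, axis=1) - np.log(m)))
    bor = float(1.0 / (1.0 + np.exp(F1 - F0)))

    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=m) / n_draws

    pep = bor / m + (1.0 - bor) * ep
    return BMSResult(
        models=list(models),
        expected_frequencies=alpha / alpha.sum(),
        exceedance_prob=ep,
        protected_exceedance_prob=pep,
        bor=bor,
        alpha=alpha,
        assignment_prob=z,
    )
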