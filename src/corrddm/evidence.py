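"""Ideal-observer mathematics for pairwise-correlated Gaussian evidence.

On each stimulus frame the observer sees a pair of samples ``(x1, x2)``
drawn from a bivariate Gaussian with equal means ``±mu_g`` (sign set by the
generative source), common standard deviation ``sigma_g`` and pairwise
correlation ``rho``.  The normative weight of evidence for the right vs.
left source is the log-likelihood ratio, which for this symmetric problem
collapses onto the sum statistic::

    logLR(x1, x2) = 2 mu_g / (sigma_g**2 (1 + rho)) * (x1 + x2)

so that the correlation enters only through the scale factor
``1 / (1 + rho)``: positive correlations make the two samples redundant
(down-weight), negative correlations make them synergistic (up-weight).

The expected logLR of a single pair — the *evidence strength* — is
``4 mu_g**2 / (sigma_g**2 (1 + rho))``, which is held constant across
correlation conditions by calibrating the generative mean as
``mu_rho = mu_0 sqrt(1 + rho)``.

All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "GenerativeSpec",
    "loglr_pair",
    "expected_evidence_strength",
    "calibrated_mean",
    "correlation_scale_factor",
    "empirical_correlation",
    "fisher_z",
    "fisher_z_inverse",
]


class InvalidCorrelationError(ValueError):
    """Correlation outside the open interval (-1, 1)."""


def _check_rho(rho: float) -> None:
    if not -1.0 < rho < 1.0:
        raise InvalidCorrelationError(f"correlation must lie in (-1, 1); got {rho}")


@dataclass(frozen=True)
class GenerativeSpec:
    """Generative distribution of a single stimulus pair.

    Parameters
    ----------
    mu_g : float
        Per-coordinate mean magnitude, in window-height units.
    sigma_g : float
        Per-coordinate standard deviation, window-height units.
    rho : float
        Pairwise correlation, in (-1, 1).
    mu_0 : float, optional
        Zero-correlation reference mean; when the task is calibrated,
        ``mu_g == mu_0 * sqrt(1 + rho)``.
    """

    mu_g: float
    sigma_g: float = 0.1
    rho: float = 0.0
    mu_0: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_g <= 0:
            raise ValueError(f"sigma_g must be positive; got {self.sigma_g}")
        _check_rho(self.rho)


def loglr_pair(x1, x2, spec: GenerativeSpec):
    """Log-likelihood ratio (right vs. left source) of one observation pair.

    Equals ``2 mu_g / (sigma_g**2 (1 + rho)) * (x1 + x2)``; additive over
    independent pairs and a function of the pair only through ``x1 + x2``.
    """
    _check_rho(spec.rho)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    scale = 2.0 * spec.mu_g / (spec.sigma_g**2 * (1.0 + spec.rho))
    out = scale * (x1 + x2)
    return out if out.ndim else float(out)


def expected_evidence_strength(spec: GenerativeSpec) -> float:
    """Expected logLR of a single pair drawn from the positive source.

    ``4 mu_g**2 / (sigma_g**2 (1 + rho))`` — the task's objective evidence
    strength for one condition.
    """
    _check_rho(spec.rho)
    return 4.0 * spec.mu_g**2 / (spec.sigma_g**2 * (1.0 + spec.rho))


def calibrated_mean(mu_0: float, rho: float) -> float:
    """Generative mean that equates evidence strength with the rho=0 condition.

    Solves E[logLR_rho] = E[logLR_0] for the condition mean, giving
    ``mu_rho = mu_0 * sqrt(1 + rho)``.
    """
    if rho <= -1.0:
        raise InvalidCorrelationError(f"correlation must exceed -1; got {rho}")
    if mu_0 <= 0:
        raise ValueError(f"mu_0 must be positive; got {mu_0}")
    return mu_0 * np.sqrt(1.0 + rho)


def correlation_scale_factor(rho: float) -> float:
    """Normative scale factor ``1 / (1 + rho)`` applied to the evidence sum.

    Equals 1 for independent samples, exceeds 1 for negative correlations
    (synergy) and falls below 1 for positive correlations (redundancy);
    diverges as ``rho -> -1``.
    """
    if rho <= -1.0:
        raise InvalidCorrelationError(f"correlation must exceed -1; got {rho}")
    return 1.0 / (1.0 + rho)


def empirical_correlation(pairs) -> float:
    """Sample Pearson correlation of a within-trial stream of pairs.

    Notes
    -----
    On short streams this estimator's magnitude is biased toward zero,
    which matters when modeling observers who estimate the correlation
    from the few pairs seen within a trial.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        arr = arr.reshape(-1, 2)
    if arr.shape[0] < 2:
        raise ValueError(f"need at least 2 pairs; got {arr.shape[0]}")
    x, y = arr[:, 0], arr[:, 1]
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(rho):
    """Fisher z-transform, ``atanh(rho)``; variance-stabilizing for averaging."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise InvalidCorrelationError("fisher_z requires |rho| < 1")
    out = np.arctanh(rho)
    return out if out.ndim else float(out)


def fisher_z_inverse(z):
    """Inverse Fisher transform, ``tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)
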