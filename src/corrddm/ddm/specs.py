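"""DDM variant specifications and correlation-dependent condition parameters.

Six variants share five basic free parameters — drift sensitivity ``k0``,
initial bound height ``B0``, linear bound collapse rate ``tB``, non-decision
time ``ndt`` and lapse rate ``lapse`` — and differ in whether and how the
pairwise stimulus correlation ``rho`` adjusts the drift rate and bound
height.  With the zero-correlation generative noise absorbed into ``k0``
and ``B0`` (unit diffusion coefficient), the drift rate is

    drift(rho) = k0 * mu_0 * sqrt(1 + rho) / sqrt(1 + rho_hat_SD)

where ``sqrt(1 + rho)`` comes from the task's evidence-strength calibration
of the generative mean and ``rho_hat_SD`` is the correlation reflected in
the observer's internal (encoded) observation distribution.  The
instantaneous bound is ``scale * (B0 - tB * t)`` with a variant-specific
correlation scale:

==================== ====================================== =========================================
variant              drift sensitivity                      bound scale
==================== ====================================== =========================================
base                 k0 (rho_hat_SD = rho)                  1
drift                k-, k0, k+ per condition               1
bound_rho            k0 (rho_hat_SD = rho)                  sqrt(1 + rho_hat_B) / sqrt(1 + rho)
full_rho             k0 / sqrt(1+rho_hat) * sqrt(1+rho)     sqrt(1 + rho_hat) / sqrt(1 + rho)
scaled_rho           k0 / sqrt(1+rho_hat_SD) * sqrt(1+rho)  (1 + rho_hat_B) / (sqrt(1+rho) sqrt(1+rho_hat_SD))
bound_rho_plus_drift k-, k0, k+ per condition               sqrt(1 + rho_hat_B) / sqrt(1 + rho)
==================== ====================================== =========================================

Subjective correlations are fit separately for the negative and positive
correlation conditions (``*_minus``, ``*_plus``); the zero-correlation
condition always uses 0.  In the ``full_rho`` variant the same subjective
correlation enters both drift and bound, so ``rho_hat = rho`` cancels
exactly and all conditions share drift ``k0 * mu_0`` and bound ``B0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np


__all__ = [
    "DDMSpec",
    "ConditionParams",
    "VARIANTS",
    "condition_params",
    "n_free_params",
    "SpecificationError",
]


class SpecificationError(ValueError):
    """Variant/parameter mismatch in a DDMSpec."""


#: extra free parameters each variant adds to (k0, B0, tB, ndt, lapse)
VARIANTS: dict[str, tuple[str, ...]] = {
    "base": (),
    "drift": ("k_minus", "k_plus"),
    "bound_rho": ("rho_hat_minus", "rho_hat_plus"),
    "full_rho": ("rho_hat_minus", "rho_hat_plus"),
    "scaled_rho": (
        "rho_hat_sd_minus",
        "rho_hat_sd_plus",
        "rho_hat_minus",
        "rho_hat_plus",
    ),
    "bound_rho_plus_drift": (
        "k_minus",
        "k_plus",
        "rho_hat_minus",
        "rho_hat_plus",
    ),
}

_N_BASIC = 5


def n_free_params(variant: str) -> int:
    """Number of free parameters of a variant (5 basic + variant extras)."""
    if variant not in VARIANTS:
        raise SpecificationError(f"unknown variant {variant!r}")
    return _N_BASIC + len(VARIANTS[variant])


@dataclass
class DDMSpec:
    """Full parameterization of one DDM variant.

    ``mu_0`` is the task's zero-correlation generative mean, either a single
    value or a mapping from evidence level (``"low"``/``"high"``) to means.
    ``rho_hat_minus``/``rho_hat_plus`` hold the subjective correlation in
    the variant's primary slot (rho_hat for ``full_rho``, rho_hat_B for the
    bound variants); ``scaled_rho`` additionally carries the encoding slot
    ``rho_hat_sd_minus``/``rho_hat_sd_plus``.
    """

    variant: str
    k0: float
    B0: float
    tB: float = 0.0
    ndt: float = 0.0
    lapse: float = 0.0
    rho_hat_minus: float | None = None
    rho_hat_plus: float | None = None
    rho_hat_sd_minus: float | None = None
    rho_hat_sd_plus: float | None = None
    k_minus: float | None = None
    k_plus: float | None = None
    mu_0: float | Mapping[str, float] = field(default=0.03)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise SpecificationError(f"unknown variant {self.variant!r}")
        if self.k0 <= 0 or self.B0 <= 0:
            raise SpecificationError("k0 and B0 must be positive")
        if self.tB < 0 or self.ndt < 0:
            raise SpecificationError("tB and ndt must be non-negative")
        if not 0.0 <= self.lapse <= 1.0:
            raise SpecificationError("lapse must lie in [0, 1]")
        missing = [p for p in VARIANTS[self.variant] if getattr(self, p) is None]
        if missing:
            raise SpecificationError(
                f"variant {self.variant!r} requires parameters {missing}"
            )
        for p in ("rho_hat_minus", "rho_hat_plus", "rho_hat_sd_minus", "rho_hat_sd_plus"):
            v = getattr(self, p)
            if v is not None and not -1.0 < v < 1.0:
                raise SpecificationError(f"{p} must lie in (-1, 1); got {v}")

    # -- helpers -----------------------------------------------------------

    def mu0_for(self, evidence_level: str) -> float:
        if isinstance(self.mu_0, Mapping):
            try:
                return float(self.mu_0[evidence_level])
            except KeyError:
                raise SpecificationError(
                    f"mu_0 mapping has no level {evidence_level!r}"
                ) from None
        return float(self.mu_0)

    @property
    def n_free(self) -> int:
        return n_free_params(self.variant)

    def to_json(self) -> str:
        d = asdict(self)
        if isinstance(self.mu_0, Mapping):
            d["mu_0"] = dict(self.mu_0)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "DDMSpec":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class ConditionParams:
    """Effective drift and bound for one (evidence level, correlation) cell.

    The instantaneous bound is ``b0 - slope * t`` (clamped in the solver);
    diffusion coefficient is 1.
    """

    drift: float
    b0: float
    slope: float

    def bound_at(self, t) -> np.ndarray:
        return np.maximum(self.b0 - self.slope * np.asarray(t, dtype=float), 0.0)


def _select_signed(rho: float, minus: float | None, plus: float | None) -> float:
    """Pick the subjective-correlation slot matching the condition's sign."""
    if rho == 0.0:
        return 0.0
    v = minus if rho < 0 else plus
    assert v is not None  # guaranteed by DDMSpec validation
    return v


def condition_params(spec: DDMSpec, rho: float, evidence_level: str) -> ConditionParams:
    """Resolve a variant's drift rate and bound for one stimulus condition."""
    if not -1.0 < rho < 1.0:
        raise SpecificationError(f"rho must lie in (-1, 1); got {rho}")
    mu0 = spec.mu0_for(evidence_level)
    v = spec.variant

    if v in ("drift", "bound_rho_plus_drift"):
        k = _select_signed(rho, spec.k_minus, spec.k_plus) if rho != 0.0 else spec.k0
    else:
        k = spec.k0

    if v in ("base", "drift"):
        # rho_hat_SD = rho: the sqrt(1+rho) calibration of the mean cancels
        drift = k * mu0
        scale = 1.0
    elif v == "bound_rho":
        rb = _select_signed(rho, spec.rho_hat_minus, spec.rho_hat_plus)
        drift = k * mu0
        scale = np.sqrt((1.0 + rb) / (1.0 + rho))
    elif v == "full_rho":
        rh = _select_signed(rho, spec.rho_hat_minus, spec.rho_hat_plus)
        drift = k * mu0 * np.sqrt((1.0 + rho) / (1.0 + rh))
        scale = np.sqrt((1.0 + rh) / (1.0 + rho))
    elif v == "scaled_rho":
        rsd = _select_signed(rho, spec.rho_hat_sd_minus, spec.rho_hat_sd_plus)
        rb = _select_signed(rho, spec.rho_hat_minus, spec.rho_hat_plus)
        drift = k * mu0 * np.sqrt((1.0 + rho) / (1.0 + rsd))
        scale = (1.0 + rb) / (np.sqrt(1.0 + rho) * np.sqrt(1.0 + rsd))
    elif v == "bound_rho_plus_drift":
        rb = _select_signed(rho, spec.rho_hat_minus, spec.rho_hat_plus)
        drift = k * mu0
        scale = np.sqrt((1.0 + rb) / (1.0 + rho))
    else:  # pragma: no cover
        raise SpecificationError(f"unknown variant {v!r}")

    return ConditionParams(
        drift=float(drift), b0=float(scale * spec.B0), slope=float(scale * spec.tB)
    )
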