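"""Maximum-likelihood fitting of DDM variants and psychometric models.

`DriftDiffusionEstimator` fits one participant's full choice/RT
distribution by global optimization (differential evolution) of the
negative log-likelihood, where the predicted defective RT densities per
condition come from the Fokker-Planck solver.  `PsychometricEstimator`
fits a lapse-bounded logistic choice model, either jointly across
correlation conditions or separately per condition.  Both follow the
scikit-learn estimator protocol (``fit``, ``score``, ``get_params``) and
compose with sklearn model-selection tooling; the module-level functions
(`fit_participant`, `fit_split_half`, `fit_psychometric`) are thin
wrappers returning plain result records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from sklearn.base import BaseEstimator

from .ddm.specs import DDMSpec, VARIANTS, condition_params, n_free_params
from .ddm.fpt import solve_first_passage, trial_log_densities
from .model_selection import aic


__all__ = [
    "FitResult",
    "PsychometricFit",
    "DriftDiffusionEstimator",
    "PsychometricEstimator",
    "apply_rt_exclusions",
    "ddm_negative_log_likelihood",
    "fit_participant",
    "fit_split_half",
    "fit_psychometric",
    "DEFAULT_BOUNDS",
]

RT_MIN = 0.3  # seconds, inclusive
RT_MAX = 15.0  # seconds, inclusive

#: default box constraints per parameter for differential evolution
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k0": (0.5, 50.0),
    "k_minus": (0.5, 50.0),
    "k_plus": (0.5, 50.0),
    "B0": (0.05, 10.0),
    "tB": (0.0, 2.0),
    "ndt": (0.0, 1.0),
    "lapse": (0.0, 0.1),
    "rho_hat_minus": (-0.95, 0.95),
    "rho_hat_plus": (-0.95, 0.95),
    "rho_hat_sd_minus": (-0.95, 0.95),
    "rho_hat_sd_plus": (-0.95, 0.95),
}

_BASIC = ("k0", "B0", "tB", "ndt", "lapse")


def param_names(variant: str) -> tuple[str, ...]:
    """Ordered free-parameter names of a variant's optimization vector."""
    return _BASIC + VARIANTS[variant]


@dataclass
class FitResult:
    participant_id: str
    variant: str
    parameters: dict[str, float]
    log_likelihood: float
    n_trials: int
    aic: float
    optimizer_meta: dict = field(default_factory=dict)

    def to_spec(self, mu_0) -> DDMSpec:
        return DDMSpec(variant=self.variant, mu_0=mu_0, **self.parameters)


@dataclass
class PsychometricFit:
    participant_id: str
    mode: str  # "joint" or "separate"
    parameters: dict  # {"joint": {...}} or {cond: {...}}
    log_likelihood: float
    n_trials: int
    aic: float


def apply_rt_exclusions(
    dataset: pd.DataFrame, rt_min: float = RT_MIN, rt_max: float = RT_MAX
) -> pd.DataFrame:
    """Drop off-task trials (RT < 0.3 s or > 15 s; boundaries retained).

    The excluded fraction is recorded in ``result.attrs["excluded_fraction"]``.
    """
    rt = dataset["rt_seconds"].to_numpy(dtype=float)
    keep = (rt >= rt_min) & (rt <= rt_max)
    out = dataset.loc[keep].copy()
    out.attrs["excluded_fraction"] = float(1.0 - keep.mean()) if len(dataset) else 0.0
    return out


def _infer_mu0(dataset: pd.DataFrame) -> dict[str, float]:
    """Recover the zero-correlation generative mean per evidence level.

    The dataset stores the condition mean ``mu_rho = ±mu_0 sqrt(1+rho)``,
    so ``mu_0 = |mu_rho| / sqrt(1+rho)`` (constant within a level).
    """
    mu0 = {}
    for level, g in dataset.groupby("evidence_level"):
        vals = np.abs(g["mu_rho"].to_numpy()) / np.sqrt(1.0 + g["rho"].to_numpy())
        mu0[str(level)] = float(np.median(vals))
    return mu0


def _dataset_arrays(dataset: pd.DataFrame):
    rho = dataset["rho"].to_numpy(dtype=float)
    level = dataset["evidence_level"].astype(str).to_numpy()
    rt = dataset["rt_seconds"].to_numpy(dtype=float)
    correct = dataset["accuracy"].to_numpy(dtype=float) > 0.5
    return rho, level, rt, correct


class DriftDiffusionEstimator(BaseEstimator):
    """Maximum-likelihood DDM fit to one participant's choice/RT data.

    Parameters
    ----------
    variant : str
        One of ``base``, ``drift``, ``bound_rho``, ``full_rho``,
        ``scaled_rho``, ``bound_rho_plus_drift``.
    mu_0 : float, mapping or None
        Zero-correlation generative mean per evidence level; inferred from
        the dataset's ``mu_rho``/``rho`` columns when ``None``.
    bounds : mapping, optional
        Overrides of the default box constraints, keyed by parameter name.
    popsize, maxiter, tol, polish, init
        Differential-evolution settings (popsize is scipy's per-parameter
        multiplier).
    dt, dx, horizon
        Solver grid; the time horizon also defines the lapse support.
    seed : int
        Seeds the optimizer; fits are deterministic given the seed.

    Attributes
    ----------
    params_ : dict mapping parameter name to fitted value
    log_likelihood_ : float
    aic_ : float
    n_trials_ : int
    optimizer_meta_ : dict with iterations, convergence flag and seed
    """

    def __init__(
        self,
        variant: str = "full_rho",
        mu_0=None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        popsize: int = 8,
        maxiter: int = 40,
        tol: float = 0.01,
        polish: bool = True,
        init: str = "latinhypercube",
        dt: float = 0.01,
        dx: float = 0.01,
        horizon: float = 15.0,
        seed: int = 0,
    ):
        self.variant = variant
        self.mu_0 = mu_0
        self.bounds = bounds
        self.popsize = popsize
        self.maxiter = maxiter
        self.tol = tol
        self.polish = polish
        self.init = init
        self.dt = dt
        self.dx = dx
        self.horizon = horizon
        self.seed = seed

    # -- likelihood --------------------------------------------------------

    def _resolve_mu0(self, dataset: pd.DataFrame):
        if self.mu_0 is not None:
            return self.mu_0
        return _infer_mu0(dataset)

    def _spec_from_vector(self, theta: np.ndarray, mu_0) -> DDMSpec:
        names = param_names(self.variant)
        kw = dict(zip(names, (float(v) for v in theta)))
        return DDMSpec(variant=self.variant, mu_0=mu_0, **kw)

    def _nll_arrays(self, spec: DDMSpec, rho, level, rt, correct) -> float:
        if rt.size == 0:
            return 0.0
        # conditions share a decision-time solution; cache per (rho, level)
        max_rt = float(rt.max())
        horizon_eff = min(self.horizon, max_rt + 2 * self.dt)
        total = 0.0
        for key in {(r, lv) for r, lv in zip(rho, level)}:
            mask = (rho == key[0]) & (level == key[1])
            cp = condition_params(spec, key[0], key[1])
            sol = solve_first_passage(cp, dt=self.dt, dx=self.dx, horizon=horizon_eff)
            logd = trial_log_densities(
                sol, rt[mask], correct[mask], spec.ndt, spec.lapse, self.horizon
            )
            total += float(np.sum(logd))
        return -total

    def negative_log_likelihood(self, dataset: pd.DataFrame, spec: DDMSpec) -> float:
        """-sum of log predicted defective densities at each trial's (choice, RT)."""
        rho, level, rt, correct = _dataset_arrays(dataset)
        n_over = int(np.sum(rt > self.horizon))
        if n_over:
            warnings.warn(
                f"{n_over} trials beyond the {self.horizon} s horizon are "
                "absorbed by the survival deficit (density floor)"
            )
        return self._nll_arrays(spec, rho, level, rt, correct)

    # -- estimator protocol ------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "DriftDiffusionEstimator":
        names = param_names(self.variant)
        bounds_map = dict(DEFAULT_BOUNDS)
        if self.bounds:
            bounds_map.update(self.bounds)
        box = [bounds_map[p] for p in names]
        mu_0 = self._resolve_mu0(X)
        rho, level, rt, correct = _dataset_arrays(X)

        def objective(theta):
            # invalid corners of the box (and bound collapse faster than the
            # grid can track) are excluded with a large penalty
            try:
                spec = self._spec_from_vector(theta, mu_0)
                return self._nll_arrays(spec, rho, level, rt, correct)
            except ValueError:
                return 1e12

        result = differential_evolution(
            objective,
            box,
            seed=self.seed,
            popsize=self.popsize,
            maxiter=self.maxiter,
            tol=self.tol,
            polish=self.polish,
            init=self.init,
            updating="immediate",
        )
        if not result.success:
            warnings.warn(
                f"differential evolution did not converge ({result.message}); "
                "returning best solution found"
            )
        self.params_ = dict(zip(names, (float(v) for v in result.x)))
        self.mu_0_ = mu_0
        self.log_likelihood_ = -float(result.fun)
        self.n_trials_ = int(len(X))
        self.aic_ = aic(self.log_likelihood_, len(names))
        self.optimizer_meta_ = {
            "iterations": int(result.nit),
            "n_evaluations": int(result.nfev),
            "converged": bool(result.success),
            "seed": self.seed,
        }
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per trial under the fitted parameters."""
        spec = self.spec_()
        return -self.negative_log_likelihood(X, spec) / max(len(X), 1)

    def spec_(self) -> DDMSpec:
        return DDMSpec(variant=self.variant, mu_0=self.mu_0_, **self.params_)

    def to_result(self, participant_id: str = "sim") -> FitResult:
        return FitResult(
            participant_id=participant_id,
            variant=self.variant,
            parameters=dict(self.params_),
            log_likelihood=self.log_likelihood_,
            n_trials=self.n_trials_,
            aic=self.aic_,
            optimizer_meta=dict(self.optimizer_meta_),
        )


def ddm_negative_log_likelihood(
    dataset: pd.DataFrame,
    spec: DDMSpec,
    dt: float = 0.01,
    dx: float = 0.01,
    horizon: float = 15.0,
) -> float:
    """Negative log-likelihood of a dataset under a fully specified DDM."""
    est = DriftDiffusionEstimator(variant=spec.variant, dt=dt, dx=dx, horizon=horizon)
    return est.negative_log_likelihood(dataset, spec)


def fit_participant(
    dataset: pd.DataFrame,
    variant: str,
    bounds: Mapping | None = None,
    seed: int = 0,
    participant_id: str | None = None,
    **estimator_kwargs,
) -> FitResult:
    """Fit one DDM variant to one participant's trials; returns a FitResult."""
    est = DriftDiffusionEstimator(
        variant=variant, bounds=bounds, seed=seed, **estimator_kwargs
    )
    est.fit(dataset)
    if participant_id is None:
        participant_id = (
            str(dataset["participant_id"].iloc[0])
            if "participant_id" in dataset and len(dataset)
            else "sim"
        )
    return est.to_result(participant_id)


def fit_split_half(
    dataset: pd.DataFrame,
    variant: str,
    seed: int = 0,
    **estimator_kwargs,
) -> tuple[FitResult, FitResult]:
    """Independent fits on the first and second halves of trials (by order)."""
    order = dataset.sort_values("trial_index") if "trial_index" in dataset else dataset
    n = len(order)
    first, second = order.iloc[: n // 2], order.iloc[n // 2 :]
    for half, name in ((first, "first"), (second, "second")):
        counts = half.groupby(["rho", "evidence_level"]).size()
        if len(half) == 0 or (counts < 2).any():
            raise ValueError(f"{name} half has fewer than 2 trials in some condition")
    r1 = fit_participant(first, variant, seed=seed, **estimator_kwargs)
    r2 = fit_participant(second, variant, seed=seed, **estimator_kwargs)
    return r1, r2


# -- psychometric (logistic) model ----------------------------------------


def _signed_strength(dataset: pd.DataFrame, sigma_g: float) -> np.ndarray:
    """Signed expected logLR per trial (positive toward the right source)."""
    mu = dataset["mu_rho"].to_numpy(dtype=float)
    rho = dataset["rho"].to_numpy(dtype=float)
    return 4.0 * np.sign(mu) * mu**2 / (sigma_g**2 * (1.0 + rho))


def _logistic_nll(theta, E, chose_right):
    b0, be, lam = theta
    p = lam + (1.0 - 2.0 * lam) / (1.0 + np.exp(-(b0 + be * E)))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(
        np.sum(np.where(chose_right, np.log(p), np.log1p(-p)))
    )


def _fit_logistic(E, chose_right) -> tuple[np.ndarray, float]:
    best = None
    for b0, be in ((0.0, 1.0), (0.0, 0.1), (0.0, 5.0)):
        res = minimize(
            _logistic_nll,
            x0=np.array([b0, be, 0.01]),
            args=(E, chose_right),
            method="L-BFGS-B",
            bounds=[(-10.0, 10.0), (-50.0, 50.0), (0.0, 0.499)],
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -float(best.fun)


class PsychometricEstimator(BaseEstimator):
    """Lapse-bounded logistic choice model.

    Fits ``P(right) = lam + (1 - 2 lam) / (1 + exp(-(b0 + be * E)))`` by
    maximum likelihood, with the signed expected logLR ``E`` as regressor.
    In ``joint`` mode the three parameters are shared across correlation
    conditions (3 free parameters); in ``separate`` mode each condition
    gets its own set (9).
    """

    def __init__(self, mode: str = "joint", sigma_g: float = 0.1):
        self.mode = mode
        self.sigma_g = sigma_g

    def fit(self, X: pd.DataFrame, y=None) -> "PsychometricEstimator":
        if self.mode not in ("joint", "separate"):
            raise ValueError(f"mode must be 'joint' or 'separate'; got {self.mode!r}")
        E = _signed_strength(X, self.sigma_g)
        chose_right = X["choice"].astype(str).to_numpy() == "right"
        if self.mode == "joint":
            theta, ll = _fit_logistic(E, chose_right)
            self.params_ = {"joint": dict(zip(("beta_0", "beta_e", "lapse"), theta))}
            self.log_likelihood_ = ll
            k = 3
        else:
            self.params_ = {}
            ll = 0.0
            for cond, idx in X.groupby("correlation_condition").groups.items():
                loc = X.index.get_indexer(idx)
                th, l = _fit_logistic(E[loc], chose_right[loc])
                self.params_[str(cond)] = dict(zip(("beta_0", "beta_e", "lapse"), th))
                ll += l
            self.log_likelihood_ = ll
            k = 9
        self.n_trials_ = int(len(X))
        self.aic_ = aic(self.log_likelihood_, k)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(choose right) per trial under the fitted curve(s)."""
        E = _signed_strength(X, self.sigma_g)
        out = np.empty(len(X))
        if self.mode == "joint":
            p = self.params_["joint"]
            out[:] = p["lapse"] + (1 - 2 * p["lapse"]) / (
                1.0 + np.exp(-(p["beta_0"] + p["beta_e"] * E))
            )
        else:
            cond = X["correlation_condition"].astype(str).to_numpy()
            for c, p in self.params_.items():
                m = cond == c
                out[m] = p["lapse"] + (1 - 2 * p["lapse"]) / (
                    1.0 + np.exp(-(p["beta_0"] + p["beta_e"] * E[m]))
                )
        return out

    def score(self, X: pd.DataFrame, y=None) -> float:
        p = np.clip(self.predict_proba(X), 1e-12, 1 - 1e-12)
        right = X["choice"].astype(str).to_numpy() == "right"
        return float(np.mean(np.where(right, np.log(p), np.log1p(-p))))


def fit_psychometric(
    dataset: pd.DataFrame,
    mode: str = "joint",
    sigma_g: float = 0.1,
    participant_id: str | None = None,
) -> PsychometricFit:
    """Fit the logistic choice model; thin wrapper over PsychometricEstimator."""
    est = PsychometricEstimator(mode=mode, sigma_g=sigma_g).fit(dataset)
    if participant_id is None:
        participant_id = (
            str(dataset["participant_id"].iloc[0])
            if "participant_id" in dataset and len(dataset)
            else "sim"
        )
    return PsychometricFit(
        participant_id=participant_id,
        mode=mode,
        parameters=est.params_,
        log_likelihood=est.log_likelihood_,
        n_trials=est.n_trials_,
        aic=est.aic_,
    )
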