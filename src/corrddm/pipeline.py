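"""End-to-end synthetic cohorts: simulate, fit, compare, summarize.

`run_cohort` reproduces the study workflow on simulated observers with
known parameters: per participant, a staircase calibrates the evidence
levels, a full session of trials is simulated from a DDM observer drawn
from a population distribution, RT exclusions are applied, a set of DDM
variants is fit by maximum likelihood, and the cohort-level AIC matrix
feeds the random-effects model comparison.  Summary analyses mirror the
study's descriptive figures: RT-versus-correlation curves, the
positive-minus-negative RT difference with solver reference curves for
different evidence-weighing regimes, and the subjective-versus-objective
correlation relationship on the Fisher-z scale.

The default profile is desk-scale (one correlation-magnitude group, few
participants, reduced optimizer budget) so a full run stays interactive;
study-scale settings are plain config values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evidence import fisher_z, fisher_z_inverse
from .task import (
    TaskConfig,
    TrialRecord,
    ddm_staircase_observer,
    evidence_levels_from_threshold,
    records_to_dataframe,
    run_staircase,
    simulate_observer_dataset,
)
from .ddm.specs import DDMSpec, condition_params, ConditionParams
from .ddm.fpt import solve_first_passage
from .fitting import FitResult, apply_rt_exclusions, fit_participant, fit_split_half
from .model_selection import evidence_from_aic, random_effects_bms

logger = logging.getLogger("corrddm.pipeline")

__all__ = [
    "CohortConfig",
    "ObserverPopulation",
    "run_cohort",
    "ideal_vs_naive_projection",
    "rt_difference_summary",
    "rt_difference_reference",
    "subjective_correlation_summary",
    "REGIME_BOUND_SCALES",
]


@dataclass
class ObserverPopulation:
    """Population distribution of synthetic observer parameters.

    Defaults are the package's own choices for a plausible cohort: drift
    sensitivities and bounds in the range that yields ~70-90% accuracy and
    ~1-1.5 s mean RTs after staircase calibration, and subjective
    correlations attenuated toward zero (``rho_hat = attenuation * rho``
    plus Fisher-z noise), emulating observers who underestimate the
    objective correlation.
    """

    variant: str = "full_rho"
    k0_mean: float = 8.0
    k0_sd: float = 1.5
    B0_mean: float = 1.2
    B0_sd: float = 0.15
    tB_mean: float = 0.05
    tB_sd: float = 0.02
    ndt_mean: float = 0.35
    ndt_sd: float = 0.05
    lapse_max: float = 0.03
    attenuation: float = 0.7
    rho_hat_noise_z: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in (0, 1]")

    def draw(self, rho_magnitude: float, rng: np.random.Generator) -> dict:
        """Draw one observer's parameters (without mu_0, set by staircase)."""
        z = fisher_z(self.attenuation * rho_magnitude)
        rh_plus = float(
            fisher_z_inverse(z + rng.normal(0.0, self.rho_hat_noise_z))
        )
        rh_minus = float(
            fisher_z_inverse(-z + rng.normal(0.0, self.rho_hat_noise_z))
        )
        params = {
            "variant": self.variant,
            "k0": float(np.clip(rng.normal(self.k0_mean, self.k0_sd), 2.0, 20.0)),
            "B0": float(np.clip(rng.normal(self.B0_mean, self.B0_sd), 0.5, 3.0)),
            "tB": float(np.clip(rng.normal(self.tB_mean, self.tB_sd), 0.0, 0.3)),
            "ndt": float(np.clip(rng.normal(self.ndt_mean, self.ndt_sd), 0.1, 0.8)),
            "lapse": float(rng.uniform(0.0, self.lapse_max)),
        }
        if self.variant in ("bound_rho", "full_rho", "bound_rho_plus_drift"):
            params.update(rho_hat_minus=rh_minus, rho_hat_plus=rh_plus)
        elif self.variant == "scaled_rho":
            params.update(
                rho_hat_minus=rh_minus,
                rho_hat_plus=rh_plus,
                rho_hat_sd_minus=rh_minus,
                rho_hat_sd_plus=rh_plus,
            )
        elif self.variant == "drift":
            params.update(k_minus=params["k0"], k_plus=params["k0"])
        if self.variant == "bound_rho_plus_drift":
            params.update(k_minus=params["k0"], k_plus=params["k0"])
        return params


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort run (desk-scale defaults)."""

    groups: tuple[float, ...] = (0.6,)
    n_participants_per_group: int = 8
    n_blocks: int = 1
    trials_per_block: int = 192
    observer_population: ObserverPopulation = field(default_factory=ObserverPopulation)
    fit_variants: tuple[str, ...] = ("base", "drift", "full_rho")
    master_seed: int = 0
    # reduced optimizer/solver budget for interactive runs
    de_popsize: int = 6
    de_maxiter: int = 25
    solver_dt: float = 0.01
    solver_dx: float = 0.01
    split_half: bool = False

    def __post_init__(self):
        for g in self.groups:
            if not 0.0 < g < 1.0:
                raise ValueError(f"group magnitude must lie in (0, 1); got {g}")


def _simulate_participant(pid, magnitude, config: CohortConfig, seed):
    rng = np.random.default_rng(seed)
    pop = config.observer_population
    params = pop.draw(magnitude, rng)

    task = TaskConfig(
        correlation_magnitude=magnitude,
        n_blocks=config.n_blocks,
        trials_per_block=config.trials_per_block,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    probe = DDMSpec(mu_0=0.05, **params)
    stair = run_staircase(ddm_staircase_observer(probe), config=task, rng=rng)
    mu_0 = evidence_levels_from_threshold(stair.threshold_mean, task)
    spec = DDMSpec(mu_0=mu_0, **params)

    records = simulate_observer_dataset(spec, task, rng)
    df = records_to_dataframe(records, participant_id=pid, config=task)
    return df, spec, stair


def run_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate, fit and compare a full synthetic cohort.

    Returns a dict with the trial-level ``cohort`` frame, per-participant
    ``true_specs`` and ``fits``, the ``bms`` result (overall and per
    group) and the ``summary`` analyses.  Fully reproducible from
    ``master_seed``.  Participants whose fitting stage fails are flagged
    and skipped rather than aborting the run.
    """
    ss = np.random.SeedSequence(config.master_seed)
    frames, true_specs, all_fits, split_fits, failed = [], {}, {}, {}, []

    participant_seeds = ss.spawn(len(config.groups) * config.n_participants_per_group)
    k = 0
    for magnitude in config.groups:
        for i in range(config.n_participants_per_group):
            pid = f"g{magnitude:g}_p{i:02d}"
            seed = participant_seeds[k]
            k += 1
            df, spec, stair = _simulate_participant(pid, magnitude, config, seed)
            df = apply_rt_exclusions(df)
            logger.info(
                "participant %s: threshold fit, %.1f%% excluded",
                pid,
                100 * df.attrs.get("excluded_fraction", 0.0),
            )
            frames.append(df)
            true_specs[pid] = spec
            fit_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
            fits = {}
            try:
                for variant in config.fit_variants:
                    fits[variant] = fit_participant(
                        df,
                        variant,
                        seed=fit_seed,
                        popsize=config.de_popsize,
                        maxiter=config.de_maxiter,
                        dt=config.solver_dt,
                        dx=config.solver_dx,
                    )
                if config.split_half:
                    best = min(fits.values(), key=lambda r: r.aic)
                    split_fits[pid] = fit_split_half(
                        df,
                        best.variant,
                        seed=fit_seed,
                        popsize=config.de_popsize,
                        maxiter=config.de_maxiter,
                        dt=config.solver_dt,
                        dx=config.solver_dx,
                    )
            except Exception:  # noqa: BLE001 — flag and continue
                logger.exception("fitting failed for participant %s", pid)
                failed.append(pid)
                continue
            all_fits[pid] = fits

    cohort = pd.concat(frames, ignore_index=True)

    bms = None
    bms_per_group = {}
    if all_fits and len(config.fit_variants) >= 2 and len(all_fits) >= 2:
        variants = list(config.fit_variants)
        aics = np.array(
            [[all_fits[p][v].aic for v in variants] for p in sorted(all_fits)]
        )
        bms_rng = np.random.default_rng(ss.spawn(1)[0])
        bms = random_effects_bms(evidence_from_aic(aics), rng=bms_rng, models=variants)
        for magnitude in config.groups:
            pids = [p for p in sorted(all_fits) if p.startswith(f"g{magnitude:g}_")]
            if len(pids) >= 2:
                sub = np.array([[all_fits[p][v].aic for v in variants] for p in pids])
                bms_per_group[magnitude] = {
                    "mean_delta_aic": (sub - sub.min(axis=1, keepdims=True))
                    .mean(axis=0)
                    .tolist(),
                    "pep": random_effects_bms(
                        evidence_from_aic(sub), rng=bms_rng, models=variants
                    ).protected_exceedance_prob.tolist(),
                }

    summary = {
        "rt_by_correlation": _rt_by_correlation(cohort),
        "rt_difference": rt_difference_summary(cohort, reference_curves=True),
        "failed_participants": failed,
    }
    rho_bearing = [v for v in config.fit_variants if "rho" in v]
    if rho_bearing and all_fits:
        variant = (
            bms.best_model()
            if bms is not None and "rho" in bms.best_model()
            else rho_bearing[0]
        )
        summary["subjective_correlation"] = subjective_correlation_summary(
            {p: f[variant] for p, f in all_fits.items()},
            {p: true_specs[p] for p in all_fits},
        )

    artifacts = {
        "cohort": cohort,
        "true_specs": true_specs,
        "fits": all_fits,
        "split_half": split_fits,
        "bms": bms,
        "bms_per_group": bms_per_group,
        "summary": summary,
    }
    if out_dir is not None:
        _write_artifacts(artifacts, Path(out_dir))
    return artifacts


def _rt_by_correlation(cohort: pd.DataFrame) -> dict:
    correct = cohort[cohort["accuracy"] == 1]
    tab = (
        correct.groupby(
            ["group_magnitude", "participant_id", "correlation_condition"]
        )["rt_seconds"]
        .mean()
        .groupby(["group_magnitude", "correlation_condition"])
        .mean()
    )
    return {
        f"{g:g}": {c: tab.get((g, c), np.nan) for c in ("negative", "zero", "positive")}
        for g in cohort["group_magnitude"].unique()
    }


#: bound scale factor f(rho) relative to rho = 0 for a fixed bound on
#: evidence weighed under each regime (see rt_difference_reference)
REGIME_BOUND_SCALES = {
    "unscaled": lambda rho: (1.0 + rho) ** -0.5,
    "naive": lambda rho: (1.0 + rho) ** -1.0,
    "true": lambda rho: 1.0,
    "underestimate_0.9": lambda rho: (1.0 + 0.9 * rho) / (1.0 + rho),
}


def rt_difference_reference(
    magnitude: float,
    regime: str,
    drift0: float = 0.75,
    bound0: float = 1.2,
    dt: float = 0.005,
    dx: float = 0.005,
) -> float:
    """Predicted RT(rho+) - RT(rho-) for a fixed bound on weighed evidence.

    Decisions accumulate ``w(rho) * (x1 + x2)`` to a fixed bound.  After
    normalizing to unit diffusion the drift is correlation-independent
    (the task equates the per-sample SNR across conditions) and the bound
    scales as ``f(rho)`` per regime: ``(1+rho)^-1/2`` for unscaled
    observations, ``(1+rho)^-1`` for naive (correlation-blind logLR), 1
    for the true logLR, and ``(1+0.9 rho)/(1+rho)`` for a slight
    underestimate of the scale factor.  Mean correct RTs come from the
    first-passage solver.
    """
    f = REGIME_BOUND_SCALES[regime]
    out = {}
    for rho in (+magnitude, -magnitude):
        sol = solve_first_passage(
            ConditionParams(drift=drift0, b0=bound0 * f(rho), slope=0.0),
            dt=dt,
            dx=dx,
        )
        out[rho] = sol.mean_rt("correct")
    return float(out[+magnitude] - out[-magnitude])


def rt_difference_summary(
    dataset: pd.DataFrame,
    reference_curves: bool = False,
    drift0: float = 0.75,
    bound0: float = 1.2,
) -> dict:
    """Per-participant mean correct-RT difference, positive minus negative.

    Participants missing one of the signed conditions are skipped with a
    warning.  With ``reference_curves`` the solver predictions for the
    four weighing regimes are attached per correlation magnitude.
    """
    correct = dataset[dataset["accuracy"] == 1]
    diffs: dict[str, float] = {}
    groups: dict[str, float] = {}
    for pid, g in correct.groupby("participant_id"):
        means = g.groupby("correlation_condition")["rt_seconds"].mean()
        if "positive" not in means or "negative" not in means:
            logger.warning("participant %s lacks a signed correlation condition", pid)
            continue
        diffs[str(pid)] = float(means["positive"] - means["negative"])
        groups[str(pid)] = float(g["group_magnitude"].iloc[0])
    out: dict = {"per_participant": diffs, "group_magnitude": groups}
    if diffs:
        arr = np.array(list(diffs.values()))
        out["median"] = float(np.median(arr))
        out["mean"] = float(np.mean(arr))
    if reference_curves:
        mags = sorted(set(groups.values()))
        out["reference"] = {
            regime: {
                f"{m:g}": rt_difference_reference(m, regime, drift0, bound0)
                for m in mags
            }
            for regime in REGIME_BOUND_SCALES
        }
    return out


def subjective_correlation_summary(
    fits: dict[str, FitResult], true_specs: dict[str, DDMSpec] | None = None
) -> dict:
    """Fisher-z regression of fitted subjective on objective correlations.

    Pools the positive- and negative-condition estimates across
    participants; the slope below 1 indicates attenuation.  The deviation
    summary sign-flips the negative-condition deviations so under- and
    overestimates share a sign, then averages on the z scale.
    """
    zs_obj, zs_fit, deviations = [], [], []
    for pid, fr in fits.items():
        if "rho_hat_plus" not in fr.parameters:
            continue
        # objective magnitude from the cohort's participant-id convention
        # (g<mag>_pNN); rows without it are skipped
        rho = None
        if pid.startswith("g"):
            try:
                rho = float(pid.split("_")[0][1:])
            except ValueError:
                rho = None
        if rho is None:
            continue
        for sign, key in ((+1, "rho_hat_plus"), (-1, "rho_hat_minus")):
            z_o = fisher_z(sign * rho)
            z_f = fisher_z(fr.parameters[key])
            zs_obj.append(z_o)
            zs_fit.append(z_f)
            deviations.append(sign * (z_f - z_o))
    result: dict = {"n_estimates": len(zs_obj)}
    if len(zs_obj) >= 2:
        slope, intercept = np.polyfit(zs_obj, zs_fit, 1)
        result.update(
            slope_fisher_z=float(slope),
            intercept_fisher_z=float(intercept),
            mean_signed_deviation_z=float(np.mean(deviations)),
            mean_back_transformed={
                "positive": float(
                    fisher_z_inverse(
                        np.mean([z for z, o in zip(zs_fit, zs_obj) if o > 0])
                    )
                )
                if any(o > 0 for o in zs_obj)
                else np.nan,
                "negative": float(
                    fisher_z_inverse(
                        np.mean([z for z, o in zip(zs_fit, zs_obj) if o < 0])
                    )
                )
                if any(o < 0 for o in zs_obj)
                else np.nan,
            },
        )
    return result


def ideal_vs_naive_projection(
    fit: FitResult,
    rho_magnitude: float,
    mu_0,
    dt: float = 0.005,
    dx: float = 0.005,
    horizon: float = 15.0,
) -> dict:
    """Expected accuracy and mean RT for fitted, ideal and naive observers.

    The ideal observer uses the objective correlation in place of the
    fitted subjective one (``rho_hat = rho``); the naive observer keeps
    the fitted subjective correlation in the encoding (noise) term but
    applies no correlation-dependent bound adjustment (``rho_hat_B = 0``).
    All other parameters are held at their fitted values.
    """
    if "rho_hat_plus" not in fit.parameters:
        raise ValueError(
            f"variant {fit.variant!r} carries no subjective correlation; "
            "projection requires a rho_hat-bearing variant"
        )
    p = dict(fit.parameters)
    basic = {k: p[k] for k in ("k0", "B0", "tB", "ndt", "lapse")}
    rh_m, rh_p = p["rho_hat_minus"], p["rho_hat_plus"]

    specs = {
        "fitted": DDMSpec(
            variant=fit.variant, mu_0=mu_0, **{k: v for k, v in p.items()}
        ),
        "ideal": DDMSpec(
            variant="full_rho",
            mu_0=mu_0,
            **basic,
            rho_hat_minus=-rho_magnitude,
            rho_hat_plus=rho_magnitude,
        ),
        "naive": DDMSpec(
            variant="scaled_rho",
            mu_0=mu_0,
            **basic,
            rho_hat_sd_minus=rh_m,
            rho_hat_sd_plus=rh_p,
            rho_hat_minus=0.0,
            rho_hat_plus=0.0,
        ),
    }

    out: dict = {}
    for name, spec in specs.items():
        per = {}
        for level in ("low", "high"):
            accs, rts = [], []
            for rho in (-rho_magnitude, 0.0, rho_magnitude):
                cp = condition_params(spec, rho, level)
                sol = solve_first_passage(cp, dt=dt, dx=dx, horizon=horizon)
                lam = spec.lapse
                acc = (1 - lam) * sol.p_correct + lam / 2
                g = sol.density_correct + sol.density_error
                mass = np.sum(g) * sol.dt
                mean_dt = float(np.sum(sol.t * g) * sol.dt / mass)
                rt = (1 - lam) * (mean_dt + spec.ndt) + lam * horizon / 2
                accs.append(acc)
                rts.append(rt)
            per[level] = {
                "accuracy": dict(zip(("negative", "zero", "positive"), accs)),
                "mean_rt": dict(zip(("negative", "zero", "positive"), rts)),
            }
        out[name] = per
    return out


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_artifacts(artifacts: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts["cohort"].to_csv(out_dir / "cohort.csv", index=False)
    fits = {
        pid: {v: _jsonable(fr) for v, fr in d.items()}
        for pid, d in artifacts["fits"].items()
    }
    (out_dir / "fits.json").write_text(json.dumps(fits, indent=1))
    if artifacts["bms"] is not None:
        payload = _jsonable(artifacts["bms"])
        payload["per_group"] = _jsonable(artifacts["bms_per_group"])
        (out_dir / "bms.json").write_text(json.dumps(payload, indent=1))
    (out_dir / "summary.json").write_text(
        json.dumps(_jsonable(artifacts["summary"]), indent=1)
    )
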