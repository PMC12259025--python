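"""Stimulus, trial-structure and staircase generation for the star-pair task.

Observers view pairs of "stars" whose horizontal positions are drawn every
0.2 s from a bivariate Gaussian with equal means (``±mu_rho``, sign set by
the generative source), SD ``sigma_g = 0.1`` (window-height units) and a
trial-wise pairwise correlation in {-|rho|, 0, +|rho|}; positions are
clipped at ±0.7 so stars stay on screen.  A session is 4 blocks of 192
trials; each block holds 16 sets that each present the 12 crossed
conditions (2 sources x 2 evidence levels x 3 correlations) once in random
order, for 64 repetitions per condition.  Evidence strengths are
participant-calibrated by a 3-down-1-up staircase run at a fixed 1.4 s
viewing duration in the zero-correlation condition, targeting the accuracy
p with p^3 = 0.5 (~79.4%); the main task then uses 0.4x (low) and 2.5x
(high) the threshold evidence strength, with the generative mean of the
correlated conditions scaled by sqrt(1 + rho) to equate expected logLR.

This module also simulates complete behavioral datasets from DDM observers
with known parameters, which stand in for human cohorts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .evidence import calibrated_mean, expected_evidence_strength, GenerativeSpec
from .ddm.specs import DDMSpec
from .ddm.sampling import simulate_trials


__all__ = [
    "TaskConfig",
    "Condition",
    "TrialRecord",
    "StaircaseState",
    "StaircaseResult",
    "ConfigurationError",
    "NonConvergenceError",
    "ALL_SOURCES",
    "ALL_LEVELS",
    "ALL_CORR_CONDITIONS",
    "all_conditions",
    "build_trial_sequence",
    "generate_stimulus_stream",
    "run_staircase",
    "staircase_target_accuracy",
    "ideal_staircase_observer",
    "ddm_staircase_observer",
    "evidence_levels_from_threshold",
    "simulate_observer_dataset",
    "records_to_dataframe",
]

ALL_SOURCES = ("left", "right")
ALL_LEVELS = ("low", "high")
ALL_CORR_CONDITIONS = ("negative", "zero", "positive")

N_CONDITIONS = 12


class ConfigurationError(ValueError):
    pass


class NonConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Condition:
    source: str
    evidence_level: str
    correlation_condition: str

    def __post_init__(self):
        if self.source not in ALL_SOURCES:
            raise ConfigurationError(f"bad source {self.source!r}")
        if self.evidence_level not in ALL_LEVELS:
            raise ConfigurationError(f"bad evidence level {self.evidence_level!r}")
        if self.correlation_condition not in ALL_CORR_CONDITIONS:
            raise ConfigurationError(
                f"bad correlation condition {self.correlation_condition!r}"
            )


def all_conditions() -> list[Condition]:
    """The 12 crossed conditions (2 sources x 2 levels x 3 correlations)."""
    return [
        Condition(s, e, c)
        for s, e, c in itertools.product(ALL_SOURCES, ALL_LEVELS, ALL_CORR_CONDITIONS)
    ]


@dataclass
class TaskConfig:
    """Design constants of the behavioral task (window-height units)."""

    correlation_magnitude: float = 0.6
    sigma_g: float = 0.1
    frame_interval: float = 0.2
    truncation_limit: float = 0.7
    n_blocks: int = 4
    trials_per_block: int = 192
    evidence_multipliers: tuple[float, float] = (0.4, 2.5)  # (low, high)
    rng_seed: int = 0
    #: whether the threshold multipliers apply to the expected logLR
    #: ("strength") or directly to the generative mean ("mean")
    multiplier_applies_to: str = "strength"

    def __post_init__(self):
        if not 0.0 < self.correlation_magnitude < 1.0:
            raise ConfigurationError(
                f"correlation_magnitude must lie in (0, 1); got {self.correlation_magnitude}"
            )
        if self.sigma_g <= 0 or self.truncation_limit <= 0:
            raise ConfigurationError("sigma_g and truncation_limit must be positive")
        total = self.n_blocks * self.trials_per_block
        if self.trials_per_block % N_CONDITIONS != 0:
            raise ConfigurationError(
                f"trials_per_block={self.trials_per_block} is not divisible by "
                f"{N_CONDITIONS} conditions ({self.n_blocks} blocks, {total} trials)"
            )
        if self.multiplier_applies_to not in ("strength", "mean"):
            raise ConfigurationError(
                f"multiplier_applies_to must be 'strength' or 'mean'; "
                f"got {self.multiplier_applies_to!r}"
            )

    def rho_for(self, correlation_condition: str) -> float:
        return {
            "negative": -self.correlation_magnitude,
            "zero": 0.0,
            "positive": self.correlation_magnitude,
        }[correlation_condition]


@dataclass
class TrialRecord:
    """One trial: condition labels, stimulus stream, and the response."""

    condition: Condition
    rho: float
    mu_rho: float  # signed; negative for the left source
    stimulus: np.ndarray | None = None  # (n_frames, 2)
    choice: str | None = None
    rt: float | None = None


@dataclass
class StaircaseState:
    """3-down-1-up staircase configuration and running state.

    Steps are multiplicative in log10 space: ``step_log_units`` initially,
    shrinking to ``fine_step_log_units`` after ``coarse_reversals``
    reversals.  The threshold is the mean of the reversal values after
    discarding the first ``discard_reversals``.
    """

    current_mean: float = 0.2
    step_log_units: float = 0.05
    fine_step_log_units: float = 0.02
    coarse_reversals: int = 4
    n_down: int = 3
    n_up: int = 1
    stop_reversals: int = 12
    discard_reversals: int = 2
    trial_duration: float = 1.4
    max_trials: int = 2000
    mean_floor: float = 1e-5
    # means beyond the clip limit are meaningless; reaching the ceiling
    # signals an observer the staircase cannot calibrate (at/below chance)
    mean_ceiling: float = 0.7
    reversal_values: list[float] = field(default_factory=list)


@dataclass
class StaircaseResult:
    threshold_mean: float
    reversal_values: list[float]
    n_trials: int


def staircase_target_accuracy(n_down: int = 3) -> float:
    """Accuracy targeted by an n-down-1-up rule: the root of p**n = 0.5."""
    return 0.5 ** (1.0 / n_down)


def truncation_percent_of_half_width(
    truncation_limit: float = 0.7, aspect_width: int = 16, aspect_height: int = 9
) -> float:
    """Clip limit as a percentage of the center-to-edge distance.

    Positions are expressed in window-height units, so on a display of the
    given aspect ratio the center-to-edge half-width is
    ``aspect_width / aspect_height / 2`` window heights.  Computed in exact
    rational arithmetic and rounded to one decimal (78.8 for the default
    0.7 limit on a 16:9 display).
    """
    from fractions import Fraction

    half_width = Fraction(aspect_width, aspect_height) / 2
    frac = Fraction(truncation_limit).limit_denominator(10**9) / half_width
    return round(float(100 * frac), 1)


def build_trial_sequence(config: TaskConfig) -> list[Condition]:
    """Blocked, set-balanced pseudo-random condition sequence.

    Each block is divided into sets containing every condition exactly
    once, shuffled independently, so all 12 conditions appear before any
    repeats.
    """
    rng = np.random.default_rng(config.rng_seed)
    conds = all_conditions()
    sets_per_block = config.trials_per_block // N_CONDITIONS
    seq: list[Condition] = []
    for _ in range(config.n_blocks):
        for _ in range(sets_per_block):
            order = rng.permutation(N_CONDITIONS)
            seq.extend(conds[i] for i in order)
    return seq


def generate_stimulus_stream(
    mu_rho: float,
    sigma_g: float,
    rho: float,
    n_frames: int,
    rng: np.random.Generator,
    truncation_limit: float = 0.7,
) -> np.ndarray:
    """Draw an (n_frames, 2) stream of clipped correlated Gaussian pairs."""
    if not -1.0 < rho < 1.0:
        raise ConfigurationError(f"correlation must lie in (-1, 1); got {rho}")
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    cov = sigma_g**2 * np.array([[1.0, rho], [rho, 1.0]])
    x = rng.multivariate_normal([mu_rho, mu_rho], cov, size=n_frames, method="cholesky")
    return np.clip(x, -truncation_limit, truncation_limit)


def ideal_staircase_observer(config: TaskConfig):
    """Ideal responder for fixed-duration zero-correlation staircase trials.

    Decides by the sign of the summed evidence over the
    ``trial_duration / frame_interval`` frames, giving accuracy
    ``Phi(sqrt(2 n) * mean / sigma_g)``.  Truncation is neglected (its
    effect is negligible at staircase-scale means).
    """

    def observer(mean: float, rng: np.random.Generator, duration: float = 1.4) -> bool:
        n = max(1, round(duration / config.frame_interval))
        p = norm.cdf(np.sqrt(2.0 * n) * mean / config.sigma_g)
        return bool(rng.random() < p)

    return observer


def ddm_staircase_observer(spec: DDMSpec):
    """Fixed-duration (interrogation) responder implied by a DDM observer.

    Accuracy at generative mean ``mean`` over duration T is
    ``Phi(k0 * mean * sqrt(T))`` under unit diffusion, with lapses mixed in.
    """

    def observer(mean: float, rng: np.random.Generator, duration: float = 1.4) -> bool:
        if spec.lapse > 0 and rng.random() < spec.lapse:
            return bool(rng.random() < 0.5)
        p = norm.cdf(spec.k0 * mean * np.sqrt(duration))
        return bool(rng.random() < p)

    return observer


def run_staircase(
    observer,
    state: StaircaseState | None = None,
    config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
) -> StaircaseResult:
    """Run a 3-down-1-up staircase on the zero-correlation condition.

    ``observer(mean, rng, duration)`` must return correct/incorrect for a
    fixed-duration trial at the candidate generative mean.  The mean is
    decreased after ``n_down`` consecutive correct responses and increased
    after every error; the threshold estimate is the mean of the reversal
    values after discarding the first two.
    """
    state = state if state is not None else StaircaseState()
    config = config if config is not None else TaskConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)

    mean = state.current_mean
    consecutive = 0
    direction = 0  # -1 going down, +1 going up
    reversals: list[float] = []
    n_trials = 0
    descending = True  # initial 1-down-1-up descent until the first error

    while n_trials < state.max_trials:
        n_trials += 1
        correct = observer(mean, rng, state.trial_duration)
        if descending:
            # quick descent from the easy start level; without this phase
            # the n-down-1-up reversals sample the approach transient and
            # the threshold estimate is biased toward easier levels
            step = -1 if correct else +1
            if not correct:
                descending = False
            direction = step
            mean *= 10.0 ** (step * state.step_log_units)
            if mean < state.mean_floor:
                raise NonConvergenceError(
                    f"staircase hit the mean floor {state.mean_floor} during "
                    f"the descent phase after {n_trials} trials"
                )
            continue
        step = None
        if correct:
            consecutive += 1
            if consecutive >= state.n_down:
                consecutive = 0
                step = -1
        else:
            consecutive = 0
            step = +1
        if step is None:
            continue
        if direction != 0 and step != direction:
            reversals.append(mean)
            if len(reversals) >= state.stop_reversals:
                state.reversal_values = reversals
                usable = reversals[state.discard_reversals :]
                return StaircaseResult(
                    threshold_mean=float(np.mean(usable)),
                    reversal_values=reversals,
                    n_trials=n_trials,
                )
        direction = step
        log_step = (
            state.step_log_units
            if len(reversals) < state.coarse_reversals
            else state.fine_step_log_units
        )
        mean *= 10.0 ** (step * log_step)
        if mean < state.mean_floor:
            raise NonConvergenceError(
                f"staircase hit the mean floor {state.mean_floor} after "
                f"{n_trials} trials ({len(reversals)} reversals)"
            )
        if mean > state.mean_ceiling:
            raise NonConvergenceError(
                f"staircase exceeded the mean ceiling {state.mean_ceiling} "
                f"after {n_trials} trials; observer performs at or below "
                "the target accuracy even at the easiest levels"
            )
    raise NonConvergenceError(
        f"staircase did not reach {state.stop_reversals} reversals in "
        f"{state.max_trials} trials ({len(reversals)} reversals)"
    )


def evidence_levels_from_threshold(
    threshold_mean: float, config: TaskConfig
) -> dict[str, float]:
    """Zero-correlation generative means for the low/high evidence levels.

    In ``"strength"`` mode the multipliers apply to the expected logLR
    (proportional to mean squared), so the mean scales by sqrt(multiplier);
    in ``"mean"`` mode they apply to the generative mean directly.
    """
    lo, hi = config.evidence_multipliers
    if config.multiplier_applies_to == "strength":
        return {"low": threshold_mean * math.sqrt(lo), "high": threshold_mean * math.sqrt(hi)}
    return {"low": threshold_mean * lo, "high": threshold_mean * hi}


def simulate_observer_dataset(
    spec: DDMSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    include_stimuli: bool = False,
    horizon: float = 15.0,
) -> list[TrialRecord]:
    """Simulate a complete session of the task from one DDM observer.

    Choices and RTs are drawn from the observer's path distribution under
    each trial's condition-specific drift and bound (RTs include the
    non-decision time; lapses are uniform-RT coin flips).  Stimulus streams
    cover ``ceil(rt / frame_interval)`` frames.
    """
    seq = build_trial_sequence(config)
    cond_keys = [
        (config.rho_for(c.correlation_condition), c.evidence_level) for c in seq
    ]
    correct, rt = simulate_trials(spec, cond_keys, rng, horizon=horizon)

    records: list[TrialRecord] = []
    for i, cond in enumerate(seq):
        rho = cond_keys[i][0]
        mu0 = spec.mu0_for(cond.evidence_level)
        mu = calibrated_mean(mu0, rho)
        if cond.source == "left":
            mu = -mu
        if correct[i]:
            choice = cond.source
        else:
            choice = "left" if cond.source == "right" else "right"
        stim = None
        if include_stimuli:
            n_frames = max(1, math.ceil(rt[i] / config.frame_interval))
            stim = generate_stimulus_stream(
                mu, config.sigma_g, rho, n_frames, rng, config.truncation_limit
            )
        records.append(
            TrialRecord(
                condition=cond,
                rho=rho,
                mu_rho=mu,
                stimulus=stim,
                choice=choice,
                rt=float(rt[i]),
            )
        )
    return records


def records_to_dataframe(
    records: list[TrialRecord],
    participant_id: str = "sim",
    config: TaskConfig | None = None,
    points: bool = False,
) -> pd.DataFrame:
    """Flatten trial records into the behavioral CSV schema.

    Scoring (+1 correct / -2 error, floored at zero cumulative points) is
    attached as annotation columns when ``points`` is set; it never feeds
    back into simulated behavior.
    """
    config = config if config is not None else TaskConfig()
    tpb = config.trials_per_block
    rows = []
    for i, r in enumerate(records):
        acc = int(r.choice == r.condition.source) if r.choice is not None else np.nan
        rows.append(
            {
                "participant_id": participant_id,
                "group_magnitude": config.correlation_magnitude,
                "block": i // tpb,
                "trial_index": i,
                "source": r.condition.source,
                "evidence_level": r.condition.evidence_level,
                "correlation_condition": r.condition.correlation_condition,
                "rho": r.rho,
                "mu_rho": r.mu_rho,
                "choice": r.choice,
                "rt_seconds": r.rt,
                "accuracy": acc,
                "n_frames": (
                    max(1, math.ceil(r.rt / config.frame_interval))
                    if r.rt is not None
                    else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows)
    if points:
        raw = np.where(df["accuracy"] == 1, 1, -2)
        cum, total = [], 0
        for p in raw:  # running total is floored at zero after each trial
            total = max(total + int(p), 0)
            cum.append(total)
        df["points"] = raw
        df["cumulative_points"] = cum
    return df
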