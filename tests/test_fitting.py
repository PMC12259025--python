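"""Likelihood evaluation, DDM fitting, psychometric fits, RT exclusions."""

import numpy as np
import pandas as pd
import pytest

from corrddm.fitting import (
    DriftDiffusionEstimator,
    PsychometricEstimator,
    apply_rt_exclusions,
    ddm_negative_log_likelihood,
    fit_participant,
    fit_psychometric,
    fit_split_half,
    param_names,
)
from corrddm.model_selection import aic

from conftest import MU0_K8, make_dataset, make_spec


class TestRTExclusions:
    def test_boundaries(self):
        df = pd.DataFrame(
            {
                "rt_seconds": [0.2, 0.3, 1.0, 15.0, 15.1],
                "accuracy": [1, 1, 0, 1, 0],
            }
        )
        out = apply_rt_exclusions(df)
        assert out["rt_seconds"].tolist() == [0.3, 1.0, 15.0]
        assert out.attrs["excluded_fraction"] == pytest.approx(2 / 5)

    def test_all_valid_unchanged(self):
        df = pd.DataFrame({"rt_seconds": [0.5, 1.2], "accuracy": [1, 0]})
        out = apply_rt_exclusions(df)
        assert len(out) == 2
        assert out.attrs["excluded_fraction"] == 0.0


class TestDDMLikelihood:
    def test_true_spec_beats_perturbed(self, reference_spec):
        df = make_dataset(reference_spec, seed=21, trials_per_block=960)
        worse = make_spec(k0=reference_spec.k0 * 1.5)
        nll_true = ddm_negative_log_likelihood(df, reference_spec)
        nll_pert = ddm_negative_log_likelihood(df, worse)
        assert nll_true < nll_pert

    def test_empty_dataset(self, reference_spec):
        df = pd.DataFrame(
            columns=["rho", "evidence_level", "rt_seconds", "accuracy"]
        ).astype({"rho": float, "rt_seconds": float, "accuracy": float})
        assert ddm_negative_log_likelihood(df, reference_spec) == 0.0

    def test_pure_lapse_closed_form(self):
        # lapse 1: every trial has density 1/(2*horizon) regardless of data
        spec = make_spec(lapse=1.0)
        df = make_dataset(spec, seed=3, trials_per_block=48)
        n = len(df)
        want = n * np.log(2 * 15.0)
        assert ddm_negative_log_likelihood(df, spec) == pytest.approx(want, rel=1e-9)

    def test_trial_order_permutation_invariance(self, reference_spec, small_dataset):
        shuffled = small_dataset.sample(frac=1.0, random_state=0)
        a = ddm_negative_log_likelihood(small_dataset, reference_spec)
        b = ddm_negative_log_likelihood(shuffled, reference_spec)
        assert a == pytest.approx(b, rel=1e-12)

    def test_gap_grows_with_sample_size(self, reference_spec):
        # likelihood consistency proxy: evidence against a misspecified
        # model accumulates linearly with trials
        worse = make_spec(k0=reference_spec.k0 * 1.5)
        gaps = []
        for n, seed in ((192, 31), (768, 32), (3072, 33)):
            df = make_dataset(reference_spec, seed=seed, trials_per_block=n)
            gaps.append(
                ddm_negative_log_likelihood(df, worse)
                - ddm_negative_log_likelihood(df, reference_spec)
            )
        assert 0 < gaps[0] < gaps[1] < gaps[2]


class TestDDMFitting:
    def test_seed_determinism(self, small_dataset):
        kw = dict(popsize=4, maxiter=3, polish=False, seed=7)
        r1 = fit_participant(small_dataset, "base", **kw)
        r2 = fit_participant(small_dataset, "base", **kw)
        assert r1.parameters == r2.parameters
        assert r1.log_likelihood == r2.log_likelihood

    def test_aic_identity_and_metadata(self, small_dataset):
        r = fit_participant(
            small_dataset, "base", popsize=4, maxiter=3, polish=False, seed=0
        )
        assert r.aic == pytest.approx(aic(r.log_likelihood, 5), rel=1e-12)
        assert r.n_trials == len(small_dataset)
        assert set(r.parameters) == set(param_names("base"))
        assert r.optimizer_meta["seed"] == 0

    def test_estimator_sklearn_protocol(self, small_dataset):
        est = DriftDiffusionEstimator(
            variant="base", popsize=4, maxiter=3, polish=False, seed=1
        )
        params = est.get_params()
        assert params["variant"] == "base"
        est.set_params(maxiter=2).fit(small_dataset)
        assert hasattr(est, "params_")
        assert est.score(small_dataset) == pytest.approx(
            est.log_likelihood_ / len(small_dataset), rel=1e-9
        )


class TestSplitHalf:
    def test_deterministic_and_split_by_order(self, reference_spec):
        df = make_dataset(reference_spec, seed=13, trials_per_block=96)
        kw = dict(popsize=4, maxiter=3, polish=False, seed=3)
        a1, a2 = fit_split_half(df, "base", **kw)
        b1, b2 = fit_split_half(df, "base", **kw)
        assert a1.parameters == b1.parameters
        assert a2.parameters == b2.parameters
        assert a1.n_trials + a2.n_trials == len(df)

    def test_insufficient_trials_raises(self, reference_spec):
        df = make_dataset(reference_spec, seed=14, trials_per_block=12, exclusions=False)
        with pytest.raises(ValueError, match="half"):
            fit_split_half(df, "base")


def _psychometric_dataset(rng, beta_e=1.0, lapse=0.0, n_per=250):
    """Choices from a known logistic over signed evidence strengths."""
    rows = []
    strengths = {"low": 0.5, "high": 2.0}
    for cond, rho in (("negative", -0.6), ("zero", 0.0), ("positive", 0.6)):
        for level, s in strengths.items():
            for source, sign in (("left", -1), ("right", 1)):
                e = sign * s
                p = lapse + (1 - 2 * lapse) / (1 + np.exp(-beta_e * e))
                chose_right = rng.random(n_per) < p
                mu = sign * np.sqrt(s * 0.01 * (1 + rho) / 4)
                for cr in chose_right:
                    rows.append(
                        {
                            "correlation_condition": cond,
                            "evidence_level": level,
                            "source": source,
                            "rho": rho,
                            "mu_rho": mu,
                            "choice": "right" if cr else "left",
                        }
                    )
    return pd.DataFrame(rows)


class TestPsychometric:
    def test_recovers_logistic_curve(self):
        rng = np.random.default_rng(0)
        df = _psychometric_dataset(rng, beta_e=1.0, lapse=0.0)
        est = PsychometricEstimator(mode="joint").fit(df)
        p = est.params_["joint"]
        assert p["beta_0"] == pytest.approx(0.0, abs=0.15)
        assert p["beta_e"] == pytest.approx(1.0, rel=0.2)
        # predicted choice probability at E = 1 for the true curve
        probe = df.iloc[:1].copy()
        probe["mu_rho"] = np.sqrt(1.0 * 0.01 / 4)
        probe["rho"] = 0.0
        assert est.predict_proba(probe)[0] == pytest.approx(0.7311, abs=0.03)

    def test_joint_beats_separate_on_shared_data(self):
        # when the generating parameters are shared across correlation
        # conditions, the 3-parameter model wins on average AIC
        rng = np.random.default_rng(1)
        deltas = []
        for _ in range(12):
            df = _psychometric_dataset(rng, beta_e=1.2, lapse=0.02, n_per=60)
            joint = fit_psychometric(df, mode="joint")
            separate = fit_psychometric(df, mode="separate")
            assert joint.aic == pytest.approx(aic(joint.log_likelihood, 3))
            assert separate.aic == pytest.approx(aic(separate.log_likelihood, 9))
            deltas.append(joint.aic - separate.aic)
        assert np.mean(deltas) < 0

    def test_separate_mode_has_three_parameter_sets(self):
        rng = np.random.default_rng(2)
        df = _psychometric_dataset(rng, n_per=40)
        fit = fit_psychometric(df, mode="separate")
        assert set(fit.parameters) == {"negative", "zero", "positive"}

    def test_complete_separation_stays_bounded(self):
        # deterministic choices: lapse-bounded fit remains finite
        rng = np.random.default_rng(3)
        df = _psychometric_dataset(rng, beta_e=50.0, n_per=30)
        est = PsychometricEstimator(mode="joint").fit(df)
        assert np.isfinite(est.log_likelihood_)
        assert est.params_["joint"]["beta_e"] <= 50.0
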