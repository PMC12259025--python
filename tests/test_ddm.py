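"""DDM variant semantics, first-passage solver accuracy, sampler agreement."""

import numpy as np
import pytest

from corrddm.ddm import (
    DDMSpec,
    ConditionParams,
    bound_equivalence_check,
    condition_params,
    n_free_params,
    predicted_rt_distribution,
    sample_paths,
    solve_first_passage,
)
from corrddm.ddm.specs import SpecificationError
from corrddm.ddm.fpt import ResolutionError


MU0 = {"low": 0.0548, "high": 0.1371}


def total_mean_rt(sol):
    g = sol.density_correct + sol.density_error
    mass = np.sum(g) * sol.dt
    return float(np.sum(sol.t * g) * sol.dt / mass)


class TestConditionParams:
    def test_full_rho_exact_cancellation(self):
        spec = DDMSpec(
            variant="full_rho", k0=8, B0=1.2, tB=0.05, mu_0=MU0,
            rho_hat_minus=-0.6, rho_hat_plus=0.6,
        )
        ref = condition_params(spec, 0.0, "high")
        for rho in (-0.6, 0.6):
            cp = condition_params(spec, rho, "high")
            assert cp.drift == pytest.approx(ref.drift, rel=1e-12)
            assert cp.b0 == pytest.approx(ref.b0, rel=1e-12)
            assert cp.slope == pytest.approx(ref.slope, rel=1e-12)

    def test_bound_rho_printed_scale(self):
        spec = DDMSpec(
            variant="bound_rho", k0=10, B0=1.0, mu_0=0.15,
            rho_hat_minus=0.0, rho_hat_plus=0.0,
        )
        cp = condition_params(spec, 0.6, "low")
        assert cp.b0 == pytest.approx(1.0 / np.sqrt(1.6), rel=1e-12)
        assert cp.b0 == pytest.approx(0.7906, abs=5e-5)
        assert cp.drift == pytest.approx(10 * 0.15, rel=1e-12)

    def test_full_rho_partial_estimate(self):
        spec = DDMSpec(
            variant="full_rho", k0=10, B0=1.0, mu_0=0.15,
            rho_hat_minus=-0.3, rho_hat_plus=0.3,
        )
        cp = condition_params(spec, 0.6, "low")
        assert cp.drift == pytest.approx(10 * 0.15 * np.sqrt(1.6 / 1.3), rel=1e-12)
        assert cp.drift == pytest.approx(1.6641, abs=5e-5)
        assert cp.b0 == pytest.approx(np.sqrt(1.3 / 1.6), rel=1e-12)
        assert cp.b0 == pytest.approx(0.9014, abs=5e-5)

    def test_base_has_no_correlation_scaling(self):
        spec = DDMSpec(variant="base", k0=8, B0=1.2, tB=0.1, mu_0=MU0)
        for rho in (-0.6, 0.0, 0.6):
            cp = condition_params(spec, rho, "low")
            assert cp.drift == pytest.approx(8 * MU0["low"], rel=1e-12)
            assert cp.b0 == pytest.approx(1.2, rel=1e-12)
            assert cp.slope == pytest.approx(0.1, rel=1e-12)

    def test_scaled_rho_general_bound(self):
        spec = DDMSpec(
            variant="scaled_rho", k0=8, B0=1.0, mu_0=0.1,
            rho_hat_sd_minus=-0.2, rho_hat_sd_plus=0.2,
            rho_hat_minus=-0.4, rho_hat_plus=0.4,
        )
        cp = condition_params(spec, 0.6, "low")
        want = (1 + 0.4) / (np.sqrt(1.6) * np.sqrt(1.2))
        assert cp.b0 == pytest.approx(want, rel=1e-12)
        assert cp.drift == pytest.approx(8 * 0.1 * np.sqrt(1.6 / 1.2), rel=1e-12)

    def test_missing_parameters_are_named(self):
        with pytest.raises(SpecificationError, match="rho_hat_minus"):
            DDMSpec(variant="full_rho", k0=8, B0=1.2, mu_0=0.1)

    def test_free_parameter_counts(self):
        assert n_free_params("base") == 5
        assert n_free_params("drift") == 7
        assert n_free_params("full_rho") == 7
        assert n_free_params("scaled_rho") == 9
        assert n_free_params("bound_rho_plus_drift") == 9

    def test_spec_json_round_trip(self):
        spec = DDMSpec(
            variant="full_rho", k0=8, B0=1.2, tB=0.05, ndt=0.3, lapse=0.01,
            mu_0=MU0, rho_hat_minus=-0.5, rho_hat_plus=0.5,
        )
        assert DDMSpec.from_json(spec.to_json()) == spec


class TestFirstPassageSolver:
    def test_zero_drift_symmetry(self):
        sol = solve_first_passage(ConditionParams(0.0, 1.0, 0.0))
        assert sol.p_correct == pytest.approx(0.5, abs=1e-6)
        assert sol.p_error == pytest.approx(0.5, abs=1e-6)

    def test_constant_bound_closed_forms(self):
        # p = 1/(1+exp(-2 m B)), E[T] = (B/m) tanh(m B), unit diffusion
        for m, B in [(1.0, 1.0), (0.5, 1.5), (2.0, 0.8)]:
            sol = solve_first_passage(ConditionParams(m, B, 0.0))
            assert sol.p_correct == pytest.approx(1 / (1 + np.exp(-2 * m * B)), rel=0.01)
            assert total_mean_rt(sol) == pytest.approx((B / m) * np.tanh(m * B), rel=0.01)

    def test_mass_conservation_and_positivity(self):
        sol = solve_first_passage(ConditionParams(0.8, 1.2, 0.1))
        assert np.all(sol.density_correct >= 0)
        assert np.all(sol.density_error >= 0)
        assert sol.p_correct + sol.p_error + sol.survival == pytest.approx(1.0, abs=1e-3)
        # trapezoidal integral consistent with reported masses
        assert np.trapezoid(sol.density_correct, sol.t) == pytest.approx(
            sol.p_correct, abs=1e-3
        )

    def test_full_collapse_forces_absorption(self):
        # bound hits zero at t* = B0/slope: all mass absorbed by then
        sol = solve_first_passage(ConditionParams(0.3, 1.0, 0.5))
        t_star = 1.0 / 0.5
        assert sol.p_correct + sol.p_error == pytest.approx(1.0, abs=1e-6)
        late = sol.t > t_star + sol.dt
        assert np.all(sol.density_correct[late] == 0)

    def test_resolution_guard(self):
        with pytest.raises(ResolutionError):
            solve_first_passage(ConditionParams(1.0, 1.0, 5.0), dt=0.01, dx=0.005)

    def test_grid_convergence(self):
        coarse = solve_first_passage(ConditionParams(1.0, 1.0, 0.0), dt=0.01, dx=0.01)
        fine = solve_first_passage(ConditionParams(1.0, 1.0, 0.0), dt=0.0025, dx=0.0025)
        assert coarse.p_correct == pytest.approx(fine.p_correct, abs=2e-3)
        assert total_mean_rt(coarse) == pytest.approx(total_mean_rt(fine), rel=5e-3)


class TestSamplerSolverAgreement:
    def test_ks_and_accuracy(self):
        spec = DDMSpec(variant="base", k0=8, B0=1.2, tB=0.05, ndt=0.35, mu_0=MU0)
        rng = np.random.default_rng(1)
        correct, rt = sample_paths(spec, 0.0, "low", 100_000, rng)
        sol = solve_first_passage(condition_params(spec, 0.0, "low"))
        se = np.sqrt(sol.p_correct * (1 - sol.p_correct) / 100_000)
        assert correct.mean() == pytest.approx(sol.p_correct, abs=3 * se)
        cdf = sol.cdf("correct")
        samp = np.sort(rt[correct] - spec.ndt)
        emp = np.arange(1, samp.size + 1) / samp.size
        model = np.interp(samp, sol.t, cdf / cdf[-1])
        assert np.max(np.abs(emp - model)) < 0.01

    def test_zero_drift_choice_frequencies(self):
        spec = DDMSpec(variant="base", k0=8, B0=1.0, mu_0=1e-12)
        rng = np.random.default_rng(2)
        correct, _ = sample_paths(spec, 0.0, "low", 20_000, rng)
        assert correct.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(20_000))


class TestPredictedRT:
    def test_no_lapse_equals_shifted_solution(self):
        spec = DDMSpec(variant="base", k0=8, B0=1.2, ndt=0.3, lapse=0.0, mu_0=MU0)
        pred = predicted_rt_distribution(spec, 0.0, "high")
        raw = solve_first_passage(condition_params(spec, 0.0, "high"))
        shift = int(round(0.3 / pred.dt))
        np.testing.assert_allclose(
            pred.density_correct[shift:], raw.density_correct[: len(raw.t) - shift]
        )

    def test_lapse_mixture_weights(self):
        # lapse 0.01: 99% DDM + 1% uniform over the horizon, split by choice
        spec = DDMSpec(variant="base", k0=8, B0=1.2, ndt=0.3, lapse=0.01, mu_0=MU0)
        pred = predicted_rt_distribution(spec, 0.0, "high", horizon=15.0)
        raw = solve_first_passage(condition_params(spec, 0.0, "high"))
        assert pred.p_correct == pytest.approx(0.99 * raw.p_correct + 0.005, abs=2e-3)
        # below the non-decision time only the lapse density remains
        early = pred.t < 0.3 - pred.dt
        np.testing.assert_allclose(
            pred.density_correct[early], 0.01 / 30.0, rtol=1e-9
        )


class TestBoundEquivalence:
    def test_identity_scale(self):
        spec = DDMSpec(variant="base", k0=8, B0=1.2, mu_0=MU0)
        rep = bound_equivalence_check(spec, 0.0, 1.0, n=20_000, seed=0)
        assert rep["p_correct_solver"] == pytest.approx(
            rep["p_correct_simulated"], abs=0.015
        )

    def test_joint_rescaling_invariance(self):
        # dividing the evidence by c while scaling the bound by c leaves
        # choices and RTs unchanged
        spec = DDMSpec(variant="base", k0=8, B0=0.8, mu_0=MU0)
        rep = bound_equivalence_check(spec, 0.0, 2.0, n=50_000, seed=1)
        assert rep["p_correct_solver"] == pytest.approx(
            rep["p_correct_simulated"], rel=0.01
        )
        assert rep["mean_rt_solver"] == pytest.approx(
            rep["mean_rt_simulated"], rel=0.01
        )
        assert rep["ks_correct"] < 0.015


class TestNormativePredictions:
    def test_choice_invariance_under_misestimation(self):
        # full-rho: with a fixed bound, accuracy depends only on the
        # product drift x bound, which is rho-free for any rho_hat; a
        # collapsing bound makes the invariance approximate
        kw = dict(variant="full_rho", k0=8, B0=1.2, mu_0=MU0,
                  rho_hat_minus=-0.3, rho_hat_plus=0.3)
        fixed = DDMSpec(tB=0.0, **kw)
        cps = [condition_params(fixed, rho, "high") for rho in (-0.6, 0.0, 0.6)]
        products = [cp.drift * cp.b0 for cp in cps]
        assert max(products) - min(products) < 1e-12
        ps = [solve_first_passage(cp).p_correct for cp in cps]
        assert max(ps) - min(ps) < 1e-3
        collapsing = DDMSpec(tB=0.05, **kw)
        ps_c = [
            solve_first_passage(condition_params(collapsing, rho, "high")).p_correct
            for rho in (-0.6, 0.0, 0.6)
        ]
        assert max(ps_c) - min(ps_c) < 0.01

    def test_rt_ordering_under_underestimation(self):
        # |rho_hat| < |rho|: faster for rho+, slower for rho-
        spec = DDMSpec(
            variant="full_rho", k0=8, B0=1.2, tB=0.05, mu_0=MU0,
            rho_hat_minus=-0.3, rho_hat_plus=0.3,
        )
        rt = {
            rho: total_mean_rt(solve_first_passage(condition_params(spec, rho, "high")))
            for rho in (-0.6, 0.0, 0.6)
        }
        assert rt[0.6] < rt[0.0] < rt[-0.6]

    def test_bound_misweighing_changes_both(self):
        # bound-rho with rho_hat_B != rho shifts accuracy and RT together
        spec = DDMSpec(
            variant="bound_rho", k0=8, B0=1.2, tB=0.05, mu_0=MU0,
            rho_hat_minus=0.0, rho_hat_plus=0.0,
        )
        acc, rt = {}, {}
        for rho in (-0.6, 0.0, 0.6):
            sol = solve_first_passage(condition_params(spec, rho, "high"))
            acc[rho] = sol.p_correct
            rt[rho] = total_mean_rt(sol)
        assert acc[-0.6] > acc[0.0] > acc[0.6]
        assert rt[-0.6] > rt[0.0] > rt[0.6]
        assert acc[-0.6] - acc[0.6] > 1e-3
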