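import json
from dataclasses import replace

import numpy as np
import pytest

from viscofit import (
    FitConfig,
    GeneralizedMaxwell,
    compare_methods,
    fit_elastic,
    fit_iterative,
    fit_open_search,
    select_terms,
    sse_cost,
)
from viscofit.exceptions import DegenerateInputError, DomainError
from viscofit.fitting import _Residual, _bounds
from viscofit.simulate import RampProtocol, default_benchmark_model

from conftest import make_curve, max_param_rel_err

FAST = FitConfig(max_terms=2, n_attempts=8, seed=0, max_nfev=300)


class TestSseCost:
    def test_self_fit_is_quadrature_floor(self, sls_model, sls_curve):
        assert sse_cost(sls_model, sls_curve) <= 1e-12

    def test_wrong_model_positive(self, sls_curve):
        wrong = GeneralizedMaxwell(Ge=1000.0)
        assert sse_cost(wrong, sls_curve) > 0.0

    def test_doubled_elastic_modulus_closed_form(self, elastic_curve, geom):
        # on Hertz data with generator Ge: residual = (2 Ge - Ge) y = Ge y
        doubled = GeneralizedMaxwell(Ge=2000.0)
        y = elastic_curve.h ** 1.5
        expected = float(1000.0**2 * (y @ y))
        assert sse_cost(doubled, elastic_curve) == pytest.approx(expected, rel=1e-9)

    def test_predict_invariant_to_arm_ordering(self, sls_curve, geom):
        res = _Residual(sls_curve, geom, "maxwell")
        x_sorted = np.log10([100.0, 300.0, 1e-4, 500.0, 1e-3])
        x_shuffled = np.log10([100.0, 500.0, 1e-3, 300.0, 1e-4])
        np.testing.assert_allclose(res.predict(x_sorted), res.predict(x_shuffled),
                                   rtol=1e-12)

    def test_build_model_sorts_taus(self, sls_curve, geom):
        res = _Residual(sls_curve, geom, "maxwell")
        m = res.build_model(np.log10([100.0, 500.0, 1e-3, 300.0, 1e-4]))
        assert m.taus[0] == pytest.approx(1e-4)
        assert m.moduli[0] == pytest.approx(300.0)


class TestJacobian:
    @pytest.mark.parametrize("family", ["maxwell", "kelvinvoigt"])
    def test_matches_finite_differences(self, family, sls_curve, geom):
        res = _Residual(sls_curve, geom, family)
        x = np.log10([200.0, 400.0, 3e-4]) if family == "maxwell" \
            else np.log10([5e-3, 2e-3, 3e-4])
        jac = res.jacobian(x)
        eps = 1e-7
        for j in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            fd = (res.residual(xp) - res.residual(xm)) / (2 * eps)
            np.testing.assert_allclose(jac[:, j], fd, rtol=1e-5, atol=1e-12)


class TestFitElastic:
    def test_exact_recovery_on_hertz_data(self, elastic_curve):
        assert fit_elastic(elastic_curve) == pytest.approx(1000.0, rel=1e-12)

    def test_linearity_in_force(self, elastic_curve):
        doubled = replace(elastic_curve, F=2.0 * elastic_curve.F)
        assert fit_elastic(doubled) == pytest.approx(2000.0, rel=1e-12)

    def test_relaxing_data_bracketed(self, sls_model, sls_curve):
        g = fit_elastic(sls_curve)
        assert sls_model.Ge < g < sls_model.glassy_modulus

    def test_degenerate_input(self, elastic_curve):
        zero = replace(elastic_curve, h=np.zeros_like(elastic_curve.h))
        with pytest.raises(DegenerateInputError):
            fit_elastic(zero)


class TestOpenSearch:
    def test_noiseless_one_arm_recovery(self, sls_curve, sls_model, geom):
        cfg = replace(FAST, n_attempts=20, tau_seed=1e-3)
        r = fit_open_search(sls_curve, geom, 1, cfg)
        assert max_param_rel_err(r.model, sls_model) < 0.01
        assert r.converged

    def test_elastic_data_arm_negligible(self, elastic_curve, geom):
        r = fit_open_search(elastic_curve, geom, 1, replace(FAST, n_attempts=12))
        share = r.model.moduli[0] / r.model.glassy_modulus
        assert share < 0.01 or r.sse < 1e-25

    def test_determinism(self, sls_curve, geom):
        a = fit_open_search(sls_curve, geom, 1, FAST)
        b = fit_open_search(sls_curve, geom, 1, FAST)
        assert a.model == b.model
        assert a.attempt_log == b.attempt_log

    def test_attempt_log_length_and_bounds(self, sls_curve, geom):
        cfg = replace(FAST, n_attempts=5)
        r = fit_open_search(sls_curve, geom, 2, cfg)
        assert len(r.attempt_log) == 5
        lo, hi = cfg.magnitude_bounds
        assert lo <= r.model.Ge <= hi
        for g, tau in r.model.arms:
            assert lo <= g <= hi

    def test_invalid_n_terms(self, sls_curve, geom):
        with pytest.raises(DomainError):
            fit_open_search(sls_curve, geom, 0, FAST)


class TestIterative:
    def test_noiseless_two_arm_recovery(self, geom):
        truth = default_benchmark_model(2)
        c = make_curve(truth, duration=0.02)
        cfg = FitConfig(max_terms=2, n_attempts=12, seed=1, max_nfev=300)
        results = fit_iterative(c, geom, cfg)
        assert max_param_rel_err(results[-1].model, truth) < 0.05

    def test_stage_costs_monotone(self, geom):
        truth = default_benchmark_model(2)
        c = make_curve(truth, duration=0.02, noise_sd=2e-13, seed=3)
        results = fit_iterative(c, geom, replace(FAST, max_terms=3))
        costs = [r.sse for r in results]
        # exact nesting is broken by the 1 Pa lower bound on new arms, so
        # monotonicity holds up to that floor plus solver tolerance
        assert all(b <= a * (1 + 1e-3) for a, b in zip(costs, costs[1:]))

    def test_elastic_data_stage1_not_worse_than_elastic_fit(self, elastic_curve, geom):
        ge = fit_elastic(elastic_curve)
        elastic_cost = sse_cost(GeneralizedMaxwell(Ge=ge), elastic_curve)
        r1 = fit_iterative(elastic_curve, geom, replace(FAST, max_terms=1))[0]
        obs_scale = float(np.sum((elastic_curve.F / 1.886e-2) ** 2))
        # the mandatory >= 1 Pa arm keeps stage 1 a hair above the pure
        # elastic optimum; both costs are at the numerical floor
        assert r1.sse <= elastic_cost + 1e-11 * obs_scale

    def test_determinism(self, sls_curve, geom):
        a = fit_iterative(sls_curve, geom, FAST)
        b = fit_iterative(sls_curve, geom, FAST)
        for x, y in zip(a, b):
            assert x.model == y.model and x.sse == y.sse

    def test_kelvinvoigt_family_self_consistent(self, sls_model, geom):
        from viscofit import sls_interconvert

        c = make_curve(sls_model, duration=0.02)
        cfg = FitConfig(family="kelvinvoigt", max_terms=1, n_attempts=12,
                        seed=0, tau_seed=4e-3, max_nfev=400)
        r = fit_iterative(c, geom, cfg)[0]
        kv_truth = sls_interconvert(sls_model)
        assert r.model.Jg == pytest.approx(kv_truth.Jg, rel=0.05)
        assert r.model.arms[0][1] == pytest.approx(kv_truth.arms[0][1], rel=0.10)


class TestSelectTerms:
    def test_two_arm_truth_selected(self, geom):
        truth = default_benchmark_model(2)
        c = make_curve(truth, duration=0.02)
        results = fit_iterative(c, geom, replace(FAST, max_terms=3, n_attempts=10))
        assert select_terms(results, c, geom) == 2

    def test_elastic_selects_one(self, elastic_curve, geom):
        results = fit_iterative(elastic_curve, geom, replace(FAST, max_terms=2))
        assert select_terms(results, elastic_curve, geom) == 1

    def test_huge_eps_selects_one(self, geom, sls_curve):
        results = fit_iterative(sls_curve, geom, replace(FAST, max_terms=2))
        assert select_terms(results, sls_curve, geom, eps=1e12) == 1

    def test_empty_results_error(self, sls_curve, geom):
        with pytest.raises(DomainError):
            select_terms([], sls_curve, geom)


@pytest.fixture(scope="module")
def report():
    from conftest import GEOM as geom

    truth = default_benchmark_model(1)
    protocol = RampProtocol(max_force=None, max_indentation=4e-8,
                            noise_sd=2e-15)
    cfg = FitConfig(max_terms=1, n_attempts=4, seed=0, max_nfev=200)
    return compare_methods(truth, protocol, geom, cfg, n_replicates=3, seed=5)


class TestCompareMethods:
    def test_structure(self, report):
        assert set(report["iterative"]) == {"1"}
        assert len(report["iterative"]["1"]["costs"]) == 3
        assert report["open"]["1"]["median"] >= 0.0

    def test_bit_exact_reproducibility(self, geom, report):
        truth = default_benchmark_model(1)
        protocol = RampProtocol(max_force=None, max_indentation=4e-8,
                                noise_sd=2e-15)
        cfg = FitConfig(max_terms=1, n_attempts=4, seed=0, max_nfev=200)
        again = compare_methods(truth, protocol, geom, cfg, n_replicates=3, seed=5)
        a = {k: v for k, v in report.items() if k != "wall_time_s"}
        b = {k: v for k, v in again.items() if k != "wall_time_s"}
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


class TestConfig:
    def test_tau_windows_non_overlapping_increasing(self):
        cfg = FitConfig()
        prev_hi = 0.0
        for n in range(1, 5):
            lo, hi = cfg.tau_window(n)
            assert lo >= prev_hi * (1 - 1e-12)
            assert lo < hi
            prev_hi = hi

    def test_invalid_config(self):
        with pytest.raises(DomainError):
            FitConfig(family="powerlaw")
        with pytest.raises(DomainError):
            FitConfig(n_attempts=0)
        with pytest.raises(DomainError):
            FitConfig(modulus_bounds=(0.0, 1.0))

    def test_bounds_layout(self):
        lo, hi = _bounds(FitConfig(), 2)
        assert lo.size == hi.size == 5
        assert np.all(lo < hi)
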