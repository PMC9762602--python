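"""MTLR, soft-L1-Hinge finetuning, and the Cox/AFT baselines."""

import numpy as np
import pytest

from bcaisd.cohort_sim import GeneratorConfig, generate_cohort
from bcaisd.eval_metrics import km_greenwood, l1_hinge
from bcaisd.isd_curves import median_event_time, survival_at
from bcaisd.isd_models import (DEFAULT_ROSTER, MTLR, MTLRParams,
                               default_registry, default_time_grid,
                               expected_event_time, finetune_soft_l1,
                               fit_aft_isd, fit_cox_breslow_isd, fit_mtlr,
                               mtlr_predict, mtlr_predict_many, mtlr_survival)


def exponential_cohort(rng, n, beta=None, scale=120.0, censor=(50.0, 250.0)):
    p = 0 if beta is None else len(beta)
    X = rng.normal(size=(n, p))
    eta = X @ np.asarray(beta) if p else np.zeros(n)
    T = rng.exponential(scale * np.exp(-eta))
    C = rng.uniform(*censor, size=n)
    return X, np.minimum(T, C), (T <= C).astype(int)


class TestMTLRFit:
    def test_covariate_free_matches_km(self, default_cohort):
        table, _ = default_cohort
        t, d = table.time, table.event
        params = fit_mtlr(np.zeros((len(t), 0)), t, d)
        S = mtlr_survival(params, np.zeros((1, 0)))[0]
        km = km_greenwood(t, d)
        assert np.abs(S - km.survival_at(params.taus)).max() < 0.02

    def test_zero_parameters_give_uniform_sequence_distribution(self):
        taus = np.array([10.0, 20.0, 30.0])
        params = MTLRParams(taus, np.zeros((3, 2)), np.zeros(3), 1.0, 0.0)
        S = mtlr_survival(params, np.zeros((1, 2)))[0]
        m = 3
        assert np.allclose(S, (m + 1 - np.arange(1, m + 1)) / (m + 1))

    def test_training_loss_decreases_monotonically(self):
        rng = np.random.default_rng(0)
        X, t, d = exponential_cohort(rng, 400, [0.8, -0.3])
        params = fit_mtlr(X, t, d, C=1.0)
        hist = np.array(params.loss_history)
        assert len(hist) > 1
        assert (np.diff(hist) <= 1e-9).all()

    def test_deterministic_from_zero_init(self):
        rng = np.random.default_rng(1)
        X, t, d = exponential_cohort(rng, 300, [0.5])
        p1 = fit_mtlr(X, t, d)
        p2 = fit_mtlr(X, t, d)
        assert np.array_equal(p1.Theta, p2.Theta)

    def test_needs_two_events(self):
        with pytest.raises(ValueError):
            fit_mtlr(np.zeros((5, 1)), np.arange(1.0, 6.0), np.zeros(5, int))

    def test_grid_size_tracks_event_count(self):
        rng = np.random.default_rng(2)
        _, t, d = exponential_cohort(rng, 800, None)
        taus = default_time_grid(t, d)
        assert 2 <= len(taus) <= int(np.ceil(np.sqrt(d.sum())))
        assert (np.diff(taus) > 0).all()


class TestMTLRPredict:
    def test_curve_invariants_fuzzed(self):
        rng = np.random.default_rng(3)
        X, t, d = exponential_cohort(rng, 500, [0.8, -0.5])
        params = fit_mtlr(X, t, d)
        for x in rng.normal(size=(200, 2)):
            c = mtlr_predict(params, x)
            assert c.times[0] == 0.0 and c.probs[0] == 1.0
            assert (np.diff(c.probs) <= 1e-12).all()
            assert (c.probs >= 0).all() and (c.probs <= 1).all()

    def test_higher_risk_feature_lowers_curve_everywhere(self):
        rng = np.random.default_rng(4)
        X, t, d = exponential_cohort(rng, 1500, [1.0, 0.0])
        params = fit_mtlr(X, t, d)
        hi = mtlr_predict(params, np.array([2.0, 0.0]))
        lo = mtlr_predict(params, np.array([-2.0, 0.0]))
        assert (hi.probs[1:] < lo.probs[1:]).all()

    def test_dimension_mismatch_rejected(self):
        params = MTLRParams(np.array([10.0, 20.0]), np.zeros((2, 3)),
                            np.zeros(2), 1.0, 0.0)
        with pytest.raises(ValueError):
            mtlr_predict(params, np.zeros(2))

    def test_curves_can_cross(self):
        """Per-time weights allow crossings that proportional hazards forbids."""
        taus = np.array([10.0, 20.0])
        params = MTLRParams(taus, np.array([[2.0], [-2.0]]), np.zeros(2), 1.0, 0.0)
        a = mtlr_predict(params, np.array([1.0]))
        b = mtlr_predict(params, np.array([-1.0]))
        assert a.probs[1] < b.probs[1]
        assert a.probs[2] > b.probs[2]

    def test_curves_need_not_reach_zero_at_horizon(self, default_cohort):
        """With ~97% censoring the ISD mass beyond the last grid point stays
        large — no constraint forces S to 0 at the horizon."""
        table, _ = default_cohort
        t, d = table.time, table.event
        params = fit_mtlr(np.zeros((len(t), 0)), t, d)
        S = mtlr_survival(params, np.zeros((1, 0)))[0]
        assert S[-1] > 0.5


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    X, t, d = exponential_cohort(rng, 1000, [0.8, -0.4])
    return X, t, d, fit_mtlr(X, t, d, C=1.0)


class TestFinetune:
    def _train_l1(self, params, X, t, d):
        cap = 10 * t.max()
        med = np.array([min(median_event_time(c), cap)
                        for c in mtlr_predict_many(params, X)])
        return l1_hinge(med, t, d)[1]

    def test_zero_epochs_identity(self, fitted):
        X, t, d, params = fitted
        out = finetune_soft_l1(params, X, t, d, epochs=0)
        assert np.array_equal(out.Theta, params.Theta)
        assert np.array_equal(out.bias, params.bias)

    def test_training_l1_hinge_never_increases(self, fitted):
        X, t, d, params = fitted
        before = self._train_l1(params, X, t, d)
        out = finetune_soft_l1(params, X, t, d, epochs=25, step=1e-4)
        assert self._train_l1(out, X, t, d) <= before + 1e-12

    def test_curves_remain_monotone(self, fitted):
        X, t, d, params = fitted
        out = finetune_soft_l1(params, X, t, d, epochs=10, step=1e-4)
        for c in mtlr_predict_many(out, X[:50]):
            assert (np.diff(c.probs) <= 1e-12).all()

    def test_expected_event_time_gradient_direction(self, fitted):
        """Finite-difference check of the surrogate's analytic building block."""
        X, t, d, params = fitted
        that, _, _ = expected_event_time(params, X[:4])
        eps = 1e-6
        pert = params.copy()
        pert.Theta[1, 0] += eps
        that2, _, _ = expected_event_time(pert, X[:4])
        fd = (that2 - that) / eps
        assert np.all(np.isfinite(fd))


class TestCoxBreslowISD:
    def test_null_covariate_matches_nelson_aalen_survival(self):
        rng = np.random.default_rng(6)
        _, t, d = exponential_cohort(rng, 400, None)
        model = fit_cox_breslow_isd(np.zeros((400, 1)), t, d)
        curves = model.predict_curves(np.zeros((2, 1)))
        # Nelson-Aalen by hand
        order = np.argsort(t, kind="stable")
        ts, ds = t[order], d[order]
        na = {}
        H = 0.0
        for et in np.unique(ts[ds == 1]):
            n_at = (ts >= et).sum()
            d_at = ((ts == et) & (ds == 1)).sum()
            H += d_at / n_at
            na[et] = np.exp(-H)
        for et, s in list(na.items())[::10]:
            assert survival_at(curves[0], et) == pytest.approx(s, abs=1e-6)
        assert np.allclose(curves[0].probs, curves[1].probs)

    def test_hazard_ratio_two_recovered(self):
        rng = np.random.default_rng(7)
        x = (rng.uniform(size=5000) < 0.5).astype(float)
        T = rng.exponential(100 * np.exp(-np.log(2) * x))
        C = rng.uniform(20, 300, 5000)
        t, d = np.minimum(T, C), (T <= C).astype(int)
        model = fit_cox_breslow_isd(x[:, None], t, d)
        assert 0.6 <= model.coef_[0] <= 0.8

    def test_curves_never_cross(self):
        rng = np.random.default_rng(8)
        X, t, d = exponential_cohort(rng, 800, [0.8, -0.5])
        model = fit_cox_breslow_isd(X, t, d)
        curves = model.predict_curves(rng.normal(size=(20, 2)))
        grid = np.linspace(1, 200, 40)
        vals = np.array([[survival_at(c, g) for g in grid] for c in curves])
        for i in range(len(curves)):
            for j in range(i + 1, len(curves)):
                diff = vals[i] - vals[j]
                inner = diff[(vals[i] > 1e-9) & (vals[i] < 1 - 1e-9)]
                if len(inner) > 1:
                    assert (inner >= -1e-9).all() or (inner <= 1e-9).all()

    def test_coxnet_penalty_variant(self):
        rng = np.random.default_rng(9)
        X, t, d = exponential_cohort(rng, 600, [0.8, 0.0])
        model = fit_cox_breslow_isd(X, t, d, penalty=(0.01, 0.5))
        curves = model.predict_curves(X[:3])
        assert all(c.probs[0] == 1.0 for c in curves)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox_breslow_isd(np.zeros((10, 1)), np.arange(1.0, 11.0),
                                np.zeros(10, int))


class TestAFT:
    def test_weibull_shape_recovered_from_generator(self):
        cfg = GeneratorConfig(n=5000, seed=31, item_missing_rate=0.0,
                              block_missing_rates={})
        table, truth = generate_cohort(cfg)
        model = fit_aft_isd(np.zeros((5000, 0)), table.time, table.event,
                            family="weibull")
        rho = float(model.estimator.summary.loc[("rho_", "Intercept"), "coef"])
        shape_hat = np.exp(rho)
        assert abs(shape_hat - truth.baseline_shape) / truth.baseline_shape < 0.10

    def test_zero_covariates_matches_direct_mle(self):
        from lifelines import WeibullFitter

        rng = np.random.default_rng(10)
        _, t, d = exponential_cohort(rng, 1000, None)
        model = fit_aft_isd(np.zeros((1000, 0)), t, d, family="weibull")
        wf = WeibullFitter().fit(t, d)
        ours = survival_at(model.predict_curves(np.zeros((1, 0)))[0], 100.0)
        theirs = float(wf.survival_function_at_times(100.0).iloc[0])
        assert ours == pytest.approx(theirs, abs=1e-3)

    def test_s0_is_one_and_curves_valid(self):
        rng = np.random.default_rng(11)
        X, t, d = exponential_cohort(rng, 500, [0.5])
        for family in ("weibull", "lognormal"):
            model = fit_aft_isd(X, t, d, family=family)
            for c in model.predict_curves(X[:10]):
                assert c.probs[0] == 1.0
                assert (np.diff(c.probs) <= 1e-12).all()

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            fit_aft_isd(np.zeros((10, 1)), np.arange(1.0, 11.0),
                        np.ones(10, int), family="gamma")


class TestRegistry:
    def test_roster_names_and_adapter_slots(self):
        reg = default_registry()
        assert set(DEFAULT_ROSTER) == set(reg.names())
        assert len(DEFAULT_ROSTER) == 9
        for implemented in ("MTLR", "CoxPH", "CoxNet", "AFT"):
            assert reg.available(implemented)
        for slot in ("RSF", "GBCM", "CW-GBCM", "DeepHit", "DSM"):
            assert not reg.available(slot)
            with pytest.raises(KeyError):
                reg.create(slot)

    def test_registered_adapter_becomes_available(self):
        reg = default_registry()
        reg.register("RSF", MTLR)        # any conforming constructor
        assert reg.available("RSF")

    def test_all_registered_models_produce_valid_curves(self):
        rng = np.random.default_rng(12)
        X, t, d = exponential_cohort(rng, 400, [0.8, -0.3])
        reg = default_registry()
        for name in ("MTLR", "CoxPH", "CoxNet", "AFT"):
            model = reg.create(name)
            model.fit(X, t, d)
            for c in model.predict_curves(X[:5]):
                assert c.times[0] == 0.0 and c.probs[0] == 1.0
                assert (np.diff(c.probs) <= 1e-12).all()
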