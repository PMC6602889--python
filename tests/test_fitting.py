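"""Weighted NLS estimation, the diet-intake constraint, and the F-test."""

import numpy as np
import pytest
from scipy import stats

import vakinetics as vk
from conftest import lognormal_noise

GRID = vk.DEFAULT_SAMPLING_GRID


def noisy_obs(params, spec, rng, M5=5.0, intake=None, cv=0.05):
    clean = vk.simulate_fdp(params, spec, GRID)
    y = np.clip(clean.fdp * lognormal_noise(rng, clean.fdp.size, cv), 0, 1)
    return vk.ObservationSet(
        tracer=vk.TracerCurve(times=clean.times, fdp=y),
        plasma_pool_M5=M5,
        intake_obs=vk.IntakeObservation(intake) if intake is not None else None,
    )


class TestWeightedResiduals:
    def test_self_fit_residuals_vanish(self, us_params, spec2):
        clean = vk.simulate_fdp(us_params, spec2, GRID)
        obs = vk.ObservationSet(tracer=clean, plasma_pool_M5=5.0)
        r = vk.weighted_residuals(obs, us_params, spec2)
        assert np.max(np.abs(r)) < 1e-8

    def test_matches_definition(self, us_params, spec2):
        rng = np.random.default_rng(1)
        obs = noisy_obs(us_params, spec2, rng)
        r = vk.weighted_residuals(obs, us_params, spec2)
        yhat = vk.simulate_fdp(us_params, spec2, GRID).fdp
        y = obs.tracer.fdp
        np.testing.assert_allclose(r, (y - yhat) / (0.05 * y), rtol=1e-12)

    def test_intake_residual_hand_values(self):
        # kinetics with U1 = 1.12 x M5: at M5 = 2.5 the predicted intake is
        # exactly 2.8 µmol/d; at M5 = 5 it is 5.6
        spec = vk.ModelSpec(variant=vk.Variant.ONE_EV, include_diet_constraint=True)
        p = vk.KineticParameters.from_dict({
            "L_2_1": 1.2, "L_3_2": 5.0, "DT_3": 0.1, "L_5_4": 2.5,
            "L_6_5": 0.84, "L_5_6": 0.0, "L_10_6": 1.0,
        })
        clean = vk.simulate_fdp(p, spec, GRID)
        for m5, expected in [(2.5, 0.0), (5.0, -10.0)]:
            obs = vk.ObservationSet(
                tracer=clean, plasma_pool_M5=m5,
                intake_obs=vk.IntakeObservation(2.8, fsd=0.1),
            )
            r = vk.weighted_residuals(obs, p, spec)
            assert r[-1] == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_observation_rejected_or_dropped(self, us_params, spec2):
        t = GRID[:5]
        y = np.array([0.0, 0.01, 0.02, 0.03, 0.02])
        obs = vk.ObservationSet(tracer=vk.TracerCurve(times=t, fdp=y))
        with pytest.raises(ValueError):
            vk.weighted_residuals(obs, us_params, spec2)
        with pytest.warns(UserWarning):
            r = vk.weighted_residuals(obs, us_params, spec2, on_nonpositive="drop")
        assert r.size == 4


class TestFit:
    def test_noise_free_recovery(self, us_params, spec2):
        """Noise-free self-consistency: the optimiser recovers the generating
        kinetics (the absorption-chain rates up to their inherent permutation
        ambiguity) and the steady-state outputs to 0.1%."""
        clean = vk.simulate_fdp(us_params, spec2, GRID)
        obs = vk.ObservationSet(tracer=clean, plasma_pool_M5=5.0)
        truth = us_params.to_dict()
        start = {k: v * (2.0 if i % 2 else 0.5)
                 for i, (k, v) in enumerate(truth.items())}
        res = vk.fit(obs, spec2, start=start)
        assert res.converged
        assert res.wss < 1e-12
        est = res.params.to_dict()
        for name in ("L_6_5", "L_5_6", "L_10_6", "L_7_5", "L_5_7", "DT_3"):
            assert est[name] == pytest.approx(truth[name], rel=1e-3), name
        # absorption chain: identifiable as an unordered rate set
        a = spec2.absorption_efficiency
        up_true = sorted([truth["L_2_1"] / a, truth["L_3_2"], truth["L_5_4"]])
        up_est = sorted([est["L_2_1"] / a, est["L_3_2"], est["L_5_4"]])
        np.testing.assert_allclose(up_est, up_true, rtol=1e-3)
        ss_true = vk.solve_steady_state(us_params, spec2, 5.0)
        ss_est = res.steady_state()
        assert ss_est.TBS == pytest.approx(ss_true.TBS, rel=1e-3)
        assert ss_est.DR == pytest.approx(ss_true.DR, rel=1e-3)

    def test_deterministic_given_start_and_seed(self, us_params, spec2):
        rng = np.random.default_rng(11)
        obs = noisy_obs(us_params, spec2, rng)
        r1 = vk.fit(obs, spec2, n_starts=3, seed=5)
        r2 = vk.fit(obs, spec2, n_starts=3, seed=5)
        assert r1.params.to_dict() == r2.params.to_dict()
        assert r1.wss == r2.wss

    def test_diet_constraint_improves_loss_rate(self, us_params, spec2, spec2_di):
        """With 52-d data the fractional loss L(10,6) is poorly identified;
        anchoring the steady-state intake at the true dietary input reduces
        its estimation error (the method's central mechanism)."""
        errs_plain, errs_di = [], []
        truth = us_params.get(10, 6)
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            obs = noisy_obs(us_params, spec2, rng, intake=2.8)
            res_di = vk.fit(obs, spec2_di)
            obs_plain = vk.ObservationSet(
                tracer=obs.tracer, plasma_pool_M5=obs.plasma_pool_M5
            )
            res_plain = vk.fit(obs_plain, spec2)
            errs_di.append(abs(res_di.params.get(10, 6) / truth - 1))
            errs_plain.append(abs(res_plain.params.get(10, 6) / truth - 1))
        assert np.median(errs_di) < np.median(errs_plain)

    def test_weighted_ss_is_order_one_under_correct_weighting(
        self, one_ev_params, spec1
    ):
        """Fractional-SD weights put wss/dof on the unit scale (the flexible
        exponential model absorbs somewhat more noise than its parameter
        count, so the ratio sits below 1)."""
        ratios = []
        for rep in range(10):
            rng = np.random.default_rng(900 + rep)
            obs = noisy_obs(one_ev_params, spec1, rng)
            res = vk.fit(obs, spec1)
            ratios.append(res.wss / res.dof)
        assert 0.2 < np.mean(ratios) < 2.0

    def test_too_few_observations_rejected(self, us_params, spec2):
        clean = vk.simulate_fdp(us_params, spec2, GRID[:5])
        obs = vk.ObservationSet(tracer=clean, plasma_pool_M5=5.0)
        with pytest.raises(ValueError):
            vk.fit(obs, spec2)

    def test_intake_weight_tightens_constraint(self, us_params, spec2):
        """As the dietary fsd shrinks, the fitted steady-state intake
        converges to the observed value."""
        rng = np.random.default_rng(77)
        clean = vk.simulate_fdp(us_params, spec2, GRID)
        y = np.clip(clean.fdp * lognormal_noise(rng, clean.fdp.size), 0, 1)
        curve = vk.TracerCurve(times=clean.times, fdp=y)
        spec_di = vk.ModelSpec(variant=vk.Variant.TWO_EV,
                               include_diet_constraint=True)
        gaps = []
        for fsd in (1.0, 0.1, 0.01):
            obs = vk.ObservationSet(
                tracer=curve, plasma_pool_M5=5.0,
                intake_obs=vk.IntakeObservation(2.8, fsd=fsd),
            )
            res = vk.fit(obs, spec_di)
            gaps.append(abs(res.steady_state().U1 - 2.8))
        assert gaps[2] < gaps[0]
        assert gaps[2] < 0.05


class TestModelResultsInterface:
    def test_from_dataframe_and_summary(self, us_params, spec2):
        import pandas as pd
        clean = vk.simulate_fdp(us_params, spec2, GRID)
        df = pd.DataFrame({"time_d": clean.times, "fdp": clean.fdp})
        model = vk.TracerKineticsModel.from_dataframe(df, spec2, plasma_pool_M5=5.0)
        res = model.fit(start=us_params)
        text = res.summary()
        assert "L_10_6" in text and "2EV" in text
        assert res.predict(GRID).fdp == pytest.approx(clean.fdp, rel=1e-6)

    def test_param_fsd_reported_for_adjustables(self, us_params, spec2):
        rng = np.random.default_rng(3)
        obs = noisy_obs(us_params, spec2, rng)
        res = vk.fit(obs, spec2)
        assert set(res.param_fsd) == set(spec2.adjustable)
        assert all(np.isfinite(v) and v >= 0 for v in res.param_fsd.values())


class TestFTest:
    def test_equal_wss_gives_unit_p(self, us_params, spec2, spec1):
        rng = np.random.default_rng(21)
        obs = noisy_obs(us_params, spec2, rng)
        r2 = vk.fit(obs, spec2)
        r1 = vk.fit(vk.ObservationSet(tracer=obs.tracer, plasma_pool_M5=5.0), spec1)
        r1b = vk.KineticsFitResults(**{**r1.__dict__})
        r1b.wss = r2.wss  # forced tie
        r1b.n_obs = r2.n_obs
        out = vk.f_test(r1b, r2)
        assert out["F"] == 0.0
        assert out["p"] == 1.0

    def test_hand_arithmetic(self, us_params, spec1, spec2):
        rng = np.random.default_rng(22)
        obs = noisy_obs(us_params, spec2, rng)
        simple = vk.fit(vk.ObservationSet(tracer=obs.tracer, plasma_pool_M5=5.0),
                        spec1)
        complex_ = vk.fit(obs, spec2)
        simple.wss, complex_.wss = 20.0, 10.0
        simple.n_free, complex_.n_free = 7, 9
        simple.n_obs = complex_.n_obs = 21  # n - p_c = 12
        out = vk.f_test(simple, complex_)
        assert out["F"] == pytest.approx(6.0, rel=1e-12)
        assert out["p"] == pytest.approx(stats.f.sf(6.0, 2, 12), rel=1e-12)

    def test_non_nested_rejected(self, us_params, spec2):
        rng = np.random.default_rng(23)
        obs = noisy_obs(us_params, spec2, rng)
        res = vk.fit(obs, spec2)
        with pytest.raises(ValueError):
            vk.f_test(res, res)

    def test_power_against_two_pool_data(self, spec1, spec2):
        """Composite curves generated with two exchanging pools: the two-pool
        fit is a significant improvement in most replicates.  The two-pool
        fit takes the better of a nested start (one-pool solution plus a tiny
        second pool) and the default start, since the nested start alone can
        sit in a local minimum."""
        n_sig = 0
        for rep in range(20):
            cfg = vk.GeneratorConfig(n_subjects=7, seed=1300 + rep,
                                     param_between_subject_gsd=1.0)
            comp = vk.geometric_mean_curve(vk.generate_group(cfg))
            obs = vk.ObservationSet(tracer=comp, plasma_pool_M5=5.0)
            r1 = vk.fit(obs, spec1)
            nested_start = r1.params.to_dict()
            nested_start.update({"L_7_5": 1e-3, "L_5_7": 0.2})
            r2a = vk.fit(obs, spec2, start=nested_start)
            r2b = vk.fit(obs, spec2)
            r2 = r2a if r2a.wss < r2b.wss else r2b
            if vk.f_test(r1, r2)["p"] < 0.05:
                n_sig += 1
        assert n_sig > 10
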