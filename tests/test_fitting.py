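"""Weighted least-squares fitting: forward model, residuals, recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ferrodyn import (
    FitSpec,
    ModelState,
    ObservationModel,
    TimecourseDataset,
    TimecourseFitter,
    fit,
    predict_observables,
    residuals,
)
from ferrodyn.fitting import compute_weights


@pytest.fixture()
def obs():
    return ObservationModel(ros_scale=1.0, ros_baseline=0.2)


class TestPredictObservables:
    def test_no_death_means_no_dead_signal(self, canonical, obs):
        p = canonical.with_(beta=0.0)
        pred = predict_observables(p, obs, ModelState(n=0.3, r=0.0), np.arange(0, 50, 2.0))
        np.testing.assert_allclose(pred["dead_per_confluence"], 0.0, atol=1e-12)

    def test_no_ros_production_keeps_ratio_at_baseline(self, canonical, obs):
        p = canonical.with_(a=0.0, c=0.0)
        pred = predict_observables(p, obs, ModelState(n=0.3, r=0.0), np.arange(0, 50, 2.0))
        np.testing.assert_allclose(pred["lipid_ros_ratio"], obs.ros_baseline, atol=1e-10)

    def test_initial_confluence_exact(self, canonical, obs):
        pred = predict_observables(canonical, obs, ModelState(n=0.37, r=0.0), [0.0, 2.0])
        assert pred["confluence_pct"].iloc[0] == pytest.approx(37.0, abs=1e-9)

    def test_dead_signal_is_cumulative(self, canonical, obs):
        """The dead-cell dye marks cells once; the integrated signal never decreases."""
        pred = predict_observables(canonical, obs, ModelState(n=0.2, r=0.0), np.arange(0, 100, 2.0))
        dead_area = pred["dead_per_confluence"] * pred["confluence_pct"] / 100
        assert np.all(np.diff(dead_area) >= -1e-10)


class TestResiduals:
    def test_zero_on_self_generated_data(self, noiseless_md):
        res = residuals(
            noiseless_md.true_params["MD"], noiseless_md.observation, noiseless_md.noiseless
        )
        # data generated at rtol 1e-8, residual path at 1e-7; confluence is
        # on a 0-100 scale, so agreement to ~1e-5 absolute is solver-exact
        assert np.max(np.abs(res)) < 1e-4

    def test_linear_in_weights(self, noisy_md):
        ds = noisy_md.noisy
        w = compute_weights(ds)
        r1 = residuals(noisy_md.true_params["MD"], noisy_md.observation, ds, w)
        r2 = residuals(noisy_md.true_params["MD"], noisy_md.observation, ds, 2.0 * w)
        np.testing.assert_allclose(r2, 2.0 * r1, rtol=1e-12)

    def test_rss_matches_naive_loop(self, noisy_md):
        """Vectorised objective equals a record-by-record brute-force sum."""
        ds = noisy_md.noisy
        w = compute_weights(ds)
        p = noisy_md.true_params["MD"]
        obs = noisy_md.observation
        res = residuals(p, obs, ds, w)
        rss = float(np.sum(res**2))

        from ferrodyn.fitting import _default_inits

        init = _default_inits(ds, {"MD": obs})["MD"]
        times = np.unique(ds.records["time_h"])
        pred = predict_observables(p, obs, init, times).set_index("time_h")
        naive = 0.0
        for row, wi in zip(ds.records.itertuples(), w):
            naive += (wi * (row.value - pred.loc[row.time_h, row.observable])) ** 2
        assert rss == pytest.approx(naive, rel=1e-10)

    def test_unknown_observable_rejected(self):
        df = pd.DataFrame(
            {
                "condition": ["c"] * 4,
                "replicate": [1] * 4,
                "time_h": [0.0, 2.0, 0.0, 2.0],
                "observable": ["confluence_pct"] * 2 + ["bogus"] * 2,
                "value": [10.0, 11.0, 1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="bogus"):
            TimecourseDataset(df)


class TestFit:
    def test_noiseless_recovery_within_five_percent(self, noiseless_md):
        spec = FitSpec(free=("alpha", "K", "beta", "r0"), multistart=4, seed=0)
        result = fit(noiseless_md.noiseless, spec)
        true = noiseless_md.true_params["MD"]
        for name, est in result.shared.items():
            assert est == pytest.approx(getattr(true, name), rel=0.05), name

    def test_joint_fit_recovers_threshold_contrast(self, joint_control_rsl3):
        """r0 fitted per condition: GPX4 inhibition must come out lower."""
        spec = FitSpec(
            free=("alpha", "K", "beta", "r0"), condition_specific=("r0",),
            multistart=4, seed=5,
        )
        result = fit(joint_control_rsl3.noisy, spec)
        assert result.per_condition["RSL3"]["r0"] < result.per_condition["control"]["r0"]

    def test_reported_rss_equals_recomputed(self, noisy_md):
        spec = FitSpec(free=("alpha", "K"), multistart=2, seed=1)
        fitter = TimecourseFitter(free=spec.free, multistart=2, seed=1)
        fitter.fit(noisy_md.noisy)
        res = residuals(
            fitter.params_, fitter.observation_, noisy_md.noisy,
            fitter.weights_, fitter.init_states_,
        )
        assert fitter.rss_ == pytest.approx(float(np.sum(res**2)), rel=1e-8)

    def test_same_seed_reproduces_bit_identically(self, noisy_md):
        spec = FitSpec(free=("alpha", "K"), multistart=3, seed=7)
        a = fit(noisy_md.noisy, spec)
        b = fit(noisy_md.noisy, spec)
        assert a.shared == b.shared
        assert a.rss == b.rss

    def test_confounded_parameters_refused(self):
        with pytest.raises(ValueError, match="confounded"):
            FitSpec(free=("a", "ros_scale"))

    def test_condition_specific_must_be_free(self):
        with pytest.raises(ValueError):
            FitSpec(free=("alpha",), condition_specific=("r0",))


class TestEstimatorContract:
    def test_get_set_params_and_clone(self):
        est = TimecourseFitter(free=("alpha", "K"), multistart=3, seed=9)
        params = est.get_params()
        assert params["multistart"] == 3
        cloned = clone(est)
        assert cloned.get_params()["seed"] == 9
        est.set_params(seed=1)
        assert est.seed == 1

    def test_predict_requires_fit(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            TimecourseFitter().predict([0.0, 2.0])

    def test_predict_returns_fitted_curves(self, noiseless_md):
        fitter = TimecourseFitter(free=("alpha", "K", "beta", "r0"), multistart=2, seed=0)
        fitter.fit(noiseless_md.noiseless)
        pred = fitter.predict(np.arange(0, 20, 2.0))
        assert set(pred["condition"]) == {"MD"}
        obs_cols = {"confluence_pct", "lipid_ros_ratio", "dead_per_confluence"}
        assert obs_cols <= set(pred.columns)
        # fitted curve starts at the initial condition taken from the data
        assert pred["confluence_pct"].iloc[0] == pytest.approx(44.0, rel=1e-6)
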