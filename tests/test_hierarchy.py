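"""Bayesian mixed-model calibration fit and posterior summaries."""

import numpy as np
import pandas as pd
import pytest

from proxcal import ALL_STRATA, GeneratorTruth, hierarchy, synthetic
from proxcal.hierarchy import McmcSettings, PosteriorSummary, build_response
from proxcal.propagation import directivity_db


class TestBuildResponse:
    @pytest.mark.parametrize(
        "rssi,r,expected", [(-2.0, 10.0, 18.0), (5.0, 1.0, 5.0)]
    )
    def test_values(self, rssi, r, expected):
        assert build_response(rssi, r) == pytest.approx(expected)

    def test_rejects_non_positive_distance(self):
        with pytest.raises(ValueError):
            build_response(1.0, 0.0)

    def test_inverts_spreading_term(self, rng, default_params):
        # y - (kappa + beta r + gamma delta) == 0 identically when rssi is
        # the deterministic model prediction
        from proxcal.propagation import expected_rssi

        params = default_params[ALL_STRATA[0]]
        for _ in range(50):
            r = float(rng.uniform(0.5, 30))
            theta, phi = rng.uniform(0, 360, 2)
            delta = directivity_db(theta, phi)
            rssi = expected_rssi(r, params, delta)
            y = build_response(rssi, r)
            assert y - (params.kappa + params.beta * r + params.gamma * delta) == (
                pytest.approx(0.0, abs=1e-10)
            )


class TestMcmcSettings:
    def test_default_schedule_retains_5000(self):
        assert McmcSettings().n_retained == 5000

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcSettings(thin=0)


class TestSummarize:
    def test_known_normal(self):
        rng = np.random.default_rng(1)
        samples = {"x": rng.normal(3.0, 1.0, 5000)}
        summ = hierarchy.summarize(samples)
        assert summ.mode("x") == pytest.approx(3.0, abs=0.1)
        lo, hi = summ.interval("x")
        assert lo == pytest.approx(3 - 1.959964, abs=0.1)
        assert hi == pytest.approx(3 + 1.959964, abs=0.1)

    def test_constant_samples(self):
        summ = hierarchy.summarize({"x": np.full(200, 2.5)})
        assert summ.mode("x") == 2.5
        assert summ.interval("x") == (2.5, 2.5)

    def test_mode_within_interval(self):
        rng = np.random.default_rng(2)
        samples = {"x": rng.exponential(2.0, 3000)}
        summ = hierarchy.summarize(samples)
        lo, hi = summ.interval("x")
        assert lo <= summ.mode("x") <= hi

    def test_perfectly_correlated_send_receive(self):
        v = np.abs(np.random.default_rng(3).normal(1.0, 0.1, 500))
        samples = {
            "var_send": v,
            "var_receive": v,
            "cov_send_receive": v,  # cov = sqrt(vs * vr) exactly
        }
        summ = hierarchy.summarize(samples)
        np.testing.assert_allclose(summ.samples["corr_send_receive"], 1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="100"):
            hierarchy.summarize({"x": np.arange(50.0)})


class TestPredictionBand:
    def _summary(self, total_var: float) -> PosteriorSummary:
        stratum = ALL_STRATA[0]
        rows = [
            (f"kappa:{stratum.label}", 22.0, 21.0, 23.0),
            (f"beta:{stratum.label}", -0.6, -0.7, -0.5),
            ("gamma", 1.0, 0.9, 1.1),
            ("var_send", total_var / 4, 0.0, 1.0),
            ("var_receive", total_var / 4, 0.0, 1.0),
            (f"var_exchange:{stratum.label}", total_var / 4, 0.0, 1.0),
            ("var_replicate", 0.0, 0.0, 0.0),
            ("var_residual", total_var / 4, 0.0, 1.0),
        ]
        return PosteriorSummary(
            table=pd.DataFrame(rows, columns=["name", "mode", "lower", "upper"])
        )

    def test_zero_variance_collapses_to_mean(self):
        summ = self._summary(0.0)
        lo, hi = hierarchy.prediction_band(5.0, ALL_STRATA[0], 0.0, summ)
        assert lo == hi
        assert lo == pytest.approx(22.0 - 3.0 - 20 * np.log10(5.0))

    def test_width_closed_form(self):
        summ = self._summary(4.0)
        for r in (0.5, 2.0, 10.0, 25.0):
            lo, hi = hierarchy.prediction_band(r, ALL_STRATA[0], -2.5, summ)
            assert hi - lo == pytest.approx(2 * 1.959964 * 2.0, abs=1e-4)

    def test_edges_monotone_decreasing(self):
        summ = self._summary(4.0)
        r = np.linspace(0.5, 30, 100)
        lo, hi = hierarchy.prediction_band(r, ALL_STRATA[0], 0.0, summ)
        assert np.all(np.diff(lo) < 0)
        assert np.all(np.diff(hi) < 0)

    def test_unknown_stratum_rejected(self):
        summ = self._summary(1.0)
        with pytest.raises(ValueError, match="not in fitted model"):
            hierarchy.prediction_band(5.0, ALL_STRATA[9], 0.0, summ)


def _tiny_noise_fit(default_params, two_strata, seed=0):
    truth = GeneratorTruth(
        params=default_params, var_send=0.0, var_receive=0.0,
        cov_send_receive=0.0, var_replicate=0.0, var_residual=0.01,
    )
    designs = [
        synthetic.build_array(12, stratum=s, trial_id=i)
        for i, s in enumerate(two_strata)
    ]
    obs = synthetic.simulate_calibration(designs, truth, 2, seed=seed)
    settings = McmcSettings(n_iterations=1600, burn_in=400, thin=2, seed=seed + 1)
    return obs, hierarchy.fit(obs, settings=settings)


class TestFit:
    def test_zero_variance_recovery(self, default_params, two_strata):
        # with (almost) no noise the posterior must sit on the generating
        # coefficients: modes within 3 posterior SDs of truth
        _, summ = _tiny_noise_fit(default_params, two_strata)
        for s in two_strata:
            for prefix, truth_val in (
                ("kappa", default_params[s].kappa),
                ("beta", default_params[s].beta),
            ):
                name = f"{prefix}:{s.label}"
                sd = float(np.std(summ.samples[name]))
                assert summ.mode(name) == pytest.approx(truth_val, abs=3 * sd + 1e-6)
        sd = float(np.std(summ.samples["gamma"]))
        assert summ.mode("gamma") == pytest.approx(1.0, abs=3 * sd + 1e-6)

    def test_retained_sample_count_honoured(self, small_calibration):
        settings = McmcSettings(n_iterations=700, burn_in=200, thin=5, seed=4)
        summ = hierarchy.fit(small_calibration, settings=settings)
        assert all(len(v) == settings.n_retained for v in summ.samples.values())

    def test_reproducible_under_seed(self, small_calibration):
        settings = McmcSettings(n_iterations=400, burn_in=100, thin=3, seed=12)
        a = hierarchy.fit(small_calibration, settings=settings)
        b = hierarchy.fit(small_calibration, settings=settings)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_rank_deficient_design_reported(self):
        # a single distance makes the intercept and slope columns
        # collinear; the failure must name the confounded terms
        n = 40
        rng = np.random.default_rng(0)
        obs = pd.DataFrame(
            {
                "sender_id": rng.integers(0, 4, n),
                "receiver_id": rng.integers(4, 8, n),
                "r": 5.0,
                "theta": rng.uniform(0, 180, n),
                "phi": rng.uniform(0, 180, n),
                "habitat": "fig",
                "height": "ground",
                "trial_id": 0,
                "replicate_id": "a",
                "rssi": rng.normal(0, 1, n),
            }
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            hierarchy.fit(obs, settings=McmcSettings(n_iterations=10, burn_in=1))

    def test_too_few_tags_rejected(self):
        obs = pd.DataFrame(
            {
                "sender_id": [1] * 5,
                "receiver_id": [1] * 5,
                "r": np.linspace(1, 5, 5),
                "theta": 0.0,
                "phi": 90.0,
                "habitat": "fig",
                "height": "ground",
                "trial_id": 0,
                "replicate_id": "a",
                "rssi": 0.0,
            }
        )
        with pytest.raises(ValueError, match="2 distinct tags"):
            hierarchy.fit(obs)

    def test_shift_equivariance(self, default_params, two_strata):
        # adding c dB to every RSSI shifts the kappa posteriors by c and
        # leaves slopes and gamma unchanged (within MC error)
        obs, base = _tiny_noise_fit(default_params, two_strata, seed=21)
        shifted_obs = obs.copy()
        shifted_obs["rssi"] = shifted_obs["rssi"] + 7.0
        settings = McmcSettings(n_iterations=1600, burn_in=400, thin=2, seed=22)
        shifted = hierarchy.fit(shifted_obs, settings=settings)
        for s in two_strata:
            dk = shifted.mode(f"kappa:{s.label}") - base.mode(f"kappa:{s.label}")
            assert dk == pytest.approx(7.0, abs=0.1)
            db = shifted.mode(f"beta:{s.label}") - base.mode(f"beta:{s.label}")
            assert db == pytest.approx(0.0, abs=0.05)
        assert shifted.mode("gamma") == pytest.approx(base.mode("gamma"), abs=0.1)

    def test_fixed_effects_match_ols_cross_check(self, default_params, two_strata):
        # independent route: with only residual noise, the mixed model's
        # fixed-effect posterior means must agree with an ordinary
        # least-squares fit of y on the same design (statsmodels)
        import statsmodels.api as sm

        from proxcal.propagation import directivity_db

        truth = GeneratorTruth(
            params=default_params, var_send=0.0, var_receive=0.0,
            cov_send_receive=0.0, var_replicate=0.0, var_residual=1.0,
        )
        designs = [
            synthetic.build_array(12, stratum=s, trial_id=i)
            for i, s in enumerate(two_strata)
        ]
        obs = synthetic.simulate_calibration(designs, truth, 4, seed=55)
        settings = McmcSettings(n_iterations=4000, burn_in=1000, thin=5, seed=56)
        summ = hierarchy.fit(obs, settings=settings)

        y = build_response(obs["rssi"].to_numpy(), obs["r"].to_numpy())
        cols = {}
        for s in two_strata:
            in_s = ((obs["habitat"] == s.habitat) & (obs["height"] == s.height.value)).to_numpy(float)
            cols[f"kappa:{s.label}"] = in_s
            cols[f"beta:{s.label}"] = in_s * obs["r"].to_numpy()
        cols["gamma"] = np.asarray(directivity_db(obs["theta"], obs["phi"]))
        X = pd.DataFrame(cols)
        ols = sm.OLS(y, X).fit()
        for name in X.columns:
            post_mean = float(np.mean(summ.samples[name]))
            sd = max(float(np.std(summ.samples[name])), 1e-3)
            assert post_mean == pytest.approx(ols.params[name], abs=3 * sd)

    def test_residual_variance_error_shrinks_with_n(self, default_params):
        # posterior mean of the residual variance approaches the
        # generating value as the dataset grows
        truth = GeneratorTruth(
            params=default_params, var_send=0.0, var_receive=0.0,
            cov_send_receive=0.0, var_replicate=0.0, var_residual=4.0,
        )
        errs = []
        for pulses in (2, 16):
            design = synthetic.build_array(12, stratum=ALL_STRATA[0])
            obs = synthetic.simulate_calibration(design, truth, pulses, seed=31)
            settings = McmcSettings(n_iterations=1200, burn_in=300, thin=2, seed=32)
            summ = hierarchy.fit(obs, settings=settings)
            errs.append(abs(float(np.mean(summ.samples["var_residual"])) - 4.0))
        assert errs[1] < errs[0]
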