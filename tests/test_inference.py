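"""Inference tests: measurement-error model, directional and default BFs."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pupilbayes.inference import (
    BDI_ITEM_LABELS,
    McmcSettings,
    NoisyPairData,
    PriorSpec,
    bf10_pearson,
    bf10_ttest,
    bf_directional,
    evidence_label,
    fit_latent_correlation,
    measurement_se,
    residualize,
    run_item_screen,
)

from _oracles import bf10_pearson_quadrature, bf10_ttest_quadrature


class TestMeasurementSE:
    @pytest.mark.parametrize(
        "sd,rel,expected",
        [
            (1.0, 0.87, 0.36055512754639896),  # pupil split-half plug-in
            (1.0, 1.0, 0.0),
            (2.0, 0.78, 2.0 * np.sqrt(0.22)),  # interview test-retest plug-in
            (0.0, 0.5, 0.0),
        ],
    )
    def test_values(self, sd, rel, expected):
        assert measurement_se(sd, rel) == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        with pytest.raises(ValueError):
            measurement_se(1.0, 1.2)
        with pytest.raises(ValueError):
            measurement_se(-1.0, 0.5)


class TestDirectionalBF:
    def test_half_and_half(self):
        samples = np.concatenate([-np.ones(500), np.ones(500)])
        assert bf_directional(samples) == (1.0, False)

    def test_counting_ratio(self):
        samples = np.concatenate([-np.ones(2999), np.ones(1)])
        bf, lower = bf_directional(samples)
        assert bf == 2999.0 and not lower

    def test_lower_bound_convention(self):
        bf, lower = bf_directional(-np.abs(np.random.default_rng(0).normal(size=20000)) - 0.01)
        assert bf == 20000.0 and lower

    def test_positive_direction_symmetric(self):
        samples = np.concatenate([-np.ones(100), np.ones(300)])
        assert bf_directional(samples, direction=1) == (3.0, False)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            bf_directional(np.array([]))

    def test_monotone_in_negative_mass(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=10000)
        bfs = []
        for shift in (0.0, -0.2, -0.5, -1.0, -2.0):
            bfs.append(bf_directional(base + shift)[0])
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))


class TestPearsonBF:
    @pytest.mark.parametrize("n", [10, 20, 50, 136])
    def test_null_r_favours_null(self, n):
        assert bf10_pearson(r=0.0, n=n).bf10 < 1.0

    @pytest.mark.parametrize("n,r", [(20, 0.6), (50, -0.4), (136, -0.26), (10, 0.3)])
    def test_quadrature_oracle(self, n, r):
        assert bf10_pearson(r=r, n=n).bf10 == pytest.approx(
            bf10_pearson_quadrature(r, n), rel=0.01
        )

    @pytest.mark.parametrize("n,r", [(20, 0.6), (136, -0.26), (70, -0.1)])
    def test_matches_pingouin_closed_form(self, n, r):
        pingouin = pytest.importorskip("pingouin")
        assert bf10_pearson(r=r, n=n).bf10 == pytest.approx(
            float(pingouin.bayesfactor_pearson(r, n)), rel=0.005
        )

    def test_perfect_correlation_capped(self):
        x = np.arange(10.0)
        res = bf10_pearson(x, x)
        assert res.capped and res.bf10 >= 1e12

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            bf10_pearson(np.ones(10), np.arange(10.0))

    def test_data_and_stat_paths_agree(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = bf10_pearson(x, y)
        res2 = bf10_pearson(r=res.statistic, n=30)
        assert res.bf10 == pytest.approx(res2.bf10, rel=1e-9)


class TestTTestBF:
    def test_identical_groups_favour_null(self):
        assert bf10_ttest(t=0.0, n1=30, n2=30).bf10 < 1.0

    @pytest.mark.parametrize("t,n1,n2", [(2.0, 30, 30), (3.5, 50, 50), (-1.2, 20, 25)])
    def test_quadrature_oracle(self, t, n1, n2):
        assert bf10_ttest(t=t, n1=n1, n2=n2).bf10 == pytest.approx(
            bf10_ttest_quadrature(t, n1, n2), rel=0.01
        )

    @pytest.mark.parametrize("t,n1,n2", [(2.0, 30, 30), (1.46, 30, 20)])
    def test_matches_pingouin(self, t, n1, n2):
        pingouin = pytest.importorskip("pingouin")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = float(pingouin.bayesfactor_ttest(t, n1, n2, paired=False))
        assert bf10_ttest(t=t, n1=n1, n2=n2).bf10 == pytest.approx(ref, rel=0.01)

    def test_large_effect_always_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            a = rng.normal(2.0, 1.0, 50)
            b = rng.normal(0.0, 1.0, 50)
            if bf10_ttest(a, b).bf10 > 100:
                hits += 1
        assert hits == 20

    def test_zero_pooled_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            bf10_ttest(np.ones(5), np.ones(5))


class TestLatentCorrelation:
    def _noisy_pairs(self, n, rho, seed, se_x=0.05, se_y=1.5):
        rng = np.random.default_rng(seed)
        cov = [[0.01, rho * 0.1 * 3.0], [rho * 0.1 * 3.0, 9.0]]
        lat = rng.multivariate_normal([0.2, 7.0], cov, size=n)
        x = lat[:, 0] + rng.normal(0, se_x, n)
        y = lat[:, 1] + rng.normal(0, se_y, n)
        return NoisyPairData(x=x, y=y, se_x=se_x, se_y=se_y)

    def test_null_data_centred_posterior(self):
        data = self._noisy_pairs(200, 0.0, seed=0, se_x=0.0, se_y=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_latent_correlation(data, settings=McmcSettings.reduced(), seed=1)
        assert abs(post.rho_mean) < 0.08

    def test_scale_equivariance(self):
        data = self._noisy_pairs(70, -0.5, seed=4)
        scaled = NoisyPairData(x=100.0 * data.x, y=data.y, se_x=100.0 * data.se_x, se_y=data.se_y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_latent_correlation(data, settings=McmcSettings.reduced(), seed=2)
            b = fit_latent_correlation(scaled, settings=McmcSettings.reduced(), seed=2)
        assert a.rho_mean == pytest.approx(b.rho_mean, abs=0.02)

    def test_deterministic_given_seed(self):
        data = self._noisy_pairs(40, -0.4, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_latent_correlation(data, settings=McmcSettings.reduced(), seed=3)
            b = fit_latent_correlation(data, settings=McmcSettings.reduced(), seed=3)
        assert a.rho_mean == b.rho_mean
        np.testing.assert_array_equal(a.rho_samples, b.rho_samples)

    def test_prior_widening_warns(self):
        rng = np.random.default_rng(6)
        data = NoisyPairData(
            x=rng.normal(5.0, 1.0, 30),  # outside the (-2, 2) location prior
            y=rng.normal(10.0, 2.0, 30),
            se_x=0.1,
            se_y=0.5,
        )
        with pytest.warns(UserWarning, match="widening"):
            fit_latent_correlation(data, settings=McmcSettings.reduced(), seed=0)

    def test_diagnostics_reported(self):
        data = self._noisy_pairs(50, -0.3, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_latent_correlation(data, settings=McmcSettings.reduced(), seed=4)
        assert set(post.rhat) == {"mu_x", "sigma_x", "mu_y", "sigma_y", "rho"}
        assert max(post.rhat.values()) <= 1.01
        assert post.ess["rho"] > 200
        assert post.n_chains == 4
        assert -1 <= post.rho_ci95[0] < post.rho_ci95[1] <= 1
        assert np.all(np.abs(post.rho_samples) < 1.0)

    def test_invalid_data_rejected(self):
        with pytest.raises(ValueError):
            NoisyPairData(x=[1.0, 2.0], y=[1.0, 2.0], se_x=0.0, se_y=0.0)
        with pytest.raises(ValueError):
            NoisyPairData(x=[1, 2, 3], y=[1, 2, 3], se_x=-0.1, se_y=0.0)

    def test_prior_spec_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(rho=(1.0, -1.0))


class TestItemScreen:
    def _frames(self, n=40, seed=0, constant_item=None):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        feats = pd.DataFrame(
            {"participant_id": [f"P{i}" for i in range(n)], "diff_reward_minus_control": x}
        )
        clin = {"participant_id": [f"P{i}" for i in range(n)]}
        for j in range(1, 22):
            clin[f"bdi_item_{j:02d}"] = rng.integers(0, 4, n)
        clin["anhedonia_score"] = rng.integers(0, 10, n)
        clin = pd.DataFrame(clin)
        if constant_item:
            clin[constant_item] = 2
        return feats, clin

    def test_always_22_rows(self):
        feats, clin = self._frames()
        screen = run_item_screen(feats, clin)
        assert len(screen) == 22
        assert list(screen["label"][:21]) == list(BDI_ITEM_LABELS)

    def test_constant_item_not_computable(self):
        feats, clin = self._frames(constant_item="bdi_item_07")
        screen = run_item_screen(feats, clin)
        row = screen[screen["item"] == "bdi_item_07"].iloc[0]
        assert not row["computable"] and not row["moderate"]
        assert np.isnan(row["bf10"])


class TestHelpers:
    def test_residualize_removes_linear_trend(self):
        rng = np.random.default_rng(1)
        cov = rng.normal(size=50)
        noise = rng.normal(size=50)
        y = 3.0 + 2.0 * cov + noise
        resid = residualize(y, cov)
        assert abs(np.corrcoef(resid, cov)[0, 1]) < 1e-10
        assert abs(resid.mean()) < 1e-10

    @pytest.mark.parametrize(
        "bf,label",
        [
            (150, "extreme"), (50, "very strong"), (15, "strong"),
            (5, "moderate"), (2, "anecdotal"), (0.5, "anecdotal (null)"),
            (0.1, "favors null"),
        ],
    )
    def test_evidence_bands(self, bf, label):
        assert evidence_label(bf) == label
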