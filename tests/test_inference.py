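"""Cluster permutation, Bayes factors, jackknife onsets, ANOVA, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from tagshift import inference as inf


class TestClusterTest:
    def test_identical_conditions_yield_no_clusters(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 80))
        with pytest.warns(UserWarning, match="zero variance"):
            res = inf.running_cluster_test(x, x, n_perm=100, seed=1)
        assert len(res.clusters) == 0
        assert np.all(res.t_values == 0.0)

    def test_minimum_subjects_enforced(self):
        with pytest.raises(ValueError, match="at least 5"):
            inf.running_cluster_test(np.zeros((4, 10)))

    def test_injected_difference_is_detected(self):
        rng = np.random.default_rng(2)
        times = np.arange(96) / 64.0
        effect = np.where((times >= 0.5) & (times <= 1.0), 1.0, 0.0)
        x = rng.normal(size=(30, 96)) + effect
        res = inf.running_cluster_test(x, times=times, n_perm=500, seed=3)
        sig = res.significant_clusters
        assert len(sig) >= 1
        big = sig.loc[sig["sum_t"].idxmax()]
        assert big["start_ms"] < 600.0 and big["end_ms"] > 900.0
        assert big["p_value"] < 0.01

    def test_permutation_p_bounds(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 50)) + 2.0
        res = inf.running_cluster_test(x, n_perm=200, seed=5)
        p = res.clusters["p_value"]
        assert (p >= 1.0 / 201.0).all()
        assert (p <= 1.0).all()

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 60)) + 0.4
        a = inf.running_cluster_test(x, n_perm=300, seed=7)
        b = inf.running_cluster_test(x, n_perm=300, seed=7)
        pd.testing.assert_frame_equal(a.clusters, b.clusters)

    def test_two_sided_tail_catches_negative_effects(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 60)) - 1.0
        res = inf.running_cluster_test(x, tail="two-sided", n_perm=300, seed=9)
        assert len(res.significant_clusters) >= 1
        res_greater = inf.running_cluster_test(x, tail="greater", n_perm=300, seed=9)
        assert len(res_greater.significant_clusters) == 0

    def test_agrees_with_mne_cluster_boundaries(self):
        """Independent reference: MNE's sign-flip cluster test, same threshold."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(10)
        times = np.arange(100) / 64.0
        x = rng.normal(size=(15, 100)) + np.where((times > 0.4) & (times < 1.0), 0.9, 0)
        res = inf.running_cluster_test(x, times=times, n_perm=500, seed=11)
        thresh = stats.t.ppf(0.95, 14)
        _, clusters, pvals, _ = mne.stats.permutation_cluster_1samp_test(
            x, threshold=thresh, n_permutations=500, tail=1, seed=12, verbose=False
        )
        ours = {(int(c["start_idx"]), int(c["end_idx"])) for _, c in res.clusters.iterrows()}
        theirs = {(int(np.min(c[0])), int(np.max(c[0]))) for c in clusters}
        assert ours == theirs


class TestJZSBayesFactor:
    def test_null_favored_at_t_zero(self):
        assert inf.jzs_bf_from_t(0.0, 30) < 1.0

    def test_matches_independent_quadrature_oracle(self):
        """Oracle: the Liang et al. g-prior integral, an independent route."""
        def oracle(t, n, r=0.71):
            nu = n - 1

            def integrand(g):
                return (
                    (1 + n * g * r**2) ** -0.5
                    * (1 + t**2 / ((1 + n * g * r**2) * nu)) ** (-(nu + 1) / 2)
                    * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g))
                )

            num, _ = integrate.quad(integrand, 0, np.inf, limit=300)
            den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
            return num / den

        for t, n in [(0.0, 30), (1.5, 30), (2.5, 12), (-2.0, 20), (4.5, 8)]:
            assert inf.jzs_bf_from_t(t, n) == pytest.approx(
                oracle(t, n), rel=1e-6
            )

    def test_monotone_in_absolute_t(self):
        ts = np.linspace(0, 5, 11)
        bfs = [inf.jzs_bf_from_t(t, 25) for t in ts]
        assert np.all(np.diff(bfs) > 0)

    def test_bf_at_zero_decreases_with_n(self):
        bfs = [inf.jzs_bf_from_t(0.0, n) for n in (5, 10, 20, 40, 80)]
        assert np.all(np.diff(bfs) < 0)

    def test_paired_interface_and_errors(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        assert inf.jzs_bf_paired(x, y) > 0
        with pytest.raises(ValueError, match="zero-variance"):
            inf.jzs_bf_paired(np.ones(10), np.zeros(10) + 1.0)

    def test_symmetric_in_sign_of_t(self):
        assert inf.jzs_bf_from_t(2.0, 15) == pytest.approx(
            inf.jzs_bf_from_t(-2.0, 15), rel=1e-9
        )


class TestRunningBF:
    def test_mask_is_definitional(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(30, 25))
        y = rng.normal(size=(30, 25))
        tc = inf.running_bf(x, y)
        assert np.array_equal(tc.null_mask, tc.bf10 < 0.33)

    def test_identical_conditions_mostly_favor_null(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(30, 40))
        y = x + rng.normal(size=(30, 40)) * 0.5
        tc = inf.running_bf(x, y)
        assert tc.null_mask.mean() > 0.5

    def test_sustained_difference_gives_strong_evidence(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=(30, 20)) + 1.5
        y = rng.normal(size=(30, 20))
        tc = inf.running_bf(x, y)
        assert (tc.bf10 > 3.0).all()


class TestJackknifeOnsets:
    times = np.linspace(0.0, 1.5, 97)

    def _ramp(self, onset_ms, plateau=30.0, rise_ms=120.0):
        t = self.times * 1000.0
        start = onset_ms - 0.85 * rise_ms
        return plateau * np.clip((t - start) / rise_ms, 0.0, 1.0)

    def test_identical_traces_give_grand_onset_everywhere(self):
        x = np.tile(self._ramp(400.0), (12, 1))
        est = inf.jackknife_onsets(x, self.times)
        assert est.grand_onset_ms == pytest.approx(400.0, abs=2.0)
        assert np.allclose(est.subsample_onsets_ms, est.grand_onset_ms)
        assert np.allclose(est.individual_onsets_ms, est.grand_onset_ms)

    def test_smulders_back_transform_identity(self):
        rng = np.random.default_rng(17)
        x = self._ramp(400.0) + rng.normal(size=(10, 97)) * 3.0
        est = inf.jackknife_onsets(x, self.times)
        n = est.n
        recon = n * est.grand_onset_ms - (n - 1) * est.subsample_onsets_ms
        assert np.allclose(est.individual_onsets_ms, recon)

    def test_onset_recovery_with_noise(self):
        rng = np.random.default_rng(18)
        x = self._ramp(400.0) + rng.normal(size=(30, 97)) * 5.0
        est = inf.jackknife_onsets(x, self.times)
        assert np.nanmean(est.individual_onsets_ms) == pytest.approx(400.0, abs=40.0)

    def test_criterion_never_reached_aborts(self):
        x = np.zeros((10, 97))
        x[:, -1] = 1e-12
        with pytest.raises(ValueError):
            inf.jackknife_onsets(np.zeros((10, 97)) - 1.0, self.times)

    def test_onset_difference_detected_by_paired_test(self):
        rng = np.random.default_rng(19)
        a = self._ramp(350.0) + rng.normal(size=(30, 97)) * 4.0
        b = self._ramp(700.0) + rng.normal(size=(30, 97)) * 4.0
        res = inf.compare_onsets(
            inf.jackknife_onsets(a, self.times), inf.jackknife_onsets(b, self.times)
        )
        assert res["p_value"] < 0.05
        assert res["mean_diff_ms"] < 0


class TestWindowContrasts:
    times = np.linspace(0.0, 1.5, 97)

    def _traces(self, rng, gains):
        return {
            c: rng.normal(size=(20, 97)) * 2.0 + g for c, g in gains.items()
        }

    def test_identical_conditions_give_t_zero_and_null_support(self):
        rng = np.random.default_rng(20)
        base = rng.normal(size=(30, 97))
        traces = {
            "cued": base, "cued_match": base.copy(),
            "uncued": rng.normal(size=(30, 97)),
            "uncued_non_match": rng.normal(size=(30, 97)),
            "uncued_match": rng.normal(size=(30, 97)),
        }
        res = inf.window_contrasts(traces, self.times)
        row = res[res["contrast"] == "cued_vs_cued_match"].iloc[0]
        assert row["t"] == 0.0
        assert np.isnan(row["bf10"]) or row["bf10"] < 1.0

    def test_feature_effect_yields_positive_t(self):
        rng = np.random.default_rng(21)
        traces = self._traces(rng, {
            "cued": 30.0, "cued_match": 30.0, "uncued_match": 18.0,
            "uncued_non_match": 7.0, "uncued": 12.0,
        })
        res = inf.window_contrasts(traces, self.times).set_index("contrast")
        assert res.loc["uncued_match_vs_uncued", "t"] > 2.0
        assert res.loc["uncued_match_vs_uncued", "p_value"] < 0.05

    def test_window_outside_analysis_raises(self):
        rng = np.random.default_rng(22)
        traces = self._traces(rng, {c: 0.0 for c in (
            "cued", "cued_match", "uncued_match", "uncued_non_match", "uncued")})
        with pytest.raises(ValueError, match="window"):
            inf.window_contrasts(traces, self.times, window=(1.0, 2.0))


class TestRmAnova:
    def test_identical_levels_give_f_zero(self):
        rng = np.random.default_rng(23)
        arr = np.tile(rng.normal(size=(8, 1)), (1, 4))
        res = inf.rm_anova(arr)
        assert res.loc[0, "F"] == 0.0

    def test_two_level_factor_has_epsilon_one(self):
        rng = np.random.default_rng(24)
        res = inf.rm_anova(rng.normal(size=(10, 2)))
        assert res.loc[0, "eps"] == pytest.approx(1.0)

    def test_matches_statsmodels_and_hand_gg_epsilon(self):
        """Independent oracle: statsmodels AnovaRM F plus hand-computed epsilon."""
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(25)
        k, n = 4, 12
        data = rng.normal(size=(n, k)) + np.linspace(0, 1, k)
        res = inf.rm_anova(data)

        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "level": np.tile([f"l{i}" for i in range(k)], n),
            "value": data.ravel(),
        })
        sm = AnovaRM(long, "value", "subject", within=["level"]).fit()
        f_oracle = float(sm.anova_table["F Value"].iloc[0])
        assert res.loc[0, "F"] == pytest.approx(f_oracle, rel=1e-6)

        # Greenhouse-Geisser epsilon from the double-centered covariance
        s = np.cov(data, rowvar=False)
        sc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
        eig = np.linalg.eigvalsh(sc)
        eps_oracle = eig.sum() ** 2 / ((k - 1) * (eig**2).sum())
        assert res.loc[0, "eps"] == pytest.approx(eps_oracle, rel=1e-6)

        p_oracle = stats.f.sf(f_oracle, eps_oracle * (k - 1), eps_oracle * (k - 1) * (n - 1))
        assert res.loc[0, "p_GG_corr"] == pytest.approx(p_oracle, rel=1e-6)

    def test_two_way_band_by_frequency_layout(self):
        rng = np.random.default_rng(26)
        n = 10
        rows = []
        for s in range(n):
            for band in ("peak", "side"):
                for f in (18, 21, 24, 27):
                    rows.append({
                        "subject": s, "band": band, "freq": str(f),
                        "value": rng.normal() + (2.0 if band == "peak" else 0.0),
                    })
        res = inf.rm_anova(
            pd.DataFrame(rows), dv="value", within=["band", "freq"], subject="subject"
        )
        assert set(res["Source"]) == {"band", "freq", "band * freq"}
        assert res.set_index("Source").loc["band", "p_unc"] < 0.001

    def test_missing_cells_raise(self):
        df = pd.DataFrame({
            "subject": [0, 0, 1], "level": ["a", "b", "a"], "value": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="balanced"):
            inf.rm_anova(df, dv="value", within="level", subject="subject")


class TestHolm:
    def test_single_p_unchanged(self):
        assert inf.holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_down(self):
        # sorted .01,.03,.04 -> x3, x2, x1 -> .03,.06,.04 -> monotone .03,.06,.06
        out = inf.holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(out, [0.03, 0.06, 0.06])

    def test_equal_ps_multiply_by_m_and_cap(self):
        assert np.allclose(inf.holm_adjust([0.2, 0.2, 0.2]), [0.6, 0.6, 0.6])
        assert np.allclose(inf.holm_adjust([0.5, 0.5, 0.5]), [1.0, 1.0, 1.0])

    def test_order_invariance(self):
        p = [0.04, 0.001, 0.2, 0.012]
        a = inf.holm_adjust(p)
        order = np.argsort(p)
        b = inf.holm_adjust(np.asarray(p)[order])
        assert np.allclose(a[order], b)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            inf.holm_adjust([0.5, 1.2])


class TestPower:
    def test_reference_sample_size_is_27(self):
        assert inf.apriori_n(0.66, power=0.9, alpha=0.05, tails=2) == 27

    def test_huge_effect_gives_minimum_n(self):
        assert inf.apriori_n(100.0, power=0.9) == 2

    def test_bracketing_by_direct_noncentral_t(self):
        """Returned n reaches the target and n-1 does not (definitional)."""
        for d, power in [(0.66, 0.9), (0.5, 0.8), (0.3, 0.95)]:
            n = inf.apriori_n(d, power=power)

            def direct(n_):
                df = n_ - 1
                crit = stats.t.ppf(0.975, df)
                nc = d * np.sqrt(n_)
                return 1 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)

            assert direct(n) >= power
            if n > 2:
                assert direct(n - 1) < power

    def test_one_tailed_needs_fewer_subjects(self):
        assert inf.apriori_n(0.66, tails=1) < inf.apriori_n(0.66, tails=2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inf.apriori_n(-1.0)
        with pytest.raises(ValueError):
            inf.apriori_n(0.5, power=1.5)
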