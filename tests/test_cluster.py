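"""Sliding OLS, cluster formation, permutation p-values, and FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from cogdbs.cluster import (
    Cluster,
    SingleTrialRegression,
    apply_fdr,
    cluster_mass_fraction,
    design_from_trials,
    fdr_stepdown,
    form_clusters,
    permutation_cluster_test,
    sliding_ols,
    subject_demean,
)

SFREQ = 1450.0 / 3.0


class TestDesign:
    def test_unit_interval_scaling(self):
        meta = pd.DataFrame({"valence": [1.0, 5.0, 9.0], "arousal": [2.0, 2.0, 4.0]})
        X = design_from_trials(meta, ["valence", "arousal"])
        np.testing.assert_allclose(X["valence"], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(X["arousal"], [0.0, 0.0, 1.0])

    def test_binary_text_dummy(self):
        meta = pd.DataFrame({"dbs": ["OFF", "ON", "ON"]})
        X = design_from_trials(meta, ["dbs"])
        np.testing.assert_array_equal(X["dbs"], [0.0, 1.0, 1.0])

    def test_interaction_is_product(self):
        meta = pd.DataFrame(
            {"interference": [0, 1, 1, 0], "dbs": ["ON", "ON", "OFF", "OFF"]}
        )
        X = design_from_trials(meta, ["interference", "dbs", "interference:dbs"])
        np.testing.assert_allclose(
            X["interference:dbs"], X["interference"] * X["dbs"]
        )

    def test_constant_column_maps_to_zero(self):
        meta = pd.DataFrame({"trial": [3, 3, 3]})
        X = design_from_trials(meta, ["trial"])
        np.testing.assert_array_equal(X["trial"], 0.0)

    def test_multilevel_text_rejected(self):
        meta = pd.DataFrame({"dbs": ["ON", "OFF", "SHAM"]})
        with pytest.raises(ValueError, match="levels"):
            design_from_trials(meta, ["dbs"])


class TestSubjectDemean:
    def test_means_removed(self, rng):
        data = rng.normal(size=(20, 30))
        subj = np.repeat(["A", "B"], 10)
        out = subject_demean(data, subj)
        for s in ("A", "B"):
            np.testing.assert_allclose(out[subj == s].mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        data = rng.normal(size=(12, 5))
        subj = np.repeat(["A", "B", "C"], 4)
        once = subject_demean(data, subj)
        np.testing.assert_allclose(subject_demean(once, subj), once, atol=1e-12)

    def test_contrasts_preserved(self, rng):
        # demeaning removes between-subject offsets but not within-subject
        # condition differences
        data = rng.normal(size=(20, 1))
        cond = np.tile([0, 1], 10)
        data[cond == 1] += 5.0
        subj = np.repeat(["A", "B"], 10)
        out = subject_demean(data, subj)
        diff = out[cond == 1].mean() - out[cond == 0].mean()
        raw = data[cond == 1].mean() - data[cond == 0].mean()
        assert diff == pytest.approx(raw, abs=1e-12)


class TestSlidingOls:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 30)
        data = np.outer(2.0 + 3.0 * x, np.ones(10))
        design = pd.DataFrame({"x": x})
        beta, t = sliding_ols(data, design)
        np.testing.assert_allclose(beta[0], 3.0, atol=1e-10)

    def test_matches_hand_computed_ols(self):
        # 6-trial fixture checked against the closed-form two-variable OLS
        x = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        y = np.array([1.0, 1.5, 1.3, 2.4, 2.1, 3.0])
        design = pd.DataFrame({"x": x})
        beta, t = sliding_ols(y[:, None], design)
        res = sps.linregress(x, y)
        assert beta[0, 0] == pytest.approx(res.slope, rel=1e-12)
        assert t[0, 0] == pytest.approx(res.slope / res.stderr, rel=1e-10)

    def test_matches_statsmodels_multivariate(self, rng):
        import statsmodels.api as sm

        X = pd.DataFrame(rng.uniform(0, 1, (40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        beta, t = sliding_ols(y[:, None], X)
        sm_res = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(beta[:, 0], sm_res.params[1:], rtol=1e-10)
        np.testing.assert_allclose(t[:, 0], sm_res.tvalues[1:], rtol=1e-10)

    def test_row_permutation_invariance(self, rng):
        X = pd.DataFrame({"x": rng.uniform(0, 1, 25)})
        Y = rng.normal(size=(25, 8))
        beta, t = sliding_ols(Y, X)
        perm = rng.permutation(25)
        beta2, t2 = sliding_ols(Y[perm], X.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(beta, beta2, atol=1e-10)
        np.testing.assert_allclose(t, t2, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.uniform(0, 1, 20)
        X = pd.DataFrame({"x": x, "x_copy": x})
        with pytest.raises(ValueError, match="x_copy"):
            sliding_ols(rng.normal(size=(20, 4)), X)

    def test_too_few_trials_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="n_trials"):
            sliding_ols(np.zeros((2, 3)), X)


class TestFormClusters:
    def test_flat_series_no_clusters(self):
        times = np.arange(100) / SFREQ
        assert form_clusters(np.zeros(100), times, df=50) == []

    def test_duration_threshold_at_sampling_rate(self):
        # at 1450/3 Hz, 0.05 s spans 24.17 samples: 24 samples is too short,
        # 25 samples passes
        times = np.arange(200) / SFREQ
        df = 100
        crit = sps.t.ppf(0.975, df)
        for n_samp, expected in [(24, 0), (25, 1)]:
            t = np.zeros(200)
            t[10 : 10 + n_samp] = crit + 1.0
            assert len(form_clusters(t, times, df)) == expected

    def test_mass_is_hand_sum(self):
        times = np.arange(300) / SFREQ
        df = 80
        crit = sps.t.ppf(0.975, df)
        t = np.zeros(300)
        vals = crit + 1.0 + 0.01 * np.arange(30)
        t[100:130] = vals
        (c,) = form_clusters(t, times, df)
        assert c.mass == pytest.approx(vals.sum())
        assert c.start == 100 and c.stop == 129
        assert c.t_start == pytest.approx(times[100])
        assert c.t_end == pytest.approx(times[129])

    def test_sign_change_splits_cluster(self):
        times = np.arange(200) / SFREQ
        df = 80
        crit = sps.t.ppf(0.975, df)
        t = np.zeros(200)
        t[50:80] = crit + 1
        t[80:110] = -(crit + 1)
        clusters = form_clusters(t, times, df)
        assert len(clusters) == 2
        assert clusters[0].sign == 1 and clusters[1].sign == -1

    def test_subthreshold_gap_splits_runs(self):
        times = np.arange(200) / SFREQ
        df = 80
        crit = sps.t.ppf(0.975, df)
        t = np.zeros(200)
        t[40:70] = crit + 1
        t[75:105] = crit + 1
        assert len(form_clusters(t, times, df)) == 2


def exhaustive_cluster_p(data, x, subjects, times, **kw):
    """Enumerate all within-subject permutations of x for a tiny design."""
    subjects = np.asarray(subjects)
    blocks = [np.where(subjects == s)[0] for s in np.unique(subjects)]
    X = pd.DataFrame({"x": x})
    model = SingleTrialRegression(data, X, subjects, times, **kw)
    obs = model.permutation_test("x", n_perm=10, seed=0)
    if not obs:
        return obs, None

    def all_perms():
        per_block = [list(itertools.permutations(range(len(b)))) for b in blocks]
        for combo in itertools.product(*per_block):
            perm = np.arange(len(x))
            for blk, order in zip(blocks, combo):
                perm[blk] = blk[list(order)]
            yield perm

    x = np.asarray(x, float)
    null = []
    for perm in all_perms():
        Xp = pd.DataFrame({"x": x[perm]})
        m = SingleTrialRegression(data, Xp, subjects, times, **kw)
        _, t = m.fit()
        cl = form_clusters(t.to_numpy()[0], np.asarray(times), m.df)
        null.append(max((abs(c.mass) for c in cl), default=0.0))
    null = np.asarray(null)
    p_exact = {c.start: (null >= abs(c.mass)).mean() for c in obs}
    return obs, p_exact


class TestPermutation:
    def _fixture(self, seed=0, effect=2.0):
        rng = np.random.default_rng(seed)
        n, T = 6, 60
        times = np.arange(T) / SFREQ
        x = np.array([0.0, 0.5, 1.0, 0.0, 0.5, 1.0])
        subjects = np.repeat(["A", "B"], 3)
        data = rng.normal(0, 0.3, (n, T))
        data[:, 20:50] += effect * x[:, None]
        return data, x, subjects, times

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        data, x, subjects, times = self._fixture(seed=3)
        obs, p_exact = exhaustive_cluster_p(data, x, subjects, times)
        assert obs, "fixture must produce at least one cluster"
        model = SingleTrialRegression(
            data, pd.DataFrame({"x": x}), subjects, times
        )
        mc = model.permutation_test("x", n_perm=2000, seed=7)
        for c in mc:
            assert c.p_perm == pytest.approx(p_exact[c.start], abs=0.03)

    def test_observed_clusters_seed_independent(self):
        data, x, subjects, times = self._fixture(seed=4)
        X = pd.DataFrame({"x": x})
        a = permutation_cluster_test(data, X, subjects, times, "x", n_perm=50, seed=1)
        b = permutation_cluster_test(data, X, subjects, times, "x", n_perm=50, seed=99)
        assert [(c.start, c.stop, c.mass) for c in a] == [
            (c.start, c.stop, c.mass) for c in b
        ]

    def test_p_never_zero(self):
        data, x, subjects, times = self._fixture(seed=5, effect=50.0)
        clusters = permutation_cluster_test(
            data, pd.DataFrame({"x": x}), subjects, times, "x", n_perm=100, seed=0
        )
        assert clusters
        for c in clusters:
            assert c.p_perm >= 1.0 / 101.0

    def test_unknown_predictor_rejected(self):
        data, x, subjects, times = self._fixture()
        model = SingleTrialRegression(data, pd.DataFrame({"x": x}), subjects, times)
        with pytest.raises(KeyError):
            model.permutation_test("nope")

    def test_freedman_lane_agrees_on_strong_effect(self):
        # larger fixture: 6 trials admit only 36 distinct permutations,
        # bounding p above 0.05 by granularity alone
        rng = np.random.default_rng(6)
        n, T = 16, 60
        times = np.arange(T) / SFREQ
        x = np.tile([0.0, 1 / 3, 2 / 3, 1.0], 4)
        subjects = np.repeat(["A", "B"], 8)
        data = rng.normal(0, 0.3, (n, T))
        data[:, 20:50] += 3.0 * x[:, None]
        X = pd.DataFrame({"x": x})
        manly = permutation_cluster_test(
            data, X, subjects, times, "x", n_perm=500, seed=0, scheme="manly"
        )
        fl = permutation_cluster_test(
            data, X, subjects, times, "x", n_perm=500, seed=0, scheme="freedman-lane"
        )
        assert manly and fl
        assert manly[0].p_perm < 0.05 and fl[0].p_perm < 0.05

    def test_tiny_subject_excluded_with_warning(self):
        data, x, subjects, times = self._fixture(seed=7)
        data = np.vstack([data, data[:1]])
        x = np.append(x, 0.5)
        subjects = np.append(subjects, "C")
        with pytest.warns(UserWarning, match="excluding"):
            model = SingleTrialRegression(
                data, pd.DataFrame({"x": x}), subjects, times
            )
        assert model.data.shape[0] == 6


class TestFdr:
    def test_bh_hand_calculation(self):
        # p(i) * m / i, cumulative minimum from the largest rank
        p = [0.01, 0.04, 0.03, 0.005]
        adj = fdr_stepdown(p)
        m = 4
        ranked = np.sort(p)
        raw = ranked * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        expected = stepped[np.argsort(np.argsort(p))]
        np.testing.assert_allclose(adj, expected)

    def test_equal_spacing_all_collapse(self):
        np.testing.assert_allclose(
            fdr_stepdown([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_stepdown([0.037]), [0.037])

    def test_empty_ok(self):
        assert fdr_stepdown([]).size == 0

    def test_apply_fdr_never_below_p_perm(self):
        clusters = [
            Cluster(0, 1, 0.0, 0.1, 5.0, 1, p_perm=p)
            for p in (0.001, 0.02, 0.9)
        ]
        apply_fdr(clusters)
        for c in clusters:
            assert c.p_fdr >= c.p_perm


class TestMassFraction:
    def _cluster(self, samples, tvals):
        samples = np.asarray(samples)
        return Cluster(
            start=int(samples[0]),
            stop=int(samples[-1]),
            t_start=0.0,
            t_end=0.0,
            mass=float(np.sum(tvals)),
            sign=1,
            samples=samples,
            t_values=np.asarray(tvals, float),
        )

    def test_fully_inside_is_100(self):
        times = np.linspace(0, 1, 101)
        c = self._cluster(np.arange(40, 60), np.full(20, 3.0))
        assert cluster_mass_fraction([c], times, (0.3, 0.7)) == pytest.approx(100.0)

    def test_fully_outside_is_0(self):
        times = np.linspace(0, 1, 101)
        c = self._cluster(np.arange(80, 95), np.full(15, 3.0))
        assert cluster_mass_fraction([c], times, (0.0, 0.5)) == pytest.approx(0.0)

    def test_half_overlap_is_50(self):
        times = np.linspace(0, 1, 101)
        # samples 40..59 (times 0.40..0.59), window covers 0.40..0.495
        c = self._cluster(np.arange(40, 60), np.full(20, 2.5))
        assert cluster_mass_fraction([c], times, (0.395, 0.495)) == pytest.approx(50.0)

    def test_no_clusters_nan(self):
        assert np.isnan(cluster_mass_fraction([], np.linspace(0, 1, 10), (0, 1)))
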