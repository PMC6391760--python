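"""Statistics chain: ANOVA, nonparametrics, DFA, permutation null,
Mahalanobis placement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from volecall.stats import (classify, compare_proportions_chi2, fit_dfa,
                            individual_means, intermediacy_summary,
                            kruskal_wallis_median, mahalanobis_placement,
                            one_way_anova, randomization_null, split_half_cv)


def two_cloud_frame(rng, n1=30, n2=30, sep=6.0, p=2,
                    groups=("A", "B")) -> pd.DataFrame:
    X1 = rng.standard_normal((n1, p))
    X2 = rng.standard_normal((n2, p))
    X2[:, 0] += sep
    df = pd.DataFrame(np.vstack([X1, X2]),
                      columns=[f"f{i}" for i in range(p)])
    df["group"] = [groups[0]] * n1 + [groups[1]] * n2
    return df


FEATS2 = ("f0", "f1")


class TestAnova:
    def test_hand_computed_toy(self):
        r = one_way_anova([np.array([1, 2, 3]), np.array([2, 3, 4]),
                           np.array([3, 4, 5])])
        assert r.F == pytest.approx(3.0)
        assert (r.df_between, r.df_within) == (2, 6)

    def test_equal_means_give_zero_f(self):
        g = np.array([1.0, 2.0, 3.0])
        r = one_way_anova([g, g, g])
        assert r.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_t_squared_identity(self, rng):
        """For two groups, F equals the squared pooled-variance t statistic."""
        for _ in range(20):
            a = rng.standard_normal(rng.integers(5, 30))
            b = rng.standard_normal(rng.integers(5, 30)) + rng.normal()
            r = one_way_anova([a, b])
            t, p_t = sps.ttest_ind(a, b)
            assert r.F == pytest.approx(t ** 2, rel=1e-10)
            assert r.p == pytest.approx(p_t, rel=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.standard_normal(12) + i for i in range(3)]
        r = one_way_anova(groups)
        F, p = sps.f_oneway(*groups)
        assert r.F == pytest.approx(F, rel=1e-12)
        assert r.p == pytest.approx(p, rel=1e-12)

    def test_tukey_flags_separated_pair(self, rng):
        groups = [rng.standard_normal(20), rng.standard_normal(20),
                  rng.standard_normal(20) + 10.0]
        r = one_way_anova(groups, names=["a", "b", "c"])
        assert r.posthoc[("a", "c")] and r.posthoc[("b", "c")]
        assert not r.posthoc[("a", "b")]

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([np.ones(5), np.ones(5) * 2])


class TestKruskalMedian:
    def test_maximal_h_for_nonoverlapping_groups(self):
        """Two n=10 groups with disjoint ranges reach the maximal
        H = 14.29 of the rank formula at extreme ranks."""
        r = kruskal_wallis_median([np.arange(10.0), np.arange(10.0) + 100])
        assert r.H == pytest.approx(12 / (20 * 21) * (10 * 25 + 10 * 25),
                                    rel=1e-6)
        assert r.H == pytest.approx(14.2857, abs=1e-3)

    def test_identical_groups_near_zero(self, rng):
        g = rng.standard_normal(30)
        r = kruskal_wallis_median([g, g + 1e-9])
        assert r.H < 0.5
        assert r.p_kruskal > 0.4

    def test_median_chi2_matches_contingency_formula(self, rng):
        a, b = rng.standard_normal(40), rng.standard_normal(40) + 0.8
        r = kruskal_wallis_median([a, b])
        grand = np.median(np.concatenate([a, b]))
        table = np.array([[np.sum(a > grand), np.sum(b > grand)],
                          [np.sum(a <= grand), np.sum(b <= grand)]])
        chi2 = sps.chi2_contingency(table, correction=True).statistic
        assert r.median_chi2 == pytest.approx(chi2, rel=1e-9)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_median([np.ones(5), np.ones(6)])


class TestDfa:
    def test_axis_aligned_direction(self, rng):
        df = two_cloud_frame(rng, sep=4.0)
        m = fit_dfa(df, groups=("A", "B"), features=FEATS2)
        direction = m.coef / np.linalg.norm(m.coef)
        assert abs(direction[0]) > 0.97

    def test_label_swap_flips_coefficients(self, rng):
        df = two_cloud_frame(rng)
        m1 = fit_dfa(df, groups=("A", "B"), features=FEATS2)
        m2 = fit_dfa(df, groups=("B", "A"), features=FEATS2)
        assert np.allclose(m1.coef, -m2.coef)

    def test_coefficients_equal_closed_form(self):
        """Six-point toy set: coefficients match Sigma^-1 (mu1 - mu2) by
        direct matrix inversion."""
        df = pd.DataFrame({
            "f0": [0.0, 1.0, 0.5, 4.0, 5.0, 4.5],
            "f1": [0.0, 0.5, 1.0, 1.0, 0.0, 0.5],
            "group": ["A"] * 3 + ["B"] * 3,
        })
        m = fit_dfa(df, groups=("A", "B"), features=FEATS2)
        A = df.loc[df.group == "A", ["f0", "f1"]].to_numpy()
        B = df.loc[df.group == "B", ["f0", "f1"]].to_numpy()
        Sa = (A - A.mean(0)).T @ (A - A.mean(0))
        Sb = (B - B.mean(0)).T @ (B - B.mean(0))
        cov = (Sa + Sb) / (len(A) + len(B) - 2)
        expected = np.linalg.inv(cov) @ (A.mean(0) - B.mean(0))
        assert np.allclose(m.coef, expected, rtol=1e-10)

    def test_predictions_match_sklearn_lda(self, rng):
        """Independent cross-check: attribution agrees with scikit-learn's
        LDA under matching priors."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        df = two_cloud_frame(rng, n1=40, n2=25, sep=2.0, p=3)
        feats = ("f0", "f1", "f2")
        m = fit_dfa(df, groups=("A", "B"), features=feats, priors="equal")
        res = classify(m, df)
        lda = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        lda.fit(df[list(feats)], df["group"])
        sk_correct = 100 * (lda.predict(df[list(feats)]) ==
                            df["group"]).mean()
        assert res.percent_correct == pytest.approx(sk_correct, abs=1e-9)

    def test_perfect_separation_classifies_fully(self, rng):
        df = two_cloud_frame(rng, sep=20.0)
        m = fit_dfa(df, groups=("A", "B"), features=FEATS2)
        res = classify(m, df)
        assert res.percent_correct == 100.0
        assert res.confusion.loc["A", "A"] == 30
        assert int(res.confusion.to_numpy().sum()) == 60

    def test_no_signal_resubstitution_near_chance(self, rng):
        """Identical distributions, equal sizes: resubstitution sits at 50%
        plus a small overfitting bias (permutation-simulation oracle)."""
        accs = []
        for _ in range(30):
            df = two_cloud_frame(rng, n1=50, n2=50, sep=0.0, p=3)
            m = fit_dfa(df, groups=("A", "B"), features=("f0", "f1", "f2"))
            accs.append(classify(m, df).percent_correct)
        assert 50.0 < np.mean(accs) < 60.0

    def test_percent_correct_invariant_to_feature_rescaling(self, rng):
        df = two_cloud_frame(rng, sep=2.5)
        m = fit_dfa(df, groups=("A", "B"), features=FEATS2)
        base = classify(m, df).percent_correct
        scaled = df.copy()
        scaled["f0"] = scaled["f0"] * 1000.0 + 7.0   # seconds -> ms style
        m2 = fit_dfa(scaled, groups=("A", "B"), features=FEATS2)
        assert classify(m2, scaled).percent_correct == pytest.approx(base)

    def test_wilks_partial_ranks_informative_feature(self, rng):
        df = two_cloud_frame(rng, sep=5.0)
        m = fit_dfa(df, groups=("A", "B"), features=FEATS2)
        res = classify(m, df)
        assert 0.0 < res.wilks_lambda <= 1.0
        # f0 carries the separation: removing it costs most
        assert res.wilks_partial["f0"] < res.wilks_partial["f1"]
        assert all(0.0 < v <= 1.0 for v in res.wilks_partial.values())

    def test_feature_mismatch_rejected(self, rng):
        df = two_cloud_frame(rng)
        m = fit_dfa(df, groups=("A", "B"), features=FEATS2)
        with pytest.raises(ValueError):
            classify(m, df.rename(columns={"f1": "other"}))


class TestSplitHalfCv:
    def test_perfectly_separated_clouds(self, rng):
        df = two_cloud_frame(rng, sep=20.0)
        assert split_half_cv(df, groups=("A", "B"), features=FEATS2,
                             seed=3) == 100.0

    def test_deterministic_for_seed(self, rng):
        df = two_cloud_frame(rng, sep=1.5)
        a = split_half_cv(df, groups=("A", "B"), features=FEATS2, seed=9)
        b = split_half_cv(df, groups=("A", "B"), features=FEATS2, seed=9)
        assert a == b

    def test_too_small_groups_rejected(self, rng):
        df = two_cloud_frame(rng, n1=3, n2=10)
        with pytest.raises(ValueError):
            split_half_cv(df, groups=("A", "B"), features=FEATS2, seed=0)

    def test_resubstitution_exceeds_crossvalidation_on_average(self, rng):
        """Overfitting direction: training-set attribution >= held-out
        attribution averaged over 20 split seeds."""
        df = two_cloud_frame(rng, n1=40, n2=40, sep=1.2, p=3)
        feats = ("f0", "f1", "f2")
        m = fit_dfa(df, groups=("A", "B"), features=feats)
        resub = classify(m, df).percent_correct
        cvs = [split_half_cv(df, groups=("A", "B"), features=feats, seed=s)
               for s in range(20)]
        assert resub >= np.mean(cvs) - 1e-9


class TestRandomizationNull:
    def test_no_signal_equal_sizes_near_chance(self, rng):
        df = two_cloud_frame(rng, n1=100, n2=100, sep=0.0, p=3)
        r = randomization_null(df, groups=("A", "B"),
                               features=("f0", "f1", "f2"),
                               n_reps=50, seed=1)
        assert 50.0 < r.mean_percent < 56.0
        assert r.n_reps == len(r.per_rep) == 50
        assert r.se_percent == pytest.approx(
            r.per_rep.std(ddof=1) / np.sqrt(50))

    def test_permutation_destroys_real_signal(self, rng):
        df = two_cloud_frame(rng, sep=10.0)
        m = fit_dfa(df, groups=("A", "B"), features=FEATS2)
        observed = classify(m, df).percent_correct
        r = randomization_null(df, groups=("A", "B"), features=FEATS2,
                               n_reps=30, seed=2)
        assert observed - r.mean_percent > 30.0

    def test_too_few_reps_rejected(self, rng):
        with pytest.raises(ValueError):
            randomization_null(two_cloud_frame(rng), groups=("A", "B"),
                               features=FEATS2, n_reps=1, seed=0)


class TestProportionChi2:
    def test_identical_proportions_give_zero(self):
        chi2, p = compare_proportions_chi2(50.0, 100, 50.0, 100, yates=False)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_table(self):
        """(30/10; 10/30) without correction: N(ad-bc)^2 / products = 20."""
        chi2, _ = compare_proportions_chi2(75.0, 40, 25.0, 40, yates=False)
        assert chi2 == pytest.approx(20.0)

    def test_close_attribution_rates_not_significant(self):
        chi2, p = compare_proportions_chi2(94.4, 196, 92.9, 98)
        assert chi2 < 1.0 and p > 0.05

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions_chi2(120.0, 10, 50.0, 10)


class TestMahalanobis:
    def make_parents(self, rng, p=3, n=40, sep=4.0):
        df = two_cloud_frame(rng, n1=n, n2=n, sep=sep, p=p,
                             groups=("P1", "P2"))
        return df, tuple(f"f{i}" for i in range(p))

    def test_individual_at_centroid(self, rng):
        parents, feats = self.make_parents(rng)
        mu_a = parents.loc[parents.group == "P1", list(feats)].mean()
        ind = pd.DataFrame([{"individual_id": "x", "group": "hybrid",
                             **mu_a.to_dict()}])
        pl = mahalanobis_placement(parents, ind, ("P1", "P2"),
                                   features=feats)
        assert pl.table["d2_a"].iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert pl.table["d2_b"].iloc[0] > 1.0

    def test_identity_covariance_reduces_to_euclidean(self):
        rng = np.random.default_rng(0)
        n = 4000  # large n so the pooled covariance is close to identity
        X = rng.standard_normal((2 * n, 3))
        parents = pd.DataFrame(X, columns=["f0", "f1", "f2"])
        parents["group"] = ["P1"] * n + ["P2"] * n
        ind = pd.DataFrame([{"individual_id": "h", "group": "hybrid",
                             "f0": 1.0, "f1": 2.0, "f2": 2.0}])
        pl = mahalanobis_placement(parents, ind, ("P1", "P2"),
                                   features=("f0", "f1", "f2"))
        mu = parents.loc[parents.group == "P1",
                         ["f0", "f1", "f2"]].mean().to_numpy()
        d2_euclid = np.sum((np.array([1.0, 2.0, 2.0]) - mu) ** 2)
        assert pl.table["d2_a"].iloc[0] == pytest.approx(d2_euclid, rel=0.1)

    def test_matches_bruteforce_quadratic_form(self, rng):
        """Random 3-feature instances agree with the explicit
        inverse-covariance quadratic form to 1e-10 relative."""
        parents, feats = self.make_parents(rng, p=3)
        inds = pd.DataFrame(rng.standard_normal((5, 3)), columns=feats)
        inds["individual_id"] = [f"i{k}" for k in range(5)]
        inds["group"] = "hybrid"
        pl = mahalanobis_placement(parents, inds, ("P1", "P2"),
                                   features=feats)
        mats = {g: parents.loc[parents.group == g, list(feats)].to_numpy()
                for g in ("P1", "P2")}
        scatter = sum((m - m.mean(0)).T @ (m - m.mean(0))
                      for m in mats.values())
        cov = scatter / (sum(len(m) for m in mats.values()) - 2)
        inv = np.linalg.inv(cov)
        for k in range(5):
            x = inds.loc[k, list(feats)].to_numpy(dtype=float)
            for col, g in (("d2_a", "P1"), ("d2_b", "P2")):
                mu = mats[g].mean(0)
                expected = (x - mu) @ inv @ (x - mu)
                assert pl.table[col].iloc[k] == pytest.approx(expected,
                                                              rel=1e-10)

    def test_midpoint_hybrid_reported_as_tie(self):
        rng = np.random.default_rng(3)
        parents, feats = self.make_parents(rng, p=2, sep=6.0)
        mu = parents.groupby("group")[list(feats)].mean()
        mid = (mu.loc["P1"] + mu.loc["P2"]) / 2
        ind = pd.DataFrame([{"individual_id": "h", "group": "hybrid",
                             **mid.to_dict()}])
        pl = mahalanobis_placement(parents, ind, ("P1", "P2"),
                                   features=feats)
        s = intermediacy_summary(pl)
        assert s.per_hybrid["nearer"].iloc[0] == "tie"
        assert s.majority_nearer == "tie"

    def test_hybrid_at_parent_b_centroid_nearer_b(self):
        rng = np.random.default_rng(4)
        parents, feats = self.make_parents(rng, p=2, sep=6.0)
        mu_b = parents.loc[parents.group == "P2", list(feats)].mean()
        ind = pd.DataFrame([{"individual_id": "h", "group": "hybrid",
                             **mu_b.to_dict()}])
        pl = mahalanobis_placement(parents, ind, ("P1", "P2"),
                                   features=feats)
        s = intermediacy_summary(pl)
        assert s.per_hybrid["nearer"].iloc[0] == "P2"
        assert s.majority_nearer == "P2"

    def test_individual_means_one_row_per_animal(self, rng):
        df = two_cloud_frame(rng, n1=10, n2=10)
        df["individual_id"] = ["a1"] * 5 + ["a2"] * 5 + ["b1"] * 10
        m = individual_means(df, features=FEATS2)
        assert len(m) == 3
        assert set(m["individual_id"]) == {"a1", "a2", "b1"}
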