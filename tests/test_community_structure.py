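"""Bray-Curtis, PERMANOVA, nMDS, indicator values, and morphology ANOVA.

Permutation P-values are checked against independent exhaustive-enumeration
oracles written here with naive loops, and the PERMANOVA pseudo-F against
scikit-bio's implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import reefscape.community_structure as cs


# ---------------------------------------------------------------------------
# independent oracles (naive, loop-based)

def oracle_pseudo_f(D, groups):
    groups = np.asarray(groups)
    n = len(groups)
    labels = sorted(set(groups.tolist()))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += D[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for lab in labels:
        idx = [i for i in range(n) if groups[i] == lab]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ss_within += D[idx[a], idx[b]] ** 2 / len(idx)
    a = len(labels)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def oracle_exhaustive_p(D, groups, stat_fn):
    obs = stat_fn(D, groups)
    perms = set(itertools.permutations(groups))
    count = sum(stat_fn(D, np.asarray(p)) >= obs - 1e-12 for p in perms)
    return count / len(perms)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        D = cs.bray_curtis([[1, 2, 3], [1, 2, 3]])
        assert D[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        assert cs.bray_curtis([[1, 0], [0, 1]])[0, 1] == pytest.approx(1.0)

    def test_hand_computed(self):
        assert cs.bray_curtis([[2, 2], [1, 1]])[0, 1] == pytest.approx(1.0 / 3.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cs.bray_curtis([[1, 2], [0, 0]])

    def test_metric_properties_and_scale_invariance(self, rng):
        X = rng.uniform(0, 5, size=(8, 6))
        D = cs.bray_curtis(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0 and D.max() <= 1
        assert np.allclose(cs.bray_curtis(3.7 * X), D)

    def test_matches_scikit_bio(self, rng):
        from skbio.diversity import beta_diversity
        X = rng.uniform(0, 10, size=(6, 5))
        ours = cs.bray_curtis(X)
        theirs = beta_diversity("braycurtis", X).data
        assert np.allclose(ours, theirs, atol=1e-12)


class TestPermanova:
    def two_block_D(self):
        # two tight pairs, distance 1 between blocks
        D = np.ones((4, 4))
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 0.0
        return D

    def test_exhaustive_two_by_two_third(self):
        """Only 3 distinct 2|2 splits: perfect separation gives P = 1/3."""
        D = self.two_block_D()
        res = cs.permanova(D, ["a", "a", "b", "b"], exhaustive=True)
        assert res.p_value == pytest.approx(1.0 / 3.0)

    def test_matches_exhaustive_oracle_small_designs(self, rng):
        for groups in (["a", "a", "b", "b"], ["a", "a", "b", "b", "b"]):
            n = len(groups)
            X = rng.uniform(0, 4, size=(n, 5))
            D = cs.bray_curtis(X)
            res = cs.permanova(D, groups, exhaustive=True)
            expected = oracle_exhaustive_p(D, np.asarray(groups), oracle_pseudo_f)
            assert res.p_value == pytest.approx(expected, abs=1e-12)
            assert res.pseudo_f == pytest.approx(oracle_pseudo_f(D, groups))

    def test_monte_carlo_approximates_exhaustive(self, rng):
        X = rng.uniform(0, 4, size=(8, 5))
        groups = ["a"] * 4 + ["b"] * 4
        D = cs.bray_curtis(X)
        exact = cs.permanova(D, groups, exhaustive=True).p_value
        mc = cs.permanova(D, groups, n_perm=2000, seed=1).p_value
        assert mc == pytest.approx(exact, abs=0.05)

    def test_pseudo_f_matches_scikit_bio(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        X = rng.uniform(0, 4, size=(12, 6))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        D = cs.bray_curtis(X)
        ours = cs.permanova(D, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(DistanceMatrix(D), grouping=list(groups),
                                 permutations=9)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_null_p_values_roughly_uniform(self, rng):
        pvals = []
        for _ in range(200):
            X = rng.uniform(0, 4, size=(10, 4))
            D = cs.bray_curtis(X)
            groups = rng.permutation(["a"] * 5 + ["b"] * 5)
            pvals.append(cs.permanova(D, groups, n_perm=99,
                                      seed=int(rng.integers(2**31))).p_value)
        assert 0.35 < np.mean(pvals) < 0.65
        assert (np.asarray(pvals) < 0.1).mean() < 0.25

    def test_singleton_group_rejected(self):
        D = self.two_block_D()
        with pytest.raises(ValueError):
            cs.permanova(D, ["a", "b", "b", "b"])


class TestNmds:
    def test_embeddable_configuration_low_stress(self, rng):
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        res = cs.nmds(D, k=2, n_restarts=4, seed=0)
        assert res.stress < 0.01
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-8)

    def test_simplex_not_embeddable_in_plane(self):
        D = np.ones((4, 4)) - np.eye(4)
        res = cs.nmds(D, k=2, n_restarts=4, seed=0)
        assert res.stress > 0.0

    def test_stress_non_increasing_in_k(self, rng):
        X = rng.uniform(0, 3, size=(9, 6))
        D = cs.bray_curtis(X)
        stresses = [cs.nmds(D, k=k, n_restarts=8, seed=0).stress
                    for k in (1, 2, 3)]
        assert stresses[1] <= stresses[0] + 1e-3
        assert stresses[2] <= stresses[1] + 1e-3

    def test_shepard_pairs_cover_all_dyads(self, rng):
        X = rng.uniform(0, 3, size=(7, 5))
        D = cs.bray_curtis(X)
        res = cs.nmds(D, seed=0, n_restarts=2)
        assert len(res.shepard) == 7 * 6 // 2
        assert (res.shepard["disparity"].diff().dropna() >= -1e-9).all()


class TestIndicatorAnalysis:
    def test_perfect_indicator_stat_one(self):
        X = pd.DataFrame({"taxon1": [5, 4, 6, 0, 0, 0],
                          "taxon2": [1, 1, 1, 1, 1, 1]})
        groups = ["g1"] * 3 + ["g2"] * 3
        out = cs.indicator_analysis(X, groups, n_perm=99, seed=0)
        row = out[(out["taxon"] == "taxon1") & (out["group"] == "g1")]
        assert row["stat"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_stat(self):
        # A = 3/(3+1) = 0.75 (group means 3 vs 1), B = 2/3 occupancy
        X = pd.DataFrame({"t": [4.5, 4.5, 0.0, 1.0, 1.0, 1.0]})
        groups = ["g1"] * 3 + ["g2"] * 3
        out = cs.indicator_analysis(X, groups, n_perm=9, seed=0)
        row = out[(out["group"] == "g1")]
        assert row["stat"].iloc[0] == pytest.approx(np.sqrt(0.75 * 2 / 3))
        assert row["stat"].iloc[0] == pytest.approx(0.7071, abs=1e-3)

    def test_exhaustive_matches_oracle(self):
        X = pd.DataFrame({"t": [5.0, 4.0, 6.0, 0.0, 0.0, 1.0]})
        groups = np.array(["g1"] * 3 + ["g2"] * 3)

        def stat_g1(_D, perm):
            g1 = X["t"].to_numpy()[perm == "g1"]
            g2 = X["t"].to_numpy()[perm == "g2"]
            A = g1.mean() / (g1.mean() + g2.mean())
            B = (g1 > 0).mean()
            return np.sqrt(A * B)

        expected = oracle_exhaustive_p(None, groups, stat_g1)
        out = cs.indicator_analysis(X, groups, exhaustive=True)
        row = out[out["group"] == "g1"]
        assert row["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_group_combinations_reported(self):
        X = pd.DataFrame({"t": [1.0, 2, 3, 4, 5, 6, 7, 8]})
        groups = ["a", "a", "b", "b", "c", "c", "d", "d"]
        out = cs.indicator_analysis(X, groups, n_perm=9, seed=0)
        names = set(out["group"])
        assert "a" in names and "a+b" in names and "c+d" in names
        assert len(names) == 4 + 6 + 4  # singles, pairs, triples

    def test_absent_taxon_excluded_with_warning(self):
        X = pd.DataFrame({"t": [1.0, 2, 1, 2], "empty": [0.0, 0, 0, 0]})
        with pytest.warns(UserWarning, match="absent"):
            out = cs.indicator_analysis(X, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert "empty" not in set(out["taxon"])


class TestMorphologyAnova:
    def test_degrees_of_freedom_from_group_sizes(self, rng):
        sizes = {"pavement_rubble": 38, "ledge": 29, "concrete": 17, "ship": 39}
        values, groups = [], []
        for g, n in sizes.items():
            values.extend(rng.lognormal(3, 0.5, n))
            groups.extend([g] * n)
        res = cs.morphology_anova(values, groups, transform="log")
        assert res.df == (3, 119)
        assert len(res.posthoc) == 6

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(5, 1, 12)
        b = rng.normal(6, 1, 15)
        res = cs.morphology_anova(np.r_[a, b], ["a"] * 12 + ["b"] * 15,
                                  transform="none")
        t, _ = stats.ttest_ind(a, b)
        assert res.f == pytest.approx(t ** 2, rel=1e-10)

    def test_null_f_near_one_in_expectation(self, rng):
        fs = []
        for _ in range(200):
            y = rng.normal(size=24)
            fs.append(cs.morphology_anova(y, ["a", "b", "c"] * 8,
                                          transform="none").f)
        assert 0.7 < np.mean(fs) < 1.4

    def test_log_zero_fallback_warns(self):
        with pytest.warns(UserWarning, match="log"):
            res = cs.morphology_anova([0.0, 1, 2, 3, 4, 5],
                                      ["a", "a", "a", "b", "b", "b"],
                                      transform="log")
        assert np.isfinite(res.f)

    def test_holm_adjustment_monotone(self, rng):
        y = np.r_[rng.normal(0, 1, 10), rng.normal(3, 1, 10),
                  rng.normal(6, 1, 10)]
        res = cs.morphology_anova(y, ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                                  transform="none")
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-12).all()


def test_planted_community_contrast_detected():
    """Concrete vs ship composition contrast: PERMANOVA significant and
    pelagic families among top ship indicators in most replicate studies."""
    from reefscape.studies import community_signal_detection
    df = community_signal_detection(seeds=range(1, 11), n_perm=99)
    assert (df["permanova_p"] < 0.05).mean() >= 0.8
    assert df["pelagic_top"].mean() >= 0.8
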