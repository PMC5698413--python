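"""AMOVA: distance matrices, variance components vs an independent
coordinate-ANOVA oracle, and permutation behaviour."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from ylineage.amova import (AmovaDesign, amova, amova_with_pvalues,
                            distance_matrix, permutation_test)
from conftest import make_str_table

# ---------------------------------------------------------------------------
# independent oracle: nested ANOVA on coordinate embeddings.
# stepwise_squared is the squared Euclidean distance of repeat vectors, and
# loci_differing is the squared Euclidean distance of one-hot allele
# indicators scaled by 1/sqrt(2); variance components then follow from
# classical sums of squares about means and the expected-mean-square
# equations solved numerically.
# ---------------------------------------------------------------------------


def onehot_embedding(m):
    cols = []
    for j in range(m.shape[1]):
        for v in sorted(set(m[:, j])):
            cols.append((m[:, j] == v).astype(float) / math.sqrt(2))
    return np.column_stack(cols)


def anova_oracle(coords, pops, groups=None):
    pops = np.asarray(pops)
    n_tot = len(pops)
    popnames = list(dict.fromkeys(pops))
    sizes = {p: int((pops == p).sum()) for p in popnames}
    ss_total = ((coords - coords.mean(axis=0)) ** 2).sum()
    ss_wp = sum(((coords[pops == p] - coords[pops == p].mean(axis=0)) ** 2).sum()
                for p in popnames)
    if groups is None:
        n_pops = len(popnames)
        ms = np.array([(ss_total - ss_wp) / (n_pops - 1),
                       ss_wp / (n_tot - n_pops)])
        nc = (n_tot - sum(s * s for s in sizes.values()) / n_tot) / (n_pops - 1)
        coef = np.array([[nc, 1.0], [0.0, 1.0]])
        sa, sw = np.linalg.solve(coef, ms)
        return {"among_populations": sa, "within_populations": sw}
    garr = np.asarray([groups[p] for p in pops])
    gnames = list(dict.fromkeys(garr))
    n_groups, n_pops = len(gnames), len(popnames)
    ss_wg = sum(((coords[garr == g] - coords[garr == g].mean(axis=0)) ** 2).sum()
                for g in gnames)
    gsizes = {g: int((garr == g).sum()) for g in gnames}
    pg = {p: groups[p] for p in popnames}
    sum_npg = sum(sum(sizes[p] ** 2 for p in popnames if pg[p] == g) / gsizes[g]
                  for g in gnames)
    n1 = (n_tot - sum_npg) / (n_pops - n_groups)
    n2 = (sum_npg - sum(sizes[p] ** 2 for p in popnames) / n_tot) / (n_groups - 1)
    n3 = (n_tot - sum(gsizes[g] ** 2 for g in gnames) / n_tot) / (n_groups - 1)
    ms = np.array([(ss_total - ss_wg) / (n_groups - 1),
                   (ss_wg - ss_wp) / (n_pops - n_groups),
                   ss_wp / (n_tot - n_pops)])
    coef = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    sa, sb, sc = np.linalg.solve(coef, ms)
    return {"among_groups": sa, "among_populations_within_groups": sb,
            "within_populations": sc}


class TestDistanceMatrix:
    def test_identical_pair_zero(self):
        d = distance_matrix(np.array([[13, 29], [13, 29]]))
        assert d[0, 1] == 0.0

    def test_hand_computed_metrics(self):
        haps = np.array([[13, 29], [15, 29]])
        assert distance_matrix(haps, "loci_differing")[0, 1] == 1
        assert distance_matrix(haps, "stepwise_squared")[0, 1] == 4

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_loci_differing_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(9, 14, size=(6, 3))
        d = distance_matrix(haps, "loci_differing")
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        haps = rng.integers(9, 14, size=(7, 4))
        d = distance_matrix(haps)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)


class TestComponents:
    @pytest.mark.parametrize("metric", ["stepwise_squared", "loci_differing"])
    def test_one_level_matches_coordinate_anova_oracle(self, metric):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n = int(rng.integers(6, 13))
            haps = rng.integers(9, 14, size=(n, 4))
            pops = rng.choice(["a", "b", "c"], size=n)
            _, counts = np.unique(pops, return_counts=True)
            if (counts < 2).any() or len(counts) < 2:
                continue
            coords = (haps.astype(float) if metric == "stepwise_squared"
                      else onehot_embedding(haps))
            res = amova(haps, AmovaDesign(populations=list(pops), metric=metric))
            expected = anova_oracle(coords, pops)
            for key, val in expected.items():
                assert res.variance_components[key] == pytest.approx(val, abs=1e-9)

    def test_two_level_matches_oracle(self):
        rng = np.random.default_rng(12)
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        for _ in range(10):
            haps = rng.integers(9, 14, size=(12, 3))
            pops = np.repeat(["a", "b", "c", "d"], 3)
            res = amova(haps, AmovaDesign(populations=list(pops), groups=groups,
                                          metric="stepwise_squared"))
            expected = anova_oracle(haps.astype(float), pops, groups)
            for key, val in expected.items():
                assert res.variance_components[key] == pytest.approx(val, abs=1e-9)

    def test_fully_fixed_two_populations(self):
        haps = np.array([[10, 10]] * 4 + [[13, 12]] * 4)
        res = amova(haps, AmovaDesign(populations=["x"] * 4 + ["y"] * 4))
        assert res.phi_statistics["phi_st"] == pytest.approx(1.0)
        assert res.percent_variation["among_populations"] == pytest.approx(100.0)

    def test_percent_components_sum_to_100(self):
        rng = np.random.default_rng(13)
        haps = rng.integers(9, 14, size=(15, 4))
        pops = list(np.repeat(["a", "b", "c"], 5))
        res = amova(haps, AmovaDesign(populations=pops,
                                      groups={"a": "g1", "b": "g1", "c": "g2"}))
        assert sum(res.percent_variation.values()) == pytest.approx(100.0)

    def test_single_group_collapses_to_one_level(self):
        rng = np.random.default_rng(14)
        haps = rng.integers(9, 14, size=(10, 3))
        pops = list(np.repeat(["a", "b"], 5))
        one = amova(haps, AmovaDesign(populations=pops))
        two = amova(haps, AmovaDesign(populations=pops,
                                      groups={"a": "g", "b": "g"}))
        assert two.variance_components == one.variance_components

    def test_singleton_population_excluded_with_warning(self):
        haps = np.array([[10], [10], [11], [11], [12]])
        pops = ["a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="single sample"):
            res = amova(haps, AmovaDesign(populations=pops))
        assert "phi_st" in res.phi_statistics

    def test_phi_st_at_most_one(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            haps = rng.integers(9, 14, size=(12, 3))
            pops = list(np.repeat(["a", "b"], 6))
            res = amova(haps, AmovaDesign(populations=pops))
            assert res.phi_statistics["phi_st"] <= 1.0 + 1e-12


class TestPermutation:
    def test_fixed_partition_p_is_minimal_when_recurrence_is_negligible(self):
        # 10 vs 10: probability a random relabelling reproduces the
        # original split is ~1e-5, so no permutation reaches phi = 1
        haps = np.array([[10, 10]] * 10 + [[13, 12]] * 10)
        design = AmovaDesign(populations=["x"] * 10 + ["y"] * 10)
        p = permutation_test(haps, design, n_perm=999, seed=5)
        assert p["phi_st"] == pytest.approx(1 / 1000)

    def test_tiny_case_matches_exact_enumeration(self):
        # 3+3 fixed haplotypes: 72 of the 720 label orderings preserve the
        # partition and reach phi = 1, so the exact p is 0.1
        haps = np.array([[10]] * 3 + [[13]] * 3)
        labels = ["x"] * 3 + ["y"] * 3
        design = AmovaDesign(populations=labels)
        obs = amova(haps, design).phi_statistics["phi_st"]
        hits = 0
        perms = list(itertools.permutations(labels))
        for perm in perms:
            phi = amova(haps, AmovaDesign(populations=list(perm))
                        ).phi_statistics["phi_st"]
            hits += phi >= obs - 1e-12
        exact = hits / len(perms)
        assert exact == pytest.approx(72 / 720)
        p = permutation_test(haps, design, n_perm=1999, seed=3)
        # Monte-Carlo estimate should sit within 4 binomial SE of exact
        se = math.sqrt(exact * (1 - exact) / 1999)
        assert abs(p["phi_st"] - exact) < 4 * se

    def test_null_pvalues_are_uniform_under_exchangeable_labels(self):
        # KS test at alpha = 0.01 over 100 independent null panels
        rng = np.random.default_rng(21)
        pvals = []
        for rep in range(100):
            haps = rng.integers(9, 14, size=(16, 3))
            pops = list(np.repeat(["a", "b"], 8))
            pvals.append(permutation_test(
                haps, AmovaDesign(populations=pops), n_perm=199,
                seed=int(rng.integers(2 ** 31)))["phi_st"])
        ks = sstats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_seeded_runs_reproduce(self):
        rng = np.random.default_rng(22)
        haps = rng.integers(9, 14, size=(12, 3))
        design = AmovaDesign(populations=list(np.repeat(["a", "b"], 6)))
        p1 = permutation_test(haps, design, n_perm=499, seed=7)
        p2 = permutation_test(haps, design, n_perm=499, seed=7)
        assert p1 == p2

    def test_random_labels_centre_phi_on_zero(self):
        rng = np.random.default_rng(23)
        phis = []
        for _ in range(100):
            haps = rng.integers(9, 14, size=(14, 3))
            pops = list(rng.permutation(np.repeat(["a", "b"], 7)))
            phis.append(amova(haps, AmovaDesign(populations=pops))
                        .phi_statistics["phi_st"])
        assert abs(np.mean(phis)) < 0.05

    def test_two_level_pvalues_present(self):
        rng = np.random.default_rng(24)
        haps = rng.integers(9, 14, size=(16, 3))
        pops = list(np.repeat(["a", "b", "c", "d"], 4))
        design = AmovaDesign(populations=pops,
                             groups={"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        res = amova_with_pvalues(haps, design, n_perm=199, seed=9)
        assert set(res.p_values) == {"phi_st", "phi_ct", "phi_sc"}
        assert all(0 < p <= 1 for p in res.p_values.values())
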