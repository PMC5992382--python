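"""Community statistics against hand oracles, brute force, and scikit-bio."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import skbio
from skbio.diversity import beta_diversity

import cryoclean as cc
from cryoclean import ConfigurationError, OtuTable, ValidationError
from cryoclean.simulate import simulate_tree


def random_table_and_tree(seed, n_samples=4, n_otus=6):
    rng = np.random.default_rng(seed)
    otus = [f"O{i}" for i in range(n_otus)]
    counts = rng.integers(0, 60, size=(n_samples, n_otus))
    counts[:, 0] += 1  # no empty samples
    table = OtuTable(counts, [f"S{i}" for i in range(n_samples)], otus)
    return table, simulate_tree(otus, seed=seed + 1000)


def bruteforce_unifrac(table, tree, variant):
    """Literal per-branch enumeration, independent of the implementation."""
    rel = table.relative_abundance().rel_abund
    n = len(rel.index)
    out = np.zeros((n, n))
    branches = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        branches.append((float(node.length or 0.0), tips))
    for a, b in itertools.combinations(range(n), 2):
        pa = rel.iloc[a]
        pb = rel.iloc[b]
        num = den = 0.0
        for length, tips in branches:
            ma = sum(pa.get(t, 0.0) for t in tips)
            mb = sum(pb.get(t, 0.0) for t in tips)
            num += length * abs(ma - mb)
            den += length * (ma + mb)
        d = num if variant == "raw" else (num / den if den else 0.0)
        out[a, b] = out[b, a] = d
    return out


class TestWeightedUnifrac:
    def test_identical_samples_distance_zero(self):
        table, tree = random_table_and_tree(0)
        dup = OtuTable(np.vstack([table.counts[0], table.counts[0]]),
                       ["x", "y"], table.otu_ids)
        dm = cc.weighted_unifrac(dup, tree)
        assert dm["x", "y"] == 0.0

    def test_two_tip_star_tree_hand_values(self, tmp_path):
        tree = skbio.TreeNode.read([u"(T1:1,T2:1);"])
        table = OtuTable([[10, 0], [0, 5]], ["A", "B"], ["T1", "T2"])
        raw = cc.weighted_unifrac(table, tree, "raw")
        norm = cc.weighted_unifrac(table, tree, "normalized")
        assert raw["A", "B"] == pytest.approx(2.0)
        assert norm["A", "B"] == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["raw", "normalized"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_trees(self, seed, variant):
        table, tree = random_table_and_tree(seed)
        dm = cc.weighted_unifrac(table, tree, variant)
        expected = bruteforce_unifrac(table, tree, variant)
        assert np.abs(dm.data - expected).max() <= 1e-12

    @pytest.mark.parametrize("variant,normalized", [("raw", False),
                                                    ("normalized", True)])
    def test_matches_scikit_bio(self, variant, normalized):
        table, tree = random_table_and_tree(9, n_samples=5)
        dm = cc.weighted_unifrac(table, tree, variant)
        sk = beta_diversity("weighted_unifrac", table.counts,
                            ids=table.sample_ids, taxa=table.otu_ids,
                            tree=tree, normalized=normalized)
        assert np.abs(dm.data - sk.data).max() <= 1e-10

    def test_extra_tips_pruned_missing_tips_error(self):
        table, tree = random_table_and_tree(2)
        sub = table.select_otus(table.otu_ids[:4])
        dm_full_tree = cc.weighted_unifrac(sub, tree)
        assert list(dm_full_tree.ids) == sub.sample_ids
        with pytest.raises(ValidationError, match="O5"):
            cc.weighted_unifrac(table, tree.shear(table.otu_ids[:4]))


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        d = np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]],
                     dtype=float)
        dm = skbio.DistanceMatrix(d, ids=list("abcd"))
        res = cc.anosim(dm, ["g1", "g1", "g2", "g2"], permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_all_equal_distances_give_r_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = skbio.DistanceMatrix(d, ids=list("abcd"))
        res = cc.anosim(dm, ["g1", "g1", "g2", "g2"], permutations=99, seed=0)
        assert res.statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_r_matches_scikit_bio(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0.1, 1.0, size=len(iu[0]))
        d += d.T
        dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        groups = ["a", "a", "a", "b", "b", "b"]
        mine = cc.anosim(dm, groups, permutations=999, seed=1)
        sk = skbio.stats.distance.anosim(
            dm, pd.DataFrame({"g": groups}, index=dm.ids), column="g",
            permutations=0)
        assert mine.statistic == pytest.approx(sk["test statistic"], abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_exhaustive_p_matches_independent_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 5
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(size=len(iu[0]))
        d += d.T
        dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        groups = np.array(["a", "a", "b", "b", "b"])
        res = cc.anosim(dm, groups, permutations="exhaustive")

        def r_of(labels):
            ranks = scipy.stats.rankdata(d[iu])
            within = np.array([labels[i] == labels[j]
                               for i, j in zip(*iu)])
            rw, rb = ranks[within].mean(), ranks[~within].mean()
            return (rb - rw) / (n * (n - 1) / 4)

        observed = r_of(groups)
        stats = [r_of(groups[list(p)])
                 for p in itertools.permutations(range(n))]
        expected_p = np.mean([s >= observed - 1e-12 for s in stats])
        assert res.statistic == pytest.approx(observed)
        assert res.p_value == pytest.approx(expected_p)

    def test_permutation_p_reproducible_and_corrected(self):
        table, tree = random_table_and_tree(4, n_samples=6)
        dm = cc.weighted_unifrac(table, tree)
        g = ["a", "a", "a", "b", "b", "b"]
        r1 = cc.anosim(dm, g, permutations=199, seed=7)
        r2 = cc.anosim(dm, g, permutations=199, seed=7)
        assert r1.p_value == r2.p_value > 0.0

    def test_degenerate_groupings_rejected(self):
        dm = skbio.DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        with pytest.raises(ConfigurationError):
            cc.anosim(dm, ["g", "g", "g"])

    def test_null_p_values_roughly_uniform(self):
        """Under shuffled labels the permutation p-value is ~Uniform(0,1)."""
        rng = np.random.default_rng(42)
        n = 8
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(size=len(iu[0]))
        d += d.T
        dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        ps = []
        for i in range(200):
            labels = rng.permutation(["a"] * 4 + ["b"] * 4)
            ps.append(cc.anosim(dm, labels, permutations=99,
                                seed=int(rng.integers(2 ** 31))).p_value)
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.statistic < 0.15


class TestPcoa:
    def test_recovers_planar_distances(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ord_ = cc.pcoa(skbio.DistanceMatrix(d, ids=list("abc")))
        rec = np.sqrt(((ord_.coordinates[:, None] -
                        ord_.coordinates[None]) ** 2).sum(-1))
        assert np.abs(rec - d).max() <= 1e-9

    def test_all_zero_distances(self):
        ord_ = cc.pcoa(skbio.DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))
        assert np.allclose(ord_.coordinates, 0.0)

    def test_duplicate_samples_coincide(self):
        d = np.array([[0, 0, 5], [0, 0, 5], [5, 5, 0]], dtype=float)
        ord_ = cc.pcoa(skbio.DistanceMatrix(d, ids=list("abc")))
        assert np.allclose(ord_.coordinates[0], ord_.coordinates[1])

    def test_proportions_match_scikit_bio(self):
        table, tree = random_table_and_tree(5, n_samples=6)
        dm = cc.weighted_unifrac(table, tree)
        mine = cc.pcoa(dm)
        sk = skbio.stats.ordination.pcoa(dm, method="eigh")
        k = len(mine.proportion_explained)
        sk_prop = sk.proportion_explained.to_numpy()
        sk_prop = sk_prop / sk_prop[:k].sum()
        assert np.allclose(mine.proportion_explained, sk_prop[:k], atol=1e-6)
        assert mine.proportion_explained.sum() <= 1 + 1e-9


class TestUpgma:
    def test_two_samples_merge_at_half_distance(self):
        dm = skbio.DistanceMatrix([[0, 4], [4, 0]], ids=["a", "b"])
        den = cc.upgma(dm)
        assert den.merges == [(frozenset({"a"}), frozenset({"b"}), 2.0)]
        assert den.to_newick() == "(a:2,b:2);"

    def test_three_sample_hand_trace(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        den = cc.upgma(skbio.DistanceMatrix(d, ids=["A", "B", "C"]))
        (a1, b1, h1), (a2, b2, h2) = den.merges
        assert {a1, b1} == {frozenset({"A"}), frozenset({"B"})} and h1 == 1.0
        assert a2 | b2 == frozenset({"A", "B", "C"}) and h2 == 3.0

    @pytest.mark.parametrize("seed", range(5))
    def test_heights_non_decreasing_and_match_scipy(self, seed):
        import scipy.cluster.hierarchy as sch
        rng = np.random.default_rng(seed)
        n = 7
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0.5, 2.0, size=len(iu[0]))
        d += d.T
        dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        den = cc.upgma(dm)
        heights = den.heights
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
        z = sch.average(dm.condensed_form())
        assert np.allclose(sorted(heights), sorted(z[:, 2] / 2.0))


class TestMantel:
    def _dm(self, seed, n=5):
        rng = np.random.default_rng(seed)
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(size=len(iu[0]))
        d += d.T
        return skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])

    def test_self_correlation_is_one(self):
        dm = self._dm(1)
        assert cc.mantel(dm, dm, permutations=99).statistic == pytest.approx(1.0)

    def test_affine_transform_correlation_is_one(self):
        dm = self._dm(2)
        d2 = skbio.DistanceMatrix(dm.data * 3.0 + (1 - np.eye(5)) * 0.7,
                                  ids=dm.ids)
        assert cc.mantel(dm, d2, permutations=99).statistic \
            == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration_n5(self):
        d1, d2 = self._dm(3), self._dm(4)
        res = cc.mantel(d1, d2, permutations="exhaustive")
        iu = np.triu_indices(5, 1)
        x = d1.data[iu]
        obs = scipy.stats.pearsonr(x, d2.data[iu]).statistic
        hits = total = 0
        for p in itertools.permutations(range(5)):
            perm = d2.data[np.ix_(p, p)][iu]
            total += 1
            if abs(scipy.stats.pearsonr(x, perm).statistic) \
                    >= abs(obs) - 1e-12:
                hits += 1
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(hits / total)

    def test_mismatched_ids_rejected(self):
        d1 = self._dm(5)
        d2 = skbio.DistanceMatrix(d1.data, ids=["x0", "x1", "x2", "x3", "x4"])
        with pytest.raises(ValidationError):
            cc.mantel(d1, d2)

    def test_reproducible_with_seed(self):
        d1, d2 = self._dm(6), self._dm(7)
        a = cc.mantel(d1, d2, permutations=199, seed=3)
        b = cc.mantel(d1, d2, permutations=199, seed=3)
        assert a.p_value == b.p_value


class TestPairedProfileTest:
    def test_identical_profiles_give_p_one(self):
        prof = {"a": 0.5, "b": 0.3, "c": 0.2}
        res = cc.paired_profile_test(prof, dict(prof), list(prof))
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_symmetric_differences_give_t_zero(self):
        a = {"a": 0.5, "b": 0.5}
        b = {"a": 0.4, "b": 0.6}
        res = cc.paired_profile_test(a, b, ["a", "b"])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_scipy_on_five_taxa(self):
        a = [0.40, 0.25, 0.15, 0.12, 0.08]
        b = [0.35, 0.28, 0.17, 0.10, 0.10]
        taxa = list("vwxyz")
        res = cc.paired_profile_test(dict(zip(taxa, a)), dict(zip(taxa, b)),
                                     taxa)
        ref = scipy.stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ConfigurationError):
            cc.paired_profile_test({"a": 1.0}, {"a": 1.0}, ["a"])
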