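"""Community-comparison statistics.

These are deliberately self-contained implementations of the classic
phylogenetic beta-diversity toolkit — weighted UniFrac, ANOSIM, classical
PCoA, UPGMA and the Mantel test — plus the paired-t comparison of original
vs pre-amplified profiles. The permutation tests share one convention: the
p-value is (#{permuted statistic at least as extreme} + 1) / (permutations
+ 1), so it is never exactly zero; exhaustive enumerations (feasible for a
handful of samples) divide the plain count by the number of permutations,
the identity included.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import skbio

from .model import (
    ConfigurationError,
    Dendrogram,
    Ordination,
    OtuTable,
    Profile,
    TestResult,
    ValidationError,
)

__all__ = ["weighted_unifrac", "anosim", "pcoa", "upgma", "mantel",
           "paired_profile_test"]

EXHAUSTIVE = "exhaustive"


# ---------------------------------------------------------------------------
# weighted UniFrac
# ---------------------------------------------------------------------------

def _proportions(data: OtuTable | Profile) -> pd.DataFrame:
    if isinstance(data, OtuTable):
        return data.relative_abundance().rel_abund
    return data.rel_abund


def _branch_table(tree: skbio.TreeNode, otu_ids: Sequence[str]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch lengths and tip-membership indicators for ``otu_ids``.

    The tree is sheared to the requested tips (extra tips pruned); a missing
    tip is an error. The root carries no branch.
    """
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(otu_ids) - tips)
    if missing:
        raise ValidationError(f"OTU(s) absent from the tree: {missing}")
    work = tree.copy()
    if set(otu_ids) != tips:
        work = work.shear(list(otu_ids))
    idx = {o: j for j, o in enumerate(otu_ids)}
    lengths: list[float] = []
    members: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in work.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(otu_ids))
            vec[idx[node.name]] = 1.0
        else:
            vec = np.sum([below[id(c)] for c in node.children], axis=0)
        below[id(node)] = vec
        if node is not work:  # root has no branch above it
            lengths.append(float(node.length or 0.0))
            members.append(vec)
    return np.asarray(lengths), np.asarray(members)


def weighted_unifrac(data: OtuTable | Profile, tree: skbio.TreeNode,
                     variant: str = "raw") -> skbio.DistanceMatrix:
    """Weighted UniFrac distances between all sample pairs.

    The raw variant is d(A, B) = sum_b l_b * |p_A(b) - p_B(b)| over branches
    b with length l_b, where p_X(b) is the fraction of sample X's reads on
    tips below b; the normalized variant divides by
    sum_b l_b * (p_A(b) + p_B(b)).
    """
    if variant not in ("raw", "normalized"):
        raise ConfigurationError(f"unknown UniFrac variant {variant!r}")
    rel = _proportions(data)
    lengths, members = _branch_table(tree, list(rel.columns))
    # branch x sample matrix of descendant read fractions
    masses = members @ rel.to_numpy(float).T
    n = rel.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = float(lengths @ np.abs(masses[:, i] - masses[:, j]))
            if variant == "normalized":
                denom = float(lengths @ (masses[:, i] + masses[:, j]))
                diff = diff / denom if denom > 0 else 0.0
            dist[i, j] = dist[j, i] = diff
    return skbio.DistanceMatrix(dist, ids=list(rel.index))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n = int((1 + math.isqrt(1 + 8 * len(ranks))) // 2)
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (n * (n - 1) / 4.0))


def anosim(dist: skbio.DistanceMatrix, groups: Sequence[str],
           permutations: int | str = 999, seed: int = 0) -> TestResult:
    """Analysis of similarities on ranked pairwise distances.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with mid-ranks for ties; R is 1 when all between-group distances exceed
    all within-group ones and 0 when ranks are interchangeable. The p-value
    comes from label permutations (``permutations="exhaustive"`` enumerates
    all n! orderings — only sensible for small n).
    """
    labels = np.asarray([str(g) for g in groups])
    n = len(dist.ids)
    if len(labels) != n:
        raise ValidationError(f"{len(labels)} group labels for {n} samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ConfigurationError("ANOSIM requires at least two groups")
    if counts.max() == n:
        raise ConfigurationError("a single group spans every sample")
    condensed = dist.condensed_form()
    ranks = scipy.stats.rankdata(condensed)  # mid-ranks for ties
    pairs = list(itertools.combinations(range(n), 2))
    same = np.array([labels[i] == labels[j] for i, j in pairs])
    observed = _anosim_r(ranks, same)

    if permutations == EXHAUSTIVE:
        total = 0
        at_least = 0
        for perm in itertools.permutations(range(n)):
            lab = labels[list(perm)]
            w = np.array([lab[i] == lab[j] for i, j in pairs])
            total += 1
            if _anosim_r(ranks, w) >= observed - 1e-12:
                at_least += 1
        return TestResult(observed, at_least / total, total, None,
                          "anosim/exhaustive")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(permutations)):
        lab = labels[rng.permutation(n)]
        w = np.array([lab[i] == lab[j] for i, j in pairs])
        if _anosim_r(ranks, w) >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (int(permutations) + 1)
    return TestResult(observed, p, int(permutations), seed, "anosim")


# ---------------------------------------------------------------------------
# PCoA (classical metric scaling)
# ---------------------------------------------------------------------------

def pcoa(dist: skbio.DistanceMatrix) -> Ordination:
    """Classical scaling: double-center -D^2/2, eigendecompose, embed.

    Coordinates are eigenvectors scaled by sqrt of the positive eigenvalues;
    negative eigenvalues (non-Euclidean distance matrices) are reported in
    ``eigenvalues`` but contribute no axis. ``proportion_explained`` is each
    positive eigenvalue over the positive-eigenvalue total.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-9 * abs(eigval).max()) if n else 0.0
    positive = eigval > tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    pos_sum = eigval[positive].sum()
    prop = eigval[positive] / pos_sum if pos_sum > 0 else eigval[positive]
    if not positive.any():  # degenerate all-zero matrix: one zero axis
        coords = np.zeros((n, 1))
        prop = np.zeros(1)
    return Ordination(list(dist.ids), coords, eigval, prop)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dist: skbio.DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration; merge height is half the distance.

    Inter-cluster distance is the size-weighted mean of member distances,
    which makes heights non-decreasing (ultrametric). Ties pick the
    lexicographically smallest cluster pair (by smallest member id).
    """
    ids = list(dist.ids)
    if len(ids) < 2:
        raise ConfigurationError("UPGMA needs at least two samples")
    clusters: dict[frozenset, str] = {frozenset([s]): s for s in ids}
    sizes = {frozenset([s]): 1 for s in ids}
    d = {}
    for a, b in itertools.combinations(ids, 2):
        d[frozenset([frozenset([a]), frozenset([b])])] = float(dist[a, b])
    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(clusters) > 1:
        def sort_key(pair):
            x, y = sorted(pair, key=lambda c: clusters[c])
            return (d[frozenset(pair)], clusters[x], clusters[y])
        best = min((frozenset(p) for p in
                    itertools.combinations(clusters, 2)), key=sort_key)
        a, b = sorted(best, key=lambda c: clusters[c])
        height = d[best] / 2.0
        merged = a | b
        merges.append((a, b, height))
        na, nb = sizes[a], sizes[b]
        for other in list(clusters):
            if other in (a, b):
                continue
            dm = (na * d[frozenset([a, other])] + nb * d[frozenset([b, other])]) \
                / (na + nb)
            d[frozenset([merged, other])] = dm
        for other in list(clusters):
            d.pop(frozenset([a, other]), None)
            d.pop(frozenset([b, other]), None)
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[merged] = min(merged)  # representative: smallest member id
        sizes[merged] = na + nb
    return Dendrogram(ids, merges)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel(d1: skbio.DistanceMatrix, d2: skbio.DistanceMatrix,
           permutations: int | str = 999, seed: int = 0) -> TestResult:
    """Two-tailed Mantel test: Pearson r of upper triangles, row/column
    permutations of the second matrix, p on |r|."""
    if list(d1.ids) != list(d2.ids):
        raise ValidationError(
            "Mantel requires identical sample sets in identical order; got "
            f"{list(d1.ids)} vs {list(d2.ids)}"
        )
    n = len(d1.ids)
    x = d1.condensed_form()
    m2 = np.asarray(d2.data, dtype=float)
    iu = np.triu_indices(n, k=1)

    def corr(perm: np.ndarray) -> float:
        y = m2[np.ix_(perm, perm)][iu]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    observed = corr(np.arange(n))
    if permutations == EXHAUSTIVE:
        total = at_least = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(corr(np.array(perm))) >= abs(observed) - 1e-12:
                at_least += 1
        return TestResult(observed, at_least / total, total, None,
                          "mantel/exhaustive")
    rng = np.random.default_rng(seed)
    hits = sum(
        abs(corr(rng.permutation(n))) >= abs(observed) - 1e-12
        for _ in range(int(permutations))
    )
    p = (hits + 1) / (int(permutations) + 1)
    return TestResult(observed, p, int(permutations), seed, "mantel")


# ---------------------------------------------------------------------------
# paired t on profiles
# ---------------------------------------------------------------------------

def paired_profile_test(profile_a, profile_b, taxa: Sequence[str],
                        transform: str = "none") -> TestResult:
    """Two-tailed paired t-test over per-taxon abundance differences.

    ``profile_a``/``profile_b`` are abundance vectors indexed by taxon (e.g.
    one sample's genus profile, original vs pre-amplified); the pairing is
    across the ``taxa`` list, with k-1 degrees of freedom. All-zero
    differences give t = 0, p = 1 by convention. Abundances are compared
    untransformed by default; ``transform`` may be ``arcsine``
    (arcsin sqrt) or ``logit`` (with a half-minimum floor) for users who
    prefer variance-stabilised proportions.
    """
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ConfigurationError("paired test needs at least two taxa")
    a = pd.Series(profile_a).reindex(taxa)
    b = pd.Series(profile_b).reindex(taxa)
    if a.isna().any() or b.isna().any():
        missing = [t for t in taxa if pd.isna(a[t]) or pd.isna(b[t])]
        raise ValidationError(f"taxa missing from a profile: {missing}")
    av, bv = a.to_numpy(float), b.to_numpy(float)
    if transform == "arcsine":
        av, bv = np.arcsin(np.sqrt(av)), np.arcsin(np.sqrt(bv))
    elif transform == "logit":
        floor = min(x for x in np.concatenate([av, bv]) if x > 0) / 2.0
        av, bv = np.clip(av, floor, 1 - floor), np.clip(bv, floor, 1 - floor)
        av, bv = np.log(av / (1 - av)), np.log(bv / (1 - bv))
    elif transform != "none":
        raise ConfigurationError(f"unknown transform {transform!r}")
    diff = av - bv
    k = len(diff)
    if np.allclose(diff, 0.0):
        return TestResult(0.0, 1.0, 0, None, "paired_t")
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if sd == 0:  # constant non-zero shift: infinitely strong evidence
        return TestResult(math.copysign(math.inf, mean), 0.0, 0, None, "paired_t")
    t = mean / (sd / math.sqrt(k))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), df=k - 1))
    return TestResult(float(t), min(p, 1.0), 0, None, "paired_t")
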