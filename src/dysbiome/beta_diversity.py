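"""Weighted UniFrac, principal coordinates, and PERMANOVA.

UniFrac and PCoA are delegated to scikit-bio behind thin, validating
surfaces.  PERMANOVA is computed in-package from the distance matrix so the
permutation stream is driven by an explicit seed (and can be cross-checked
against scikit-bio's implementation, which shares the pseudo-F).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core_tables import OtuTable


def weighted_unifrac(table: OtuTable, tree: skbio.TreeNode,
                     variant: str = "normalized") -> skbio.DistanceMatrix:
    """Pairwise weighted UniFrac distances between samples.

    Branch proportions are taken on per-sample relative abundances.  The
    ``normalized`` variant (default) divides each raw distance by the
    abundance-weighted total branch length, bounding it in [0, 1].  Every
    OTU with nonzero counts must be a tip of ``tree``.
    """
    if variant not in ("raw", "normalized"):
        raise ValueError(f"unknown variant {variant!r}")
    totals = table.counts.sum(axis=1)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total counts: {zero[:5]}")
    tips = {t.name for t in tree.tips()}
    present = table.counts.sum(axis=0) > 0
    missing = [o for o, p in zip(table.otu_ids, present) if p and o not in tips]
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing[:10]}")
    keep = [o for o in table.otu_ids if o in tips]
    sub = table.select_otus(keep)
    return beta_diversity(
        "weighted_unifrac", sub.counts, ids=sub.sample_ids,
        taxa=sub.otu_ids, tree=tree, normalized=(variant == "normalized"),
        validate=True)


def pcoa(dm: skbio.DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical-scaling embedding of a distance matrix.

    Returns (coordinates, eigenvalues) restricted to strictly positive
    eigenvalues, sorted descending; negative eigenvalues (non-Euclidean
    input) are dropped.
    """
    res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12
    coords = res.samples.to_numpy()[:, pos]
    return (pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{i + 1}" for i in range(pos.sum())]),
            eig[pos])


@dataclasses.dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def _pseudo_f(sq: np.ndarray, groups: np.ndarray, group_ids: np.ndarray,
              ss_total: float) -> float:
    n = sq.shape[0]
    a = len(group_ids)
    ss_within = 0.0
    for g in group_ids:
        idx = np.flatnonzero(groups == g)
        ss_within += sq[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _n_arrangements(counts: np.ndarray) -> float:
    from math import comb
    total, n_arr = int(counts.sum()), 1
    for c in counts:
        n_arr *= comb(total, int(c))
        total -= int(c)
    return n_arr


def permanova(dm: skbio.DistanceMatrix, labels, n_perm: int = 999,
              seed: int = 0, exact_if_feasible: bool = True
              ) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = [SS_between/(a-1)] / [SS_within/(N-a)] from squared
    distances; the p-value is (1 + #{permuted F >= observed F}) /
    (1 + n_perm) under free label permutation, deterministic under ``seed``.
    When the number of distinct label arrangements does not exceed
    ``n_perm`` (tiny designs) the test is run exactly over the complete
    arrangement set instead of by sampling, so the p-value is the exact
    permutation p (the observed arrangement counts itself).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != dm.shape[0]:
        raise ValueError("labels length must match distance matrix")
    group_ids, groups = np.unique(labels, return_inverse=True)
    if len(group_ids) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    counts = np.bincount(groups)
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    sq = dm.data ** 2
    n = sq.shape[0]
    ss_total = sq.sum() / (2 * n)
    gid = np.arange(len(group_ids))
    f_obs = _pseudo_f(sq, groups, gid, ss_total)

    if (exact_if_feasible and len(group_ids) == 2
            and _n_arrangements(counts) <= n_perm):
        from itertools import combinations
        hits = total = 0
        for idx in combinations(range(n), int(counts[0])):
            arr = np.ones(n, dtype=int)
            arr[list(idx)] = 0
            total += 1
            if _pseudo_f(sq, arr, gid, ss_total) >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(float(f_obs), hits / total, total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _pseudo_f(sq, perm, gid, ss_total) >= f_obs:
            hits += 1
    return PermanovaResult(float(f_obs), (1 + hits) / (1 + n_perm), n_perm)
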