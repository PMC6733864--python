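"""Headline dysbiosis metrics aggregated over per-comparison DA results.

Three summaries: (1) the fold difference per comparison — #OTUs enriched in
the healthy group over #enriched in the disease group — tested per disease
against 1 with a one-sample t-test and Holm correction; (2) genus "presence"
matrices: per disease and genus, the fraction of that disease's comparisons
in which the genus had at least one significant OTU on a given side; and
(3) hierarchical clustering of the disease rows with bootstrap probability
(BP) and approximately unbiased (AU) support from a multiscale bootstrap of
the genus columns.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .core_tables import TaxonomyMap, reduce_to_genus
from .design import Comparison
from .differential_abundance import DaResult


@dataclasses.dataclass
class FoldDifferenceRecord:
    """One comparison's enrichment imbalance.

    ``fold_difference = n1 / n2`` (healthy-enriched over disease-enriched),
    with a zero denominator substituted by 1 and flagged.  ``plot_value``
    mirrors the plotting convention: ratios below 1 are inverted and made
    negative, so +2 and -2 denote two-fold imbalance in either direction.
    """

    comparison_id: str
    n_enriched_group1: int
    n_enriched_group2: int
    fold_difference: float
    plot_value: float
    zero_denominator: bool = False
    undefined: bool = False


def fold_difference(n1: int, n2: int, comparison_id: str = "",
                    zero_policy: str = "substitute") -> FoldDifferenceRecord:
    """Fold difference in enriched-OTU counts for one comparison.

    ``zero_policy='substitute'`` replaces a zero denominator with 1 (flagged);
    ``'exclude'`` marks the record unusable instead.  Both counts zero is
    always undefined and excluded from the t-test.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 == 0 and n2 == 0:
        return FoldDifferenceRecord(comparison_id, 0, 0, np.nan, np.nan,
                                    undefined=True)
    zero_den = n2 == 0
    if zero_den and zero_policy == "exclude":
        return FoldDifferenceRecord(comparison_id, n1, n2, np.nan, np.nan,
                                    zero_denominator=True, undefined=True)
    fd = n1 / max(n2, 1)
    # plotting transform inverts sub-1 ratios; a zero numerator is plotted
    # with 1 substituted the same way the zero denominator is
    plot = fd if fd >= 1 else -max(n2, 1.0) if fd == 0 else -1.0 / fd
    return FoldDifferenceRecord(comparison_id, n1, n2, fd, plot,
                                zero_denominator=zero_den)


def records_to_frame(records: Sequence[FoldDifferenceRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def test_fold_bias(records_by_disease: Mapping[str, Sequence[FoldDifferenceRecord]]
                   ) -> pd.DataFrame:
    """One-sample t-test of fold differences against 1, Holm-corrected.

    For each disease the usable fold-difference ratios are tested two-sided
    against a mean of 1 (no enrichment imbalance); Holm correction is applied
    across the diseases tested together.  Zero-variance edge cases: all
    values exactly 1 gives p = 1; zero variance away from 1 is degenerate
    and reported as p = 0 with a flag.
    """
    rows = []
    for disease, records in records_by_disease.items():
        vals = np.array([r.fold_difference for r in records if not r.undefined])
        if len(vals) < 2:
            raise ValueError(f"{disease}: need >= 2 usable fold differences")
        degenerate = False
        if np.allclose(vals.std(ddof=1), 0):
            if np.allclose(vals, 1.0):
                t, p = 0.0, 1.0
            else:
                t, p, degenerate = np.inf * np.sign(vals[0] - 1), 0.0, True
        else:
            t, p = stats.ttest_1samp(vals, popmean=1.0)
        rows.append({"disease": disease, "n_comparisons": len(vals),
                     "mean_fold_difference": float(vals.mean()),
                     "t_stat": float(t), "p_value": float(p),
                     "degenerate": degenerate})
    df = pd.DataFrame(rows).set_index("disease")
    df["p_holm"] = multipletests(df["p_value"], method="holm")[1]
    return df


# ---------------------------------------------------------------------------
# genus presence matrices
# ---------------------------------------------------------------------------

def genus_presence(results: Mapping[str, DaResult],
                   comparisons: Sequence[Comparison],
                   taxonomy: TaxonomyMap,
                   alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disease x genus proportion matrices, one per enrichment side.

    Cell value = fraction of the disease's comparisons in which the genus had
    >= 1 significantly differential OTU on that side (healthy side = genus
    depleted in disease, "potentially beneficial"; disease side = enriched in
    disease, "potentially pathogenic").  OTUs unclassified at genus level are
    dropped; genera never significant on either side are pruned.

    Returns (healthy_side, disease_side) DataFrames sharing the pruned genus
    columns.
    """
    per_disease: dict[str, list[Comparison]] = {}
    for comp in comparisons:
        per_disease.setdefault(comp.disease, []).append(comp)

    counts = {side: {} for side in ("healthy", "disease")}
    genera_seen: set[str] = set()
    for disease, comps in per_disease.items():
        h_hits: dict[str, int] = {}
        d_hits: dict[str, int] = {}
        for comp in comps:
            res = results[comp.comparison_id]
            sig = np.isfinite(res.p_adj) & (res.p_adj < alpha)
            ids = np.array(res.otu_ids)
            healthy_otus = ids[sig & (res.log2fc < 0)]
            disease_otus = ids[sig & (res.log2fc > 0)]
            for bucket, otus in ((h_hits, healthy_otus), (d_hits, disease_otus)):
                for genus in reduce_to_genus(otus, taxonomy):
                    bucket[genus] = bucket.get(genus, 0) + 1
                    genera_seen.add(genus)
        n = len(comps)
        counts["healthy"][disease] = {g: c / n for g, c in h_hits.items()}
        counts["disease"][disease] = {g: c / n for g, c in d_hits.items()}

    genera = sorted(genera_seen)
    diseases = list(per_disease)
    mats = []
    for side in ("healthy", "disease"):
        mat = pd.DataFrame(0.0, index=diseases, columns=genera)
        for disease, vals in counts[side].items():
            for genus, frac in vals.items():
                mat.loc[disease, genus] = frac
        mats.append(mat)
    return mats[0], mats[1]


# ---------------------------------------------------------------------------
# hierarchical clustering with multiscale-bootstrap support
# ---------------------------------------------------------------------------

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


@dataclasses.dataclass
class ClusterSupport:
    """Dendrogram of the disease rows plus per-node support values."""

    linkage: np.ndarray
    labels: list[str]
    nodes: pd.DataFrame     # columns: members (frozenset of labels), bp, au


def _node_leaf_sets(linkage: np.ndarray, labels: Sequence[str]
                    ) -> list[frozenset]:
    """Leaf-label set of each internal node of a scipy linkage, in merge order."""
    n = len(labels)
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(linkage):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + k] = merged
        out.append(merged)
    return out


def _cluster_sets(x: np.ndarray, labels: Sequence[str], method: str,
                  metric: str) -> set[frozenset]:
    z = hierarchy.linkage(x, method=method, metric=metric)
    return set(_node_leaf_sets(z, labels))


def fit_au(scales: np.ndarray, bp: np.ndarray, n_boot: int) -> float:
    """Approximately unbiased support from per-scale bootstrap probabilities.

    Fits probit(1 - bp(r)) = v*sqrt(r) + c/sqrt(r) by weighted least squares
    (binomial variance weights) and evaluates AU = 1 - Phi(v - c).  BP values
    are clamped away from {0, 1} before the probit; unanimous support (bp = 1
    at every scale) or unanimous absence maps to AU = 1 or 0 directly.
    """
    bp = np.asarray(bp, dtype=float)
    if np.all(bp >= 1.0):
        return 1.0
    if np.all(bp <= 0.0):
        return 0.0
    lo, hi = 1.0 / (n_boot + 1), n_boot / (n_boot + 1.0)
    bpc = np.clip(bp, lo, hi)
    z = stats.norm.ppf(1.0 - bpc)
    sq = np.sqrt(scales)
    design = np.column_stack([sq, 1.0 / sq])
    w = n_boot * stats.norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
    wsq = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * wsq[:, None], z * wsq, rcond=None)
    v, c = coef
    return float(stats.norm.sf(v - c))


def cluster_with_support(matrix: pd.DataFrame, n_boot: int = 1000,
                         scales: Sequence[float] = DEFAULT_SCALES,
                         seed: int = 0, method: str = "complete",
                         metric: str = "euclidean") -> ClusterSupport:
    """Cluster matrix rows and attach multiscale-bootstrap AU/BP support.

    For each scale r the genus columns are resampled with replacement at size
    ceil(r * m), the rows re-clustered, and bp(node, r) recorded as the
    fraction of replicates whose dendrogram contains the node's leaf set; AU
    follows from the probit fit over scales (see ``fit_au``).  Reported bp is
    the fraction at the scale closest to 1.  Deterministic under ``seed``.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 rows to cluster")
    labels = [str(i) for i in matrix.index]
    x = matrix.to_numpy(dtype=float)
    m = x.shape[1]
    rng = np.random.default_rng(seed)
    scales = np.asarray(sorted(scales), dtype=float)

    z = hierarchy.linkage(x, method=method, metric=metric)
    node_sets = _node_leaf_sets(z, labels)

    if np.allclose(pdist(x), 0):
        # all rows identical: topology is forced, support is total
        nodes = pd.DataFrame({"members": node_sets,
                              "bp": 1.0, "au": 1.0})
        return ClusterSupport(z, labels, nodes)

    bp_by_scale = np.zeros((len(node_sets), len(scales)))
    for si, r in enumerate(scales):
        m_r = max(2, int(np.ceil(r * m)))
        hits = np.zeros(len(node_sets))
        for _ in range(n_boot):
            cols = rng.integers(0, m, size=m_r)
            found = _cluster_sets(x[:, cols], labels, method, metric)
            for ni, s in enumerate(node_sets):
                if s in found:
                    hits[ni] += 1
        bp_by_scale[:, si] = hits / n_boot

    ref = int(np.argmin(np.abs(scales - 1.0)))
    nodes = pd.DataFrame({
        "members": node_sets,
        "bp": bp_by_scale[:, ref],
        "au": [fit_au(scales, bp_by_scale[ni], n_boot)
               for ni in range(len(node_sets))],
    })
    return ClusterSupport(z, labels, nodes)


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    n = len(labels)
    reps: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for k, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        reps[n + k] = f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g})"
        heights[n + k] = h
    return reps[n + len(linkage) - 1] + ";"
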