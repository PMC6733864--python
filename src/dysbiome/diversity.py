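"""Genus-diversity adjustment of dysbiosis calls.

Genera with many constituent OTUs accumulate dysbiotic OTUs by diversity
alone.  This module quantifies that relationship (Spearman correlation of
total vs dysbiotic OTUs per genus) and flags genera whose dysbiotic-OTU
count exceeds the diversity-based expectation by more than three residual
standard deviations — the three-sigma rule, one-sided (excess only).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_tables import TaxonomyMap, reduce_to_genus
from .design import Comparison
from .differential_abundance import DaResult


@dataclasses.dataclass
class GenusDiversityRecord:
    genus: str
    total_otus: int
    dysbiotic_otus: float
    expected: float = np.nan
    residual_sd_units: float = np.nan
    flagged: bool = False


def build_genus_records(results: Mapping[str, DaResult],
                        comparisons: Sequence[Comparison],
                        taxonomy: TaxonomyMap,
                        all_otu_ids: Sequence[str],
                        alpha: float = 0.05,
                        counting: str = "unique",
                        side: str = "both") -> list[GenusDiversityRecord]:
    """Per-genus totals and dysbiotic-OTU counts for one disease's comparisons.

    ``total_otus`` counts unique OTUs per genus in the full (filtered) table;
    ``dysbiotic_otus`` counts, per genus, either unique OTUs significant in
    >= 1 comparison (``counting='unique'``) or OTU x comparison significance
    events (``'events'``).  ``side`` pools both enrichment directions by
    default; 'healthy' or 'disease' restricts to one.
    """
    totals = {g: len(o) for g, o in reduce_to_genus(all_otu_ids, taxonomy).items()}
    hit_otus: dict[str, set[str]] = {g: set() for g in totals}
    hit_events: dict[str, float] = {g: 0.0 for g in totals}
    for comp in comparisons:
        res = results[comp.comparison_id]
        sig = np.isfinite(res.p_adj) & (res.p_adj < alpha)
        if side == "healthy":
            sig &= res.log2fc < 0
        elif side == "disease":
            sig &= res.log2fc > 0
        ids = np.array(res.otu_ids)[sig]
        for genus, otus in reduce_to_genus(ids, taxonomy).items():
            if genus in totals:
                hit_otus[genus] |= otus
                hit_events[genus] += len(otus)
    records = []
    for genus, total in totals.items():
        dys = len(hit_otus[genus]) if counting == "unique" else hit_events[genus]
        records.append(GenusDiversityRecord(genus, total, float(dys)))
    return records


def spearman_diversity_corr(records: Sequence[GenusDiversityRecord]
                            ) -> tuple[float, float]:
    """Spearman correlation (average ranks for ties) of total vs dysbiotic
    OTU counts across genera, with its large-sample p-value."""
    if len(records) < 4:
        raise ValueError("need >= 4 genera")
    x = np.array([r.total_otus for r in records], dtype=float)
    y = np.array([r.dysbiotic_otus for r in records], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def three_sigma_flags(records: Sequence[GenusDiversityRecord],
                      model: str = "ols",
                      sd_threshold: float = 3.0
                      ) -> list[GenusDiversityRecord]:
    """Flag genera more dysbiotic than their diversity predicts.

    The expectation is a least-squares line of dysbiotic on total OTU counts
    (``model='ols'``; ``'through_origin'`` forces a zero intercept,
    ``'robust'`` uses a Theil-Sen fit).  Residual SD uses n-2 degrees of
    freedom; a genus is flagged only when its residual exceeds
    ``sd_threshold`` standard deviations *above* the line (one-sided).
    """
    if len(records) < 4:
        raise ValueError("need >= 4 genera")
    x = np.array([r.total_otus for r in records], dtype=float)
    y = np.array([r.dysbiotic_otus for r in records], dtype=float)
    if model == "ols":
        slope, intercept = np.polyfit(x, y, 1)
    elif model == "through_origin":
        slope, intercept = float(x @ y / (x @ x)), 0.0
    elif model == "robust":
        slope, intercept, *_ = stats.theilslopes(y, x)
    else:
        raise ValueError(f"unknown model {model!r}")
    expected = slope * x + intercept
    resid = y - expected
    sd = float(np.sqrt((resid ** 2).sum() / max(len(x) - 2, 1)))
    out = []
    for rec, e, r in zip(records, expected, resid):
        units = r / sd if sd > 0 else 0.0
        out.append(dataclasses.replace(
            rec, expected=float(e), residual_sd_units=float(units),
            flagged=bool(sd > 0 and units > sd_threshold)))
    return out


def records_to_frame(records: Sequence[GenusDiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records]
                        ).set_index("genus")
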