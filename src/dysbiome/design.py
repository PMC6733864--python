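"""Cohort subdivision into independent populations and the stochastic null.

Each health status is split into disjoint subsets by assigned uniform random
numbers: samples are ranked by their number and cut into consecutive blocks
(lowest, middle, highest ...), giving independent populations.  A parallel
"stochastic" labelling reassigns fresh random numbers independent of all
metadata and splits samples into two pseudo-statuses, which serve as the
null for every downstream dysbiosis metric.  Pairwise comparisons are then
enumerated either as a full cross of healthy x disease subsets (pooled-source
design) or one comparison per study (study-wise design).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised when a cohort cannot support the requested subdivision."""


@dataclasses.dataclass
class Comparison:
    comparison_id: str
    group1: list[str]           # healthy / stochastic-group-1 sample ids
    group2: list[str]           # disease / stochastic-group-2 sample ids
    disease: str
    cohort: str

    def __post_init__(self) -> None:
        if set(self.group1) & set(self.group2):
            raise DesignError(f"{self.comparison_id}: groups overlap")


@dataclasses.dataclass
class ComparisonPlan:
    comparisons: list[Comparison]

    def __len__(self) -> int:
        return len(self.comparisons)

    def by_disease(self) -> dict[str, list[Comparison]]:
        out: dict[str, list[Comparison]] = {}
        for c in self.comparisons:
            out.setdefault(c.disease, []).append(c)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = [dataclasses.asdict(c) for c in self.comparisons]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ComparisonPlan":
        payload = json.loads(Path(path).read_text())
        return cls([Comparison(**c) for c in payload])


def assign_random_numbers(samples: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Attach a uniform [0, 1) ``random_number`` column (re-drawn on the
    measure-zero event of a collision so ranks are strict)."""
    rng = np.random.default_rng(seed)
    n = len(samples)
    nums = rng.random(n)
    while len(np.unique(nums)) < n:   # pragma: no cover - probability ~0
        nums = rng.random(n)
    out = samples.copy()
    out["random_number"] = nums
    return out


def subdivide(samples: pd.DataFrame, subset_size: int = 100,
              n_subsets: int = 3) -> list[list[str]]:
    """Split one health status into disjoint rank-block subsets.

    Samples are ordered by ``random_number``; subset k holds ranks
    ``k*subset_size .. (k+1)*subset_size - 1``.  When fewer than
    ``subset_size * n_subsets`` samples are available but at least one full
    subset fits, the lowest block(s) that fit are returned (the small-cohort
    case); fewer than one subset is an error.
    """
    if "random_number" not in samples.columns:
        raise DesignError("samples need assigned random numbers; "
                          "call assign_random_numbers first")
    n = len(samples)
    if n < subset_size:
        raise DesignError(
            f"{n} samples cannot fill even one subset of {subset_size}")
    k = min(n_subsets, n // subset_size)
    ordered = samples.sort_values("random_number").index.to_list()
    return [ordered[i * subset_size:(i + 1) * subset_size] for i in range(k)]


def make_stochastic_groups(samples: pd.DataFrame, seed: int,
                           subset_size: int = 100, n_subsets: int = 3
                           ) -> tuple[list[list[str]], list[list[str]]]:
    """Build the stochastic-label null: fresh random numbers independent of
    all metadata, then 2 pseudo-statuses x ``n_subsets`` subsets each.

    Returns (group1_subsets, group2_subsets).  Ranks 1..3k go to stochastic
    group 1 and ranks 3k+1..6k to group 2, each cut into rank blocks.
    """
    need = 2 * subset_size * n_subsets
    if len(samples) < need:
        raise DesignError(f"need >= {need} samples for stochastic groups, "
                          f"have {len(samples)}")
    relabelled = assign_random_numbers(samples, seed)
    ordered = relabelled.sort_values("random_number").index.to_list()
    half = subset_size * n_subsets
    g1, g2 = ordered[:half], ordered[half:2 * half]
    cut = lambda ids: [ids[i * subset_size:(i + 1) * subset_size]
                       for i in range(n_subsets)]
    return cut(g1), cut(g2)


def enumerate_comparisons(design: str, healthy_subsets: list[list[str]],
                          disease_subsets: list[list[str]], disease: str,
                          cohort: str = "pooled") -> ComparisonPlan:
    """Enumerate pairwise comparisons for one disease.

    ``design='cross'``: every healthy subset against every disease subset
    (3x3 = 9, or 3x1 = 3 for a single-subset disease).  ``design='study'``:
    subsets are paired positionally, one comparison per study.
    """
    comps = []
    if design == "cross":
        for i, h in enumerate(healthy_subsets):
            for j, d in enumerate(disease_subsets):
                comps.append(Comparison(f"{disease}_h{i + 1}_d{j + 1}",
                                        list(h), list(d), disease, cohort))
    elif design == "study":
        if len(healthy_subsets) != len(disease_subsets):
            raise DesignError("study-wise design needs one healthy and one "
                              "disease subset per study")
        for i, (h, d) in enumerate(zip(healthy_subsets, disease_subsets)):
            comps.append(Comparison(f"{disease}_study{i + 1}",
                                    list(h), list(d), disease,
                                    f"{cohort}_study{i + 1}"))
    else:
        raise DesignError(f"unknown design {design!r}")
    return ComparisonPlan(comps)
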