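"""Domain containers and plain-text I/O shared by every analysis stage.

The pipeline operates on four objects: an OTU count table (samples x OTUs),
a Greengenes-style taxonomy map, a rooted phylogeny whose tips are OTU ids,
and a per-sample metadata frame.  Everything downstream (differential
abundance, UniFrac, genus summaries) consumes these containers, so their
invariants are enforced here, once.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import skbio

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

METADATA_COLUMNS = ("cohort_id", "health_status", "antibiotic_last_year")


class FormatError(ValueError):
    """Raised when an input file violates the expected format or invariants."""


@dataclasses.dataclass
class OtuTable:
    """Integer count matrix with rows = samples and columns = OTUs.

    Parameters
    ----------
    counts : ndarray of shape (n_samples, n_otus)
        Non-negative integer read counts.
    sample_ids, otu_ids : list of str
        Unique identifiers for the rows and columns respectively.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise FormatError("counts must be numeric")
        if not np.all(np.isfinite(self.counts)):
            raise FormatError("counts must be finite")
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if np.any(self.counts != np.floor(self.counts)):
            raise FormatError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if len(self.sample_ids) != self.counts.shape[0]:
            raise FormatError("sample_ids length does not match matrix rows")
        if len(self.otu_ids) != self.counts.shape[1]:
            raise FormatError("otu_ids length does not match matrix columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        """Subset (and reorder) to the given samples."""
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        rows = [index[s] for s in wanted]
        return OtuTable(self.counts[rows], wanted, list(self.otu_ids))

    def select_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        wanted = list(otu_ids)
        index = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in wanted if o not in index]
        if missing:
            raise KeyError(f"OTUs not in table: {missing[:5]}")
        cols = [index[o] for o in wanted]
        return OtuTable(self.counts[:, cols], list(self.sample_ids), wanted)


class TaxonomyMap:
    """OTU id -> ranked lineage (kingdom ... species); ranks may be absent.

    An OTU is "unclassified at genus" when its genus token is missing, empty,
    or a bare ``g__`` prefix — Greengenes emits all three forms.
    """

    def __init__(self, lineages: Mapping[str, Mapping[str, str | None]]):
        self._lineages: dict[str, dict[str, str | None]] = {
            str(k): {r: v.get(r) for r in RANKS} for k, v in lineages.items()
        }

    def __len__(self) -> int:
        return len(self._lineages)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self._lineages

    def otu_ids(self) -> list[str]:
        return list(self._lineages)

    def lineage(self, otu_id: str) -> dict[str, str | None] | None:
        return self._lineages.get(otu_id)

    def rank(self, otu_id: str, rank: str) -> str | None:
        lin = self._lineages.get(otu_id)
        return None if lin is None else lin.get(rank)

    def genus(self, otu_id: str) -> str | None:
        """Genus name, or None when the OTU is unclassified at genus level."""
        return self.rank(otu_id, "genus")

    @classmethod
    def from_lineage_strings(cls, strings: Mapping[str, str]) -> "TaxonomyMap":
        out = {}
        for otu, s in strings.items():
            tokens = [t.strip() for t in str(s).split(";")]
            lineage: dict[str, str | None] = {}
            for rank, prefix, token in zip(RANKS, _RANK_PREFIXES, tokens):
                if token.startswith(prefix):
                    token = token[len(prefix):]
                token = token.strip()
                lineage[rank] = token if token else None
            out[otu] = lineage
        return cls(out)

    def to_lineage_strings(self) -> dict[str, str]:
        out = {}
        for otu, lineage in self._lineages.items():
            parts = []
            for rank, prefix in zip(RANKS, _RANK_PREFIXES):
                val = lineage.get(rank)
                parts.append(prefix + (val if val is not None else ""))
            out[otu] = "; ".join(parts)
        return out


# ---------------------------------------------------------------------------
# readers / writers (all plain TSV or Newick)
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, otus_as_columns: bool = True) -> OtuTable:
    """Read a TSV count table.

    With ``otus_as_columns`` (default) the first row holds OTU ids and the
    first column sample ids; the flag transposes on read for tables stored in
    the BIOM orientation (OTUs as rows).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not otus_as_columns:
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric cell in count table")
    return OtuTable(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of OTU id -> Greengenes lineage string."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"],
                     dtype=str, keep_default_na=False)
    return TaxonomyMap.from_lineage_strings(
        dict(zip(df["otu_id"], df["lineage"]))
    )


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu, lineage in taxonomy.to_lineage_strings().items():
            fh.write(f"{otu}\t{lineage}\n")


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted Newick tree; tips must carry OTU ids, branches lengths >= 0."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    validate_tree(tree)
    return tree


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def validate_tree(tree: skbio.TreeNode) -> None:
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise FormatError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError("negative branch length in tree")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (index = sample id).

    Requires columns cohort_id, health_status, antibiotic_last_year; the
    antibiotic flag may be missing (empty cell) and is parsed to a nullable
    boolean.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    df["antibiotic_last_year"] = _parse_bool(df["antibiotic_last_year"])
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def _parse_bool(col: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}

    def conv(v):
        if pd.isna(v) or v == "":
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return mapping[str(v).strip().lower()]

    return col.map(conv).astype("boolean")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_low_count(table: OtuTable, min_total: int = 10) -> OtuTable:
    """Drop OTUs with fewer than ``min_total`` reads summed over all samples.

    Mirrors the standard low-count filter for combined 16S datasets: an OTU
    seen fewer than 10 times across the whole dataset is removed; the sample
    set is unchanged.  Idempotent.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.counts.sum(axis=0) >= min_total
    return OtuTable(table.counts[:, keep],
                    list(table.sample_ids),
                    [o for o, k in zip(table.otu_ids, keep) if k])


def reduce_to_genus(otu_ids: Iterable[str], taxonomy: TaxonomyMap
                    ) -> dict[str, set[str]]:
    """Bucket OTUs by genus; OTUs unclassified at genus level are dropped."""
    out: dict[str, set[str]] = {}
    for otu in otu_ids:
        genus = taxonomy.genus(otu)
        if genus is None:
            continue
        out.setdefault(genus, set()).add(otu)
    return out
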