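"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure of combined 16S gut-microbiome cohorts:
negative-binomial OTU counts over lognormal library depths, a heavy-tailed
rank-abundance curve, genus-structured taxonomy with power-law genus sizes,
a random rooted phylogeny over the OTUs, a disease effect realised mostly as
depletion of a configurable OTU subset (loss-of-function dysbiosis) plus a
smaller enriched subset, and an antibiotic covariate that shifts community
composition.  Every downstream stage is recovery-tested against the planted
truth this module returns.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

from .core_tables import OtuTable, TaxonomyMap


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclasses.dataclass
class SimulationConfig:
    """Generative settings for one two-group (healthy vs disease) cohort.

    Defaults mirror a single AGP-style health-status pool: 300 samples per
    group (three subsets of 100), a few hundred OTUs spread over dozens of
    genera with power-law sizes, ~20k-read lognormal libraries, moderate NB
    overdispersion, and a disease effect that depletes three times as many
    OTUs as it enriches (loss-of-function dysbiosis) at four-fold strength.
    """

    n_samples_per_group: int = 300
    n_otus: int = 500
    n_genera: int = 40
    genus_size_exponent: float = 1.5
    frac_unclassified_genus: float = 0.05
    depth_log_mean: float = math.log(2e4)
    depth_log_sd: float = 0.4
    nb_dispersion: float = 0.3
    frac_depleted_in_disease: float = 0.15
    frac_enriched_in_disease: float = 0.05
    effect_log2fc: float = 2.0
    antibiotic_effect_log2fc: float = 1.0
    frac_antibiotic_affected: float = 0.2
    antibiotic_prevalence_healthy: float = 0.25
    antibiotic_prevalence_disease: float = 0.45
    abundance_log_sd: float = 1.5
    branch_length_scale: float = 0.1
    disease_name: str = "disease"
    planted_excess_genus: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genera > self.n_otus:
            raise ConfigError("n_genera cannot exceed n_otus")
        if self.n_otus < 2 or self.n_samples_per_group < 1:
            raise ConfigError("need at least 2 OTUs and 1 sample per group")
        if self.frac_depleted_in_disease + self.frac_enriched_in_disease > 1:
            raise ConfigError("frac_depleted + frac_enriched must be <= 1")
        for name in ("frac_depleted_in_disease", "frac_enriched_in_disease",
                     "frac_unclassified_genus", "frac_antibiotic_affected",
                     "antibiotic_prevalence_healthy",
                     "antibiotic_prevalence_disease"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.effect_log2fc < 0 or self.antibiotic_effect_log2fc < 0:
            raise ConfigError("effect sizes must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Planted effects, the oracle for recovery tests."""

    otu_ids: list[str]
    true_log2fc: np.ndarray           # disease relative to healthy
    dysbiotic_flag: np.ndarray        # 'depleted' | 'enriched' | 'null'
    antibiotic_log2fc: np.ndarray
    planted_excess_genus: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "otu_id": self.otu_ids,
            "true_log2fc": self.true_log2fc,
            "dysbiotic_flag": self.dysbiotic_flag,
            "antibiotic_log2fc": self.antibiotic_log2fc,
        }).set_index("otu_id")


def _genus_assignment(cfg: SimulationConfig, rng: np.random.Generator
                      ) -> list[str | None]:
    """Assign OTUs to genera with power-law genus sizes; some stay unclassified."""
    weights = np.arange(1, cfg.n_genera + 1, dtype=float) ** (-cfg.genus_size_exponent)
    weights /= weights.sum()
    genera = [f"Genus{g:03d}" for g in range(1, cfg.n_genera + 1)]
    n_unclassified = int(round(cfg.frac_unclassified_genus * cfg.n_otus))
    n_classified = cfg.n_otus - n_unclassified
    # guarantee every genus is non-empty, then fill multinomially
    assignment: list[str | None] = list(genera[:min(cfg.n_genera, n_classified)])
    extra = n_classified - len(assignment)
    if extra > 0:
        assignment += [genera[i] for i in rng.choice(cfg.n_genera, size=extra,
                                                     p=weights)]
    assignment += [None] * n_unclassified
    rng.shuffle(assignment)
    return assignment


def _taxonomy_from_assignment(otu_ids: Sequence[str],
                              assignment: Sequence[str | None]) -> TaxonomyMap:
    lineages = {}
    for otu, genus in zip(otu_ids, assignment):
        lineages[otu] = {
            "kingdom": "Bacteria", "phylum": "SimPhylum", "class": "SimClass",
            "order": "SimOrder", "family": "SimFamily",
            "genus": genus, "species": None,
        }
    return TaxonomyMap(lineages)


def random_coalescent_tree(tip_ids: Sequence[str], rng: np.random.Generator,
                           branch_length_scale: float = 0.1) -> skbio.TreeNode:
    """Random rooted bifurcating tree built by successive random joins,
    with exponential branch lengths."""
    nodes = [skbio.TreeNode(name=t) for t in tip_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        a.length = float(rng.exponential(branch_length_scale))
        b.length = float(rng.exponential(branch_length_scale))
        parent = skbio.TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB draws parameterised by mean and dispersion alpha (var = m + alpha m^2)."""
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-300))
    out = rng.negative_binomial(size, p)
    out[mean <= 0] = 0
    return out


def simulate_cohort(cfg: SimulationConfig
                    ) -> tuple[OtuTable, TaxonomyMap, skbio.TreeNode,
                               pd.DataFrame, GroundTruth]:
    """Simulate one healthy-vs-disease cohort with planted effects.

    Counts for OTU i in sample j are negative binomial with mean

        rel_abund_i * depth_j * 2**(disease_j * lfc_i + abx_j * abx_lfc_i)

    and shared dispersion.  Same config (incl. seed) gives identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_otus
    otu_ids = [f"OTU{i:05d}" for i in range(n)]

    assignment = _genus_assignment(cfg, rng)
    taxonomy = _taxonomy_from_assignment(otu_ids, assignment)

    # heavy-tailed baseline relative abundances (Dirichlet via per-OTU gammas
    # with lognormal concentrations)
    conc = rng.lognormal(mean=0.0, sigma=cfg.abundance_log_sd, size=n)
    raw = rng.gamma(shape=conc, scale=1.0)
    raw = np.maximum(raw, 1e-12)
    rel_abund = raw / raw.sum()

    # planted disease effects
    true_lfc, flags, excess_genus = _plant_effects(cfg, rng, assignment)

    # antibiotic effect: depletion of an affected OTU subset
    abx_lfc = np.zeros(n)
    if cfg.antibiotic_effect_log2fc > 0 and cfg.frac_antibiotic_affected > 0:
        n_abx = int(round(cfg.frac_antibiotic_affected * n))
        affected = rng.choice(n, size=n_abx, replace=False)
        abx_lfc[affected] = -cfg.antibiotic_effect_log2fc

    # samples
    n_per = cfg.n_samples_per_group
    sample_ids = ([f"H{i:04d}" for i in range(n_per)]
                  + [f"D{i:04d}" for i in range(n_per)])
    disease_ind = np.repeat([0, 1], n_per)
    abx_prev = np.where(disease_ind == 1, cfg.antibiotic_prevalence_disease,
                        cfg.antibiotic_prevalence_healthy)
    abx_flag = rng.random(2 * n_per) < abx_prev
    depth = rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=2 * n_per)

    log2_shift = (np.outer(disease_ind, true_lfc)
                  + np.outer(abx_flag.astype(float), abx_lfc))
    mean = rel_abund[None, :] * depth[:, None] * np.exp2(log2_shift)
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)

    table = OtuTable(counts, sample_ids, otu_ids)
    meta = pd.DataFrame({
        "cohort_id": "sim",
        "health_status": np.where(disease_ind == 1, cfg.disease_name, "healthy"),
        "antibiotic_last_year": abx_flag,
    }, index=pd.Index(sample_ids, name="sample_id"))

    tree = random_coalescent_tree(otu_ids, rng, cfg.branch_length_scale)
    truth = GroundTruth(otu_ids, true_lfc, flags, abx_lfc, excess_genus)
    return table, taxonomy, tree, meta, truth


def _plant_effects(cfg: SimulationConfig, rng: np.random.Generator,
                   assignment: Sequence[str | None]
                   ) -> tuple[np.ndarray, np.ndarray, dict[str, bool]]:
    """Draw the depleted / enriched OTU sets for one disease."""
    n = cfg.n_otus
    true_lfc = np.zeros(n)
    flags = np.full(n, "null", dtype=object)
    excess_genus: dict[str, bool] = {}
    if cfg.effect_log2fc <= 0:
        return true_lfc, flags, excess_genus
    n_dep = int(round(cfg.frac_depleted_in_disease * n))
    n_enr = int(round(cfg.frac_enriched_in_disease * n))
    pool = np.arange(n)
    if cfg.planted_excess_genus and n_dep > 0:
        target = "Genus001"
        members = np.array([i for i, g in enumerate(assignment) if g == target])
        take = members[:max(1, min(len(members), n_dep // 2))]
        rest_pool = np.setdiff1d(pool, take)
        rest = rng.choice(rest_pool, size=n_dep - len(take), replace=False)
        depleted = np.concatenate([take, rest])
        excess_genus[target] = True
    else:
        depleted = rng.choice(pool, size=n_dep, replace=False)
    remaining = np.setdiff1d(pool, depleted)
    enriched = rng.choice(remaining, size=n_enr, replace=False)
    true_lfc[depleted] = -cfg.effect_log2fc
    true_lfc[enriched] = cfg.effect_log2fc
    flags[depleted] = "depleted"
    flags[enriched] = "enriched"
    return true_lfc, flags, excess_genus


def simulate_study(cfg: SimulationConfig, diseases: Sequence[str],
                   n_samples_by_disease: Mapping[str, int] | None = None
                   ) -> tuple[OtuTable, TaxonomyMap, skbio.TreeNode,
                              pd.DataFrame, dict[str, GroundTruth]]:
    """Simulate one healthy pool plus several disease groups over a shared
    community (the pooled-source study structure).

    All groups share the taxonomy, phylogeny, baseline relative abundances
    and antibiotic-affected OTU set; each disease draws its own planted
    depleted/enriched sets (so diseases overlap in their dysbiotic OTUs by
    chance, in proportion to the fractions configured).  Returns the ground
    truth per disease.
    """
    cfg.validate()
    if not diseases:
        raise ConfigError("need at least one disease")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_otus
    otu_ids = [f"OTU{i:05d}" for i in range(n)]
    assignment = _genus_assignment(cfg, rng)
    taxonomy = _taxonomy_from_assignment(otu_ids, assignment)

    conc = rng.lognormal(mean=0.0, sigma=cfg.abundance_log_sd, size=n)
    raw = rng.gamma(shape=conc, scale=1.0)
    rel_abund = np.maximum(raw, 1e-12)
    rel_abund = rel_abund / rel_abund.sum()

    abx_lfc = np.zeros(n)
    if cfg.antibiotic_effect_log2fc > 0 and cfg.frac_antibiotic_affected > 0:
        n_abx = int(round(cfg.frac_antibiotic_affected * n))
        affected = rng.choice(n, size=n_abx, replace=False)
        abx_lfc[affected] = -cfg.antibiotic_effect_log2fc

    truths: dict[str, GroundTruth] = {}
    group_names = ["healthy"] + list(diseases)
    blocks, meta_rows, sample_ids = [], [], []
    for gi, group in enumerate(group_names):
        if group == "healthy":
            lfc = np.zeros(n)
        else:
            lfc, flags, excess = _plant_effects(cfg, rng, assignment)
            truths[group] = GroundTruth(otu_ids, lfc, flags, abx_lfc, excess)
        n_g = cfg.n_samples_per_group
        if n_samples_by_disease and group in n_samples_by_disease:
            n_g = n_samples_by_disease[group]
        prev = (cfg.antibiotic_prevalence_healthy if group == "healthy"
                else cfg.antibiotic_prevalence_disease)
        abx_flag = rng.random(n_g) < prev
        depth = rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=n_g)
        shift = lfc[None, :] + np.outer(abx_flag.astype(float), abx_lfc)
        mean = rel_abund[None, :] * depth[:, None] * np.exp2(shift)
        blocks.append(_nb_draw(rng, mean, cfg.nb_dispersion))
        ids = [f"G{gi}S{i:04d}" for i in range(n_g)]
        sample_ids.extend(ids)
        for sid, fl in zip(ids, abx_flag):
            meta_rows.append({"sample_id": sid, "cohort_id": "sim",
                              "health_status": group,
                              "antibiotic_last_year": bool(fl)})

    table = OtuTable(np.vstack(blocks), sample_ids, otu_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    tree = random_coalescent_tree(otu_ids, rng, cfg.branch_length_scale)
    return table, taxonomy, tree, meta, truths


def simulate_antibiotic_table(n_per_group: int, prev_healthy: float,
                              prev_disease: float, seed: int) -> np.ndarray:
    """2x2 antibiotic-exposure contingency table.

    Rows = (disease, healthy), columns = (antibiotic, no antibiotic); each
    row's margin is ``n_per_group`` and exposure cells are Binomial draws at
    the group prevalence.
    """
    if not (0 <= prev_healthy <= 1 and 0 <= prev_disease <= 1):
        raise ConfigError("prevalences must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a = int(rng.binomial(n_per_group, prev_disease))
    c = int(rng.binomial(n_per_group, prev_healthy))
    return np.array([[a, n_per_group - a], [c, n_per_group - c]], dtype=np.int64)
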