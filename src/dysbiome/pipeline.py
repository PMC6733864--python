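"""End-to-end orchestration: simulate-or-load -> filter -> design -> DA ->
dysbiosis summaries -> diversity adjustment -> antibiotic association ->
beta diversity -> manifest.

Stages communicate via plain-text files in the output directory so each is
inspectable and the whole run is reproducible: a manifest records every seed
and a checksum of every artifact, and rerunning a config byte-reproduces the
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import antibiotics as abx
from . import beta_diversity as beta
from . import core_tables as ct
from . import design as dsg
from . import diversity as dvs
from . import summary as smr
from .differential_abundance import DaResult, count_enriched, wald_test
from .synthetic import SimulationConfig, simulate_study

log = logging.getLogger("dysbiome")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted in stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    mode: str = "simulate"                    # 'simulate' | 'load'
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    diseases: list[str] = dataclasses.field(
        default_factory=lambda: ["cardiovascular", "diabetes", "obesity"])
    # load-mode inputs
    otu_table: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    metadata: str | None = None
    # analysis settings
    min_total_count: int = 10
    alpha: float = 0.05
    subset_size: int = 100
    n_subsets: int = 3
    design: str = "cross"
    seed_subdivision: int = 11
    seed_stochastic: int = 23
    seed_bootstrap: int = 37
    seed_permutation: int = 47
    n_boot: int = 1000
    n_perm: int = 999
    unifrac_variant: str = "normalized"
    beta_max_samples: int | None = 120
    run_beta: bool = True
    run_cluster: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage failure halts the run with the failing stage named; artifacts
    written by earlier stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": _config_dict(cfg),
        "stages": {},
        "files": {},
    }
    stage = "inputs"
    try:
        t0 = time.time()
        if cfg.mode == "simulate":
            table, taxonomy, tree, meta, truths = simulate_study(
                cfg.simulation, cfg.diseases)
            pd.concat({d: t.to_frame() for d, t in truths.items()},
                      names=["disease"]).to_csv(out / "ground_truth.tsv",
                                                sep="\t")
            ct.write_taxonomy(taxonomy, out / "taxonomy.tsv")
            ct.write_tree(tree, out / "tree.nwk")
        elif cfg.mode == "load":
            for name in ("otu_table", "taxonomy", "metadata"):
                p = getattr(cfg, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} path missing: {p}")
            table = ct.read_otu_table(cfg.otu_table)
            taxonomy = ct.read_taxonomy(cfg.taxonomy)
            meta = ct.read_metadata(cfg.metadata)
            tree = None  # loaded lazily by the beta stage
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")
        _stage_done(manifest, stage, t0)

        stage = "filter"
        t0 = time.time()
        table = ct.filter_low_count(table, cfg.min_total_count)
        ct.write_otu_table(table, out / "filtered_table.tsv")
        ct.write_metadata(meta, out / "metadata.tsv")
        _stage_done(manifest, stage, t0)

        stage = "plan"
        t0 = time.time()
        meta = meta.loc[[s for s in table.sample_ids]]
        statuses = sorted(set(meta["health_status"]))
        diseases = [s for s in statuses if s != "healthy"]
        meta_rnd = dsg.assign_random_numbers(meta, cfg.seed_subdivision)
        healthy_subs = dsg.subdivide(meta_rnd[meta_rnd.health_status == "healthy"],
                                     cfg.subset_size, cfg.n_subsets)
        all_comparisons: list[dsg.Comparison] = []
        for disease in diseases:
            d_subs = dsg.subdivide(meta_rnd[meta_rnd.health_status == disease],
                                   cfg.subset_size, cfg.n_subsets)
            plan = dsg.enumerate_comparisons(cfg.design, healthy_subs, d_subs,
                                             disease)
            all_comparisons.extend(plan.comparisons)
        g1, g2 = dsg.make_stochastic_groups(meta, cfg.seed_stochastic,
                                            cfg.subset_size, cfg.n_subsets)
        stoch = dsg.enumerate_comparisons("cross", g1, g2, "stochastic")
        all_comparisons.extend(stoch.comparisons)
        full_plan = dsg.ComparisonPlan(all_comparisons)
        full_plan.to_json(out / "comparison_plan.json")
        _stage_done(manifest, stage, t0)

        stage = "differential_abundance"
        t0 = time.time()
        da_dir = out / "da"
        da_dir.mkdir(exist_ok=True)
        results: dict[str, DaResult] = {}
        for comp in full_plan.comparisons:
            sub = table.select_samples(comp.group1 + comp.group2)
            labels = np.array([0] * len(comp.group1) + [1] * len(comp.group2))
            res = wald_test(sub, labels)
            results[comp.comparison_id] = res
            res.to_frame().to_csv(da_dir / f"{comp.comparison_id}.tsv", sep="\t")
        _stage_done(manifest, stage, t0)

        stage = "fold_difference"
        t0 = time.time()
        records_by_disease: dict[str, list[smr.FoldDifferenceRecord]] = {}
        for comp in full_plan.comparisons:
            n1, n2 = count_enriched(results[comp.comparison_id], cfg.alpha)
            rec = smr.fold_difference(n1, n2, comp.comparison_id)
            records_by_disease.setdefault(comp.disease, []).append(rec)
        all_records = [r for recs in records_by_disease.values() for r in recs]
        smr.records_to_frame(all_records).to_csv(
            out / "fold_differences.tsv", sep="\t", index=False)
        # a group with < 2 defined fold differences (e.g. stochastic labels
        # with no discoveries) cannot be tested; reported as NaN
        testable = {d: r for d, r in records_by_disease.items()
                    if sum(not x.undefined for x in r) >= 2}
        skipped = sorted(set(records_by_disease) - set(testable))
        ttests = smr.test_fold_bias(testable) if testable else pd.DataFrame()
        for d in skipped:
            ttests.loc[d] = np.nan
        ttests.to_csv(out / "fold_difference_tests.tsv", sep="\t")
        _stage_done(manifest, stage, t0)

        stage = "genus_summary"
        t0 = time.time()
        disease_comps = [c for c in full_plan.comparisons
                         if c.disease != "stochastic"]
        mat_h, mat_d = smr.genus_presence(results, disease_comps, taxonomy,
                                          cfg.alpha)
        mat_h.to_csv(out / "genus_matrix_healthy_side.tsv", sep="\t")
        mat_d.to_csv(out / "genus_matrix_disease_side.tsv", sep="\t")
        if cfg.run_cluster and mat_h.shape[0] >= 3:
            support_rows = []
            for side, mat in (("healthy", mat_h), ("disease", mat_d)):
                cs = smr.cluster_with_support(mat, cfg.n_boot,
                                              seed=cfg.seed_bootstrap)
                (out / f"dendrogram_{side}_side.nwk").write_text(
                    smr.linkage_to_newick(cs.linkage, cs.labels) + "\n")
                for _, row in cs.nodes.iterrows():
                    support_rows.append({
                        "side": side,
                        "members": "|".join(sorted(row["members"])),
                        "bp": row["bp"], "au": row["au"]})
            pd.DataFrame(support_rows).to_csv(out / "cluster_support.tsv",
                                              sep="\t", index=False)
        _stage_done(manifest, stage, t0)

        stage = "diversity_adjustment"
        t0 = time.time()
        div_rows = []
        for disease, comps in full_plan.by_disease().items():
            if disease == "stochastic":
                continue
            recs = dvs.build_genus_records(results, comps, taxonomy,
                                           table.otu_ids, cfg.alpha)
            try:
                rho, p = dvs.spearman_diversity_corr(recs)
            except ValueError:
                rho, p = np.nan, np.nan
            flagged = dvs.three_sigma_flags(recs)
            df = dvs.records_to_frame(flagged)
            df.insert(0, "disease", disease)
            df["spearman_rho"] = rho
            df["spearman_p"] = p
            div_rows.append(df)
        pd.concat(div_rows).to_csv(out / "genus_diversity.tsv", sep="\t")
        _stage_done(manifest, stage, t0)

        stage = "antibiotic_association"
        t0 = time.time()
        assoc = abx.antibiotic_association(meta)
        assoc.to_csv(out / "antibiotic_association.tsv", sep="\t")
        _stage_done(manifest, stage, t0)

        if cfg.run_beta:
            stage = "phylo_beta"
            t0 = time.time()
            if tree is None:
                if cfg.tree is None or not Path(cfg.tree).exists():
                    raise FileNotFoundError(
                        f"beta-diversity stage needs a tree: {cfg.tree}")
                tree = ct.read_tree(cfg.tree)
            beta_table, beta_meta = table, meta
            if (cfg.beta_max_samples is not None
                    and table.n_samples > cfg.beta_max_samples):
                rng = np.random.default_rng(cfg.seed_permutation)
                pick = sorted(rng.choice(table.n_samples,
                                         cfg.beta_max_samples, replace=False))
                ids = [table.sample_ids[i] for i in pick]
                beta_table = table.select_samples(ids)
                beta_meta = meta.loc[ids]
            dm = beta.weighted_unifrac(beta_table, tree, cfg.unifrac_variant)
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)
                         ).to_csv(out / "unifrac_distances.tsv", sep="\t")
            coords, eig = beta.pcoa(dm)
            coords.iloc[:, :10].to_csv(out / "pcoa_coordinates.tsv", sep="\t")
            labels = beta_meta["antibiotic_last_year"].astype(bool).to_numpy()
            perm = beta.permanova(dm, labels, cfg.n_perm, cfg.seed_permutation)
            (out / "permanova.json").write_text(json.dumps(
                dataclasses.asdict(perm), indent=1))
            _stage_done(manifest, stage, t0)

        stage = "manifest"
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][str(f.relative_to(out))] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _stage_done(manifest: dict, stage: str, t0: float) -> None:
    elapsed = round(time.time() - t0, 3)
    manifest["stages"][stage] = {"status": "ok"}
    log.info("stage %s done in %.2fs", stage, elapsed)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
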