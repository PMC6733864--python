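"""Dysbiosis metrics: fold differences and genus-level commonalities.

From the per-comparison DA tables: (1) the fold difference in enriched-OTU
counts (healthy over disease) per comparison, with one-sample t-tests
against 1 and Holm correction — the loss-of-function signal; (2) disease x
genus presence-proportion matrices per enrichment side; (3) hierarchical
clustering of the disease rows with multiscale-bootstrap AU/BP support.
"""

from pathlib import Path

import pandas as pd

from dysbiome import core_tables as ct
from dysbiome import summary as smr
from dysbiome.design import ComparisonPlan
from dysbiome.differential_abundance import DaResult, count_enriched

ROOT = Path(__file__).resolve().parent.parent / "results"
ALPHA = 0.05
SEED_BOOT = 37


def main() -> None:
    plan = ComparisonPlan.from_json(ROOT / "comparison_plan.json")
    taxonomy = ct.read_taxonomy(ROOT / "data" / "taxonomy.tsv")
    results = {c.comparison_id:
               DaResult.from_frame(pd.read_csv(ROOT / "da" /
                                               f"{c.comparison_id}.tsv",
                                               sep="\t", index_col=0))
               for c in plan.comparisons}

    records_by_disease = {}
    for comp in plan.comparisons:
        n1, n2 = count_enriched(results[comp.comparison_id], ALPHA)
        rec = smr.fold_difference(n1, n2, comp.comparison_id)
        records_by_disease.setdefault(comp.disease, []).append(rec)
    all_recs = [r for v in records_by_disease.values() for r in v]
    smr.records_to_frame(all_recs).to_csv(ROOT / "fold_differences.tsv",
                                          sep="\t", index=False)
    testable = {d: r for d, r in records_by_disease.items()
                if sum(not x.undefined for x in r) >= 2}
    tests = smr.test_fold_bias(testable)
    tests.to_csv(ROOT / "fold_difference_tests.tsv", sep="\t")
    print("fold-difference t-tests vs 1 (Holm-corrected):")
    print(tests[["n_comparisons", "mean_fold_difference", "p_holm"]]
          .round(4).to_string())
    skipped = set(records_by_disease) - set(testable)
    if skipped:
        print(f"groups with <2 defined fold differences (no evidence of "
              f"bias): {sorted(skipped)}")

    disease_comps = [c for c in plan.comparisons if c.disease != "stochastic"]
    mat_h, mat_d = smr.genus_presence(results, disease_comps, taxonomy, ALPHA)
    mat_h.to_csv(ROOT / "genus_matrix_healthy_side.tsv", sep="\t")
    mat_d.to_csv(ROOT / "genus_matrix_disease_side.tsv", sep="\t")
    print(f"\ngenus presence matrices: {mat_h.shape[0]} diseases x "
          f"{mat_h.shape[1]} genera")

    support_rows = []
    for side, mat in (("healthy", mat_h), ("disease", mat_d)):
        cs = smr.cluster_with_support(mat, n_boot=1000, seed=SEED_BOOT)
        (ROOT / f"dendrogram_{side}_side.nwk").write_text(
            smr.linkage_to_newick(cs.linkage, cs.labels) + "\n")
        for _, row in cs.nodes.iterrows():
            support_rows.append({"side": side,
                                 "members": "|".join(sorted(row["members"])),
                                 "bp": round(row["bp"], 3),
                                 "au": round(row["au"], 3)})
    support = pd.DataFrame(support_rows)
    support.to_csv(ROOT / "cluster_support.tsv", sep="\t", index=False)
    print("\ndisease clustering with AU/BP support (AU > 0.95 significant):")
    print(support.to_string(index=False))


if __name__ == "__main__":
    main()
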