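"""Genus diversity vs dysbiosis, and over-dysbiotic genera.

Per disease: Spearman correlation between the number of OTUs per genus and
the number of dysbiotic OTUs per genus, then the three-sigma rule — genera
whose dysbiotic-OTU count lies more than three residual standard deviations
above the diversity-fitted line.  Writes results/genus_diversity.tsv and a
disease x genus flag matrix.
"""

from pathlib import Path

import pandas as pd

from dysbiome import core_tables as ct
from dysbiome import diversity as dvs
from dysbiome.design import ComparisonPlan
from dysbiome.differential_abundance import DaResult

ROOT = Path(__file__).resolve().parent.parent / "results"
ALPHA = 0.05


def main() -> None:
    plan = ComparisonPlan.from_json(ROOT / "comparison_plan.json")
    taxonomy = ct.read_taxonomy(ROOT / "data" / "taxonomy.tsv")
    table = ct.read_otu_table(ROOT / "data" / "otu_table.tsv")
    results = {c.comparison_id:
               DaResult.from_frame(pd.read_csv(ROOT / "da" /
                                               f"{c.comparison_id}.tsv",
                                               sep="\t", index_col=0))
               for c in plan.comparisons}

    frames, flags = [], {}
    for disease, comps in plan.by_disease().items():
        if disease == "stochastic":
            continue
        recs = dvs.build_genus_records(results, comps, taxonomy,
                                       table.otu_ids, ALPHA)
        rho, p = dvs.spearman_diversity_corr(recs)
        out = dvs.three_sigma_flags(recs)
        df = dvs.records_to_frame(out)
        df.insert(0, "disease", disease)
        frames.append(df)
        flags[disease] = {r.genus for r in out if r.flagged}
        print(f"{disease}: Spearman rho = {rho:.3f} (p = {p:.2e}); "
              f"{len(flags[disease])} genera beyond three sigma")

    pd.concat(frames).to_csv(ROOT / "genus_diversity.tsv", sep="\t")
    genera = sorted(set().union(*flags.values())) if flags else []
    matrix = pd.DataFrame({d: [g in f for g in genera]
                           for d, f in flags.items()}, index=genera)
    matrix.to_csv(ROOT / "over_dysbiotic_genera.tsv", sep="\t")
    if genera:
        print("\nover-dysbiotic genera (three-sigma rule):")
        print(matrix.to_string())


if __name__ == "__main__":
    main()
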