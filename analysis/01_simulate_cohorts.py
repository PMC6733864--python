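"""Simulate the study cohorts.

Builds one shared gut community and draws a healthy pool (300 samples) plus
four disease groups — cardiovascular disease, diabetes and obesity at 300
samples each and kidney disease at 100 (a single-subset group) — with
loss-of-function dysbiosis planted on three times as many OTUs as
gain-of-function, and antibiotic exposure more prevalent in disease.
Writes the OTU table, taxonomy, tree, metadata and per-disease ground truth
under results/data/.
"""

from pathlib import Path

from dysbiome import core_tables as ct
from dysbiome.synthetic import SimulationConfig, simulate_study

import pandas as pd

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
DISEASES = ["cardiovascular", "diabetes", "obesity", "kidney"]
SEED = 20260921


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    table, taxonomy, tree, meta, truths = simulate_study(
        cfg, DISEASES, n_samples_by_disease={"kidney": 100})
    table = ct.filter_low_count(table, 10)
    ct.write_otu_table(table, OUT / "otu_table.tsv")
    ct.write_taxonomy(taxonomy, OUT / "taxonomy.tsv")
    ct.write_tree(tree, OUT / "tree.nwk")
    ct.write_metadata(meta, OUT / "metadata.tsv")
    pd.concat({d: t.to_frame() for d, t in truths.items()},
              names=["disease"]).to_csv(OUT / "ground_truth.tsv", sep="\t")
    print(f"simulated {table.n_samples} samples x {table.n_otus} OTUs "
          f"(after <10-count filter) across healthy + {len(DISEASES)} "
          f"disease groups -> {OUT}")


if __name__ == "__main__":
    main()
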