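"""Per-comparison differential abundance.

Subdivides each health status into rank-block subsets by assigned random
numbers (three subsets of 100; kidney disease fills only one), crosses
healthy x disease subsets into pairwise comparisons, builds the
stochastic-label null the same way, and runs the NB Wald test for every
comparison.  Writes the comparison plan and one DA table per comparison
under results/da/.
"""

from pathlib import Path

import numpy as np

from dysbiome import core_tables as ct
from dysbiome import design as dsg
from dysbiome.differential_abundance import wald_test

ROOT = Path(__file__).resolve().parent.parent / "results"
SUBSET_SIZE = 100
SEED_SUBDIVISION = 11
SEED_STOCHASTIC = 23


def main() -> None:
    table = ct.read_otu_table(ROOT / "data" / "otu_table.tsv")
    meta = ct.read_metadata(ROOT / "data" / "metadata.tsv")
    meta = dsg.assign_random_numbers(meta, SEED_SUBDIVISION)

    healthy = dsg.subdivide(meta[meta.health_status == "healthy"], SUBSET_SIZE)
    comparisons = []
    for disease in sorted(set(meta["health_status"]) - {"healthy"}):
        subs = dsg.subdivide(meta[meta.health_status == disease], SUBSET_SIZE)
        plan = dsg.enumerate_comparisons("cross", healthy, subs, disease)
        comparisons.extend(plan.comparisons)
        print(f"{disease}: {len(subs)} subsets -> {len(plan)} comparisons")
    g1, g2 = dsg.make_stochastic_groups(meta, SEED_STOCHASTIC, SUBSET_SIZE)
    stoch = dsg.enumerate_comparisons("cross", g1, g2, "stochastic")
    comparisons.extend(stoch.comparisons)
    print(f"stochastic null: {len(stoch)} comparisons")

    full = dsg.ComparisonPlan(comparisons)
    full.to_json(ROOT / "comparison_plan.json")
    da_dir = ROOT / "da"
    da_dir.mkdir(exist_ok=True)
    for comp in full.comparisons:
        sub = table.select_samples(comp.group1 + comp.group2)
        labels = np.array([0] * len(comp.group1) + [1] * len(comp.group2))
        res = wald_test(sub, labels)
        res.to_frame().to_csv(da_dir / f"{comp.comparison_id}.tsv", sep="\t")
    print(f"wrote {len(full)} DA tables to {da_dir}")


if __name__ == "__main__":
    main()
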