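"""Antibiotic use vs chronic disease.

For each disease group, compares last-year antibiotic exposure against the
healthy pool: relative risk with 95% CI, two-sided Fisher's exact test, and
Holm correction across diseases.  Writes results/antibiotic_association.tsv.
"""

from pathlib import Path

from dysbiome.antibiotics import antibiotic_association
from dysbiome.core_tables import read_metadata

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = read_metadata(ROOT / "data" / "metadata.tsv")
    assoc = antibiotic_association(meta)
    assoc.to_csv(ROOT / "antibiotic_association.tsv", sep="\t")
    print(assoc.round(4).to_string())
    n_sig = int((assoc["p_holm"] < 0.05).sum())
    print(f"\n{n_sig}/{len(assoc)} diseases significantly associated with "
          "antibiotic use after Holm correction")


if __name__ == "__main__":
    main()
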