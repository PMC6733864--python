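"""Antibiotic-use vs chronic-disease association.

For each disease, exposure to antibiotics in the last year is compared
between disease and healthy samples: relative risk with a log-normal 95%
confidence interval, a post-hoc two-sided Fisher's exact test
(probability-mass rule), and Holm correction across the diseases analysed
together.  Samples with missing antibiotic metadata are excluded listwise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclasses.dataclass
class ContingencyTable2x2:
    """Rows = (disease, healthy), columns = (antibiotic, no antibiotic)."""

    a: int  # disease, exposed
    b: int  # disease, unexposed
    c: int  # healthy, exposed
    d: int  # healthy, unexposed

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table total must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @classmethod
    def from_array(cls, arr) -> "ContingencyTable2x2":
        (a, b), (c, d) = np.asarray(arr, dtype=np.int64)
        return cls(int(a), int(b), int(c), int(d))


def relative_risk(t: ContingencyTable2x2
                  ) -> tuple[float, tuple[float, float] | None]:
    """Relative risk of exposure in disease vs healthy, with log-normal 95% CI.

    rr = [a/(a+b)] / [c/(c+d)].  A zero exposed count in the healthy row
    makes rr infinite with no CI; a zero exposed count in either row leaves
    the CI undefined.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("both row totals must be positive")
    p1 = t.a / (t.a + t.b)
    p2 = t.c / (t.c + t.d)
    if p2 == 0:
        return float("inf"), None
    rr = p1 / p2
    if t.a == 0:
        return rr, None
    se = np.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    log_rr = np.log(rr)
    return float(rr), (float(np.exp(log_rr - 1.96 * se)),
                       float(np.exp(log_rr + 1.96 * se)))


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p (probability-mass rule): sum of
    hypergeometric probabilities of all same-margin tables no more probable
    than the observed one."""
    _, p = stats.fisher_exact(t.to_array(), alternative="two-sided")
    return float(min(p, 1.0))


def holm_correct(p_values) -> np.ndarray:
    """Holm step-down family-wise adjustment, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def antibiotic_association(meta: pd.DataFrame,
                           healthy_label: str = "healthy") -> pd.DataFrame:
    """Per-disease antibiotic association table from sample metadata.

    Builds one 2x2 table per non-healthy health status against the healthy
    samples (missing antibiotic flags dropped listwise), computes rr + CI and
    the Fisher p, then Holm-corrects across all diseases in the frame.
    """
    usable = meta.dropna(subset=["antibiotic_last_year"])
    healthy = usable[usable["health_status"] == healthy_label]
    c = int(healthy["antibiotic_last_year"].sum())
    d = int(len(healthy) - c)
    rows = []
    for disease in sorted(set(usable["health_status"]) - {healthy_label}):
        grp = usable[usable["health_status"] == disease]
        a = int(grp["antibiotic_last_year"].sum())
        b = int(len(grp) - a)
        t = ContingencyTable2x2(a, b, c, d)
        rr, ci = relative_risk(t)
        rows.append({"disease": disease, "a": a, "b": b, "c": c, "d": d,
                     "rr": rr,
                     "ci_low": ci[0] if ci else np.nan,
                     "ci_high": ci[1] if ci else np.nan,
                     "p_fisher": fisher_exact(t)})
    df = pd.DataFrame(rows).set_index("disease")
    df["p_holm"] = holm_correct(df["p_fisher"])
    df["stars"] = df["p_holm"].map(significance_stars)
    return df
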