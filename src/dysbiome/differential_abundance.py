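"""Negative-binomial Wald differential abundance between two sample groups.

Per OTU, a negative-binomial GLM with log link, a group indicator, and a
log-size-factor offset is fit by iteratively reweighted least squares with
the dispersion held fixed at a method-of-moments estimate.  The Wald
statistic is the log2 fold change divided by its standard error (lfcse);
p-values are two-sided normal and Benjamini-Hochberg adjusted.

This is a deliberate simplification of the full DESeq2 machinery: no
dispersion shrinkage toward a fitted trend, no outlier refitting, no
independent filtering, no LFC shrinkage.  Validity is established by
calibration and recovery tests rather than by replicating those internals;
an optional trend-shrinkage step is available via ``shrink_dispersion``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_tables import OtuTable

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


@dataclasses.dataclass
class DaResult:
    """Per-OTU differential-abundance statistics.

    ``log2fc`` is positive when the group-2 mean exceeds the group-1 mean.
    OTUs with all-zero counts (or failed fits) carry NaN statistics.
    """

    otu_ids: list[str]
    base_mean: np.ndarray
    log2fc: np.ndarray
    lfcse: np.ndarray
    wald_stat: np.ndarray
    p_value: np.ndarray
    p_adj: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "base_mean": self.base_mean, "log2fc": self.log2fc,
            "lfcse": self.lfcse, "wald_stat": self.wald_stat,
            "p_value": self.p_value, "p_adj": self.p_adj,
        }, index=pd.Index(self.otu_ids, name="otu_id"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DaResult":
        return cls(list(df.index.astype(str)),
                   df["base_mean"].to_numpy(), df["log2fc"].to_numpy(),
                   df["lfcse"].to_numpy(), df["wald_stat"].to_numpy(),
                   df["p_value"].to_numpy(), df["p_adj"].to_numpy())


def estimate_size_factors(table: OtuTable | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference for each OTU is its geometric mean across samples, taken
    over OTUs that are nonzero in every sample; when no such OTU exists the
    geometric mean is computed over positive counts only (poscounts-style
    fallback).  A sample with all-zero counts is an error.
    """
    counts = table.counts if isinstance(table, OtuTable) else np.asarray(table)
    sample_ids = table.sample_ids if isinstance(table, OtuTable) else \
        [str(i) for i in range(counts.shape[0])]
    zero_samples = [s for s, row in zip(sample_ids, counts) if row.sum() == 0]
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples[:5]}")

    c = counts.astype(float)
    all_positive = np.all(c > 0, axis=0)
    with np.errstate(divide="ignore"):
        logc = np.where(c > 0, np.log(c), np.nan)
    if all_positive.any():
        ref = np.exp(np.nanmean(logc[:, all_positive], axis=0))
        ratios = c[:, all_positive] / ref[None, :]
        factors = np.median(ratios, axis=1)
    else:
        # positive-counts geometric mean per OTU; per-sample median over
        # the OTUs that sample actually observed
        npos = (c > 0).sum(axis=0)
        usable = npos > 0
        ref = np.exp(np.nansum(logc[:, usable], axis=0) / npos[usable])
        ratios = np.where(c[:, usable] > 0, c[:, usable] / ref[None, :], np.nan)
        factors = np.nanmedian(ratios, axis=1)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        bad = [s for s, f in zip(sample_ids, factors)
               if not np.isfinite(f) or f <= 0]
        raise ValueError(f"could not estimate size factors for: {bad[:5]}")
    return factors / np.exp(np.mean(np.log(factors)))


def estimate_dispersion(table: OtuTable | np.ndarray,
                        size_factors: np.ndarray,
                        floor: float = DISPERSION_FLOOR) -> np.ndarray:
    """Per-OTU method-of-moments NB dispersion on normalized counts:
    alpha = max(floor, (s^2 - mbar) / mbar^2)."""
    counts = table.counts if isinstance(table, OtuTable) else np.asarray(table)
    q = counts / np.asarray(size_factors)[:, None]
    mbar = q.mean(axis=0)
    s2 = q.var(axis=0, ddof=1) if counts.shape[0] > 1 else np.zeros_like(mbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mbar) / mbar**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return np.maximum(alpha, floor)


def shrink_dispersion(dispersions: np.ndarray, base_means: np.ndarray,
                      weight: float = 0.5) -> np.ndarray:
    """Optional shrinkage of per-OTU dispersions toward a mean-dependent trend
    (log-log linear fit), blended on the log scale."""
    ok = (base_means > 0) & (dispersions > DISPERSION_FLOOR * 10)
    if ok.sum() < 10:
        return dispersions
    x, y = np.log(base_means[ok]), np.log(dispersions[ok])
    slope, intercept = np.polyfit(x, y, 1)
    with np.errstate(divide="ignore"):
        trend = np.where(base_means > 0,
                         np.exp(slope * np.log(np.maximum(base_means, 1e-12))
                                + intercept),
                         dispersions)
    out = np.exp((1 - weight) * np.log(np.maximum(dispersions, DISPERSION_FLOOR))
                 + weight * np.log(np.maximum(trend, DISPERSION_FLOOR)))
    return np.maximum(out, DISPERSION_FLOOR)


def _irls_two_group(counts: np.ndarray, group: np.ndarray,
                    size_factors: np.ndarray, dispersions: np.ndarray,
                    tol: float = 1e-8, max_iter: int = 100
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for the two-group NB GLM with offset log(size factor).

    Returns (beta0, beta1, se_beta1) in natural-log units; beta1 is the
    group-2 vs group-1 coefficient.  The design is the same for every OTU,
    so the 2x2 normal equations are solved in closed form across all OTUs.
    """
    y = np.asarray(counts, dtype=float)            # samples x otus
    sf = size_factors[:, None]
    x = group.astype(float)[:, None]               # samples x 1
    alpha = dispersions[None, :]

    # initialise from group means of normalized counts
    q = y / sf
    m1 = q[group == 0].mean(axis=0)
    m2 = q[group == 1].mean(axis=0)
    b0 = np.log(np.maximum(m1, 1e-8))
    b1 = np.log(np.maximum(m2, 1e-8)) - b0

    dev_old = np.full(y.shape[1], np.inf)
    active = np.ones(y.shape[1], dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + x * b1[None, :], -50, 50)
        mu = sf * np.exp(eta)
        w = mu / (1.0 + alpha * mu)                # NB working weights
        z = eta + (y - mu) / mu                    # working response (log link)
        sw = w.sum(axis=0)
        sw2 = (w * x).sum(axis=0)                  # x^2 = x for an indicator
        swz = (w * z).sum(axis=0)
        sw2z = (w * x * z).sum(axis=0)
        det = sw * sw2 - sw2**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        b0_new = (sw2 * swz - sw2 * sw2z) / det
        b1_new = (sw * sw2z - sw2 * swz) / det
        b0 = np.where(active & np.isfinite(b0_new), b0_new, b0)
        b1 = np.where(active & np.isfinite(b1_new), b1_new, b1)
        # NB quasi-deviance surrogate: weighted residual sum of squares
        dev = np.nansum(w * (z - (b0[None, :] + x * b1[None, :]))**2, axis=0)
        done = np.abs(dev - dev_old) < tol * (np.abs(dev) + tol)
        active &= ~done
        dev_old = dev
        if not active.any():
            break

    eta = np.clip(b0[None, :] + x * b1[None, :], -50, 50)
    mu = sf * np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    sw = w.sum(axis=0)
    sw2 = (w * x).sum(axis=0)
    det = sw * sw2 - sw2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det                           # [ (X'WX)^-1 ]_22
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    return b0, b1, se


def wald_test(table: OtuTable, group_labels: np.ndarray,
              size_factors: np.ndarray | None = None,
              dispersions: np.ndarray | None = None) -> DaResult:
    """Two-group NB Wald test for every OTU in the table.

    ``group_labels`` is a binary (0/1) vector per sample; log2fc is positive
    when the group-1-labelled (indicator = 1) mean exceeds the group-0 mean.
    OTUs whose fit fails carry NaN statistics; all-zero OTUs are skipped.
    """
    group = np.asarray(group_labels).astype(int)
    if group.shape[0] != table.n_samples:
        raise ValueError("group_labels length must match sample count")
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group_labels must be binary 0/1")
    if (group == 0).sum() == 0 or (group == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")

    if size_factors is None:
        size_factors = estimate_size_factors(table)
    if dispersions is None:
        dispersions = estimate_dispersion(table, size_factors)

    counts = table.counts
    nonzero = counts.sum(axis=0) > 0
    n_otus = table.n_otus
    log2fc = np.full(n_otus, np.nan)
    lfcse = np.full(n_otus, np.nan)
    wald = np.full(n_otus, np.nan)
    pval = np.full(n_otus, np.nan)

    if nonzero.any():
        y = counts[:, nonzero].astype(float)
        # an OTU absent from one whole group has an infinite MLE; a half-count
        # pseudocount added across samples keeps its estimate finite and
        # label-flip symmetric
        sep = (y[group == 0].sum(axis=0) == 0) | (y[group == 1].sum(axis=0) == 0)
        y[:, sep] += 0.5
        _, b1, se = _irls_two_group(y, group, size_factors,
                                    dispersions[nonzero])
        log2fc[nonzero] = b1 / LN2
        lfcse[nonzero] = se / LN2
        with np.errstate(invalid="ignore"):
            wald[nonzero] = b1 / se
        pval[nonzero] = 2.0 * stats.norm.sf(np.abs(wald[nonzero]))

    base_mean = (counts / size_factors[:, None]).mean(axis=0)
    padj = np.full(n_otus, np.nan)
    ok = np.isfinite(pval)
    if ok.any():
        padj[ok] = benjamini_hochberg(pval[ok])
    return DaResult(list(table.otu_ids), base_mean, log2fc, lfcse, wald,
                    pval, padj)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def count_enriched(result: DaResult, alpha: float = 0.05) -> tuple[int, int]:
    """Number of significantly enriched OTUs per side.

    Returns (n_enriched_group1, n_enriched_group2): an OTU counts for group 1
    when p_adj < alpha and log2fc < 0 (higher in group 1), for group 2 when
    p_adj < alpha and log2fc > 0.  Zero-fold-change significant OTUs count
    for neither side.
    """
    sig = np.isfinite(result.p_adj) & (result.p_adj < alpha)
    n1 = int(np.sum(sig & (result.log2fc < 0)))
    n2 = int(np.sum(sig & (result.log2fc > 0)))
    return n1, n2
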