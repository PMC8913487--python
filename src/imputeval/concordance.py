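"""Truth-vs-imputed genotype concordance statistics.

The central statistic is the imputation quality score (IQS): chance-
corrected agreement between truth and imputed genotype calls in the
kappa form, computed on 3x3 confusion tables stratified by 0.01-wide
MAF bins. Also provides per-genotype concordance rates, non-reference
concordance, per-MAF-bin mean dosage r^2, and a Welch t-test comparing
per-sample accuracies between reference-panel and non-panel breeds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._binning import N_MAF_BINS, bin_edges, maf_bin_index
from .variant_io import GenotypeMatrix, MafTable, MISSING

DEFAULT_MAF_RANGES = ((0.0, 0.05), (0.05, 0.1), (0.1, 0.2), (0.2, 0.5))


@dataclass
class ConfusionTable:
    """3x3 truth-by-imputed genotype counts for one stratum.

    Rows index the truth genotype (0, 1, 2), columns the imputed
    genotype. maf_bin is the 0.01-bin index (None = pooled over bins).
    """

    counts: np.ndarray
    maf_bin: int | None = None
    filtered: bool = False
    maf_source: str = "truth"
    scope: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion counts must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.counts + other.counts, maf_bin=None,
                              filtered=self.filtered, maf_source=self.maf_source)


@dataclass
class ConcordanceSummary:
    p_o: float | None = None
    p_c: float | None = None
    iqs: float | None = None
    overall_concordance: float | None = None
    nonref_concordance: float | None = None
    per_genotype: tuple | None = None
    mean_r2: float | None = None


def _check_aligned(truth: GenotypeMatrix, imputed: GenotypeMatrix):
    if truth.samples != imputed.samples:
        raise ValueError("truth and imputed must share identical sample ordering")
    if truth.sites != imputed.sites:
        raise ValueError(
            "truth and imputed must share identical site ordering; "
            "intersect the matrices on their common site set first"
        )


def intersect_on_sites(truth: GenotypeMatrix, imputed: GenotypeMatrix):
    """Restrict both matrices to their shared sites, in truth order."""
    common = truth.site_set() & imputed.site_set()
    keys = [k for k in truth.sites if k in common]
    return truth.select_sites(keys), imputed.select_sites(keys)


def confusion_table(truth: GenotypeMatrix, imputed: GenotypeMatrix,
                    maf: MafTable, site_mask=None, sample_mask=None,
                    filtered: bool = False) -> list:
    """Per-MAF-bin 3x3 confusion tables.

    Pairs where either call is missing are excluded; each remaining
    (site, sample) pair contributes to exactly one bin's table. Sites
    with MAF 0 or undefined MAF fall outside every bin and are skipped.
    """
    _check_aligned(truth, imputed)
    bins = maf_bin_index(maf.aligned_to(truth.sites))
    smask = np.ones(truth.n_sites, bool) if site_mask is None else np.asarray(site_mask, bool)
    cmask = np.ones(truth.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
    valid = (truth.calls != MISSING) & (imputed.calls != MISSING)
    valid &= smask[:, None] & cmask[None, :] & (bins >= 0)[:, None]
    t = truth.calls[valid].astype(np.int64)
    i = imputed.calls[valid].astype(np.int64)
    b = np.broadcast_to(bins[:, None], truth.calls.shape)[valid].astype(np.int64)
    flat = np.bincount(b * 9 + t * 3 + i, minlength=N_MAF_BINS * 9)
    cube = flat.reshape(N_MAF_BINS, 3, 3)
    return [
        ConfusionTable(cube[k], maf_bin=k, filtered=filtered, maf_source=maf.source)
        for k in range(N_MAF_BINS) if cube[k].sum() > 0
    ]


def pool_tables(tables) -> ConfusionTable:
    """Sum confusion tables into one pooled table."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to pool")
    counts = np.sum([t.counts for t in tables], axis=0)
    return ConfusionTable(counts, maf_bin=None, filtered=tables[0].filtered,
                          maf_source=tables[0].maf_source)


def iqs(ct: ConfusionTable) -> ConcordanceSummary:
    """Imputation quality score: chance-corrected agreement.

    P_o = trace/total (observed agreement), P_c = sum_g row_g*col_g /
    total^2 (agreement expected by chance from the marginals),
    IQS = (P_o - P_c) / (1 - P_c). Undefined (None) when the table is
    empty or P_c = 1 (a single-cell table, where chance fully explains
    agreement).
    """
    n = ct.total
    if n <= 0:
        raise ValueError("IQS undefined for an all-zero table")
    p_o = float(np.trace(ct.counts)) / n
    rows = ct.counts.sum(axis=1)
    cols = ct.counts.sum(axis=0)
    p_c = float(rows @ cols) / n ** 2
    score = None if p_c >= 1.0 - 1e-15 else (p_o - p_c) / (1.0 - p_c)
    return ConcordanceSummary(p_o=p_o, p_c=p_c, iqs=score, overall_concordance=p_o)


def genotype_concordance(ct: ConfusionTable) -> pd.DataFrame:
    """Row-normalized rates: fraction of each truth genotype imputed as each genotype.

    Rows with zero total are returned as NaN (undefined). Defined rows
    sum to 1.
    """
    rows = ct.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = ct.counts / rows[:, None]
    rates = np.where(rows[:, None] > 0, rates, np.nan)
    return pd.DataFrame(rates, index=["homref", "het", "homalt"],
                        columns=["homref", "het", "homalt"])


def nonref_concordance(ct: ConfusionTable, denominator: str = "either") -> float:
    """Agreement rate among calls involving a non-reference allele.

    'either' (default): concordant non-ref calls (cells (1,1) + (2,2))
    over all calls where truth or imputed is non-ref (everything except
    cell (0,0)). 'truth': restricts the denominator to truth-non-ref
    calls (rows 1 and 2). Returns NaN when the denominator is zero.
    """
    c = ct.counts
    num = c[1, 1] + c[2, 2]
    if denominator == "either":
        den = c.sum() - c[0, 0]
    elif denominator == "truth":
        den = c[1:, :].sum()
    else:
        raise ValueError("denominator must be 'either' or 'truth'")
    return float(num / den) if den > 0 else float("nan")


def summarize_confusion(ct: ConfusionTable,
                        denominator: str = "either") -> ConcordanceSummary:
    """Full agreement summary (IQS, overall, per-genotype, non-ref) for one table."""
    s = iqs(ct)
    rates = genotype_concordance(ct)
    s.per_genotype = tuple(np.diag(rates.to_numpy()))
    s.nonref_concordance = nonref_concordance(ct, denominator=denominator)
    return s


def mean_r2(truth: GenotypeMatrix, imputed: GenotypeMatrix,
            maf: MafTable) -> pd.DataFrame:
    """Per-MAF-bin mean squared Pearson correlation of genotype dosages.

    r^2 is computed per site across samples (pairwise-excluding missing
    calls), then averaged over the bin's sites with a defined r^2.
    Sites with <2 complete pairs or zero variance in either dosage
    vector are excluded and counted.
    """
    _check_aligned(truth, imputed)
    t = truth.calls.astype(float)
    i = imputed.calls.astype(float)
    valid = (truth.calls != MISSING) & (imputed.calls != MISSING)
    t[~valid] = 0.0
    i[~valid] = 0.0
    n = valid.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mt = t.sum(axis=1) / n
        mi = i.sum(axis=1) / n
        sxy = (t * i).sum(axis=1) - n * mt * mi
        sxx = (t * t).sum(axis=1) - n * mt ** 2
        syy = (i * i).sum(axis=1) - n * mi ** 2
        r2 = sxy ** 2 / (sxx * syy)
    defined = (n >= 2) & (sxx > 1e-12) & (syy > 1e-12)
    bins = maf_bin_index(maf.aligned_to(truth.sites))
    rows = []
    for k in range(N_MAF_BINS):
        in_bin = bins == k
        if not in_bin.any():
            continue
        ok = in_bin & defined
        lo, hi = bin_edges(k)
        rows.append({
            "maf_bin": k, "maf_bin_low": lo, "maf_bin_high": hi,
            "mean_r2": float(r2[ok].mean()) if ok.any() else np.nan,
            "n_sites": int(ok.sum()),
            "n_excluded": int((in_bin & ~defined).sum()),
        })
    return pd.DataFrame(rows)


def per_sample_nonref_concordance(truth: GenotypeMatrix, imputed: GenotypeMatrix,
                                  maf: MafTable, ranges=DEFAULT_MAF_RANGES,
                                  site_mask=None,
                                  denominator: str = "either") -> pd.DataFrame:
    """Per-sample imputation accuracy (non-reference concordance) per MAF range.

    Ranges are (low, high] on the folded MAF. Output is tidy: one row
    per (sample, range) with breed and panel membership attached.
    """
    _check_aligned(truth, imputed)
    m = maf.aligned_to(truth.sites)
    smask = np.ones(truth.n_sites, bool) if site_mask is None else np.asarray(site_mask, bool)
    valid = (truth.calls != MISSING) & (imputed.calls != MISSING) & smask[:, None]
    concordant_nonref = valid & (truth.calls == imputed.calls) & (truth.calls > 0)
    if denominator == "either":
        involved = valid & ((truth.calls > 0) | (imputed.calls > 0))
    else:
        involved = valid & (truth.calls > 0)
    meta = truth.sample_meta
    rows = []
    for lo, hi in ranges:
        in_range = (m > lo) & (m <= hi)
        num = (concordant_nonref & in_range[:, None]).sum(axis=0)
        den = (involved & in_range[:, None]).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = num / den
        for j, s in enumerate(truth.samples):
            rows.append({
                "sample": s,
                "breed": meta.loc[s, "breed"] if meta is not None else None,
                "in_reference_panel": bool(meta.loc[s, "in_reference_panel"])
                if meta is not None else None,
                "maf_range": f"({lo:g},{hi:g}]",
                "maf_low": lo, "maf_high": hi,
                "nonref_concordance": acc[j],
            })
    return pd.DataFrame(rows)


def accuracy_by_group(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Welch's unequal-variance t-test of accuracy, panel vs non-panel breeds.

    Input is the tidy frame from per_sample_nonref_concordance (needs
    columns maf_range, in_reference_panel, nonref_concordance). Returns
    one row per MAF range with group means, the Welch t statistic,
    Welch-Satterthwaite degrees of freedom and a two-sided p value.
    """
    rows = []
    for rng_label, grp in per_sample.groupby("maf_range", sort=False):
        a = grp.loc[grp["in_reference_panel"].astype(bool), "nonref_concordance"].dropna()
        b = grp.loc[~grp["in_reference_panel"].astype(bool), "nonref_concordance"].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >=2 samples per group in range {rng_label}")
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "maf_range": rng_label,
            "mean_panel": a.mean(), "mean_nonpanel": b.mean(),
            "t": float(res.statistic), "df": float(res.df),
            "p_value": float(res.pvalue),
            "n_panel": len(a), "n_nonpanel": len(b),
        })
    return pd.DataFrame(rows)
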