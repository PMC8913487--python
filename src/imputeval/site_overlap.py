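"""Three-way variant-site overlap analysis.

Partitions three site sets (by exact (chrom, pos, ref, alt) identity)
into the seven regions of a Venn diagram, summarizes region sizes and
shared fractions, and computes partition-wise MAF histograms and
per-sample non-reference site fractions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, MafTable, MISSING

REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")
DEFAULT_MAF_BINS = (0.0, 0.01, 0.05, 0.5)


@dataclass
class VennPartition:
    """Disjoint assignment of site keys to the 7 three-set regions."""

    regions: dict
    names: tuple = ("imputed", "wgs", "panel")

    def __post_init__(self):
        missing = set(REGIONS) - set(self.regions)
        if missing:
            raise ValueError(f"partition lacks regions {sorted(missing)}")

    def dataset_sites(self, letter: str) -> set:
        """Union of all regions containing a dataset letter (A, B or C)."""
        return set().union(*(self.regions[r] for r in REGIONS if letter in r))

    def counts(self) -> dict:
        return {r: len(self.regions[r]) for r in REGIONS}


def match_sites(a: set, b: set, c: set,
                names: tuple = ("imputed", "wgs", "panel")) -> VennPartition:
    """Assign every site to exactly one of the 7 overlap regions.

    Sites match only if chromosome, position, reference allele and
    alternate allele are all identical.
    """
    a, b, c = set(a), set(b), set(c)
    abc = a & b & c
    regions = {
        "ABC": abc,
        "AB": (a & b) - abc,
        "AC": (a & c) - abc,
        "BC": (b & c) - abc,
        "A": a - b - c,
        "B": b - a - c,
        "C": c - a - b,
    }
    return VennPartition(regions=regions, names=names)


def shared_fraction_pct(n_shared: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of a dataset's sites found in a shared region.

    Reported to one decimal place, matching the convention of published
    overlap summaries (e.g. 13,943,807 / 14,845,499 -> 93.9).
    """
    if n_total <= 0:
        raise ValueError("fraction undefined for an empty dataset")
    return round(100.0 * n_shared / n_total, decimals)


def partition_summary(vp: VennPartition) -> pd.DataFrame:
    """Region counts plus per-dataset fraction columns.

    For each region, fraction_of_X is the region size over the total
    size of dataset X (NaN when the region does not involve X or the
    dataset is empty, with a warning in the latter case).
    """
    counts = vp.counts()
    totals = {L: len(vp.dataset_sites(L)) for L in "ABC"}
    for L, t in totals.items():
        if t == 0:
            warnings.warn(f"dataset {L} is empty; its fractions are undefined")
    rows = []
    for r in REGIONS:
        row = {"region": r, "count": counts[r]}
        for L in "ABC":
            if L in r and totals[L] > 0:
                row[f"fraction_of_{L}"] = shared_fraction_pct(counts[r], totals[L])
            else:
                row[f"fraction_of_{L}"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("region")
    df.attrs["totals"] = totals
    return df


def maf_by_partition(vp: VennPartition, maf: MafTable,
                     bins=DEFAULT_MAF_BINS) -> pd.DataFrame:
    """Per-region MAF histogram under one MAF source.

    bins are edges for intervals [e0, e1), ..., [e_{k-1}, e_k] (last
    closed). Sites lacking a MAF in the chosen source are counted in an
    explicit 'unavailable' column, so each row sums to the region size.
    """
    edges = np.asarray(bins, dtype=float)
    labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    lookup = maf.as_dict()
    rows = {}
    for r in REGIONS:
        counts = np.zeros(len(labels), dtype=int)
        unavailable = 0
        for key in vp.regions[r]:
            m = lookup.get(key, np.nan)
            if np.isnan(m):
                unavailable += 1
                continue
            i = int(np.searchsorted(edges, m, side="right")) - 1
            i = min(max(i, 0), len(labels) - 1)
            counts[i] += 1
        rows[r] = list(counts) + [unavailable]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=labels + ["unavailable"])


def per_sample_nonref_fraction(vp: VennPartition, gm: GenotypeMatrix,
                               region: str) -> pd.DataFrame:
    """Fraction of a region's sites carrying a non-reference allele, per sample.

    Denominator counts only non-missing calls. Rows carry breed and
    reference-panel membership when sample metadata is attached.
    """
    keys = [k for k in gm.sites if k in vp.regions[region]]
    if not keys:
        return pd.DataFrame(columns=["sample", "breed", "in_reference_panel",
                                     "region", "nonref_fraction"])
    sub = gm.select_sites(keys)
    valid = sub.calls != MISSING
    nonref = (sub.calls == 1) | (sub.calls == 2)
    denom = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = nonref.sum(axis=0) / denom
    meta = gm.sample_meta
    rows = []
    for j, s in enumerate(gm.samples):
        rows.append({
            "sample": s,
            "breed": meta.loc[s, "breed"] if meta is not None else None,
            "in_reference_panel": bool(meta.loc[s, "in_reference_panel"])
            if meta is not None else None,
            "region": region,
            "nonref_fraction": frac[j],
        })
    return pd.DataFrame(rows)
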