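"""VCF genotype I/O and per-site allele-frequency computation.

Genotypes are stored as integer codes: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, -1 = missing. Phase is
ignored and half-calls (``0/.``) are treated as missing. Site identity
is the tuple (chrom, pos, ref, alt) — string equality only, no
normalization beyond multiallelic splitting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
MAF_SOURCES = ("imputed", "panel", "truth")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a normalized biallelic site (1-based VCF position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError("VariantKey.alt must be a single allele")


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype calls with optional GP triplets.

    calls has shape (n_sites, n_samples), dtype int8, values in
    {0, 1, 2, -1}. gp, when present, has shape (n_sites, n_samples, 3)
    holding (p_homref, p_het, p_homalt); rows with all-NaN triplets mean
    "GP unavailable for this call". sample_meta is an optional DataFrame
    indexed by sample id with columns ``breed`` and
    ``in_reference_panel``.
    """

    sites: list
    samples: list
    calls: np.ndarray
    gp: np.ndarray | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_sites={len(self.sites)}, "
                f"n_samples={len(self.samples)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if self.gp is not None:
            self.gp = np.asarray(self.gp, dtype=float)
            if self.gp.shape != self.calls.shape + (3,):
                raise ValueError(f"gp shape {self.gp.shape} invalid")
            present = ~np.isnan(self.gp).all(axis=2)
            vals = self.gp[present]
            if vals.size:
                if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
                    raise ValueError("GP components must lie in [0, 1]")
                sums = vals.sum(axis=1)
                if np.max(np.abs(sums - 1.0)) > 1e-6:
                    raise ValueError("present GP triplets must sum to 1 within 1e-6")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_set(self) -> set:
        return set(self.sites)

    def site_index(self) -> dict:
        return {k: i for i, k in enumerate(self.sites)}

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            calls=self.calls[idx],
            gp=None if self.gp is None else self.gp[idx],
            sample_meta=self.sample_meta,
        )

    def select_sites(self, keys: Sequence[VariantKey]) -> "GenotypeMatrix":
        index = self.site_index()
        idx = np.array([index[k] for k in keys], dtype=int)
        return self.subset_sites(idx)


@dataclass
class MafTable:
    """Per-site folded minor allele frequency with a provenance tag."""

    keys: list
    maf: np.ndarray
    source: str

    def __post_init__(self):
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (len(self.keys),):
            raise ValueError("maf length must match keys")
        if self.source not in MAF_SOURCES:
            raise ValueError(f"maf source must be one of {MAF_SOURCES}")
        finite = self.maf[~np.isnan(self.maf)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 0.5 + 1e-12):
            raise ValueError("MAF must lie in [0, 0.5]")

    def as_dict(self) -> dict:
        return dict(zip(self.keys, self.maf))

    def aligned_to(self, sites: Sequence[VariantKey], strict: bool = False) -> np.ndarray:
        """MAF array aligned to an external site list (NaN where absent)."""
        d = self.as_dict()
        out = np.array([d.get(k, np.nan) for k in sites], dtype=float)
        if strict and np.isnan(out).any():
            raise KeyError("MAF missing for some requested sites")
        return out


@dataclass
class RawRecord:
    """One parsed VCF record prior to biallelic normalization.

    gt holds allele indices with shape (n_samples, 2); -1 encodes '.'.
    gp holds the raw FORMAT/GP matrix (n_samples x n_genotypes) or None.
    """

    chrom: str
    pos: int
    ref: str
    alts: list
    gt: np.ndarray
    gp: np.ndarray | None = None


def _parse_vcf(path, load_gp: bool):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for lineno, v in enumerate(vcf, start=1):
        gts = np.array([g[:2] for g in v.genotypes], dtype=int)
        gp = None
        if load_gp:
            gp = v.format("GP")
            if gp is None:
                raise ValueError(
                    f"GP requested but absent at record {lineno} "
                    f"({v.CHROM}:{v.POS})"
                )
            gp = np.asarray(gp, dtype=float)
        records.append(RawRecord(v.CHROM, int(v.POS), v.REF, list(v.ALT), gts, gp))
    vcf.close()
    return samples, records


def split_multiallelic(records: Iterable[RawRecord]) -> list:
    """Split records with >=2 ALT alleles into one biallelic record each.

    For the output record of allele k, any sample allele equal to k maps
    to the alternate, any other non-missing allele (including other ALTs)
    maps to the reference side, and missing stays missing. Total non-
    reference dosage per sample per locus is conserved across the split
    set. GP is retained only for already-biallelic records (a
    multiallelic GP vector has no 3-genotype interpretation post-split).
    """
    out = []
    for rec in records:
        if len(rec.alts) <= 1:
            out.append(rec)
            continue
        for k, alt in enumerate(rec.alts, start=1):
            gt = np.where(rec.gt == k, 1, np.where(rec.gt >= 0, 0, MISSING))
            out.append(RawRecord(rec.chrom, rec.pos, rec.ref, [alt], gt, None))
    return out


def records_to_matrix(samples: Sequence[str], records: Sequence[RawRecord],
                      with_gp: bool = False) -> GenotypeMatrix:
    """Assemble biallelic records into a GenotypeMatrix.

    Half-calls (one missing allele) become missing. GP triplets absent on
    a record become all-NaN rows when GP is carried.
    """
    sites, rows, gps = [], [], []
    for rec in records:
        if len(rec.alts) != 1:
            raise ValueError("records_to_matrix requires biallelic records; "
                             "run split_multiallelic first")
        sites.append(VariantKey(rec.chrom, rec.pos, rec.ref, rec.alts[0]))
        any_missing = (rec.gt < 0).any(axis=1)
        calls = np.where(any_missing, MISSING, rec.gt.clip(0, 1).sum(axis=1))
        rows.append(calls.astype(np.int8))
        if with_gp:
            if rec.gp is not None and rec.gp.shape[1] == 3:
                gps.append(rec.gp)
            else:
                gps.append(np.full((len(samples), 3), np.nan))
    calls = np.array(rows, dtype=np.int8).reshape(len(sites), len(samples))
    gp = np.array(gps, dtype=float).reshape(len(sites), len(samples), 3) if with_gp else None
    return GenotypeMatrix(sites=sites, samples=list(samples), calls=calls, gp=gp)


def read_vcf_genotypes(path, load_gp: bool = False) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, splitting multiallelic records.

    Diploid GT values are mapped to {0, 1, 2}; ``./.`` and half-calls map
    to missing; phased and unphased separators are treated identically.
    Raises if GP is requested but the field is absent.
    """
    samples, records = _parse_vcf(path, load_gp)
    records = split_multiallelic(records)
    return records_to_matrix(samples, records, with_gp=load_gp)


def remove_invariant_sites(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop sites with no non-reference call.

    Sites where every call is homozygous reference are removed, as are
    sites where every call is missing (they carry no information).
    """
    keep = ((gm.calls == 1) | (gm.calls == 2)).any(axis=1)
    if not keep.any():
        warnings.warn("all sites are invariant; returning an empty matrix")
    return gm.subset_sites(keep)


def compute_maf(gm: GenotypeMatrix, source: str) -> MafTable:
    """Folded minor allele frequency per site.

    f = (het + 2*homalt) / (2 * non-missing calls); MAF = min(f, 1-f).
    Sites with all calls missing get NaN (flagged, excluded downstream).
    """
    if gm.n_sites == 0:
        raise ValueError("cannot compute MAF on an empty matrix")
    valid = gm.calls != MISSING
    n = valid.sum(axis=1)
    alt = np.where(valid, gm.calls, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = alt / (2.0 * n)
    maf = np.minimum(f, 1.0 - f)
    maf = np.where(n == 0, np.nan, maf)
    return MafTable(keys=list(gm.sites), maf=maf, source=source)


def write_vcf(gm: GenotypeMatrix, path, with_gp: bool = False) -> None:
    """Write a GenotypeMatrix as a VCF 4.2 text file.

    GT is always written; GP triplets are written to 4 decimals when
    requested (absent triplets as '.'). Sites are sorted by
    (chrom, pos, ref, alt).
    """
    order = sorted(range(gm.n_sites), key=lambda i: gm.sites[i])
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2"]
    for chrom in sorted({k.chrom for k in gm.sites}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_gp:
        lines.append('##FORMAT=<ID=GP,Number=G,Type=Float,'
                     'Description="Genotype posterior probabilities">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples))
    fmt = "GT:GP" if with_gp else "GT"
    for i in order:
        k = gm.sites[i]
        fields = [k.chrom, str(k.pos), ".", k.ref, k.alt, ".", ".", ".", fmt]
        for j in range(gm.n_samples):
            cell = gtmap[int(gm.calls[i, j])]
            if with_gp:
                trip = gm.gp[i, j] if gm.gp is not None else None
                if trip is None or np.isnan(trip).any():
                    cell += ":."
                else:
                    cell += ":" + ",".join(f"{x:.4f}" for x in trip)
            fields.append(cell)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV: sample_id, breed, in_reference_panel."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "breed": str})
    required = {"sample_id", "breed", "in_reference_panel"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    df = df.set_index("sample_id")
    df["in_reference_panel"] = df["in_reference_panel"].astype(int).astype(bool)
    return df
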