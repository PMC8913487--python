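"""Seeded synthetic genotype datasets with the error structure the analysis assumes.

Emulates the statistical shape of a low-pass imputation experiment:
biallelic sites with a configurable MAF spectrum, independent
Hardy-Weinberg genotypes per sample, imputation errors drawn from
MAF-binned 3x3 channels with elevated heterozygote error at low MAF,
GP triplets calibrated so that higher max GP implies higher probability
of correctness, per-sample breed labels with a reference-panel
membership flag (non-panel breeds get a configurable error inflation),
and a three-dataset site-overlap design with low-MAF enrichment in the
dataset-specific regions. All randomness flows from a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._binning import N_MAF_BINS, maf_bin_index
from .error_model import ErrorModel, parametric_error_model
from .variant_io import GenotypeMatrix, MafTable, VariantKey, MISSING

_ALLELES = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))

DEFAULT_OVERLAP = {
    "ABC": 0.70, "AB": 0.05, "AC": 0.08, "BC": 0.05,
    "A": 0.04, "B": 0.06, "C": 0.02,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the scale of the motivating experiment: 97 test
    samples, a rare-skewed site-frequency spectrum, an error channel
    that decays with MAF and doubles for heterozygotes, and GP triplets
    sharp enough for confidence filtering to be informative.
    """

    n_samples: int = 97
    n_sites: int = 50_000
    # ("beta", a, b): maf = 0.5*Beta(a,b); ("uniform", lo, hi); ("fixed", m)
    maf_spectrum: tuple = ("beta", 0.7, 2.0)
    channel: ErrorModel | None = None  # None -> parametric_error_model()
    gp_calibration: float = 30.0  # Beta concentration of the max-GP draw
    gp_separation: float = 0.8    # how much correct calls outscore errors
    nonpanel_error_multiplier: float = 1.3
    n_breeds: int = 20
    panel_breed_fraction: float = 0.5
    overlap_design: dict = field(default_factory=lambda: dict(DEFAULT_OVERLAP))
    specific_maf_range: tuple = (0.001, 0.01)
    pairwise_maf_range: tuple = (0.01, 0.05)
    shared_maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    def resolved_channel(self) -> ErrorModel:
        return self.channel if self.channel is not None else parametric_error_model()


def _sample_metadata(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic breed assignment: samples cycle through breeds;
    the first panel_breed_fraction of breeds are in the reference panel."""
    breeds = [f"BR{i:02d}" for i in range(cfg.n_breeds)]
    n_panel = int(round(cfg.panel_breed_fraction * cfg.n_breeds))
    rows = []
    for i in range(cfg.n_samples):
        b = i % cfg.n_breeds
        rows.append({"sample_id": f"S{i:03d}", "breed": breeds[b],
                     "in_reference_panel": b < n_panel})
    return pd.DataFrame(rows).set_index("sample_id")


def _draw_maf(cfg: SimConfig, n: int, rng) -> np.ndarray:
    kind = cfg.maf_spectrum[0]
    if kind == "beta":
        _, a, b = cfg.maf_spectrum
        m = 0.5 * rng.beta(a, b, size=n)
        return np.clip(m, 1e-4, 0.5)
    if kind == "uniform":
        _, lo, hi = cfg.maf_spectrum
        if not 0 < lo < hi <= 0.5:
            raise ValueError("uniform spectrum needs 0 < lo < hi <= 0.5")
        return rng.uniform(lo, hi, size=n)
    if kind == "fixed":
        m = float(cfg.maf_spectrum[1])
        if m <= 0:
            raise ValueError("degenerate spectrum: all mass at MAF 0")
        return np.full(n, m)
    raise ValueError(f"unknown maf_spectrum kind {kind!r}")


def _sites(n: int, start_pos: int = 101, spacing: int = 37) -> list:
    return [
        VariantKey("1", start_pos + spacing * i, *_ALLELES[i % len(_ALLELES)])
        for i in range(n)
    ]


def _hwe_calls(maf: np.ndarray, n_samples: int, rng) -> np.ndarray:
    """HWE genotype draw per site; invariant sites are re-drawn."""
    p = maf
    t1 = ((1 - p) ** 2)[:, None]
    t2 = t1 + (2 * p * (1 - p))[:, None]
    u = rng.random((len(p), n_samples))
    calls = ((u > t1).astype(np.int8) + (u > t2).astype(np.int8))
    for _ in range(100):
        bad = ~(calls > 0).any(axis=1)
        if not bad.any():
            break
        u = rng.random((int(bad.sum()), n_samples))
        calls[bad] = ((u > t1[bad]).astype(np.int8) + (u > t2[bad]).astype(np.int8))
    else:
        bad = ~(calls > 0).any(axis=1)
        calls[bad, 0] = 1  # force one het rather than loop forever at tiny p*n
    return calls


def generate_truth(cfg: SimConfig, rng=None) -> tuple:
    """Draw the truth cohort: (GenotypeMatrix, MafTable).

    Site MAFs come from the configured spectrum; genotypes are i.i.d.
    HWE per site; invariant draws are re-sampled. The returned MafTable
    holds the population (spectrum) MAF, tagged 'panel' — it plays the
    role of reference-panel allele frequencies, known without reference
    to the cohort's realized genotypes.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    maf = _draw_maf(cfg, cfg.n_sites, rng)
    calls = _hwe_calls(maf, cfg.n_samples, rng)
    meta = _sample_metadata(cfg)
    gm = GenotypeMatrix(sites=_sites(cfg.n_sites), samples=list(meta.index),
                        calls=calls, sample_meta=meta)
    return gm, MafTable(keys=list(gm.sites), maf=maf, source="panel")


def _group_channels(cfg: SimConfig, regime: str = "unfiltered") -> np.ndarray:
    """(50, 2, 3, 3) channel array: group 0 = panel breeds, 1 = non-panel.

    Non-panel rows scale off-diagonal mass by nonpanel_error_multiplier
    with the diagonal renormalized (errors capped so rows stay
    stochastic).
    """
    P0 = cfg.resolved_channel().matrices[regime]
    m = cfg.nonpanel_error_multiplier
    off = P0 * (1 - np.eye(3))
    scaled = off * m
    tot = scaled.sum(axis=2, keepdims=True)
    over = np.clip(tot, 1e-300, None)
    scale_back = np.where(tot > 0.95, 0.95 / over, 1.0)
    scaled = scaled * scale_back
    P1 = scaled + np.eye(3) * (1 - scaled.sum(axis=2, keepdims=True))
    return np.stack([P0, P1], axis=1)


def effective_error_model(cfg: SimConfig) -> ErrorModel:
    """Cohort-level channel: sample-weighted mixture of panel and non-panel channels."""
    meta = _sample_metadata(cfg)
    f = 1.0 - meta["in_reference_panel"].mean()
    matrices = {}
    for regime in ("unfiltered", "filtered"):
        P = _group_channels(cfg, regime)
        matrices[regime] = (1 - f) * P[:, 0] + f * P[:, 1]
    return ErrorModel(matrices=matrices)


def generate_imputed(truth: GenotypeMatrix, maf: MafTable, cfg: SimConfig,
                     rng=None) -> GenotypeMatrix:
    """Resample each truth call through its MAF bin's error channel, with GP.

    The imputed call is drawn from the channel row of the truth
    genotype. The called genotype's GP is drawn from a Beta whose
    overall expectation equals the channel's posterior probability that
    the call is correct (HWE prior at the site's population MAF);
    conditional on the call being correct the mean is raised and on an
    error lowered (gp_separation), so max GP is informative about
    correctness, with sharpness set by gp_calibration. The residual
    probability splits across the other genotypes in proportion to
    their posteriors.
    """
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    bins = maf_bin_index(maf.aligned_to(truth.sites, strict=True))
    if (bins < 0).any():
        raise ValueError("every truth site needs a positive population MAF")
    meta = truth.sample_meta
    if meta is None:
        grp = np.zeros(truth.n_samples, dtype=int)
    else:
        grp = (~meta["in_reference_panel"].to_numpy()).astype(int)
    P = _group_channels(cfg, "unfiltered")  # (50, 2, 3, 3)
    calls = truth.calls
    present = calls != MISSING
    safe_calls = np.where(present, calls, 0)

    probs = P[bins[:, None], grp[None, :], safe_calls, :]  # (S, N, 3)
    cum = np.cumsum(probs, axis=2)
    u = rng.random(calls.shape)
    imp = (u[:, :, None] > cum).sum(axis=2).astype(np.int8)

    # posterior weights w_t = pi_t * P[t, imputed_call]
    p = maf.aligned_to(truth.sites)
    pi = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=1)  # (S, 3)
    col = P[bins[:, None, None], grp[None, :, None],
            np.arange(3)[None, None, :], imp[:, :, None].astype(int)]  # (S, N, 3)
    w = pi[:, None, :] * col
    denom = w.sum(axis=2)
    c = np.take_along_axis(w, imp[:, :, None].astype(int), axis=2)[:, :, 0] / denom

    correct = imp == safe_calls
    sep = cfg.gp_separation
    mean = np.where(correct, c + sep * (1 - c), c * (1 - sep))
    # the called genotype is the argmax of its GP triplet (as in real
    # imputation output), so its probability lives on [1/3, 1]; draw a
    # Beta on that range with the target mean (floored where the target
    # falls below 1/3, which only happens for error calls)
    target = np.clip((3.0 * mean - 1.0) / 2.0, 1e-6, 1 - 1e-6)
    kappa = cfg.gp_calibration
    beta = rng.beta(target * kappa, (1 - target) * kappa)
    maxgp = (1.0 + 2.0 * beta) / 3.0

    # residual splits across the other genotypes by posterior weight,
    # capped at maxgp so the called genotype stays the maximum
    other = w.copy()
    call_idx = imp[:, :, None].astype(int)
    np.put_along_axis(other, call_idx, 0.0, axis=2)
    osum = other.sum(axis=2, keepdims=True)
    frac = np.where(osum > 0, other / np.where(osum == 0, 1, osum), 0.5)
    np.put_along_axis(frac, call_idx, 0.0, axis=2)
    frac = frac / frac.sum(axis=2, keepdims=True)
    gp = frac * (1 - maxgp)[:, :, None]
    cap = maxgp[:, :, None]
    over = np.clip(gp - cap, 0.0, None)  # at most one component can exceed
    others_mask = np.ones_like(gp, dtype=bool)
    np.put_along_axis(others_mask, call_idx, False, axis=2)
    gp = gp - over + (over.sum(axis=2, keepdims=True) - over) * others_mask
    np.put_along_axis(gp, call_idx, cap, axis=2)

    imp = np.where(present, imp, MISSING).astype(np.int8)
    gp[~present] = np.nan
    return GenotypeMatrix(sites=list(truth.sites), samples=list(truth.samples),
                          calls=imp, gp=gp, sample_meta=truth.sample_meta)


def generate_overlap_trio(cfg: SimConfig, rng=None) -> tuple:
    """Three datasets with a constructed Venn design and MAF enrichment.

    Region sizes are exact integer shares of n_sites per
    cfg.overlap_design (fractions over the union must sum to 1; the
    rounding remainder goes to the all-shared region). Dataset-specific
    sites draw MAFs from specific_maf_range, pairwise-shared from
    pairwise_maf_range, all-shared from shared_maf_range. Returns
    (region -> site-key set, dataset name -> GenotypeMatrix, MafTable),
    with datasets keyed 'imputed' (A), 'wgs' (B), 'panel' (C).
    """
    rng = np.random.default_rng(cfg.seed + 2 if rng is None else rng)
    fracs = cfg.overlap_design
    regions = ("ABC", "AB", "AC", "BC", "A", "B", "C")
    if set(fracs) != set(regions):
        raise ValueError(f"overlap_design must define exactly regions {regions}")
    vals = np.array([fracs[r] for r in regions], dtype=float)
    if (vals < 0).any() or (vals > 1).any() or abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError("overlap fractions must lie in [0,1] and sum to 1")
    counts = {r: int(round(fracs[r] * cfg.n_sites)) for r in regions}
    counts["ABC"] += cfg.n_sites - sum(counts.values())

    sites = _sites(cfg.n_sites)
    labels, maf = [], np.empty(cfg.n_sites)
    pos = 0
    ranges = {1: cfg.specific_maf_range, 2: cfg.pairwise_maf_range,
              3: cfg.shared_maf_range}
    region_sets = {}
    for r in regions:
        n = counts[r]
        lo, hi = ranges[len(r)]
        maf[pos:pos + n] = rng.uniform(lo, hi, size=n)
        region_sets[r] = set(sites[pos:pos + n])
        labels.extend([r] * n)
        pos += n

    calls = _hwe_calls(maf, cfg.n_samples, rng)
    meta = _sample_metadata(cfg)
    union = GenotypeMatrix(sites=sites, samples=list(meta.index), calls=calls,
                           sample_meta=meta)
    label_arr = np.array(labels)
    datasets = {}
    for letter, name in zip("ABC", ("imputed", "wgs", "panel")):
        mask = np.array([letter in lab for lab in label_arr])
        datasets[name] = union.subset_sites(mask)
    table = MafTable(keys=sites, maf=maf, source="panel")
    return region_sets, datasets, table
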