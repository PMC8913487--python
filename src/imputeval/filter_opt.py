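"""Dual-threshold genotype-confidence filtering and its ROC evaluation.

A call is low-confidence when its maximum genotype probability (max GP)
falls below a threshold X; a site is removed when the number of its
low-confidence calls reaches a count threshold Y (count >= Y removes).
Strategies are scored against the high-coverage truth by treating
discordant calls as the positives to be removed: TPR = discordant calls
removed / all discordant, FPR = concordant calls removed / all
concordant, FDR = discordant calls remaining / calls remaining, and the
keep rate = calls remaining / all compared calls.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, MISSING

DEFAULT_GP_GRID = (0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90)
DEFAULT_LOWCONF_GRID = tuple(range(1, 9))


@dataclass
class FilterSpec:
    """X: max-GP confidence threshold in (0,1); Y: low-confidence count threshold."""

    X: float
    Y: int

    def __post_init__(self):
        if not 0.0 < self.X < 1.0:
            raise ValueError("GP threshold X must lie in (0, 1)")
        if self.Y < 0:
            raise ValueError("low-confidence count threshold Y must be >= 0")


@dataclass
class FilterMetrics:
    tpr: float
    fpr: float
    fdr: float
    keep_rate: float
    n_sites_kept: int
    n_calls_kept: int


def flag_low_confidence(gm: GenotypeMatrix, X: float) -> np.ndarray:
    """Boolean (site, sample) matrix: True where max GP < X (strict).

    Missing calls are flagged. A call whose GP triplet is absent (all
    NaN) is also flagged: no confidence information means no confidence.
    """
    if gm.gp is None:
        raise ValueError("GP triplets are required to flag low-confidence calls")
    if not 0.0 < X < 1.0:
        raise ValueError("GP threshold X must lie in (0, 1)")
    with np.errstate(invalid="ignore"):
        maxgp = np.nanmax(np.where(np.isnan(gm.gp), -np.inf, gm.gp), axis=2)
    flags = maxgp < X
    flags |= gm.calls == MISSING
    return flags


def apply_site_filter(flags: np.ndarray, Y: int) -> np.ndarray:
    """Kept-site mask: a site survives iff its flagged-call count is < Y.

    Sites with a low-confidence count greater than or equal to Y are
    removed; Y = 0 removes every site.
    """
    if Y < 0:
        raise ValueError("Y must be >= 0")
    return np.asarray(flags, bool).sum(axis=1) < Y


def filter_metrics(truth: GenotypeMatrix, imputed: GenotypeMatrix,
                   kept: np.ndarray) -> FilterMetrics:
    """Score one kept-site set against the truth.

    Only pairs where both calls are present are compared; missing-call
    pairs are excluded from every numerator and denominator (though
    they do count toward a site's low-confidence tally upstream). TPR
    is NaN when the data contain no discordant calls at all.
    """
    if truth.sites != imputed.sites or truth.samples != imputed.samples:
        raise ValueError("truth and imputed must be aligned on sites and samples")
    kept = np.asarray(kept, bool)
    valid = (truth.calls != MISSING) & (imputed.calls != MISSING)
    discord = valid & (truth.calls != imputed.calls)
    concord = valid & (truth.calls == imputed.calls)
    total = int(valid.sum())
    total_disc = int(discord.sum())
    total_conc = int(concord.sum())
    removed = ~kept
    disc_removed = int(discord[removed].sum())
    conc_removed = int(concord[removed].sum())
    n_calls_kept = int(valid[kept].sum())
    disc_kept = total_disc - disc_removed
    return FilterMetrics(
        tpr=disc_removed / total_disc if total_disc else float("nan"),
        fpr=conc_removed / total_conc if total_conc else float("nan"),
        fdr=disc_kept / n_calls_kept if n_calls_kept else float("nan"),
        keep_rate=n_calls_kept / total if total else float("nan"),
        n_sites_kept=int(kept.sum()),
        n_calls_kept=n_calls_kept,
    )


def roc_grid(truth: GenotypeMatrix, imputed: GenotypeMatrix,
             gp_grid=DEFAULT_GP_GRID,
             lowconf_grid=DEFAULT_LOWCONF_GRID) -> pd.DataFrame:
    """Filter metrics over a (X, Y) threshold grid.

    One row per (X, Y); for fixed X, rows ordered by Y trace one ROC
    curve. The default grid is 7 GP thresholds x 8 count thresholds.
    """
    if len(gp_grid) == 0 or len(lowconf_grid) == 0:
        raise ValueError("threshold grids must be non-empty")
    rows = []
    for x in gp_grid:
        flags = flag_low_confidence(imputed, x)
        for y in lowconf_grid:
            kept = apply_site_filter(flags, int(y))
            m = filter_metrics(truth, imputed, kept)
            rows.append({"X": x, "Y": int(y), "tpr": m.tpr, "fpr": m.fpr,
                         "fdr": m.fdr, "keep_rate": m.keep_rate,
                         "n_sites_kept": m.n_sites_kept,
                         "n_calls_kept": m.n_calls_kept})
    return pd.DataFrame(rows)
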