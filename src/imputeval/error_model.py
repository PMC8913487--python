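"""MAF-binned genotype error channels and I = G.P simulation.

The error model is a family of row-stochastic 3x3 matrices P, one per
0.01 MAF bin and per filter regime (unfiltered / filtered), estimated
from confusion tables: rows are the true genotype, columns the imputed
genotype, entries the observed fraction of each true genotype imputed
as each genotype. Imputation's effect on genotype counts is simulated
as I = G.P, where G is a 1x3 vector of true genotype counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._binning import N_MAF_BINS, bin_edges, maf_bin_index

REGIMES = ("unfiltered", "filtered")
_ROW_TOL = 1e-9


@dataclass
class ErrorModel:
    """Per-(MAF bin, regime) genotype error channel.

    matrices maps a regime name to an array of shape (50, 3, 3);
    supported marks which (bin, row) entries were estimated from data
    (False = filled by the nearest-supported-bin borrowing rule, or the
    identity row when a genotype was never observed in the regime).
    """

    matrices: dict
    supported: dict = field(default_factory=dict)

    def __post_init__(self):
        for regime, P in self.matrices.items():
            P = np.asarray(P, dtype=float)
            if P.shape != (N_MAF_BINS, 3, 3):
                raise ValueError(f"{regime}: expected shape (50, 3, 3), got {P.shape}")
            if (P < -1e-12).any() or (P > 1 + 1e-12).any():
                raise ValueError(f"{regime}: entries must lie in [0, 1]")
            if np.max(np.abs(P.sum(axis=2) - 1.0)) > _ROW_TOL:
                raise ValueError(f"{regime}: rows must sum to 1 within {_ROW_TOL}")
            self.matrices[regime] = P
            self.supported.setdefault(regime, np.ones((N_MAF_BINS, 3), dtype=bool))

    @property
    def regimes(self) -> tuple:
        return tuple(self.matrices)

    def matrix(self, bin_idx: int, regime: str) -> np.ndarray:
        return self.matrices[regime][bin_idx]

    def for_maf(self, maf: float, regime: str) -> np.ndarray:
        k = int(maf_bin_index(maf))
        if k < 0:
            raise ValueError(f"MAF {maf} falls outside every bin")
        return self.matrix(k, regime)

    def to_tsv(self, path) -> None:
        rows = []
        for regime, P in self.matrices.items():
            sup = self.supported[regime]
            for k in range(N_MAF_BINS):
                lo, hi = bin_edges(k)
                row = {"maf_bin_low": lo, "maf_bin_high": hi, "regime": regime}
                for g in range(3):
                    for i in range(3):
                        row[f"p_{g}{i}"] = P[k, g, i]
                row["supported_rows"] = "".join("1" if s else "0" for s in sup[k])
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ErrorModel":
        df = pd.read_csv(path, sep="\t", dtype={"supported_rows": str})
        matrices, supported = {}, {}
        for regime, grp in df.groupby("regime"):
            P = np.zeros((N_MAF_BINS, 3, 3))
            sup = np.ones((N_MAF_BINS, 3), dtype=bool)
            for _, row in grp.iterrows():
                k = int(maf_bin_index(row["maf_bin_high"]))
                for g in range(3):
                    for i in range(3):
                        P[k, g, i] = row[f"p_{g}{i}"]
                if "supported_rows" in row and isinstance(row["supported_rows"], str):
                    sup[k] = [c == "1" for c in row["supported_rows"]]
            matrices[regime] = P
            supported[regime] = sup
        return cls(matrices=matrices, supported=supported)


def estimate_error_matrices(tables) -> ErrorModel:
    """Estimate the channel family from per-bin confusion tables.

    Each table must carry its maf_bin index; its ``filtered`` flag
    selects the regime. Row g of P is the table's row g normalized by
    its total. Rows with no observations are marked unsupported and
    borrowed from the nearest bin (in bin index) where that row is
    supported within the same regime; a row supported nowhere falls
    back to the identity row.
    """
    tables = list(tables)
    if not tables or all(t.total == 0 for t in tables):
        raise ValueError("no confusion data to estimate an error model from")
    counts = {}
    for t in tables:
        if t.maf_bin is None:
            raise ValueError("confusion tables must be MAF-binned (maf_bin set)")
        regime = "filtered" if t.filtered else "unfiltered"
        acc = counts.setdefault(regime, np.zeros((N_MAF_BINS, 3, 3)))
        acc[t.maf_bin] += t.counts
    matrices, supported = {}, {}
    for regime, acc in counts.items():
        rowtot = acc.sum(axis=2)
        sup = rowtot > 0
        P = np.zeros((N_MAF_BINS, 3, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(sup[:, :, None], acc / np.where(rowtot == 0, 1, rowtot)[:, :, None], 0.0)
        for g in range(3):
            sup_bins = np.flatnonzero(sup[:, g])
            for k in np.flatnonzero(~sup[:, g]):
                if sup_bins.size:
                    nearest = sup_bins[np.argmin(np.abs(sup_bins - k))]
                    P[k, g] = P[nearest, g]
                else:
                    P[k, g] = np.eye(3)[g]
        matrices[regime] = P
        supported[regime] = sup
    return ErrorModel(matrices=matrices, supported=supported)


def parametric_error_model(eps0: float = 0.01, eps1: float = 0.15,
                           tau: float = 0.05, het_multiplier: float = 2.0,
                           filtered_scale: float = 0.5) -> ErrorModel:
    """Smooth default channel family: errors decay with MAF, worst for hets.

    The per-bin error rate is eps(m) = eps0 + eps1*exp(-m/tau) at the
    bin center m, multiplied by het_multiplier for the heterozygous row
    (capped at 0.5). Off-diagonal mass splits between the two wrong
    genotypes in proportion to their Hardy-Weinberg frequencies at the
    bin center, so a rare-allele het is misimputed mostly as homozygous
    reference. The filtered regime scales all error rates by
    filtered_scale (< 1: filtering removes a share of the errors).
    """
    matrices = {}
    for regime, scale in (("unfiltered", 1.0), ("filtered", filtered_scale)):
        P = np.zeros((N_MAF_BINS, 3, 3))
        for k in range(N_MAF_BINS):
            m = (k + 0.5) / 100.0
            eps = (eps0 + eps1 * np.exp(-m / tau)) * scale
            pi = np.array([(1 - m) ** 2, 2 * m * (1 - m), m ** 2])
            for g in range(3):
                e = min(eps * (het_multiplier if g == 1 else 1.0), 0.5)
                others = [i for i in range(3) if i != g]
                wts = pi[others]
                wts = wts / wts.sum()
                P[k, g, g] = 1.0 - e
                for i, w in zip(others, wts):
                    P[k, g, i] = e * w
        matrices[regime] = P
    return ErrorModel(matrices=matrices)


def hwe_genotype_counts(maf: float, n: float) -> np.ndarray:
    """Expected Hardy-Weinberg genotype counts (hom-ref, het, hom-alt).

    G = n * ((1-p)^2, 2p(1-p), p^2) with p = maf; fractional counts are
    allowed (expected counts, not a sample).
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5]")
    if n <= 0:
        raise ValueError("n must be positive")
    p = maf
    return n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])


def _check_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (3, 3):
        raise ValueError("P must be 3x3")
    if (P < -1e-12).any() or (P > 1 + 1e-12).any() or \
            np.max(np.abs(P.sum(axis=1) - 1.0)) > _ROW_TOL:
        raise ValueError("P must be row-stochastic with entries in [0, 1]")
    return P


def simulate_imputed_counts(G, P, mode: str = "expectation",
                            rng=None) -> np.ndarray:
    """Push true genotype counts through an error channel: I = G.P.

    expectation mode returns the exact (possibly fractional) product.
    multinomial mode resamples each true-genotype count across the
    imputed genotypes with the row's probabilities (counts must be
    integral); pass a seeded numpy Generator for reproducibility. The
    total count is conserved exactly in both modes.
    """
    G = np.asarray(G, dtype=float)
    if G.shape != (3,) or (G < 0).any():
        raise ValueError("G must be a 1x3 vector of non-negative counts")
    P = _check_stochastic(P)
    if mode == "expectation":
        return G @ P
    if mode == "multinomial":
        if not np.allclose(G, np.round(G)):
            raise ValueError("multinomial mode requires integer counts")
        rng = np.random.default_rng(rng)
        I = np.zeros(3)
        for g in range(3):
            if G[g] > 0:
                I += rng.multinomial(int(round(G[g])), P[g])
        return I
    raise ValueError("mode must be 'expectation' or 'multinomial'")
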