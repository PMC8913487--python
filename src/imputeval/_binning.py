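"""MAF binning shared across modules.

Strata are the 50 half-open intervals (k/100, (k+1)/100] for k = 0..49.
A folded MAF of exactly 0 (invariant site) belongs to no bin and is
excluded from binned statistics; MAF = 0.5 falls in the top bin.
"""
from __future__ import annotations

import numpy as np

N_MAF_BINS = 50
BIN_WIDTH = 0.01


def maf_bin_index(maf) -> np.ndarray:
    """Map folded MAF values to bin indices 0..49; -1 for MAF <= 0 or NaN.

    Values are rounded to 9 decimals before binning so that float noise
    (e.g. 0.01 stored as 0.010000000000000002) cannot shift a value
    across a bin edge.
    """
    m = np.asarray(maf, dtype=float)
    with np.errstate(invalid="ignore"):
        k = np.ceil(np.round(m * 100.0, 9)).astype(int) - 1
        k = np.minimum(k, N_MAF_BINS - 1)
        k = np.where(np.isnan(m) | (m <= 0), -1, k)
    if np.any(np.asarray(m) > 0.5 + 1e-12):
        raise ValueError("folded MAF must lie in [0, 0.5]")
    return k


def bin_edges(k: int) -> tuple[float, float]:
    """(low, high] edges of bin k."""
    return k * BIN_WIDTH, (k + 1) * BIN_WIDTH
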