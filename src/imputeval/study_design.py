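"""Case-control chi-square power and required sample sizes.

Association is modeled as a chi-square test (df = 1, no continuity
correction) on a 2x2 table of minor-allele carrier status (carrier =
het or hom-alt) by case/control group, with genotype counts built from
Hardy-Weinberg equilibrium at each group's MAF. Imputation's impact is
simulated by pushing each group's genotype counts through the error
channel of the pooled-MAF bin before forming the table. Effect size is
Cohen's w against a null in which the pooled carrier frequency is
shared by both groups; power is the noncentral chi-square upper-tail
mass (ncp = N*w^2) beyond the central critical value at alpha.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .error_model import ErrorModel, hwe_genotype_counts, _check_stochastic

REGIME_CHANNELS = {"true": None, "imputed": "unfiltered",
                   "filtered-imputed": "filtered"}
DEFAULT_RATIOS = ((1, 1), (1, 3), (3, 1))


def default_maf_pairs() -> list:
    """21 (case, control) MAF pairs: all ordered pairs from 0.05..0.35 step 0.05."""
    grid = [round(0.05 * i, 2) for i in range(1, 8)]
    return [(hi, lo) for lo, hi in combinations(grid, 2)]


@dataclass
class DesignConfig:
    case_maf: float
    control_maf: float
    ratio: tuple = (1, 1)
    alpha: float = 5e-8
    target_power: float = 0.8
    n_min: int = 100
    n_max: int = 7000
    reference_n: int = 1000
    regime: str = "true"

    def __post_init__(self):
        for m in (self.case_maf, self.control_maf):
            if not 0.0 <= m <= 0.5:
                raise ValueError("MAFs must lie in [0, 0.5]")
        if min(self.ratio) <= 0:
            raise ValueError("ratio components must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must lie in (0, 1)")
        if self.regime not in REGIME_CHANNELS:
            raise ValueError(f"regime must be one of {tuple(REGIME_CHANNELS)}")

    @property
    def case_fraction(self) -> float:
        return self.ratio[0] / (self.ratio[0] + self.ratio[1])

    @property
    def pooled_maf(self) -> float:
        """Ratio-weighted population MAF; selects the error bin and the null."""
        r = self.case_fraction
        return r * self.case_maf + (1 - r) * self.control_maf


@dataclass
class PowerResult:
    case_maf: float
    control_maf: float
    pooled_maf: float
    ratio: tuple
    regime: str
    w: float
    required_n: float  # NaN = not achievable within n_max
    power_at_nmax: float
    chisq_stat: float
    p_value: float
    delta_n: float = float("nan")

    @property
    def delta_maf(self) -> float:
        return self.case_maf - self.control_maf

    @property
    def achievable(self) -> bool:
        return np.isfinite(self.required_n)


def build_contingency(G_case, G_ctrl) -> np.ndarray:
    """2x2 table: rows case/control, columns carrier / non-carrier.

    A carrier holds at least one copy of the minor allele (het or
    hom-alt). Fractional expected counts are permitted.
    """
    G_case = np.asarray(G_case, dtype=float)
    G_ctrl = np.asarray(G_ctrl, dtype=float)
    if (G_case < 0).any() or (G_ctrl < 0).any():
        raise ValueError("genotype counts must be non-negative")
    return np.array([
        [G_case[1] + G_case[2], G_case[0]],
        [G_ctrl[1] + G_ctrl[2], G_ctrl[0]],
    ])


def chisq_test(table) -> tuple:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    Fractional cells are allowed (expected counts from the error-channel
    simulation feed in directly). Returns (statistic, p). Raises when a
    marginal is zero, where the statistic is undefined.
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2) or (O < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("chi-square undefined: a table marginal is zero")
    E = np.outer(rows, cols) / O.sum()
    stat = float(((O - E) ** 2 / E).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def cohens_w(p_alt, p_null) -> float:
    """Chi-square effect size: w = sqrt(sum (p_alt - p_null)^2 / p_null)."""
    p_alt = np.asarray(p_alt, dtype=float)
    p_null = np.asarray(p_null, dtype=float)
    for p in (p_alt, p_null):
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("cell probabilities must sum to 1")
    if (p_null <= 0).any():
        raise ValueError("null cell probabilities must be positive")
    return float(np.sqrt((((p_alt - p_null) ** 2) / p_null).sum()))


def power_chisq(w, n, df: int = 1, alpha: float = 5e-8):
    """Power of the chi-square test at effect size w and total sample size n.

    Noncentral chi-square upper tail beyond the central critical value,
    with noncentrality n*w^2 (the computation behind R's
    pwr::pwr.chisq.test). Vectorized over n. w = 0 returns alpha.
    """
    w = float(w)
    if w < 0:
        raise ValueError("w must be >= 0")
    n = np.asarray(n, dtype=float)
    if (n <= 0).any():
        raise ValueError("n must be positive")
    crit = stats.chi2.isf(alpha, df)
    out = stats.ncx2.sf(crit, df, n * w * w)
    return float(out) if out.ndim == 0 else out


def carrier_probabilities(cfg: DesignConfig, em: ErrorModel | None = None) -> tuple:
    """(q_case, q_ctrl): per-group carrier probability under the regime.

    HWE genotype probabilities at each group's MAF, pushed through the
    pooled-MAF bin's channel for imputed regimes ('true' uses the
    identity channel).
    """
    channel = REGIME_CHANNELS[cfg.regime]
    if channel is None:
        P = np.eye(3)
    else:
        if em is None:
            raise ValueError(f"regime {cfg.regime!r} requires an error model")
        P = _check_stochastic(em.for_maf(cfg.pooled_maf, channel))
    qs = []
    for m in (cfg.case_maf, cfg.control_maf):
        g = hwe_genotype_counts(m, 1.0)
        i = g @ P
        qs.append(float(i[1] + i[2]))
    return tuple(qs)


def _cell_probabilities(q_case: float, q_ctrl: float, r_case: float) -> tuple:
    """(p_alt, p_null) 4-vectors: carrier/non-carrier by group."""
    p_alt = np.array([
        r_case * q_case, r_case * (1 - q_case),
        (1 - r_case) * q_ctrl, (1 - r_case) * (1 - q_ctrl),
    ])
    q_bar = r_case * q_case + (1 - r_case) * q_ctrl
    p_null = np.array([
        r_case * q_bar, r_case * (1 - q_bar),
        (1 - r_case) * q_bar, (1 - r_case) * (1 - q_bar),
    ])
    return p_alt, p_null


def effect_size(cfg: DesignConfig, em: ErrorModel | None = None) -> float:
    """Cohen's w for a design configuration under its regime."""
    q_case, q_ctrl = carrier_probabilities(cfg, em)
    p_alt, p_null = _cell_probabilities(q_case, q_ctrl, cfg.case_fraction)
    return cohens_w(p_alt, p_null)


def required_sample_size(cfg: DesignConfig,
                         em: ErrorModel | None = None) -> PowerResult:
    """Smallest total N in [n_min, n_max] reaching the target power.

    Scans every integer N (step 1); required_n is NaN when no N in the
    range qualifies (in particular whenever case and control MAFs are
    equal, where w = 0). The chi-square statistic and p value are
    reported at reference_n using expected fractional counts.
    """
    w = effect_size(cfg, em)
    ns = np.arange(cfg.n_min, cfg.n_max + 1)
    powers = power_chisq(w, ns, alpha=cfg.alpha)
    hits = np.flatnonzero(powers >= cfg.target_power)
    required = float(ns[hits[0]]) if hits.size else float("nan")
    q_case, q_ctrl = carrier_probabilities(cfg, em)
    r = cfg.case_fraction
    n_ref = cfg.reference_n
    table = np.array([
        [n_ref * r * q_case, n_ref * r * (1 - q_case)],
        [n_ref * (1 - r) * q_ctrl, n_ref * (1 - r) * (1 - q_ctrl)],
    ])
    if w > 0:
        stat, p = chisq_test(table)
    else:
        stat, p = 0.0, 1.0
    return PowerResult(
        case_maf=cfg.case_maf, control_maf=cfg.control_maf,
        pooled_maf=cfg.pooled_maf, ratio=cfg.ratio, regime=cfg.regime,
        w=w, required_n=required, power_at_nmax=float(powers[-1]),
        chisq_stat=stat, p_value=p,
    )


def run_design_grid(em: ErrorModel, maf_pairs=None, ratios=DEFAULT_RATIOS,
                    regimes=("true", "imputed", "filtered-imputed"),
                    **cfg_kwargs) -> pd.DataFrame:
    """PowerResults over (MAF pair) x (ratio) x (regime).

    The default grid is the 21 ordered MAF pairs from 0.05..0.35 (step
    0.05, case > control) crossed with ratios 1:1, 1:3, 3:1. delta_n is
    each row's required_n minus the true-genotype regime's required_n
    for the same pair and ratio (0 for true rows by construction).
    """
    if maf_pairs is None:
        maf_pairs = default_maf_pairs()
    if not maf_pairs:
        raise ValueError("maf_pairs must be non-empty")
    rows = []
    for case_maf, control_maf in maf_pairs:
        for ratio in ratios:
            base = None
            for regime in regimes:
                cfg = DesignConfig(case_maf=case_maf, control_maf=control_maf,
                                   ratio=tuple(ratio), regime=regime, **cfg_kwargs)
                res = required_sample_size(cfg, em)
                if regime == "true":
                    base = res.required_n
                res.delta_n = res.required_n - base if base is not None else float("nan")
                rows.append({
                    "case_maf": res.case_maf, "control_maf": res.control_maf,
                    "pooled_maf": res.pooled_maf,
                    "delta_maf": round(res.delta_maf, 10),  # kill float noise for grouping
                    "ratio": f"{ratio[0]}:{ratio[1]}",
                    "regime": res.regime, "w": res.w,
                    "required_n": res.required_n, "delta_n": res.delta_n,
                    "power_at_nmax": res.power_at_nmax,
                })
    return pd.DataFrame(rows)
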