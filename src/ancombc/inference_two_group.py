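"""Bias-corrected two-group tests, p-values, and simultaneous intervals.

The primary statistic standardizes the bias-corrected log fold change:

    W_i  = (Delta_i - delta_hat_EM) / sqrt(sigma2_i1 + sigma2_i2),

asymptotically standard normal under the null.  When sample sizes are
modest or many taxa are non-null, the uncertainty of the bias estimate is
no longer negligible and the conservative variant is used instead:

    W*_i = (Delta_i - delta_hat_WLS)
           / (sqrt(sigma2_i1 + sigma2_i2) + sqrt(Var_hat(delta_hat_WLS))),

whose denominator bounds the standard deviation of the numerator from
above (it absorbs the worst-case correlation between Delta_i and the
shared bias estimate).  Simultaneous 95% confidence intervals use the
Bonferroni-adjusted normal quantile z_{1 - alpha/(2m)}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .bias_correction import MixtureFit, VarEstimate, DeltaSeries

__all__ = ["TwoGroupTestConfig", "TwoGroupStats", "test_statistics",
           "pvalues_ci", "adjust_pvalues", "choose_statistic"]

_ADJUST_ALIASES = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}


@dataclass
class TwoGroupTestConfig:
    statistic: str = "auto"   # "W", "W_star", or "auto"
    alpha: float = 0.05
    adjust: str = "bonferroni"
    # heuristic switch for "auto": W_star below this per-group size, or
    # when the estimated non-null fraction exceeds max_nonnull_fraction
    small_sample_n: int = 30
    max_nonnull_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.adjust not in _ADJUST_ALIASES:
            raise ValueError(f"unknown adjustment {self.adjust!r}")
        if self.statistic not in ("W", "W_star", "auto"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class TwoGroupStats:
    effect: np.ndarray
    se: np.ndarray
    W: np.ndarray
    statistic: str  # which variant was used


def choose_statistic(cfg: TwoGroupTestConfig, n1: int, n2: int,
                     fit: MixtureFit) -> str:
    """Resolve 'auto' to W or W_star.

    W_star is selected when either per-group size is below
    ``small_sample_n`` or the fitted non-null mass pi1 + pi2 exceeds
    ``max_nonnull_fraction``; otherwise the simpler W is adequate.
    """
    if cfg.statistic != "auto":
        return cfg.statistic
    if min(n1, n2) < cfg.small_sample_n:
        return "W_star"
    if fit.pi[1] + fit.pi[2] > cfg.max_nonnull_fraction:
        return "W_star"
    return "W"


def test_statistics(
    series: DeltaSeries,
    nu0_2: np.ndarray,
    ve: VarEstimate,
    fit: MixtureFit,
    cfg: TwoGroupTestConfig,
    n1: int | None = None,
    n2: int | None = None,
) -> TwoGroupStats:
    """Per-taxon effect, standard error, and standardized statistic.

    ``nu0_2`` is sigma2_i1 + sigma2_i2 for the pair under test (usually
    ``series.nu0_2``).  Taxa with zero standard error get NaN statistics.
    """
    stat = cfg.statistic
    if stat == "auto":
        if n1 is None or n2 is None:
            stat = "W"
        else:
            stat = choose_statistic(cfg, n1, n2, fit)
    base_se = np.sqrt(nu0_2)
    if stat == "W":
        effect = series.delta_i - fit.delta_em
        se = base_se
    else:
        effect = series.delta_i - ve.delta_wls
        se = base_se + np.sqrt(max(ve.var_wls, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(se > 0, effect / se, np.nan)
    return TwoGroupStats(effect=effect, se=se, W=W, statistic=stat)


def pvalues_ci(
    stats: TwoGroupStats, cfg: TwoGroupTestConfig, m: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided normal p-values, adjusted p-values, simultaneous CIs.

    The CI multiplier z_{1 - alpha/(2m)} gives intervals with joint
    coverage >= 1 - alpha across all m taxa (Bonferroni), using the same
    standard error as the test statistic.
    """
    if m is None:
        m = int(np.sum(np.isfinite(stats.W)))
    m = max(m, 1)
    p = np.where(np.isfinite(stats.W),
                 2.0 * norm.sf(np.abs(stats.W)), np.nan)
    p_adj = adjust_pvalues(p, cfg.adjust)
    z = norm.ppf(1.0 - cfg.alpha / (2.0 * m))
    ci_lo = stats.effect - z * stats.se
    ci_hi = stats.effect + z * stats.se
    return p, p_adj, ci_lo, ci_hi


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity adjustment: bonferroni, holm, or bh; NaNs pass through."""
    if method not in _ADJUST_ALIASES:
        raise ValueError(f"unknown adjustment {method!r}")
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(
            p[finite], method=_ADJUST_ALIASES[method]
        )[1]
    return out
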