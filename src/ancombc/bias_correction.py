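"""Estimation of the between-group sampling-fraction bias delta.

The naive difference of estimated log group means,
Delta_i = mu_hat_i1 - mu_hat_i2, is shifted by a common bias
delta = d_bar_1. - d_bar_2. (difference of group-averaged log sampling
fractions), identical for every taxon.  Pooling across taxa, Delta_i is
modeled as a three-component Gaussian mixture:

    f(Delta_i) = pi0 N(delta,      nu2_i0)
               + pi1 N(delta + l1, nu2_i1)     l1 < 0  (down in group 1)
               + pi2 N(delta + l2, nu2_i2)     l2 > 0  (up in group 1)

with per-taxon null variances nu2_i0 = sigma2_i1 + sigma2_i2 plugged in
from the estimation stage and inflated variances nu2_ir = nu2_i0 + kappa_r
(kappa_r >= 0) for the two non-null components.  A generalized E-M
algorithm maximizes the likelihood; the location estimate of the null
component is delta_hat_EM.

Because the likelihood is not regular, the variance of delta_hat_EM is
approximated by the variance of the weighted-least-squares estimator
delta_hat_WLS computed on the E-M classification; the two estimators are
nearly perfectly correlated in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = ["DeltaSeries", "EMConfig", "MixtureFit", "VarEstimate",
           "em_fit", "wls_delta", "var_wls"]

_TINY = 1e-12


@dataclass
class DeltaSeries:
    """Per-taxon mean differences and their null variances.

    delta_i : Delta_i = mu_hat_i1 - mu_hat_i2 over testable taxa.
    nu0_2 : matching variance estimates Var(Delta_i) under the null.
    """

    delta_i: np.ndarray
    nu0_2: np.ndarray
    taxon_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.delta_i = np.asarray(self.delta_i, dtype=float)
        self.nu0_2 = np.asarray(self.nu0_2, dtype=float)
        if self.delta_i.shape != self.nu0_2.shape:
            raise ValueError("delta_i and nu0_2 must have equal length")
        if np.any(self.nu0_2 < 0) or not np.all(np.isfinite(self.nu0_2)):
            raise ValueError("nu0_2 must be finite and non-negative")


@dataclass
class EMConfig:
    max_iter: int = 100
    tol: float = 1e-5
    lower_quantile: float = 0.10
    upper_quantile: float = 0.90
    min_sign: float = 1e-8  # smallest |l_r| honoring the strict sign constraints
    null_only: bool = False  # disable both non-null components


@dataclass
class MixtureFit:
    """Fitted three-component mixture and derived classification."""

    delta_em: float
    pi: np.ndarray           # (pi0, pi1, pi2)
    l1: float
    l2: float
    kappa1: float
    kappa2: float
    responsibilities: np.ndarray  # (m x 3)
    classes: np.ndarray           # argmax labels in {0, 1, 2}
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def class_sizes(self) -> tuple[int, int, int]:
        return tuple(int(np.sum(self.classes == r)) for r in range(3))


@dataclass
class VarEstimate:
    delta_wls: float
    var_wls: float


def _component_params(series: DeltaSeries, fit_l: np.ndarray,
                      kappa: np.ndarray, delta: float):
    """Means (m x 3) and variances (m x 3) of the three components."""
    means = delta + fit_l[np.newaxis, :]
    var = series.nu0_2[:, np.newaxis] + kappa[np.newaxis, :]
    return means, np.maximum(var, _TINY)


def _log_density(series: DeltaSeries, pi: np.ndarray, fit_l: np.ndarray,
                 kappa: np.ndarray, delta: float) -> np.ndarray:
    """(m x 3) matrix of log(pi_r) + log phi(Delta_i; mean_r, var_ir)."""
    means, var = _component_params(series, fit_l, kappa, delta)
    x = series.delta_i[:, np.newaxis]
    logphi = norm.logpdf(x, loc=means, scale=np.sqrt(var))
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(pi, _TINY))[np.newaxis, :] + logphi


def _loglik(logdens: np.ndarray) -> float:
    mx = logdens.max(axis=1, keepdims=True)
    return float(np.sum(mx[:, 0] + np.log(np.exp(logdens - mx).sum(axis=1))))


def _responsibilities(logdens: np.ndarray) -> np.ndarray:
    mx = logdens.max(axis=1, keepdims=True)
    w = np.exp(logdens - mx)
    return w / w.sum(axis=1, keepdims=True)


def _init(series: DeltaSeries, cfg: EMConfig):
    """Quantile-based initialization.

    delta starts at the median of Delta (robust to non-null contamination);
    the tails below/above the configured quantiles seed the down/up
    components.
    """
    d = series.delta_i
    delta0 = float(np.median(d))
    lo = np.quantile(d, cfg.lower_quantile)
    hi = np.quantile(d, cfg.upper_quantile)
    c1 = d < lo
    c2 = d > hi
    m = d.size
    pi = np.array([
        max(1.0 - c1.mean() - c2.mean(), 0.02),
        max(c1.mean(), 0.01),
        max(c2.mean(), 0.01),
    ])
    pi = pi / pi.sum()
    l1 = min(float(d[c1].mean() - delta0) if c1.any() else -1.0, -cfg.min_sign)
    l2 = max(float(d[c2].mean() - delta0) if c2.any() else 1.0, cfg.min_sign)
    return delta0, pi, np.array([0.0, l1, l2]), np.array([0.0, 0.0, 0.0])


def _update_kappa(series: DeltaSeries, resp_r: np.ndarray, mean_r: float,
                  kappa_cur: float) -> float:
    """1-D bounded maximization of the expected log-likelihood in kappa_r.

    No closed form exists because nu2_i0 varies by taxon.  Keeps the
    current value if the numeric optimum is not an improvement
    (generalized E-M step).
    """
    d = series.delta_i
    sq = (d - mean_r) ** 2

    def negq(kap: float) -> float:
        var = np.maximum(series.nu0_2 + kap, _TINY)
        return float(np.sum(resp_r * (np.log(var) + sq / var)) / 2.0)

    hi = max(float(np.var(d)) * 10.0 + 1.0, kappa_cur * 2.0 + 1.0)
    res = minimize_scalar(negq, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-8})
    cand = float(res.x)
    return cand if negq(cand) <= negq(kappa_cur) else kappa_cur


def em_fit(series: DeltaSeries, config: EMConfig | None = None) -> MixtureFit:
    """Fit the three-component mixture by a generalized E-M algorithm.

    The E-step computes responsibilities with proper normal densities
    (standard deviation sqrt(nu2_ir)).  The M-step updates pi in closed
    form, delta and (l1, l2) by weighted means with the sign constraints
    l1 < 0 < l2 enforced by clamping, and kappa_1, kappa_2 by bounded 1-D
    numeric maximization.  The observed-data log-likelihood is
    non-decreasing across iterations.  Ties in the final argmax
    classification break toward the null class.
    """
    cfg = config or EMConfig()
    if series.delta_i.size < 3:
        raise ValueError("at least 3 taxa are required to fit the mixture")
    if cfg.null_only:
        return _fit_null_only(series, cfg)
    delta, pi, l, kappa = _init(series, cfg)
    trace: list[float] = []
    converged = False
    resp = None
    for _ in range(cfg.max_iter):
        logdens = _log_density(series, pi, l, kappa, delta)
        ll = _loglik(logdens)
        if trace and abs(ll - trace[-1]) < cfg.tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        resp = _responsibilities(logdens)

        # M-step: mixing proportions (closed form)
        pi = resp.mean(axis=0)
        pi = np.maximum(pi, 0.0)
        pi = pi / pi.sum()

        # delta given current l: weighted mean over all components
        var = np.maximum(series.nu0_2[:, np.newaxis] + kappa[np.newaxis, :],
                         _TINY)
        w = resp / var
        num = float(np.sum(w * (series.delta_i[:, np.newaxis]
                                - l[np.newaxis, :])))
        den = float(np.sum(w))
        if den > _TINY:
            delta = num / den

        # l1, l2 given delta: per-component weighted means, sign-clamped
        for r, (lo_b, hi_b) in ((1, (-np.inf, -cfg.min_sign)),
                                (2, (cfg.min_sign, np.inf))):
            wr = w[:, r]
            sw = float(wr.sum())
            if sw > _TINY:
                l_new = float(np.sum(wr * (series.delta_i - delta)) / sw)
                l[r] = float(np.clip(l_new, lo_b, hi_b))

        # kappa: generalized (numeric) maximization per non-null component
        for r in (1, 2):
            kappa[r] = _update_kappa(series, resp[:, r], delta + l[r],
                                     kappa[r])

    if not converged:
        logger.warning("E-M did not converge in %d iterations", cfg.max_iter)
    logdens = _log_density(series, pi, l, kappa, delta)
    resp = _responsibilities(logdens)
    # argmax with ties toward the null class: stable because index 0 wins
    # equal values under argmax over the reversed comparison order.
    classes = np.argmax(resp, axis=1)
    top = resp.max(axis=1)
    classes[resp[:, 0] >= top - 1e-12] = 0
    return MixtureFit(
        delta_em=float(delta),
        pi=pi.copy(),
        l1=float(l[1]),
        l2=float(l[2]),
        kappa1=float(kappa[1]),
        kappa2=float(kappa[2]),
        responsibilities=resp,
        classes=classes,
        loglik_trace=trace,
        converged=converged,
    )


def _fit_null_only(series: DeltaSeries, cfg: EMConfig) -> MixtureFit:
    """Single-component fit: delta is the inverse-variance weighted mean."""
    var = np.maximum(series.nu0_2, _TINY)
    w = 1.0 / var
    delta = float(np.sum(w * series.delta_i) / np.sum(w))
    m = series.delta_i.size
    resp = np.zeros((m, 3))
    resp[:, 0] = 1.0
    ll = float(np.sum(norm.logpdf(series.delta_i, loc=delta,
                                  scale=np.sqrt(var))))
    return MixtureFit(delta_em=delta, pi=np.array([1.0, 0.0, 0.0]),
                      l1=-cfg.min_sign, l2=cfg.min_sign, kappa1=0.0,
                      kappa2=0.0, responsibilities=resp,
                      classes=np.zeros(m, dtype=int), loglik_trace=[ll],
                      converged=True)


def _class_weights(series: DeltaSeries, fit: MixtureFit):
    """Inverse-variance weights 1/nu2_{i,class(i)} per taxon."""
    kappa = np.array([0.0, fit.kappa1, fit.kappa2])
    var = np.maximum(series.nu0_2 + kappa[fit.classes], _TINY)
    return 1.0 / var


def wls_delta(series: DeltaSeries, fit: MixtureFit) -> VarEstimate:
    """Weighted-least-squares bias estimate on the E-M classification.

    Each taxon contributes (Delta_i - l_hat_class) weighted by the inverse
    of its class variance; null taxa contribute Delta_i itself.
    """
    if fit.classes.size == 0:
        raise ValueError("empty classification")
    l_vec = np.array([0.0, fit.l1, fit.l2])[fit.classes]
    w = _class_weights(series, fit)
    den = float(w.sum())
    if den <= 0:
        raise ValueError("zero total weight in WLS estimator")
    dw = float(np.sum(w * (series.delta_i - l_vec)) / den)
    return VarEstimate(delta_wls=dw, var_wls=1.0 / den)


def var_wls(series: DeltaSeries, fit: MixtureFit) -> VarEstimate:
    """Variance of delta_hat_WLS neglecting inter-taxon covariances.

    Var = 1 / sum_i 1/nu2_{i,class(i)}; with m0 null taxa of equal
    variance v this reduces to v/m0, the i.i.d.-mean variance.
    """
    ve = wls_delta(series, fit)
    return ve
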