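"""Least-squares estimation for the offset log-linear abundance model.

The observed log count decomposes as

    y_ijk = d_jk + mu_ij + eps_ijk,

where d_jk = log sampling fraction of sample k in group j (a per-sample
offset shared by all taxa) and mu_ij = log mean absolute abundance of taxon
i in group j.  Because every taxon in a sample shares the same sampling
fraction, averaging log counts over a large number of taxa isolates d_jk:

    d_hat_jk  = mean_i y_ijk - mean_{i,k in j} y_ijk   (within-group centered)
    mu_hat_ij = mean_{k in j} y_ijk.

mu_hat_ij is biased by the group-average offset d_bar_j.; that bias is what
the mixture stage (:mod:`ancombc.bias_correction`) estimates and removes.
Variances use the mean residual sum of squares with a 1/n^2 prefactor,
which estimates Var(mu_hat_ij) directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AbundanceTable, GroupDesign

__all__ = ["LogAbundance", "EstimationResult", "log_transform",
           "estimate_mu_d", "estimate_sigma2", "estimate"]


@dataclass
class LogAbundance:
    """Natural-log counts with a cell-level exclusion mask.

    ``y`` is (m x N); excluded cells (structural zeros) hold NaN and are
    omitted from every mean.
    """

    y: np.ndarray
    excluded: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]


@dataclass
class EstimationResult:
    """Least-squares estimates on the log scale.

    mu_hat : (m x g) group means (biased by group-average offsets).
    d_hat : per-sample offset estimates, within-group centered.
    sigma2_hat : (m x g) estimated Var(mu_hat_ij); NaN where excluded.
    group_labels / taxon_ids / sample_ids fix the index maps.
    """

    mu_hat: np.ndarray
    d_hat: np.ndarray
    sigma2_hat: np.ndarray | None
    taxon_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]

    def nu0_2(self, j1: int, j2: int) -> np.ndarray:
        """Var(mu_hat_i,j1 - mu_hat_i,j2) = sigma2_i,j1 + sigma2_i,j2."""
        return self.sigma2_hat[:, j1] + self.sigma2_hat[:, j2]


def log_transform(
    table: AbundanceTable, excluded: np.ndarray | None = None
) -> LogAbundance:
    """Elementwise natural log of an imputed count table.

    Every included cell must be strictly positive (imputation must already
    have replaced sampling zeros).
    """
    if excluded is None:
        excluded = np.zeros(table.counts.shape, dtype=bool)
    counts = table.counts
    bad = (counts <= 0) & ~excluded
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive included count at taxon {table.taxon_ids[i]!r}, "
            f"sample {table.sample_ids[j]!r}; impute sampling zeros first"
        )
    y = np.full(counts.shape, np.nan)
    inc = ~excluded
    y[inc] = np.log(counts[inc])
    return LogAbundance(y, excluded.copy(), list(table.taxon_ids),
                        list(table.sample_ids))


def estimate_mu_d(y: LogAbundance, design: GroupDesign) -> EstimationResult:
    """Least-squares estimates of group means and per-sample offsets.

    Means are taken over included cells only; a sample whose cells are all
    excluded cannot contribute an offset and raises an error.
    """
    gi = design.group_index(y.sample_ids)
    g = design.n_groups
    m, N = y.y.shape
    yv = np.where(y.excluded, np.nan, y.y)
    included = ~np.isnan(yv)
    n_inc_col = included.sum(axis=0)
    if np.any(n_inc_col == 0):
        k = int(np.flatnonzero(n_inc_col == 0)[0])
        raise ValueError(
            f"sample {y.sample_ids[k]!r} has no included cells; cannot "
            "estimate its sampling-fraction offset"
        )
    col_means = np.nansum(yv, axis=0) / n_inc_col  # y_bar_.jk, included taxa
    d_hat = np.empty(N)
    mu_hat = np.full((m, g), np.nan)
    for j in range(g):
        cols = gi == j
        d_hat[cols] = col_means[cols] - col_means[cols].mean()
        n_inc = included[:, cols].sum(axis=1)
        ok = n_inc > 0
        mu_hat[ok, j] = np.nansum(yv[:, cols], axis=1)[ok] / n_inc[ok]
    return EstimationResult(mu_hat, d_hat, None, list(y.taxon_ids),
                            list(y.sample_ids), list(design.group_labels))


def estimate_sigma2(
    y: LogAbundance, est: EstimationResult, design: GroupDesign
) -> EstimationResult:
    """Mean residual sum of squares, scaled to estimate Var(mu_hat_ij).

    sigma2_ij = (1/n_ij^2) * sum_k (y_ijk - d_hat_jk - mu_hat_ij)^2 where
    n_ij counts the included cells of taxon i in group j.  No
    degrees-of-freedom correction is applied; the n^-2 prefactor makes this
    the variance of the group mean, not of a single observation.
    """
    gi = design.group_index(y.sample_ids)
    g = design.n_groups
    m = y.y.shape[0]
    resid = np.where(y.excluded, np.nan, y.y) - est.d_hat[np.newaxis, :]
    sigma2 = np.full((m, g), np.nan)
    for j in range(g):
        cols = gi == j
        r = resid[:, cols] - est.mu_hat[:, j][:, np.newaxis]
        n_inc = np.sum(~np.isnan(r), axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            ss = np.nansum(r ** 2, axis=1)
        ok = n_inc > 0
        sigma2[ok, j] = ss[ok] / n_inc[ok] ** 2
    return EstimationResult(est.mu_hat, est.d_hat, sigma2, est.taxon_ids,
                            est.sample_ids, est.group_labels)


def estimate(y: LogAbundance, design: GroupDesign) -> EstimationResult:
    """Full estimation pass: offsets, group means, then variances."""
    est = estimate_mu_d(y, design)
    return estimate_sigma2(y, est, design)
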