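"""End-to-end orchestration: zeros -> estimation -> bias correction -> tests.

Two entry points: :func:`run_two_group` for g = 2 designs and
:func:`run_multigroup` for g >= 3 (pairwise de-biasing against a
reference plus the max-statistic global test).  Both return a result
object holding per-taxon :class:`~ancombc.data_model.TaxonResult` rows
together with the intermediate fits for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import AbundanceTable, GroupDesign, TaxonResult
from . import zero_handling as zh
from .estimation import EstimationResult, estimate, log_transform
from .bias_correction import (DeltaSeries, EMConfig, MixtureFit, VarEstimate,
                              em_fit, wls_delta)
from .inference_two_group import (TwoGroupTestConfig, TwoGroupStats,
                                  pvalues_ci, test_statistics)
from .inference_multigroup import (GlobalTestResult, MultiGroupFit,
                                   debias_multigroup, global_test,
                                   pairwise_stats)

logger = logging.getLogger(__name__)

__all__ = ["TwoGroupResult", "MultiGroupResult", "run_two_group",
           "run_multigroup"]


@dataclass
class _Prepared:
    table: AbundanceTable
    design: GroupDesign
    mask: zh.StructuralZeroMask
    decisions: zh.StructuralZeroDecisions
    est: EstimationResult
    testable: np.ndarray  # (m x g) boolean, not structurally zero


def _prepare(
    table: AbundanceTable,
    design: GroupDesign,
    pseudo: float,
    struct_zero: bool,
    z: float,
) -> _Prepared:
    """Shared front half: structural zeros, imputation, estimation."""
    summary = zh.presence_proportions(table, design)
    if struct_zero:
        mask = zh.detect_structural_zeros(summary, z=z)
    else:
        mask = zh.StructuralZeroMask(
            np.zeros(summary.p_hat.shape, dtype=bool),
            list(summary.taxon_ids), list(summary.group_labels),
        )
        # taxa with no observations anywhere still cannot be modeled
        mask.mask[summary.p_hat.sum(axis=1) == 0, :] = True
    decisions = zh.structural_zero_decisions(mask, design)
    if decisions.dropped:
        logger.info("dropping %d taxa structurally zero in every group",
                    len(decisions.dropped))
    keep = [t for t in table.taxon_ids if t not in set(decisions.dropped)]
    if not keep:
        raise ValueError("no taxa remain after removing all-zero taxa")
    table = table.subset_taxa(keep)
    keep_idx = [mask.taxon_ids.index(t) for t in keep]
    mask = zh.StructuralZeroMask(mask.mask[keep_idx], keep,
                                 list(mask.group_labels))
    imputed, excl = zh.impute_table(table, design, mask, pseudo=pseudo)
    y = log_transform(imputed, excl)
    est = estimate(y, design)
    return _Prepared(table, design, mask, decisions, est, ~mask.mask)


@dataclass
class TwoGroupResult:
    results: list[TaxonResult]
    fit: MixtureFit
    ve: VarEstimate
    est: EstimationResult
    stats: TwoGroupStats
    mask: zh.StructuralZeroMask
    decisions: zh.StructuralZeroDecisions
    series_taxa: list[str] = field(default_factory=list)

    @property
    def delta_em(self) -> float:
        return self.fit.delta_em

    @property
    def delta_wls(self) -> float:
        return self.ve.delta_wls

    def debias_offsets(self, design: GroupDesign) -> np.ndarray:
        """Per-sample offsets comparable across groups: the second group's
        offsets are shifted by -delta_hat_EM so both groups estimate the
        true log sampling fraction up to one shared constant."""
        gi = design.group_index(self.est.sample_ids)
        d_star = self.est.d_hat.copy()
        d_star[gi == 1] -= self.fit.delta_em
        return d_star


def run_two_group(
    table: AbundanceTable,
    design: GroupDesign,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    statistic: str = "auto",
    pseudo: float = 1.0,
    struct_zero: bool = True,
    struct_zero_z: float = 1.96,
    em_config: EMConfig | None = None,
) -> TwoGroupResult:
    """Differential-abundance analysis between two groups.

    The effect reported per taxon is the bias-corrected natural-log fold
    change of group 1 over group 2 (group order as declared in the
    design).  Taxa whose structural-zero pattern differs between the
    groups are declared differentially abundant without testing (p = 0
    convention, ``decided_by_structural_zero=True``) and excluded from the
    bias estimation.
    """
    if design.n_groups != 2:
        raise ValueError(
            f"run_two_group needs exactly 2 groups, found {design.n_groups}; "
            "use run_multigroup"
        )
    cfg = TwoGroupTestConfig(statistic=statistic, alpha=alpha, adjust=adjust)
    prep = _prepare(table, design, pseudo, struct_zero, struct_zero_z)
    est = prep.est
    testable = prep.testable[:, 0] & prep.testable[:, 1]
    testable &= np.all(np.isfinite(est.mu_hat), axis=1)
    testable &= np.all(np.isfinite(est.sigma2_hat), axis=1)
    if testable.sum() < 3:
        raise ValueError(
            f"only {int(testable.sum())} testable taxa; at least 3 are "
            "needed to estimate the sampling-fraction bias"
        )
    series = DeltaSeries(
        est.mu_hat[testable, 0] - est.mu_hat[testable, 1],
        est.nu0_2(0, 1)[testable],
        [t for t, ok in zip(est.taxon_ids, testable) if ok],
    )
    fit = em_fit(series, em_config)
    ve = wls_delta(series, fit)
    sizes = design.sizes()
    n1, n2 = (sizes[lab] for lab in design.group_labels)
    stats = test_statistics(series, series.nu0_2, ve, fit, cfg, n1, n2)
    p, p_adj, ci_lo, ci_hi = pvalues_ci(stats, cfg, m=series.delta_i.size)

    results: list[TaxonResult] = []
    t2i = {t: i for i, t in enumerate(series.taxon_ids)}
    for row, tid in enumerate(prep.table.taxon_ids):
        flags = prep.mask.flags_for(tid)
        if tid in t2i:
            i = t2i[tid]
            results.append(TaxonResult(
                tid, effect=float(stats.effect[i]), se=float(stats.se[i]),
                W=float(stats.W[i]), p=float(p[i]), p_adj=float(p_adj[i]),
                ci_lo=float(ci_lo[i]), ci_hi=float(ci_hi[i]),
                structural_zero_flags=flags,
            ))
        elif prep.decisions.auto_da.get(tid):
            results.append(TaxonResult(
                tid, p=0.0, p_adj=0.0, structural_zero_flags=flags,
                decided_by_structural_zero=True,
            ))
        else:
            results.append(TaxonResult(tid, structural_zero_flags=flags))
    return TwoGroupResult(results, fit, ve, est, stats, prep.mask,
                          prep.decisions, list(series.taxon_ids))


@dataclass
class MultiGroupResult:
    results: list[TaxonResult]
    fit: MultiGroupFit
    est: EstimationResult
    global_result: GlobalTestResult
    mask: zh.StructuralZeroMask
    decisions: zh.StructuralZeroDecisions


def run_multigroup(
    table: AbundanceTable,
    design: GroupDesign,
    reference: str | None = None,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    B: int = 1000,
    seed: int = 0,
    pseudo: float = 1.0,
    struct_zero: bool = True,
    struct_zero_z: float = 1.96,
    em_config: EMConfig | None = None,
) -> MultiGroupResult:
    """Global differential-abundance test across g >= 2 groups.

    Group means are de-biased against the reference group (default: the
    design's declared reference), pairwise standardized differences are
    formed, and each taxon's max-of-absolutes statistic is compared with a
    simulated null shared across taxa.  A taxon structurally zero in some
    but not all groups is auto-declared differentially abundant for the
    discordant pairs; it still enters the global test restricted to its
    testable groups when at least two remain.
    """
    if reference is None:
        reference = design.reference
    prep = _prepare(table, design, pseudo, struct_zero, struct_zero_z)
    est = prep.est
    gi = design.group_index(prep.table.sample_ids)
    fit = debias_multigroup(est, gi, reference, em_config,
                            testable=prep.testable)
    W = pairwise_stats(fit, est)
    # blank out pairs involving a structurally-zero group for each taxon
    for j in range(design.n_groups):
        bad = ~prep.testable[:, j]
        W[bad, j, :] = np.nan
        W[bad, :, j] = np.nan
    gres = global_test(W, B=B, seed=seed, group_labels=design.group_labels,
                       adjust=adjust)
    results: list[TaxonResult] = []
    for row, tid in enumerate(prep.table.taxon_ids):
        flags = prep.mask.flags_for(tid)
        auto = bool(prep.decisions.auto_da.get(tid))
        if np.isfinite(gres.W_global[row]):
            results.append(TaxonResult(
                tid, W=float(gres.W_global[row]), p=float(gres.p[row]),
                p_adj=float(gres.p_adj[row]), structural_zero_flags=flags,
                decided_by_structural_zero=False,
            ))
        elif auto:
            results.append(TaxonResult(
                tid, p=0.0, p_adj=0.0, structural_zero_flags=flags,
                decided_by_structural_zero=True,
            ))
        else:
            results.append(TaxonResult(tid, structural_zero_flags=flags))
    return MultiGroupResult(results, fit, est, gres, prep.mask,
                            prep.decisions)
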