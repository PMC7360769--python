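"""Zero classification and imputation.

Zeros in microbiome count tables are of two kinds: structural zeros (the
taxon is genuinely absent from an ecosystem) and sampling zeros (the taxon
was simply missed in the specimen).  A taxon declared structurally zero in
a group is excluded from model estimation for that group and, when the
pattern differs across groups, the differential-abundance call is decided
directly from the pattern.  Remaining zeros are treated as sampling zeros
and imputed with a pseudo-count so logarithms are finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import AbundanceTable, GroupDesign

__all__ = [
    "PresenceSummary",
    "StructuralZeroMask",
    "presence_proportions",
    "detect_structural_zeros",
    "StructuralZeroDecisions",
    "structural_zero_decisions",
    "impute_sampling_zeros",
    "impute_table",
    "exclusion_matrix",
]


@dataclass
class PresenceSummary:
    """Per-taxon per-group fraction of non-zero samples p_hat (m x g)."""

    p_hat: np.ndarray
    n: np.ndarray  # group sizes, length g
    taxon_ids: list[str]
    group_labels: list[str]


@dataclass
class StructuralZeroMask:
    """Boolean (m x g) matrix; True marks taxon i structurally zero in group j."""

    mask: np.ndarray
    taxon_ids: list[str]
    group_labels: list[str]

    def flags_for(self, taxon_id: str) -> dict[str, bool]:
        i = self.taxon_ids.index(taxon_id)
        return {g: bool(self.mask[i, j]) for j, g in enumerate(self.group_labels)}


@dataclass
class StructuralZeroDecisions:
    """Automatic DA calls and remaining testable groups per taxon.

    ``auto_da[i]`` lists group-label pairs auto-declared differentially
    abundant because exactly one of the pair is structurally zero;
    ``testable_groups[i]`` are the groups in which taxon i can still be
    modeled; ``dropped`` are taxa structurally zero in every group.
    """

    auto_da: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    testable_groups: dict[str, list[str]] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)


def presence_proportions(
    table: AbundanceTable, design: GroupDesign
) -> PresenceSummary:
    """p_hat_ij = fraction of samples of group j where taxon i is non-zero."""
    g = design.n_groups
    gi = design.group_index(table.sample_ids)
    p_hat = np.empty((table.n_taxa, g))
    n = np.empty(g, dtype=int)
    nonzero = table.counts != 0
    for j in range(g):
        cols = gi == j
        n[j] = cols.sum()
        p_hat[:, j] = nonzero[:, cols].mean(axis=1)
    return PresenceSummary(p_hat, n, list(table.taxon_ids), list(design.group_labels))


def detect_structural_zeros(
    summary: PresenceSummary, z: float = 1.96
) -> StructuralZeroMask:
    """Declare structural zeros from presence proportions.

    Taxon i is structurally zero in group j if p_hat_ij = 0 or if the
    normal-approximation lower confidence bound
    p_hat_ij - z * sqrt(p_hat_ij (1 - p_hat_ij) / n_j) falls at or below 0.
    The default multiplier z = 1.96 is the two-sided 95% bound.
    """
    p = summary.p_hat
    n = summary.n.astype(float)
    lower = p - z * np.sqrt(p * (1.0 - p) / n[np.newaxis, :])
    mask = (p == 0.0) | (lower <= 0.0)
    return StructuralZeroMask(mask, list(summary.taxon_ids), list(summary.group_labels))


def structural_zero_decisions(
    mask: StructuralZeroMask, design: GroupDesign
) -> StructuralZeroDecisions:
    """Turn structural-zero patterns into automatic DA calls.

    For every pair of groups where exactly one member is structurally zero,
    the taxon is declared differentially abundant between that pair without
    testing.  The taxon remains testable only among groups where it is not
    structurally zero; taxa structurally zero everywhere are dropped.
    """
    out = StructuralZeroDecisions()
    labels = mask.group_labels
    for i, tid in enumerate(mask.taxon_ids):
        row = mask.mask[i]
        pairs = [
            (labels[a], labels[b])
            for a in range(len(labels))
            for b in range(a + 1, len(labels))
            if row[a] != row[b]
        ]
        testable = [labels[j] for j in range(len(labels)) if not row[j]]
        if not testable:
            out.dropped.append(tid)
            continue
        out.auto_da[tid] = pairs
        out.testable_groups[tid] = testable
    return out


def impute_sampling_zeros(
    table: AbundanceTable,
    mask: StructuralZeroMask | None = None,
    pseudo: float = 1.0,
    design: GroupDesign | None = None,
) -> AbundanceTable:
    """Replace sampling zeros with a pseudo-count on the raw count scale.

    Zero cells of taxa in groups where the taxon is NOT structurally zero
    are set to ``pseudo`` (default 1).  Cells in structurally-zero groups
    are left at 0; they are excluded from estimation downstream, not
    log-transformed.  Pass ``mask=None`` (or no design) to impute every zero.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo-count must be positive, got {pseudo}")
    if mask is not None and design is not None:
        return impute_table(table, design, mask, pseudo)[0]
    counts = table.counts.copy()
    counts[counts == 0] = pseudo
    return AbundanceTable(counts, list(table.taxon_ids), list(table.sample_ids))


def exclusion_matrix(
    table: AbundanceTable, design: GroupDesign, mask: StructuralZeroMask
) -> np.ndarray:
    """Boolean (m x N) matrix: True = cell excluded (structurally zero group)."""
    if mask.taxon_ids != table.taxon_ids:
        raise ValueError("structural-zero mask does not match table taxa")
    if mask.group_labels != design.group_labels:
        raise ValueError("structural-zero mask does not match design groups")
    gi = design.group_index(table.sample_ids)
    return mask.mask[:, gi]


def impute_table(
    table: AbundanceTable,
    design: GroupDesign,
    mask: StructuralZeroMask,
    pseudo: float = 1.0,
) -> tuple[AbundanceTable, np.ndarray]:
    """Impute sampling zeros and return the cell-level exclusion matrix.

    Zeros in non-excluded cells become ``pseudo``; excluded cells (taxon
    structurally zero in the sample's group) stay 0 and are flagged.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo-count must be positive, got {pseudo}")
    excl = exclusion_matrix(table, design, mask)
    counts = table.counts.copy()
    counts[(counts == 0) & ~excl] = pseudo
    counts[excl] = 0.0
    return (
        AbundanceTable(counts, list(table.taxon_ids), list(table.sample_ids)),
        excl,
    )
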