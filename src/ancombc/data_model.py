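"""Core domain types and I/O for count tables, sample metadata, and results.

The package follows the microbiome convention that count tables are stored
taxa-in-rows, samples-in-columns, with a header row of sample identifiers
and the first column holding taxon identifiers.  Sample metadata is one row
per sample with a categorical group column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "GroupDesign",
    "TaxonResult",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_metadata",
    "align",
    "write_results",
    "read_results",
    "microbial_load",
    "empirical_sampling_fraction",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """A taxa-by-samples matrix of observed counts O_ij.

    Parameters
    ----------
    counts
        Non-negative matrix of shape (m taxa, N samples).  Integer-valued on
        input; imputation may later introduce non-integer pseudo-counts, so
        the dtype is float internally.
    taxon_ids, sample_ids
        Unique row/column identifiers.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        m, n = self.counts.shape
        if m != len(self.taxon_ids):
            raise ValidationError(
                f"counts has {m} rows but {len(self.taxon_ids)} taxon ids"
            )
        if n != len(self.sample_ids):
            raise ValidationError(
                f"counts has {n} columns but {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.taxon_ids, "taxon id")
        _check_unique(self.sample_ids, "sample id")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Column sums O_.j — total observed counts per sample."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(
            self.counts[:, idx], list(self.taxon_ids), list(sample_ids)
        )

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return AbundanceTable(
            self.counts[idx, :], list(taxon_ids), list(self.sample_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxon_ids, columns=self.sample_ids
        )


@dataclass
class GroupDesign:
    """Assignment of samples to g >= 2 experimental groups.

    ``group_labels`` fixes the group index j; the first label is the default
    reference group.  Each group must contain at least two samples so that
    within-group variances are estimable.
    """

    assignment: dict[str, str]
    group_labels: list[str] = field(default_factory=list)
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.group_labels:
            seen: list[str] = []
            for lab in self.assignment.values():
                if lab not in seen:
                    seen.append(lab)
            self.group_labels = seen
        extra = set(self.assignment.values()) - set(self.group_labels)
        if extra:
            raise ValidationError(f"samples assigned to unknown groups: {sorted(extra)}")
        if len(self.group_labels) < 2:
            raise ValidationError(
                f"need at least 2 groups, found {len(self.group_labels)}"
            )
        for lab in self.group_labels:
            n_j = sum(1 for v in self.assignment.values() if v == lab)
            if n_j < 2:
                raise ValidationError(
                    f"group {lab!r} has {n_j} sample(s); at least 2 are required "
                    "for the within-group variance to be estimable"
                )
        if self.reference is None:
            self.reference = self.group_labels[0]
        if self.reference not in self.group_labels:
            raise ValidationError(
                f"reference group {self.reference!r} not among {self.group_labels}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    def sizes(self) -> dict[str, int]:
        return {
            lab: sum(1 for v in self.assignment.values() if v == lab)
            for lab in self.group_labels
        }

    def samples_in(self, label: str) -> list[str]:
        return [s for s, v in self.assignment.items() if v == label]

    def group_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Integer group index j (position in group_labels) per sample."""
        lookup = {lab: j for j, lab in enumerate(self.group_labels)}
        return np.array([lookup[self.assignment[s]] for s in sample_ids])

    def subset(self, sample_ids: Iterable[str]) -> "GroupDesign":
        keep = {s: self.assignment[s] for s in sample_ids}
        labels = [
            lab for lab in self.group_labels if lab in set(keep.values())
        ]
        ref = self.reference if self.reference in labels else None
        return GroupDesign(keep, labels, ref)


@dataclass
class TaxonResult:
    """Per-taxon output of a differential-abundance analysis.

    ``effect`` is the bias-corrected log fold change (natural log scale),
    ``W`` the standardized statistic, ``ci_lo``/``ci_hi`` the simultaneous
    confidence interval.  Taxa decided purely from structural-zero patterns
    carry NaN statistics and ``decided_by_structural_zero=True``.
    """

    taxon_id: str
    effect: float = np.nan
    se: float = np.nan
    W: float = np.nan
    p: float = np.nan
    p_adj: float = np.nan
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    structural_zero_flags: dict[str, bool] = field(default_factory=dict)
    decided_by_structural_zero: bool = False


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what}(s): {dups}")


def _sep_for(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    return "," if fmt == "csv" else "\t"


def read_counts(path: str, format: str | None = None) -> AbundanceTable:
    """Read a taxa-by-samples count table.

    The first row is a header of sample ids; the first column holds taxon
    ids.  Cells must be non-negative integers.
    """
    sep = _sep_for(path, format)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric cell at taxon {bad[0]!r}, sample {col!r}"
            )
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative count at taxon {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValidationError(
            f"{path}: non-integer count at taxon {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return AbundanceTable(values, list(df.index), list(df.columns))


def write_counts(table: AbundanceTable, path: str, format: str | None = None) -> None:
    """Write a count table in the dialect that :func:`read_counts` reads."""
    sep = _sep_for(path, format)
    df = table.to_frame()
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        df = df.astype(np.int64)
    df.to_csv(path, sep=sep, index_label="taxon_id")


def read_metadata(
    path: str,
    group_column: str,
    sample_column: str | None = None,
    format: str | None = None,
    strict: bool = False,
) -> GroupDesign:
    """Read sample metadata and build a :class:`GroupDesign`.

    The sample-id column defaults to the first column.  Group labels are
    ordered by first appearance.  Samples with a missing group cell are
    excluded with a warning unless ``strict`` is set.
    """
    sep = _sep_for(path, format)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if sample_column is None:
        sample_column = df.columns[0]
    for col in (sample_column, group_column):
        if col not in df.columns:
            raise ValidationError(
                f"{path}: column {col!r} not found; available columns: "
                f"{list(df.columns)}"
            )
    missing = df[group_column].isna()
    if missing.any():
        dropped = list(df.loc[missing, sample_column])
        if strict:
            raise ValidationError(
                f"{path}: missing group label for samples {dropped}"
            )
        logger.warning(
            "excluding %d sample(s) with missing %r: %s",
            len(dropped), group_column, dropped,
        )
        df = df.loc[~missing]
    _check_unique(list(df[sample_column]), "sample id")
    assignment = dict(zip(df[sample_column], df[group_column]))
    return GroupDesign(assignment)


def align(
    table: AbundanceTable,
    design: GroupDesign,
    policy: str = "intersect",
) -> tuple[AbundanceTable, GroupDesign]:
    """Reconcile sample ids between a count table and a design.

    ``intersect`` keeps shared samples (columns reordered to the design's
    order, extras logged and dropped); ``strict`` errors on any mismatch.
    """
    if policy not in ("intersect", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    table_ids = set(table.sample_ids)
    design_ids = set(design.sample_ids)
    shared = [s for s in design.sample_ids if s in table_ids]
    if policy == "strict" and table_ids != design_ids:
        raise ValidationError(
            "sample ids differ between counts and metadata: "
            f"only-in-counts={sorted(table_ids - design_ids)}, "
            f"only-in-metadata={sorted(design_ids - table_ids)}"
        )
    if not shared:
        raise ValidationError("no shared sample ids between counts and metadata")
    dropped_t = sorted(table_ids - set(shared))
    dropped_d = sorted(design_ids - set(shared))
    if dropped_t:
        logger.warning("dropping %d count column(s) not in metadata: %s",
                       len(dropped_t), dropped_t)
    if dropped_d:
        logger.warning("dropping %d metadata sample(s) not in counts: %s",
                       len(dropped_d), dropped_d)
    new_design = design.subset(shared)
    sizes = new_design.sizes()
    bad = {k: v for k, v in sizes.items() if v < 2}
    if bad:
        raise ValidationError(
            f"after alignment, group(s) {bad} have fewer than 2 samples"
        )
    return table.subset_samples(shared), new_design


_RESULT_FLOAT_COLS = ["effect", "se", "W", "p", "p_adj", "ci_lo", "ci_hi"]


def write_results(
    results: list[TaxonResult],
    path: str,
    group_labels: Sequence[str] | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Write results as TSV, one row per taxon, missing values as ``NA``.

    Column order is stable: taxon_id, the float statistics, one
    ``structural_zero_<group>`` flag per group, then
    ``decided_by_structural_zero``.
    """
    if group_labels is None:
        labels: list[str] = []
        for r in results:
            for g in r.structural_zero_flags:
                if g not in labels:
                    labels.append(g)
    else:
        labels = list(group_labels)
    cols = (
        ["taxon_id"]
        + _RESULT_FLOAT_COLS
        + [f"structural_zero_{g}" for g in labels]
        + ["decided_by_structural_zero"]
    )
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for r in results:
            row = [r.taxon_id]
            for c in _RESULT_FLOAT_COLS:
                v = getattr(r, c)
                row.append("NA" if v is None or not np.isfinite(v) else repr(float(v)))
            for g in labels:
                row.append(str(bool(r.structural_zero_flags.get(g, False))))
            row.append(str(bool(r.decided_by_structural_zero)))
            fh.write("\t".join(row) + "\n")


def read_results(path: str) -> list[TaxonResult]:
    """Parse a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    sz_cols = [c for c in df.columns if c.startswith("structural_zero_")]
    out: list[TaxonResult] = []
    for _, row in df.iterrows():
        flags = {
            c[len("structural_zero_"):]: bool(row[c]) for c in sz_cols
        }
        out.append(
            TaxonResult(
                taxon_id=str(row["taxon_id"]),
                **{c: float(row[c]) if pd.notna(row[c]) else np.nan
                   for c in _RESULT_FLOAT_COLS},
                structural_zero_flags=flags,
                decided_by_structural_zero=bool(row["decided_by_structural_zero"]),
            )
        )
    return out


def microbial_load(ecosystem_abundances: Iterable[float]) -> float:
    """Total absolute abundance of all taxa in a unit volume of ecosystem."""
    return float(np.sum(np.asarray(list(ecosystem_abundances), dtype=float)))


def empirical_sampling_fraction(library_size: float, load: float) -> float:
    """Sampling fraction c = library size / microbial load.

    The fraction of a sample's ecosystem that was captured in the sequenced
    specimen; e.g. a specimen of 6 reads from an ecosystem of load 18 has
    sampling fraction 1/3.
    """
    if load <= 0:
        raise ValueError("microbial load must be positive")
    return float(library_size) / float(load)
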