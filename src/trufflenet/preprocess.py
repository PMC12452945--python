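"""Abundance-table preprocessing: closure, prevalence filter, zeros, CLR.

The canonical order, matching how compositional microbiome tables are
prepared for correlation analysis, is::

    relative_abundance -> prevalence_filter -> replace_zeros -> clr_transform

Prevalence is always computed on true zeros (before replacement). Filtering
before the centered log-ratio transform is the default; the alternative
(transforming first, then filtering) is exposed through
:func:`preprocess_pipeline`'s ``filter_first`` flag rather than chosen
silently, because dropping taxa changes every sample's geometric mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.composition import multi_replace

from .tables import AbundanceTable, TableValidationError

__all__ = [
    "ClrMatrix",
    "FilterReport",
    "relative_abundance",
    "prevalence_filter",
    "replace_zeros",
    "clr_transform",
    "preprocess_pipeline",
]

log = logging.getLogger(__name__)

ROW_CENTER_TOL = 1e-8

#: Default prevalence cutoff: taxa detected in fewer than 10% of samples are
#: removed; exactly-10% taxa are kept (the rule drops "prevalence < 10%").
DEFAULT_MIN_PREVALENCE = 0.10


@dataclass
class ClrMatrix:
    """Centered log-ratio coordinates: real-valued, rows centered at zero."""

    data: pd.DataFrame
    #: False only for column subsets of a larger CLR matrix, whose rows no
    #: longer sum to zero by construction.
    centered: bool = True

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TableValidationError("CLR matrix contains non-finite entries")
        if self.centered:
            rowsums = values.sum(axis=1)
            if np.abs(rowsums).max() > ROW_CENTER_TOL * max(1.0, values.shape[1]):
                raise TableValidationError(
                    f"CLR rows must sum to 0; worst deviation {np.abs(rowsums).max()}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class FilterReport:
    kept: list[str]
    dropped: list[str]
    prevalence: dict[str, float]
    min_prevalence: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, self.prevalence[t], "kept" if t in set(self.kept) else "dropped")
            for t in list(self.kept) + list(self.dropped)
        ]
        df = pd.DataFrame(rows, columns=["taxon", "prevalence", "status"])
        return df.sort_values("taxon").reset_index(drop=True)


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample's counts to percentages summing to 100 (OTU %)."""
    if table.unit != "counts":
        raise TableValidationError("relative_abundance expects a counts table")
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise TableValidationError(
            f"cannot compute relative abundance: sample(s) with zero total "
            f"counts: {list(zero.index)}"
        )
    pct = table.data.div(totals, axis=0) * 100.0
    return AbundanceTable(pct, "percent")


def taxon_prevalence(table: AbundanceTable) -> pd.Series:
    """Fraction of samples in which each taxon is detected (abundance > 0)."""
    return (table.data > 0).mean(axis=0)


def prevalence_filter(
    table: AbundanceTable, min_prevalence: float = DEFAULT_MIN_PREVALENCE
) -> tuple[AbundanceTable, FilterReport]:
    """Drop rare taxa: keep a taxon iff its prevalence is >= min_prevalence.

    Column order is preserved among kept taxa. Idempotent: re-filtering the
    output at the same threshold keeps everything.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError(f"min_prevalence must be in [0, 1], got {min_prevalence}")
    prev = taxon_prevalence(table)
    kept = [t for t in table.taxa if prev[t] >= min_prevalence]
    dropped = [t for t in table.taxa if prev[t] < min_prevalence]
    if not kept:
        raise TableValidationError(
            f"prevalence filter at {min_prevalence} would drop every taxon"
        )
    out = table.subset_taxa(kept)
    report = FilterReport(kept, dropped, prev.to_dict(), min_prevalence)
    log.info(
        "prevalence_filter: kept %d / %d taxa at min_prevalence=%.3g",
        len(kept), len(table.taxa), min_prevalence,
    )
    return out, report


def replace_zeros(
    table: AbundanceTable, strategy: str = "multiplicative"
) -> AbundanceTable:
    """Make the table strictly positive so the log-ratio transform is defined.

    multiplicative
        Zeros become delta = 0.5 x (smallest nonzero relative abundance in
        the whole table); the observed components of each sample are rescaled
        so rows still close. Ratios among observed components are preserved.
    pseudocount
        Add one to every count (counts tables only).
    """
    values = table.values
    if strategy == "pseudocount":
        if table.unit != "counts":
            raise TableValidationError("pseudocount strategy requires a counts table")
        return AbundanceTable(table.data + 1, "counts")
    if strategy != "multiplicative":
        raise ValueError(f"unknown zero-replacement strategy {strategy!r}")

    if (values > 0).all():
        return table
    if (values.sum(axis=1) <= 0).any():
        raise TableValidationError("sample with all-zero abundances")
    if (values.sum(axis=0) <= 0).any():
        bad = [t for t, s in zip(table.taxa, values.sum(axis=0)) if s <= 0]
        raise TableValidationError(
            f"all-zero taxon column(s) {bad}; run prevalence_filter first"
        )
    # Work on closed proportions regardless of input unit.
    props = values / values.sum(axis=1, keepdims=True)
    delta = 0.5 * props[props > 0].min()
    replaced = multi_replace(props, delta=delta)
    out = pd.DataFrame(replaced * 100.0, index=table.data.index,
                       columns=table.data.columns)
    return AbundanceTable(out, "percent")


def clr_transform(table: AbundanceTable) -> ClrMatrix:
    """Centered log-ratio transform: ln x_ij minus the row mean of ln x_i.

    Rows of the result sum to zero; the transform is invariant to per-sample
    scaling, so counts and percent inputs give identical coordinates.
    """
    values = table.values
    if (values <= 0).any():
        raise TableValidationError(
            "CLR requires strictly positive entries; apply replace_zeros first"
        )
    logx = np.log(values)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(clr, index=table.data.index,
                                  columns=table.data.columns))


def preprocess_pipeline(
    table: AbundanceTable,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    zero_strategy: str = "multiplicative",
    filter_first: bool = True,
) -> tuple[AbundanceTable, ClrMatrix, FilterReport]:
    """Run closure -> prevalence filter -> zero replacement -> CLR.

    Returns the filtered percent table, the CLR matrix and the filter report.
    With ``filter_first=False`` the CLR geometric means are computed on the
    unfiltered composition and rare columns are dropped from the transformed
    matrix afterwards.
    """
    pct = relative_abundance(table) if table.unit == "counts" else table
    if filter_first:
        filtered, report = prevalence_filter(pct, min_prevalence)
        positive = replace_zeros(
            table if zero_strategy == "pseudocount" else filtered, zero_strategy
        )
        if zero_strategy == "pseudocount":
            positive = positive.subset_taxa(report.kept)
        clr = clr_transform(positive)
    else:
        filtered, report = prevalence_filter(pct, min_prevalence)
        positive = replace_zeros(
            table if zero_strategy == "pseudocount" else pct, zero_strategy
        )
        clr_full = clr_transform(positive)
        # Keep the coordinates computed on the full composition; the subset's
        # rows no longer sum to zero, which is the substantive difference
        # between the two orders.
        clr = ClrMatrix(clr_full.data[report.kept].copy(), centered=False)
    log.info(
        "preprocess: %d samples x %d taxa -> %d taxa after filter",
        len(table.samples), len(table.taxa), len(filtered.taxa),
    )
    return filtered, clr, report
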