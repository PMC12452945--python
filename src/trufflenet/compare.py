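"""Compartment-composition statistics.

Per-taxon OTU% summaries (mean +- sample SD) by truffle species and
compartment, nonparametric surface-vs-gleba comparisons with the
Mann-Whitney U test, and presence/absence bookkeeping (shared and unique
taxa across the four species x compartment groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, SampleMeta

__all__ = [
    "TaxonSummary",
    "ComparisonResult",
    "PresenceMatrix",
    "taxon_summary",
    "mann_whitney",
    "compare_compartments",
    "presence_matrix",
    "shared_unique",
    "format_mean_sd",
]

log = logging.getLogger(__name__)

#: Largest combined sample size at which the exact U null distribution is
#: enumerated (ties force the normal approximation regardless).
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class TaxonSummary:
    taxon: str
    species: str
    compartment: str
    mean_pct: float
    sd_pct: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    taxon: str
    u_statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    method: str


@dataclass
class PresenceMatrix:
    """Boolean presence per (taxon, group); group = (species, compartment)."""

    entries: dict[tuple[str, tuple[str, str]], bool]

    @property
    def taxa(self) -> list[str]:
        return sorted({t for t, _ in self.entries})

    @property
    def groups(self) -> list[tuple[str, str]]:
        return sorted({g for _, g in self.entries})

    def present(self, taxon: str, group: tuple[str, str]) -> bool:
        return self.entries.get((taxon, group), False)

    def to_frame(self) -> pd.DataFrame:
        """Render with '+' for presence and '-' for absence."""
        groups = self.groups
        rows = {
            t: ["+" if self.present(t, g) else "-" for g in groups]
            for t in self.taxa
        }
        cols = [f"{sp}:{comp}" for sp, comp in groups]
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def format_mean_sd(mean: float, sd: float, digits: int = 2) -> str:
    """Render as the reporting convention "mean +- SD", e.g. "6.84 ± 0.67"."""
    return f"{mean:.{digits}f} ± {sd:.{digits}f}"


def _meta_by_sample(meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


def _require_metadata(table: AbundanceTable, meta: Sequence[SampleMeta]) -> None:
    by_id = _meta_by_sample(meta)
    missing = [s for s in table.samples if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")


def taxon_summary(
    table: AbundanceTable, meta: Sequence[SampleMeta]
) -> list[TaxonSummary]:
    """Mean and sample SD (n-1 denominator; SD = 0 for n = 1) of OTU% per
    (taxon, species, compartment) group."""
    if table.unit != "percent":
        raise ValueError("taxon_summary expects a percent table")
    _require_metadata(table, meta)
    by_id = _meta_by_sample(meta)
    out: list[TaxonSummary] = []
    groups: dict[tuple[str, str], list[str]] = {}
    for s in table.samples:
        groups.setdefault(by_id[s].group, []).append(s)
    for (species, compartment), samples in sorted(groups.items()):
        block = table.data.loc[samples]
        n = len(samples)
        means = block.mean(axis=0)
        sds = block.std(axis=0, ddof=1) if n > 1 else pd.Series(0.0, index=block.columns)
        for taxon in table.taxa:
            out.append(TaxonSummary(
                taxon=taxon, species=species, compartment=compartment,
                mean_pct=float(means[taxon]), sd_pct=float(sds[taxon]), n=n,
            ))
    return out


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test (U of group_a, midranks for ties).

    The exact null distribution is enumerated when the combined sample size
    is at most 12 and there are no ties — the regime of 3-4 replicates per
    compartment, where the normal approximation is poor. Otherwise the
    normal approximation with tie and continuity corrections is used.
    All-constant data carries no evidence: U = n1*n2/2, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult("", n1 * n2 / 2.0, 1.0, (n1, n2), "degenerate")
    has_ties = len(np.unique(pooled)) < pooled.size
    if n1 + n2 <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return ComparisonResult("", float(res.statistic), float(res.pvalue),
                            (n1, n2), method)


def compare_compartments(
    table: AbundanceTable,
    meta: Sequence[SampleMeta],
    species: str,
    taxa: Sequence[str] | None = None,
) -> list[ComparisonResult]:
    """Surface-vs-gleba Mann-Whitney test per taxon within one species.

    The caller chooses the taxon scope (default: every taxon in the table);
    no multiplicity correction is applied across taxa.
    """
    _require_metadata(table, meta)
    by_id = _meta_by_sample(meta)
    surface = [s for s in table.samples
               if by_id[s].species == species and by_id[s].compartment == "surface"]
    gleba = [s for s in table.samples
             if by_id[s].species == species and by_id[s].compartment == "gleba"]
    if not surface or not gleba:
        raise ValueError(
            f"species {species!r} needs samples in both compartments "
            f"(surface: {len(surface)}, gleba: {len(gleba)})"
        )
    results = []
    for taxon in (taxa if taxa is not None else table.taxa):
        res = mann_whitney(table.data.loc[surface, taxon].to_numpy(),
                           table.data.loc[gleba, taxon].to_numpy())
        results.append(ComparisonResult(taxon, res.u_statistic, res.p_value,
                                        res.group_sizes, res.method))
    return results


def presence_matrix(
    table: AbundanceTable, meta: Sequence[SampleMeta]
) -> PresenceMatrix:
    """Presence = abundance > 0 in at least one replicate of the group."""
    _require_metadata(table, meta)
    by_id = _meta_by_sample(meta)
    entries: dict[tuple[str, tuple[str, str]], bool] = {}
    groups: dict[tuple[str, str], list[str]] = {}
    for s in table.samples:
        groups.setdefault(by_id[s].group, []).append(s)
    for group, samples in groups.items():
        block = table.data.loc[samples]
        present = (block > 0).any(axis=0)
        for taxon in table.taxa:
            entries[(taxon, group)] = bool(present[taxon])
    return PresenceMatrix(entries)


def shared_unique(matrix: PresenceMatrix) -> dict:
    """Taxa present in every group, and taxa unique to a single group."""
    groups = matrix.groups
    shared_all = set()
    unique: dict[tuple[str, str], set[str]] = {g: set() for g in groups}
    for taxon in matrix.taxa:
        present_in = [g for g in groups if matrix.present(taxon, g)]
        if len(present_in) == len(groups) and groups:
            shared_all.add(taxon)
        elif len(present_in) == 1:
            unique[present_in[0]].add(taxon)
    return {"shared_all": shared_all, "unique": unique}
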