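"""Signed co-occurrence network construction from CLR coordinates.

All unordered taxon pairs are tested with the Pearson product-moment
correlation on their CLR columns; two-sided p-values come from the exact
t transform with n - 2 degrees of freedom; the batch of p-values is
adjusted with the Benjamini-Hochberg step-up procedure. An edge is drawn
iff |r| >= r_min and the adjusted q <= alpha (defaults |r| >= 0.1,
q <= 0.05); its sign is the sign of r, positive for co-occurrence, negative
for mutual exclusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ClrMatrix
from .tables import TaxonMeta

__all__ = [
    "CorrelationRecord",
    "CoNetwork",
    "pairwise_correlations",
    "drop_undefined",
    "fdr_adjust",
    "build_network",
    "DEFAULT_R_MIN",
    "DEFAULT_ALPHA",
]

log = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.1
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationRecord:
    """One tested taxon pair; taxon_a < taxon_b lexicographically."""

    taxon_a: str
    taxon_b: str
    r: float
    p: float
    q: float | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.r) and math.isfinite(self.p)

    @property
    def sign(self) -> int:
        return 1 if self.r >= 0 else -1


@dataclass
class CoNetwork:
    """Signed, simple, undirected taxon graph.

    ``graph`` is a :class:`networkx.Graph` whose edges carry ``r``, ``p``,
    ``q`` and ``sign`` attributes; isolated nodes are retained so node counts
    match the number of taxa that entered correlation testing.
    """

    graph: nx.Graph
    r_min: float = DEFAULT_R_MIN
    alpha: float = DEFAULT_ALPHA

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_records(self) -> list[tuple[str, str, dict]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, d))
        return sorted(out, key=lambda t: (t[0], t[1]))

    @property
    def n_positive(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] < 0)


def pairwise_correlations(clr: ClrMatrix) -> list[CorrelationRecord]:
    """Pearson r and two-sided p for every unordered taxon pair.

    Pairs are enumerated in lexicographic taxon order. Pairs in which either
    column has zero variance (possible after aggressive filtering at very
    small n) are emitted with ``r`` and ``p`` set to NaN and a logged
    warning; :func:`drop_undefined` removes them before FDR adjustment.
    """
    n, k = clr.values.shape
    if n < 3:
        raise ValueError(
            f"need at least 3 samples for correlation p-values, got {n}"
        )
    if k < 2:
        raise ValueError(f"need at least 2 taxa, got {k}")
    taxa = sorted(clr.taxa)
    X = clr.data[taxa].to_numpy(dtype=float)
    sd = X.std(axis=0)
    degenerate = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    dof = n - 2
    records: list[CorrelationRecord] = []
    for i in range(k):
        for j in range(i + 1, k):
            if degenerate[i] or degenerate[j]:
                log.warning(
                    "zero-variance column in pair (%s, %s); excluded from testing",
                    taxa[i], taxa[j],
                )
                records.append(CorrelationRecord(taxa[i], taxa[j],
                                                 float("nan"), float("nan")))
                continue
            r = float(R[i, j])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt(dof / (1.0 - r * r))
                p = 2.0 * float(stats.t.sf(abs(t), dof))
            records.append(CorrelationRecord(taxa[i], taxa[j], r, min(p, 1.0)))
    return records


def drop_undefined(records: Iterable[CorrelationRecord]) -> list[CorrelationRecord]:
    return [rec for rec in records if rec.defined]


def fdr_adjust(records: Sequence[CorrelationRecord]) -> list[CorrelationRecord]:
    """Benjamini-Hochberg step-up over the full batch of tested pairs."""
    records = list(records)
    if not records:
        return []
    pvals = np.array([rec.p for rec in records], dtype=float)
    if np.isnan(pvals).any():
        raise ValueError("undefined p-values; call drop_undefined first")
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [replace(rec, q=float(q)) for rec, q in zip(records, qvals)]


def build_network(
    records: Sequence[CorrelationRecord],
    r_min: float = DEFAULT_R_MIN,
    alpha: float = DEFAULT_ALPHA,
    use_raw_p: bool = False,
    taxa: Sequence[str] | None = None,
    taxon_meta: Sequence[TaxonMeta] | None = None,
    mean_abundance: dict[str, float] | None = None,
) -> CoNetwork:
    """Threshold correlation records into a signed co-occurrence graph.

    Edge rule: |r| >= r_min AND q <= alpha (raw p instead of q when
    ``use_raw_p``; the significance threshold is interpreted on the
    FDR-adjusted value by default, otherwise the correction would be
    inert). Nodes are all taxa that entered testing, so taxa with no
    significant partner remain as isolated nodes.
    """
    G = nx.Graph()
    node_set = set(taxa) if taxa is not None else set()
    for rec in records:
        node_set.add(rec.taxon_a)
        node_set.add(rec.taxon_b)
    G.add_nodes_from(sorted(node_set))

    meta_by_id = {t.taxon_id: t for t in taxon_meta} if taxon_meta else {}
    for node in G.nodes:
        m = meta_by_id.get(node)
        G.nodes[node]["phylum"] = m.phylum if m else ""
        G.nodes[node]["kingdom"] = m.kingdom if m else ""
        if mean_abundance is not None:
            G.nodes[node]["mean_abundance"] = float(mean_abundance.get(node, 0.0))

    n_skipped = 0
    for rec in records:
        if not rec.defined:
            n_skipped += 1
            continue
        crit = rec.p if use_raw_p else rec.q
        if crit is None:
            raise ValueError("records must be FDR-adjusted before build_network")
        if abs(rec.r) >= r_min and crit <= alpha:
            G.add_edge(
                rec.taxon_a, rec.taxon_b,
                r=rec.r, p=rec.p, q=float("nan") if rec.q is None else rec.q,
                sign=rec.sign, weight=abs(rec.r),
            )
    if n_skipped:
        log.warning("build_network: skipped %d undefined pairs", n_skipped)
    log.info(
        "build_network: %d nodes, %d edges (|r| >= %g, %s <= %g)",
        G.number_of_nodes(), G.number_of_edges(), r_min,
        "p" if use_raw_p else "q", alpha,
    )
    return CoNetwork(G, r_min=r_min, alpha=alpha)
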