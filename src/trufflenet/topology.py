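"""Topological characterization of co-occurrence networks.

Implements the quantities used to describe the truffle networks: density,
average clustering, community detection with Newman-Girvan modularity Q,
degree centrality, within-module connectivity Zi, among-module connectivity
(participation coefficient) Pi, and the Zi-Pi role taxonomy
(peripheral / module hub / connector / network hub).

All metrics operate on the unweighted, unsigned skeleton of the
significant-edge graph; edge sign is reporting metadata only. Zi uses the
population standard deviation of within-module degrees, which makes the
analytic extremes of minimal 3-node modules come out at exactly +-1.414 and
-0.707.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import networkx as nx
import numpy as np

from .network import CoNetwork

__all__ = [
    "ModulePartition",
    "NodeTopology",
    "NetworkSummary",
    "density",
    "avg_clustering",
    "detect_communities",
    "modularity",
    "degree_centrality",
    "within_module_z",
    "participation_coefficient",
    "classify_roles",
    "compute_node_topology",
    "summarize",
    "ZI_HUB_CUT",
    "PI_CONNECTOR_CUT",
]

log = logging.getLogger(__name__)

#: Canonical Zi-Pi role cutoffs (Guimera-Amaral taxonomy, simplified to the
#: four quadrants used for microbial networks).
ZI_HUB_CUT = 2.5
PI_CONNECTOR_CUT = 0.62

#: Components up to this many nodes are partitioned by exhaustive search;
#: larger ones by greedy agglomeration plus local node moves.
_EXACT_SEARCH_MAX_NODES = 10


@dataclass
class ModulePartition:
    """Assignment of every node to exactly one module, labels 0..k-1."""

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if labels and labels != list(range(len(labels))):
            raise ValueError(f"module labels must be contiguous from 0, got {labels}")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, label: int) -> list[str]:
        return sorted(n for n, lbl in self.assignment.items() if lbl == label)

    def modules(self) -> list[list[str]]:
        return [self.members(lbl) for lbl in range(self.n_modules)]

    @classmethod
    def from_groups(cls, groups: Sequence[Sequence[str]]) -> "ModulePartition":
        # canonical labelling: modules ordered by their smallest node
        ordered = sorted((sorted(g) for g in groups), key=lambda g: g[0])
        return cls({n: i for i, g in enumerate(ordered) for n in g})

    @classmethod
    def single_module(cls, nodes: Sequence[str]) -> "ModulePartition":
        return cls({n: 0 for n in nodes})


@dataclass
class NodeTopology:
    node: str
    degree: int
    degree_centrality: float
    zi: float
    pi: float
    module: int
    role: str | None = None


@dataclass
class NetworkSummary:
    """Report-level network statistics (rounded to the reporting precision:
    percentages 1 d.p., modularity 4 d.p., Zi/Pi 3 d.p.)."""

    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    density_pct: float
    avg_clustering_pct: float
    modularity: float
    n_modules: int
    zi_range: tuple[float, float]
    pi_range: tuple[float, float]

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["zi_range"] = list(self.zi_range)
        d["pi_range"] = list(self.pi_range)
        return d


def _as_graph(network: CoNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, CoNetwork) else network


def density(network: CoNetwork | nx.Graph) -> float:
    """Edge density as a percentage: 100 * 2E / (N(N-1))."""
    G = _as_graph(network)
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError(f"density requires at least 2 nodes, got {n}")
    return 100.0 * nx.density(G)


def avg_clustering(network: CoNetwork | nx.Graph) -> float:
    """Mean local clustering coefficient as a percentage.

    Nodes with degree < 2 contribute zero (no neighbor pairs to close).
    """
    G = _as_graph(network)
    if G.number_of_nodes() < 1:
        raise ValueError("avg_clustering requires at least 1 node")
    return 100.0 * nx.average_clustering(G)


def degree_centrality(network: CoNetwork | nx.Graph) -> dict[str, float]:
    """Degree / (N - 1) per node, sign-blind."""
    G = _as_graph(network)
    if G.number_of_nodes() < 2:
        raise ValueError("degree_centrality requires at least 2 nodes")
    return {n: float(c) for n, c in nx.degree_centrality(G).items()}


# ---------------------------------------------------------------------------
# community detection


def _rgs_partitions(n: int) -> Iterator[list[int]]:
    """All set partitions of range(n) as restricted-growth label strings."""
    a = [0] * n
    while True:
        yield a
        maxes = [0] * n  # maxes[i] = max(a[:i])
        for i in range(1, n):
            maxes[i] = max(maxes[i - 1], a[i - 1])
        j = next((i for i in range(n - 1, 0, -1) if a[i] <= maxes[i]), None)
        if j is None:
            return
        a[j] += 1
        for i in range(j + 1, n):
            a[i] = 0


def _q_contribution(
    labels: Sequence[int], edges: Sequence[tuple[int, int]],
    degrees: Sequence[int], m: int,
) -> float:
    """Sum over this node set's modules of e_c/m - (d_c/2m)^2."""
    k = max(labels) + 1 if labels else 0
    e_c = [0.0] * k
    d_c = [0.0] * k
    for u, v in edges:
        if labels[u] == labels[v]:
            e_c[labels[u]] += 1.0
    for i, lbl in enumerate(labels):
        d_c[lbl] += degrees[i]
    return sum(e / m - (d / (2.0 * m)) ** 2 for e, d in zip(e_c, d_c))


def _exact_component_partition(
    nodes: list[str], G: nx.Graph, m: int
) -> list[list[str]]:
    idx = {n: i for i, n in enumerate(nodes)}
    edges = [(idx[u], idx[v]) for u, v in G.subgraph(nodes).edges()]
    degrees = [G.degree(n) for n in nodes]
    best_q = -np.inf
    best: list[int] | None = None
    for labels in _rgs_partitions(len(nodes)):
        q = _q_contribution(labels, edges, degrees, m)
        if q > best_q + 1e-12:
            best_q = q
            best = list(labels)
    assert best is not None
    groups: dict[int, list[str]] = {}
    for node, lbl in zip(nodes, best):
        groups.setdefault(lbl, []).append(node)
    return list(groups.values())


def _local_move_refine(
    G: nx.Graph, groups: list[set[str]], m: int
) -> list[set[str]]:
    """Deterministic hill climbing: move single nodes between modules while
    modularity strictly improves."""
    label = {n: i for i, grp in enumerate(groups) for n in grp}
    nodes = sorted(G.nodes)
    improved = True
    while improved:
        improved = False
        for v in nodes:
            s = label[v]
            k_v = G.degree(v)
            if k_v == 0:
                continue
            # degree totals per module
            d = {}
            for n2, lbl in label.items():
                d[lbl] = d.get(lbl, 0) + G.degree(n2)
            k_to = {}
            for nb in G.neighbors(v):
                k_to[label[nb]] = k_to.get(label[nb], 0) + 1
            candidates = sorted(set(k_to) - {s})
            best_gain, best_t = 0.0, None
            for t in candidates:
                gain = (k_to.get(t, 0) - k_to.get(s, 0)) / m \
                    - k_v * (d[t] - (d[s] - k_v)) / (2.0 * m * m)
                if gain > best_gain + 1e-12:
                    best_gain, best_t = gain, t
            if best_t is not None:
                label[v] = best_t
                improved = True
    out: dict[int, set[str]] = {}
    for n2, lbl in label.items():
        out.setdefault(lbl, set()).add(n2)
    return [grp for grp in out.values() if grp]


def detect_communities(network: CoNetwork | nx.Graph) -> ModulePartition:
    """Deterministic modularity-maximizing partition of the unsigned graph.

    Connected components are partitioned independently (merging modules
    across components can only lower Q). Components with up to
    ``_EXACT_SEARCH_MAX_NODES`` nodes are solved by exhaustive search over
    set partitions, scored with the global edge count m; larger components
    fall back to greedy agglomeration (Clauset-Newman-Moore) refined by
    deterministic single-node moves. Isolated nodes become singleton
    modules. No randomness is involved, so repeated runs agree exactly.
    """
    G = _as_graph(network)
    if G.number_of_nodes() == 0:
        return ModulePartition({})
    m = G.number_of_edges()
    if m == 0:
        return ModulePartition.from_groups([[n] for n in G.nodes])
    groups: list[list[str]] = []
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        if len(nodes) == 1:
            groups.append(nodes)
        elif len(nodes) <= _EXACT_SEARCH_MAX_NODES:
            groups.extend(_exact_component_partition(nodes, G, m))
        else:
            sub = G.subgraph(nodes)
            cnm = nx.community.greedy_modularity_communities(sub)
            refined = _local_move_refine(sub, [set(c) for c in cnm], m)
            groups.extend(sorted(g) for g in refined)
    return ModulePartition.from_groups(groups)


def modularity(
    network: CoNetwork | nx.Graph, partition: ModulePartition
) -> float:
    """Newman-Girvan Q of a partition on the unweighted, unsigned graph.

    Q = sum_c [ e_c/m - (d_c/2m)^2 ]; defined as 0 (with a warning) for
    edgeless graphs.
    """
    G = _as_graph(network)
    missing = set(G.nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
    if G.number_of_edges() == 0:
        warnings.warn("modularity of an edgeless graph is defined as 0",
                      stacklevel=2)
        return 0.0
    communities = [set(mod) & set(G.nodes) for mod in partition.modules()]
    communities = [c for c in communities if c]
    return float(nx.community.modularity(G, communities, weight=None))


# ---------------------------------------------------------------------------
# Zi / Pi


def within_module_z(
    network: CoNetwork | nx.Graph, partition: ModulePartition
) -> dict[str, float]:
    """Within-module degree z-score Zi.

    For node i in module s, Zi = (k_i - mean_s) / sd_s where k_i is i's
    number of neighbors inside s and sd_s is the population standard
    deviation of within-module degrees over s. Zi = 0 for modules with
    fewer than 2 members or no degree spread.
    """
    G = _as_graph(network)
    missing = set(G.nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
    zi: dict[str, float] = {}
    for members in partition.modules():
        members = [n for n in members if n in G]
        if not members:
            continue
        member_set = set(members)
        k = np.array(
            [sum(1 for nb in G.neighbors(n) if nb in member_set) for n in members],
            dtype=float,
        )
        sd = k.std()  # population SD
        if len(members) < 2 or sd == 0.0:
            for n in members:
                zi[n] = 0.0
        else:
            z = (k - k.mean()) / sd
            for n, val in zip(members, z):
                zi[n] = float(val)
    return zi


def participation_coefficient(
    network: CoNetwork | nx.Graph, partition: ModulePartition
) -> dict[str, float]:
    """Among-module connectivity Pi = 1 - sum_s (k_is / k_i)^2.

    Pi = 0 for isolated nodes and for nodes whose edges all stay inside
    their own module; the supremum for a node touching c modules is 1 - 1/c.
    """
    G = _as_graph(network)
    missing = set(G.nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
    pi: dict[str, float] = {}
    for n in G.nodes:
        k_i = G.degree(n)
        if k_i == 0:
            pi[n] = 0.0
            continue
        per_module: dict[int, int] = {}
        for nb in G.neighbors(n):
            lbl = partition.assignment[nb]
            per_module[lbl] = per_module.get(lbl, 0) + 1
        pi[n] = float(1.0 - sum((k / k_i) ** 2 for k in per_module.values()))
    return pi


def classify_roles(
    topologies: Sequence[NodeTopology],
    zi_cut: float = ZI_HUB_CUT,
    pi_cut: float = PI_CONNECTOR_CUT,
) -> list[NodeTopology]:
    """Assign Zi-Pi quadrant roles: peripheral / connector / module hub /
    network hub, at the canonical cutoffs Zi = 2.5 and Pi = 0.62."""
    out = []
    for t in topologies:
        if t.zi >= zi_cut:
            role = "network_hub" if t.pi > pi_cut else "module_hub"
        else:
            role = "connector" if t.pi > pi_cut else "peripheral"
        out.append(replace(t, role=role))
    return out


def compute_node_topology(
    network: CoNetwork | nx.Graph,
    partition: ModulePartition | None = None,
    zi_cut: float = ZI_HUB_CUT,
    pi_cut: float = PI_CONNECTOR_CUT,
) -> tuple[list[NodeTopology], ModulePartition]:
    """Degree, centrality, Zi, Pi and role for every node."""
    G = _as_graph(network)
    if partition is None:
        partition = detect_communities(G)
    zi = within_module_z(G, partition)
    pi = participation_coefficient(G, partition)
    cent = degree_centrality(G) if G.number_of_nodes() >= 2 else \
        {n: 0.0 for n in G.nodes}
    tops = [
        NodeTopology(
            node=n,
            degree=int(G.degree(n)),
            degree_centrality=cent[n],
            zi=zi[n],
            pi=pi[n],
            module=partition.assignment[n],
        )
        for n in sorted(G.nodes)
    ]
    return classify_roles(tops, zi_cut, pi_cut), partition


def summarize(
    network: CoNetwork, partition: ModulePartition | None = None
) -> NetworkSummary:
    """Assemble the per-network report: counts, density, clustering, Q and
    the attained Zi/Pi ranges under the partition actually used."""
    G = network.graph
    if partition is None:
        partition = detect_communities(G)
    tops, partition = compute_node_topology(network, partition)
    zis = [t.zi for t in tops] or [0.0]
    pis = [t.pi for t in tops] or [0.0]
    n = G.number_of_nodes()
    dens = density(G) if n >= 2 else 0.0
    clus = avg_clustering(G) if n >= 1 else 0.0
    q = modularity(G, partition)
    return NetworkSummary(
        n_nodes=n,
        n_edges=G.number_of_edges(),
        n_positive=network.n_positive,
        n_negative=network.n_negative,
        density_pct=round(dens, 1),
        avg_clustering_pct=round(clus, 1),
        modularity=round(q, 4),
        n_modules=partition.n_modules,
        zi_range=(round(min(zis), 3), round(max(zis), 3)),
        pi_range=(round(min(pis), 3), round(max(pis), 3)),
    )
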