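"""Export of networks, node tables and Zi-Pi plot data.

GraphML is the interchange format for downstream renderers: node attributes
carry phylum, mean abundance, degree centrality, Zi, Pi and role; edge
attributes carry r, q and sign so positive and negative associations can be
colored distinctly (red for positive, blue for negative). Layout is left to
the renderer — force-directed coordinates are cosmetic and nondeterministic
across libraries, so none are written.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .network import CoNetwork
from .topology import NetworkSummary, NodeTopology, PI_CONNECTOR_CUT, ZI_HUB_CUT

__all__ = [
    "export_graph",
    "read_edge_tsv",
    "edge_table",
    "node_table",
    "zi_pi_plot_data",
    "write_summary_json",
    "plot_zi_pi",
]


def edge_table(network: CoNetwork) -> pd.DataFrame:
    rows = [
        (a, b, d["r"], d.get("p", float("nan")), d.get("q", float("nan")),
         d["sign"])
        for a, b, d in network.edge_records()
    ]
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p", "q", "sign"])


def node_table(topologies: Sequence[NodeTopology],
               network: CoNetwork | None = None) -> pd.DataFrame:
    phylum = {}
    if network is not None:
        phylum = {n: network.graph.nodes[n].get("phylum", "")
                  for n in network.graph.nodes}
    rows = [
        (t.node, phylum.get(t.node, ""), t.degree,
         round(t.degree_centrality, 6), round(t.zi, 3), round(t.pi, 3),
         t.module, t.role or "")
        for t in topologies
    ]
    return pd.DataFrame(rows, columns=[
        "node", "phylum", "degree", "degree_centrality", "zi", "pi",
        "module", "role",
    ])


def export_graph(
    network: CoNetwork,
    path: str | Path,
    topologies: Sequence[NodeTopology] | None = None,
    format: str = "graphml",
) -> Path:
    """Write the signed network as GraphML or as an edge-list TSV."""
    path = Path(path)
    if format == "edge_tsv":
        edge_table(network).to_csv(path, sep="\t", index=False,
                                   float_format="%.10g")
        return path
    if format != "graphml":
        raise ValueError(f"unknown export format {format!r}")
    G = network.graph.copy()
    if topologies:
        by_node = {t.node: t for t in topologies}
        for n in G.nodes:
            t = by_node.get(n)
            if t is None:
                continue
            G.nodes[n]["degree_centrality"] = t.degree_centrality
            G.nodes[n]["zi"] = t.zi
            G.nodes[n]["pi"] = t.pi
            G.nodes[n]["role"] = t.role or ""
            G.nodes[n]["module"] = t.module
    for u, v, d in G.edges(data=True):
        if "q" in d and (d["q"] is None or (isinstance(d["q"], float)
                                            and math.isnan(d["q"]))):
            d["q"] = -1.0  # GraphML has no NaN; -1 marks "not adjusted"
    nx.write_graphml(G, path)
    return path


def read_edge_tsv(path: str | Path) -> CoNetwork:
    """Rebuild a CoNetwork from an exported edge-list TSV (round-trip of
    :func:`export_graph` with ``format='edge_tsv'``; isolated nodes are not
    representable in an edge list and are lost)."""
    df = pd.read_csv(path, sep="\t")
    G = nx.Graph()
    for row in df.itertuples():
        G.add_edge(row.taxon_a, row.taxon_b, r=float(row.r), p=float(row.p),
                   q=float(row.q), sign=int(row.sign), weight=abs(float(row.r)))
    return CoNetwork(G)


def zi_pi_plot_data(
    topologies: Sequence[NodeTopology],
    thresholds: tuple[float, float] = (ZI_HUB_CUT, PI_CONNECTOR_CUT),
) -> pd.DataFrame:
    """Plot-ready Zi-Pi coordinates with the role-threshold lines attached
    as DataFrame attrs (``zi_cut``, ``pi_cut``)."""
    df = pd.DataFrame(
        [(t.node, t.zi, t.pi, t.role or "") for t in topologies],
        columns=["node", "zi", "pi", "role"],
    )
    df.attrs["zi_cut"], df.attrs["pi_cut"] = thresholds
    return df


def write_summary_json(summary: NetworkSummary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def plot_zi_pi(
    plot_data: pd.DataFrame, path: str | Path, seed: int | None = None
) -> Path:
    """Optional static Zi-Pi scatter (matplotlib imported lazily)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    zi_cut = plot_data.attrs.get("zi_cut", ZI_HUB_CUT)
    pi_cut = plot_data.attrs.get("pi_cut", PI_CONNECTOR_CUT)
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"peripheral": "tab:gray", "connector": "tab:orange",
              "module_hub": "tab:blue", "network_hub": "tab:red", "": "k"}
    for role, grp in plot_data.groupby("role"):
        ax.scatter(grp["pi"], grp["zi"], label=role or "unclassified",
                   c=colors.get(role, "k"), s=30)
    ax.axhline(zi_cut, ls="--", c="k", lw=0.8)
    ax.axvline(pi_cut, ls="--", c="k", lw=0.8)
    ax.set_xlabel("Pi (among-module connectivity)")
    ax.set_ylabel("Zi (within-module connectivity)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
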