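"""End-to-end orchestration: preprocess -> correlations -> network -> topology
-> composition statistics, with every stage's parameters and survivor counts
logged and all artifacts written at fixed precision so identical inputs give
bit-identical outputs.

Correlation networks are built per truffle species with the two compartments
pooled (the per-species sample pool is the caller's explicit choice; at 3-4
replicates per compartment, pooling is what makes Pearson p-values usable at
all). Composition statistics are computed across all groups.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import compare as compare_mod
from . import export as export_mod
from . import preprocess as prep
from . import network as net
from . import topology as topo
from .tables import (
    AbundanceTable,
    SampleMeta,
    TaxonMeta,
    read_abundance_table,
    read_sample_metadata,
    read_taxon_metadata,
    write_abundance_table,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_from_files"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; the defaults are the method's canonical thresholds
    (rare-taxon prevalence < 10%; edges at |r| >= 0.1 and q <= 0.05)."""

    min_prevalence: float = prep.DEFAULT_MIN_PREVALENCE
    zero_strategy: str = "multiplicative"
    filter_first: bool = True
    r_min: float = net.DEFAULT_R_MIN
    alpha: float = net.DEFAULT_ALPHA
    use_raw_p: bool = False
    zi_cut: float = topo.ZI_HUB_CUT
    pi_cut: float = topo.PI_CONNECTOR_CUT
    pool: str = "per_species"  # or "all": pool every sample into one network
    seed: int | None = None    # recorded for synthetic provenance
    output_dir: str | Path | None = None

    def to_dict(self) -> dict:
        # output_dir is the bundle's own location and is omitted so that
        # identical analyses produce bit-identical effective configs.
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        return d


@dataclass
class SpeciesNetworkResult:
    species: str
    filtered: AbundanceTable
    clr: prep.ClrMatrix
    filter_report: prep.FilterReport
    records: list[net.CorrelationRecord]
    network: net.CoNetwork
    partition: topo.ModulePartition
    topologies: list[topo.NodeTopology]
    summary: topo.NetworkSummary


@dataclass
class PipelineResult:
    config: RunConfig
    networks: dict[str, SpeciesNetworkResult]
    summaries: list[compare_mod.TaxonSummary]
    comparisons: list[compare_mod.ComparisonResult]
    presence: compare_mod.PresenceMatrix
    shared_unique: dict
    output_files: dict[str, Path] = field(default_factory=dict)


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name for diagnosis."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _sample_pools(
    table: AbundanceTable, meta: Sequence[SampleMeta], pool: str
) -> dict[str, list[str]]:
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in table.samples if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    if pool == "all":
        return {"all": list(table.samples)}
    if pool != "per_species":
        raise ValueError(f"unknown pool {pool!r}")
    pools: dict[str, list[str]] = {}
    for s in table.samples:
        pools.setdefault(by_id[s].species, []).append(s)
    return pools


def run_pipeline(
    table: AbundanceTable,
    meta: Sequence[SampleMeta],
    config: RunConfig | None = None,
    taxon_meta: Sequence[TaxonMeta] | None = None,
) -> PipelineResult:
    """Run the full analysis and (if configured) write the artifact bundle."""
    config = config or RunConfig()
    networks: dict[str, SpeciesNetworkResult] = {}
    for pool_name, samples in sorted(_sample_pools(table, meta, config.pool).items()):
        sub = table.subset_samples(samples)
        log.info("pool %s: %d samples", pool_name, len(samples))
        filtered, clr, report = _stage("preprocess")(prep.preprocess_pipeline)(
            sub, config.min_prevalence, config.zero_strategy, config.filter_first
        )
        records = _stage("correlations")(net.pairwise_correlations)(clr)
        defined = net.drop_undefined(records)
        log.info("pool %s: %d pairs tested (%d undefined)",
                 pool_name, len(defined), len(records) - len(defined))
        adjusted = _stage("fdr")(net.fdr_adjust)(defined)
        mean_ab = filtered.data.mean(axis=0).to_dict()
        network = _stage("network")(net.build_network)(
            adjusted, r_min=config.r_min, alpha=config.alpha,
            use_raw_p=config.use_raw_p, taxa=clr.taxa,
            taxon_meta=taxon_meta, mean_abundance=mean_ab,
        )
        tops, partition = _stage("topology")(topo.compute_node_topology)(
            network, None, config.zi_cut, config.pi_cut
        )
        summary = topo.summarize(network, partition)
        log.info("pool %s: %d nodes, %d edges, Q=%.4f, %d modules",
                 pool_name, summary.n_nodes, summary.n_edges,
                 summary.modularity, summary.n_modules)
        networks[pool_name] = SpeciesNetworkResult(
            pool_name, filtered, clr, report, adjusted, network,
            partition, tops, summary,
        )

    pct = prep.relative_abundance(table) if table.unit == "counts" else table
    summaries = _stage("compare")(compare_mod.taxon_summary)(pct, meta)
    comparisons: list[compare_mod.ComparisonResult] = []
    by_species: dict[str, set[str]] = {}
    for m in meta:
        by_species.setdefault(m.species, set()).add(m.compartment)
    for species, comps in sorted(by_species.items()):
        if {"surface", "gleba"} <= comps:
            comparisons.extend(
                compare_mod.compare_compartments(pct, meta, species)
            )
    presence = compare_mod.presence_matrix(table, meta)
    shared = compare_mod.shared_unique(presence)

    result = PipelineResult(config, networks, summaries, comparisons,
                            presence, shared)
    if config.output_dir is not None:
        _write_bundle(result, Path(config.output_dir))
    return result


def run_from_files(
    table_path: str | Path,
    sample_meta_path: str | Path,
    taxon_meta_path: str | Path | None = None,
    config: RunConfig | None = None,
    delimiter: str = "\t",
) -> PipelineResult:
    """File-based entry point; validates all inputs before any computation."""
    meta = read_sample_metadata(sample_meta_path, delimiter)
    taxon_meta = (read_taxon_metadata(taxon_meta_path, delimiter)
                  if taxon_meta_path else None)
    table = read_abundance_table(table_path, delimiter)
    return run_pipeline(table, meta, config, taxon_meta)


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = result.output_files
    with open(outdir / "config.json", "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["config"] = outdir / "config.json"

    for name, res in result.networks.items():
        prefix = outdir / name
        prefix.mkdir(exist_ok=True)
        files[f"{name}/filtered"] = write_abundance_table(
            res.filtered, prefix / "filtered_table.tsv")
        res.clr.data.to_csv(prefix / "clr_matrix.tsv", sep="\t",
                            index_label="sample_id", float_format="%.10g")
        files[f"{name}/clr"] = prefix / "clr_matrix.tsv"
        res.filter_report.to_frame().to_csv(
            prefix / "filter_report.tsv", sep="\t", index=False,
            float_format="%.10g")
        files[f"{name}/filter_report"] = prefix / "filter_report.tsv"
        corr = pd.DataFrame(
            [(r.taxon_a, r.taxon_b, r.r, r.p, r.q) for r in res.records],
            columns=["taxon_a", "taxon_b", "r", "p", "q"],
        )
        corr.to_csv(prefix / "correlations.tsv", sep="\t", index=False,
                    float_format="%.10g")
        files[f"{name}/correlations"] = prefix / "correlations.tsv"
        files[f"{name}/edges"] = export_mod.export_graph(
            res.network, prefix / "edges.tsv", res.topologies, "edge_tsv")
        files[f"{name}/graphml"] = export_mod.export_graph(
            res.network, prefix / "network.graphml", res.topologies, "graphml")
        files[f"{name}/nodes"] = prefix / "node_table.tsv"
        export_mod.node_table(res.topologies, res.network).to_csv(
            prefix / "node_table.tsv", sep="\t", index=False,
            float_format="%.10g")
        files[f"{name}/summary"] = export_mod.write_summary_json(
            res.summary, prefix / "summary.json")
        plot_df = export_mod.zi_pi_plot_data(
            res.topologies, (result.config.zi_cut, result.config.pi_cut))
        plot_df.to_csv(prefix / "zi_pi.tsv", sep="\t", index=False,
                       float_format="%.10g")
        files[f"{name}/zi_pi"] = prefix / "zi_pi.tsv"

    pd.DataFrame(
        [(s.taxon, s.species, s.compartment, s.n,
          round(s.mean_pct, 6), round(s.sd_pct, 6))
         for s in result.summaries],
        columns=["taxon", "species", "compartment", "n", "mean_pct", "sd_pct"],
    ).to_csv(outdir / "taxon_summary.tsv", sep="\t", index=False,
             float_format="%.10g")
    files["taxon_summary"] = outdir / "taxon_summary.tsv"

    pd.DataFrame(
        [(c.taxon, c.u_statistic, c.p_value, c.group_sizes[0],
          c.group_sizes[1], c.method) for c in result.comparisons],
        columns=["taxon", "U", "p", "n1", "n2", "method"],
    ).to_csv(outdir / "mann_whitney.tsv", sep="\t", index=False,
             float_format="%.10g")
    files["mann_whitney"] = outdir / "mann_whitney.tsv"

    result.presence.to_frame().to_csv(outdir / "presence_matrix.tsv",
                                      sep="\t", index_label="taxon")
    files["presence_matrix"] = outdir / "presence_matrix.tsv"

    shared = {
        "shared_all": sorted(result.shared_unique["shared_all"]),
        "unique": {f"{sp}:{comp}": sorted(taxa)
                   for (sp, comp), taxa in result.shared_unique["unique"].items()},
    }
    with open(outdir / "shared_unique.json", "w") as fh:
        json.dump(shared, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["shared_unique"] = outdir / "shared_unique.json"
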