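"""Synthetic compositional count tables with known correlation structure.

The generator emulates the structure of a small amplicon survey: a latent
multivariate normal on the log scale carries planted correlation modules,
exponentiation and closure produce per-sample proportions, and a
multinomial draw at a log-normally varying sequencing depth produces
integer counts that sum exactly to each sample's depth. A configurable
fraction of taxa is depressed on the log scale so that they fall under the
10% prevalence rule in expectation, exercising the rare-taxon filter.

Defaults mirror the scale of the truffle study: two species, two
compartments (surface / gleba), four replicates per group, 25 taxa, and a
minimum sequencing output of about 10,000 reads per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CoNetwork
from .tables import (
    COMPARTMENTS,
    SPECIES,
    AbundanceTable,
    SampleMeta,
    write_abundance_table,
    write_sample_metadata,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "RecoveryReport",
    "simulate_counts",
    "evaluate_recovery",
    "write_simulation",
]

log = logging.getLogger(__name__)

#: Log-mean depression applied to rare taxa. exp(-12) ~ 6e-6 keeps their
#: expected counts below one read per sample at depths up to ~1e5.
RARE_LOG_OFFSET = 12.0

PSD_TOL = -1e-8


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the latent covariance is validated at construction.

    ``module_sizes`` blocks occupy the leading taxon indices and get
    ``within_module_rho`` on every off-diagonal; ``cross_module_edges`` are
    extra (i, j, rho) entries between arbitrary taxon indices. Taxa after
    the modules host the optional gleba compartment effect, and the trailing
    ``rare_taxon_fraction`` of taxa are depressed below the detection floor.
    """

    seed: int
    n_samples_per_group: int = 4
    n_taxa: int = 25
    module_sizes: tuple[int, ...] = (5, 5)
    within_module_rho: float = 0.8
    cross_module_edges: tuple[tuple[int, int, float], ...] = ()
    base_log_mean_spread: float = 1.0
    sequencing_depth: int = 10_000
    depth_dispersion: float = 0.3
    rare_taxon_fraction: float = 0.2
    compartment_effect: float = 0.0
    n_compartment_taxa: int = 2

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1 or self.n_taxa < 2:
            raise ValueError("need at least 1 sample per group and 2 taxa")
        if sum(self.module_sizes) > self.n_taxa:
            raise ValueError("sum(module_sizes) exceeds n_taxa")
        if not abs(self.within_module_rho) < 1:
            raise ValueError("|within_module_rho| must be < 1")
        if not 0.0 <= self.rare_taxon_fraction <= 1.0:
            raise ValueError("rare_taxon_fraction must be in [0, 1]")
        if self.sequencing_depth < 1 or self.depth_dispersion < 0:
            raise ValueError("invalid sequencing depth parameters")
        self.latent_covariance()  # raises if not PSD

    def taxon_names(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [f"taxon_{i + 1:0{width}d}" for i in range(self.n_taxa)]

    def module_blocks(self) -> list[list[int]]:
        blocks, start = [], 0
        for size in self.module_sizes:
            blocks.append(list(range(start, start + size)))
            start += size
        return blocks

    def rare_indices(self) -> list[int]:
        n_rare = int(round(self.rare_taxon_fraction * self.n_taxa))
        in_module = sum(self.module_sizes)
        free = list(range(in_module, self.n_taxa))
        return free[len(free) - min(n_rare, len(free)):]

    def compartment_indices(self) -> list[int]:
        in_module = sum(self.module_sizes)
        rare = set(self.rare_indices())
        free = [i for i in range(in_module, self.n_taxa) if i not in rare]
        return free[: self.n_compartment_taxa] if self.compartment_effect else []

    def latent_covariance(self) -> np.ndarray:
        cov = np.eye(self.n_taxa)
        for block in self.module_blocks():
            for i in block:
                for j in block:
                    if i != j:
                        cov[i, j] = self.within_module_rho
        for i, j, rho in self.cross_module_edges:
            if i == j:
                raise ValueError("cross-module edge cannot be a self-pair")
            if not abs(rho) < 1:
                raise ValueError("|rho| must be < 1 for cross-module edges")
            cov[i, j] = cov[j, i] = rho
        if np.linalg.eigvalsh(cov).min() < PSD_TOL:
            raise ValueError(
                "requested latent covariance is not positive semi-definite"
            )
        return cov


@dataclass(frozen=True)
class GroundTruth:
    """Planted edges (sign-annotated, taxon_a < taxon_b) and the latent
    covariance they came from."""

    true_edges: frozenset[tuple[str, str, int]]
    latent_covariance: np.ndarray
    taxa: tuple[str, ...]
    differential_taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for a, b, sign in self.true_edges:
            if a >= b:
                raise ValueError(f"edge ({a}, {b}) not in sorted order")
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +-1, got {sign}")


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float
    precision: float
    zero_inferred: bool
    n_true: int
    n_inferred: int
    n_matched: int


def _true_edges(config: SimConfig) -> frozenset[tuple[str, str, int]]:
    names = config.taxon_names()
    edges = set()
    sign = 1 if config.within_module_rho >= 0 else -1
    for block in config.module_blocks():
        for ii, i in enumerate(block):
            for j in block[ii + 1:]:
                a, b = sorted((names[i], names[j]))
                edges.add((a, b, sign))
    for i, j, rho in config.cross_module_edges:
        a, b = sorted((names[i], names[j]))
        edges.add((a, b, 1 if rho >= 0 else -1))
    return frozenset(edges)


def simulate_counts(
    config: SimConfig,
) -> tuple[AbundanceTable, list[SampleMeta], GroundTruth]:
    """Draw a seeded sample x taxon count table with planted structure.

    Per sample: latent z ~ MVN(mu, Sigma) -> proportions softmax(z) ->
    counts ~ Multinomial(depth, proportions), with depth drawn log-normally
    around ``sequencing_depth`` (constant when dispersion is 0). The same
    seed reproduces the table, metadata and ground truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    names = config.taxon_names()
    cov = config.latent_covariance()

    mu = rng.normal(0.0, config.base_log_mean_spread, size=config.n_taxa)
    rare = config.rare_indices()
    mu[rare] -= RARE_LOG_OFFSET
    diff_idx = config.compartment_indices()

    meta: list[SampleMeta] = []
    for species in SPECIES:
        for compartment in COMPARTMENTS:
            for rep in range(1, config.n_samples_per_group + 1):
                meta.append(SampleMeta(
                    sample_id=f"{species}_{compartment}_{rep}",
                    species=species, compartment=compartment, replicate=rep,
                ))

    n_samples = len(meta)
    # jitter guards the Cholesky factorization at |rho| close to 1
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(config.n_taxa))
    noise = rng.standard_normal((n_samples, config.n_taxa))
    latent = mu + noise @ L.T
    for i, m in enumerate(meta):
        if m.compartment == "gleba" and diff_idx:
            latent[i, diff_idx] += config.compartment_effect

    if config.depth_dispersion == 0:
        depths = np.full(n_samples, config.sequencing_depth, dtype=np.int64)
    else:
        draw = rng.normal(0.0, config.depth_dispersion, size=n_samples)
        depths = np.maximum(
            1, np.rint(np.exp(np.log(config.sequencing_depth) + draw))
        ).astype(np.int64)

    shifted = latent - latent.max(axis=1, keepdims=True)
    props = np.exp(shifted)
    props /= props.sum(axis=1, keepdims=True)
    counts = np.vstack([
        rng.multinomial(int(depths[i]), props[i]) for i in range(n_samples)
    ])

    table = AbundanceTable(
        pd.DataFrame(counts, index=[m.sample_id for m in meta], columns=names),
        "counts",
    )
    truth = GroundTruth(
        true_edges=_true_edges(config),
        latent_covariance=cov,
        taxa=tuple(names),
        differential_taxa=tuple(names[i] for i in diff_idx),
    )
    log.info(
        "simulate_counts: %d samples x %d taxa, %d planted edges, %d rare taxa",
        n_samples, config.n_taxa, len(truth.true_edges), len(rare),
    )
    return table, meta, truth


def evaluate_recovery(truth: GroundTruth, network: CoNetwork) -> RecoveryReport:
    """Sign-aware sensitivity and precision of an inferred network.

    The network's nodes must be a subset of the truth's taxon universe
    (rare taxa legitimately vanish at the prevalence filter); unknown nodes
    raise. With zero inferred edges, precision is reported as 1.0 together
    with an explicit ``zero_inferred`` flag so threshold sweeps never divide
    by zero.
    """
    unknown = set(network.nodes) - set(truth.taxa)
    if unknown:
        raise ValueError(f"network contains taxa absent from the truth: "
                         f"{sorted(unknown)}")
    inferred = {
        (a, b, int(d["sign"])) for a, b, d in network.edge_records()
    }
    matched = truth.true_edges & inferred
    n_true = len(truth.true_edges)
    n_inf = len(inferred)
    sensitivity = len(matched) / n_true if n_true else 1.0
    precision = len(matched) / n_inf if n_inf else 1.0
    return RecoveryReport(
        sensitivity=sensitivity,
        precision=precision,
        zero_inferred=(n_inf == 0),
        n_true=n_true,
        n_inferred=n_inf,
        n_matched=len(matched),
    )


def write_simulation(
    config: SimConfig, outdir: str | Path
) -> dict[str, Path]:
    """Emit the table, sample metadata and ground-truth edge list as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, meta, truth = simulate_counts(config)
    paths = {
        "table": write_abundance_table(table, outdir / "counts.tsv"),
        "sample_meta": write_sample_metadata(meta, outdir / "sample_meta.tsv"),
    }
    edges = pd.DataFrame(
        sorted(truth.true_edges), columns=["taxon_a", "taxon_b", "sign"]
    )
    edges.to_csv(outdir / "true_edges.tsv", sep="\t", index=False)
    paths["true_edges"] = outdir / "true_edges.tsv"
    return paths
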