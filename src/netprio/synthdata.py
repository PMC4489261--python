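"""Synthetic benchmark instances with planted drug targets.

Emulates the statistical structure the diffusion method assumes: a
heavy-tailed (preferential-attachment) association network whose edge
confidences follow a Beta distribution, and treatment signatures in which
the transcriptional response concentrates on the *neighbors* of the target
while the target gene itself stays at background level.  That construction
is exactly the regime where neighborhood diffusion must beat ranking by raw
differential expression, so recovery of the planted target measures the
method end to end.

Per-gene evidence is simulated on the z-scale: background genes draw
z ~ Normal(0, 1); a fraction of the target's neighbors have |z| inflated by
``effect_mu``; two-sided P-values come from the normal tail and log2 ratios
are z / 2.  A suite adds, per experiment, a "true" gene set (the perturbed
neighborhood plus the target) among size-matched random decoys, so the
enrichment module is exercised with known ground truth.

Everything is a pure function of the config (seeded generators throughout);
the writers emit the exact file formats the other modules read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrich import GeneSet, GeneSetCollection, write_gmt
from .evaluate import KnownTargets, write_known_targets
from .io import write_signature
from .network import AssociationNetwork, write_edge_list

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    n_genes / attachment: preferential-attachment network size and edges
    per new node.  confidence_beta (a, b) with confidence_range: edge
    confidences are Beta(a, b) draws rescaled into the range — right-skewed
    like STRING scores.  effect_mu: mean |z| inflation of perturbed
    neighbors (2.5 gives strong but not saturated signal).
    neighbor_fraction: fraction of the target's neighbors perturbed.
    target_self_signal: 'low' leaves the target at background (the regime
    where diffusion is needed); 'high' also perturbs it.  n_decoy_sets:
    decoys per experiment in the gene-set collection.
    """

    n_genes: int = 500
    attachment: int = 3
    confidence_beta: tuple[float, float] = (4.0, 2.0)
    confidence_range: tuple[float, float] = (0.15, 0.999)
    effect_mu: float = 2.5
    neighbor_fraction: float = 0.8
    target_self_signal: str = "low"
    n_experiments: int = 20
    n_decoy_sets: int = 30
    topology: str = "preferential-attachment"
    edge_prob: float = 0.02  # used by the Erdos-Renyi topology only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.attachment < 1 or self.n_experiments < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 < self.neighbor_fraction <= 1.0):
            raise ValueError("neighbor_fraction must lie in (0, 1]")
        if self.target_self_signal not in ("low", "high"):
            raise ValueError("target_self_signal must be 'low' or 'high'")
        if self.topology not in ("preferential-attachment", "erdos-renyi"):
            raise ValueError("unknown topology")


def _symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def make_network(cfg: SimConfig) -> AssociationNetwork:
    """Scale-free (or optionally Erdos-Renyi) network on synthetic symbols
    G0001..., edge confidences drawn from the configured Beta law."""
    rng = np.random.default_rng([cfg.seed, 0])
    if cfg.topology == "preferential-attachment":
        if cfg.n_genes < cfg.attachment + 1:
            raise ValueError("n_genes must exceed the attachment parameter")
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment,
                                     seed=int(rng.integers(2**31)))
    else:
        g = nx.gnp_random_graph(cfg.n_genes, cfg.edge_prob,
                                seed=int(rng.integers(2**31)))
    names = _symbols(cfg.n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    a, b = cfg.confidence_beta
    lo, hi = cfg.confidence_range
    for _, _, data in sorted(g.edges(data=True)):
        data["confidence"] = float(lo + (hi - lo) * rng.beta(a, b))
    net = AssociationNetwork(g)
    if cfg.topology == "erdos-renyi":
        net.add_nodes(names)  # keep isolated nodes
    return net


def make_signature(net: AssociationNetwork, target: str, cfg: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Signature with signal planted on ``target``'s neighborhood.

    Returns (signature DataFrame, truth record) where the truth record
    holds the target and the perturbed gene set.
    """
    if target not in net:
        raise ValueError(f"target {target!r} not in the network")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    nodes = net.nodes
    z = rng.standard_normal(len(nodes))

    neighbors = [g for g, _ in net.neighborhood(target)]
    degenerate = False
    if not neighbors and cfg.neighbor_fraction > 0:
        warnings.warn(f"target {target} is isolated; degenerate instance")
        degenerate = True
        perturbed: list[str] = []
    else:
        n_pert = max(1, int(round(cfg.neighbor_fraction * len(neighbors))))
        perturbed = sorted(rng.choice(neighbors, size=n_pert, replace=False))
    idx = {g: i for i, g in enumerate(nodes)}
    for g in perturbed:
        i = idx[g]
        z[i] = np.sign(z[i]) * (abs(z[i]) + cfg.effect_mu) if z[i] != 0 else cfg.effect_mu
    if cfg.target_self_signal == "high" and not degenerate:
        i = idx[target]
        z[i] = np.sign(z[i]) * (abs(z[i]) + cfg.effect_mu) if z[i] != 0 else cfg.effect_mu

    p = 2.0 * stats.norm.sf(np.abs(z))
    sig = pd.DataFrame({"gene": nodes, "log2_ratio": 0.5 * z, "p_value": p})
    truth = {"target": target, "perturbed": set(perturbed),
             "degenerate": degenerate}
    return sig, truth


@dataclass
class SyntheticSuite:
    """A benchmark: one shared network, one signature per experiment with
    its planted truth, the known-targets table, and per-experiment gene-set
    collections (one true set among decoys)."""

    network: AssociationNetwork
    signatures: dict[str, pd.DataFrame]
    truths: dict[str, dict]
    targets: KnownTargets
    gene_sets: dict[str, GeneSetCollection]
    config: SimConfig


def make_suite(cfg: SimConfig) -> SyntheticSuite:
    """Generate ``cfg.n_experiments`` experiments on one shared network
    with distinct random targets."""
    net = make_network(cfg)
    rng = np.random.default_rng([cfg.seed, 2])
    nodes = net.nodes
    targets_list = [str(t) for t in
                    rng.choice(nodes, size=cfg.n_experiments, replace=False)]
    width = max(2, len(str(cfg.n_experiments)))
    signatures, truths, targets, gene_sets = {}, {}, {}, {}
    for j, target in enumerate(targets_list):
        exp = f"E{j + 1:0{width}d}"
        sig_rng = np.random.default_rng([cfg.seed, 3, j])
        sig, truth = make_signature(net, target, cfg, rng=sig_rng)
        signatures[exp] = sig
        truths[exp] = truth
        targets[exp] = {target}

        true_members = frozenset(truth["perturbed"] | {target})
        set_rng = np.random.default_rng([cfg.seed, 4, j])
        sets = [GeneSet(set_id=f"TRUE_{exp}", name=f"perturbed neighborhood of {target}",
                        genes=true_members)]
        for d in range(cfg.n_decoy_sets):
            size = max(2, int(set_rng.normal(len(true_members), 1.0)))
            size = min(size, len(nodes))
            members = frozenset(str(g) for g in
                                set_rng.choice(nodes, size=size, replace=False))
            sets.append(GeneSet(set_id=f"DECOY_{exp}_{d + 1:02d}",
                                name="random decoy", genes=members))
        gene_sets[exp] = GeneSetCollection(sets=sets, namespace="pathway")
    return SyntheticSuite(network=net, signatures=signatures, truths=truths,
                          targets=targets, gene_sets=gene_sets, config=cfg)


def write_suite(suite: SyntheticSuite, outdir: str | Path) -> None:
    """Write the suite in the formats the other modules read: edge-list
    TSV, per-experiment signature TSVs and GMTs, the known-targets TSV and
    a truth JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edge_list(suite.network, outdir / "network.tsv")
    write_known_targets(suite.targets, outdir / "targets.tsv")
    for exp, sig in suite.signatures.items():
        write_signature(sig, outdir / f"signature_{exp}.csv")
        write_gmt(suite.gene_sets[exp], outdir / f"sets_{exp}.gmt")
    truth_doc = {exp: {"target": t["target"],
                       "perturbed": sorted(t["perturbed"]),
                       "degenerate": t["degenerate"]}
                 for exp, t in suite.truths.items()}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=int(seed))
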