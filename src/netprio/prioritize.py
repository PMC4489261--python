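"""Network-diffusion drug target prioritization.

The premise: when a compound engages a protein, the transcriptional response
concentrates in that protein's functional neighborhood rather than on the
target gene itself (targets are often not differentially expressed).  Each
network gene therefore receives a score that blends its own
differential-expression signal with a confidence-weighted average of its
neighbors' signals:

    score_i = alpha * x_i + (1 - alpha) * sum_j (c_ij / sum_k c_ik) * x_j

with x the per-gene signal (by default -log10 P, capped), c_ij the edge
confidences, and alpha the self-retention weight.  Isolated nodes keep their
own signal.  The operator can be iterated; alpha = 1 degenerates to the raw
differential-expression ranking.

Significance is assessed by a permutation null: the signal vector is
randomly reassigned to the network nodes B times and each gene's observed
score is compared with its permuted scores, using the add-one estimator
p_i = (1 + #{score_perm >= score_obs}) / (B + 1).  Benjamini-Hochberg FDR
is applied across genes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .de import bh_adjust
from .network import AssociationNetwork

logger = logging.getLogger(__name__)

SIGNALS = ("neglog10p", "abs_log2fc", "abs_t")
RANKED_COLUMNS = ["rank", "gene", "score", "p_value", "adj_p"]


def build_signal(sig: pd.DataFrame, net: AssociationNetwork,
                 signal: str = "neglog10p", signal_cap: float = 16.0) -> np.ndarray:
    """Map a signature onto the network's (sorted) node order.

    Genes present in the network but absent from the signature carry zero
    signal; signature genes missing from the network are ignored (count
    logged).  ``signal`` chooses the per-gene statistic: capped -log10 P,
    |log2 ratio| or |moderated t|.
    """
    if signal not in SIGNALS:
        raise ValueError(f"unknown signal {signal!r}; expected one of {SIGNALS}")
    if signal_cap <= 0:
        raise ValueError("signal_cap must be positive")
    if len(sig) == 0 or net.n_nodes == 0:
        raise ValueError("empty signature or network")
    if signal == "neglog10p":
        with np.errstate(divide="ignore"):
            vals = -np.log10(sig["p_value"].to_numpy(dtype=float))
    elif signal == "abs_log2fc":
        vals = np.abs(sig["log2_ratio"].to_numpy(dtype=float))
    else:
        if "t_stat" not in sig.columns:
            raise ValueError("signal 'abs_t' requires a t_stat column in the signature")
        vals = np.abs(sig["t_stat"].to_numpy(dtype=float))
    vals = np.minimum(vals, signal_cap)
    lookup = dict(zip(sig["gene"], vals))
    nodes = net.nodes
    x = np.array([lookup.get(g, 0.0) for g in nodes])
    n_overlap = sum(g in lookup for g in nodes)
    if n_overlap == 0:
        raise ValueError("no overlap between signature genes and network nodes")
    n_outside = len(lookup) - n_overlap
    if n_outside:
        logger.info("%d signature gene(s) absent from the network ignored", n_outside)
    return x


def diffuse(x: np.ndarray, net: AssociationNetwork, alpha: float = 0.5,
            steps: int = 1) -> np.ndarray:
    """Apply the self-retaining neighborhood-averaging operator ``steps``
    times to the node-signal vector ``x`` (ordered as ``net.nodes``)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if steps < 1:
        raise ValueError("steps must be a positive integer")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("signal must be non-negative")
    nodes, p = net.row_stochastic()
    if x.shape != (len(nodes),):
        raise ValueError("signal vector does not match the network's node count")
    s = x
    for _ in range(steps):
        s = alpha * s + (1.0 - alpha) * (p @ s)
    return s


def permutation_pvalues(x: np.ndarray, net: AssociationNetwork,
                        alpha: float = 0.5, steps: int = 1,
                        n_permutations: int = 1000,
                        random_state: int | None = None,
                        permutations: np.ndarray | None = None,
                        chunk: int = 512) -> np.ndarray:
    """Permutation P-values for the diffusion scores.

    The signal vector is reassigned uniformly at random over the nodes
    (the exchangeable null of a signature with no relation to network
    position) and p_i = (1 + #{b : score_b,i >= score_i}) / (B + 1).  The
    b-th permutation depends only on (random_state, b), so partial reruns
    reproduce.  ``permutations`` may supply an explicit (B, n) array of
    index permutations instead (e.g. the full symmetric group on tiny
    networks).
    """
    x = np.asarray(x, dtype=float)
    nodes, p = net.row_stochastic()
    n = len(nodes)
    observed = diffuse(x, net, alpha=alpha, steps=steps)

    if permutations is not None:
        perms = np.asarray(permutations)
        if perms.ndim != 2 or perms.shape[1] != n:
            raise ValueError("permutations must be a (B, n) index array")
        n_permutations = perms.shape[0]
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if permutations is None and random_state is None:
        random_state = int(np.random.SeedSequence().generate_state(1)[0] % 2**31)
        logger.info("no seed supplied; drew %d", random_state)

    counts = np.zeros(n, dtype=np.int64)
    for start in range(0, n_permutations, chunk):
        stop = min(start + chunk, n_permutations)
        if permutations is not None:
            block = x[perms[start:stop]]
        else:
            block = np.empty((stop - start, n))
            for b in range(start, stop):
                rng = np.random.default_rng([int(random_state), b])
                block[b - start] = x[rng.permutation(n)]
        s = block.T  # n x chunk
        for _ in range(steps):
            s = alpha * s + (1.0 - alpha) * (p @ s)
        counts += (s >= observed[:, None]).sum(axis=1)
    return (1.0 + counts) / (n_permutations + 1.0)


def _rank_order(nodes: Sequence[str], scores: np.ndarray,
                pvalues: np.ndarray | None = None) -> np.ndarray:
    """Indices sorting by score desc, then p asc, then symbol asc."""
    df = pd.DataFrame({"gene": list(nodes), "score": scores})
    df["p"] = pvalues if pvalues is not None else 0.0
    order = df.sort_values(["score", "p", "gene"],
                           ascending=[False, True, True], kind="stable").index
    return np.asarray(order)


def top_contributors(gene: str, x_lookup: dict[str, float],
                     net: AssociationNetwork, alpha: float,
                     m: int = 10) -> list[tuple[str, float]]:
    """The <= m neighbors contributing most to ``gene``'s one-step score,
    as (neighbor, (1 - alpha) * w_ij * x_j) pairs, contribution desc then
    symbol asc."""
    nbrs = net.neighborhood(gene)
    if not nbrs:
        return []
    total = sum(c for _, c in nbrs)
    contrib = [(nbr, (1.0 - alpha) * (c / total) * x_lookup.get(nbr, 0.0))
               for nbr, c in nbrs]
    contrib.sort(key=lambda t: (-t[1], t[0]))
    return contrib[:m]


class DiffusionPrioritizer(BaseEstimator):
    """Ranks every network gene as a candidate drug target.

    Composes signal construction, diffusion, permutation P-values and BH
    FDR.  Parameters mirror the pipeline knobs: ``alpha`` self-retention in
    [0, 1], ``steps`` diffusion iterations, ``signal`` in
    {'neglog10p', 'abs_log2fc', 'abs_t'}, ``signal_cap`` for infinite
    -log10 P, ``n_permutations`` (B) and ``random_state``.

    After :meth:`fit`: ``nodes_``, ``signal_``, ``scores_``, ``pvalues_``,
    ``adj_pvalues_`` (node order) and ``results_`` (the ranked table).
    """

    def __init__(self, alpha: float = 0.5, steps: int = 1,
                 signal: str = "neglog10p", signal_cap: float = 16.0,
                 n_permutations: int = 1000, random_state: int | None = None):
        self.alpha = alpha
        self.steps = steps
        self.signal = signal
        self.signal_cap = signal_cap
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, signature: pd.DataFrame,
            network: AssociationNetwork) -> "DiffusionPrioritizer":
        x = build_signal(signature, network, signal=self.signal,
                         signal_cap=self.signal_cap)
        nodes = network.nodes
        scores = diffuse(x, network, alpha=self.alpha, steps=self.steps)
        pvals = permutation_pvalues(x, network, alpha=self.alpha,
                                    steps=self.steps,
                                    n_permutations=self.n_permutations,
                                    random_state=self.random_state)
        adj = bh_adjust(pvals)
        order = _rank_order(nodes, scores, pvals)

        self.network_ = network
        self.nodes_ = nodes
        self.signal_ = x
        self.scores_ = scores
        self.pvalues_ = pvals
        self.adj_pvalues_ = adj
        self._x_lookup = dict(zip(nodes, x))

        ranked = pd.DataFrame({
            "rank": np.arange(1, len(nodes) + 1),
            "gene": np.asarray(nodes, dtype=object)[order],
            "score": scores[order],
            "p_value": pvals[order],
            "adj_p": adj[order],
        })
        ranked["contributors"] = [
            top_contributors(g, self._x_lookup, network, self.alpha)
            for g in ranked["gene"]
        ]
        self.results_ = ranked
        return self

    def transform(self, signature: pd.DataFrame) -> np.ndarray:
        """Diffusion scores (node order) for a new signature on the fitted
        network."""
        x = build_signal(signature, self.network_, signal=self.signal,
                         signal_cap=self.signal_cap)
        return diffuse(x, self.network_, alpha=self.alpha, steps=self.steps)


def prioritize(sig: pd.DataFrame, net: AssociationNetwork,
               alpha: float = 0.5, steps: int = 1,
               signal: str = "neglog10p", signal_cap: float = 16.0,
               n_permutations: int = 1000,
               random_state: int | None = None) -> pd.DataFrame:
    """One-call prioritization: returns the ranked table with columns rank,
    gene, score, p_value, adj_p, contributors."""
    est = DiffusionPrioritizer(alpha=alpha, steps=steps, signal=signal,
                               signal_cap=signal_cap,
                               n_permutations=n_permutations,
                               random_state=random_state)
    return est.fit(sig, net).results_


def rank_by_score(sig: pd.DataFrame, net: AssociationNetwork,
                  alpha: float = 0.5, steps: int = 1,
                  signal: str = "neglog10p", signal_cap: float = 16.0) -> list[str]:
    """Ranking by diffusion score only (no permutation P-values) — the
    cheap path for evaluation, identical to :func:`prioritize`'s order up
    to the P-value tie-break on exactly tied scores."""
    x = build_signal(sig, net, signal=signal, signal_cap=signal_cap)
    scores = diffuse(x, net, alpha=alpha, steps=steps)
    nodes = net.nodes
    order = _rank_order(nodes, scores)
    return [nodes[i] for i in order]


def export_subnetwork(results: pd.DataFrame, sig: pd.DataFrame,
                      net: AssociationNetwork, gene: str) -> dict:
    """Neighbor-graph document for one gene: the focal gene and its <= 10
    top contributors, with per-node log2 ratio (color) and a significance
    statistic (size: |t| when available, else -log10 P), plus the edge
    confidences among the included nodes."""
    row = results[results["gene"] == gene]
    if row.empty:
        raise ValueError(f"gene {gene!r} not present in the prioritization results")
    contributors = list(row.iloc[0]["contributors"])

    sig_idx = sig.set_index("gene")

    def node_doc(g: str) -> dict:
        if g in sig_idx.index:
            rec = sig_idx.loc[g]
            lfc = float(rec["log2_ratio"])
            if "t_stat" in sig.columns and np.isfinite(rec.get("t_stat", np.nan)):
                size = abs(float(rec["t_stat"]))
            else:
                size = float(min(-np.log10(max(rec["p_value"], 1e-300)), 300.0))
        else:
            lfc, size = 0.0, 0.0
        return {"gene": g, "log2_ratio": lfc, "size_stat": size}

    members = [gene] + [g for g, _ in contributors]
    edges = [{"a": a, "b": b, "confidence": net.confidence(a, b)}
             for i, a in enumerate(members) for b in members[i + 1:]
             if b in dict(net.neighborhood(a))]
    return {
        "focal": gene,
        "contributors": [{"gene": g, "contribution": c} for g, c in contributors],
        "nodes": [node_doc(g) for g in members],
        "edges": edges,
    }


def write_subnetwork_tsv(doc: dict, nodes_path, edges_path) -> None:
    """Write a subnetwork document as a two-file TSV (nodes, edges)."""
    pd.DataFrame(doc["nodes"]).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(doc["edges"], columns=["a", "b", "confidence"]).to_csv(
        edges_path, sep="\t", index=False)


def write_ranked_csv(results: pd.DataFrame, path) -> None:
    """Write the ranked table (rank, gene, score, p_value, adj_p) as CSV."""
    results.to_csv(path, columns=RANKED_COLUMNS, index=False)
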