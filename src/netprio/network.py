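"""Confidence-weighted functional protein association networks.

The network is an undirected graph over gene symbols whose edges carry a
confidence in (0, 1] that the two proteins act together functionally —
the shape of a STRING edge list after mapping protein IDs to symbols.
STRING ships integer scores on a 0-999 scale; any confidence above 1 in an
input file triggers division of the whole file by 1000.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class AssociationNetwork:
    """Undirected gene-symbol graph with edge confidences in (0, 1].

    Self-loops are dropped and duplicate pairs collapse to the maximum
    confidence.  Backed by a :class:`networkx.Graph` (edge attribute
    ``confidence``), exposed read-only through this wrapper.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "AssociationNetwork":
        """Build from (geneA, geneB, confidence) triples already on the
        (0, 1] scale; symbols are upper-cased, self-loops dropped,
        duplicates collapsed to the max confidence."""
        g = nx.Graph()
        n_self = 0
        for a, b, c in edges:
            a = str(a).strip().upper()
            b = str(b).strip().upper()
            c = float(c)
            if a == b:
                n_self += 1
                continue
            if not (0.0 < c <= 1.0):
                raise ValueError(f"confidence {c} for ({a}, {b}) outside (0, 1]")
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], c)
            else:
                g.add_edge(a, b, confidence=c)
        if n_self:
            logger.info("dropped %d self-loop(s)", n_self)
        return cls(g)

    def add_nodes(self, nodes: Iterable[str]) -> None:
        self._g.add_nodes_from(str(n).strip().upper() for n in nodes)

    # -- inspection ---------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def degree(self, gene: str) -> int:
        return self._g.degree[gene] if gene in self._g else 0

    def confidence(self, a: str, b: str) -> float:
        return float(self._g[a][b]["confidence"])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for a, b, data in self._g.edges(data=True):
            yield a, b, float(data["confidence"])

    def neighborhood(self, gene: str) -> list[tuple[str, float]]:
        """All (neighbor, confidence) pairs incident to ``gene``; an unknown
        or isolated gene yields an empty list."""
        if gene not in self._g:
            logger.debug("neighborhood query for unknown gene %s", gene)
            return []
        return sorted((nbr, float(data["confidence"]))
                      for nbr, data in self._g[gene].items())

    # -- linear-algebra views ----------------------------------------------

    def adjacency(self) -> tuple[list[str], sp.csr_matrix]:
        """Sorted node list and the symmetric confidence-weighted adjacency."""
        nodes = self.nodes
        w = nx.to_scipy_sparse_array(self._g, nodelist=nodes,
                                     weight="confidence", format="csr")
        return nodes, sp.csr_matrix(w)

    def row_stochastic(self) -> tuple[list[str], sp.csr_matrix]:
        """Confidence-row-normalized transition matrix P = D^-1 W.

        Isolated nodes get an identity row, so applying P leaves their
        signal in place.
        """
        nodes, w = self.adjacency()
        deg = np.asarray(w.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
        p = sp.diags(inv) @ w
        isolated = np.flatnonzero(deg == 0)
        if isolated.size:
            p = p.tolil()
            for i in isolated:
                p[i, i] = 1.0
            p = p.tocsr()
        return nodes, sp.csr_matrix(p)


def read_edge_list(path: str | Path, min_confidence: float = 0.0) -> AssociationNetwork:
    """Read a three-column (geneA, geneB, confidence) edge list, TSV or
    whitespace-delimited, optionally gzipped.

    A header line is tolerated when its confidence field is non-numeric.
    Confidence scale is auto-detected: any value above 1 switches the whole
    file to the STRING 0-999 integer interpretation (divide by 1000); values
    above 1000 are rejected as an ambiguous scale.  Records with
    non-numeric confidences are skipped with a logged count; self-loops are
    dropped; duplicate pairs keep the maximum confidence.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    rows: list[tuple[str, str, float]] = []
    n_rejected = 0
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                n_rejected += 1
                continue
            try:
                conf = float(fields[2])
            except ValueError:
                if lineno == 0:
                    continue  # header line
                n_rejected += 1
                continue
            rows.append((fields[0], fields[1], conf))
    if n_rejected:
        logger.info("%s: rejected %d malformed record(s)", path.name, n_rejected)
    if not rows:
        raise ValueError(f"{path}: zero usable edges")
    confs = np.array([c for _, _, c in rows])
    if confs.max() > 1.0:
        if confs.max() > 1000.0:
            raise ValueError(f"{path}: ambiguous confidence scale (value > 1000)")
        rows = [(a, b, c / 1000.0) for a, b, c in rows]
    usable = [(a, b, c) for a, b, c in rows if c > 0.0]
    n_nonpos = len(rows) - len(usable)
    if n_nonpos:
        logger.info("%s: dropped %d edge(s) with non-positive confidence",
                    path.name, n_nonpos)
    if min_confidence > 0.0:
        usable = [(a, b, c) for a, b, c in usable if c >= min_confidence]
    if not usable:
        raise ValueError(f"{path}: zero usable edges")
    net = AssociationNetwork.from_edges(usable)
    if net.n_edges == 0:  # e.g. self-loops only
        raise ValueError(f"{path}: zero usable edges")
    return net


def write_edge_list(net: AssociationNetwork, path: str | Path,
                    float_format: str = "%.6f") -> None:
    """Write a (geneA, geneB, confidence) TSV on the (0, 1] scale."""
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tconfidence\n")
        triples = sorted((min(a, b), max(a, b), c) for a, b, c in net.edges())
        for a, b, c in triples:
            fh.write(f"{a}\t{b}\t{float_format % c}\n")
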