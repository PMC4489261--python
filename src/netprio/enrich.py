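"""Hypergeometric over-representation analysis against gene-set collections.

Pathway (Reactome-style) and disease-phenotype (HPO-style) collections are
carried in GMT format.  For each set, the overlap k between the
differentially expressed genes (adjusted P at or below a threshold, default
0.01) and the set is tested with the upper tail of the hypergeometric
distribution — P(X >= k) for X ~ Hypergeom(N, K, n) — followed by
Benjamini-Hochberg correction across the sets of the collection.

The default universe is the intersection of measured (signature) genes and
genes annotated in at least one set of the collection, which avoids the
inflation that counting never-annotated genes produces; ``universe=
"all-measured"`` uses every signature gene instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .de import bh_adjust

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["set_id", "set_name", "K", "k", "n", "N",
                  "p_value", "adj_p", "overlap_genes"]
CSV_COLUMNS = ["set_id", "set_name", "K", "k", "p_value", "adj_p", "overlap_genes"]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets with unique IDs; namespace tags the collection as
    pathway, phenotype or other."""

    sets: list[GeneSet] = field(default_factory=list)
    namespace: str = "other"

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValueError("set_ids must be unique")
        if any(not s.genes for s in self.sets):
            raise ValueError("every gene set must be nonempty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def union_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return out


def read_gmt(path: str | Path, namespace: str = "other") -> GeneSetCollection:
    """Read a GMT file: per line, set_id TAB description TAB gene1 TAB ...

    Symbols are upper-cased; duplicate members within a line collapse;
    lines with fewer than three fields (no members) are skipped with a log
    entry.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if not any(fields):
                continue
            genes = frozenset(g.upper() for g in fields[2:] if g)
            if len(fields) < 3 or not genes:
                n_skipped += 1
                continue
            sets.append(GeneSet(set_id=fields[0], name=fields[1], genes=genes))
    if n_skipped:
        logger.info("%s: skipped %d malformed/empty line(s)", path.name, n_skipped)
    return GeneSetCollection(sets=sets, namespace=namespace)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.name] + sorted(s.genes)) + "\n")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), X ~ Hypergeom(N, K, n):
    the chance that a uniformly drawn size-n subset of an N-gene universe
    hits a K-gene set at least k times."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) is computed from log-space terms internally; numerically stable
    return float(stats.hypergeom.sf(k - 1, N, K, n))


class HypergeometricEnricher(BaseEstimator):
    """Over-representation test of a DE gene list against a collection.

    Parameters: ``threshold`` — adjusted-P cutoff selecting the DE list
    (default 0.01); ``universe`` — 'annotated' (measured AND annotated,
    default) or 'all-measured'.

    After :meth:`fit`: ``results_`` — a DataFrame with one row per tested
    set (columns set_id, set_name, K, k, n, N, p_value, adj_p,
    overlap_genes) sorted by adj_p, p, set_id; ``universe_``, ``de_genes_``.
    """

    def __init__(self, threshold: float = 0.01, universe: str = "annotated"):
        self.threshold = threshold
        self.universe = universe

    def fit(self, signature: pd.DataFrame,
            collection: GeneSetCollection) -> "HypergeometricEnricher":
        if "adj_p" not in signature.columns:
            raise ValueError("signature needs an adj_p column (run bh_adjust first)")
        if self.universe not in ("annotated", "all-measured"):
            raise ValueError("universe must be 'annotated' or 'all-measured'")
        measured = set(signature["gene"])
        if self.universe == "annotated":
            universe = measured & collection.union_genes()
        else:
            universe = measured
        de = set(signature.loc[signature["adj_p"] <= self.threshold, "gene"]) & universe
        self.universe_ = universe
        self.de_genes_ = de

        rows = []
        if not de:
            warnings.warn("no differentially expressed genes at threshold "
                          f"{self.threshold}; empty enrichment result")
        else:
            N, n = len(universe), len(de)
            for s in collection:
                members = s.genes & universe
                K = len(members)
                if K == 0:
                    continue
                overlap = sorted(members & de)
                k = len(overlap)
                rows.append({
                    "set_id": s.set_id, "set_name": s.name,
                    "K": K, "k": k, "n": n, "N": N,
                    "p_value": hypergeom_upper(k, K, n, N),
                    "overlap_genes": overlap,
                })
        res = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "adj_p"])
        if len(res):
            res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
            res = res.sort_values(["adj_p", "p_value", "set_id"],
                                  kind="stable").reset_index(drop=True)
        else:
            res["adj_p"] = pd.Series(dtype=float)
        self.results_ = res[RESULT_COLUMNS]
        return self


def enrich(sig: pd.DataFrame, sets: GeneSetCollection, threshold: float = 0.01,
           universe: str = "annotated") -> pd.DataFrame:
    """Functional wrapper over :class:`HypergeometricEnricher`."""
    return HypergeometricEnricher(threshold=threshold,
                                  universe=universe).fit(sig, sets).results_


def top_enrichment_graph(results: pd.DataFrame, sig: pd.DataFrame,
                         m: int = 10) -> dict:
    """Bipartite document of the top-m most significant sets and their
    overlap genes, genes annotated with log2 ratio (for fold-change
    coloring); shared genes are deduplicated."""
    top = results.head(m)
    lfc = dict(zip(sig["gene"], sig["log2_ratio"]))
    genes: dict[str, dict] = {}
    edges = []
    for row in top.itertuples(index=False):
        for g in row.overlap_genes:
            genes.setdefault(g, {"gene": g, "log2_ratio": float(lfc.get(g, 0.0))})
            edges.append({"set_id": row.set_id, "gene": g})
    return {
        "sets": [{"set_id": r.set_id, "set_name": r.set_name,
                  "adj_p": float(r.adj_p)} for r in top.itertuples(index=False)],
        "genes": sorted(genes.values(), key=lambda d: d["gene"]),
        "edges": edges,
    }


def write_enrichment_csv(results: pd.DataFrame, path) -> None:
    """CSV with columns set_id, set_name, K, k, p_value, adj_p,
    overlap_genes (semicolon-joined)."""
    out = results.copy()
    if len(out):
        out["overlap_genes"] = out["overlap_genes"].map(";".join)
    out.to_csv(path, columns=CSV_COLUMNS, index=False)
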