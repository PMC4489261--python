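"""ROC/AUC evaluation of ranked gene lists against known drug targets.

Each treatment experiment yields a full ranking of the network's genes; the
known targets of the treatment compound are the positives.  Per-experiment
performance is the Mann-Whitney AUC (probability a random positive outranks
a random negative).  To pool experiments of different sizes, every gene
becomes one instance with score 1 - (rank - 0.5) / n_e — its normalized
(percentile) rank within its own experiment — and a single ROC curve is
swept over the pooled instances.  This percentile pooling is the scale-free
way to make heterogeneous rankings commensurable; targets missing from an
experiment's ranking are dropped from that experiment with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics

from .network import AssociationNetwork
from .prioritize import rank_by_score

logger = logging.getLogger(__name__)

KnownTargets = dict[str, set]  # experiment_id -> set of target symbols


def read_known_targets(path: str | Path) -> KnownTargets:
    """Read a TSV of (experiment_id, target_symbol) rows, one per pair."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (experiment, target)")
    first = str(df.iloc[0, 0]).strip().lower()
    if first in {"experiment", "experiment_id", "exp"}:
        df = df.iloc[1:]
    targets: KnownTargets = {}
    for exp, gene in df.itertuples(index=False):
        targets.setdefault(str(exp).strip(), set()).add(str(gene).strip().upper())
    if not targets or any(not v for v in targets.values()):
        raise ValueError(f"{path}: every experiment needs at least one target")
    return targets


def write_known_targets(targets: KnownTargets, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("experiment_id\ttarget\n")
        for exp in sorted(targets):
            for gene in sorted(targets[exp]):
                fh.write(f"{exp}\t{gene}\n")


@dataclass
class RocCurve:
    """A step-function ROC curve from (0,0) to (1,1) and its area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def to_csv(self, path) -> None:
        pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr}).to_csv(path, index=False)


def auc_single(ranking: Sequence[str], positives: set) -> float:
    """Mann-Whitney AUC of one ranking (rank 1 = best) against a positive
    set; ranks are strict, so no tie handling is needed."""
    positives = set(positives)
    pos_ranks = [r for r, g in enumerate(ranking, start=1) if g in positives]
    n_pos = len(pos_ranks)
    n_neg = len(ranking) - n_pos
    if n_pos == 0:
        raise ValueError("no positives present in the ranking")
    if n_neg == 0:
        raise ValueError("ranking contains no negatives")
    # of the n_pos*n_neg positive-negative pairs, those where the negative
    # ranks better number sum(rank_p) - n_pos*(n_pos+1)/2
    discordant = sum(pos_ranks) - n_pos * (n_pos + 1) // 2
    return 1.0 - discordant / (n_pos * n_neg)


def _pooled_instances(rankings: Mapping[str, Sequence[str]],
                      targets: KnownTargets) -> tuple[np.ndarray, np.ndarray]:
    labels, scores = [], []
    for exp, pos in targets.items():
        if exp not in rankings:
            raise ValueError(f"experiment {exp!r} has no ranking")
        ranking = list(rankings[exp])
        present = set(ranking)
        kept = set(pos) & present
        dropped = len(pos) - len(kept)
        if dropped:
            logger.info("experiment %s: %d target(s) absent from the ranking dropped",
                        exp, dropped)
        if not kept:
            logger.warning("experiment %s: no targets present; contributes only "
                           "negatives", exp)
        n_e = len(ranking)
        for r, g in enumerate(ranking, start=1):
            labels.append(1 if g in kept else 0)
            scores.append(1.0 - (r - 0.5) / n_e)
    return np.asarray(labels), np.asarray(scores)


def pooled_roc(rankings: Mapping[str, Sequence[str]],
               targets: KnownTargets) -> RocCurve:
    """ROC over all experiments' genes pooled on normalized ranks."""
    if not targets:
        raise ValueError("no experiments to evaluate")
    labels, scores = _pooled_instances(rankings, targets)
    if labels.sum() == 0:
        raise ValueError("no positives present in any ranking")
    fpr, tpr, _ = metrics.roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(metrics.auc(fpr, tpr)))


class MethodComparison(NamedTuple):
    auc_diffusion: float
    auc_raw: float
    roc_diffusion: RocCurve
    roc_raw: RocCurve


def compare_methods(sigs: Mapping[str, pd.DataFrame], net: AssociationNetwork,
                    targets: KnownTargets, alpha: float = 0.5, steps: int = 1,
                    signal: str = "neglog10p",
                    signal_cap: float = 16.0) -> MethodComparison:
    """Pooled AUC of network diffusion versus the raw differential-
    expression ranking (alpha = 1) on the same signatures, network and
    known targets."""
    rank_d = {exp: rank_by_score(sig, net, alpha=alpha, steps=steps,
                                 signal=signal, signal_cap=signal_cap)
              for exp, sig in sigs.items()}
    rank_r = {exp: rank_by_score(sig, net, alpha=1.0, steps=steps,
                                 signal=signal, signal_cap=signal_cap)
              for exp, sig in sigs.items()}
    roc_d = pooled_roc(rank_d, targets)
    roc_r = pooled_roc(rank_r, targets)
    return MethodComparison(auc_diffusion=roc_d.auc, auc_raw=roc_r.auc,
                            roc_diffusion=roc_d, roc_raw=roc_r)
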