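"""Evaluation of co-occurrence scoring against comorbidity ground truth.

The protocol labels one disease at a time (leave-one-out over the set of
diseases with known comorbid partners), scores every other disease on the
network, and measures how well the scores rank the disease's recorded
partners above the rest by AUC.  A degree-preserving randomization of the
network provides the chance-level baseline (AUC ~ 0.5), and paired
t-tests compare per-disease AUC lists between network variants.  A
k-fold variant labels whole folds of diseases jointly; with singleton
folds it coincides with leave-one-out.

A limitation shared with literature-derived comorbidity labels: diseases
not recorded as comorbid with the target are treated as negatives even
though some may simply be unsurveyed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.stats
from sklearn.metrics import roc_auc_score

from .io import ComorbidityLabels, DiseaseNetwork
from .scoring import ScoringProblem, solve_clamped, solve_full

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "auc",
    "loo_comorbidity_auc",
    "kfold_cv",
    "randomize_network",
    "paired_t_test",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Per-trial AUCs with their mean and (sample) standard deviation."""

    per_label_auc: Mapping[str, float]
    network_tag: str
    mean_auc: float = field(init=False)
    std_auc: float = field(init=False)
    n_trials: int = field(init=False)

    def __post_init__(self):
        vals = np.array(list(self.per_label_auc.values()), dtype=float)
        if vals.size == 0:
            raise ValueError("report needs at least one trial")
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("AUC values must lie in [0, 1]")
        object.__setattr__(self, "mean_auc", float(vals.mean()))
        object.__setattr__(
            self, "std_auc", float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        )
        object.__setattr__(self, "n_trials", int(vals.size))


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney; ties count one half).

    Equals the fraction of (positive, negative) pairs in which the
    positive item outscores the negative one, counting ties as 0.5.
    """
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _trial_scores(network, primary, mu, method):
    problem = ScoringProblem(network, frozenset(primary), mu)
    if method == "clamped":
        return solve_clamped(problem)
    if method == "full":
        full = solve_full(problem)
        return {d: v for d, v in full.items() if d not in primary}
    raise ValueError("method must be 'clamped' or 'full'")


def _fold_auc(network, labels, fold, mu, method):
    """AUC of one trial: label `fold`, rank the rest against its partners."""
    scores = _trial_scores(network, fold, mu, method)
    positives = set()
    for d in fold:
        positives |= labels.partners(d)
    positives &= set(scores)
    if not positives or len(positives) == len(scores):
        return None
    ids = sorted(scores)
    return auc([scores[d] for d in ids], [int(d in positives) for d in ids])


def loo_comorbidity_auc(
    network: DiseaseNetwork,
    labels: ComorbidityLabels,
    mu: float = 100.0,
    method: str = "clamped",
) -> EvaluationReport:
    """Leave-one-out scoring AUC over every disease with comorbid partners.

    For each disease d appearing in `labels` (and in the network): label
    only d, score all other diseases, and compute the AUC with positives
    = the recorded partners of d and negatives = all remaining unlabeled
    diseases.
    """
    unknown = labels.diseases - set(network.diseases)
    if unknown:
        raise ValueError(f"labeled diseases missing from network: {sorted(unknown)}")
    per_label: dict[str, float] = {}
    for d in sorted(labels.diseases):
        value = _fold_auc(network, labels, [d], mu, method)
        if value is None:
            logger.warning("disease %s skipped: no evaluable partners", d)
            continue
        per_label[d] = value
    if not per_label:
        raise ValueError("no evaluable disease in the label set")
    return EvaluationReport(per_label, network.layer_tag)


def kfold_cv(
    network: DiseaseNetwork,
    labels: ComorbidityLabels,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    mu: float = 100.0,
    method: str = "clamped",
) -> list[EvaluationReport]:
    """Repeated k-fold variant of the leave-one-out protocol.

    Diseases with comorbidity labels are randomly partitioned into k
    folds (one permutation per repeat).  Each fold's diseases are labeled
    jointly and the AUC measures recovery of any fold member's partners
    among the non-fold diseases.  With k equal to the number of labeled
    diseases this reduces exactly to :func:`loo_comorbidity_auc`.
    """
    pool = sorted(labels.diseases & set(network.diseases))
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(pool) < k:
        raise ValueError(f"{len(pool)} labeled diseases cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    reports = []
    for rep in range(repeats):
        perm = list(rng.permutation(pool))
        folds = np.array_split(perm, k)
        per_fold: dict[str, float] = {}
        for fold in folds:
            fold = sorted(fold)
            value = _fold_auc(network, labels, fold, mu, method)
            if value is None:
                warnings.warn(f"fold {fold} skipped: no positives among scored diseases")
                continue
            per_fold["+".join(fold)] = value
        reports.append(
            EvaluationReport(per_fold, f"{network.layer_tag}|{k}fold rep{rep}")
        )
    return reports


def randomize_network(
    network: DiseaseNetwork, seed: int, n_swaps: int | None = None
) -> DiseaseNetwork:
    """Degree-preserving randomization (double edge swaps) of a network.

    The binarized topology is shuffled by repeated double-edge swaps, so
    every disease keeps its exact edge degree and the edge count is
    unchanged; the multiset of edge weights is then reassigned to the new
    edges by a seeded random permutation.  Deterministic given `seed`.
    """
    W = network.weights
    n = network.n_diseases
    iu = np.triu_indices(n, 1)
    present = W[iu] > 0
    m = int(present.sum())
    if m < 2:
        raise ValueError("randomization needs at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * m  # standard mixing heuristic

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[0][present], iu[1][present]))
    if m < n * (n - 1) // 2:  # a complete topology admits no swap at all
        try:
            nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=int(seed))
        except nx.NetworkXException as exc:
            warnings.warn(
                f"double-edge swap stopped early ({exc}); returning best effort"
            )

    rng = np.random.default_rng(seed)
    weight_pool = rng.permutation(W[iu][present])
    new_W = np.zeros_like(W)
    for (a, b), w in zip(sorted(tuple(sorted(e)) for e in g.edges), weight_pool):
        new_W[a, b] = new_W[b, a] = w

    result = DiseaseNetwork(
        network.diseases, new_W, layer_tag=f"{network.layer_tag}|randomized(seed={seed})"
    )
    # degree preservation is a hard contract: assert on every call
    old_deg = (W > 0).sum(axis=1)
    new_deg = (result.weights > 0).sum(axis=1)
    assert (old_deg == new_deg).all(), "degree sequence changed during randomization"
    assert result.n_edges == m, "edge count changed during randomization"
    return result


def paired_t_test(auc_a: Sequence[float], auc_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on per-trial AUC differences.

    Degenerate cases follow a documented convention: identical lists give
    (0.0, 1.0); constant non-zero differences (zero variance) give
    (signed inf, 0.0).
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1-d sequences of length >= 2")
    d = a - b
    if np.ptp(d) <= 1e-12:  # constant differences: degenerate by convention
        if abs(d[0]) <= 1e-12:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), 0.0
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)
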