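"""Graph-based semi-supervised scoring of disease co-occurrence.

Given a weighted disease network W and a unary label vector y (1 on the
primary disease(s), 0 elsewhere), scores f are obtained by minimizing the
loss-plus-smoothness objective

    H(f) = (f - y)^T (f - y) + mu f^T L f,       L = D - W,

whose minimizer is f = (I + mu L)^{-1} y (the *full* solver).  The
*clamped* solver instead fixes the labeled scores to their labels and
solves the unlabeled block only,

    f_u = mu { I + mu (D_uu - W_uu) }^{-1} W_ul y_l,

where D_uu carries the full degrees (over labeled and unlabeled
neighbors alike).  The two estimators differ: the full solver shrinks the
labeled scores as well.  Clamped is the default used for co-occurrence
scoring; with non-negative weights its scores satisfy 0 <= f_u < 1, with
f_u > 0 exactly when a positive-weight path to a labeled disease exists.

Scores are mapped to co-occurrence probabilities through a sigmoid of the
(normalized) score, Prob(u|l) = 1 / (1 + exp(-f_u / sigma_f)).
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .io import DiseaseNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringProblem",
    "ScoringResult",
    "SemiSupervisedScorer",
    "graph_laplacian",
    "solve_full",
    "solve_clamped",
    "to_probability",
    "score_diseases",
]


@dataclass(frozen=True)
class ScoringProblem:
    """A network, the unary-labeled disease set, and the tradeoff mu."""

    network: DiseaseNetwork
    labeled: frozenset[str]
    mu: float = 100.0

    def __post_init__(self):
        object.__setattr__(self, "labeled", frozenset(self.labeled))
        if not self.labeled:
            raise ValueError("labeled set must be non-empty")
        unknown = self.labeled - set(self.network.diseases)
        if unknown:
            raise ValueError(f"labeled diseases not in network: {sorted(unknown)}")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    @property
    def label_vector(self) -> np.ndarray:
        y = np.zeros(self.network.n_diseases)
        for d in self.labeled:
            y[self.network.index(d)] = 1.0
        return y


@dataclass(frozen=True)
class ScoringResult:
    """Scores and probabilities for the unlabeled diseases, ranked."""

    scores: Mapping[str, float]
    probabilities: Mapping[str, float]
    method_tag: str
    sigma_f: float
    ranking: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        if set(self.scores) != set(self.probabilities):
            raise ValueError("scores and probabilities cover different diseases")
        order = sorted(self.scores, key=lambda d: (-self.probabilities[d], d))
        object.__setattr__(self, "ranking", tuple(order))


def graph_laplacian(network: DiseaseNetwork | np.ndarray) -> np.ndarray:
    """Combinatorial Laplacian L = D - W (symmetric, zero row sums, PSD)."""
    W = network.weights if isinstance(network, DiseaseNetwork) else np.asarray(network, float)
    return np.diag(W.sum(axis=1)) - W


def _spd_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    return scipy.linalg.solve(A, b, assume_a="pos")


def _solve_full_array(W: np.ndarray, y: np.ndarray, mu: float) -> np.ndarray:
    A = np.eye(len(y)) + mu * graph_laplacian(W)
    return _spd_solve(A, y)


def _solve_clamped_array(W: np.ndarray, labeled: np.ndarray, mu: float) -> np.ndarray:
    """Scores for the unlabeled block (in unlabeled order)."""
    u = ~labeled
    d_full = W.sum(axis=1)
    Wuu = W[np.ix_(u, u)]
    Wul = W[np.ix_(u, labeled)]
    y_l = np.ones(int(labeled.sum()))
    A = np.eye(int(u.sum())) + mu * (np.diag(d_full[u]) - Wuu)
    return mu * _spd_solve(A, Wul @ y_l)


def solve_full(problem: ScoringProblem) -> dict[str, float]:
    """Minimize H(f) over all diseases: f = (I + mu L)^{-1} y."""
    f = _solve_full_array(problem.network.weights, problem.label_vector, problem.mu)
    return dict(zip(problem.network.diseases, f))


def solve_clamped(problem: ScoringProblem) -> dict[str, float]:
    """Solve the unlabeled block with labeled scores clamped to 1.

    Returns scores for the unlabeled diseases only.  The degree matrix of
    the unlabeled block uses full degrees d_i = sum_j w_ij over all
    neighbors, labeled and unlabeled.
    """
    net = problem.network
    labeled_mask = np.zeros(net.n_diseases, dtype=bool)
    for d in problem.labeled:
        labeled_mask[net.index(d)] = True
    if labeled_mask.all():
        return {}
    f_u = _solve_clamped_array(net.weights, labeled_mask, problem.mu)
    unlabeled = [d for d, m in zip(net.diseases, labeled_mask) if not m]
    return dict(zip(unlabeled, f_u))


def to_probability(
    scores: Mapping[str, float],
    sigma_f: float = 1.0,
    normalization: str = "zscore",
) -> dict[str, float]:
    """Sigmoid transform of (normalized) scores into (0, 1) probabilities.

    The transform is strictly increasing, so the rank order of the scores
    is preserved exactly.  Degenerate normalizations (zero variance or
    zero range) fall back to the raw scores with a warning.
    """
    if sigma_f <= 0:
        raise ValueError("sigma_f must be positive")
    if normalization not in ("zscore", "minmax", "none"):
        raise ValueError("normalization must be 'zscore', 'minmax' or 'none'")
    if not scores:
        raise ValueError("no scores to transform")
    ids = sorted(scores)
    f = np.array([scores[d] for d in ids], dtype=float)
    if normalization == "zscore":
        sd = f.std()
        if sd == 0:
            warnings.warn("zero score variance; skipping z-score normalization")
        else:
            f = (f - f.mean()) / sd
    elif normalization == "minmax":
        rng = f.max() - f.min()
        if rng == 0:
            warnings.warn("zero score range; skipping min-max normalization")
        else:
            f = (f - f.min()) / rng
    p = 1.0 / (1.0 + np.exp(-f / sigma_f))
    return dict(zip(ids, p))


class SemiSupervisedScorer(BaseEstimator):
    """Scikit-learn style transductive scorer on a precomputed disease network.

    ``fit(X, y)`` takes the symmetric non-negative weight matrix ``X`` of
    the disease network and a unary label vector ``y`` (1 for the primary
    disease(s), 0 for every disease to be scored) and stores the scores
    and co-occurrence probabilities for the unlabeled nodes, in the spirit
    of the transductive attributes of label-spreading estimators.

    Parameters
    ----------
    mu : float, default 100.0
        Loss-smoothness tradeoff; large mu emphasises smoothness over the
        network.
    sigma_f : float, default 1.0
        Scale of the sigmoid mapping scores to probabilities.
    method : {"clamped", "full"}, default "clamped"
        Clamp labeled scores to their labels and solve the unlabeled
        block, or solve the unclamped global minimizer.
    normalization : {"zscore", "minmax", "none"}, default "zscore"
        Score normalization applied before the sigmoid.

    Attributes
    ----------
    scores_ : ndarray of shape (n,)
        Scores for every disease; labeled entries are 1 under the clamped
        method and the (shrunk) solved values under the full method.
    probabilities_ : ndarray of shape (n,)
        Co-occurrence probabilities for unlabeled entries; NaN on labeled.
    labeled_mask_ : ndarray of bool, shape (n,)
    ranking_ : ndarray of int
        Unlabeled indices sorted by decreasing probability (ties by index).
    """

    def __init__(
        self,
        mu: float = 100.0,
        sigma_f: float = 1.0,
        method: str = "clamped",
        normalization: str = "zscore",
    ):
        self.mu = mu
        self.sigma_f = sigma_f
        self.method = method
        self.normalization = normalization

    def fit(self, X, y):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        if self.method not in ("clamped", "full"):
            raise ValueError("method must be 'clamped' or 'full'")
        if isinstance(X, DiseaseNetwork):
            X = X.weights
        W = np.asarray(X, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("X must be a square weight matrix")
        if np.abs(W - W.T).max() > 1e-10 or W.min() < 0:
            raise ValueError("X must be symmetric with non-negative weights")
        y = np.asarray(y)
        if y.shape != (W.shape[0],) or not set(np.unique(y)) <= {0, 1}:
            raise ValueError("y must be a 0/1 vector of length n")
        labeled = y.astype(bool)
        if not labeled.any():
            raise ValueError("at least one disease must be labeled")
        if labeled.all():
            raise ValueError("all diseases are labeled; nothing to score")

        n = W.shape[0]
        W = _zero_diag(W)
        if self.method == "full":
            scores = _solve_full_array(W, labeled.astype(float), self.mu)
        else:
            scores = np.where(labeled, 1.0, 0.0)
            scores[~labeled] = _solve_clamped_array(W, labeled, self.mu)
        unl = np.nonzero(~labeled)[0]
        probs = to_probability(
            {f"{i:09d}": float(scores[i]) for i in unl},
            self.sigma_f,
            self.normalization,
        )
        probabilities = np.full(n, np.nan)
        for key, p in probs.items():
            probabilities[int(key)] = p
        self.n_features_in_ = n
        self.labeled_mask_ = labeled
        self.scores_ = scores
        self.probabilities_ = probabilities
        self.ranking_ = unl[np.lexsort((unl, -probabilities[unl]))]
        return self

    def fit_predict(self, X, y):
        """Scores for every disease (see ``scores_``)."""
        return self.fit(X, y).scores_


def _zero_diag(W: np.ndarray) -> np.ndarray:
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    U = np.triu(W, 1)
    return U + U.T


def score_diseases(
    network: DiseaseNetwork,
    primary: Iterable[str],
    mu: float = 100.0,
    sigma_f: float = 1.0,
    method: str = "clamped",
    normalization: str = "zscore",
) -> ScoringResult:
    """End-to-end scoring of the non-primary diseases of a network.

    Builds the unary label vector for `primary`, solves, normalizes, and
    maps to probabilities; the result ranks unlabeled diseases by
    decreasing probability with lexicographic tie-breaking.
    """
    primary = frozenset(primary)
    problem = ScoringProblem(network, primary, mu)  # validates membership
    if primary == set(network.diseases):
        raise ValueError("all diseases are primary; nothing to score")
    y = problem.label_vector
    est = SemiSupervisedScorer(mu=mu, sigma_f=sigma_f, method=method,
                               normalization=normalization)
    est.fit(network.weights, y)
    unl = ~est.labeled_mask_
    ids = [d for d, m in zip(network.diseases, unl) if m]
    scores = {d: float(est.scores_[network.index(d)]) for d in ids}
    probabilities = {d: float(est.probabilities_[network.index(d)]) for d in ids}
    return ScoringResult(scores, probabilities, method_tag=method, sigma_f=sigma_f)
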