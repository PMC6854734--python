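"""Disease-disease networks from q-step walks on a PPI graph.

A disease is initially represented by a binary indicator vector over the
protein universe (1 where a seed protein is recorded).  A *q-step walk*
travels q edges on the PPI graph; expanding a disease vector by q steps
adds every protein reachable from a seed within q edges.  Two diseases are
associated at layer q when a walk of length at most q connects a protein
of one to a protein of the other; the edge weight is a Gaussian of the
cosine distance between the corresponding indicator vectors,

    w_ij = exp(-dist(x_i, x_j) / sigma^2)   if i ~ j,   0 otherwise,

with dist(x, y) = 1 - x.y / (||x|| ||y||).  Layers q = 0, 1, 2, ... grow
monotonically denser; an *integrated* network piles the layers up
(element-wise sum, rescaled back into [0, 1]).

Two pairing conventions are supported when comparing diseases at layer q:

* ``"one-sided"`` (default): the q-expanded vector of one disease is
  compared against the other's seed vector, so an association corresponds
  to a single walk of length <= q between a protein of each disease; the
  distance is symmetrized by taking the smaller of the two directions.
* ``"mutual"``: both vectors are expanded before comparison (an
  association may then straddle up to 2q edges).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import cosine_similarity

from .io import DiseaseNetwork, DiseaseSeedMap, ProteinGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseLayerVectors",
    "QStepNetworkBuilder",
    "reachable_within",
    "expand_vectors",
    "cosine_distance",
    "gaussian_similarity",
    "build_layer_network",
    "build_network",
    "build_layers",
    "integrate_networks",
    "network_density",
]


@dataclass(frozen=True)
class DiseaseLayerVectors:
    """Per-disease binary indicators over the protein universe at step q.

    ``indicator[i, p]`` is True when protein ``protein_universe[p]`` is
    reachable from a seed of ``diseases[i]`` within q edges (cumulative
    expansion) or at exactly q edges (exact expansion).
    """

    diseases: tuple[str, ...]
    protein_universe: tuple[str, ...]
    indicator: np.ndarray
    q: int

    def __post_init__(self):
        ind = np.asarray(self.indicator, dtype=bool)
        if ind.shape != (len(self.diseases), len(self.protein_universe)):
            raise ValueError("indicator shape does not match labels")
        object.__setattr__(self, "indicator", ind)

    def row(self, disease: str) -> set[str]:
        i = self.diseases.index(disease)
        mask = self.indicator[i]
        return {p for p, m in zip(self.protein_universe, mask) if m}


def reachable_within(
    graph: ProteinGraph, seeds: Iterable[str], q: int, expansion: str = "cumulative"
) -> set[str]:
    """Proteins reachable from `seeds` by a walk of length <= q (or == q).

    Cumulative expansion returns every protein at shortest-path distance at
    most q from some seed (seeds included).  Exact expansion returns the
    frontier at distance exactly q (for q=0, the seeds themselves).
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    seeds = set(seeds)
    adj = graph.to_networkx().adj
    for s in seeds:
        if s not in graph:
            raise ValueError(f"seed protein {s!r} not in graph")
    reached = set(seeds)
    frontier = set(seeds)
    for _ in range(q):
        nxt = {nbr for v in frontier for nbr in adj[v]} - reached
        if not nxt:
            frontier = nxt
            break
        reached |= nxt
        frontier = nxt
    if expansion == "cumulative":
        return reached
    if expansion == "exact":
        return frontier
    raise ValueError("expansion must be 'cumulative' or 'exact'")


def _expand_indicator(X0: np.ndarray, A: sp.spmatrix, q: int, expansion: str) -> np.ndarray:
    """Vectorized multi-source BFS: expand each row of X0 by q steps on A."""
    reached = X0.copy()
    frontier = X0.copy()
    for _ in range(q):
        nxt = (frontier @ A).astype(bool) & ~reached
        if not nxt.any():
            frontier = nxt
            break
        reached |= nxt
        frontier = nxt
    return reached if expansion == "cumulative" else frontier


def expand_vectors(
    seed_map: DiseaseSeedMap,
    graph: ProteinGraph,
    q: int,
    expansion: str = "cumulative",
) -> DiseaseLayerVectors:
    """Expand every disease's seed vector by q-step walks on the PPI graph.

    The protein universe is the graph's proteins (sorted) plus any seed
    proteins kept outside the graph, which behave as isolated nodes.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    if expansion not in ("cumulative", "exact"):
        raise ValueError("expansion must be 'cumulative' or 'exact'")
    in_graph = sorted(graph.proteins)
    extras = sorted(
        {p for s in seed_map.seeds.values() for p in s if p not in graph}
    )
    universe = tuple(in_graph + extras)
    pidx = {p: i for i, p in enumerate(universe)}
    n, m = seed_map.n_diseases, len(universe)

    X0 = np.zeros((n, m), dtype=bool)
    for i, d in enumerate(seed_map.diseases):
        for p in seed_map.seeds[d]:
            X0[i, pidx[p]] = True

    A = graph.adjacency(order=tuple(in_graph))
    if extras:  # pad isolated columns
        A = sp.block_diag(
            [A, sp.csr_array((len(extras), len(extras)), dtype=bool)], format="csr"
        )
    X = _expand_indicator(X0, A, q, expansion)
    return DiseaseLayerVectors(seed_map.diseases, universe, X, q)


def cosine_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine distance 1 - x.y/(||x|| ||y||) between two non-zero vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0 or ny == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    d = 1.0 - float(x @ y) / (nx_ * ny)
    if abs(d) < 1e-12:  # identical directions: snap float residue to zero
        d = 0.0
    return float(np.clip(d, 0.0, 1.0))


def gaussian_similarity(dist: float, sigma: float = 1.0, connected: bool = True) -> float:
    """Gaussian similarity exp(-dist/sigma^2) for connected pairs, else 0."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not connected:
        return 0.0
    return float(np.exp(-dist / sigma**2))


def _pairwise_weights(
    Xq: np.ndarray, X0: np.ndarray | None, sigma: float
) -> np.ndarray:
    """Symmetric weight matrix from indicator matrices (zero diagonal)."""
    Xq = Xq.astype(float)
    if X0 is None:  # mutual: both sides expanded
        S = cosine_similarity(Xq)
        shared = (Xq @ Xq.T) > 0.5
        D = 1.0 - S
        D = np.minimum(D, D.T)
    else:  # one-sided: expanded vs seed, best of the two directions
        X0 = X0.astype(float)
        S = cosine_similarity(Xq, X0)
        shared = ((Xq @ X0.T) > 0.5) | ((Xq @ X0.T) > 0.5).T
        D = 1.0 - S
        D = np.minimum(D, D.T)
    np.clip(D, 0.0, 1.0, out=D)
    W = np.where(shared | shared.T, np.exp(-D / sigma**2), 0.0)
    np.fill_diagonal(W, 0.0)
    np.clip(W, 0.0, 1.0, out=W)
    U = np.triu(W, 1)  # exact symmetry
    return U + U.T


class QStepNetworkBuilder(BaseEstimator, TransformerMixin):
    """Transform disease seed indicators into a disease-disease weight matrix.

    The transformer takes a binary disease x protein indicator matrix
    ``X`` (rows = diseases, columns = the protein universe in the order of
    `adjacency`), expands each row by q-step walks on the PPI graph, and
    returns the symmetric weight matrix of the layer ``q`` network — or,
    with ``integrate=True``, of the integrated network piling up layers
    ``0..q``.

    Parameters
    ----------
    adjacency : sparse or dense (p, p) boolean matrix
        PPI adjacency over the protein universe.  Passed at construction
        like the ``connectivity`` matrix of agglomerative clustering.
    q : int, default 3
        Walk length.
    sigma : float, default 1.0
        Gaussian bandwidth of the similarity kernel.
    integrate : bool, default False
        Sum layers 0..q and rescale by the maximum entry.
    comparison : {"one-sided", "mutual"}, default "one-sided"
        Whether the expanded vector is compared against the other
        disease's seed vector or against its expanded vector.
    expansion : {"cumulative", "exact"}, default "cumulative"
        Reachability within q steps, or the distance-q frontier only.
    """

    def __init__(
        self,
        adjacency=None,
        q: int = 3,
        sigma: float = 1.0,
        integrate: bool = False,
        comparison: str = "one-sided",
        expansion: str = "cumulative",
    ):
        self.adjacency = adjacency
        self.q = q
        self.sigma = sigma
        self.integrate = integrate
        self.comparison = comparison
        self.expansion = expansion

    def _validate(self, X):
        if self.adjacency is None:
            raise ValueError("adjacency matrix is required")
        if self.q < 0:
            raise ValueError("q must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.comparison not in ("one-sided", "mutual"):
            raise ValueError("comparison must be 'one-sided' or 'mutual'")
        if self.expansion not in ("cumulative", "exact"):
            raise ValueError("expansion must be 'cumulative' or 'exact'")
        X = np.asarray(X).astype(bool)
        A = sp.csr_array(self.adjacency).astype(bool)
        if X.ndim != 2 or X.shape[1] != A.shape[0]:
            raise ValueError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"adjacency is {A.shape[0]}x{A.shape[1]}"
            )
        if not X.any(axis=1).all():
            raise ValueError("every disease needs at least one seed protein")
        return X, A

    def fit(self, X, y=None):
        X, _ = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Weight matrix of shape (n_diseases, n_diseases)."""
        X0, A = self._validate(X)
        qs = range(self.q + 1) if self.integrate else (self.q,)
        total = None
        for q in qs:
            Xq = _expand_indicator(X0, A, q, self.expansion)
            base = X0 if self.comparison == "one-sided" else None
            W = _pairwise_weights(Xq, base, self.sigma)
            total = W if total is None else total + W
        if self.integrate and total.max() > 0:
            total = total / total.max()
        U = np.triu(total, 1)
        return U + U.T

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)


def build_layer_network(
    vectors: DiseaseLayerVectors,
    sigma: float = 1.0,
    base: DiseaseLayerVectors | None = None,
) -> DiseaseNetwork:
    """Disease network from expanded layer vectors.

    Two diseases are connected when their (expanded) vectors share at
    least one protein; the weight is the Gaussian of their cosine
    distance.  When `base` is given (normally the q=0 seed vectors), the
    comparison is one-sided: each disease's expanded row against the
    other's base row, keeping the smaller distance of the two directions.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if base is not None:
        if base.diseases != vectors.diseases or base.protein_universe != vectors.protein_universe:
            raise ValueError("base vectors must share diseases and protein universe")
        W = _pairwise_weights(vectors.indicator, base.indicator, sigma)
    else:
        W = _pairwise_weights(vectors.indicator, None, sigma)
    return DiseaseNetwork(vectors.diseases, W, layer_tag=f"q={vectors.q}")


def build_network(
    graph: ProteinGraph,
    seed_map: DiseaseSeedMap,
    q: int,
    sigma: float = 1.0,
    comparison: str = "one-sided",
    expansion: str = "cumulative",
) -> DiseaseNetwork:
    """Single-layer disease network at walk length q (thin estimator wrapper)."""
    vectors = expand_vectors(seed_map, graph, q, expansion)
    if comparison == "one-sided":
        base = expand_vectors(seed_map, graph, 0, "cumulative")
        return build_layer_network(vectors, sigma, base=base)
    if comparison == "mutual":
        return build_layer_network(vectors, sigma)
    raise ValueError("comparison must be 'one-sided' or 'mutual'")


def build_layers(
    graph: ProteinGraph,
    seed_map: DiseaseSeedMap,
    qs: Iterable[int],
    sigma: float = 1.0,
    comparison: str = "one-sided",
    expansion: str = "cumulative",
) -> list[DiseaseNetwork]:
    """One network per walk length in `qs`."""
    return [
        build_network(graph, seed_map, q, sigma, comparison, expansion) for q in qs
    ]


def integrate_networks(layers: Sequence[DiseaseNetwork]) -> DiseaseNetwork:
    """Pile layer networks up: element-wise sum, rescaled by the maximum.

    All layers must cover the same disease set; they are aligned to the
    first layer's ordering.  The result keeps weights in [0, 1].
    """
    if not layers:
        raise ValueError("no layers to integrate")
    first = layers[0]
    total = np.zeros_like(first.weights)
    for layer in layers:
        if set(layer.diseases) != set(first.diseases):
            raise ValueError("layers cover different disease sets")
        total += layer.reorder(first.diseases).weights
    if total.max() > 0:
        total = total / total.max()
    tags = [layer.layer_tag for layer in layers]
    qvals = []
    for t in tags:
        if t.startswith("q=") and t[2:].isdigit():
            qvals.append(int(t[2:]))
    if len(qvals) == len(tags) and qvals:
        tag = f"integrated {min(qvals)}~{max(qvals)}"
    else:
        tag = "integrated " + "+".join(tags)
    return DiseaseNetwork(first.diseases, total, layer_tag=tag)


def network_density(network: DiseaseNetwork) -> float:
    """Percentage of unordered disease pairs that carry an edge."""
    n = network.n_diseases
    if n < 2:
        raise ValueError("density undefined for fewer than 2 diseases")
    return 100.0 * network.n_edges / (n * (n - 1) / 2)
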