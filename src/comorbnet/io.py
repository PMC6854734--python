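"""Domain containers and file I/O for disease-network analysis.

The package works with three kinds of input, all plain tab-separated text
with ``#`` comment lines:

* a protein-protein interaction (PPI) edge list (two columns of protein
  identifiers, one undirected interaction per line),
* a disease-protein association table (disease identifier, protein
  identifier), and
* an optional table of known comorbid disease pairs used as evaluation
  ground truth.

Identifiers are opaque, case-sensitive strings; no vocabulary semantics
(MeSH, Entrez, ...) are enforced.  Loading is order-insensitive: permuting
the lines of any input yields an equal in-memory object.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinGraph",
    "DiseaseSeedMap",
    "DiseaseNetwork",
    "ComorbidityLabels",
    "load_ppi",
    "load_disease_proteins",
    "load_comorbidity",
    "write_network",
    "read_network",
]

#: tolerance used when validating symmetry of weight matrices
SYMMETRY_TOL = 1e-12


def _data_lines(path):
    """Yield ``(lineno, line)`` for non-empty, non-comment lines."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _split_columns(line, lineno, path, n_cols):
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) != n_cols:
        raise ValueError(
            f"{path}: line {lineno}: expected {n_cols} columns, got {len(fields)}"
        )
    return fields


class ProteinGraph:
    """Undirected, unweighted protein-protein interaction graph.

    Parameters
    ----------
    proteins : iterable of str
        Protein identifiers (node set).  Duplicates are collapsed; first
        occurrence fixes insertion order.
    edges : iterable of (str, str)
        Undirected interactions.  ``(a, b)`` and ``(b, a)`` are the same
        edge.  Endpoints must appear in `proteins`; self-loops are rejected
        (they add no inter-protein path).
    """

    def __init__(self, proteins: Iterable[str], edges: Iterable[tuple[str, str]]):
        g = nx.Graph()
        g.add_nodes_from(proteins)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop edge on protein {a!r}")
            if a not in g or b not in g:
                missing = a if a not in g else b
                raise ValueError(f"edge references unknown protein {missing!r}")
            g.add_edge(a, b)
        self._g = g

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edge set as sorted 2-tuples (one entry per undirected edge)."""
        return {tuple(sorted(e)) for e in self._g.edges}

    @property
    def n_proteins(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def neighbors(self, protein: str) -> set[str]:
        return set(self._g.adj[protein])

    def to_networkx(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (treat as read-only)."""
        return self._g

    def adjacency(self, order: tuple[str, ...] | None = None):
        """Boolean sparse adjacency matrix in the given protein order."""
        nodes = list(order) if order is not None else list(self._g.nodes)
        return nx.to_scipy_sparse_array(self._g, nodelist=nodes, dtype=bool, format="csr")

    def __eq__(self, other) -> bool:  # set semantics: input order irrelevant
        if not isinstance(other, ProteinGraph):
            return NotImplemented
        return set(self.proteins) == set(other.proteins) and self.edges == other.edges

    def __repr__(self) -> str:
        return f"ProteinGraph(n_proteins={self.n_proteins}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class DiseaseSeedMap:
    """Bipartite disease -> seed-protein mapping.

    ``seeds[d]`` is the non-empty set of proteins directly recorded as
    associated with disease ``d`` (the '1' entries of the binary disease
    vector before any walk expansion).  Diseases are kept in sorted order
    so that matrix layouts are deterministic.
    """

    seeds: Mapping[str, frozenset[str]]
    diseases: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        clean = {d: frozenset(s) for d, s in self.seeds.items()}
        for d, s in clean.items():
            if not s:
                raise ValueError(f"disease {d!r} has no seed proteins")
        object.__setattr__(self, "seeds", clean)
        object.__setattr__(self, "diseases", tuple(sorted(clean)))

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiseaseSeedMap):
            return NotImplemented
        return dict(self.seeds) == dict(other.seeds)


class DiseaseNetwork:
    """Symmetric, non-negative disease-disease weight matrix, zero diagonal.

    Parameters
    ----------
    diseases : tuple of str
        Node labels, fixing row/column order of `weights`.
    weights : ndarray of shape (n, n)
        Edge weights in ``[0, 1]``.  Must be symmetric to within 1e-12
        (stored exactly symmetrized) with an exactly-zero diagonal.
    layer_tag : str
        Provenance label, e.g. ``"q=2"`` or ``"integrated 0~3"``.
    """

    def __init__(self, diseases: Iterable[str], weights: np.ndarray, layer_tag: str = ""):
        diseases = tuple(diseases)
        W = np.asarray(weights, dtype=float)
        n = len(diseases)
        if W.shape != (n, n):
            raise ValueError(f"weights shape {W.shape} does not match {n} diseases")
        if len(set(diseases)) != n:
            raise ValueError("duplicate disease identifiers")
        if n and np.abs(W - W.T).max() > SYMMETRY_TOL:
            raise ValueError("weight matrix is not symmetric within 1e-12")
        if n and np.abs(np.diag(W)).max() != 0.0:
            raise ValueError("weight matrix diagonal must be exactly zero")
        if n and (W.min() < 0 or W.max() > 1 + SYMMETRY_TOL):
            raise ValueError("weights must lie in [0, 1]")
        # store exactly symmetric
        U = np.triu(W, 1)
        self.weights = U + U.T
        self.diseases = diseases
        self.layer_tag = layer_tag
        self._index = {d: i for i, d in enumerate(diseases)}

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def index(self, disease: str) -> int:
        return self._index[disease]

    def reorder(self, diseases: Iterable[str]) -> "DiseaseNetwork":
        """Same network with rows/columns permuted to the given order."""
        diseases = tuple(diseases)
        if set(diseases) != set(self.diseases):
            raise ValueError("reorder must use the same disease set")
        idx = [self._index[d] for d in diseases]
        return DiseaseNetwork(diseases, self.weights[np.ix_(idx, idx)], self.layer_tag)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiseaseNetwork):
            return NotImplemented
        if set(self.diseases) != set(other.diseases):
            return False
        aligned = other.reorder(self.diseases)
        return bool(np.allclose(self.weights, aligned.weights, rtol=0, atol=SYMMETRY_TOL))

    def __repr__(self) -> str:
        return (
            f"DiseaseNetwork(n_diseases={self.n_diseases}, n_edges={self.n_edges}, "
            f"layer_tag={self.layer_tag!r})"
        )


@dataclass(frozen=True)
class ComorbidityLabels:
    """Unordered disease pairs known to co-occur (evaluation ground truth)."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self):
        norm = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} is not a comorbidity")
            norm.add((min(a, b), max(a, b)))
        object.__setattr__(self, "pairs", frozenset(norm))

    @property
    def diseases(self) -> set[str]:
        return {d for pair in self.pairs for d in pair}

    def partners(self, disease: str) -> set[str]:
        return {b if a == disease else a for a, b in self.pairs if disease in (a, b)}

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def load_ppi(path, drop_self_loops: bool = True) -> ProteinGraph:
    """Read an undirected PPI edge list (two tab-separated columns).

    Duplicate lines and reversed duplicates collapse to a single edge.
    Self-loop lines are dropped (default) or raise, per `drop_self_loops`.
    """
    proteins: dict[str, None] = {}
    edges: set[tuple[str, str]] = set()
    n_lines = n_dup = n_self = 0
    for lineno, line in _data_lines(path):
        a, b = _split_columns(line, lineno, path, 2)
        n_lines += 1
        if a == b:
            if not drop_self_loops:
                raise ValueError(f"{path}: line {lineno}: self-loop on {a!r}")
            n_self += 1
            proteins.setdefault(a)
            continue
        proteins.setdefault(a)
        proteins.setdefault(b)
        edge = (min(a, b), max(a, b))
        if edge in edges:
            n_dup += 1
        else:
            edges.add(edge)
    if n_lines == 0:
        raise ValueError(f"{path}: no interaction lines found")
    logger.info(
        "load_ppi(%s): %d lines, %d edges, %d duplicate lines dropped, "
        "%d self-loops dropped",
        path, n_lines, len(edges), n_dup, n_self,
    )
    return ProteinGraph(proteins, sorted(edges))


def load_disease_proteins(
    path, graph: ProteinGraph, missing_proteins: str = "drop"
) -> DiseaseSeedMap:
    """Read a disease-protein association table against a companion graph.

    Seed proteins absent from `graph` are reported and dropped
    (``missing_proteins="drop"``, default) or kept as isolated seeds
    (``"keep"``).  Diseases left with no seeds are excluded with a warning
    — mirroring the restriction of a disease list to entries with at least
    one protein relationship.
    """
    if missing_proteins not in ("drop", "keep"):
        raise ValueError("missing_proteins must be 'drop' or 'keep'")
    raw: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        disease, protein = _split_columns(line, lineno, path, 2)
        raw.setdefault(disease, set()).add(protein)
    if not raw:
        raise ValueError(f"{path}: no association lines found")

    seeds: dict[str, frozenset[str]] = {}
    n_missing = 0
    excluded = []
    for disease, prots in raw.items():
        absent = {p for p in prots if p not in graph}
        n_missing += len(absent)
        kept = prots if missing_proteins == "keep" else prots - absent
        if kept:
            seeds[disease] = frozenset(kept)
        else:
            excluded.append(disease)
    if n_missing:
        logger.warning(
            "load_disease_proteins(%s): %d seed proteins absent from the PPI "
            "graph (%s)", path, n_missing, missing_proteins + "ped" if missing_proteins == "drop" else "kept isolated",
        )
    if excluded:
        logger.warning(
            "load_disease_proteins(%s): excluded %d diseases with no in-graph "
            "seeds: %s", path, len(excluded), ", ".join(sorted(excluded)),
        )
    if not seeds:
        raise ValueError(f"{path}: every disease was filtered out")
    return DiseaseSeedMap(seeds)


def load_comorbidity(path, diseases: Iterable[str]) -> ComorbidityLabels:
    """Read known-comorbid disease pairs, restricted to a disease universe."""
    universe = set(diseases)
    pairs = set()
    n_dropped = 0
    for lineno, line in _data_lines(path):
        a, b = _split_columns(line, lineno, path, 2)
        if a == b:
            n_dropped += 1
            continue
        if a in universe and b in universe:
            pairs.add((min(a, b), max(a, b)))
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning(
            "load_comorbidity(%s): dropped %d pairs outside the disease set",
            path, n_dropped,
        )
    return ComorbidityLabels(frozenset(pairs))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_network(
    network: DiseaseNetwork,
    path,
    fmt: str = "tsv",
    header_lines: Iterable[str] = (),
) -> None:
    """Write a disease network as a TSV triplet list or GraphML.

    The TSV format lists each undirected edge once (``disease_a``,
    ``disease_b``, ``weight``) and records the full node list and layer tag
    in ``#`` comment lines so that isolated diseases round-trip.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph(layer_tag=network.layer_tag)
        g.add_nodes_from(network.diseases)
        W = network.weights
        for i, j in zip(*np.nonzero(np.triu(W, 1))):
            g.add_edge(network.diseases[i], network.diseases[j], weight=float(W[i, j]))
        nx.write_graphml(g, path)
        return
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# layer_tag: {network.layer_tag}\n")
        fh.write("# diseases: " + "|".join(network.diseases) + "\n")
        fh.write("# disease_a\tdisease_b\tweight\n")
        W = network.weights
        for i, j in zip(*np.nonzero(np.triu(W, 1))):
            fh.write(
                f"{network.diseases[i]}\t{network.diseases[j]}\t{W[i, j]:.17g}\n"
            )


def read_network(path) -> DiseaseNetwork:
    """Read a disease network written by :func:`write_network` (TSV or GraphML)."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        diseases = tuple(g.nodes)
        n = len(diseases)
        idx = {d: i for i, d in enumerate(diseases)}
        W = np.zeros((n, n))
        for a, b, data in g.edges(data=True):
            w = float(data.get("weight", 1.0))
            W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
        return DiseaseNetwork(diseases, W, g.graph.get("layer_tag", ""))

    diseases: tuple[str, ...] | None = None
    layer_tag = ""
    triplets: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("layer_tag:"):
                    layer_tag = body[len("layer_tag:"):].strip()
                elif body.startswith("diseases:"):
                    listed = body[len("diseases:"):].strip()
                    diseases = tuple(listed.split("|")) if listed else ()
                continue
            a, b, w = _split_columns(line, lineno, path, 3)
            triplets.append((a, b, float(w)))
    if diseases is None:
        diseases = tuple(sorted({d for a, b, _ in triplets for d in (a, b)}))
    idx = {d: i for i, d in enumerate(diseases)}
    n = len(diseases)
    W = np.zeros((n, n))
    for a, b, w in triplets:
        if a not in idx or b not in idx:
            raise ValueError(f"{path}: edge ({a}, {b}) references unlisted disease")
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return DiseaseNetwork(diseases, W, layer_tag)
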