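"""Synthetic inputs: a six-protein toy fixture and planted-module data.

The toy fixture is a minimal worked example: six proteins in two PPI
components, three diseases whose seed sets only become mutually reachable
as the walk length grows (D_B and D_C share a protein outright; D_A needs
a 1-step walk to reach them and a 3-step walk to cover everything).

The random generator emulates the premise that comorbid diseases share
proteins or nearby PPI neighborhoods.  Diseases are partitioned into
modules; each module owns a pool of proteins that is densely wired
internally and holds a shared "core" seed set.  A disease keeps each core
protein with probability `intra_module_protein_overlap` and otherwise
swaps it for a pool protein not used by its module siblings, so

* overlap = 1 makes within-module seed sets identical (associated already
  at q = 0), and
* overlap = 0 makes them disjoint — invisible at q = 0, but recoverable
  at q >= 1 through the dense wiring of the module pool.

All within-module disease pairs form the comorbidity ground truth.
Background proteins (outside every pool) and sparse background edges add
realistic off-module reachability at larger q.  Everything is determined
by the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ComorbidityLabels, DiseaseSeedMap, ProteinGraph

__all__ = ["SyntheticSpec", "fig5_toy", "generate"]


def fig5_toy() -> tuple[ProteinGraph, DiseaseSeedMap]:
    """The six-protein, three-disease worked example.

    Graph: P1-P2, P3-P4, P4-P5, P5-P6.  Seeds: D_A {P2, P3},
    D_B {P1}, D_C {P1}.
    """
    graph = ProteinGraph(
        proteins=[f"P{i}" for i in range(1, 7)],
        edges=[("P1", "P2"), ("P3", "P4"), ("P4", "P5"), ("P5", "P6")],
    )
    seeds = DiseaseSeedMap(
        {
            "D_A": frozenset({"P2", "P3"}),
            "D_B": frozenset({"P1"}),
            "D_C": frozenset({"P1"}),
        }
    )
    return graph, seeds


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module generator.

    Defaults give 60 diseases in 6 modules over 600 proteins with 30%
    seed overlap — small enough to evaluate in seconds, large enough for
    the layer-density and scoring contrasts to be measurable.
    """

    n_diseases: int = 60
    n_proteins: int = 600
    n_modules: int = 6
    seeds_per_disease: tuple[int, int] = (3, 6)
    intra_module_protein_overlap: float = 0.3
    ppi_edge_prob: float = 0.005
    module_edge_prob: float = 0.25
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.seeds_per_disease
        if not (1 <= lo <= hi):
            raise ValueError("seeds_per_disease must be a range with 1 <= lo <= hi")
        if not (1 <= self.n_modules <= self.n_diseases):
            raise ValueError("need 1 <= n_modules <= n_diseases")
        if not (0.0 <= self.intra_module_protein_overlap <= 1.0):
            raise ValueError("overlap must lie in [0, 1]")
        if not (0.0 < self.ppi_edge_prob < 1.0):
            raise ValueError("ppi_edge_prob must lie in (0, 1)")
        if not (0.0 < self.module_edge_prob <= 1.0):
            raise ValueError("module_edge_prob must lie in (0, 1]")

    @property
    def pool_size(self) -> int:
        # each module pool gets an equal share of 3/4 of the proteins;
        # the rest are background
        return (3 * self.n_proteins) // (4 * self.n_modules)


def _random_edges(rng, nodes, prob):
    """Bernoulli edges over all unordered pairs of `nodes`."""
    nodes = list(nodes)
    iu = np.triu_indices(len(nodes), 1)
    mask = rng.random(len(iu[0])) < prob
    return {(nodes[i], nodes[j]) for i, j in zip(iu[0][mask], iu[1][mask])}


def generate(
    spec: SyntheticSpec,
) -> tuple[ProteinGraph, DiseaseSeedMap, ComorbidityLabels]:
    """Generate (PPI graph, seed map, within-module comorbidity labels)."""
    lo, hi = spec.seeds_per_disease
    if spec.pool_size < hi:
        raise ValueError(
            f"module pool ({spec.pool_size} proteins) smaller than the maximum "
            f"seeds per disease ({hi})"
        )
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_proteins)))
    proteins = [f"P{i:0{width}d}" for i in range(spec.n_proteins)]
    dwidth = max(2, len(str(spec.n_diseases)))
    diseases = [f"D{i:0{dwidth}d}" for i in range(spec.n_diseases)]

    pools = [
        proteins[m * spec.pool_size:(m + 1) * spec.pool_size]
        for m in range(spec.n_modules)
    ]

    # module assignment: contiguous, nearly equal blocks
    assignment = np.array_split(np.arange(spec.n_diseases), spec.n_modules)

    # PPI edges: dense within each module pool, sparse everywhere
    edges: set[tuple[str, str]] = set()
    for pool in pools:
        edges |= _random_edges(rng, pool, spec.module_edge_prob)
    edges |= _random_edges(rng, proteins, spec.ppi_edge_prob)
    graph = ProteinGraph(proteins, sorted(edges))

    seeds: dict[str, frozenset[str]] = {}
    overlap = spec.intra_module_protein_overlap
    for m, members in enumerate(assignment):
        pool = pools[m]
        s = int(rng.integers(lo, hi + 1))
        core = [str(p) for p in rng.choice(pool, size=s, replace=False)]
        # replacements disjoint across module members while supply lasts
        spare = [p for p in pool if p not in core]
        rng.shuffle(spare)
        spare_iter = iter(spare)
        for i in members:
            chosen = []
            for c in core:
                if rng.random() < overlap:
                    chosen.append(c)
                else:
                    nxt = next(spare_iter, None)
                    if nxt is None:  # pool exhausted: fall back to reuse
                        nxt = str(rng.choice(spare))
                    chosen.append(nxt)
            seeds[diseases[i]] = frozenset(chosen)
    seed_map = DiseaseSeedMap(seeds)

    pairs = set()
    for members in assignment:
        names = [diseases[i] for i in members]
        for a_i in range(len(names)):
            for b_i in range(a_i + 1, len(names)):
                pairs.add((names[a_i], names[b_i]))
    labels = ComorbidityLabels(frozenset(pairs))
    return graph, seed_map, labels
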