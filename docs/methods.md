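# Methods

## Model

### Disease networks from q-step walks

Input is an undirected, unweighted PPI graph over proteins and a bipartite
disease → seed-protein map. Disease *i* at step 0 is the binary indicator
vector **x**ᵢ⁽⁰⁾ of its seed proteins. The q-step expansion **x**ᵢ⁽q⁾ marks
every protein at shortest-path distance ≤ q from a seed. (In a simple
undirected graph a walk of length q from u to v exists whenever
dist(u, v) ≤ q once reachability is taken cumulatively, so BFS distance is
the right primitive; no walk enumeration is needed.)

Two diseases are *associated at layer q* when a walk of length ≤ q joins a
protein of one to a protein of the other, i.e. when the q-expanded vector
of either disease overlaps the other's **seed** vector. The edge weight is
the Gaussian-of-cosine similarity

    w_ij = exp(−dist(x_i, x_j)/σ²)  if associated, else 0,
    dist(x, y) = 1 − x·y/(‖x‖‖y‖),

computed between the expanded vector of one disease and the seed vector of
the other, taking the smaller distance of the two directions so that W is
exactly symmetric. This *one-sided* pairing is the default (`comparison=
"one-sided"`); the alternative that expands both vectors before comparison
(`"mutual"`) is available but associates diseases whose seeds are up to 2q
edges apart, which changes the effective walk length of a layer. On the
six-protein toy system the one-sided convention gives the D_A–D_B weight
e^(−0.5) at q = 1 (expanded D_A = {P1..P4} against seed D_B = {P1}).

An *exact* expansion variant (`expansion="exact"`) uses only the
distance-q frontier instead of cumulative reachability; cumulative is the
default because it makes layer edge sets, and hence layer densities,
monotone in q.

The integrated network 0~q is the element-wise sum of layers 0..q rescaled
by its maximum entry, keeping weights in [0, 1]. Summation is used for
"piling up" layers because it preserves multiplicity of evidence: a pair
associated in several layers outweighs a pair associated in one.

### Semi-supervised scoring

Given W and unary labels y (1 on the primary diseases, 0 elsewhere),
scores minimize H(f) = (f−y)ᵀ(f−y) + μ fᵀLf with L = D − W. Two solvers:

* **full** — the unconstrained minimizer f = (I + μL)⁻¹y. Labeled scores
  are shrunk below 1.
* **clamped** (default) — fix f_l = y_l and solve the unlabeled block
  f_u = μ{I + μ(D_uu − W_uu)}⁻¹ W_ul y_l, where D_uu holds the *full*
  degrees (over labeled and unlabeled neighbors alike). These are different
  estimators, not algebraic rearrangements of each other; clamped is the
  default because co-occurrence scoring treats the primary disease as
  certain. With non-negative weights the clamped scores obey 0 ≤ f_u < 1,
  strictly positive exactly when a positive-weight path reaches a label.

Both systems are symmetric positive definite and are solved with a dense
SPD factorization (`scipy.linalg.solve(..., assume_a="pos")`); the
correctness contract is agreement with an independent dense solve to
1e-10, which the test suite checks on random instances up to n = 50.

Scores become probabilities through Prob(u|l) = 1/(1 + exp(−f_u/σ_f))
after normalization (z-score by default; min-max and none available; a
zero-variance normalization falls back to raw scores with a warning). The
transform is strictly monotone, so rankings are decided by the scores;
ties are broken lexicographically by disease identifier.

## Parameters

| parameter | default | meaning |
|---|---|---|
| q | 3 | walk length; layer densities grow with q, and beyond the point where components are covered nothing changes |
| σ (sigma) | 1.0 | Gaussian bandwidth on cosine distance (distance is dimensionless in [0,1]) |
| μ (mu) | 100 | loss–smoothness tradeoff; large values emphasise propagation through the network over fidelity to the 0 labels of unlabeled nodes |
| σ_f (sigma_f) | 1.0 | sigmoid scale for the probability transfer |
| comparison | one-sided | layer pairing convention (above) |
| expansion | cumulative | reachability ≤ q vs distance-exactly-q frontier |
| normalization | zscore | score normalization before the sigmoid |

σ and σ_f have no canonical value for this construction; 1.0 is the
neutral choice since cosine distances and normalized scores are already
O(1). μ = 100 is the standard "hard propagation" regime for this kind of
scoring.

## Evaluation protocol

For every disease d with known comorbid partners: label only d, score all
other diseases, and compute the Mann–Whitney AUC (ties 0.5, via
`sklearn.metrics.roc_auc_score`) with positives = the recorded partners of
d and negatives = all remaining scored diseases. The report aggregates
per-disease AUCs (mean, sample standard deviation). Absence of a recorded
pair is treated as a negative even though it may merely be unobserved — a
limitation inherited from literature-derived comorbidity labels.

The chance baseline randomizes the network while preserving each node's
degree: double edge swaps on the binarized topology (10× the edge count by
default, the standard mixing heuristic), then a seeded random permutation
of the weight multiset onto the new edges. How weights should move under
degree-preserving shuffling is underdetermined; permuting the multiset
destroys weight–position correlation while preserving the weight
distribution, which is the property the baseline needs. A complete
topology admits no swap, so only the weight permutation randomizes it —
which is exactly its unique degree-preserving configuration. Degree
sequence and edge count are asserted on every call.

Paired two-sided t-tests (`scipy.stats.ttest_rel`) compare per-trial AUC
lists between network variants. Degenerate inputs follow a fixed
convention: identical lists → (t = 0, p = 1); constant non-zero
differences → (±inf, 0).

The repeated k-fold variant partitions the labeled diseases into k folds
per repeat (seeded permutation), labels each fold jointly, and measures
the AUC of recovering any fold member's partners among the non-fold
diseases; with singleton folds it reduces exactly to leave-one-out.

## Synthetic data

The generator plants the structure the method is designed to detect:
comorbid diseases share proteins or nearby PPI neighborhoods. Diseases are
split into modules; each module owns a protein pool (3/4 of the proteins
are divided into pools, the rest are background) that is densely wired
internally (edge probability 0.25) on top of a sparse global background
(0.005). Each module draws a core seed set; a disease keeps each core
protein with probability `intra_module_protein_overlap` (default 0.3) and
otherwise replaces it with a pool protein unused by its module siblings.
Consequently overlap 1 forces identical within-module seed sets (modules
visible at q = 0) and overlap 0 forces disjoint seed sets (modules
invisible at q = 0, recovered at q ≥ 1 through the pool wiring). All
within-module pairs form the comorbidity ground truth. A single seeded
`numpy` generator drives everything, so outputs are reproducible
byte-for-byte.

Defaults (60 diseases, 6 modules, 600 proteins) keep the full pipeline —
generation, four layers, integration, 60-trial LOO, five randomized
baselines — under a few seconds on one core while leaving room between
the planted signal (mean LOO AUC near 1) and the chance baseline (≈ 0.5).

What the generator does **not** emulate: scale-free PPI degree
distributions, overlapping or hierarchical disease categories, noisy or
spurious disease–protein records, and cross-module comorbidity. Passing
tests therefore demonstrate correctness of the algorithms and
recoverability of clean planted structure, not performance on curated
biological databases.

## Numerical choices

* Weight matrices are stored exactly symmetric (upper triangle mirrored);
  validation tolerates 1e-12 asymmetry on input.
* Cosine distances within 1e-12 of 0 snap to exactly 0 so that identical
  vectors give weight exactly 1.
* Degenerate probability normalizations warn and fall back to raw scores.
* Rankings break ties lexicographically by disease identifier, making all
  outputs deterministic.
* Readers treat `#` lines as comments, deduplicate repeated records, and
  are insensitive to input line order; diseases are kept sorted so matrix
  layouts never depend on file order.

## Limitations

* The one-sided/mutual duality reflects a genuine ambiguity in how a
  q-step layer should compare two diseases; both are provided rather than
  adjudicated.
* The full and clamped solvers give different scores; results should name
  which solver produced them (the `method_tag` of a result does).
* LOO negatives include unsurveyed pairs (see above).
* Layer construction is dense in the number of diseases (n² pair
  comparisons); the intended scale is hundreds to a few thousand diseases.
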