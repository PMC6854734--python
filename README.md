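# comorbnet

Disease co-occurrence networks from protein interactions.

Many disease classes — metabolic diseases in particular — look almost
unconnected in gene-sharing disease networks because few disease–protein
associations are recorded for them. `comorbnet` addresses this in two steps:

1. **Network construction by q-step walks.** Each disease *i* is a binary
   vector **x**ᵢ over the protein universe (1 where a seed protein is
   recorded). Expanding the vector along walks of length ≤ *q* on the
   protein–protein interaction (PPI) graph adds proteins reachable from the
   seeds, so diseases whose proteins merely *interact* — directly or through
   a few intermediaries — become associated. The edge weight between two
   associated diseases is a Gaussian of their cosine distance,

   ```
   w_ij = exp(-dist(x_i, x_j) / σ²),   dist(x, y) = 1 − x·y / (‖x‖‖y‖),
   ```

   giving one weighted disease network per walk length (`q = 0` reduces to
   the classical shared-gene network). Layers 0..q can be *integrated*
   (element-wise sum, rescaled into [0, 1]) into a single denser network.

2. **Semi-supervised co-occurrence scoring.** Given one or more primary
   diseases labeled y = 1 on the network, scores f for the remaining
   diseases minimize the loss-plus-smoothness objective
   `H(f) = (f−y)ᵀ(f−y) + μ fᵀLf` with graph Laplacian `L = D − W`. The
   default solver clamps the labeled scores to 1 and solves the unlabeled
   block, `f_u = μ{I + μ(D_uu − W_uu)}⁻¹ W_ul y_l`; scores map to
   co-occurrence probabilities through `1/(1 + exp(−f_u/σ_f))` after
   normalization.

Evaluation follows a leave-one-out protocol against known comorbid pairs:
label one disease, rank all others, and measure by AUC how well its recorded
comorbid partners rise to the top — compared against a degree-preserving
randomization of the network (the chance baseline).

The package is aimed at computational biologists studying disease–disease
association networks, and ships a synthetic planted-module generator so the
whole pipeline runs without any database downloads.

## Worked example

The six-protein toy system has PPI edges P1–P2, P3–P4, P4–P5, P5–P6 and
three diseases: D_A (seeds P2, P3), D_B (P1), D_C (P1).

```python
import math
from comorbnet import fig5_toy, build_network, score_diseases

graph, seeds = fig5_toy()

n0 = build_network(graph, seeds, q=0)
print(n0.n_edges)                                   # 1
print(n0.weights[n0.index("D_B"), n0.index("D_C")]) # 1.0

n1 = build_network(graph, seeds, q=1)
print(n1.weights[n1.index("D_A"), n1.index("D_B")]) # 0.6065306597126334
print(math.exp(-0.5))                               # 0.6065306597126334

res = score_diseases(n1, primary={"D_B"}, mu=100.0)
print(res.ranking)                                  # ('D_C', 'D_A')
```

At `q = 0` only D_B–D_C share a protein (identical vectors, distance 0,
weight 1). A 1-step walk lets D_A reach P1 and P4, so its expanded vector
(norm 2) overlaps D_B's seed vector (norm 1) in one protein: distance
1 − 1/2, weight e^(−0.5). Scoring from D_B ranks D_C (direct partner) above
D_A.

The same pipeline from the shell:

```sh
comorbnet simulate --out-dir data             # planted-module synthetic data
comorbnet build-network --ppi data/ppi.tsv \
    --disease-proteins data/disease_proteins.tsv \
    --q 3 --integrate --out network.tsv --report-density density.tsv
comorbnet score --network network.tsv --primary D00 --out scores.tsv
comorbnet evaluate --network network.tsv --comorbidity data/comorbidity.tsv \
    --randomized-baseline --out eval.tsv
```

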