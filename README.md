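# graphfae

Graph feature auto-encoders for predicting unobserved node features on
molecular interaction networks.

Molecular networks (transcription-factor–gene, protein–protein, genetic
interaction) describe which genes work together; omics experiments measure
how active each gene is across conditions or cells. `graphfae` joins the two
views with graph neural networks, for two tasks:

1. **Structural embedding** — a graph auto-encoder (GAE) learns a
   low-dimensional embedding `Z = Ã·ReLU(Ã·X·W₀)·W₁` of the network
   (`Ã = D^{-1/2}(A+I)D^{-1/2}` is the symmetrically normalised adjacency)
   by reconstructing edges through the inner-product decoder
   `Â = σ(ZZᵀ)`. The embedding is scored by held-out link prediction
   (AUC/AP) and by the fraction of expression variance a linear readout
   explains, and can feed an indirect regression `X̃ = f(Z)` (linear or
   random-forest).
2. **End-to-end feature prediction** — a graph feature auto-encoder (GFAE)
   is trained directly on masked mean-squared error to predict missing
   expression values `X̃ᵢ = W·hᵢ + b`, where the hidden state `hᵢ` comes from
   two message-passing layers. Four layer types are provided: a GCN
   message-passing layer, GraphSAGE (closed-neighbourhood mean), GraphConv
   (neighbour sum), and **FeatGraphConv** —
   `gᵢ = W₁hᵢ; h'ᵢ = W₂·(gᵢ ‖ Mean_{j∈N(i)∪i} gⱼ)` — which transforms
   features before pooling and keeps the node's own representation alongside
   its neighbourhood average, a design aimed at feature reconstruction
   rather than structure reconstruction.

All neural components run on a small built-in reverse-mode autodiff core
(NumPy), trained with Adam; baselines and metrics use scikit-learn. A
synthetic benchmark generates Erdős–Rényi or two-block graphs together with
feature matrices that mix a graph-diffused component with low-rank
gene-program structure, so every claim is testable without downloads.

Intended users: computational biologists exploring network/omics
integration, and method developers who want a dependency-light reference
implementation of feature-targeted graph convolution.

## Worked example

```python
import numpy as np
from graphfae import (SyntheticSpec, GFAEImputer, masked_mse,
                      make_imputation_masks)

graph, x = SyntheticSpec(n_experiments=100, seed=0).generate()
mask = make_imputation_masks(x, k=10, seed=0)[0]   # hide 10% of entries

est = GFAEImputer(layer="featgraphconv", epochs=1000, seed=0)
imputed = est.fit_transform(x.values, graph=graph,
                            observed_mask=mask.train_mask)
print("test MSE :", round(masked_mse(imputed, x.values, mask.test_mask), 4))
print("naive fill:", round(masked_mse(np.zeros_like(imputed), x.values,
                                      mask.test_mask), 4))
```

Output:

```
test MSE : 0.3332
naive fill: 1.1033
```

The imputer recovers hidden expression values with less than a third of the
error of filling with zeros; on the same data an edge-shuffled control graph
or a plain MLP auto-encoder gives a visibly worse MSE (see
`docs/methods.md` for the full benchmark).

The same models are available from a shell:

```sh
graphfae generate --nodes 300 --experiments 100 \
    --edges-out edges.tsv --expression-out expr.tsv
graphfae impute --edges edges.tsv --expression expr.tsv \
    --layer featgraphconv --layer gcn --epochs 1000 --run-folds 1
graphfae embed --setting expr-graph --edges edges.tsv --expression expr.tsv
```

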