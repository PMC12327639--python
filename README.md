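# contactgo

Protein function prediction from residue contact graphs with
**edge-supervised graph attention**.

## The problem

Annotating a protein with Gene Ontology (GO) terms — its molecular
functions (MF), biological processes (BP) and cellular components (CC) —
is a multi-label prediction task. Structure-based predictors convert a
protein into a *contact graph*: residues are nodes, and two residues are
connected when their Cα atoms lie within 10 Å. Graph neural networks then
learn a protein representation from this graph plus per-residue features
(protein-language-model embeddings such as ESM-2, or a one-hot fallback).

Standard graph attention (GAT) learns its edge weights *unsupervised*:
the attention coefficient e_ij is only shaped indirectly by the
classification loss. The idea implemented here is to additionally
*supervise* the same coefficient with the edge labels that are freely
available in the contact map itself — a self-supervised auxiliary task
that encodes residue contacts into the representation explicitly.

## The model

One network per GO category. For layer l with node features h_i^l:

    h_i^{l+1} = act( Σ_{j ∈ N_i ∪ {i}}  α_ij  W^l h_j^l )          (aggregation)

    α_ij = softmax_j( LeakyReLU(e_ij) )        over N_i ∪ {i}      (unsupervised branch)
    φ_ij = σ(e_ij)                                                 (supervised branch)

Both branches share one pairwise coefficient e_ij, generated by one of
four strategies:

| strategy | coefficient e_ij |
|----------|------------------|
| AD (additive)          | aᵀ [W h_i ‖ W h_j] |
| DP (dot-product)       | (W_s h_i)ᵀ (W_s h_j) |
| SD (scaled dot-product)| e_DP / F |
| MX (mixed, default)    | e_AD · σ(e_DP) |

After three attention layers, global max pooling and a two-layer MLP with
a sigmoid head emit one score per GO term. The loss is

    L = L_v + λ_E Σ_l L_E^l ,      λ_E = 0.01

where L_v is the multi-label binary cross-entropy of the term scores and
L_E^l is the binary cross-entropy of φ against edge existence, evaluated
on sampled residue pairs: negatives (non-contacts) at rate P_n = 0.6
relative to the contact count, then a joint retention sweep at rate
P_e = 0.2, re-drawn every epoch. Evaluation uses protein-centric Fmax,
micro-averaged AUPR (step integration) and ROC AUC (rank formulation).

The whole network — forward, analytic backward pass, Adam — is pure
numpy, validated against finite differences for all four strategies.

## Worked example

A synthetic benchmark (self-avoiding Cα chains → 10 Å contact graphs →
planted structural-motif labels) makes the whole pipeline runnable
without any downloads:

```python
import numpy as np
from contactgo import (
    SyntheticConfig, build_benchmark,
    reference_model_config, reference_train_settings, train,
    evaluate_model, evaluate, supervised_contact_auc,
)

bench = build_benchmark(SyntheticConfig(n_proteins=120, seed=7))
config = reference_model_config(n_terms=len(bench.vocabulary), feature_dim=32)
result = train(bench.train, bench.val, config, reference_train_settings(seed=7))

scores = evaluate_model(result.model, bench.test)
labels = np.stack([lab.labels for _, lab in bench.test])
report = evaluate(scores, labels)
print(f"best validation Fmax : {result.best_val_fmax:.3f} (epoch {result.best_epoch})")
print(f"test Fmax            : {report.fmax:.3f} at threshold {report.fmax_threshold:.2f}")
print(f"test AUPR (micro)    : {report.aupr:.3f}")
print(f"test AUC (macro)     : {report.auc:.3f}")
print(f"contact AUC, layer 1 : {supervised_contact_auc(result.model, bench.test):.3f}")
```

prints (about half a minute on one CPU):

```
best validation Fmax : 0.886 (epoch 31)
test Fmax            : 0.835 at threshold 0.34
test AUPR (micro)    : 0.904
test AUC (macro)     : 0.860
contact AUC, layer 1 : 0.730
```

Test Fmax is the maximum pooled F1 over decision thresholds — here the
model recovers most of the planted structure→function signal from 96
training proteins. The contact AUC measures how well the supervised
attention scores φ at the first layer rank true residue contacts above
non-contacts on held-out proteins.

## Command line

The same flow as a shell tool:

```bash
contactgo simulate --out data/ --n-proteins 300 --seed 0
contactgo train    --data data/ --out run/ --category MF --strategy MX
contactgo predict  --model run/checkpoint.npz --data data/ --split test --out preds.tsv
contactgo evaluate --predictions preds.tsv --labels data/labels.tsv --out report/
contactgo build-graphs --structures pdb_dir/ --out graphs/   # real structures → edge lists
```

Ablations are flags: `--no-edge-supervision` (drop the auxiliary loss),
`--no-unsup-attention` (uniform GCN-style aggregation); both together
degenerate the model into a plain GCN.

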