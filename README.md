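# multicent

Multi-centrality hub detection in protein–protein interaction (PPI)
networks.

Large interaction networks assembled around a biological theme (here: the
human proteins linked to vitamin metabolism, signaling and transcriptional
regulation, plus their direct interactors) are sparse, fragmented into
short branches, and centralized around a small, densely interconnected
backbone.  No single centrality index captures that backbone: degree is
local, betweenness is global, and they disagree on the middle.  `multicent`
profiles every protein with six indices spanning the scales and lets a
model-based clustering procedure decide, without an arbitrary cutoff, which
proteins are *multi-centrality hubs* — topologically dominant on all six at
once.

## The method

For an undirected, unweighted network the package computes, per protein:

| index | scale | definition |
|---|---|---|
| `D` | local | degree, number of interaction partners |
| `EC` | local | dominant adjacency eigenvector, rescaled to max 1 |
| `TI1`, `TI4` | meso | topological importance over walks of ≤ 1 / ≤ 4 steps |
| `B` | global | raw shortest-path betweenness (endpoints excluded) |
| `C` | global | closeness, (n−1) / Σ shortest-path distances |

Topological importance propagates *indirect interaction effects*: the
one-step effect of protein *j* on an adjacent protein *i* is 1/D<sub>i</sub>
(row-stochastic effect matrix **E**), multi-step effects are multiplicative
along walks and additive across parallel walks (powers of **E**), and

TI<sup>m</sup><sub>i</sub> = (1/m) · Σ<sub>q=1..m</sub> φ<sub>q,i</sub>,
φ<sub>q,i</sub> = Σ<sub>j≠i</sub> (**E**<sup>q</sup>)<sub>ji</sub>.

Each index column is rescaled to maximum 1 and the 6-dimensional profiles
are clustered with Gaussian mixtures: every covariance family ×
component-count candidate is fitted by seeded EM restarts and the
BIC-maximal model kept (BIC = 2·logL − p·log n, the mclust sign
convention).  The most central mixture component — highest mean across the
six normalized indices — is re-clustered once more; its most central
component is the hub set.

Companion analyses: Goodman–Kruskal rank association (gamma) between all
index pairs, an average-linkage dendrogram of index similarity, recovery
checks for 4-index subsets, degree-preserving / G(n,m) / small-world null
models, and annotation statistics (fat- vs water-soluble chi-squared,
transcription-factor chi-squared, Kolmogorov–Smirnov comparisons,
per-vitamin enrichment profiles).

A synthetic-data module generates planted-hub networks in the empirical
regime (density ≈ 0.002, diameter ≈ 10, assortative 20-hub backbone,
hub-enriched vitamin-D labels) with ground truth for parameter-recovery
testing.

## Worked example

The six indices on a 9-node toy tree — hub `b` bound to three branch
proteins, two of which carry leaf "clouds":

```python
>>> from multicent import centrality_table
>>> from multicent.datasets import toy_hub_tree
>>> t = centrality_table(toy_hub_tree()).loc["b"]
>>> print(f"D={t.D:.0f}  TI1={t.TI1:.2f}  B={t.B:.0f}  C={t.C:.3f}  EC={t.EC:.3f}")
D=3  TI1=1.58  B=19  C=0.615  EC=0.925
```

`b` has three partners (D = 3); their reciprocal degrees sum to
1 + 0.25 + 0.33 = TI¹ ≈ 1.58; 19 of the 28 protein pairs route their
shortest path through `b` (B = 19); its mean distance to the rest is
13/8 (C = 0.615).  On eigenvector score `b` ranks only second
(EC = 0.925 vs 1.000 for the branch node with four partners) — exactly the
disagreement between scales that motivates the multi-index approach.

End-to-end on a synthetic network with 20 planted hubs:

```python
>>> from multicent import (SyntheticSpec, generate_network, centrality_table,
...                        detect_hubs, recovery_metrics)
>>> net, truth = generate_network(SyntheticSpec(seed=1))
>>> res = detect_hubs(centrality_table(net), seed=1)
>>> m = recovery_metrics(res.hubs, truth)
>>> len(res.hubs), round(m.recall, 2), round(m.precision, 2)
(20, 1.0, 1.0)
```

with round-1 selecting an ellipsoidal 7-component model whose most central
cluster holds exactly the 20 planted hubs, and round 2 confirming it as a
single component.  The rank-association matrix of the same run shows the
redundancy structure typical of assortative PPI backbones — degree and
betweenness nearly interchangeable, eigenvector grouped with closeness,
TI¹ idiosyncratic:

```
         D     EC    TI1    TI4      B      C
D    1.000  0.326  0.840  0.997  0.855  0.346
B    0.855  0.356  0.569  0.705  1.000  0.374
EC   0.326  1.000  0.020  0.166  0.356  0.921
C    0.346  0.921  0.030  0.176  0.374  1.000
```

The same pipeline is scriptable from the shell:

```
multicent synth --seed 1 -o demo           # planted-hub network + annotations
multicent run demo_edgelist.tsv --annotations demo_annotations.tsv -o out
```

## Layout

- `src/multicent/graphio.py` — edgelist I/O, giant component, global stats
- `src/multicent/centrality.py` — the six indices, effect matrix, normalization
- `src/multicent/hubdetect.py` — BIC mixture selection + two-round hub detection (sklearn-style estimators)
- `src/multicent/redundancy.py` — gamma association, index dendrogram, subset evaluation
- `src/multicent/nullmodels.py` — G(n,m), degree-preserving rewiring, small-world nulls
- `src/multicent/annotstats.py` — chi-squared / KS tests, enrichment profiles
- `src/multicent/synthetic.py` — planted-hub generator with ground truth
- `src/multicent/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter rationale, limitations
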