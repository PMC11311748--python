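# formulanet

Prescription-rule mining for multi-herb formula corpora: Jaccard-distance
clustering of prescriptions with validity sensitivity analysis, and
bipartite herb–indication co-occurrence networks.

## The problem

Classical East Asian herbal formularies record hundreds of prescriptions,
each a set of herbs with a set of therapeutic indications. Two questions
recur when mining such a corpus: *which prescriptions form families* (they
share constituent herbs), and *which herb combinations serve which
indications* (herbs and indications co-occur across prescriptions).
`formulanet` answers both quantitatively for corpora of tokenized
prescriptions — e.g. a transcription of a classical text where experts
have standardized herb names (`H1`, `H2`, …) and indication phrases
(`S1`, …, `S22`).

## The method

Each prescription becomes a binary herb vector. Similarity between
prescriptions X, Y is the Jaccard coefficient of their herb sets,

    J(X,Y) = |X ∩ Y| / |X ∪ Y|,        d(X,Y) = 1 − J(X,Y),

and d is a metric, so the distance matrix feeds:

- **hierarchical clustering** (complete/average/single linkage, exported
  as Newick dendrograms), and
- **k-means** on a classical-MDS embedding of the distance matrix, with
  seeded Forgy initialization so one seed = one run.

k-means results are validated two ways across sensitivity sweeps over k
and over the initialization seed: the **silhouette index**
s(i) = (b−a)/max(a,b) on the Jaccard distances, and a domain-specific
**misclassification statistic** — the fraction of all C(n,2) prescription
pairs that share *no* herb (J = 0) yet land in the same cluster.
Prescriptions co-clustered in every sweep run form **stable cores**.

The **herb–indication (H-I) network** is bipartite: node frequency =
number of prescriptions containing the token, edge weight = number of
prescriptions containing both endpoints. Cluster-specific subnetworks and
their "common major" herbs/indications compare what different prescription
families treat and with what.

A **planted-partition generator** produces synthetic corpora with known
cluster structure (disjoint cluster herb pools plus a shared pool of
globally frequent tonifying herbs), so the whole pipeline is testable:
recovery is scored by adjusted Rand index against the planted labels.

## Worked example

Simulate a 45-prescription corpus with 5 planted groups, then sweep k:

```
$ formulanet simulate --seed 42 --out sim
wrote 45 prescriptions to sim/corpus.tsv

$ formulanet sweep --input sim/corpus.tsv --k-min 3 --k-max 8 --seed 12345 --out sweeps
k=3: silhouette=0.24 misclassification=4.24%
k=4: silhouette=0.31 misclassification=0.71%
k=5: silhouette=0.23 misclassification=0.20%
k=6: silhouette=0.33 misclassification=0.00%
k=7: silhouette=0.15 misclassification=2.63%
k=8: silhouette=0.28 misclassification=0.00%

$ formulanet network --input sim/corpus.tsv --out net
network over 45 prescriptions: 56 herbs, 22 indications, 378 edges
```

Reading the sweep: at k = 3 the corpus' 5 planted groups are forced
together, so 4.24% of all 990 prescription pairs are herb-disjoint yet
co-clustered; from k = 6 on, no zero-overlap pair shares a cluster
(misclassification 0.00%). The misclassification minimum flags the k at
and beyond which clusters stop mixing unrelated prescriptions, while the
silhouette rates cohesion/separation; the analyst weighs both. The
network line summarizes the bipartite H-I graph written to
`net/edges.tsv`, `net/nodes.tsv` and `net/network.graphml`.

The same analysis runs end to end from a YAML config
(`formulanet run-all --config cfg.yaml`), writing distance matrices,
dendrograms, assignments, sensitivity tables, networks and a SHA-256
manifest; identical configs reproduce byte-identical outputs.

Library use mirrors the CLI:

```python
from formulanet import (SyntheticSpec, generate_corpus, jaccard_distance_matrix,
                        classical_mds, kmeans_partition, adjusted_rand_index)

corpus, planted = generate_corpus(SyntheticSpec(seed=42))
emb = classical_mds(jaccard_distance_matrix(corpus))
best = min((kmeans_partition(emb, k=5, seed=s) for s in range(10)),
           key=lambda a: a.inertia)
```

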