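# Methods

## Problem and data model

`formulanet` analyzes corpora of multi-herb prescriptions from East Asian
traditional medicine. Each prescription is a set of standardized herb
tokens (ids like `H1`) and a set of indication tokens (`S13`); dosage is
deliberately out of scope. The analysis unit is the prescription; the two
binary incidence matrices (prescriptions × herbs, prescriptions ×
indications) are the only inputs every downstream stage consumes. Input is
a long-format table, one row per prescription–token pair, because a single
tidy format is unambiguous when two token kinds coexist; a wide binary
matrix reader is provided for convenience. Prescriptions with no herbs are
rejected (herb vectors drive all clustering); prescriptions with no
indications are accepted with a warning (they contribute node frequencies
but no herb–indication edges).

## Similarity

Similarity between prescriptions X and Y is the Jaccard coefficient of
their herb sets, J(X,Y) = |X∩Y| / |X∪Y|, and the distance is d = 1 − J.
J of two empty sets is 0/0 and raises an error rather than returning a
convention value; valid corpora guarantee non-empty herb sets so the case
cannot arise in the pipeline. d is a metric on finite sets (the test suite
checks the triangle inequality on random triples), so it can feed both
agglomerative clustering and classical MDS directly. Distances are
computed vectorized from the incidence matrix and agree exactly with
pairwise set evaluation; matrices export as TSV at 10 significant digits.
An option computes similarity on indication sets or the combined sets for
exploration; clustering defaults to herbs only.

## Hierarchical clustering

Standard agglomerative clustering on the Jaccard distance matrix with
complete (default), average, or single linkage. Complete linkage is the
default because it is the documented default of the R `stats::hclust`
family of implementations this kind of analysis is usually run with, and
it resists the chaining that single linkage shows on sparse binary data.
Among equal-distance merge candidates, the pair with the lexicographically
smallest (min node index, max node index) tuple merges first; this makes
trees deterministic across platforms (ties are common in Jaccard matrices
of small integer sets). Cutting the tree at k clusters removes the k−1
highest merges; because merge heights are monotone for the supported
linkages this equals replaying the first n−k merges. Dendrograms export as
Newick (branch length = parent height − child height) and as a merge
table.

The agglomeration is O(n³) by direct recomputation of linkage distances
from the base matrix. Corpora in this domain are tens of prescriptions, so
clarity was preferred over a nearest-neighbor-chain implementation; tests
cross-check against `scipy.cluster.hierarchy` on tie-free random matrices.

## k-means and the embedding

k-means needs coordinates, but the analysis defines only a distance
matrix. The default feature space is the classical (Torgerson) MDS
embedding of the Jaccard matrix: double-center −D²/2, eigendecompose,
keep every strictly positive eigenvalue (tolerance 1e-10 relative to the
largest), scale eigenvectors by √λ. Jaccard distances are metric but not
Euclidean-embeddable in general, so small negative eigenvalues are
dropped; retained dimensions reproduce Euclidean inputs to 1e-8 in tests.
An alternative mode runs k-means on the raw binary herb vectors; the
choice is recorded in run metadata.

Lloyd's algorithm with Forgy initialization: the seed picks k distinct
data points as initial centroids, so one seed corresponds to exactly one
initial-centroid configuration — the property the seed-sensitivity sweep
depends on. `n_init` defaults to 1 ("one seed = one run"); the k-sweep can
use a best-of-`n_init` mode (lowest within-cluster sum of squares wins).
An emptied cluster is repaired by moving the point farthest from its
current centroid into it, keeping k fixed. Convergence is an unchanged
assignment, with a 300-iteration cap. Identical (embedding, k, seed) give
identical labels.

## Validity statistics

**Silhouette.** s(i) = (b(i) − a(i)) / max(a(i), b(i)) with a(i) the mean
intra-cluster distance (self excluded) and b(i) the smallest mean distance
to another cluster, computed on the **Jaccard** distance matrix by default
(not the embedded Euclidean distances — the statistic should measure
cohesion in the space the similarity is defined in; a flag switches).
Members of singleton clusters get width 0, the widely used convention.
Undefined for k < 2 (error).

**Misclassification.** A domain-specific validity statistic: two
prescriptions that share no herb at all (Jaccard coefficient exactly zero)
should never land in the same cluster. The count is the number of
unordered co-clustered zero-Jaccard pairs; the rate divides by **all**
C(n,2) unordered pairs. The all-pairs denominator is the convention under
which observed integer pair counts map onto the fractions of a percent
this statistic is reported in (with n = 43, C(43,2) = 903 maps counts
2, 86, 132, 14 to 0.22%, 9.52%, 14.62%, 1.55%). Every achievable rate is
an integer multiple of 1/C(n,2), and refining a partition can only
decrease the count — both are asserted in tests.

**Sweeps.** `sweep_k` varies k at a fixed seed; `sweep_seeds` varies the
seed at fixed k. Each row records mean silhouette, misclassified pairs,
and the rate. `stable_cores` intersects the co-clustering relations of a
list of assignments and returns the connected components — the maximal
prescription sets co-clustered in every run; the result is always a
partition because an intersection of equivalence relations is one.

## Herb–indication network

A bipartite graph: herb nodes and indication nodes, node frequency = the
number of member prescriptions containing the token, edge weight = the
number of member prescriptions containing both endpoints. Total edge
weight therefore equals Σ over members |herbs|·|indications|, and every
edge weight is bounded by its endpoints' frequencies — both identities are
tested on random corpora. Cluster subnetworks restrict the member set to
one cluster; across a partition, subnetwork weights add back to the full
network's. `common_major_nodes` compares two subnetworks: tokens of one
kind whose frequency passes a threshold in both, with exactly one of
`min_freq` or `top_n` required because "major" has no canonical cutoff;
the pipeline default is min_freq = ⌈half the smaller cluster size⌉, which
makes comparisons reproducible and tunable. The data model stores raw
frequencies and weights only; node size/edge thickness scaling and the
seeded spring layout are renderer concerns and non-contractual.

## Synthetic corpus generator

The generator emulates the statistical shape of a hand-transcribed
formula corpus so the whole pipeline is testable without one: a few dozen
prescriptions in a handful of therapeutic groups, each drawing from a
disjoint cluster herb pool, everyone sharing a small pool of globally
frequent tonifying herbs (the ginseng/licorice pattern), plus rare stray
herbs; indications mirror this with cluster-specific pools plus two
globally shared indications (the fever/deficiency pattern), so cluster
subnetworks have non-trivial common major nodes.

Defaults: 5 clusters × 9 prescriptions; cluster herb pools of 8; shared
pool of 4; noise pool of 25 (registry totals 69 herbs — the scale of a
realistic transcription); inclusion probabilities p_core = 0.7,
p_shared = 0.6, p_noise = 0.02; indication pools of 4 per cluster plus 2
shared; p_indication = 0.6, p_shared_indication = 0.5. With these values
shared-pool herbs are the globally most frequent tokens (expected
frequency N·p_shared vs N·p_core/n_clusters for cluster herbs) and mean
within-cluster Jaccard similarity clearly exceeds between-cluster
similarity. One RNG stream seeded from the spec drives every draw in
documented order (per prescription: cluster herbs, shared herbs, noise
herbs, then indications), so corpora are bit-reproducible; herb sets are
resampled up to 1000 times until non-empty, and an all-zero-probability
spec errors out.

What the generator does **not** emulate: herb-frequency heavy tails,
correlated herb co-occurrence within a pool (herbs are included
independently), prescriptions legitimately belonging to two groups, and
any dosage structure. Passing recovery tests therefore show the pipeline
recovers planted block structure under realistic sparsity — not that any
particular historical corpus clusters cleanly.

With fully deterministic pools (p_core = 1, p_shared = p_noise = 0) the
planted partition provably has misclassification count 0 while cross-pair
Jaccard is identically zero; with p_core < 1 two same-cluster
prescriptions can draw disjoint pool subsets by chance (≈0.51⁸ per pair at
the defaults), so the zero-count guarantee is stated and tested on the
deterministic-pool configuration.

Recovery is measured by the adjusted Rand index against the planted
labels (delegating to scikit-learn after id alignment). On 50 default-spec
replicates the full pipeline (Jaccard → MDS → k-means, best of 10 seeds at
the true k) reaches ARI ≥ 0.8 in ≥ 90% of replicates — the suite and the
acceptance script both recompute this.

## Pipeline and reproducibility

`run_full_analysis` chains corpus (read or simulate) → distances → HCA →
sweeps → best k-means assignment (lowest misclassification over the seed
sweep) → full network and per-cluster subnetworks, writing TSV / JSON /
Newick / GraphML artifacts and a manifest with SHA-256 checksums. Stage
failures abort with the stage name. Fixed configuration and seeds give
byte-identical non-figure outputs; human-readable reports print
percentages to 2 decimals while machine outputs keep full precision. The
CLI (`formulanet simulate|cluster|sweep|network|run-all`) exits 0 on
success, 2 on configuration errors, 1 on stage failures.

## Numerical choices and limitations

- Hierarchical tie-break and k-means argmin ties both resolve to the
  lowest index, fixing platform-independent determinism.
- MDS eigenvalue cutoff 1e-10 (relative); requested dimensions above the
  positive-eigenvalue count are clamped with a warning; an all-coincident
  input returns a single zero coordinate.
- k-means inertia comparisons use a 1e-12 slack so the first of
  exactly-tied inits wins.
- Problem sizes throughout tests and the acceptance script (≤ 50
  prescriptions, 50 replicates, 10 seeds) match the corpus scale the
  method is designed for; the O(n³) agglomeration and O(n²) statistics are
  comfortable well beyond it.
- Automatic selection of k is out of scope; the k-sweep reports validity
  statistics and leaves the choice to the analyst, which is how this
  method is used in practice.
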