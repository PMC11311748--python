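"""Hierarchical clustering, classical MDS embedding, and k-means partitioning.

Hierarchical agglomeration runs directly on the Jaccard distance matrix.
k-means needs coordinates, so the default feature space is a classical
(Torgerson) MDS embedding of the distance matrix retaining every
positive-eigenvalue dimension; raw binary herb vectors are an alternative
mode handled by the pipeline. All stochastic steps are seeded: one seed is
one k-means run, so seed-sensitivity sweeps are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from formulanet.errors import ParameterError
from formulanet.similarity import DistanceMatrix

logger = logging.getLogger(__name__)

LINKAGES = ("complete", "average", "single")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over prescription leaves.

    Leaves are numbered 0..n-1 in ``ids`` order; merge i creates node n+i.
    ``merges`` has one row per merge: (left node, right node, height).
    """

    ids: list
    merges: np.ndarray  # (n-1, 3) float; node indices stored as floats

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: self.ids[i] for i in range(n)}
        for m, (a, b, h) in enumerate(self.merges):
            a, b = int(a), int(b)
            la, lb = h - height[a], h - height[b]
            text[n + m] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
            height[n + m] = h
        return text[n + len(self.merges) - 1] + ";"

    def merge_table(self):
        """Merge-table rows (node, child1, child2, height) for TSV export."""
        n = self.n_leaves
        return [
            (n + m, int(a), int(b), float(h))
            for m, (a, b, h) in enumerate(self.merges)
        ]


@dataclass
class Embedding:
    """Classical-MDS coordinates for the prescriptions."""

    ids: list
    coordinates: np.ndarray  # n x d
    eigenvalues: np.ndarray  # the d retained (positive) eigenvalues

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class ClusterAssignment:
    """A partition of the prescriptions into k labeled clusters.

    Labels run 1..k and every cluster is non-empty. ``method`` and ``seed``
    record provenance for sensitivity tables.
    """

    ids: list
    labels: np.ndarray
    k: int
    method: str
    seed: int | None = None
    inertia: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.ids),):
            raise ValueError("labels must align with ids")
        present = set(self.labels.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(
                f"labels must cover 1..k with no empty cluster; got {sorted(present)}"
            )

    def label_of(self) -> dict:
        return dict(zip(self.ids, self.labels.tolist()))

    def members(self, label: int) -> list:
        return [pid for pid, lab in zip(self.ids, self.labels) if lab == label]

    def clusters(self) -> dict:
        out: dict = {}
        for pid, lab in zip(self.ids, self.labels.tolist()):
            out.setdefault(lab, []).append(pid)
        return out


def _relabel_first_appearance(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary labels to 1..k in order of first appearance."""
    mapping: dict = {}
    out = np.empty_like(raw, dtype=int)
    for i, lab in enumerate(raw.tolist()):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out, len(mapping)


# -- hierarchical ----------------------------------------------------------


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the distance matrix.

    Repeatedly merges the pair of active clusters at minimal linkage
    distance (complete = max, average = unweighted mean over leaf pairs,
    single = min). Among equal-distance candidates the pair with the
    lexicographically smallest (min node index, max node index) tuple is
    merged, which makes the tree deterministic across platforms.
    """
    if linkage not in LINKAGES:
        raise ParameterError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    n = dist.n
    if n < 2:
        raise ParameterError(f"need at least 2 items to cluster, got {n}")
    base = dist.values
    active: dict = {i: [i] for i in range(n)}  # node -> leaf indices
    merges = np.zeros((n - 1, 3))
    for m in range(n - 1):
        best = None
        nodes = sorted(active)
        for ai in range(len(nodes)):
            for bi in range(ai + 1, len(nodes)):
                a, b = nodes[ai], nodes[bi]
                block = base[np.ix_(active[a], active[b])]
                if linkage == "complete":
                    d = block.max()
                elif linkage == "single":
                    d = block.min()
                else:
                    d = block.mean()
                key = (d, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        merges[m] = (min(a, b), max(a, b), d)
        active[n + m] = active.pop(a) + active.pop(b)
    return Dendrogram(list(dist.ids), merges)


def cut_dendrogram(tree: Dendrogram, k: int) -> ClusterAssignment:
    """Partition obtained by removing the k-1 highest merges.

    Because merge heights are non-decreasing, this is the components left
    after replaying only the first n-k merges.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n - k):
        a, b, _ = tree.merges[m]
        ra, rb = find(int(a)), find(int(b))
        parent[ra] = n + m
        parent[rb] = n + m
    raw = np.array([find(i) for i in range(n)])
    labels, kk = _relabel_first_appearance(raw)
    assert kk == k
    return ClusterAssignment(list(tree.ids), labels, k, method="hca_cut")


# -- classical MDS ---------------------------------------------------------


def classical_mds(dist: DistanceMatrix, dim: int | None = None) -> Embedding:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps the top ``dim``
    strictly positive eigenvalues (all of them when ``dim`` is None).
    When the distances are Euclidean-embeddable the embedding reproduces
    them exactly; Jaccard distances are metric but generally non-Euclidean,
    so small negative eigenvalues are dropped rather than retained.
    """
    d2 = dist.values**2
    n = dist.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    n_pos = int(np.sum(evals > tol))
    if n_pos == 0:
        # all points coincide; return a single zero coordinate
        return Embedding(list(dist.ids), np.zeros((n, 1)), np.zeros(1))
    if dim is None:
        dim = n_pos
    elif dim > n_pos:
        logger.warning(
            "requested %d MDS dimensions but only %d positive eigenvalues; clamping",
            dim,
            n_pos,
        )
        dim = n_pos
    coords = evecs[:, :dim] * np.sqrt(evals[:dim])
    return Embedding(list(dist.ids), coords, evals[:dim])


# -- k-means ---------------------------------------------------------------


def _as_matrix(embedding) -> tuple[list, np.ndarray]:
    if isinstance(embedding, Embedding):
        return list(embedding.ids), np.asarray(embedding.coordinates, dtype=float)
    x = np.asarray(embedding, dtype=float)
    return [str(i) for i in range(len(x))], x


def kmeans_partition(
    embedding,
    k: int,
    seed: int,
    n_init: int = 1,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Seeded Lloyd k-means on embedding coordinates.

    Initial centroids are k distinct data points sampled uniformly with the
    given seed (Forgy), so one seed corresponds to one initial-centroid
    configuration, which is what the seed-sensitivity sweep varies. With
    ``n_init`` > 1, the run with the lowest within-cluster sum of squares
    wins (used by the k-sweep's best-of mode). An emptied cluster is
    repaired by moving the point farthest from its centroid into it, which
    keeps k fixed. Identical (embedding, k, seed) give identical labels.
    """
    ids, x = _as_matrix(embedding)
    n = len(ids)
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_init):
        idx = rng.choice(n, size=k, replace=False)
        centroids = x[idx].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            # repair empty clusters: farthest point becomes a singleton
            for c in range(k):
                if not np.any(new_labels == c):
                    resid = d2[np.arange(n), new_labels]
                    far = int(resid.argmax())
                    new_labels[far] = c
                    d2[far] = np.inf
                    d2[far, c] = 0.0
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                centroids[c] = x[labels == c].mean(axis=0)
        inertia = float(((x - centroids[labels]) ** 2).sum())
        if inertia < best_inertia - 1e-12:
            best_labels, best_inertia = labels, inertia
    out, kk = _relabel_first_appearance(best_labels)
    assert kk == k
    return ClusterAssignment(
        ids, out, k, method="kmeans", seed=seed, inertia=best_inertia
    )


# -- exports ---------------------------------------------------------------


def write_dendrogram(tree: Dendrogram, newick_path=None, table_path=None) -> None:
    if newick_path is not None:
        with open(newick_path, "w", encoding="utf-8") as fh:
            fh.write(tree.to_newick() + "\n")
    if table_path is not None:
        with open(table_path, "w", encoding="utf-8") as fh:
            fh.write("node\tchild1\tchild2\theight\n")
            for node, c1, c2, h in tree.merge_table():
                fh.write(f"{node}\t{c1}\t{c2}\t{h:.10g}\n")


def write_assignment(assignment: ClusterAssignment, path) -> None:
    """TSV of prescription_id -> label with '#' metadata header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={assignment.method}\n")
        fh.write(f"# k={assignment.k}\n")
        fh.write(f"# seed={assignment.seed}\n")
        fh.write("prescription_id\tcluster\n")
        for pid, lab in zip(assignment.ids, assignment.labels.tolist()):
            fh.write(f"{pid}\t{lab}\n")
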