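"""Cluster validity: silhouette index, misclassification statistic, sweeps.

Two validity measures are computed for every k-means assignment:

* the silhouette index s(i) = (b(i) - a(i)) / max(a(i), b(i)) on the
  Jaccard distance matrix (a(i): mean intra-cluster distance, b(i): lowest
  mean distance to another cluster; singleton clusters get s(i) = 0), and
* a misclassification statistic specific to prescription mining: a pair of
  prescriptions whose herb sets share nothing (Jaccard coefficient zero)
  should never be co-clustered; the count of such co-clustered pairs over
  all C(n, 2) unordered pairs is the misclassification rate.

The sensitivity analyses sweep the number of clusters at a fixed seed and
the seed at a fixed k, and extract the stable cores: maximal sets of
prescriptions co-clustered in every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from formulanet.clustering import ClusterAssignment, classical_mds, kmeans_partition
from formulanet.corpus_io import PrescriptionCorpus, to_incidence
from formulanet.errors import ParameterError, ValidityError
from formulanet.similarity import DistanceMatrix, jaccard_distance_matrix


@dataclass
class ValidityReport:
    """Silhouette and misclassification figures for one assignment."""

    ids: list
    silhouette_widths: np.ndarray
    mean_silhouette: float
    misclassified_pairs: int
    misclassification_rate: float  # fraction of all C(n,2) unordered pairs
    k: int
    seed: int | None

    @property
    def misclassification_percent(self) -> float:
        return 100.0 * self.misclassification_rate


@dataclass
class SensitivityTable:
    """One row per (k, seed) of a sweep, plus the assignments themselves."""

    table: pd.DataFrame
    assignments: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["misclassification_rate_percent"] = (
            100.0 * out.pop("misclassification_rate")
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)


def silhouette_widths(dist: DistanceMatrix, assignment: ClusterAssignment) -> np.ndarray:
    """Per-prescription silhouette widths on the given distance matrix.

    Widths lie in [-1, 1]; members of singleton clusters get 0 by the usual
    convention (cohesion is undefined for a lone point).
    """
    if list(assignment.ids) != list(dist.ids):
        raise ValidityError("assignment ids do not match distance-matrix ids")
    if assignment.k < 2:
        raise ValidityError("silhouette is undefined for fewer than 2 clusters")
    d = dist.values
    labels = assignment.labels
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton convention: width 0
        a = d[i, own].sum() / (n_own - 1)  # exclude self (d[i,i] = 0)
        b = min(
            d[i, labels == lab].mean()
            for lab in range(1, assignment.k + 1)
            if lab != labels[i]
        )
        widths[i] = (b - a) / max(a, b)
    return widths


def silhouette_mean(dist: DistanceMatrix, assignment: ClusterAssignment) -> float:
    """Mean silhouette width over all prescriptions."""
    return float(silhouette_widths(dist, assignment).mean())


def zero_jaccard_pairs(corpus: PrescriptionCorpus) -> set:
    """Unordered prescription-id pairs whose herb sets are disjoint."""
    inc = to_incidence(corpus, "herb").values
    inter = inc @ inc.T
    ids = corpus.ids
    n = len(ids)
    return {
        (ids[i], ids[j]) for i in range(n) for j in range(i + 1, n) if inter[i, j] == 0
    }


def misclassification_rate(
    corpus: PrescriptionCorpus, assignment: ClusterAssignment
) -> tuple[int, float]:
    """Count and rate of co-clustered herb-disjoint prescription pairs.

    The rate divides by all C(n, 2) unordered pairs; with n = 43 this
    denominator (903) is what turns small integer pair counts into the
    fractions of a percent this statistic is reported in.
    """
    if set(assignment.ids) != set(corpus.ids):
        raise ValidityError("assignment does not cover the corpus")
    label = assignment.label_of()
    count = sum(1 for a, b in zero_jaccard_pairs(corpus) if label[a] == label[b])
    n = len(corpus)
    return count, count / comb(n, 2)


def validity_report(
    corpus: PrescriptionCorpus,
    dist: DistanceMatrix,
    assignment: ClusterAssignment,
) -> ValidityReport:
    widths = silhouette_widths(dist, assignment)
    count, rate = misclassification_rate(corpus, assignment)
    return ValidityReport(
        ids=list(assignment.ids),
        silhouette_widths=widths,
        mean_silhouette=float(widths.mean()),
        misclassified_pairs=count,
        misclassification_rate=rate,
        k=assignment.k,
        seed=assignment.seed,
    )


# -- sweeps ----------------------------------------------------------------


def _kmeans_inputs(corpus: PrescriptionCorpus, mode: str):
    dist = jaccard_distance_matrix(corpus)
    if mode == "embedding":
        features = classical_mds(dist)
    elif mode == "binary":
        inc = to_incidence(corpus, "herb")
        features = inc.values.astype(float)
    else:
        raise ParameterError(f"mode must be 'embedding' or 'binary', got {mode!r}")
    return dist, features


def _run_one(corpus, dist, features, k, seed, n_init):
    assignment = kmeans_partition(features, k=k, seed=seed, n_init=n_init)
    assignment = ClusterAssignment(
        list(corpus.ids), assignment.labels, k, "kmeans", seed, assignment.inertia
    )
    return validity_report(corpus, dist, assignment), assignment


def sweep_k(
    corpus: PrescriptionCorpus,
    k_range,
    seed: int,
    n_init: int = 1,
    mode: str = "embedding",
) -> SensitivityTable:
    """Vary k over ``k_range`` with the initial-centroid seed held fixed."""
    ks = list(k_range)
    n = len(corpus)
    if any(k < 2 or k > n for k in ks):
        raise ParameterError(f"k values must lie in [2, {n}]")
    dist, features = _kmeans_inputs(corpus, mode)
    rows, assignments = [], []
    for k in ks:
        rep, assignment = _run_one(corpus, dist, features, k, seed, n_init)
        rows.append(
            {
                "k": k,
                "seed": seed,
                "mean_silhouette": rep.mean_silhouette,
                "misclassified_pairs": rep.misclassified_pairs,
                "misclassification_rate": rep.misclassification_rate,
            }
        )
        assignments.append(assignment)
    return SensitivityTable(pd.DataFrame(rows), assignments)


def sweep_seeds(
    corpus: PrescriptionCorpus,
    k: int,
    seeds,
    n_init: int = 1,
    mode: str = "embedding",
) -> SensitivityTable:
    """Vary the initial-centroid seed with the number of clusters fixed."""
    seeds = list(seeds)
    if not seeds:
        raise ParameterError("seeds must be non-empty")
    dist, features = _kmeans_inputs(corpus, mode)
    rows, assignments = [], []
    for seed in seeds:
        rep, assignment = _run_one(corpus, dist, features, k, seed, n_init)
        rows.append(
            {
                "k": k,
                "seed": seed,
                "mean_silhouette": rep.mean_silhouette,
                "misclassified_pairs": rep.misclassified_pairs,
                "misclassification_rate": rep.misclassification_rate,
            }
        )
        assignments.append(assignment)
    return SensitivityTable(pd.DataFrame(rows), assignments)


def stable_cores(assignments: list) -> list:
    """Maximal prescription sets co-clustered in every assignment.

    Formally: connected components of the intersection of the runs'
    co-clustering relations. The result is always a partition of the
    corpus (intersection of equivalence relations is an equivalence
    relation).
    """
    if len(assignments) < 2:
        raise ParameterError("need at least 2 assignments to intersect")
    ids = list(assignments[0].ids)
    for a in assignments[1:]:
        if set(a.ids) != set(ids):
            raise ParameterError("assignments cover different prescription sets")
    together = np.ones((len(ids), len(ids)), dtype=bool)
    for a in assignments:
        lab = a.label_of()
        v = np.array([lab[i] for i in ids])
        together &= v[:, None] == v[None, :]
    seen: set = set()
    cores = []
    for i, pid in enumerate(ids):
        if pid in seen:
            continue
        core = {ids[j] for j in np.flatnonzero(together[i])}
        seen |= core
        cores.append(core)
    return cores
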