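"""Jaccard similarity between prescriptions and the pairwise distance matrix.

For two prescriptions with herb sets X and Y,

    J(X, Y)  = |X n Y| / |X u Y|
    d(X, Y)  = 1 - J(X, Y)

J is 1 for identical sets, 0 for disjoint ones, and d is a metric on finite
sets, so the distance matrix can feed any metric-based clustering directly.
Similarity is computed on herb sets by default (clustering is based on the
similarity of constituent herbs); indication-set or combined-set similarity
is available for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from formulanet.corpus_io import PrescriptionCorpus
from formulanet.errors import EmptyInputError, UndefinedSimilarityError

ON_CHOICES = ("herbs", "indications", "combined")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Jaccard distance matrix with zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("Jaccard distances must lie in [0, 1]")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


def jaccard_coefficient(set_a, set_b) -> float:
    """|A n B| / |A u B|; errors on two empty sets (0/0 undefined)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise UndefinedSimilarityError(
            "Jaccard coefficient of two empty sets is undefined (0/0)"
        )
    return len(a & b) / len(union)


def jaccard_distance(set_a, set_b) -> float:
    """1 - J(A, B)."""
    return 1.0 - jaccard_coefficient(set_a, set_b)


def _token_sets(corpus: PrescriptionCorpus, on: str):
    if on == "herbs":
        return [p.herbs for p in corpus.prescriptions]
    if on == "indications":
        return [p.indications for p in corpus.prescriptions]
    if on == "combined":
        return [p.herbs | p.indications for p in corpus.prescriptions]
    raise ValueError(f"on must be one of {ON_CHOICES}, got {on!r}")


def jaccard_distance_matrix(
    corpus: PrescriptionCorpus, on: str = "herbs"
) -> DistanceMatrix:
    """Pairwise Jaccard distances between prescriptions' token sets.

    Entry (i, j) equals ``jaccard_distance(sets[i], sets[j])`` exactly;
    the computation is vectorized over the binary incidence matrix.
    """
    if len(corpus) == 0:
        raise EmptyInputError("empty corpus")
    sets = _token_sets(corpus, on)
    if any(len(s) == 0 for s in sets):
        bad = [corpus.ids[i] for i, s in enumerate(sets) if not s]
        raise UndefinedSimilarityError(
            f"empty token sets for {bad}; Jaccard undefined for empty-vs-empty pairs"
        )
    all_tokens = sorted(set().union(*sets))
    col = {t: j for j, t in enumerate(all_tokens)}
    m = np.zeros((len(sets), len(all_tokens)), dtype=np.int64)
    for i, s in enumerate(sets):
        for t in s:
            m[i, col[t]] = 1
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(corpus.ids), d)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    """TSV export with id header row/column; 10 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([""] + list(dist.ids)) + "\n")
        for i, pid in enumerate(dist.ids):
            cells = [format(x, ".10g") for x in dist.values[i]]
            fh.write("\t".join([pid] + cells) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
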