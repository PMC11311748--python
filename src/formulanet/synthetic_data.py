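"""Planted-partition synthetic prescription corpora.

The generator emulates the statistical shape of a classical multi-herb
formula corpus: a few dozen prescriptions falling into a handful of
therapeutic groups, each group drawing most of its herbs from its own
disjoint pool, everyone sharing a small pool of globally frequent
tonifying herbs (the ginseng/licorice pattern), plus occasional stray
herbs. Indications follow the same design — cluster-specific indication
profiles plus a couple of globally shared ones (the fever/deficiency
pattern) — so cluster subnetworks have non-trivial common major nodes.

Defaults give 5 clusters x 9 prescriptions over 69 herb and 22 indication
tokens, matching the scale of a realistic hand-transcribed corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from formulanet.clustering import ClusterAssignment
from formulanet.corpus_io import (
    HERB,
    INDICATION,
    Prescription,
    PrescriptionCorpus,
    Token,
)
from formulanet.errors import ParameterError, SyntheticSpecError

_MAX_RESAMPLE = 1000


@dataclass
class SyntheticSpec:
    """Parameters of the planted-partition corpus generator.

    p_core: probability each herb of the prescription's own cluster pool is
    included; p_shared: same for the globally shared pool; p_noise: same for
    the out-of-pool (noise) herbs. Cluster pools are pairwise disjoint and
    disjoint from the shared pool, so with p_shared = p_noise = 0 the
    planted clusters have zero between-cluster herb overlap.
    """

    n_clusters: int = 5
    prescriptions_per_cluster: int | tuple = 9
    herb_pool_size_per_cluster: int = 8
    shared_herb_pool_size: int = 4
    noise_herb_pool_size: int = 25
    p_core: float = 0.7
    p_shared: float = 0.6
    p_noise: float = 0.02
    indication_pool_per_cluster: int = 4
    n_shared_indications: int = 2
    p_indication: float = 0.6
    p_shared_indication: float = 0.5
    seed: int = 0

    def cluster_sizes(self) -> list:
        if isinstance(self.prescriptions_per_cluster, int):
            return [self.prescriptions_per_cluster] * self.n_clusters
        sizes = list(self.prescriptions_per_cluster)
        if len(sizes) != self.n_clusters:
            raise SyntheticSpecError(
                "prescriptions_per_cluster list must have n_clusters entries"
            )
        return sizes

    def validate(self) -> None:
        probs = {
            "p_core": self.p_core,
            "p_shared": self.p_shared,
            "p_noise": self.p_noise,
            "p_indication": self.p_indication,
            "p_shared_indication": self.p_shared_indication,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SyntheticSpecError(f"{name} must lie in [0, 1], got {p}")
        if self.n_clusters < 1 or min(self.cluster_sizes()) < 1:
            raise SyntheticSpecError("need at least one cluster of at least one prescription")
        if self.p_core == 0 and self.p_shared == 0 and self.p_noise == 0:
            raise SyntheticSpecError(
                "all herb inclusion probabilities are 0; every prescription "
                "would be herbless"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        spec = cls(**data)
        if isinstance(spec.prescriptions_per_cluster, list):
            spec.prescriptions_per_cluster = tuple(spec.prescriptions_per_cluster)
        return spec


def _herb_pools(spec: SyntheticSpec) -> tuple[list, list, list]:
    """Token-id pools: shared first (H1..), then cluster pools, then noise."""
    next_id = 1

    def take(n):
        nonlocal next_id
        ids = [f"H{i}" for i in range(next_id, next_id + n)]
        next_id += n
        return ids

    shared = take(spec.shared_herb_pool_size)
    clusters = [take(spec.herb_pool_size_per_cluster) for _ in range(spec.n_clusters)]
    noise = take(spec.noise_herb_pool_size)
    return shared, clusters, noise


def _indication_pools(spec: SyntheticSpec) -> tuple[list, list]:
    next_id = 1
    clusters = []
    for _ in range(spec.n_clusters):
        clusters.append(
            [f"S{i}" for i in range(next_id, next_id + spec.indication_pool_per_cluster)]
        )
        next_id += spec.indication_pool_per_cluster
    shared = [f"S{i}" for i in range(next_id, next_id + spec.n_shared_indications)]
    return shared, clusters


def generate_corpus(spec: SyntheticSpec) -> tuple[PrescriptionCorpus, ClusterAssignment]:
    """Draw one corpus and its planted labels.

    A single RNG stream seeded from the spec drives every draw, consumed
    prescription by prescription (herbs, then indications), so corpora are
    reproducible given the seed. Herb sets are resampled (bounded) until
    non-empty.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shared_h, cluster_h, noise_h = _herb_pools(spec)
    shared_s, cluster_s = _indication_pools(spec)

    tokens: dict = {}
    for tid in shared_h + [t for pool in cluster_h for t in pool] + noise_h:
        tokens[tid] = Token(tid, HERB)
    for tid in [t for pool in cluster_s for t in pool] + shared_s:
        tokens[tid] = Token(tid, INDICATION)

    def bernoulli_subset(pool, p):
        if not pool or p == 0:
            return []
        keep = rng.random(len(pool)) < p
        return [t for t, k in zip(pool, keep) if k]

    prescriptions, labels = [], []
    pid_counter = 1
    for c, size in enumerate(spec.cluster_sizes()):
        for _ in range(size):
            herbs: list = []
            for attempt in range(_MAX_RESAMPLE):
                herbs = (
                    bernoulli_subset(cluster_h[c], spec.p_core)
                    + bernoulli_subset(shared_h, spec.p_shared)
                    + bernoulli_subset(noise_h, spec.p_noise)
                )
                if herbs:
                    break
            else:
                raise SyntheticSpecError(
                    f"failed to draw a non-empty herb set in {_MAX_RESAMPLE} attempts"
                )
            indications = bernoulli_subset(
                cluster_s[c], spec.p_indication
            ) + bernoulli_subset(shared_s, spec.p_shared_indication)
            prescriptions.append(
                Prescription(
                    f"P-{pid_counter}", frozenset(herbs), frozenset(indications)
                )
            )
            labels.append(c + 1)
            pid_counter += 1

    corpus = PrescriptionCorpus(prescriptions, tokens)
    planted = ClusterAssignment(
        corpus.ids,
        np.array(labels),
        spec.n_clusters,
        method="planted",
        seed=spec.seed,
    )
    return corpus, planted


def adjusted_rand_index(labels_a: ClusterAssignment, labels_b: ClusterAssignment) -> float:
    """Adjusted Rand index between two partitions of the same prescriptions.

    1 for identical partitions (up to label permutation), ~0 for random
    agreement, negative for worse-than-chance agreement.
    """
    if set(labels_a.ids) != set(labels_b.ids):
        raise ParameterError("partitions cover different prescription sets")
    lab_b = labels_b.label_of()
    aligned_b = [lab_b[pid] for pid in labels_a.ids]
    return float(adjusted_rand_score(labels_a.labels, aligned_b))


def write_planted_labels(assignment: ClusterAssignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("prescription_id\tplanted_cluster\n")
        for pid, lab in zip(assignment.ids, assignment.labels.tolist()):
            fh.write(f"{pid}\t{lab}\n")
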