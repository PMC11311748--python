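"""End-to-end analysis pipeline: corpus -> distances -> clustering -> validity -> networks.

``run_full_analysis`` executes every stage and writes all artifacts plus a
manifest with SHA-256 checksums; identical configuration and seeds give
byte-identical TSV/JSON/Newick outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from formulanet import clustering, hinetwork, similarity, validity
from formulanet.corpus_io import PrescriptionCorpus, read_corpus, write_corpus
from formulanet.errors import ConfigError, StageError
from formulanet.synthetic_data import SyntheticSpec, generate_corpus, write_planted_labels

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one full analysis run."""

    input_path: str | None = None
    synthetic_spec: SyntheticSpec | None = None
    linkage: str = "complete"
    kmeans_mode: str = "embedding"  # "embedding" | "binary"
    k: int | None = None
    k_range: tuple | None = None  # (k_min, k_max) inclusive
    seeds: tuple = (123, 12345, 148, 371, 7)
    n_init: int = 1
    min_freq: int | None = None  # common-major threshold; None = pipeline default
    output_dir: str = "formulanet_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic_spec is None):
            raise ConfigError("give exactly one of input_path or synthetic_spec")
        if self.k is None and self.k_range is None:
            raise ConfigError("give k and/or k_range")
        if self.k_range is not None and self.k_range[0] > self.k_range[1]:
            raise ConfigError(f"bad k_range {self.k_range}")
        if self.kmeans_mode not in ("embedding", "binary"):
            raise ConfigError(f"bad kmeans_mode {self.kmeans_mode!r}")
        if not self.seeds:
            raise ConfigError("seeds must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "synthetic_spec" in data and data["synthetic_spec"] is not None:
            data["synthetic_spec"] = SyntheticSpec(**data["synthetic_spec"])
        for key in ("k_range", "seeds"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage; returns the result bundle (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    bundle: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    # -- corpus ----------------------------------------------------------
    try:
        stage("corpus")
        if config.synthetic_spec is not None:
            corpus, planted = generate_corpus(config.synthetic_spec)
            write_corpus(corpus, out / "corpus.tsv")
            write_planted_labels(planted, out / "planted_labels.tsv")
            config.synthetic_spec.to_yaml(out / "synthetic_spec.yaml")
            artifacts += [out / "corpus.tsv", out / "planted_labels.tsv", out / "synthetic_spec.yaml"]
            bundle["planted"] = planted
        else:
            corpus = read_corpus(config.input_path)
        bundle["corpus"] = corpus
    except Exception as exc:  # noqa: BLE001 - wrapped with stage provenance
        raise StageError("corpus", exc) from exc

    # -- distances -------------------------------------------------------
    try:
        stage("distances")
        dist = similarity.jaccard_distance_matrix(corpus)
        similarity.write_distance_matrix(dist, out / "distances.tsv")
        artifacts.append(out / "distances.tsv")
        bundle["distances"] = dist
    except Exception as exc:
        raise StageError("distances", exc) from exc

    # -- hierarchical ----------------------------------------------------
    try:
        stage("hierarchical")
        tree = clustering.hierarchical_cluster(dist, linkage=config.linkage)
        clustering.write_dendrogram(
            tree, out / "dendrogram.nwk", out / "dendrogram_merges.tsv"
        )
        artifacts += [out / "dendrogram.nwk", out / "dendrogram_merges.tsv"]
        bundle["dendrogram"] = tree
        if config.k is not None:
            hca = clustering.cut_dendrogram(tree, config.k)
            clustering.write_assignment(hca, out / f"hca_k{config.k}.tsv")
            artifacts.append(out / f"hca_k{config.k}.tsv")
            bundle["hca_assignment"] = hca
    except Exception as exc:
        raise StageError("hierarchical", exc) from exc

    # -- sweeps ----------------------------------------------------------
    try:
        stage("sweeps")
        primary_seed = config.seeds[0]
        if config.k_range is not None:
            ks = range(config.k_range[0], config.k_range[1] + 1)
            ktab = validity.sweep_k(
                corpus, ks, seed=primary_seed, n_init=config.n_init, mode=config.kmeans_mode
            )
            ktab.to_tsv(out / "sweep_k.tsv")
            ktab.to_json(out / "sweep_k.json")
            artifacts += [out / "sweep_k.tsv", out / "sweep_k.json"]
            bundle["sweep_k"] = ktab
        if config.k is not None:
            stab = validity.sweep_seeds(
                corpus, config.k, config.seeds, n_init=config.n_init, mode=config.kmeans_mode
            )
            stab.to_tsv(out / "sweep_seeds.tsv")
            stab.to_json(out / "sweep_seeds.json")
            artifacts += [out / "sweep_seeds.tsv", out / "sweep_seeds.json"]
            bundle["sweep_seeds"] = stab
            cores = validity.stable_cores(stab.assignments)
            with open(out / "stable_cores.tsv", "w", encoding="utf-8") as fh:
                fh.write("core\tprescription_ids\n")
                for i, core in enumerate(cores, 1):
                    fh.write(f"{i}\t{','.join(sorted(core))}\n")
            artifacts.append(out / "stable_cores.tsv")
            bundle["stable_cores"] = cores
    except Exception as exc:
        raise StageError("sweeps", exc) from exc

    # -- k-means reference assignment ------------------------------------
    try:
        stage("kmeans")
        if config.k is not None:
            stab = bundle["sweep_seeds"]
            best_idx = int(stab.table["misclassification_rate"].idxmin())
            best = stab.assignments[best_idx]
            clustering.write_assignment(best, out / "kmeans_best.tsv")
            artifacts.append(out / "kmeans_best.tsv")
            bundle["kmeans_assignment"] = best
    except Exception as exc:
        raise StageError("kmeans", exc) from exc

    # -- networks --------------------------------------------------------
    try:
        stage("networks")
        full = hinetwork.build_hi_network(corpus)
        hinetwork.write_edge_list(full, out / "network_edges.tsv")
        hinetwork.write_node_table(full, out / "network_nodes.tsv")
        hinetwork.write_graphml(full, out / "network.graphml")
        artifacts += [
            out / "network_edges.tsv",
            out / "network_nodes.tsv",
            out / "network.graphml",
        ]
        bundle["network"] = full
        assignment = bundle.get("kmeans_assignment")
        subnets = {}
        if assignment is not None:
            for lab in range(1, assignment.k + 1):
                sub = hinetwork.extract_subnetwork(corpus, assignment, lab)
                hinetwork.write_edge_list(sub, out / f"subnetwork_K{lab}_edges.tsv")
                hinetwork.write_node_table(sub, out / f"subnetwork_K{lab}_nodes.tsv")
                artifacts += [
                    out / f"subnetwork_K{lab}_edges.tsv",
                    out / f"subnetwork_K{lab}_nodes.tsv",
                ]
                subnets[lab] = sub
        bundle["subnetworks"] = subnets
    except Exception as exc:
        raise StageError("networks", exc) from exc

    # -- manifest --------------------------------------------------------
    manifest = {
        "artifacts": [
            {"path": p.name, "sha256": _sha256(p)} for p in artifacts
        ]
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    bundle["manifest"] = manifest
    return bundle
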