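"""Bipartite herb-indication (H-I) co-occurrence networks.

Herbs and indications are the two node classes; a herb and an indication
are joined whenever some member prescription contains both, with edge
weight = the number of such prescriptions. Node frequency = number of
member prescriptions containing the token (what node size is proportional
to in renderings). Restricting the member set to one cluster of a
partition yields that cluster's subnetwork; subnetwork edge weights add
back up to the full network's across a partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from formulanet.corpus_io import HERB, INDICATION, PrescriptionCorpus
from formulanet.clustering import ClusterAssignment
from formulanet.errors import EmptyInputError, ParameterError


@dataclass
class BipartiteNetwork:
    """Herb/indication nodes with frequencies and co-occurrence edges."""

    graph: nx.Graph  # node attrs: kind, frequency; edge attr: weight
    members: list  # prescription ids the network was built from

    def nodes(self, kind: str | None = None) -> list:
        if kind is None:
            return list(self.graph.nodes)
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == kind]

    def frequency(self, token_id: str) -> int:
        return self.graph.nodes[token_id]["frequency"]

    def weight(self, herb_id: str, indication_id: str) -> int:
        return self.graph.edges[herb_id, indication_id]["weight"]

    def edges(self) -> list:
        """(herb_id, indication_id, weight) triples, deterministically ordered."""
        out = []
        for u, v, w in self.graph.edges(data="weight"):
            if self.graph.nodes[u]["kind"] == HERB:
                out.append((u, v, w))
            else:
                out.append((v, u, w))
        return sorted(out)

    @property
    def total_edge_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges(data="weight"))


def build_hi_network(
    corpus: PrescriptionCorpus, members=None
) -> BipartiteNetwork:
    """Build the H-I network over ``members`` (default: every prescription).

    Nodes are restricted to tokens appearing in at least one member
    prescription; a prescription without indications contributes node
    frequencies but no edges, so the total edge weight equals
    sum over members of |herbs| * |indications|.
    """
    if members is None:
        members = list(corpus.ids)
    else:
        members = list(members)
    if not members:
        raise EmptyInputError("member set is empty")
    sub = [corpus[pid] for pid in members]
    g = nx.Graph()
    for p in sub:
        for h in p.herbs:
            if not g.has_node(h):
                g.add_node(h, kind=HERB, frequency=0, name=corpus.tokens[h].name)
            g.nodes[h]["frequency"] += 1
        for s in p.indications:
            if not g.has_node(s):
                g.add_node(s, kind=INDICATION, frequency=0, name=corpus.tokens[s].name)
            g.nodes[s]["frequency"] += 1
        for h in p.herbs:
            for s in p.indications:
                if g.has_edge(h, s):
                    g.edges[h, s]["weight"] += 1
                else:
                    g.add_edge(h, s, weight=1)
    return BipartiteNetwork(graph=g, members=members)


def extract_subnetwork(
    corpus: PrescriptionCorpus,
    assignment: ClusterAssignment,
    cluster_label: int,
) -> BipartiteNetwork:
    """H-I subnetwork of one cluster of a partition."""
    if cluster_label not in set(assignment.labels.tolist()):
        raise ParameterError(f"no cluster labeled {cluster_label!r} in assignment")
    return build_hi_network(corpus, assignment.members(cluster_label))


def common_major_nodes(
    net_a: BipartiteNetwork,
    net_b: BipartiteNetwork,
    kind: str,
    min_freq: int | None = None,
    top_n: int | None = None,
) -> list:
    """Tokens of one kind that are 'major' in BOTH networks.

    Exactly one threshold mode must be given: ``min_freq`` keeps tokens
    whose frequency reaches the threshold in both networks; ``top_n`` keeps
    tokens in the top-n by frequency of each network. Ordered by
    (min frequency across the two networks desc, token_id asc).
    """
    if (min_freq is None) == (top_n is None):
        raise ParameterError("give exactly one of min_freq or top_n")

    def majors(net: BipartiteNetwork) -> set:
        toks = net.nodes(kind)
        if min_freq is not None:
            return {t for t in toks if net.frequency(t) >= min_freq}
        ranked = sorted(toks, key=lambda t: (-net.frequency(t), t))
        return set(ranked[:top_n])

    common = majors(net_a) & majors(net_b)
    return sorted(
        common, key=lambda t: (-min(net_a.frequency(t), net_b.frequency(t)), t)
    )


def default_min_freq(net_a: BipartiteNetwork, net_b: BipartiteNetwork) -> int:
    """Pipeline default threshold: ceil(half the smaller member-set size)."""
    smaller = min(len(net_a.members), len(net_b.members))
    return -(-smaller // 2)


# -- exports ---------------------------------------------------------------


def write_edge_list(net: BipartiteNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("herb_id\tindication_id\tweight\n")
        for h, s, w in net.edges():
            fh.write(f"{h}\t{s}\t{w}\n")


def write_node_table(net: BipartiteNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("token_id\tkind\tfrequency\n")
        rows = sorted(
            (n, d["kind"], d["frequency"]) for n, d in net.graph.nodes(data=True)
        )
        for tid, kind, freq in rows:
            fh.write(f"{tid}\t{kind}\t{freq}\n")


def write_graphml(net: BipartiteNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def layout(net: BipartiteNetwork, seed: int = 0) -> dict:
    """Force-directed layout with heavier edges pulling nodes closer.

    Coordinates are for export convenience only and are not contractual.
    """
    return nx.spring_layout(net.graph, weight="weight", seed=seed)
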