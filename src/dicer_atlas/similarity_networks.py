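"""Sequence- and structure-similarity networks and their clustering.

Sequence mode connects proteins whose pairwise alignment reaches 50 %
identity at 80 % coverage of *both* sequences (inclusive thresholds);
structure mode connects AlphaFold models with mean pLDDT >= 70 whose
(direction-averaged) TM-score reaches 0.9. Clusters are the connected
components; the hub of a cluster is its maximum-degree member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

DEFAULT_IDENTITY_MIN = 50.0
DEFAULT_COVERAGE_MIN = 80.0
DEFAULT_TM_MIN = 0.9
DEFAULT_PLDDT_MIN = 70.0


def build_sequence_network(
    pairs: pd.DataFrame | Iterable[tuple],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> nx.Graph:
    """Thresholded sequence-similarity graph from a pairwise hit table.

    ``pairs`` rows are (id_a, id_b, identity, coverage_a, coverage_b)
    with identity/coverage in percent. Self-hits are dropped; reciprocal
    duplicates collapse to one undirected edge keeping the maximum
    identity; an edge is retained iff identity >= ``identity_min`` and
    min(coverage_a, coverage_b) >= ``coverage_min``. Every id seen in
    the table becomes a node, so proteins failing the cut-offs remain
    as singletons.
    """
    if isinstance(pairs, pd.DataFrame):
        rows = pairs.itertuples(index=False)
    else:
        rows = iter(pairs)
    graph = nx.Graph()
    for row in rows:
        id_a, id_b, identity, cov_a, cov_b = row[:5]
        for value, name in ((identity, "identity"), (cov_a, "coverage_a"),
                            (cov_b, "coverage_b")):
            if not 0.0 <= float(value) <= 100.0:
                raise ValueError(f"{name} {value} outside [0, 100]")
        graph.add_node(id_a)
        graph.add_node(id_b)
        if id_a == id_b:
            continue  # self-hit
        if identity >= identity_min and min(cov_a, cov_b) >= coverage_min:
            prev = graph.get_edge_data(id_a, id_b)
            if prev is None or identity > prev["identity"]:
                graph.add_edge(id_a, id_b, identity=float(identity))
    return graph


def build_structure_network(
    tm_pairs: pd.DataFrame | Iterable[tuple],
    mean_plddt: Mapping[str, float],
    tm_min: float = DEFAULT_TM_MIN,
    plddt_min: float = DEFAULT_PLDDT_MIN,
) -> nx.Graph:
    """Thresholded structural-similarity graph from TM-score pairs.

    ``tm_pairs`` rows are (id_a, id_b, tm_score) with TM in [0, 1];
    asymmetric directions (a->b and b->a) are averaged before
    thresholding. Models whose mean pLDDT is below ``plddt_min`` are
    excluded entirely (inclusive threshold).
    """
    if isinstance(tm_pairs, pd.DataFrame):
        rows = tm_pairs.itertuples(index=False)
    else:
        rows = iter(tm_pairs)
    passing = {m for m, p in mean_plddt.items() if p >= plddt_min}
    graph = nx.Graph()
    graph.add_nodes_from(sorted(passing))
    scores: dict[frozenset, list[float]] = {}
    for row in rows:
        id_a, id_b, tm = row[:3]
        if not 0.0 <= float(tm) <= 1.0:
            raise ValueError(f"TM-score {tm} outside [0, 1]")
        if id_a == id_b or id_a not in passing or id_b not in passing:
            continue
        scores.setdefault(frozenset((id_a, id_b)), []).append(float(tm))
    for pair, values in scores.items():
        tm_avg = sum(values) / len(values)
        if tm_avg >= tm_min:
            id_a, id_b = sorted(pair)
            graph.add_edge(id_a, id_b, tm_score=tm_avg)
    return graph


@dataclass
class Clustering:
    """Connected-component clustering with per-cluster hubs.

    Clusters are numbered 1.. in order of descending size, ties broken
    by the lexicographically smallest member. The hub of a cluster is
    its maximum-degree member, ties broken lexicographically. Singleton
    clusters are flagged.
    """

    members: dict[int, list] = field(default_factory=dict)
    hubs: dict[int, object] = field(default_factory=dict)
    singleton_ids: set = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def assignment(self) -> dict:
        """node -> cluster id map."""
        return {node: cid for cid, nodes in self.members.items() for node in nodes}

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": cid, "member": str(node), "is_hub": node == self.hubs[cid],
             "singleton": cid in self.singleton_ids}
            for cid, nodes in self.members.items()
            for node in nodes
        ]
        return pd.DataFrame(rows)


def connected_components(graph: nx.Graph) -> Clustering:
    """Cluster a similarity graph into its connected components."""
    comps = sorted(
        (sorted(c, key=str) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), str(c[0])),
    )
    result = Clustering()
    for cid, nodes in enumerate(comps, start=1):
        result.members[cid] = nodes
        result.hubs[cid] = min(
            nodes, key=lambda n: (-graph.degree(n), str(n))
        )
        if len(nodes) == 1:
            result.singleton_ids.add(cid)
    return result


def write_edge_list(graph: nx.Graph, stream) -> None:
    stream.write("id_a\tid_b\tweight\n")
    for a, b, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        weight = data.get("identity", data.get("tm_score", 1.0))
        stream.write(f"{a}\t{b}\t{weight}\n")


def read_pairs_tsv(stream, columns: Sequence[str]) -> pd.DataFrame:
    """Read a whitespace/TSV pair table with the given column layout."""
    return pd.read_csv(stream, sep="\t", names=list(columns), comment="#",
                       header=None, skip_blank_lines=True)
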