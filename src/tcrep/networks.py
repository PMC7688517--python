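"""Cross-animal clone sharing and CDR3 similarity networks.

*Sharing* asks which exact CDR3 sequences occur in two or more animals
(public clones) and whether they are confined to one response group.
*Similarity networks* connect unique CDR3 sequences at Levenshtein
distance exactly 1 — a single amino-acid substitution, insertion or
deletion — over the union of each animal's most abundant clones;
connected components of related sequences are then screened for
group exclusivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import networkx as nx
import pandas as pd

from .filtering import top_n_clones
from .repertoire import Group, RepertoireSet, ValidationError

__all__ = [
    "levenshtein",
    "OverlapResult",
    "shared_clones",
    "CloneNetwork",
    "build_network",
    "NetworkSummary",
    "network_summary",
    "write_graphml",
]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion all 1)."""
    if not a or not b:
        raise ValidationError("levenshtein distance requires non-empty strings")
    return int(edlib.align(a, b, task="distance")["editDistance"])


def _presence(
    rset: RepertoireSet,
) -> dict[str, set[str]]:
    """cdr3 -> set of animal ids whose (filtered) repertoire contains it."""
    presence: dict[str, set[str]] = {}
    for rep in rset:
        for clone in rep:
            presence.setdefault(clone.cdr3_aa, set()).add(rep.animal_id)
    return presence


def _sharing_class(n_resp: int, n_nonresp: int) -> str:
    if n_resp and not n_nonresp:
        return "responders_only"
    if n_nonresp and not n_resp:
        return "non_responders_only"
    return "mixed"


@dataclass(frozen=True)
class OverlapResult:
    """Public-clone table plus the sharing-degree histogram.

    ``table`` has one row per clone found in >= 2 animals: cdr3_aa,
    n_animals_total, n_responders, n_non_responders, sharing_class.
    ``degree_histogram`` counts clones by the number of animals sharing
    them.
    """

    table: pd.DataFrame
    degree_histogram: pd.DataFrame
    excluded: tuple[str, ...] = field(default=())


def shared_clones(
    rset: RepertoireSet, exclude: Iterable[str] | None = None
) -> OverlapResult:
    """Clones shared by two or more grouped animals.

    The tracked (transferred) clones are excluded by default — they are
    shared by construction, not by convergent recruitment. Pass
    ``exclude=[]`` to keep them. Animals without an assigned response
    group are ignored.
    """
    grouped = rset.grouped()
    if len(grouped) < 2:
        raise ValidationError(
            f"sharing analysis needs >= 2 grouped animals, got {len(grouped)}"
        )
    excluded = tuple(rset.tracked_clones if exclude is None else exclude)
    groups = {rep.animal_id: rep.group for rep in grouped}
    rows = []
    for cdr3, animals in _presence(grouped).items():
        if cdr3 in excluded or len(animals) < 2:
            continue
        n_resp = sum(1 for a in animals if groups[a] == Group.RESPONDER)
        n_nonresp = len(animals) - n_resp
        rows.append(
            {
                "cdr3_aa": cdr3,
                "n_animals_total": len(animals),
                "n_responders": n_resp,
                "n_non_responders": n_nonresp,
                "sharing_class": _sharing_class(n_resp, n_nonresp),
            }
        )
    columns = [
        "cdr3_aa",
        "n_animals_total",
        "n_responders",
        "n_non_responders",
        "sharing_class",
    ]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.sort_values(
            ["n_animals_total", "cdr3_aa"], ascending=[False, True]
        ).reset_index(drop=True)
    hist = (
        table["n_animals_total"]
        .value_counts()
        .sort_index()
        .rename_axis("n_animals")
        .reset_index(name="n_clones")
        if len(table)
        else pd.DataFrame(columns=["n_animals", "n_clones"])
    )
    return OverlapResult(table=table, degree_histogram=hist, excluded=excluded)


@dataclass
class CloneNetwork:
    """Graph over unique CDR3 sequences with Levenshtein-1 edges.

    Node attributes: ``n_animals`` (how many grouped animals carry the
    clone anywhere in their repertoire) and ``group_presence``
    (responders_only / non_responders_only / both).
    """

    graph: nx.Graph
    top_n: int

    @property
    def components(self) -> list[frozenset[str]]:
        return sorted(
            (frozenset(c) for c in nx.connected_components(self.graph)),
            key=lambda c: (-len(c), min(c)),
        )

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"cdr3_a": min(u, v), "cdr3_b": max(u, v)}
            for u, v in self.graph.edges()
        ]
        df = pd.DataFrame(rows, columns=["cdr3_a", "cdr3_b"])
        return df.sort_values(["cdr3_a", "cdr3_b"]).reset_index(drop=True)

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "cdr3_aa": node,
                "n_animals": data["n_animals"],
                "group_presence": data["group_presence"],
                "degree": self.graph.degree(node),
            }
            for node, data in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["cdr3_aa", "n_animals", "group_presence", "degree"]
        )


def _group_presence(animals: set[str], groups: dict[str, Group]) -> str:
    n_resp = sum(1 for a in animals if groups[a] == Group.RESPONDER)
    n_nonresp = len(animals) - n_resp
    if n_resp and n_nonresp:
        return "both"
    return "responders_only" if n_resp else "non_responders_only"


def build_network(
    rset: RepertoireSet,
    top_n: int = 50,
    exclude: Sequence[str] = (),
) -> CloneNetwork:
    """Build the similarity network over each grouped animal's top clones.

    Nodes are the union, over animals, of the ``top_n`` most abundant
    clones (the tracked clone is included by default — it typically ranks
    first; pass it in ``exclude`` to drop it). Node attributes are counted
    over animals' *full* repertoires, not just their top lists. Edges
    connect every pair of nodes at Levenshtein distance exactly 1; a
    length-difference <= 1 pre-filter skips pairs that cannot be that
    close. Exhaustive O(V²) comparison is instant at cohort scale.
    """
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n}")
    grouped = rset.grouped()
    excluded = set(exclude)
    nodes: set[str] = set()
    for rep in grouped:
        nodes.update(
            cdr3 for cdr3, _ in top_n_clones(rep, top_n) if cdr3 not in excluded
        )
    if not nodes:
        raise ValidationError("network node set is empty")

    presence = _presence(grouped)
    groups = {rep.animal_id: rep.group for rep in grouped}
    graph = nx.Graph()
    ordered = sorted(nodes)
    for node in ordered:
        animals = presence[node]
        graph.add_node(
            node,
            n_animals=len(animals),
            group_presence=_group_presence(animals, groups),
        )
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if abs(len(a) - len(b)) > 1:
                continue
            if levenshtein(a, b) == 1:
                graph.add_edge(a, b)
    return CloneNetwork(graph=graph, top_n=top_n)


@dataclass(frozen=True)
class NetworkSummary:
    """Headline counts of a clone network.

    ``n_nodes_in_networks`` counts clones related to at least one other
    clone (degree >= 1); ``group_exclusive_components`` lists components
    of size >= 2 whose every clone occurs in only one response group.
    """

    n_nodes: int
    n_edges: int
    n_nodes_in_networks: int
    n_components_ge2: int
    group_exclusive_components: tuple[tuple[str, tuple[str, ...]], ...]

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "n_nodes": self.n_nodes,
                "n_edges": self.n_edges,
                "n_nodes_in_networks": self.n_nodes_in_networks,
                "n_components_ge2": self.n_components_ge2,
                "group_exclusive_components": [
                    {"group_presence": cls, "cdr3_sequences": list(seqs)}
                    for cls, seqs in self.group_exclusive_components
                ],
            },
            **kwargs,
        )


def network_summary(net: CloneNetwork) -> NetworkSummary:
    g = net.graph
    comps_ge2 = [c for c in net.components if len(c) >= 2]
    exclusive = []
    for comp in comps_ge2:
        presences = {g.nodes[n]["group_presence"] for n in comp}
        if presences == {"responders_only"} or presences == {
            "non_responders_only"
        }:
            exclusive.append((presences.pop(), tuple(sorted(comp))))
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_nodes_in_networks=sum(1 for n in g if g.degree(n) >= 1),
        n_components_ge2=len(comps_ge2),
        group_exclusive_components=tuple(exclusive),
    )


def write_graphml(net: CloneNetwork, path: str | Path) -> None:
    """Export the network with node attributes to GraphML."""
    nx.write_graphml(net.graph, str(path))
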