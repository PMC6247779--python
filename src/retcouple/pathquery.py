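"""Regex path queries over typed connectome graphs.

A query is a comma-separated alternation of node regexes and edge kinds,
e.g. ``"CB.*, ribbon, GC.*"``: find every bipolar cell whose class label
matches ``CB.*`` making a ribbon synapse onto a ganglion cell. Node regexes
are anchored (full match against the class label). Chemical synapse hops
(``ribbon``, ``conventional``) traverse pre -> post only; ``gap junction``
and ``any`` hops traverse in either direction. Matches are simple paths
(no repeated neuron), returned in a deterministic sorted order.

This is the mining primitive behind coupled-network motifs such as
``GC1 :: AC > GC2``: a ganglion cell gap-junction-coupled to an amacrine
cell that feeds forward onto a second, disjoint-class ganglion cell.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .model import ConnectomeGraph

EDGE_VOCABULARY = {
    "ribbon": "ribbon",
    "conventional": "conventional",
    "gap junction": "gap_junction",
    "gap_junction": "gap_junction",
    "any": "any",
}


class QuerySyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class PathPattern:
    node_patterns: tuple[re.Pattern, ...]
    edge_kinds: tuple[str, ...]

    def __post_init__(self):
        if not self.node_patterns:
            raise QuerySyntaxError("pattern needs at least one node regex")
        if len(self.node_patterns) != len(self.edge_kinds) + 1:
            raise QuerySyntaxError("need exactly one more node pattern than edge kinds")

    @property
    def n_hops(self) -> int:
        return len(self.edge_kinds)


@dataclass(frozen=True)
class PathMatch:
    neuron_ids: tuple[str, ...]
    contact_ids: tuple[str, ...]


def parse_query(text: str) -> PathPattern:
    """Compile a comma-separated query string into a PathPattern.

    Odd positions (1st, 3rd, ...) are node regexes; even positions are edge
    kinds from {ribbon, conventional, gap junction, any}. The token count
    must be odd.
    """
    tokens = [t.strip() for t in text.split(",")]
    if len(tokens) % 2 == 0:
        raise QuerySyntaxError(
            f"query must have an odd number of comma-separated tokens, got {len(tokens)}"
        )
    node_patterns = []
    edge_kinds = []
    for pos, token in enumerate(tokens):
        if pos % 2 == 0:
            try:
                node_patterns.append(re.compile(token))
            except re.error as err:
                raise QuerySyntaxError(f"invalid regex at position {pos}: {err}") from None
        else:
            if token not in EDGE_VOCABULARY:
                raise QuerySyntaxError(
                    f"unknown edge kind {token!r} at position {pos}; "
                    f"expected one of {sorted(set(EDGE_VOCABULARY))}"
                )
            edge_kinds.append(EDGE_VOCABULARY[token])
    return PathPattern(tuple(node_patterns), tuple(edge_kinds))


def _adjacency(graph: ConnectomeGraph) -> dict[str, list]:
    """neuron id -> [(kind, contact_id, neighbour_id)], directed synapses
    traversable pre->post only, gap junctions both ways."""
    adj: dict[str, list] = defaultdict(list)
    for c in graph.contacts.values():
        if c.kind == "gap_junction":
            adj[c.pre_id].append((c.kind, c.id, c.post_id))
            adj[c.post_id].append((c.kind, c.id, c.pre_id))
        else:
            adj[c.pre_id].append((c.kind, c.id, c.post_id))
    return adj


def _kind_matches(hop_kind: str, contact_kind: str) -> bool:
    if hop_kind == "any":
        return True
    # bipolar-cell ribbonless presynapses count as conventional for queries
    if hop_kind == "conventional":
        return contact_kind in ("conventional", "bc_conventional")
    return hop_kind == contact_kind


def find_paths(graph: ConnectomeGraph, pattern: PathPattern) -> list[PathMatch]:
    """All simple paths matching the pattern, sorted by id sequence."""
    adj = _adjacency(graph)
    matches: list[PathMatch] = []

    def extend(path_neurons: list[str], path_contacts: list[str]) -> None:
        depth = len(path_contacts)
        if depth == pattern.n_hops:
            matches.append(PathMatch(tuple(path_neurons), tuple(path_contacts)))
            return
        hop_kind = pattern.edge_kinds[depth]
        node_re = pattern.node_patterns[depth + 1]
        for kind, contact_id, neighbour in adj[path_neurons[-1]]:
            if neighbour in path_neurons:
                continue
            if not _kind_matches(hop_kind, kind):
                continue
            if not node_re.fullmatch(graph.neurons[neighbour].class_label):
                continue
            extend(path_neurons + [neighbour], path_contacts + [contact_id])

    first = pattern.node_patterns[0]
    for neuron_id in graph.neurons:
        if first.fullmatch(graph.neurons[neuron_id].class_label):
            extend([neuron_id], [])
    matches.sort(key=lambda m: (m.neuron_ids, m.contact_ids))
    return matches


def count_matches(
    matches: list[PathMatch], graph: ConnectomeGraph, group_by: str = "none"
) -> pd.Series:
    """Tally matches per group; the tally always sums to len(matches)."""
    if group_by == "none":
        keys = ["all"] * len(matches)
    elif group_by == "first_class":
        keys = [graph.neurons[m.neuron_ids[0]].class_label for m in matches]
    elif group_by == "last_class":
        keys = [graph.neurons[m.neuron_ids[-1]].class_label for m in matches]
    elif group_by == "endpoint_pair":
        keys = [
            (
                graph.neurons[m.neuron_ids[0]].class_label,
                graph.neurons[m.neuron_ids[-1]].class_label,
            )
            for m in matches
        ]
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    if not matches:
        return pd.Series(dtype=int, name="count")
    return pd.Series(keys, name="count").value_counts().sort_index()


def disjoint_filter(
    matches: list[PathMatch], graph: ConnectomeGraph, pos_a: int, pos_b: int
) -> list[PathMatch]:
    """Keep matches whose neurons at two positions belong to different classes.

    Implements the disjointness constraint of coupled-feedforward chains:
    the coupled ganglion cell and the feedforward target must be of
    different classes.
    """
    out = []
    for m in matches:
        if pos_a >= len(m.neuron_ids) or pos_b >= len(m.neuron_ids) or pos_a < 0 or pos_b < 0:
            raise IndexError(f"positions ({pos_a}, {pos_b}) out of range for match {m}")
        if (
            graph.neurons[m.neuron_ids[pos_a]].class_label
            != graph.neurons[m.neuron_ids[pos_b]].class_label
        ):
            out.append(m)
    return out


def matches_to_frame(matches: list[PathMatch]) -> pd.DataFrame:
    """One row per match; columns neuron_0..neuron_k, contact_0..contact_{k-1}."""
    rows = []
    for m in matches:
        row = {f"neuron_{i}": nid for i, nid in enumerate(m.neuron_ids)}
        row.update({f"contact_{i}": cid for i, cid in enumerate(m.contact_ids)})
        rows.append(row)
    return pd.DataFrame(rows)
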