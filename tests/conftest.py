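import itertools

import numpy as np
import pytest

from retcouple.model import ConnectomeGraph, Contact, Neuron
from retcouple.pathquery import PathMatch, PathPattern
from retcouple.synthetic import rc1_summary_fixture


@pytest.fixture(scope="session")
def fixture_graph():
    return rc1_summary_fixture()


def build_graph(neurons, contacts):
    """neurons: [(id, class_label, polarity?, superclass?)], contacts: [(id, kind, pre, post, area)]."""
    g = ConnectomeGraph()
    for spec in neurons:
        nid, label = spec[0], spec[1]
        polarity = spec[2] if len(spec) > 2 else "unknown"
        superclass = spec[3] if len(spec) > 3 else "unknown"
        g.add_neuron(Neuron(id=nid, class_label=label, polarity=polarity, superclass=superclass))
    for cid, kind, pre, post, area in contacts:
        g.add_contact(Contact(id=cid, kind=kind, pre_id=pre, post_id=post, area_um2=area))
    return g


@pytest.fixture
def toy_graph():
    """Six neurons, a handful of typed contacts, covering every edge kind."""
    return build_graph(
        [
            ("b1", "CBb4w", "ON", "bipolar"),
            ("b2", "CBb5", "ON", "bipolar"),
            ("g1", "GC tON DS", "ON", "ganglion"),
            ("g2", "GC ON", "ON", "ganglion"),
            ("a1", "IAC", "ON", "amacrine"),
            ("a2", "wfAC", "ON", "amacrine"),
        ],
        [
            ("c1", "ribbon", "b1", "g1", 0.1),
            ("c2", "ribbon", "b1", "g1", 0.2),
            ("c3", "ribbon", "b2", "g1", 0.3),
            ("c4", "conventional", "a1", "g1", 0.05),
            ("c5", "conventional", "a1", "g2", 0.05),
            ("c6", "conventional", "a1", "b1", 0.05),
            ("c7", "gap_junction", "g1", "a1", 0.03),
            ("c8", "gap_junction", "a2", "g1", 0.02),
            ("c9", "bc_conventional", "b2", "g2", 0.04),
        ],
    )


# --- independent brute-force oracle for path queries -----------------------

def brute_force_paths(graph, pattern: PathPattern):
    """Exhaustive enumeration over all neuron tuples and contact choices.

    Independent of the engine's DFS: first enumerate every sequence of
    distinct neurons whose labels match the node regexes, then every way of
    realizing each hop with a concrete contact of the required kind.
    """
    ids = sorted(graph.neurons)
    k = len(pattern.node_patterns)
    matches = []
    for combo in itertools.permutations(ids, k):
        if not all(
            p.fullmatch(graph.neurons[nid].class_label)
            for p, nid in zip(pattern.node_patterns, combo)
        ):
            continue
        hop_choices = []
        ok = True
        for (u, v), kind in zip(zip(combo, combo[1:]), pattern.edge_kinds):
            options = []
            for c in graph.contacts.values():
                traversable = (c.pre_id, c.post_id) == (u, v) or (
                    c.kind == "gap_junction" and (c.pre_id, c.post_id) == (v, u)
                )
                if kind == "any":
                    kind_ok = True
                elif kind == "conventional":
                    kind_ok = c.kind in ("conventional", "bc_conventional")
                else:
                    kind_ok = c.kind == kind
                if traversable and kind_ok:
                    options.append(c.id)
            if not options:
                ok = False
                break
            hop_choices.append(options)
        if not ok:
            continue
        for contact_combo in itertools.product(*hop_choices):
            matches.append(PathMatch(tuple(combo), tuple(contact_combo)))
    matches.sort(key=lambda m: (m.neuron_ids, m.contact_ids))
    return matches


_LABELS = ["A", "B", "AB", "C1", "C2"]
_KINDS = ["ribbon", "conventional", "bc_conventional", "gap_junction"]
_NODE_REGEXES = ["A", "B", "AB", ".*", "A.*", "C.", "AB?", "C[12]"]
_EDGE_TOKENS = ["ribbon", "conventional", "gap_junction", "any"]


def random_graph(rng: np.random.Generator, max_neurons=8, max_contacts=20):
    n = int(rng.integers(2, max_neurons + 1))
    neurons = [(f"n{i}", _LABELS[int(rng.integers(len(_LABELS)))]) for i in range(n)]
    contacts = []
    for j in range(int(rng.integers(0, max_contacts + 1))):
        pre, post = rng.choice(n, size=2, replace=False)
        kind = _KINDS[int(rng.integers(len(_KINDS)))]
        contacts.append((f"c{j}", kind, f"n{pre}", f"n{post}", float(rng.uniform(0.01, 0.2))))
    return build_graph(neurons, contacts)


def random_pattern(rng: np.random.Generator, max_hops=3) -> str:
    hops = int(rng.integers(0, max_hops + 1))
    tokens = [_NODE_REGEXES[int(rng.integers(len(_NODE_REGEXES)))]]
    for _ in range(hops):
        tokens.append(_EDGE_TOKENS[int(rng.integers(len(_EDGE_TOKENS)))])
        tokens.append(_NODE_REGEXES[int(rng.integers(len(_NODE_REGEXES)))])
    return ", ".join(tokens)
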