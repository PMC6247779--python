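"""Typed attributed-graph model for retinal connectomes.

Neurons carry a class label (e.g. ``CBb4w``, ``GC tON DS``), a superclass
(photoreceptor / horizontal / bipolar / amacrine / ganglion, or ``unknown``
for orphan processes), response polarity, and transmitter content.
Intercellular contacts are either directed chemical synapses (glutamatergic
``ribbon`` synapses of bipolar cells, inhibitory ``conventional`` synapses of
amacrine cells, ribbonless ``bc_conventional`` presynapses of bipolar cells)
or undirected ``gap_junction`` electrical contacts.

Gap junctions are stored canonically with the lexicographically smaller
endpoint first; every consumer treats them as symmetric. When both a junction
diameter and an area are present they must agree under a circular-disc model,
area = pi * (d/2)^2.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

SUPERCLASSES = ("photoreceptor", "horizontal", "bipolar", "amacrine", "ganglion", "unknown")
POLARITIES = ("ON", "OFF", "ON_OFF", "unknown")
TRANSMITTERS = ("GABA", "glycine", "glutamate", "acetylcholine_GABA", "unknown")
CONTACT_KINDS = ("ribbon", "conventional", "bc_conventional", "gap_junction")

#: Prefix/label roster mapping class labels to (superclass, polarity, transmitter).
#: Exact labels take precedence over prefix rules. A superclass given explicitly
#: on a node row always overrides the roster.
CLASS_ROSTER: dict[str, tuple[str, str, str]] = {
    "AII": ("amacrine", "ON_OFF", "glycine"),
    "AI": ("amacrine", "ON", "GABA"),
    "IAC": ("amacrine", "ON", "GABA"),
    "SAC ON": ("amacrine", "ON", "acetylcholine_GABA"),
    "SAC OFF": ("amacrine", "OFF", "acetylcholine_GABA"),
    "YAC": ("amacrine", "OFF", "GABA"),
    "wfAC": ("amacrine", "ON", "GABA"),
    "GAC": ("amacrine", "unknown", "glycine"),
    "RB": ("bipolar", "ON", "glutamate"),
    "HC": ("horizontal", "unknown", "GABA"),
    "Rod": ("photoreceptor", "unknown", "glutamate"),
    "Cone": ("photoreceptor", "unknown", "glutamate"),
}

_PREFIX_ROSTER: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("CBb", ("bipolar", "ON", "glutamate")),
    ("CBa", ("bipolar", "OFF", "glutamate")),
    ("GC ON OFF", ("ganglion", "ON_OFF", "glutamate")),
    ("GC ON", ("ganglion", "ON", "glutamate")),
    ("GC OFF", ("ganglion", "OFF", "glutamate")),
    ("GC tON", ("ganglion", "ON", "glutamate")),
    ("GC", ("ganglion", "unknown", "glutamate")),
    ("YAC", ("amacrine", "unknown", "GABA")),
    ("AC", ("amacrine", "unknown", "GABA")),
)


def roster_lookup(class_label: str) -> Optional[tuple[str, str, str]]:
    """Resolve (superclass, polarity, transmitter) for a class label, or None."""
    if class_label in CLASS_ROSTER:
        return CLASS_ROSTER[class_label]
    for prefix, attrs in _PREFIX_ROSTER:
        if class_label.startswith(prefix):
            return attrs
    return None


class FormatError(ValueError):
    """Raised for malformed input files (missing columns, bad values)."""


class ReferentialError(ValueError):
    """Raised when a contact references a neuron id absent from the node table."""


@dataclass
class Neuron:
    id: str
    class_label: str
    superclass: str = "unknown"
    polarity: str = "unknown"
    transmitter: str = "unknown"
    gaba_mM: Optional[float] = None
    soma_diameter_um: Optional[float] = None
    arbor_fraction: Optional[float] = None
    dendrite_length_um: Optional[float] = None


@dataclass
class Contact:
    id: str
    kind: str
    pre_id: str
    post_id: str
    area_um2: float
    diameter_nm: Optional[float] = None
    location: Optional[tuple[float, float, float]] = None
    validated: bool = False

    def canonicalized(self) -> "Contact":
        """Gap junctions are symmetric: store the smaller endpoint id first."""
        if self.kind == "gap_junction" and self.post_id < self.pre_id:
            return replace(self, pre_id=self.post_id, post_id=self.pre_id)
        return self


def diameter_to_area(d_nm: float) -> float:
    """Area in um^2 of a circular disc of diameter ``d_nm`` nanometres."""
    if d_nm < 0:
        raise ValueError(f"diameter must be nonnegative, got {d_nm}")
    return math.pi * (d_nm / 2.0) ** 2 * 1e-6


def area_to_diameter(area_um2: float) -> float:
    """Disc diameter in nm for an area in um^2 (inverse of diameter_to_area)."""
    if area_um2 < 0:
        raise ValueError(f"area must be nonnegative, got {area_um2}")
    return 2.0 * math.sqrt(area_um2 * 1e6 / math.pi)


@dataclass
class ConnectomeGraph:
    neurons: dict[str, Neuron] = field(default_factory=dict)
    contacts: dict[str, Contact] = field(default_factory=dict)

    def add_neuron(self, neuron: Neuron) -> None:
        if neuron.id in self.neurons:
            raise ValueError(f"duplicate neuron id {neuron.id!r}")
        self.neurons[neuron.id] = neuron

    def add_contact(self, contact: Contact) -> None:
        if contact.id in self.contacts:
            raise ValueError(f"duplicate contact id {contact.id!r}")
        for endpoint in (contact.pre_id, contact.post_id):
            if endpoint not in self.neurons:
                raise ReferentialError(
                    f"contact {contact.id!r} references unknown neuron {endpoint!r}"
                )
        self.contacts[contact.id] = contact.canonicalized()

    def contacts_of(self, neuron_id: str, kind: Optional[str] = None) -> list[Contact]:
        """All contacts touching a neuron, optionally restricted to one kind."""
        out = []
        for c in self.contacts.values():
            if neuron_id not in (c.pre_id, c.post_id):
                continue
            if kind is not None and c.kind != kind:
                continue
            out.append(c)
        return out

    def incoming(self, neuron_id: str, kind: Optional[str] = None) -> list[Contact]:
        """Directed contacts terminating on a neuron (gap junctions excluded)."""
        return [
            c
            for c in self.contacts.values()
            if c.post_id == neuron_id
            and c.kind != "gap_junction"
            and (kind is None or c.kind == kind)
        ]

    def outgoing(self, neuron_id: str, kind: Optional[str] = None) -> list[Contact]:
        return [
            c
            for c in self.contacts.values()
            if c.pre_id == neuron_id
            and c.kind != "gap_junction"
            and (kind is None or c.kind == kind)
        ]

    def gap_junctions_of(self, neuron_id: str) -> list[Contact]:
        return [
            c
            for c in self.contacts.values()
            if c.kind == "gap_junction" and neuron_id in (c.pre_id, c.post_id)
        ]


NODE_COLUMNS = [
    "id",
    "class_label",
    "superclass",
    "polarity",
    "transmitter",
    "gaba_mM",
    "soma_diameter_um",
    "arbor_fraction",
    "dendrite_length_um",
]
EDGE_COLUMNS = [
    "id",
    "kind",
    "pre_id",
    "post_id",
    "area_um2",
    "diameter_nm",
    "x_nm",
    "y_nm",
    "z_nm",
    "validated",
]

_OPTIONAL_FLOAT_NODE = ("gaba_mM", "soma_diameter_um", "arbor_fraction", "dendrite_length_um")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_graph(nodes_path, edges_path) -> ConnectomeGraph:
    """Read a connectome from tab-separated node and edge tables.

    Raises FormatError on missing columns and ReferentialError (with the
    offending row index) on dangling endpoints.
    """
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"id": str}, float_precision="round_trip")
    edges = pd.read_csv(
        edges_path,
        sep="\t",
        dtype={"id": str, "pre_id": str, "post_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in NODE_COLUMNS if c not in nodes.columns]
    if missing:
        raise FormatError(f"{nodes_path}: missing node columns {missing}")
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise FormatError(f"{edges_path}: missing edge columns {missing}")

    graph = ConnectomeGraph()
    for row in nodes.itertuples(index=False):
        superclass = row.superclass if isinstance(row.superclass, str) and row.superclass else None
        rostered = roster_lookup(row.class_label)
        if superclass is None:
            superclass = rostered[0] if rostered else "unknown"
        polarity = row.polarity if isinstance(row.polarity, str) and row.polarity else (
            rostered[1] if rostered else "unknown"
        )
        transmitter = row.transmitter if isinstance(row.transmitter, str) and row.transmitter else (
            rostered[2] if rostered else "unknown"
        )
        graph.add_neuron(
            Neuron(
                id=str(row.id),
                class_label=row.class_label,
                superclass=superclass,
                polarity=polarity,
                transmitter=transmitter,
                gaba_mM=_opt_float(row.gaba_mM),
                soma_diameter_um=_opt_float(row.soma_diameter_um),
                arbor_fraction=_opt_float(row.arbor_fraction),
                dendrite_length_um=_opt_float(row.dendrite_length_um),
            )
        )
    for i, row in enumerate(edges.itertuples(index=False)):
        x, y, z = _opt_float(row.x_nm), _opt_float(row.y_nm), _opt_float(row.z_nm)
        location = (x, y, z) if None not in (x, y, z) else None
        contact = Contact(
            id=str(row.id),
            kind=row.kind,
            pre_id=str(row.pre_id),
            post_id=str(row.post_id),
            area_um2=float(row.area_um2),
            diameter_nm=_opt_float(row.diameter_nm),
            location=location,
            validated=str(row.validated).strip().lower() in ("true", "1"),
        )
        try:
            graph.add_contact(contact)
        except ReferentialError as err:
            raise ReferentialError(f"{edges_path} row {i}: {err}") from None
    return graph


def _nodes_frame(graph: ConnectomeGraph) -> pd.DataFrame:
    rows = []
    for n in graph.neurons.values():
        rows.append(
            {
                "id": n.id,
                "class_label": n.class_label,
                "superclass": n.superclass,
                "polarity": n.polarity,
                "transmitter": n.transmitter,
                "gaba_mM": n.gaba_mM,
                "soma_diameter_um": n.soma_diameter_um,
                "arbor_fraction": n.arbor_fraction,
                "dendrite_length_um": n.dendrite_length_um,
            }
        )
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def _edges_frame(graph: ConnectomeGraph) -> pd.DataFrame:
    rows = []
    for c in graph.contacts.values():
        x, y, z = c.location if c.location else (None, None, None)
        rows.append(
            {
                "id": c.id,
                "kind": c.kind,
                "pre_id": c.pre_id,
                "post_id": c.post_id,
                "area_um2": repr(c.area_um2),
                "diameter_nm": repr(c.diameter_nm) if c.diameter_nm is not None else None,
                "x_nm": x,
                "y_nm": y,
                "z_nm": z,
                "validated": c.validated,
            }
        )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def save_graph(graph: ConnectomeGraph, nodes_path, edges_path, format: str = "tsv") -> None:
    """Serialize losslessly to TSV (two files) or GraphML (nodes_path only)."""
    if format == "tsv":
        _nodes_frame(graph).to_csv(nodes_path, sep="\t", index=False)
        _edges_frame(graph).to_csv(edges_path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(to_networkx(graph), nodes_path)
    else:
        raise ValueError(f"unknown format {format!r}")


def to_networkx(graph: ConnectomeGraph) -> nx.MultiDiGraph:
    """Export as a networkx MultiDiGraph with the same attribute names."""
    g = nx.MultiDiGraph()
    for n in graph.neurons.values():
        attrs = {
            "class_label": n.class_label,
            "superclass": n.superclass,
            "polarity": n.polarity,
            "transmitter": n.transmitter,
        }
        for key in ("gaba_mM", "soma_diameter_um", "arbor_fraction", "dendrite_length_um"):
            value = getattr(n, key)
            if value is not None:
                attrs[key] = value
        g.add_node(n.id, **attrs)
    for c in graph.contacts.values():
        attrs = {"id": c.id, "kind": c.kind, "area_um2": c.area_um2, "validated": c.validated}
        if c.diameter_nm is not None:
            attrs["diameter_nm"] = c.diameter_nm
        if c.location is not None:
            attrs["x_nm"], attrs["y_nm"], attrs["z_nm"] = c.location
        g.add_edge(c.pre_id, c.post_id, key=c.id, **attrs)
    return g


def validate_graph(graph: ConnectomeGraph) -> list[str]:
    """Check all type invariants; violations are returned, never raised."""
    violations: list[str] = []
    for n in graph.neurons.values():
        if n.superclass not in SUPERCLASSES:
            violations.append(f"neuron {n.id}: unknown superclass {n.superclass!r}")
        if n.polarity not in POLARITIES:
            violations.append(f"neuron {n.id}: unknown polarity {n.polarity!r}")
        if n.gaba_mM is not None and n.gaba_mM < 0:
            violations.append(f"neuron {n.id}: negative gaba_mM {n.gaba_mM}")
        if n.arbor_fraction is not None and not (0 < n.arbor_fraction <= 1):
            violations.append(f"neuron {n.id}: arbor_fraction {n.arbor_fraction} outside (0,1]")
        rostered = roster_lookup(n.class_label)
        if rostered is not None and n.superclass != rostered[0] and n.superclass != "unknown":
            violations.append(
                f"neuron {n.id}: superclass {n.superclass!r} conflicts with roster "
                f"{rostered[0]!r} for class {n.class_label!r}"
            )
    for c in graph.contacts.values():
        if c.kind not in CONTACT_KINDS:
            violations.append(f"contact {c.id}: unknown kind {c.kind!r}")
        if not c.area_um2 > 0:
            violations.append(f"contact {c.id}: area_um2 {c.area_um2} not positive")
        if c.diameter_nm is not None and c.diameter_nm <= 0:
            violations.append(f"contact {c.id}: diameter_nm {c.diameter_nm} not positive")
        for endpoint in (c.pre_id, c.post_id):
            if endpoint not in graph.neurons:
                violations.append(f"contact {c.id}: dangling endpoint {endpoint!r}")
        if c.kind == "gap_junction":
            if c.pre_id == c.post_id:
                violations.append(f"contact {c.id}: gap junction with identical endpoints")
            if c.post_id < c.pre_id:
                violations.append(f"contact {c.id}: gap junction endpoints not canonical")
        if c.diameter_nm is not None and c.area_um2 > 0:
            disc = diameter_to_area(c.diameter_nm)
            if disc > 0 and abs(disc - c.area_um2) / c.area_um2 > 0.01:
                violations.append(
                    f"contact {c.id}: area {c.area_um2:.6f} inconsistent with disc "
                    f"area {disc:.6f} for diameter {c.diameter_nm} nm"
                )
    return violations
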