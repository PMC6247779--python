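"""Synaptic-drive tabulation, coupling census and two-sample junction statistics.

The drive table summarizes a cell's excitatory (ribbon), inhibitory
(conventional) and coupling (gap-junction) drive, and extrapolates observed
counts and PSD areas to the whole cell by dividing by the arbor fraction —
the fraction of the cell's dendritic length contained in the imaged volume.
Extrapolated values are rounded to the nearest ten when >= 1000 and to the
nearest integer otherwise, the precision at which whole-cell estimates are
conventionally reported.

"Feedforward" and "feedback" follow amacrine-cell usage: an amacrine
conventional synapse onto a bipolar cell is feedback; onto a ganglion or
another amacrine cell it is feedforward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ConnectomeGraph, Contact


def round_extrapolated(value: float) -> float:
    """Nearest ten for values >= 1000, nearest integer otherwise."""
    if value >= 1000:
        return float(round(value / 10.0) * 10)
    return float(round(value))


@dataclass
class DriveRow:
    kind: str
    n: int
    mean_area_um2: float
    sd_area_um2: float
    min_area_um2: float
    max_area_um2: float
    total_area_um2: float
    extrapolated_n: float
    extrapolated_total_area_um2: float


@dataclass
class DriveTable:
    cell_id: str
    arbor_fraction: float
    rows: dict[str, DriveRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows.values():
            recs.append(
                {
                    "kind": row.kind,
                    "n": row.n,
                    "mean_area_um2": row.mean_area_um2,
                    "sd_area_um2": row.sd_area_um2,
                    "min_area_um2": row.min_area_um2,
                    "max_area_um2": row.max_area_um2,
                    "total_area_um2": row.total_area_um2,
                    "extrapolated_n": row.extrapolated_n,
                    "extrapolated_total_area_um2": row.extrapolated_total_area_um2,
                }
            )
        return pd.DataFrame(recs).set_index("kind")

    @property
    def inhibitory_excitatory_count_ratio(self) -> Optional[float]:
        """Conventional-to-ribbon synapse count ratio (None without ribbons)."""
        rib = self.rows["ribbon_in"].n
        if rib == 0:
            return None
        return self.rows["conventional_in"].n / rib

    @property
    def inhibitory_excitatory_area_ratio(self) -> Optional[float]:
        """Inhibitory PSD area per unit ribbon PSD area."""
        rib = self.rows["ribbon_in"].total_area_um2
        if rib == 0:
            return None
        return self.rows["conventional_in"].total_area_um2 / rib


def _drive_row(kind: str, areas: Sequence[float], arbor_fraction: float) -> DriveRow:
    n = len(areas)
    arr = np.asarray(areas, dtype=float)
    total = float(arr.sum()) if n else 0.0
    return DriveRow(
        kind=kind,
        n=n,
        mean_area_um2=float(arr.mean()) if n else 0.0,
        sd_area_um2=float(arr.std(ddof=1)) if n > 1 else 0.0,
        min_area_um2=float(arr.min()) if n else 0.0,
        max_area_um2=float(arr.max()) if n else 0.0,
        total_area_um2=total,
        extrapolated_n=round_extrapolated(n / arbor_fraction),
        extrapolated_total_area_um2=round_extrapolated(total / arbor_fraction),
    )


def drive_table(
    graph: ConnectomeGraph, cell_id: str, arbor_fraction: Optional[float] = None
) -> DriveTable:
    """Tabulate a cell's synaptic and coupling drive with whole-cell extrapolation.

    ribbon_in / conventional_in count incoming synapses of those kinds
    (bc_conventional counts as conventional); gap_junction counts every
    junction touching the cell.
    """
    if cell_id not in graph.neurons:
        raise KeyError(f"unknown cell {cell_id!r}")
    if arbor_fraction is None:
        arbor_fraction = graph.neurons[cell_id].arbor_fraction or 1.0
    if not (0 < arbor_fraction <= 1):
        raise ValueError(f"arbor_fraction must be in (0, 1], got {arbor_fraction}")
    ribbon = [c.area_um2 for c in graph.incoming(cell_id, "ribbon")]
    conventional = [
        c.area_um2
        for c in graph.incoming(cell_id)
        if c.kind in ("conventional", "bc_conventional")
    ]
    junctions = [c.area_um2 for c in graph.gap_junctions_of(cell_id)]
    rows = {
        "ribbon_in": _drive_row("ribbon_in", ribbon, arbor_fraction),
        "conventional_in": _drive_row("conventional_in", conventional, arbor_fraction),
        "gap_junction": _drive_row("gap_junction", junctions, arbor_fraction),
    }
    return DriveTable(cell_id=cell_id, arbor_fraction=arbor_fraction, rows=rows)


@dataclass
class InputSpectrum:
    cell_id: str
    edge_kind: str
    counts: pd.Series  # per presynaptic class
    total: int

    @property
    def fractions(self) -> pd.Series:
        if self.total == 0:
            return self.counts.astype(float)
        return self.counts / self.total

    @property
    def dominant_class(self) -> Optional[str]:
        if self.total == 0:
            return None
        return self.fractions.idxmax()

    def exclusion_fraction(self, class_label: str) -> float:
        """Fraction of input *not* arising from the named class."""
        if self.total == 0:
            return 1.0
        return 1.0 - float(self.counts.get(class_label, 0)) / self.total


def input_spectrum(
    graph: ConnectomeGraph, cell_id: str, edge_kind: str = "ribbon"
) -> InputSpectrum:
    """Per-presynaptic-class composition of a cell's incoming drive."""
    if cell_id not in graph.neurons:
        raise KeyError(f"unknown cell {cell_id!r}")
    labels = [
        graph.neurons[c.pre_id].class_label for c in graph.incoming(cell_id, edge_kind)
    ]
    counts = (
        pd.Series(labels, dtype=object).value_counts().sort_index()
        if labels
        else pd.Series(dtype=int)
    )
    return InputSpectrum(cell_id=cell_id, edge_kind=edge_kind, counts=counts, total=len(labels))


def polarity_profile(graph: ConnectomeGraph, cell_id: str) -> dict:
    """Classify a cell's response polarity from the polarity of its ribbon drive.

    ON if no OFF bipolar input, OFF if no ON input, ON_OFF if both, unknown
    if it receives no ribbon synapses.
    """
    inputs = graph.incoming(cell_id, "ribbon")
    if not inputs:
        return {"classification": "unknown", "on_fraction": None, "off_fraction": None, "n": 0}
    on = sum(1 for c in inputs if graph.neurons[c.pre_id].polarity == "ON")
    off = sum(1 for c in inputs if graph.neurons[c.pre_id].polarity == "OFF")
    n = len(inputs)
    if off == 0 and on > 0:
        cls = "ON"
    elif on == 0 and off > 0:
        cls = "OFF"
    elif on and off:
        cls = "ON_OFF"
    else:
        cls = "unknown"
    return {"classification": cls, "on_fraction": on / n, "off_fraction": off / n, "n": n}


@dataclass
class BiasSummary:
    feedback_synapses: int
    feedforward_to_GC: int
    feedforward_to_AC: int
    target_counts: dict[str, int]  # distinct target cells per superclass
    ff_fb_ratio_by_synapse: Optional[float]
    ff_fb_ratio_by_target: Optional[float]
    feedback_free: bool


def ff_fb_bias(graph: ConnectomeGraph, cohort: Iterable[str]) -> BiasSummary:
    """Feedforward/feedback bias of a cohort of amacrine cells.

    Counts outgoing conventional synapses by target superclass (bipolar =
    feedback; ganglion or amacrine = feedforward), and distinct target cells
    likewise. Ratios are None, flagged feedback_free, when feedback is zero.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    for cid in cohort:
        if cid not in graph.neurons:
            raise KeyError(f"unknown cell {cid!r}")
    fb = ff_gc = ff_ac = 0
    targets: dict[str, set] = {"bipolar": set(), "ganglion": set(), "amacrine": set()}
    for cid in cohort:
        for c in graph.outgoing(cid, "conventional"):
            sc = graph.neurons[c.post_id].superclass
            if sc == "bipolar":
                fb += 1
                targets["bipolar"].add(c.post_id)
            elif sc == "ganglion":
                ff_gc += 1
                targets["ganglion"].add(c.post_id)
            elif sc == "amacrine":
                ff_ac += 1
                targets["amacrine"].add(c.post_id)
    target_counts = {sc: len(ids) for sc, ids in targets.items()}
    ff_syn = ff_gc + ff_ac
    ff_targets = target_counts["ganglion"] + target_counts["amacrine"]
    by_synapse = ff_syn / fb if fb else None
    by_target = ff_targets / target_counts["bipolar"] if target_counts["bipolar"] else None
    return BiasSummary(
        feedback_synapses=fb,
        feedforward_to_GC=ff_gc,
        feedforward_to_AC=ff_ac,
        target_counts=target_counts,
        ff_fb_ratio_by_synapse=by_synapse,
        ff_fb_ratio_by_target=by_target,
        feedback_free=(fb == 0 and ff_syn > 0),
    )


def network_ff_fb_totals(
    graph: ConnectomeGraph, presynaptic_superclass: str = "amacrine"
) -> dict:
    """Whole-graph conventional-synapse tallies from one presynaptic superclass.

    Returns AC->BC (feedback), AC->GC and AC->AC (feedforward) counts and
    the feedback : feedforward ratio (None when feedforward is zero).
    """
    to_bc = to_gc = to_ac = 0
    for c in graph.contacts.values():
        if c.kind != "conventional":
            continue
        if graph.neurons[c.pre_id].superclass != presynaptic_superclass:
            continue
        sc = graph.neurons[c.post_id].superclass
        if sc == "bipolar":
            to_bc += 1
        elif sc == "ganglion":
            to_gc += 1
        elif sc == "amacrine":
            to_ac += 1
    ff = to_gc + to_ac
    return {
        "feedback_to_BC": to_bc,
        "feedforward_to_GC": to_gc,
        "feedforward_to_AC": to_ac,
        "fb_ff_ratio": (to_bc / ff) if ff else None,
    }


@dataclass
class CouplingMatrix:
    categories: dict[str, str]  # contact id -> category
    class_pair_counts: pd.Series
    superclass_pair_counts: pd.Series
    partners: dict[str, list[tuple[str, str]]]  # cell id -> [(partner id, transmitter)]

    def count(self, category: str) -> int:
        return sum(1 for c in self.categories.values() if c == category)

    def homocellular_in_class_count(self, superclass: str, graph: ConnectomeGraph) -> int:
        """In-class junctions whose endpoints belong to the given superclass."""
        n = 0
        for cid, cat in self.categories.items():
            if cat != "homocellular_in_class":
                continue
            pre = graph.contacts[cid].pre_id
            if graph.neurons[pre].superclass == superclass:
                n += 1
        return n


def coupling_census(graph: ConnectomeGraph) -> CouplingMatrix:
    """Categorize every gap junction as homocellular (in-class or cross-class)
    or heterocellular (cross-superclass), and list coupled partners per cell
    with their transmitter signatures."""
    categories: dict[str, str] = {}
    class_pairs: list[tuple[str, str]] = []
    superclass_pairs: list[tuple[str, str]] = []
    partners: dict[str, list[tuple[str, str]]] = {}
    for c in graph.contacts.values():
        if c.kind != "gap_junction":
            continue
        a, b = graph.neurons[c.pre_id], graph.neurons[c.post_id]
        if a.superclass != b.superclass:
            categories[c.id] = "heterocellular"
        elif a.class_label == b.class_label:
            categories[c.id] = "homocellular_in_class"
        else:
            categories[c.id] = "homocellular_cross_class"
        class_pairs.append(tuple(sorted((a.class_label, b.class_label))))
        superclass_pairs.append(tuple(sorted((a.superclass, b.superclass))))
        partners.setdefault(a.id, []).append((b.id, b.transmitter))
        partners.setdefault(b.id, []).append((a.id, a.transmitter))
    return CouplingMatrix(
        categories=categories,
        class_pair_counts=(
            pd.Series(class_pairs).value_counts().sort_index()
            if class_pairs
            else pd.Series(dtype=int)
        ),
        superclass_pair_counts=(
            pd.Series(superclass_pairs).value_counts().sort_index()
            if superclass_pairs
            else pd.Series(dtype=int)
        ),
        partners=partners,
    )


def gj_density_per_length(graph: ConnectomeGraph, cell_id: str) -> float:
    """Gap-junction area density along the dendrite, nm^2 per um of length."""
    if cell_id not in graph.neurons:
        raise KeyError(f"unknown cell {cell_id!r}")
    length = graph.neurons[cell_id].dendrite_length_um
    if length is None or length <= 0:
        raise ValueError(f"cell {cell_id!r} has no dendrite_length_um")
    total_nm2 = sum(c.area_um2 for c in graph.gap_junctions_of(cell_id)) * 1e6
    return total_nm2 / length


@dataclass
class ComparisonResult:
    t_homoscedastic: float
    p_t_homoscedastic: float
    t_welch: float
    p_t_welch: float
    F_ratio: float
    p_F: float
    ks_D: float
    p_ks: float
    effect_size_d: float
    power: float
    alpha: float
    n1: int
    n2: int


def power_two_sample_t(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sided two-sample t-test at effect size d.

    Uses the noncentral-t distribution with noncentrality
    d * sqrt(n1 n2 / (n1 + n2)) and n1 + n2 - 2 degrees of freedom.
    """
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Pooled-SD standardized mean difference (absolute value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = math.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0
    return abs(a.mean() - b.mean()) / pooled


def compare_gap_junction_sizes(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Two-sample comparison of gap-junction size distributions.

    Runs the homoscedastic and Welch t-tests, the variance-ratio F-test and
    the two-sample Kolmogorov-Smirnov test, plus post-hoc power of the
    two-sample t at the observed pooled-SD effect size.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    t_eq, p_eq = stats.ttest_ind(a, b, equal_var=True)
    t_w, p_w = stats.ttest_ind(a, b, equal_var=False)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v2 == 0 and v1 == 0:
        F, p_F = 1.0, 1.0
    else:
        # conventional two-sided F: larger variance in the numerator
        if v1 >= v2:
            F, dfn, dfd = v1 / v2 if v2 else np.inf, len(a) - 1, len(b) - 1
        else:
            F, dfn, dfd = v2 / v1, len(b) - 1, len(a) - 1
        p_F = float(min(1.0, 2 * stats.f.sf(F, dfn, dfd)))
    ks_D, p_ks = stats.ks_2samp(a, b)
    d = cohens_d(a, b)
    return ComparisonResult(
        t_homoscedastic=float(t_eq),
        p_t_homoscedastic=float(p_eq),
        t_welch=float(t_w),
        p_t_welch=float(p_w),
        F_ratio=float(F),
        p_F=p_F,
        ks_D=float(ks_D),
        p_ks=float(p_ks),
        effect_size_d=d,
        power=power_two_sample_t(d, len(a), len(b), alpha),
        alpha=alpha,
        n1=len(a),
        n2=len(b),
    )
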