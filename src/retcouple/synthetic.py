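"""Synthetic connectomes, the deterministic summary fixture, and CMP phantoms.

Three generators back the test and demonstration surface of the package:

* :func:`generate_connectome` draws a retina-like typed multigraph from a
  seeded configuration: per-class neuron counts, wiring rules with lognormal
  synapse-area distributions, coupling rules with truncated-normal junction
  diameters (default 181 ± 56 nm on [72, 357] nm, the empirical range for
  ganglion-cell junctions), and motif switches (no in-class ganglion
  coupling, coupled-amacrine feedforward onto disjoint ganglion classes,
  amacrine feedback onto bipolar cells).

* :func:`rc1_summary_fixture` builds, with no randomness at all, a graph
  whose tallies equal the published summary of the rabbit volume: a tON DS
  ganglion-cell analog with 259 ribbon inputs (9.8 um^2), 783 conventional
  inputs (53.6 um^2) and 228 gap junctions (6.4 um^2) all onto GABAergic
  amacrine partners; an interstitial-amacrine analog targeting 38 amacrine,
  13 ganglion and 3 bipolar cells; a glycinergic AI cohort making 837
  feedback and zero feedforward synapses; and network-wide amacrine
  conventional-synapse totals of 2359 (onto bipolar), 336 (onto ganglion)
  and 564 (onto amacrine) cells.

* :func:`generate_cmp_phantom` renders multichannel soma-disc images with
  class-specific small-molecule concentrations mapped log-linearly to pixel
  values, plus ground truth for segmentation and object-count validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cmp import CalibrationModel, ChannelStack
from .model import (
    ConnectomeGraph,
    Contact,
    Neuron,
    area_to_diameter,
    diameter_to_area,
    roster_lookup,
)

# ---------------------------------------------------------------------------
# connectome generator


@dataclass
class ClassSpec:
    label: str
    count: int
    superclass: Optional[str] = None
    polarity: Optional[str] = None
    transmitter: Optional[str] = None
    gaba_mM: Optional[float] = None


@dataclass
class WiringRule:
    """Directed chemical wiring between two classes.

    expected_per_pair is the Poisson mean synapse count per (pre, post) cell
    pair; areas are lognormal(mu_log, sigma_log) on um^2.
    """

    pre_class: str
    post_class: str
    kind: str = "ribbon"
    expected_per_pair: float = 1.0
    area_mu_log: float = math.log(0.04)
    area_sigma_log: float = 0.5


@dataclass
class CouplingRule:
    """Gap-junction formation between two classes (symmetric).

    rate is the Bernoulli probability of a junction per unordered cell pair;
    diameters are Normal(mean_nm, sd_nm) truncated to [min_nm, max_nm].
    """

    class_a: str
    class_b: str
    rate: float = 0.0
    mean_nm: float = 181.0
    sd_nm: float = 56.0
    min_nm: float = 72.0
    max_nm: float = 357.0


@dataclass
class MotifSwitches:
    gc_gc_coupling: bool = False
    feedforward_to_disjoint_gc: bool = True
    ac_feedback_to_bc: bool = True
    feedforward_synapses_per_ac: int = 4
    feedback_synapses_per_ac: int = 6


@dataclass
class GeneratorConfig:
    classes: list[ClassSpec]
    wiring: list[WiringRule] = field(default_factory=list)
    coupling: list[CouplingRule] = field(default_factory=list)
    motifs: MotifSwitches = field(default_factory=MotifSwitches)
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            problems.append("duplicate class labels")
        for c in self.classes:
            if c.count < 0:
                problems.append(f"class {c.label}: negative count")
        for r in self.coupling:
            if not (0 <= r.rate <= 1):
                problems.append(f"coupling {r.class_a}::{r.class_b}: rate outside [0,1]")
            if not (r.min_nm < r.max_nm):
                problems.append(f"coupling {r.class_a}::{r.class_b}: bad truncation bounds")
            for label in (r.class_a, r.class_b):
                if label not in labels:
                    problems.append(f"coupling rule references unknown class {label!r}")
        for r in self.wiring:
            if r.expected_per_pair < 0:
                problems.append(f"wiring {r.pre_class}->{r.post_class}: negative expectation")
            for label in (r.pre_class, r.post_class):
                if label not in labels:
                    problems.append(f"wiring rule references unknown class {label!r}")
        return problems


def default_generator_config(seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults: a tON DS ganglion cohort driven by ON cone
    bipolar classes with a 0.54 CBb4w bias, coupled to GABAergic amacrine
    cells by 181 ± 56 nm junctions, with AI feedback onto rod bipolar cells."""
    classes = [
        ClassSpec("CBb4w", 8),
        ClassSpec("CBb3n", 5),
        ClassSpec("CBb4", 5),
        ClassSpec("CBb6", 4),
        ClassSpec("CBb5", 4),
        ClassSpec("GC tON DS", 3),
        ClassSpec("GC ON", 4),
        ClassSpec("GC ON OFF", 3),
        ClassSpec("IAC", 4),
        ClassSpec("wfAC", 6),
        ClassSpec("AI", 4),
        ClassSpec("RB", 6),
        ClassSpec("AII", 4),
    ]
    # ribbon drive onto tON DS ganglion cells: 54% of input from CBb4w,
    # CBb5 essentially excluded (per-pair expectations scaled per class size)
    bias = {"CBb4w": 0.54, "CBb3n": 0.16, "CBb4": 0.17, "CBb6": 0.125, "CBb5": 0.005}
    per_cell_total = 60.0
    wiring = [
        WiringRule(
            pre_class=label,
            post_class="GC tON DS",
            kind="ribbon",
            expected_per_pair=per_cell_total
            * share
            / next(c.count for c in classes if c.label == label),
            area_mu_log=math.log(0.035),
            area_sigma_log=0.5,
        )
        for label, share in bias.items()
    ] + [
        WiringRule("CBb4w", "IAC", "ribbon", 2.0, math.log(0.03), 0.5),
        WiringRule("AI", "RB", "conventional", 3.0, math.log(0.06), 0.4),
    ]
    coupling = [
        CouplingRule("GC tON DS", "IAC", rate=0.9),
        CouplingRule("GC tON DS", "wfAC", rate=0.7),
        CouplingRule("AII", "CBb4w", rate=0.3, mean_nm=200.0),
        CouplingRule("GC tON DS", "GC tON DS", rate=0.5),  # vetoed unless switched on
    ]
    return GeneratorConfig(classes=classes, wiring=wiring, coupling=coupling, seed=seed)


def sample_truncated_diameters(
    n: int,
    rng: np.random.Generator,
    mean_nm: float = 181.0,
    sd_nm: float = 56.0,
    min_nm: float = 72.0,
    max_nm: float = 357.0,
) -> np.ndarray:
    """Draw junction diameters from the truncated-normal coupling model."""
    a = (min_nm - mean_nm) / sd_nm
    b = (max_nm - mean_nm) / sd_nm
    return stats.truncnorm.rvs(a, b, loc=mean_nm, scale=sd_nm, size=n, random_state=rng)


def _neuron_from_spec(spec: ClassSpec, idx: int) -> Neuron:
    rostered = roster_lookup(spec.label)
    superclass = spec.superclass or (rostered[0] if rostered else "unknown")
    polarity = spec.polarity or (rostered[1] if rostered else "unknown")
    transmitter = spec.transmitter or (rostered[2] if rostered else "unknown")
    return Neuron(
        id=f"{spec.label}:{idx}",
        class_label=spec.label,
        superclass=superclass,
        polarity=polarity,
        transmitter=transmitter,
        gaba_mM=spec.gaba_mM,
    )


def generate_connectome(config: GeneratorConfig, seed: Optional[int] = None) -> ConnectomeGraph:
    """Draw a typed connectome honoring the wiring, coupling and motif rules."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid generator config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    graph = ConnectomeGraph()
    by_class: dict[str, list[str]] = {}
    for spec in config.classes:
        ids = []
        for i in range(spec.count):
            neuron = _neuron_from_spec(spec, i)
            graph.add_neuron(neuron)
            ids.append(neuron.id)
        by_class[spec.label] = ids

    next_id = [0]

    def add_contact(kind, pre, post, area, diameter=None, validated=False):
        next_id[0] += 1
        graph.add_contact(
            Contact(
                id=f"E{next_id[0]:06d}",
                kind=kind,
                pre_id=pre,
                post_id=post,
                area_um2=area,
                diameter_nm=diameter,
                validated=validated,
            )
        )

    for rule in config.wiring:
        for pre in by_class[rule.pre_class]:
            for post in by_class[rule.post_class]:
                if pre == post:
                    continue
                k = rng.poisson(rule.expected_per_pair)
                for area in rng.lognormal(rule.area_mu_log, rule.area_sigma_log, size=k):
                    add_contact(rule.kind, pre, post, float(area))

    superclass_of = {n.id: n.superclass for n in graph.neurons.values()}
    coupled_pairs: list[tuple[str, str]] = []  # (gc id, ac id)
    for rule in config.coupling:
        both_gc = all(
            (roster_lookup(lbl) or ("unknown",))[0] == "ganglion"
            for lbl in (rule.class_a, rule.class_b)
        )
        if both_gc and not config.motifs.gc_gc_coupling:
            continue
        seen = set()
        for a in by_class[rule.class_a]:
            for b in by_class[rule.class_b]:
                if a == b:
                    continue
                key = tuple(sorted((a, b)))
                if key in seen:
                    continue
                seen.add(key)
                if rng.random() >= rule.rate:
                    continue
                d = float(
                    sample_truncated_diameters(
                        1, rng, rule.mean_nm, rule.sd_nm, rule.min_nm, rule.max_nm
                    )[0]
                )
                add_contact("gap_junction", key[0], key[1], diameter_to_area(d), d)
                sc = {superclass_of[a], superclass_of[b]}
                if sc == {"ganglion", "amacrine"}:
                    gc, ac = (a, b) if superclass_of[a] == "ganglion" else (b, a)
                    coupled_pairs.append((gc, ac))

    gc_by_class: dict[str, list[str]] = {
        lbl: ids
        for lbl, ids in by_class.items()
        if ids and graph.neurons[ids[0]].superclass == "ganglion"
    }
    bc_ids = [n.id for n in graph.neurons.values() if n.superclass == "bipolar"]
    if config.motifs.feedforward_to_disjoint_gc:
        # each coupled amacrine feeds forward onto ganglion cells of classes
        # disjoint from its coupled partner's class
        for gc, ac in coupled_pairs:
            gc_class = graph.neurons[gc].class_label
            other = [
                nid for lbl, ids in gc_by_class.items() if lbl != gc_class for nid in ids
            ]
            if not other:
                continue
            for _ in range(config.motifs.feedforward_synapses_per_ac):
                target = other[int(rng.integers(len(other)))]
                add_contact("conventional", ac, target, float(rng.lognormal(math.log(0.06), 0.4)))
    if config.motifs.ac_feedback_to_bc and bc_ids:
        for gc, ac in coupled_pairs:
            for _ in range(config.motifs.feedback_synapses_per_ac):
                target = bc_ids[int(rng.integers(len(bc_ids)))]
                add_contact("conventional", ac, target, float(rng.lognormal(math.log(0.06), 0.4)))
    return graph


# ---------------------------------------------------------------------------
# deterministic summary fixture


def _exact_total_areas(n: int, total: float, spread: float) -> list[float]:
    """n positive areas summing exactly to `total`, symmetric about the mean.

    Per-contact sizes are unpublished; paired perturbations ±delta around the
    mean preserve the count, mean and total to full precision.
    """
    mean = total / n
    areas = []
    pairs = n // 2
    for i in range(pairs):
        delta = spread * (i + 1) / (pairs + 1)
        areas.append(mean + delta)
        areas.append(mean - delta)
    if n % 2:
        areas.append(mean)
    assert min(areas) > 0
    # compensate float summation drift on the middle element
    drift = total - math.fsum(areas)
    areas[-1] += drift
    return areas


GC606 = "GC606"
GC9787 = "GC9787"
IAC9769 = "IAC9769"


def rc1_summary_fixture() -> ConnectomeGraph:
    """Deterministic graph encoding the published summary tallies.

    Identical on every call; serializes byte-identically. See the module
    docstring for the tallies it reproduces.
    """
    graph = ConnectomeGraph()

    def neuron(id, class_label, **kw):
        rostered = roster_lookup(class_label)
        kw.setdefault("superclass", rostered[0] if rostered else "unknown")
        kw.setdefault("polarity", rostered[1] if rostered else "unknown")
        kw.setdefault("transmitter", rostered[2] if rostered else "unknown")
        graph.add_neuron(Neuron(id=id, class_label=class_label, **kw))
        return id

    counter = [0]

    def contact(kind, pre, post, area, diameter=None, validated=True):
        counter[0] += 1
        graph.add_contact(
            Contact(
                id=f"E{counter[0]:05d}",
                kind=kind,
                pre_id=pre,
                post_id=post,
                area_um2=area,
                diameter_nm=diameter,
                validated=validated,
            )
        )

    neuron(GC606, "GC tON DS", gaba_mM=0.5, arbor_fraction=0.18,
           dendrite_length_um=322.0, soma_diameter_um=35.0)
    neuron(GC9787, "GC OFF alpha", gaba_mM=0.3, dendrite_length_um=300.0)

    # --- ribbon drive of the tON DS analog: 259 synapses, 9.8 um^2 total,
    # 54% from CBb4w, CBb5 all but excluded (<1%)
    ribbon_sources: list[str] = []
    bc_roster = [("CBb4w", 12, 140), ("CBb3n", 5, 40), ("CBb4", 5, 45),
                 ("CBb6", 4, 32), ("CBb5", 1, 2)]
    source_seq: list[str] = []
    for label, n_cells, n_syn in bc_roster:
        cells = [neuron(f"{label}:{i}", label) for i in range(n_cells)]
        ribbon_sources.extend(cells)
        source_seq.extend(cells[i % n_cells] for i in range(n_syn))
    ribbon_areas = _exact_total_areas(259, 9.8, 0.02)
    for pre, area in zip(source_seq, ribbon_areas):
        contact("ribbon", pre, GC606, area)

    # --- conventional drive: 783 synapses, 53.6 um^2, from unclassified
    # orphan processes (so network amacrine tallies stay at their published
    # values, which count identified amacrine cells only)
    orphans = [neuron(f"orphan:{i}", "orphan") for i in range(20)]
    for i, area in enumerate(_exact_total_areas(783, 53.6, 0.03)):
        contact("conventional", orphans[i % len(orphans)], GC606, area)

    # --- coupling: 228 gap junctions, 6.4 um^2, all with GABAergic amacrine
    # partners; 61 traced to an identified partner (validated flag)
    partners = [neuron(IAC9769, "IAC", gaba_mM=5.0)]
    partners += [neuron(f"wfAC:{i}", "wfAC", gaba_mM=4.0) for i in range(4)]
    partners += [neuron(f"YAC:{i}", "YAC", gaba_mM=4.0) for i in range(4)]
    for i, area in enumerate(_exact_total_areas(228, 6.4, 0.02)):
        contact(
            "gap_junction",
            GC606,
            partners[i % len(partners)],
            area,
            diameter=area_to_diameter(area),
            validated=i < 61,
        )

    # --- the interstitial amacrine analog: feedforward-biased, one synapse
    # onto each of 38 amacrine, 13 ganglion and 3 bipolar targets
    ac_targets = [neuron(f"AC:{i}", "AC", gaba_mM=4.0) for i in range(38)]
    gc_targets = (
        [neuron(f"GCON:{i}", "GC ON") for i in range(6)]
        + [neuron(f"GCONOFF:{i}", "GC ON OFF") for i in range(4)]
        + [neuron(f"GCOFF:{i}", "GC OFF") for i in range(3)]
    )
    for t in ac_targets + gc_targets + ribbon_sources[:3]:
        contact("conventional", IAC9769, t, 0.06)

    # --- AI cohort: purely feedback, 837 synapses onto rod bipolar cells
    ai_cells = [neuron(f"AI:{i}", "AI") for i in range(5)]
    rb_cells = [neuron(f"RB:{i}", "RB") for i in range(10)]
    for i in range(837):
        contact("conventional", ai_cells[i % 5], rb_cells[i % 10], 0.05)

    # --- OFF alpha analog: OFF cone bipolar ribbon drive, AII conventional
    # input, and 13 junctions at exactly 9142 nm^2/um over 300 um of dendrite
    cba_cells = [neuron(f"CBa2:{i}", "CBa2") for i in range(4)]
    for i in range(20):
        contact("ribbon", cba_cells[i % 4], GC9787, 0.05)
    aii_cells = [neuron(f"AII:{i}", "AII") for i in range(6)]
    for i in range(12):
        contact("conventional", aii_cells[i % 6], GC9787, 0.04)
    gc9787_partners = [neuron("YAC7859", "YAC", gaba_mM=4.5), neuron("AC85607", "AC", gaba_mM=4.0)]
    for i, area in enumerate(_exact_total_areas(13, 9142.0 * 300.0 / 1e6, 0.05)):
        contact(
            "gap_junction",
            GC9787,
            gc9787_partners[i % 2],
            area,
            diameter=area_to_diameter(area),
        )

    # --- AII::CBb heterocellular junctions (the canonical cross-superclass
    # coupling motif of the rod pathway)
    for i in range(5):
        d = 200.0
        contact("gap_junction", aii_cells[i % 6], ribbon_sources[i], diameter_to_area(d), d)

    # --- generic amacrine pool topping network totals up to the published
    # 2359 (onto BC) / 336 (onto GC) / 564 (onto AC) conventional synapses:
    # already placed above: 3 + 837 = 840 onto BC, 13 + 12 = 25 onto GC,
    # 38 onto AC.
    pool = [neuron(f"ACpool:{i}", "AC", gaba_mM=4.0) for i in range(15)]
    bc_all = ribbon_sources + rb_cells + cba_cells
    for i in range(2359 - 840):
        contact("conventional", pool[i % 15], bc_all[i % len(bc_all)], 0.05)
    for i in range(336 - 25):
        contact("conventional", pool[i % 15], gc_targets[i % len(gc_targets)], 0.05)
    for i in range(564 - 38):
        contact("conventional", pool[i % 15], ac_targets[i % len(ac_targets)], 0.05)

    return graph


def generator_config_from_yaml(path) -> GeneratorConfig:
    """Load and validate a generator configuration from YAML.

    Top-level keys: classes (list of ClassSpec fields), wiring (WiringRule
    fields), coupling (CouplingRule fields), motifs (MotifSwitches fields),
    seed. Unknown keys raise rather than pass silently.
    """
    raw = yaml.safe_load(open(path))
    try:
        cfg = GeneratorConfig(
            classes=[ClassSpec(**c) for c in raw.get("classes", [])],
            wiring=[WiringRule(**w) for w in raw.get("wiring", [])],
            coupling=[CouplingRule(**c) for c in raw.get("coupling", [])],
            motifs=MotifSwitches(**raw.get("motifs", {})),
            seed=int(raw.get("seed", 0)),
        )
    except TypeError as err:
        raise ValueError(f"{path}: {err}") from None
    problems = cfg.validate()
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return cfg


# ---------------------------------------------------------------------------
# CMP image phantoms


@dataclass
class SomaClassSpec:
    name: str
    count: int
    conc_mM: dict[str, tuple[float, float]]  # channel -> (low, high) uniform range
    radius_px: tuple[int, int] = (8, 14)


@dataclass
class CMPPhantomConfig:
    shape: tuple[int, int] = (256, 256)
    classes: list[SomaClassSpec] = field(default_factory=list)
    background_mM: dict[str, float] = field(default_factory=dict)
    calibration: CalibrationModel = field(default_factory=CalibrationModel)
    noise_sd_pv: float = 2.0
    non_overlap: bool = True
    max_retries: int = 2000
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        for spec in self.classes:
            if spec.count < 0:
                problems.append(f"class {spec.name}: negative count")
            if spec.radius_px[0] <= 0 or spec.radius_px[0] > spec.radius_px[1]:
                problems.append(f"class {spec.name}: bad radius range")
            for ch, (lo, hi) in spec.conc_mM.items():
                if lo < 0 or hi < lo:
                    problems.append(f"class {spec.name} channel {ch}: bad range")
        if self.noise_sd_pv < 0:
            problems.append("negative noise SD")
        return problems


def fig1_phantom_config(seed: int = 0, noise_sd_pv: float = 2.0) -> CMPPhantomConfig:
    """Ganglion-cell-layer phantom: starburst amacrine cells at 5-10 mM GABA,
    provisionally coupled γ+ ganglion cells at 0.3-0.6 mM, and γ− ganglion
    cells, with the two ganglion classes sharing one glutamate distribution
    (glutamate alone cannot separate them)."""
    shared_E = (5.0, 5.0)  # one glutamate level for both GC classes
    return CMPPhantomConfig(
        classes=[
            SomaClassSpec("SAC", 8, {"γ": (5.0, 10.0), "E": (0.2, 0.5)}),
            SomaClassSpec("gamma_GC", 8, {"γ": (0.3, 0.6), "E": shared_E}),
            SomaClassSpec("GC", 8, {"γ": (0.01, 0.02), "E": shared_E}),
        ],
        background_mM={"γ": 0.005, "E": 0.02},
        noise_sd_pv=noise_sd_pv,
        seed=seed,
    )


def generate_cmp_phantom(
    config: CMPPhantomConfig, seed: Optional[int] = None
) -> tuple[ChannelStack, np.ndarray, pd.DataFrame]:
    """Render soma discs into a multichannel stack with ground truth.

    Returns (stack, label map, object table). The label map holds 0 for
    background and 1-based class indices for soma pixels; the object table
    lists one row per placed soma (class, center, radius, ground-truth area
    and per-channel concentration).
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid phantom config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.shape
    channels = sorted(
        set(config.background_mM) | {ch for s in config.classes for ch in s.conc_mM}
    )
    model = config.calibration

    def pv_of(c: float) -> float:
        return model.conc_to_pv(c) if c > 0 else 0.0

    conc_planes = {
        ch: np.full((h, w), config.background_mM.get(ch, 0.0)) for ch in channels
    }
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    placed: list[tuple[float, float, float]] = []
    records = []
    for class_idx, spec in enumerate(config.classes, start=1):
        for _ in range(spec.count):
            r = int(rng.integers(spec.radius_px[0], spec.radius_px[1] + 1))
            for attempt in range(config.max_retries + 1):
                cy = float(rng.uniform(r, h - r))
                cx = float(rng.uniform(r, w - r))
                if not config.non_overlap or all(
                    (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 3) ** 2
                    for py, px, pr in placed
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place non-overlapping soma for class {spec.name} "
                    f"after {config.max_retries} retries"
                )
            placed.append((cy, cx, r))
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            labels[disc] = class_idx
            conc = {}
            for ch in channels:
                lo, hi = spec.conc_mM.get(ch, (config.background_mM.get(ch, 0.0),) * 2)
                c = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                conc_planes[ch][disc] = c
                conc[ch] = c
            records.append(
                {
                    "class": spec.name,
                    "class_index": class_idx,
                    "center_row": cy,
                    "center_col": cx,
                    "radius_px": r,
                    "area_px": int(disc.sum()),
                    **{f"conc_{ch}_mM": conc[ch] for ch in channels},
                }
            )
    images = {}
    for ch in channels:
        pv = np.vectorize(pv_of)(conc_planes[ch])
        if config.noise_sd_pv > 0:
            pv = pv + rng.normal(0.0, config.noise_sd_pv, size=pv.shape)
        images[ch] = np.clip(np.rint(pv), 0, 255).astype(np.uint8)
    stack = ChannelStack(channels=images, registered=True)
    return stack, labels, pd.DataFrame(records)


def phantom_config_from_yaml(path) -> CMPPhantomConfig:
    """Load and validate a phantom configuration from YAML.

    Top-level keys: shape, classes (SomaClassSpec fields; conc_mM maps
    channel name -> [low, high]), background_mM, calibration
    (CalibrationModel fields), noise_sd_pv, non_overlap, seed.
    """
    raw = yaml.safe_load(open(path))
    try:
        classes = [
            SomaClassSpec(
                name=c["name"],
                count=int(c["count"]),
                conc_mM={ch: tuple(v) for ch, v in c["conc_mM"].items()},
                radius_px=tuple(c.get("radius_px", (8, 14))),
            )
            for c in raw.get("classes", [])
        ]
        cfg = CMPPhantomConfig(
            shape=tuple(raw.get("shape", (256, 256))),
            classes=classes,
            background_mM=dict(raw.get("background_mM", {})),
            calibration=CalibrationModel(**raw.get("calibration", {})),
            noise_sd_pv=float(raw.get("noise_sd_pv", 2.0)),
            non_overlap=bool(raw.get("non_overlap", True)),
            seed=int(raw.get("seed", 0)),
        )
    except (KeyError, TypeError) as err:
        raise ValueError(f"{path}: {err}") from None
    problems = cfg.validate()
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return cfg
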