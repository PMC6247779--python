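# Methods

## The circuit model

A connectome is a typed attributed multigraph. Neurons carry a *class*
label (the finest classification level, e.g. `CBb4w`, `GC tON DS`, `AII`), a
*superclass* (photoreceptor, horizontal, bipolar, amacrine, ganglion, or
`unknown` for orphan processes whose arbor leaves the volume unclassified),
a response polarity, a transmitter, and optional quantitative attributes
(soma diameter, GABA concentration, in-volume dendrite length, arbor
fraction). Contacts are directed chemical synapses — glutamatergic `ribbon`
synapses of bipolar cells, inhibitory `conventional` synapses of amacrine
cells, and ribbonless `bc_conventional` bipolar presynapses — or undirected
`gap_junction` contacts.

Gap junctions are stored canonically (lexicographically smaller endpoint
first) and every consumer treats them symmetrically, so census and query
results are invariant under the endpoint order of the input file. Junction
area and diameter are linked by a circular-disc model, *A* = π(*d*/2)²,
and validated against each other at 1% relative tolerance when both are
present: reconstructed junctions are near-circular plaques, and the model
makes the reported mean diameter (181 nm) and mean area (≈0.026–0.028 μm²)
mutually consistent. Class labels resolve superclass/polarity/transmitter
through a bundled roster (exact labels first, then prefix rules such as
`CBb*` → ON cone bipolar); an explicit superclass column always overrides
the roster, and conflicts are surfaced by the validator rather than silently
corrected.

Serialization is TSV (tab-separated, header row, UTF-8, `.` decimal, floats
written with `repr` and read back with exact round-trip parsing) so that
fixtures are bit-stable; GraphML export carries the same attribute names for
interoperability with generic graph tools.

## Path queries

A query is a comma-separated alternation of node regexes and edge kinds:
`"CB.*, ribbon, GC ON"`. Node regexes are anchored (full match) against the
class label; the edge vocabulary is {`ribbon`, `conventional`,
`gap junction`, `any`}, with `bc_conventional` contacts answering to
`conventional` (they differ only in the presynaptic superclass). Chemical
hops traverse pre→post only; gap-junction and `any` hops traverse either
direction. Matches are **simple paths** — no repeated neuron — which bounds
the search and matches how coupling motifs are read (a chain, not a walk),
and are returned sorted by id sequence so results are reproducible. The
engine is a straightforward DFS over a per-kind adjacency index; its
correctness is established against an independent exhaustive enumerator
(all neuron permutations × all contact assignments) on hundreds of small
random graphs.

The coupled-feedforward motif GC₁ :: AC > GC₂ (class₁ ≠ class₂) is the
two-hop query `"GC.*, gap junction, .*AC.*, conventional, GC.*"` followed by
`disjoint_filter(matches, graph, 0, 2)`, which drops matches whose first and
third neurons share a class.

## Drive tables and extrapolation

`drive_table` tallies, for one cell, incoming ribbon synapses, incoming
conventional synapses (including `bc_conventional`) and all touching gap
junctions: count, mean ± SD, range, and total PSD/junction area (exact sums
of per-contact areas). Whole-cell estimates divide observed quantities by
the **arbor fraction** *f* ∈ (0, 1] — the fraction of the cell's dendritic
length inside the volume — and round to the nearest ten above 1000 and the
nearest integer below, the precision at which such extrapolations are
meaningful. With *f* = 1 extrapolated counts equal observed counts exactly.

Amacrine polarity conventions: a conventional synapse onto a bipolar cell is
*feedback*; onto a ganglion or another amacrine cell it is *feedforward*.
`ff_fb_bias` reports both synapse-level and distinct-target-level tallies;
ratios are `None` (flagged `feedback_free`) when the denominator is zero
rather than infinities. `network_ff_fb_totals` applies the same partition
graph-wide for a presynaptic superclass.

## Coupling census and junction statistics

Every gap junction falls in exactly one category: *heterocellular*
(endpoints in different superclasses), *homocellular in-class* (same class)
or *homocellular cross-class* (same superclass, different classes). The
census also aggregates counts per class pair and superclass pair and lists
each cell's coupled partners with their transmitter signatures — the
machinery behind statements like "ganglion cells couple exclusively with
GABAergic amacrine cells" and "no in-class ganglion–ganglion coupling".

`compare_gap_junction_sizes` runs four two-sample tests (homoscedastic *t*,
Welch *t*, variance-ratio *F* with the larger variance in the numerator and
a two-sided p, and two-sample Kolmogorov–Smirnov) via scipy. Post-hoc power
is computed for the two-sided pooled *t* at the observed effect size
*d* = |Δmean|/SD_pooled, using the noncentral-*t* distribution with
noncentrality *d*·√(n₁n₂/(n₁+n₂)) and n₁+n₂−2 degrees of freedom. This is
the standard post-hoc convention; the estimator is verified against a
10,000-replicate Monte-Carlo rejection rate to within 0.02 absolute. For
the published configuration (n = 13 vs 228, d ≈ 0.5) it yields ≈0.41; power
figures computed by other software for the same configuration can differ
with the convention used (e.g. one- vs two-sided, exact vs approximate
noncentrality), and no attempt is made to match any particular one.

`gj_density_per_length` reports Σ junction areas (nm²) per μm of in-volume
dendrite length; the length is a user-supplied neuron attribute, since it
cannot be derived from the topology.

## CMP image pipeline

Pixel value is log-linear in small-molecule concentration:
PV = clamp(PV_ref + s·log₁₀(c/c_ref), 0, 255). The default model
(c_ref = 0.1 mM ↔ PV 96, s = 64 PV/decade) spans ≈0.003–30 mM across the
8-bit range, comfortably bracketing the 0.1–10 mM decision band; the true
constants of any given acquisition are instrument-specific, so the model is
fully configurable and the defaults are documented placeholders. The inverse
is exact on the unclamped domain.

Registration is an exhaustive integer-shift search within ±`max_shift_px`
maximizing the normalized zero-mean cross-correlation of the overlap; the
correlation score is returned so that degenerate (noise-only) registrations
can be flagged. Subpixel refinement is deliberately out of scope.

Theme maps are plain k-means (k-means++, best of 10 restarts by
within-cluster sum of squares, fixed seed) over per-pixel channel vectors;
output labels are relabelled in lexicographic order of the cluster mean
signatures so label identity is independent of initialization order.

GABA segmentation converts the γ channel to concentration and applies
half-open bands: c < 0.1 mM → γ− ; 0.1 ≤ c < 1 mM → provisional γ+ ganglion
cell; c ≥ 1 mM → amacrine (values above 10 mM remain amacrine-class). The
half-open convention is a choice — the source ranges are stated without
boundary rules — and is pinned by tests. Colocalization maps follow the
`"<channels>::<letters>"` grammar with `y` duplicating a channel into R and
G and additive saturation at 255. Object counting takes 8-connected
components of one label and drops fragments below `min_area_px`
(cross-sectioned dendrites rather than somas). Histogram separability
reports the binned two-sample KS statistic and the overlap coefficient
Σ min(p_a, p_b) of unit-area histograms.

## Synthetic data

**Connectomes.** The generator draws neurons per class, synapses per
ordered class pair (Poisson counts per cell pair; lognormal areas — positive
and right-skewed like measured PSD areas), and gap junctions per unordered
class pair (Bernoulli per pair; truncated-normal diameters, default
181 ± 56 nm on [72, 357] nm, converted to areas by the disc model). Motif
switches control in-class ganglion coupling (off by default — it has never
been demonstrated), coupled-amacrine feedforward onto ganglion classes
disjoint from the coupled partner (targets sampled uniformly over the other
classes, since only disjointness, not a distribution, is established), and
amacrine feedback onto bipolar cells. The default configuration biases the
tON DS ribbon input 54% toward CBb4w with CBb5 nearly excluded. All
randomness flows from one seed; identical seeds give bit-identical
serializations. Note the truncated-normal mean exceeds the location
parameter slightly (≈184 vs 181 nm for the default bounds); moment-recovery
tests use 3-standard-error bands that absorb this.

**The summary fixture.** `rc1_summary_fixture()` is pure construction, no
randomness. Per-contact areas are unpublished, so each contact population is
built as symmetric perturbations around its mean with the population total
pinned exactly (ribbons 259 / 9.8 μm², conventional 783 / 53.6 μm²,
junctions 228 / 6.4 μm²) — count, mean (at printed precision) and total all
reproduce, at the cost of realistic within-population variance; any analysis
of fixture area *spread* is therefore meaningless by design. The
conventional-drive sources are `unknown`-superclass orphan processes so
that the network-wide amacrine tallies (2359 AC→BC, 336 AC→GC, 564 AC→AC)
can hold simultaneously with the reference cell's 783 conventional inputs,
exactly as in a real volume where most presynaptic fragments are
unclassified. The OFF alpha analog carries 13 junctions totalling
2.7426 μm² over 300 μm of dendrite (9142 nm²/μm exactly), and the tON DS
analog's 322 μm length makes the density ratio ≈46%. 61 of the 228
junctions carry the validated (partner-traced) flag, spread round-robin
over nine GABAergic partner cells — the per-partner split is a free
parameter.

**Phantoms.** Soma discs are placed by rejection sampling (bounded retries,
error on infeasible layouts) with a small exclusion margin; each soma draws
one concentration per channel from its class range, rendered through the
calibration model with optional additive Gaussian PV noise clipped to
[0, 255]. The default ganglion-cell-layer configuration uses starburst
amacrine GABA at 5–10 mM, provisionally coupled γ+ ganglion cells at
0.3–0.6 mM (an order of magnitude below starburst levels), γ− ganglion
cells below 0.1 mM, and one shared glutamate level for both ganglion
classes so their glutamate histograms are indistinguishable by
construction. Phantoms emulate flat discs with per-soma-constant
concentration: no partial-volume effects, no silver-grain texture, no
staining gradients, no overlapping processes. Passing tests therefore
establish the correctness of the pipeline's arithmetic and its recovery of
ground truth under the stated noise model — not segmentation performance on
real micrographs.

## Problem sizes and numerical choices

The packaged fixture has ~150 neurons and ~4600 contacts; generator and
phantom defaults (tens of cells, 256×256 px) are sized so the full suite
runs in well under a minute while keeping every statistical check at the
sample sizes the analyses actually use (e.g. 228 junction diameters, 13-vs-
228 power, 10,000 Monte-Carlo replicates). Ties in k-means restarts resolve
by inertia then lowest label; query output ordering is lexicographic in
(neuron ids, contact ids); drive-table area totals are exact `fsum`-style
sums with display rounding applied only at the reporting edge.

## Known limitations

- No 3D morphology: stratification and geometry enter only as class
  attributes; spatial synapse placement is out of scope.
- The query engine's simple-path semantics will not enumerate cyclic walks;
  motifs with repeated cells need explicit composition.
- The roster covers the class vocabulary used here; unknown labels are
  allowed but resolve to `unknown` superclass and are flagged by the
  validator rather than inferred.
- Post-hoc power is reported under the pooled two-sided noncentral-*t*
  convention only.
- The fixture reproduces printed *summaries*; its per-contact values are a
  synthetic construction and carry no empirical variance structure.
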