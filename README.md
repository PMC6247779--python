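# retcouple

Tools for mining **heterocellular coupling networks** — gap-junction
partnerships between retinal ganglion cells (GCs) and GABAergic amacrine
cells (ACs) — in annotated connectome volumes, and for the **computational
molecular phenotyping** (CMP) imagery that flags coupled cells by their
intermediate GABA content.

Many GC classes carry a GABA signal well below amacrine levels. GCs neither
synthesize nor transport GABA, so an intermediate signal (0.1–1 mM,
superimposed on the classic high-glutamate GC signature) is evidence that
GABA diffuses in through gap junctions from coupled γ+ amacrine cells.
Establishing which cells couple, how much drive they exchange, and what the
coupled inhibitory network does requires (a) typed graph queries over a
densely annotated connectome and (b) quantitative pixel classification of
small-molecule immunosignal channels. This package implements both halves
for researchers in retinal connectomics and quantitative neuroanatomy:

- **`retcouple.model`** — a typed attributed multigraph: neurons with
  class/superclass/polarity/transmitter labels, directed ribbon and
  conventional synapses with PSD areas, undirected gap junctions linked to
  diameters by a circular-disc model *A* = π(*d*/2)²; lossless TSV and
  GraphML serialization, invariant validation.
- **`retcouple.pathquery`** — a regex path-query engine. A query such as
  `"CB.*, ribbon, GC ON"` alternates anchored node regexes with edge kinds;
  chemical hops run pre→post, gap-junction hops run both ways, matches are
  simple paths in deterministic order. A disjointness filter extracts the
  coupled-feedforward motif GC₁ :: AC > GC₂ with class₁ ≠ class₂.
- **`retcouple.coupling`** — drive tables (per-kind counts, PSD-area
  statistics, whole-cell extrapolation *n*/*f* at arbor fraction *f*), input
  spectra and polarity profiles, amacrine feedforward:feedback bias
  (feedback = AC→BC, feedforward = AC→GC or AC→AC), a coupling-motif census
  (homocellular in-class / homocellular cross-class / heterocellular), and
  two-sample junction-size statistics (t, Welch, F, KS) with post-hoc power
  from the noncentral-*t* distribution at pooled-SD Cohen's *d*.
- **`retcouple.cmp`** — the image pipeline: integer-shift cross-correlation
  registration, a log-linear calibration PV = PV_ref + s·log₁₀(c/c_ref)
  between pixel value and concentration, k-means theme maps, peak-normalized
  masked histograms, three-band GABA segmentation (<0.1 / 0.1–1 / ≥1 mM),
  colocalization RGB maps (`"γE::yb"`), and size-filtered object counting.
- **`retcouple.synthetic`** — seeded generators for retina-like connectomes
  and multichannel soma phantoms with ground truth, plus a deterministic
  summary fixture encoding the published tallies of a reference volume.

## Worked example

```sh
python examples/drive_table.py
```

prints

```
                   n  mean_area_um2  total_area_um2  extrapolated_n
kind
ribbon_in        259          0.038             9.8          1440.0
conventional_in  783          0.068            53.6          4350.0
gap_junction     228          0.028             6.4          1270.0

inhibitory : excitatory synapse ratio  3.02
inhibitory PSD area per ribbon area    5.5
```

The fixture's tON DS ganglion-cell analog receives 259 excitatory ribbon
synapses (9.8 μm² of PSD), 783 inhibitory conventional synapses (53.6 μm²)
and makes 228 gap junctions (6.4 μm²) inside the volume — roughly three
inhibitory synapses per excitatory input and 5.5 μm² of inhibitory PSD per
μm² of ribbon PSD. Because the in-volume arbor is 18% of the complete cell,
a whole cell of this class is estimated to carry ≈1440 ribbons, ≈4350
conventional synapses and ≈1270 gap junctions.

The other scripts in `examples/` walk through path queries and the
coupled-feedforward motif (`path_queries.py`), the coupling census,
junction-density and two-sample size comparison with power
(`coupling_census.py`), the CMP phantom pipeline (`cmp_pipeline.py`), and
the seeded connectome generator (`synthetic_connectome.py`).

A thin CLI wraps the same functions:

```sh
retcouple make-fixture --out fixtures/rc1
retcouple drive-table --graph fixtures/rc1 --cell GC606 --arbor-fraction 0.18
retcouple query --graph fixtures/rc1 --pattern "CB.*, ribbon, GC tON DS" --group-by first_class
```

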