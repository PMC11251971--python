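# Methods

## Coordinates and data model

All in-memory coordinates are 0-based half-open; 1-based conventions
(GFF3, GenBank, WIG fixedStep) exist only at file boundaries, where the
conversion is applied on read and inverted on write. Sequences are
uppercased on ingest and restricted to {A, C, G, T, N}; any other IUPAC
ambiguity code is mapped to N with a logged warning. Soft-masked
(lower-case) input is uppercased and not treated specially — masking plays
no role in the structural calculations. Multi-record FASTA files produce
one atlas per record; records are never concatenated.

A `Track` holds window-centered values: value *i* sits at
`start_offset + i·step` with `start_offset = floor(window/2)`, and a track
over a length-*L* profile has `floor((L − window)/step) + 1` values.

## Structural scales

The three packaged parameter sets are stored as plain-text TSV data files
(header lines `#name/#k/#units/#citation/#strand_symmetric`, then
`KMER<TAB>value`) so completeness (4^k entries) and reverse-complement
symmetry are asserted by tests against the files themselves.

* **Stacking energy** (k = 2, kcal/mol): the optimized base-stacking
  energies of Ornstein et al. (1978), strand-symmetric by duplex physics
  (a dinucleotide step and its reverse complement are the same stack).
  All 16 values are negative; GC (−14.59) stacks most strongly and
  TA (−3.82) most weakly, so windows near zero melt most easily.
* **Position preference** (k = 3, fractional preference): the nucleosome
  core trinucleotide preferences of Satchwell, Drew & Travers (1986),
  expanded from the 32 published complementary-pair values to all 64
  trinucleotides by reverse-complement symmetry. Low values mark
  inflexible, nucleosome-averse DNA (candidate open chromatin).
* **Curvature** (dinucleotide wedge model): wedge magnitudes and
  directions from Bolshoy et al. (1991) with the Kabsch–Sander–Trifonov
  (1982) helical twist angles. The model is pluggable — any
  `CurvatureModel` (wedge, direction, twist per dinucleotide plus a
  helical window length) can be passed to `curvature_track`; this wedge
  set is the package default because it is the classical, widely
  reproduced parameterisation of A-tract bending. A zero-wedge
  `straight_model()` control is provided for testing.

Profile lookup assigns value `scale[s[i:i+k]]` to position *i*; any k-mer
containing N yields NaN. Windowed means exclude NaN positions rather than
poisoning the window (long assembly gaps must not blank a whole lane);
a window with no valid positions is NaN and renders as background.

## Windowed tracks

Property tracks (stacking, position preference, curvature) default to
window = 0.1% of the plotted length (minimum 1 bp) and **step = 1 bp**;
reduction to pixel columns happens in the renderer, keeping tracks
resolution-independent. Step is configurable (including step = window) for
users who want non-overlapping windows. GC skew uses a fixed 10,000-bp
default window, with the skew defined as (G−C)/(G+C) — "the total" is read
as total G+C, the standard skew definition; normalisation by window length
is available via `per_window_length=True`. AT content divides by the
window length, so N counts in the denominator only.

Curvature is computed on the model's own helical window
(`window_len = 21` bp ≈ two helical turns, 20 dinucleotide steps): each
step's wedge vector `w·exp(i(φ + δ))`, with φ the cumulative twist, is
summed over the window and the magnitude divided by the step count
(degrees/step, ≥ 0 — magnitude, not signed direction, since the lane is
single-colored). That per-position profile is then smoothed by the
requested window like any other profile. In-phase A-tracts (period
~10.5 bp) add coherently and score high; shuffled sequence of identical
composition cancels.

## Repeat lanes

Identity is **ungapped** (Hamming over length-w alignments, w = 100 bp by
default): this admits an exact exhaustive oracle and an exact seeded
search, whereas gapped identity would make the bins depend on alignment
parameters. Candidate windows sharing ≥ 1 bp with the query are excluded
(self-overlap would make every bin trivially 9); the exclusion is the
query's own footprint, and sequences shorter than 2w report identity 0
with a logged note since no non-overlapping placement exists. Identities
bin as `min(floor(identity × 10), 9)` (with a 1e-9 guard so exact
rationals like 30/100 do not floor down a bin). The default query step is
the window (non-overlapping, 100-bp bin resolution — a whole-locus atlas
at ~2 kb/pixel cannot show finer steps); step is configurable down to 1.

The seeded search cuts the query into `b = floor(w/seed)` non-overlapping
blocks (seed = 12 by default) and verifies every diagonal proposed by an
exact block hit. By pigeonhole it finds every candidate with fewer than
*b* mismatches, so a seeded best with ≤ b−1 mismatches is provably the
optimum; otherwise the exhaustive scan runs as fallback. The
`--approximate` flag skips the fallback, turning low bins into lower
bounds (documented behaviour for very large inputs). With the fallback in
place, seeded and exhaustive results are equal by construction — the test
suite asserts exact equality on random fixtures, both strands.

Inverted repeats scan the reverse complement; match positions are reported
in forward-strand coordinates. Whether the original atlases used gapped
matching or a different heuristic is not documented; the choices above are
explicit substitutes chosen for testability.

## Rendering

Lanes are reduced to `width_px` pixel columns by averaging the track
values whose centers fall in each pixel's bp span (empty pixels are NaN →
background). Normalisation defaults to mean ± 3 SD saturation (the
convention of the genome-atlas lineage this follows; configurable per
lane via `saturation_k`), with σ = 0 mapping everything to mid-scale;
repeat bins use a fixed 0–9 scale. Colormaps are three-point linear
gradients chosen to match the established color language — red = easily
melting DNA, green = low position preference (open chromatin), blue =
direct repeats, red = inverted repeats, magenta/turquoise = GC skew,
red = AT-rich, dark blue = curved; exact RGB values are a documented
choice and overridable per `LaneSpec`. Resolution is always computed from
the actual region length as `length / width_px` and recorded in the
sidecar JSON together with each lane's mean, SD, window and step, and (for
CLI runs) the resolved configuration — every figure is reproducible from
its own metadata. Rendering is deterministic (fixed DPI and fonts, no
timestamps); byte-identical output across runs is test-asserted.

The whole-locus gene lane draws introns and exons combined, split into
'+' and '−' sub-lanes; zooms shade introns light and draw exons solid.
A zoom region is the gene ± flank (truncated at sequence ends with a
logged note); minus-strand genes are reverse-complemented **before** track
computation so the gene reads 5′→3′ left-to-right. Zoom lanes drop GC skew
(a global, replication-strand property that is uninformative at gene
scale) and add curvature; the AT-content and property windows shrink to
0.1% of the zoom length automatically. Zoom repeat lanes scan the
displayed region rather than the whole input — a deliberate locality
choice that keeps zoom cost proportional to the region.

## Synthetic fixtures

The fixture generator emulates only the sequence-level features the
method responds to: uniform random background, AT/GC-biased blocks, G
runs, exact planted direct/inverted repeat copies, and helically phased
A6 tracts (period 10.5 bp). It does not emulate real MHC features —
polymorphism structure, repeat families (Alu/LINE), gene density,
isochores, or assembly gaps — so green tests demonstrate correctness of
the computations and conventions, not biological conclusions about real
haplotypes. Every fixture is reproducible from (recipe, seed) with one
documented PRNG (`numpy.random.default_rng`), and recipes round-trip
through YAML.

## Problem sizes and numerical choices

Tests and the acceptance script run on 2–50 kb fixtures: a 50-kb
haplotype-like sequence for end-to-end atlas runs (20 bp/pixel at
2,500 px), a 15-kb zoom (6 bp/pixel), 5-kb planted-repeat fixtures checked
against the exhaustive scan at every window, and dozens of random 2–5-kb
fixtures for seeded-vs-exhaustive equality. These sizes exercise every
code path at full fidelity; the method scales to Mb inputs since tracks
are O(L) and repeat search O(L²/w) vectorised (with `--approximate`
available beyond that). Windowed means match a brute-force oracle to
1e-9; ties in the repeat search resolve to the lowest candidate start;
`resolution` and all identities are computed in double precision.

## Known limitations

* Ungapped repeat identity understates diverged repeats that align with
  indels.
* The curvature lane reports bend magnitude only, not direction or
  helical phase.
* No melting thermodynamics (nearest-neighbour ΔG/ΔH, salt correction) —
  stacking energy is a proxy for melting propensity.
* Scales are fixed published parameter sets; no fitting to data, RNA
  parameters, or temperature dependence.
* Epigenetic signals (base modifications) are outside the scope of the
  computation; the atlases visualise sequence-intrinsic structure only.
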