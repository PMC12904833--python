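# Methods

This note documents the model behind chromoglyph, the conventions it
commits to, the synthetic data it tests itself on, and the numerical and
design choices that were genuinely open.

## The tabular structure model

A 3D genome structure is a table linking genomic bins to coordinates.
We use plain pandas DataFrames (not a wrapper class) with reserved
columns `chrom/start/end/x/y/z`, in the style of dataframe-centric
genomics libraries: every operation is a function on DataFrames, so
structures interoperate directly with the rest of the Python ecosystem,
and the Arrow IPC form is the lossless serialization of exactly this
table.

Conventions, fixed once and applied everywhere:

- **Coordinates are 0-based, half-open** (`[start, end)`, BED
  convention). Bin width is `end − start`; abutting bins share no base.
  GTF input (1-based inclusive) is converted on read.
- **Chain order is row order.** Structure files encode polymer
  connectivity by line sequence; sorting is never implicit. The
  validator flags non-increasing starts within a chromosome as a
  *warning*, not an error.
- **Missing coordinates are hard errors.** Every spatial operation
  assumes finite points; there is no masked-coordinate state.
- **Model units are dimensionless.** The formats carry no unit
  metadata, so none is invented.
- **Duplicate `(chrom, start)` pairs are permitted with a warning**, to
  accommodate diploid models where both homologs carry the same genomic
  interval; homolog identity belongs in an annotation column, and the
  locus-centered sphere selection refuses ambiguous loci rather than
  guessing.

`infer_resolution` returns the modal bin width, ties broken toward the
smallest value — the conservative choice when a structure mixes a
dominant resolution with truncated terminal bins.

## File dialects

- `.3dg`: tab-separated `chrom start x y z`. The position field is read
  as the **bin start** (the dominant convention in the single-cell
  structure literature, where files tile the genome from 0). Since the
  format carries no `end`, bin ends are synthesized from the modal
  positive consecutive-start difference per chromosome; single-bin
  chromosomes fall back to the pooled mode or an explicit
  `resolution=` hint. Floats are written with 6 significant digits, so
  text round-trips agree to 1e-5 on unit-scale coordinates.
- **PDB chromatin dialect**: tools that reuse PDB for genome structures
  disagree on where genomic coordinates live, and nine-digit positions
  cannot fit the four-character residue-number column. Our writer
  refuses to overload fixed-width fields: resSeq holds the 1-based
  within-chromosome bin index, and a trailing `REMARK 350 BIN serial
  chrom start end` table carries the genomic intervals losslessly.
  `strict=True` turns every silently-lossy condition (≥ 37 chromosome
  labels, > 9999 bins per chromosome) into an error. The reader parses
  fixed PDB 3.3 columns with a whitespace fallback per line (tolerating
  residue numbers that overflow into the insertion-code column) and
  deliberately does **not** interpret foreign REMARK blocks — those are
  too dialect-specific — so it requires an explicit resolution.
- **Arrow IPC / Feather** (via pyarrow) is the canonical lossless form:
  bit-exact floats, annotation columns and their types preserved.

Every reader validates its output; an invalid table cannot escape the
I/O layer.

## Selections

Interval overlap and point-in-region tests are evaluated with vectorized
per-chromosome numpy broadcasting — at the ≤10⁶-bin scale of genome
structures this is faster than building acceleration structures, and the
test suite holds every operation to exact agreement with naive
double-loop oracles on randomized instances.

Boundary conventions (the formats and the field do not fix these; ours
are documented choices, tested explicitly):

- interval overlap is half-open on both sides; a query ending at
  100 000 does not touch the bin starting there;
- the cutting plane assigns signed distance 0 to the *positive* side, so
  positive and negative masks always partition the structure;
- the spherical neighborhood includes its boundary;
- chromosome names match by exact string equality — no `chr` aliasing,
  which silently empties selections when naming schemes mix; rename
  explicitly instead.

`mode="contained"` means bin ⊆ query, the natural reading when
structures are coarser than query ranges.

## Annotation aggregation

`bin_features` offers four estimators because "gene density" is not one
number: `count` (any overlap; a feature spanning k bins contributes k
times — the right visual-intent choice, and the default), `count_midpoint`
(each feature counted at most once, giving the exact conservation law
Σ bins = number of midpoints covered, used as a test oracle),
`coverage_fraction` (overlapping features unioned *before* measuring, so
stacked transcripts cannot push coverage above 1), and `mean_value`
(length-weighted over the covered part of the bin; uncovered bins get
NaN rather than a fake 0, while count/coverage get a true 0). Features
on chromosomes absent from the structure are ignored with a logged
count, since annotations are typically genome-wide.

## The view-config grammar

The config is a JSON object with exactly five keys (`mark`, `color`,
`scale`, `base_size`, `links`); unknown keys are errors (fail-fast, like
grammar-of-graphics validators — typos should not silently render
defaults). Channels are either a constant or a `field` mapping with
`scale_type`, optional `domain` and `range`. Validation is
structure-independent; field existence and type compatibility are
checked at resolve time.

Resolution rules:

- continuous channels normalize `(v − min)/(max − min)` clipped to
  [0, 1]; the domain defaults to the structure's own min/max and is
  **recomputed after filtering** — pin `domain` explicitly to compare an
  ensemble of structures on one scale (both behaviors are tested);
  zero-spread domains map everything to 0.5 with a warning;
- continuous color interpolates piecewise-linearly through a colormap's
  anchor list with round-half-up components; built-ins are `viridis`
  (the standard 256-entry table, perceptually uniform, the default) and
  `bluered` (two anchors, so its midpoint is exactly (128, 0, 128, 255));
- categorical color assigns a fixed 12-color qualitative palette
  (ColorBrewer Paired) by **first appearance in row order** — file order
  controls color order, predictable for sorted genomes — cycling with a
  warning past 12;
- the scale channel maps into `[0.25, 1.5]` by default; resolved sizes
  must be positive. `base_size: "auto"` is half the median distance
  between consecutive same-chromosome bins, so default spheres nearly
  touch along the chain regardless of the model's coordinate scale;
- explicit colors accept `#RRGGBBAA`, but no channel maps *data* to
  alpha: occlusion is handled by scaling marks down, not by
  transparency.

## Meshes and snapshots

Spheres are icosphere subdivisions of the icosahedron, fixed at level 2
(162 vertices / 320 faces) as a quality/size compromise; cubes are
8 / 12; links are open 8-sided prisms with radius 0.15× the mean of the
two bin sizes. Counts are exact linear functions of bin counts, which
the tests assert in closed form. Colors are per-vertex (uniform within a
bin) because per-vertex uchar RGBA is the most portable PLY dialect;
the written PLY is verified in tests by an independent mesh library.
The resolved `size` is the sphere radius / cube half-edge.

The static renderer (orthographic projection, painter's algorithm over
mark centers, flat discs/quads, white background) exists for smoke tests
and documentation images, not as a product renderer; its determinism is
tested, its realism is not claimed.

## Synthetic generators

All generators use numpy's PCG64 (`default_rng`) and are pure functions
of parameters + seed; seed 0 is reserved for documentation examples.

- `random_walk_chain`: freely-jointed chain, steps uniform on the unit
  sphere. Its test is the ideal-chain law ⟨R²⟩ = N·b², checked by
  Monte Carlo (200 seeds at n = 10⁴, 10% tolerance).
- `confined_chain`: the same walk with rejection of proposals leaving a
  confinement sphere or approaching prior points closer than
  `min_separation`, with single-step backtracking — a cheap
  chromosome-territory look-alike, not a physical polymer model.
- `make_test_genome`: one confined chain per chromosome on distinct
  lattice offsets. The confinement radius is `max(1.5, 0.9·step·n^(1/3))`
  per chromosome — comfortably above the sphere-packing bound for beads
  separated by `step/2` — and territory spacing defaults to 2.5× the
  largest radius, which keeps territories visibly distinct.
- `make_test_annotation`: gene-like intervals whose starts mix a uniform
  component with a Beta(2, 8) component (weight = `clustering`), giving
  a known density gradient: at `clustering = 1` the mean feature
  position is 0.2 of the chromosome length. Lengths are uniform in
  [1 kb, 10 kb].

What these fixtures do *not* emulate: loop extrusion, compartments, Hi-C
constraint satisfaction, realistic gene length/spacing distributions, or
ensemble variability between cells. Passing tests therefore demonstrate
the correctness of the table/selection/encoding machinery on inputs with
the right shape and scale — not biological fidelity of any structure.

## Problem sizes

The default verification runs use: 100 random structures of 100–2000
bins (selection oracles), 1000 structure/plane pairs (partition law), 50
genome/annotation pairs at 100 kb resolution (conservation), 5000-bin
structures for columnar round-trips, and 200 replicate chains at n = 10⁴
(random-walk limit). These sizes give exact combinatorial checks and
<10⁻² Monte-Carlo precision while keeping the whole suite fast enough to
run on every change.

## Known limitations

- No mmCIF/g3d/trajectory formats; no streaming reads (structures are
  small); no bigWig/bedGraph signals; no strand-aware aggregation.
- No k-nearest-neighbor or density queries; no KD-trees (unnecessary at
  this scale).
- No ensembles-as-objects: an ensemble is a list of tables.
- The PDB reader does not recover genomic starts from foreign REMARK
  conventions.
- OBJ export drops colors (format limitation; a warning says so).
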