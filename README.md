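# chromoglyph

A headless Python toolkit for working with **3D genome structures** — the
polymer-like models that assign XYZ coordinates to genomic loci,
reconstructed from Hi-C contact data or simulated de novo. It is aimed at
computational biologists who have such structures (from single-cell Hi-C
reconstruction pipelines, chromatin polymer simulations, or imaging-based
methods) and need to filter them, join them with genomic annotations,
specify how they should be depicted, and export portable 3D artifacts —
all scriptably, without a browser or an interactive viewer.

## The data model

A structure is a plain `pandas.DataFrame` with one row per **bin** (a
genomic interval at a fixed resolution represented as one particle):

| column | meaning |
|---|---|
| `chrom` | chromosome / segment label (exact string matching everywhere) |
| `start`, `end` | base pairs, 0-based, half-open `[start, end)` (BED convention) |
| `x`, `y`, `z` | model coordinates (dimensionless, consistent per structure) |
| anything else | numeric or categorical annotation columns |

Row order is significant: it encodes polymer chain order. Operations never
reorder or drop rows unless that is their purpose.

On top of this the package provides:

- **I/O** for the field's dialects: `.3dg` tables (single-cell Hi-C
  structure literature), CSV/TSV with an explicit column mapping, the
  reinterpreted-PDB chromatin-bead dialect, and a lossless Arrow
  IPC/Feather columnar form. Genomic coordinates can span nine digits and
  do not fit PDB's fixed-width residue field, so the PDB writer stores the
  within-chromosome bin index there and the true genomic intervals in a
  trailing `REMARK 350` table instead of abusing non-standard fields.
- **Selection**: genomic range queries (`select_by_ranges`, fed by BED
  files or any interval DataFrame), cutting planes (`cut_by_plane`,
  signed distance s = n̂·p + d, boundary to the positive side) and
  spherical neighborhoods (`select_sphere`,
  `select_sphere_around_locus`). All return boolean masks that compose
  with `combine_masks` before `apply_mask` materializes a subset.
- **Annotation**: BED/GTF readers and `bin_features`, which aggregates
  features into bins as overlap counts, midpoint counts (exactly
  conserved), union coverage fractions in [0, 1], or length-weighted mean
  values — the classic per-bin gene-density computation.
- **Declarative visual encoding**: a JSON view config maps data columns
  to visual channels (mark: sphere/box; color: constant, continuous
  colormap, or categorical palette; scale: positive size multipliers);
  `resolve_view_config` turns (structure, config) into concrete per-bin
  RGBA/size/mark attributes. Mapping `chrom` to the color channel
  categorically gives one distinct color per chromosome.
- **Export**: `build_meshes` materializes a scene (ordered structure +
  config pairs) into triangle meshes with per-vertex colors (icosphere
  162 vertices / 320 faces per bin; cube 8 / 12), written as PLY or OBJ;
  `render_static` produces a deterministic orthographic PNG snapshot.
- **Synthetic fixtures**: seeded generators for freely-jointed chains,
  confined chromosome-territory-like chains, and clustered gene-like
  annotations, so everything is testable without downloads.

## Worked example

`examples/03_gene_density.py` builds a seeded two-chromosome territory
structure (100 kb bins), piles 500 synthetic genes near the chromosome
starts, counts genes per bin, and maps the density to color and size:

```text
gene_density per bin: min=0, median=4, max=70
sparsest bin: size 0.40, rgba (68, 1, 84, 255)
densest bin:  size 1.60, rgba (253, 231, 37, 255)
```

The sparsest bin gets the smallest mark and the first viridis color
(dark purple); the densest gets the largest mark and the last anchor
(bright yellow) — gene-rich regions pop visually. The other examples
cover building/validating structures, composing genomic and spatial
selections, and mesh/snapshot export.

The same pipeline is available from the shell:

```sh
chromoglyph demo figure1d --seed 0 --prefix out   # writes out.ply + out.png
chromoglyph info structure.3dg
chromoglyph convert structure.3dg structure.arrow
chromoglyph select structure.3dg half.3dg --plane 0,0,1,0 --keep positive
chromoglyph annotate structure.3dg dens.arrow --gtf genes.gtf --mode count
```

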