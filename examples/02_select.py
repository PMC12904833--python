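"""Genomic and spatial filtering: ranges, cutting plane, spherical neighborhood.

Selections return boolean masks aligned with the bin table, so genomic
and spatial criteria compose with boolean algebra before materializing.
"""

from chromoglyph import (
    Plane,
    apply_mask,
    combine_masks,
    cut_by_plane,
    intervals,
    make_test_genome,
    select_by_ranges,
    select_sphere_around_locus,
)

genome = make_test_genome(
    [("chr1", 2_000_000), ("chr2", 1_000_000)], resolution=100_000, seed=0
)
print(f"{len(genome)} bins on {genome['chrom'].nunique()} chromosomes")

# genomic: bins overlapping chr1:400k-900k (half-open, exact chrom match)
genomic = select_by_ranges(genome, intervals(["chr1"], [400_000], [900_000]))
print(f"range query hits {genomic.sum()} bins")

# spatial: keep the half-space z >= -1 (boundary goes to the positive side)
spatial = cut_by_plane(genome, Plane(normal=(0, 0, 1), offset=1.0), "positive")
print(f"cutting plane keeps {spatial.sum()} bins")

# spherical neighborhood of the bin covering chr1:500,000
near = select_sphere_around_locus(genome, "chr1", 500_000, radius=2.0)
print(f"{near.sum()} bins within 2 model units of chr1:500000")

# compose: genomic AND spatial, then materialize the subset
both = apply_mask(genome, combine_masks(genomic, spatial, "and"))
print(f"intersection: {len(both)} bins, chain order preserved")
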