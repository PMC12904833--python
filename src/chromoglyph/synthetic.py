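"""Seeded synthetic structures and annotations with known ground truth.

Emulates the *shape* of polymer-model outputs — freely-jointed chains,
chromosome-territory-like confined chains, and clustered "gene"
annotations — so every operation in the package is testable without
downloading real structures.  These are fixtures, not physically
meaningful chromatin simulations (no loop extrusion, no Hi-C constraint
fitting).

All generators are pure functions of their parameters and seed, using
numpy's PCG64 generator (``numpy.random.default_rng``); seed 0 is
reserved for documentation examples.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import ChromoglyphError, from_coordinates


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_walk_chain(n: int, step: float = 1.0, seed: int = 0) -> np.ndarray:
    """Freely-jointed chain: n points, fixed step length, isotropic steps.

    Starts at the origin; each step direction is uniform on the unit
    sphere.  Obeys the ideal-chain law ⟨R²⟩ = (n−1)·step² in expectation.
    """
    if n < 1:
        raise ChromoglyphError(f"n must be >= 1, got {n}")
    if not step > 0:
        raise ChromoglyphError(f"step must be > 0, got {step}")
    rng = np.random.default_rng(seed)
    steps = step * _unit_vectors(rng, n - 1) if n > 1 else np.empty((0, 3))
    return np.concatenate([np.zeros((1, 3)), np.cumsum(steps, axis=0)])


def confined_chain(
    n: int,
    step: float = 1.0,
    confinement_radius: float = 5.0,
    min_separation: float = 0.5,
    seed: int = 0,
    max_attempts: int = 10_000,
    center=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Self-avoiding-ish chain confined to a sphere (territory fixture).

    Random walk with rejection: a proposed point outside the confinement
    sphere around ``center``, or within ``min_separation`` of any prior
    point, is re-drawn; repeated failure backtracks one step.  Raises
    after ``max_attempts`` total rejections.
    """
    if n < 1:
        raise ChromoglyphError(f"n must be >= 1, got {n}")
    if not confinement_radius > step:
        raise ChromoglyphError("confinement_radius must exceed step")
    if not min_separation < step:
        raise ChromoglyphError("min_separation must be smaller than step")
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    points = [center.copy()]
    failures = 0
    while len(points) < n:
        placed = False
        for _ in range(50):  # local proposals before backtracking
            cand = points[-1] + step * _unit_vectors(rng, 1)[0]
            ok_conf = np.linalg.norm(cand - center) <= confinement_radius
            arr = np.asarray(points)
            ok_sep = bool(
                (np.linalg.norm(arr - cand, axis=1) >= min_separation).all()
            )
            if ok_conf and ok_sep:
                points.append(cand)
                placed = True
                break
            failures += 1
            if failures >= max_attempts:
                raise ChromoglyphError(
                    f"confined_chain: gave up after {failures} rejected "
                    f"proposals at {len(points)}/{n} points; parameters "
                    "are likely infeasible"
                )
        if not placed and len(points) > 1:
            points.pop()  # backtrack one step and retry
    return np.asarray(points)


def _territory_radius(n: int, step: float) -> float:
    # loose packing bound for min_separation = step/2 beads in a sphere
    return max(1.5 * step, 0.9 * step * n ** (1 / 3))


def _lattice_offsets(k: int) -> np.ndarray:
    """First k points of an integer grid enumerated in shells (deterministic)."""
    side = max(1, math.ceil(k ** (1 / 3)))
    grid = [
        (ix, iy, iz)
        for iz in range(side + 1)
        for iy in range(side + 1)
        for ix in range(side + 1)
    ]
    grid.sort(key=lambda p: (max(p), p[2], p[1], p[0]))
    return np.asarray(grid[:k], dtype=float)


def make_test_genome(
    chrom_sizes,
    resolution: int = 100_000,
    territory_spacing: float | None = None,
    seed: int = 0,
    step: float = 1.0,
) -> pd.DataFrame:
    """Multi-chromosome structure with distinct territories, as a bin table.

    One confined chain per chromosome (``n = ceil(size / resolution)``
    bins), centered on distinct lattice offsets ``territory_spacing``
    apart (default 2.5× the largest confinement radius).  Genomic bins
    tile ``[0, size)`` at ``resolution``; the last bin is truncated to
    the chromosome size.
    """
    chrom_sizes = list(chrom_sizes)
    if not chrom_sizes:
        raise ChromoglyphError("need at least one chromosome")
    ns = []
    for name, size in chrom_sizes:
        if size < resolution:
            raise ChromoglyphError(
                f"chromosome {name!r} size {size} is below resolution {resolution}"
            )
        ns.append(math.ceil(size / resolution))
    radii = [_territory_radius(n, step) for n in ns]
    if territory_spacing is None:
        territory_spacing = 2.5 * max(radii)
    offsets = _lattice_offsets(len(chrom_sizes)) * float(territory_spacing)

    rng = np.random.default_rng(seed)
    tables = []
    for (name, size), n, radius, offset in zip(chrom_sizes, ns, radii, offsets):
        chain = confined_chain(
            n,
            step=step,
            confinement_radius=radius,
            min_separation=0.5 * step,
            seed=int(rng.integers(0, 2**31 - 1)),
            center=offset,
        )
        table = from_coordinates(chain, chrom=name, resolution=resolution)
        table.loc[len(table) - 1, "end"] = min(int(table["end"].iloc[-1]), int(size))
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def make_test_annotation(
    chrom_sizes,
    n_features: int = 500,
    clustering: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic gene-like intervals with a controllable density gradient.

    Feature start positions are drawn from a mixture: uniform over the
    chromosome with weight ``1 − clustering`` and Beta(2, 8)-distributed
    (piling up near the chromosome start, mean position 0.2) with weight
    ``clustering``.  Lengths are uniform in [1 kb, 10 kb], clipped to the
    chromosome.  Features carry a ``name`` and a uniform [0, 1) ``value``.
    """
    if n_features < 1:
        raise ChromoglyphError(f"n_features must be >= 1, got {n_features}")
    if not 0.0 <= clustering <= 1.0:
        raise ChromoglyphError(f"clustering must be in [0, 1], got {clustering}")
    chrom_sizes = list(chrom_sizes)
    rng = np.random.default_rng(seed)
    names = [name for name, _ in chrom_sizes]
    sizes = np.asarray([size for _, size in chrom_sizes], dtype=float)
    which = rng.choice(len(names), size=n_features, p=sizes / sizes.sum())
    clustered = rng.random(n_features) < clustering
    frac = np.where(clustered, rng.beta(2.0, 8.0, n_features), rng.random(n_features))
    lengths = rng.integers(1_000, 10_001, n_features)
    rows = []
    for i in range(n_features):
        size = int(sizes[which[i]])
        start = min(int(frac[i] * size), size - 1)
        end = min(start + int(lengths[i]), size)
        rows.append((names[which[i]], start, max(end, start + 1)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"g{i:05d}" for i in range(n_features)]
    df["value"] = rng.random(n_features)
    return df
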