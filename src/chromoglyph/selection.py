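"""Genomic-range and spatial filtering of 3D genome structures.

All selections return a boolean *mask* aligned with the row order of the
queried bin table, so that genomic and spatial criteria compose cheaply
with boolean algebra before a subset is ever materialized
(:func:`apply_mask`).  Conventions, chosen for deterministic partitions:

* genomic intervals are half-open ``[start, end)`` on both sides;
  chromosome names match by exact string equality (no ``chr`` aliasing);
* the cutting plane assigns its boundary (signed distance 0) to the
  positive side, so the positive/negative masks partition the structure;
* the spherical neighborhood includes its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ChromoglyphError, coordinates


class SelectionError(ChromoglyphError):
    pass


@dataclass
class Plane:
    """Cutting plane ``{p : n̂·p + offset = 0}``.

    ``normal`` need not be unit length; it is normalized internally.
    ``offset`` is the signed-distance term, in model units.
    """

    normal: tuple[float, float, float]
    offset: float = 0.0

    def unit_normal(self) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if not norm > 0 or not np.isfinite(norm):
            raise SelectionError("plane normal must have nonzero finite length")
        return n / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return points @ self.unit_normal() + float(self.offset)


def select_by_ranges(
    table: pd.DataFrame, query: pd.DataFrame, mode: str = "any_overlap"
) -> np.ndarray:
    """Mask of bins hit by at least one query interval on the same chromosome.

    ``mode="any_overlap"``: nonempty intersection of half-open intervals.
    ``mode="contained"``: the bin lies entirely inside some query interval
    (bin ⊆ query, the natural reading when structures are coarser than
    queries).  Query chromosomes absent from the structure match nothing.
    """
    if mode not in ("any_overlap", "contained"):
        raise SelectionError(f"unknown mode {mode!r}")
    chrom = np.asarray(table["chrom"], dtype=object)
    bs = np.asarray(table["start"], dtype=np.int64)
    be = np.asarray(table["end"], dtype=np.int64)
    mask = np.zeros(len(table), dtype=bool)
    for label, grp in query.groupby("chrom", sort=False):
        rows = np.nonzero(chrom == label)[0]
        if rows.size == 0:
            continue
        qs = np.asarray(grp["start"], dtype=np.int64)[None, :]
        qe = np.asarray(grp["end"], dtype=np.int64)[None, :]
        b0, b1 = bs[rows][:, None], be[rows][:, None]
        if mode == "any_overlap":
            hit = (b0 < qe) & (qs < b1)
        else:
            hit = (qs <= b0) & (b1 <= qe)
        mask[rows] |= hit.any(axis=1)
    return mask


def cut_by_plane(table: pd.DataFrame, plane: Plane, keep: str = "positive") -> np.ndarray:
    """Mask of bins on one side of a cutting plane (cross-section).

    With unit normal n̂ and signed distance ``s_i = n̂·p_i + offset``,
    ``keep="positive"`` selects ``s_i >= 0`` and ``keep="negative"``
    selects ``s_i < 0``; the two masks partition the structure.
    """
    if keep not in ("positive", "negative"):
        raise SelectionError(f"keep must be 'positive' or 'negative', got {keep!r}")
    s = plane.signed_distance(coordinates(table))
    return s >= 0 if keep == "positive" else s < 0


def select_sphere(table: pd.DataFrame, center, radius: float) -> np.ndarray:
    """Mask of bins within Euclidean ``radius`` of ``center`` (boundary inclusive)."""
    if not radius > 0:
        raise SelectionError(f"radius must be > 0, got {radius}")
    center = np.asarray(center, dtype=float)
    if center.shape != (3,):
        raise SelectionError(f"center must be a 3-vector, got shape {center.shape}")
    d = np.linalg.norm(coordinates(table) - center, axis=1)
    return d <= radius


def select_sphere_around_locus(
    table: pd.DataFrame, chrom: str, pos: int, radius: float
) -> np.ndarray:
    """Spherical neighborhood centered on the bin covering a genomic locus.

    Exactly one bin must satisfy ``start <= pos < end`` on ``chrom``;
    diploid structures with duplicated coordinates must be disambiguated
    (e.g. by an annotation-column filter) before calling.
    """
    hit = (
        (np.asarray(table["chrom"], dtype=object) == chrom)
        & (np.asarray(table["start"]) <= pos)
        & (pos < np.asarray(table["end"]))
    )
    n = int(hit.sum())
    if n == 0:
        raise SelectionError(f"locus {chrom}:{pos} is not covered by any bin")
    if n > 1:
        rows = np.nonzero(hit)[0].tolist()
        raise SelectionError(
            f"locus {chrom}:{pos} is covered by {n} bins (rows {rows}); "
            "disambiguate with an annotation filter before selecting"
        )
    center = coordinates(table)[np.nonzero(hit)[0][0]]
    return select_sphere(table, center, radius)


def apply_mask(table: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Materialize a mask: rows where it is true, order and columns preserved."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(table),):
        raise SelectionError(
            f"mask length {mask.shape} does not match bin count {len(table)}"
        )
    return table.loc[mask].reset_index(drop=True)


def combine_masks(a: np.ndarray, b: np.ndarray | None = None, op: str = "and") -> np.ndarray:
    """Elementwise boolean algebra on masks: ``and``, ``or``, or unary ``not_a``."""
    a = np.asarray(a, dtype=bool)
    if op == "not_a":
        return ~a
    if b is None:
        raise SelectionError(f"op {op!r} needs a second mask")
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise SelectionError(f"mask length mismatch: {a.shape} vs {b.shape}")
    if op == "and":
        return a & b
    if op == "or":
        return a | b
    raise SelectionError(f"unknown op {op!r}")
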