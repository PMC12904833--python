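"""Canonical tabular model of a 3D genome structure.

A *bin table* is a :class:`pandas.DataFrame` with one row per genomic bin
and the reserved columns ``chrom``, ``start``, ``end`` (0-based, half-open,
base pairs) and ``x``, ``y``, ``z`` (model units, dimensionless).  Any
further column is an annotation column: numeric (float/int) or categorical
(string).  Row order is significant — it encodes polymer chain order — and
every operation in this package preserves it unless it explicitly subsets
or reorders.

Following the convention of dataframe-centric genomics libraries, bin
tables are plain DataFrames rather than a wrapper class; this module
provides the validator and constructors that define the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved column names of a bin table; annotation columns may not use them.
RESERVED_COLUMNS = ("chrom", "start", "end", "x", "y", "z")

#: The three coordinate columns, in order.
COORD_COLUMNS = ("x", "y", "z")


class ChromoglyphError(Exception):
    """Base class for data errors raised by this package."""


@dataclass
class ValidationReport:
    """Outcome of a structural validation.

    ``errors`` and ``warnings`` are lists of ``(rule, row, message)``
    triples where ``row`` is a 0-based row index or ``None`` for
    table-level problems.
    """

    errors: list[tuple[str, int | None, str]] = field(default_factory=list)
    warnings: list[tuple[str, int | None, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def error(self, rule: str, row: int | None, message: str) -> None:
        self.errors.append((rule, row, message))

    def warn(self, rule: str, row: int | None, message: str) -> None:
        self.warnings.append((rule, row, message))

    def raise_if_invalid(self) -> None:
        if not self.is_valid:
            lines = [f"[{rule}] row={row}: {msg}" for rule, row, msg in self.errors]
            raise ChromoglyphError(
                "invalid structure table:\n" + "\n".join(lines)
            )


def validate_structure(table: pd.DataFrame) -> ValidationReport:
    """Validate a candidate bin table; problems are reported, never raised.

    Hard errors: missing required column, ``start >= end``, negative
    ``start``, non-finite coordinate.  Warnings: starts not strictly
    increasing within a chromosome (broken chain order), non-uniform bin
    widths within a chromosome, duplicate ``(chrom, start)`` pairs.
    """
    report = ValidationReport()
    missing = [c for c in RESERVED_COLUMNS if c not in table.columns]
    if missing:
        report.error(
            "missing-column", None, f"missing required column(s): {', '.join(missing)}"
        )
        return report  # nothing else is checkable

    start = np.asarray(table["start"])
    end = np.asarray(table["end"])
    if not (np.issubdtype(start.dtype, np.number) and np.issubdtype(end.dtype, np.number)):
        report.error("coordinate-type", None, "start/end must be numeric")
        return report

    for i in np.nonzero(start < 0)[0]:
        report.error("negative-start", int(i), f"start {start[i]} < 0")
    for i in np.nonzero(~(start < end))[0]:
        report.error("empty-interval", int(i), f"start {start[i]} >= end {end[i]}")

    coords = table[list(COORD_COLUMNS)].to_numpy(dtype=float, copy=False)
    bad = ~np.isfinite(coords).all(axis=1)
    for i in np.nonzero(bad)[0]:
        report.error("non-finite-coordinate", int(i), "x/y/z must be finite")

    # Warnings, evaluated per chromosome in row order (chain order).
    chrom = np.asarray(table["chrom"], dtype=object)
    for label in pd.unique(chrom):
        idx = np.nonzero(chrom == label)[0]
        s = start[idx]
        if len(s) > 1 and not np.all(np.diff(s) > 0):
            report.warn(
                "chain-order", None,
                f"starts not strictly increasing within chromosome {label!r}",
            )
        widths = end[idx] - s
        if len(np.unique(widths)) > 1:
            report.warn(
                "non-uniform-bins", None,
                f"non-uniform bin widths within chromosome {label!r}",
            )
    dup = table.duplicated(subset=["chrom", "start"])
    for i in np.nonzero(dup.to_numpy())[0]:
        report.warn(
            "duplicate-bin", int(i),
            f"duplicate (chrom, start) = ({chrom[i]!r}, {start[i]})",
        )
    return report


def from_coordinates(
    coords: np.ndarray,
    chrom: str = "chr1",
    resolution: int = 1,
    start_offset: int = 0,
) -> pd.DataFrame:
    """Build a bin table from a bare N×3 coordinate matrix.

    Row *i* is assigned the interval
    ``[start_offset + i*resolution, start_offset + (i+1)*resolution)`` on
    ``chrom``; coordinates are copied in order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ChromoglyphError(
            f"coordinate matrix must be N x 3, got shape {coords.shape}"
        )
    if coords.shape[0] < 1:
        raise ChromoglyphError("coordinate matrix must have at least one row")
    if resolution < 1:
        raise ChromoglyphError(f"resolution must be >= 1 bp, got {resolution}")
    if start_offset < 0:
        raise ChromoglyphError(f"start_offset must be >= 0, got {start_offset}")
    bad = np.nonzero(~np.isfinite(coords).all(axis=1))[0]
    if len(bad):
        raise ChromoglyphError(f"non-finite coordinate in row {int(bad[0])}")
    n = coords.shape[0]
    starts = start_offset + np.arange(n, dtype=np.int64) * int(resolution)
    return pd.DataFrame(
        {
            "chrom": np.repeat(np.asarray(chrom, dtype=object), n),
            "start": starts,
            "end": starts + int(resolution),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )


def infer_resolution(table: pd.DataFrame) -> int:
    """Most frequent bin width (``end - start``); ties break to the smallest.

    Invariant under row permutation.
    """
    if len(table) == 0:
        raise ChromoglyphError("cannot infer resolution of an empty table")
    widths = np.asarray(table["end"]) - np.asarray(table["start"])
    values, counts = np.unique(widths, return_counts=True)  # values sorted asc
    return int(values[np.argmax(counts)])  # argmax takes first = smallest tie


def coordinates(table: pd.DataFrame) -> np.ndarray:
    """Extract the N×3 coordinate matrix of a bin table."""
    return table[list(COORD_COLUMNS)].to_numpy(dtype=float)


def annotation_columns(table: pd.DataFrame) -> list[str]:
    """Names of the non-reserved (annotation) columns, in table order."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]
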