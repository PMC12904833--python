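"""Aggregation of genomic features into structure bins.

Loads interval annotations (BED, GTF/GFF) into plain DataFrames — chrom,
start, end in the 0-based half-open convention, plus optional name/value —
and aggregates them per bin so the result can drive visual channels
(the gene-density use case: color and scale by per-bin gene count).
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .core import RESERVED_COLUMNS, ChromoglyphError

log = logging.getLogger(__name__)

BIN_MODES = ("count", "count_midpoint", "coverage_fraction", "mean_value")

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')     # GFF2:  key "value";
_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")         # GFF3:  key=value;


def intervals(chrom, start, end, name=None, value=None) -> pd.DataFrame:
    """Build a query/annotation interval table from columns."""
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
    if name is not None:
        df["name"] = name
    if value is not None:
        df["value"] = value
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ChromoglyphError(
            f"interval start >= end at row {int(np.nonzero(bad.to_numpy())[0][0])}"
        )
    return df


def read_bed(path) -> pd.DataFrame:
    """Read BED3–BED6 into an interval table (0-based half-open, as stored).

    Column 4 becomes ``name`` and column 5 ``value`` when present;
    ``track``/``browser``/``#`` lines are skipped.
    """
    rows = []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ChromoglyphError(
                    f"{path}: line {lineno}: BED needs >= 3 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ChromoglyphError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from None
            name = fields[3] if len(fields) > 3 else None
            value = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    value = float(fields[4])
                except ValueError:
                    raise ChromoglyphError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from None
            rows.append((fields[0], start, end, name, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "value"])
    if df["name"].isna().all():
        df = df.drop(columns=["name"])
    if "value" in df and df["value"].isna().all():
        df = df.drop(columns=["value"])
    return df


def read_gtf_features(path, feature_type: str = "gene") -> pd.DataFrame:
    """Read features of one type from a GTF/GFF file.

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open (``start-1``, ``end``).  ``gene_id`` (GFF2 quoted syntax) or
    ``gene_id=``/``ID=`` (GFF3) is extracted into ``name`` when present.
    """
    rows = []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ChromoglyphError(
                    f"{path}: line {lineno}: GTF needs 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] != feature_type:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise ChromoglyphError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from None
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            if not attrs:
                attrs = {k: v.strip() for k, v in _GFF3_ATTR.findall(fields[8])}
            name = attrs.get("gene_id") or attrs.get("ID")
            rows.append((fields[0], start1 - 1, end1, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if len(df) and df["name"].isna().all():
        df = df.drop(columns=["name"])
    return df


def _union_lengths(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    """Merge half-open intervals into a disjoint sorted union."""
    order = np.argsort(starts, kind="stable")
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def bin_features(
    table: pd.DataFrame,
    features: pd.DataFrame,
    mode: str = "count",
    column: str = "feature_count",
) -> pd.DataFrame:
    """Aggregate features into bins, returning the table plus one numeric column.

    Modes:

    ``count``
        number of features overlapping the bin (half-open intersection);
        a feature spanning k bins contributes to all k.
    ``count_midpoint``
        number of features whose midpoint ``floor((start+end)/2)`` lies in
        the bin; each feature counts at most once genome-wide
        (conservation: the column sums to the number of midpoints covered
        by the binning).
    ``coverage_fraction``
        feature-covered length within the bin ÷ bin width, with
        overlapping features unioned first, so the result is in [0, 1].
    ``mean_value``
        length-weighted mean of the feature ``value`` over the covered
        part of the bin; uncovered bins get NaN (counts/coverage get 0).

    Existing columns, row count and row order are never changed.
    Features on chromosomes absent from the structure are ignored (a
    summary is logged).
    """
    if mode not in BIN_MODES:
        raise ChromoglyphError(f"unknown mode {mode!r}; choose from {BIN_MODES}")
    if column in RESERVED_COLUMNS:
        raise ChromoglyphError(f"column name {column!r} is reserved")
    if column in table.columns:
        raise ChromoglyphError(f"column {column!r} already exists in the table")
    if mode == "mean_value" and "value" not in features.columns:
        raise ChromoglyphError("mode='mean_value' requires a 'value' column")

    chrom = np.asarray(table["chrom"], dtype=object)
    bs = np.asarray(table["start"], dtype=np.int64)
    be = np.asarray(table["end"], dtype=np.int64)
    out = np.zeros(len(table), dtype=float)
    if mode == "mean_value":
        out[:] = np.nan

    structure_chroms = set(pd.unique(chrom))
    ignored = int((~features["chrom"].isin(structure_chroms)).sum())
    if ignored:
        log.info("bin_features: ignored %d features on chromosomes absent "
                 "from the structure", ignored)

    for label, grp in features.groupby("chrom", sort=False):
        rows = np.nonzero(chrom == label)[0]
        if rows.size == 0:
            continue
        fs = np.asarray(grp["start"], dtype=np.int64)
        fe = np.asarray(grp["end"], dtype=np.int64)
        b0, b1 = bs[rows], be[rows]
        if mode == "count":
            hit = (b0[:, None] < fe[None, :]) & (fs[None, :] < b1[:, None])
            out[rows] = hit.sum(axis=1)
        elif mode == "count_midpoint":
            mid = (fs + fe) // 2
            hit = (b0[:, None] <= mid[None, :]) & (mid[None, :] < b1[:, None])
            out[rows] = hit.sum(axis=1)
        elif mode == "coverage_fraction":
            union = _union_lengths(fs, fe)
            us = np.array([s for s, _ in union], dtype=np.int64)
            ue = np.array([e for _, e in union], dtype=np.int64)
            ov = np.clip(
                np.minimum(b1[:, None], ue[None, :])
                - np.maximum(b0[:, None], us[None, :]),
                0, None,
            )
            out[rows] = ov.sum(axis=1) / (b1 - b0)
        else:  # mean_value: length-weighted over the covered part of the bin
            vals = np.asarray(grp["value"], dtype=float)
            ov = np.clip(
                np.minimum(b1[:, None], fe[None, :])
                - np.maximum(b0[:, None], fs[None, :]),
                0, None,
            ).astype(float)
            covered = ov.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = (ov * vals[None, :]).sum(axis=1) / covered
            out[rows] = np.where(covered > 0, mean, np.nan)

    result = table.copy()
    result[column] = out
    return result
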