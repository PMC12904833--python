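"""Readers and writers for 3D genome structure file dialects.

Supported dialects:

* ``.3dg`` — the tab-separated table of the single-cell Hi-C structure
  literature: ``chromosome  start  x  y  z``.  The position field is the
  *bin start*; ``end`` is synthesized from the modal consecutive start
  difference per chromosome.
* CSV/TSV with an explicit :class:`ColumnMapping` — the general escape
  hatch for foreign tabular dialects; unmapped columns are carried over
  as annotation columns.
* The reinterpreted-PDB chromatin dialect — beads as pseudo-atom ATOM
  records.  Genomic coordinates can span nine digits and do not fit the
  fixed-width resSeq field, so the writer stores the within-chromosome bin
  index there and the true genomic starts in a trailing REMARK table; the
  reader requires an explicit resolution.
* Arrow IPC / Feather — the lossless columnar form; the only dialect that
  round-trips annotation columns and types bit-exactly.

Every reader validates its output: an invalid bin table never escapes
this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.feather

from .core import (
    RESERVED_COLUMNS,
    ChromoglyphError,
    validate_structure,
)

#: Text float output precision (significant digits) for the .3dg writer.
FLOAT_SIG_DIGITS = 6

# chain-id alphabet for the PDB writer: first 36 chromosome labels
_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


class FormatError(ChromoglyphError):
    """A file does not conform to its dialect."""


def _check(table: pd.DataFrame, source: str) -> pd.DataFrame:
    report = validate_structure(table)
    if not report.is_valid:
        msgs = "; ".join(m for _, _, m in report.errors[:5])
        raise FormatError(f"{source}: produced an invalid structure: {msgs}")
    return table


def _mode_smallest(values: np.ndarray) -> int:
    uniq, counts = np.unique(values, return_counts=True)
    return int(uniq[np.argmax(counts)])


# ---------------------------------------------------------------------------
# .3dg dialect
# ---------------------------------------------------------------------------

def read_3dg(path, resolution: int | None = None) -> pd.DataFrame:
    """Read a ``.3dg`` structure file (chrom, start, x, y, z; tab/space separated).

    ``end`` is synthesized as ``start + r`` where ``r`` is the mode of the
    positive consecutive start differences within each chromosome (ties
    break to the smallest).  Chromosomes with a single bin inherit the
    modal difference pooled over all chromosomes, or ``resolution`` when
    given; if no chromosome has two bins and no ``resolution`` hint is
    provided, the file is rejected.  Lines starting with ``#`` are skipped.
    """
    chroms: list[str] = []
    starts: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected 5 fields, got {len(fields)}"
                )
            try:
                start = int(fields[1])
                point = (float(fields[2]), float(fields[3]), float(fields[4]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            chroms.append(fields[0])
            starts.append(start)
            xyz.append(point)
    if not chroms:
        raise FormatError(f"{path}: no data lines")

    chrom_arr = np.asarray(chroms, dtype=object)
    start_arr = np.asarray(starts, dtype=np.int64)
    per_chrom_diffs: dict[str, np.ndarray] = {}
    for label in pd.unique(chrom_arr):
        d = np.diff(start_arr[chrom_arr == label])
        per_chrom_diffs[label] = d[d > 0]
    pooled = np.concatenate(list(per_chrom_diffs.values())) if per_chrom_diffs else np.array([])
    if pooled.size == 0 and resolution is None:
        raise FormatError(
            f"{path}: cannot synthesize bin ends: every chromosome has fewer "
            "than 2 bins and no resolution hint was given"
        )
    fallback = int(resolution) if resolution is not None else _mode_smallest(pooled)
    end_arr = np.empty_like(start_arr)
    for label, diffs in per_chrom_diffs.items():
        r = _mode_smallest(diffs) if diffs.size else fallback
        sel = chrom_arr == label
        end_arr[sel] = start_arr[sel] + r

    coords = np.asarray(xyz, dtype=float)
    table = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "start": start_arr,
            "end": end_arr,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )
    return _check(table, str(path))


def write_3dg(table: pd.DataFrame, path) -> None:
    """Write the ``.3dg`` dialect: chrom, start, x, y, z, tab-separated.

    The format carries no ``end`` and no annotation columns; floats are
    written with 6 significant digits.
    """
    fmt = f"%.{FLOAT_SIG_DIGITS}g"
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{fmt % row.x}\t{fmt % row.y}\t{fmt % row.z}\n"
            )


# ---------------------------------------------------------------------------
# CSV/TSV with column mapping
# ---------------------------------------------------------------------------

@dataclass
class ColumnMapping:
    """Maps foreign column names onto the bin-table schema.

    Exactly one of ``end_col`` / ``resolution`` must be given; with
    ``resolution``, ``end`` is synthesized as ``start + resolution``.
    """

    chrom_col: str
    start_col: str
    x_col: str
    y_col: str
    z_col: str
    end_col: str | None = None
    resolution: int | None = None

    def __post_init__(self) -> None:
        if (self.end_col is None) == (self.resolution is None):
            raise FormatError(
                "exactly one of end_col / resolution must be provided"
            )


def read_table_structure(
    path, mapping: ColumnMapping, dialect: str = "csv"
) -> pd.DataFrame:
    """Read a delimited table using an explicit column mapping.

    Unmapped input columns are carried over as annotation columns under
    their original names; a carried-over column whose name collides with
    a reserved bin-table column is an error.
    """
    if dialect not in ("csv", "tsv"):
        raise FormatError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = pd.read_csv(path, sep="," if dialect == "csv" else "\t")
    rename = {
        mapping.chrom_col: "chrom",
        mapping.start_col: "start",
        mapping.x_col: "x",
        mapping.y_col: "y",
        mapping.z_col: "z",
    }
    if mapping.end_col is not None:
        rename[mapping.end_col] = "end"
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: mapped column(s) not found: {', '.join(missing)}")
    carried = [c for c in df.columns if c not in rename]
    clash = [c for c in carried if c in RESERVED_COLUMNS]
    if clash:
        raise FormatError(
            f"{path}: unmapped column(s) {', '.join(clash)} collide with "
            "reserved names; map or drop them"
        )
    out = df.rename(columns=rename)
    if mapping.resolution is not None:
        out["end"] = out["start"] + int(mapping.resolution)
    out = out[["chrom", "start", "end", "x", "y", "z", *carried]]
    out["chrom"] = out["chrom"].astype(object).astype(str)
    return _check(out.reset_index(drop=True), str(path))


def write_table_structure(table: pd.DataFrame, path, dialect: str = "csv") -> None:
    """Write a bin table as plain CSV/TSV with canonical column names."""
    table.to_csv(path, sep="," if dialect == "csv" else "\t", index=False)


# ---------------------------------------------------------------------------
# reinterpreted-PDB chromatin dialect
# ---------------------------------------------------------------------------

def read_pdb_dialect(path, resolution: int) -> pd.DataFrame:
    """Read a chromatin-bead PDB dialect: one ATOM/HETATM record per bin.

    Chain id becomes ``chrom`` (single characters are prefixed ``chr``);
    residue number *r* becomes the interval ``[(r-1)*resolution,
    r*resolution)``.  Fixed PDB 3.3 columns are tried first; lines whose
    fixed-column fields do not parse (e.g. overflowed residue numbers)
    fall back to whitespace tokenization.  REMARK/TER/HEADER etc. are
    ignored; REMARK sidecars of foreign files are deliberately not
    interpreted.
    """
    if resolution < 1:
        raise FormatError(f"resolution must be >= 1 bp, got {resolution}")
    rows: list[tuple[str, int, float, float, float]] = []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.startswith(("ATOM", "HETATM")):
                continue
            line = raw.rstrip("\n")
            parsed = None
            try:  # PDB 3.3 fixed columns; [22:27] tolerates resSeq overflow into iCode
                chain = line[21].strip()
                resseq = int(line[22:27].strip())
                point = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                parsed = (chain, resseq, *point)
            except (ValueError, IndexError):
                fields = line.split()
                # ATOM serial name resName chain resSeq x y z ...
                if len(fields) >= 9:
                    try:
                        parsed = (
                            fields[4],
                            int(fields[5]),
                            float(fields[6]),
                            float(fields[7]),
                            float(fields[8]),
                        )
                    except ValueError:
                        parsed = None
            if parsed is None:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse ATOM record "
                    "(fixed columns and whitespace fallback both failed)"
                )
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    chroms = [f"chr{c}" if len(c) == 1 else c for c, *_ in rows]
    resseq = np.array([r for _, r, *_ in rows], dtype=np.int64)
    coords = np.array([[x, y, z] for _, _, x, y, z in rows], dtype=float)
    table = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "start": (resseq - 1) * int(resolution),
            "end": resseq * int(resolution),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )
    return _check(table, str(path))


def write_pdb_dialect(table: pd.DataFrame, path, strict: bool = False) -> None:
    """Write the chromatin-bead PDB dialect without abusing fixed fields.

    One ``ATOM`` pseudo-atom (CA) per bin.  resSeq holds the 1-based
    within-chromosome bin *index* — genomic starts can span nine digits
    and cannot fit the four-column field — and the true genomic intervals
    are written losslessly in a trailing ``REMARK 350`` table
    (``REMARK 350 BIN <serial> <chrom> <start> <end>``).  With
    ``strict=True``, conditions the fixed-width fields cannot represent
    (>= 37 chromosome labels, > 9999 bins in one chromosome, > 99999
    atoms) raise; otherwise they wrap with a warning.
    """
    labels = list(pd.unique(np.asarray(table["chrom"], dtype=object)))
    if len(labels) > len(_CHAIN_ALPHABET):
        msg = (
            f"{len(labels)} chromosome labels exceed the {len(_CHAIN_ALPHABET)} "
            f"available chain ids; first unrepresentable label: "
            f"{labels[len(_CHAIN_ALPHABET)]!r}"
        )
        if strict:
            raise FormatError(msg)
        warnings.warn(msg + " (chain ids will repeat)", stacklevel=2)
    chain_of = {lab: _CHAIN_ALPHABET[i % len(_CHAIN_ALPHABET)] for i, lab in enumerate(labels)}

    index_within: dict[str, int] = {}
    lines = []
    remarks = []
    for serial, row in enumerate(table.itertuples(index=False), start=1):
        idx = index_within.get(row.chrom, 0) + 1
        index_within[row.chrom] = idx
        if idx > 9999:
            msg = f"chromosome {row.chrom!r} has more than 9999 bins; resSeq overflows"
            if strict:
                raise FormatError(msg)
            if idx == 10000:
                warnings.warn(msg + " (wrapping modulo 10000)", stacklevel=2)
        if serial > 99999 and strict:
            raise FormatError("more than 99999 atoms; serial field overflows")
        lines.append(
            "ATOM  %5d  CA  BIN %s%4d    %8.3f%8.3f%8.3f  1.00  0.00"
            % (
                serial % 100000,
                chain_of[row.chrom],
                idx % 10000,
                row.x,
                row.y,
                row.z,
            )
        )
        remarks.append(
            f"REMARK 350 BIN {serial} {row.chrom} {int(row.start)} {int(row.end)}"
        )
    with open(path, "w") as fh:
        fh.write("HEADER    3D GENOME STRUCTURE (CHROMATIN BEAD MODEL)\n")
        for line in lines:
            fh.write(line + "\n")
        fh.write("TER\n")
        fh.write("REMARK 350 GENOMIC COORDINATES OF BINS: SERIAL CHROM START END\n")
        for line in remarks:
            fh.write(line + "\n")
        fh.write("END\n")


def read_pdb_remarks(path) -> pd.DataFrame:
    """Read back the ``REMARK 350 BIN`` sidecar written by :func:`write_pdb_dialect`.

    Returns a DataFrame (serial, chrom, start, end).  Only meaningful for
    files produced by this package; foreign REMARK dialects are not parsed.
    """
    rows = []
    with open(path, "r", newline=None) as fh:
        for raw in fh:
            if raw.startswith("REMARK 350 BIN "):
                _, _, _, serial, chrom, start, end = raw.split()
                rows.append((int(serial), chrom, int(start), int(end)))
    return pd.DataFrame(rows, columns=["serial", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Arrow IPC / Feather columnar form
# ---------------------------------------------------------------------------

def write_columnar(table: pd.DataFrame, path) -> None:
    """Write the lossless Arrow IPC (Feather) form, all columns preserved."""
    pa.feather.write_feather(
        pa.Table.from_pandas(table, preserve_index=False), str(path)
    )


def read_columnar(path) -> pd.DataFrame:
    """Read the Arrow IPC (Feather) form; requires the reserved columns."""
    df = pa.feather.read_table(str(path)).to_pandas()
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: columnar file lacks required column(s): {', '.join(missing)}"
        )
    df["chrom"] = df["chrom"].astype(object)
    return _check(df, str(path))
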