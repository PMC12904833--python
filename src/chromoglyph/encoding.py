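"""Declarative view-config grammar and its resolution to per-bin attributes.

A *view config* is a JSON-like dict mapping data columns to visual
channels, in the grammar-of-graphics style::

    {
      "mark": "sphere",                          # or "box"
      "color": {"field": "chrom", "scale_type": "categorical"},
      "scale": {"field": "gene_density",
                "scale_type": "continuous", "range": [0.25, 1.5]},
      "base_size": "auto",                       # or a float, model units
      "links": false                             # connect consecutive bins
    }

Channels are either a ``constant`` (a color string or a number) or a
``field`` mapping with an optional ``scale_type`` (``continuous`` /
``categorical``), ``domain`` and ``range``.  :func:`resolve_view_config`
turns a (bin table, config) pair into an :class:`AttributeTable` of
concrete per-bin RGBA colors, sizes and marks; resolution is
deterministic, and data-driven domains are recomputed per structure
unless pinned with an explicit ``domain``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from matplotlib import colormaps as _mpl_colormaps
from matplotlib.colors import to_rgba as _mpl_to_rgba

from .core import ChromoglyphError, ValidationReport, coordinates

MARKS = ("sphere", "box")

#: Default numeric range of the scale channel (size multipliers).
DEFAULT_SCALE_RANGE = (0.25, 1.5)
DEFAULT_COLOR = "#808080"
DEFAULT_COLORMAP = "viridis"

#: Fixed qualitative palette (ColorBrewer "Paired", 12 colors).
CATEGORICAL_PALETTE = (
    "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c",
    "#fb9a99", "#e31a1c", "#fdbf6f", "#ff7f00",
    "#cab2d6", "#6a3d9a", "#ffff99", "#b15928",
)

_CONFIG_KEYS = ("mark", "color", "scale", "base_size", "links")
_CHANNEL_KEYS = ("constant", "field", "scale_type", "domain", "range")


class EncodingError(ChromoglyphError):
    pass


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(values, dtype=float) + 0.5)


def parse_color(spec) -> np.ndarray:
    """Parse ``#RRGGBB`` / ``#RRGGBBAA`` / named colors into uint8 RGBA."""
    try:
        rgba = _mpl_to_rgba(spec)
    except (ValueError, TypeError) as exc:
        raise EncodingError(f"cannot parse color {spec!r}: {exc}") from None
    return _round_half_up(np.asarray(rgba) * 255.0).astype(np.uint8)


def _colormap_anchors(name: str) -> np.ndarray:
    """Anchor list (k×3, 0–255 floats) of a built-in continuous colormap."""
    if name == "bluered":
        return np.array([[0.0, 0.0, 255.0], [255.0, 0.0, 0.0]])
    if name == "viridis":
        # the standard published 256-entry lookup table
        table = np.asarray(_mpl_colormaps["viridis"].colors, dtype=float)
        return table * 255.0
    raise EncodingError(
        f"unknown colormap {name!r}; built-ins: 'viridis', 'bluered'"
    )


def continuous_colormap(name: str, t) -> np.ndarray:
    """Piecewise-linear colormap lookup; ``t`` in [0, 1], scalar or vector.

    Returns uint8 RGBA (alpha 255); components round half-up.
    """
    anchors = _colormap_anchors(name)
    t_arr = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), 0.0, 1.0)
    pos = t_arr * (len(anchors) - 1)
    lo = np.clip(np.floor(pos).astype(int), 0, len(anchors) - 2)
    frac = (pos - lo)[:, None]
    rgb = anchors[lo] * (1.0 - frac) + anchors[lo + 1] * frac
    rgba = np.concatenate(
        [_round_half_up(rgb), np.full((len(t_arr), 1), 255.0)], axis=1
    ).astype(np.uint8)
    return rgba[0] if np.isscalar(t) or np.ndim(t) == 0 else rgba


def categorical_palette(categories) -> dict:
    """Assign palette colors to categories in the given order, cycling past 12."""
    categories = list(categories)
    if not categories:
        raise EncodingError("need at least one category")
    if len(categories) > len(CATEGORICAL_PALETTE):
        warnings.warn(
            f"{len(categories)} categories exceed the {len(CATEGORICAL_PALETTE)}-"
            "color qualitative palette; colors will repeat", stacklevel=2,
        )
    return {
        cat: parse_color(CATEGORICAL_PALETTE[i % len(CATEGORICAL_PALETTE)])
        for i, cat in enumerate(categories)
    }


def normalize_values(values, domain=None) -> np.ndarray:
    """Affine-normalize to [0, 1] with clipping; degenerate domain maps to 0.5."""
    v = np.asarray(values, dtype=float)
    if domain is None:
        lo, hi = float(np.nanmin(v)), float(np.nanmax(v))
    else:
        lo, hi = float(domain[0]), float(domain[1])
    if hi == lo:
        return np.full(v.shape, 0.5)
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

def _validate_channel(name: str, spec, report: ValidationReport) -> None:
    if not isinstance(spec, dict):
        # a bare constant (color string / number) is shorthand for {"constant": ...}
        return
    unknown = [k for k in spec if k not in _CHANNEL_KEYS]
    if unknown:
        report.error("unknown-key", None,
                     f"{name}: unknown channel key(s) {unknown}; "
                     f"allowed: {list(_CHANNEL_KEYS)}")
    has_const, has_field = "constant" in spec, "field" in spec
    if has_const == has_field:
        report.error("channel-form", None,
                     f"{name}: exactly one of 'constant' / 'field' is required")
    st = spec.get("scale_type", "continuous")
    if st not in ("continuous", "categorical"):
        report.error("scale-type", None,
                     f"{name}: scale_type must be 'continuous' or "
                     f"'categorical', got {st!r}")
    if name == "color" and has_field and st == "continuous":
        rng = spec.get("range")
        if isinstance(rng, str):
            try:
                _colormap_anchors(rng)
            except EncodingError as exc:
                report.error("colormap", None, f"{name}: {exc}")


def validate_view_config(config) -> ValidationReport:
    """Validate a view-config document structurally (fields checked at resolve).

    The grammar is fail-fast: unknown keys are errors, not ignored.
    """
    report = ValidationReport()
    if not isinstance(config, dict):
        report.error("config-type", None, "view config must be a JSON object")
        return report
    unknown = [k for k in config if k not in _CONFIG_KEYS]
    if unknown:
        report.error("unknown-key", None,
                     f"unknown config key(s) {unknown}; allowed: {list(_CONFIG_KEYS)}")
    mark = config.get("mark", "sphere")
    if mark not in MARKS:
        report.error("mark", None, f"unknown mark {mark!r}; allowed: {list(MARKS)}")
    for channel in ("color", "scale"):
        if channel in config:
            _validate_channel(channel, config[channel], report)
    base_size = config.get("base_size", "auto")
    if base_size != "auto" and not (
        isinstance(base_size, (int, float)) and base_size > 0
    ):
        report.error("base-size", None,
                     f"base_size must be a positive number or 'auto', got {base_size!r}")
    if not isinstance(config.get("links", False), bool):
        report.error("links", None, "links must be a boolean")
    return report


# ---------------------------------------------------------------------------
# resolution
# ---------------------------------------------------------------------------

@dataclass
class AttributeTable:
    """Resolved per-bin visual attributes, row-aligned with the bin table."""

    rgba: np.ndarray   # (N, 4) uint8
    size: np.ndarray   # (N,) float, model units, all > 0
    mark: np.ndarray   # (N,) str, one of MARKS

    def __len__(self) -> int:
        return len(self.size)


@dataclass
class Scene:
    """Ordered list of (bin table, view config) pairs."""

    entries: list = dc_field(default_factory=list)

    def add(self, table: pd.DataFrame, config: dict | None = None) -> "Scene":
        self.entries.append((table, {} if config is None else config))
        return self

    def __len__(self) -> int:
        return len(self.entries)


def _field_column(table: pd.DataFrame, spec: dict, channel: str) -> pd.Series:
    name = spec["field"]
    if name not in table.columns:
        raise EncodingError(
            f"{channel}: field {name!r} not in table; available columns: "
            f"{list(table.columns)}"
        )
    return table[name]


def _first_appearance(values: pd.Series) -> list:
    return list(pd.unique(np.asarray(values, dtype=object)))


def _normalize_field(col: pd.Series, spec: dict, channel: str) -> np.ndarray:
    if not np.issubdtype(np.asarray(col).dtype, np.number):
        raise EncodingError(
            f"{channel}: continuous mapping requires a numeric column, "
            f"but {spec['field']!r} is categorical"
        )
    domain = spec.get("domain")
    v = np.asarray(col, dtype=float)
    lo, hi = (float(np.nanmin(v)), float(np.nanmax(v))) if domain is None else domain
    if lo == hi:
        warnings.warn(
            f"{channel}: zero-spread domain [{lo}, {hi}]; all values map to 0.5",
            stacklevel=3,
        )
    return normalize_values(v, domain)


def _resolve_color(table: pd.DataFrame, spec, n: int) -> np.ndarray:
    if not isinstance(spec, dict):
        return np.tile(parse_color(spec), (n, 1))
    if "constant" in spec:
        return np.tile(parse_color(spec["constant"]), (n, 1))
    col = _field_column(table, spec, "color")
    if spec.get("scale_type", "continuous") == "continuous":
        t = _normalize_field(col, spec, "color")
        rng = spec.get("range", DEFAULT_COLORMAP)
        if isinstance(rng, str):
            return continuous_colormap(rng, t)
        # explicit color list: interpolate through the given anchors
        anchors = np.array([parse_color(c)[:3] for c in rng], dtype=float)
        pos = np.clip(t, 0, 1) * (len(anchors) - 1)
        lo = np.clip(np.floor(pos).astype(int), 0, len(anchors) - 2)
        frac = (pos - lo)[:, None]
        rgb = anchors[lo] * (1 - frac) + anchors[lo + 1] * frac
        return np.concatenate(
            [_round_half_up(rgb), np.full((n, 1), 255.0)], axis=1
        ).astype(np.uint8)
    # categorical
    observed = _first_appearance(col)
    cats = list(spec["domain"]) if spec.get("domain") else observed
    cats += [c for c in observed if c not in cats]
    if spec.get("range"):
        colors = [parse_color(c) for c in spec["range"]]
        mapping = {cat: colors[i % len(colors)] for i, cat in enumerate(cats)}
    else:
        mapping = categorical_palette(cats)
    return np.array([mapping[v] for v in np.asarray(col, dtype=object)], dtype=np.uint8)


def _resolve_scale(table: pd.DataFrame, spec, n: int) -> np.ndarray:
    if not isinstance(spec, dict):
        spec = {"constant": spec}
    if "constant" in spec:
        mult = float(spec["constant"])
        if not mult > 0:
            raise EncodingError(f"scale constant must be > 0, got {mult}")
        return np.full(n, mult)
    lo, hi = spec.get("range", DEFAULT_SCALE_RANGE)
    if not (lo > 0 and hi > 0):
        raise EncodingError(f"scale range must be positive, got [{lo}, {hi}]")
    col = _field_column(table, spec, "scale")
    if spec.get("scale_type", "continuous") == "continuous":
        t = _normalize_field(col, spec, "scale")
        return lo + t * (hi - lo)
    cats = _first_appearance(col)
    levels = (
        np.linspace(lo, hi, len(cats)) if len(cats) > 1 else np.array([(lo + hi) / 2])
    )
    mapping = {cat: levels[i] for i, cat in enumerate(cats)}
    return np.array([mapping[v] for v in np.asarray(col, dtype=object)])


def auto_base_size(table: pd.DataFrame) -> float:
    """Half the median distance between consecutive same-chromosome bins.

    Falls back to 1.0 when no chromosome has two consecutive bins.
    """
    pts = coordinates(table)
    chrom = np.asarray(table["chrom"], dtype=object)
    gaps = []
    for label in pd.unique(chrom):
        p = pts[chrom == label]
        if len(p) > 1:
            gaps.append(np.linalg.norm(np.diff(p, axis=0), axis=1))
    if not gaps:
        return 1.0
    return 0.5 * float(np.median(np.concatenate(gaps)))


def resolve_view_config(table: pd.DataFrame, config: dict | None = None) -> AttributeTable:
    """Resolve a view config against a structure into concrete attributes.

    Deterministic given (table, config).  Continuous domains default to
    the structure's own data min/max — pin ``domain`` explicitly for
    cross-structure comparability.  Categorical colors are assigned by
    first appearance in row order.
    """
    config = {} if config is None else config
    report = validate_view_config(config)
    report.raise_if_invalid()
    n = len(table)
    rgba = _resolve_color(table, config.get("color", DEFAULT_COLOR), n)
    mult = _resolve_scale(table, config.get("scale", 1.0), n)
    base = config.get("base_size", "auto")
    base = auto_base_size(table) if base == "auto" else float(base)
    size = base * mult
    if n and not (size > 0).all():
        raise EncodingError("resolved sizes must all be > 0")
    mark = np.full(n, config.get("mark", "sphere"), dtype=object)
    return AttributeTable(rgba=rgba.astype(np.uint8), size=size, mark=mark)
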