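"""Triangle-mesh materialization of scenes and static raster snapshots.

Each bin becomes a mark-shaped sub-mesh — an icosphere (2 subdivisions:
162 vertices, 320 faces) or an axis-aligned cube (8 vertices, 12 faces) —
centered on the bin's coordinates, scaled by its resolved size (the size
is the sphere radius / cube half-edge), and uniformly colored with the
bin's RGBA.  ``links: true`` adds thin 8-sided open prisms between
consecutive bins of the same chromosome.  Meshes are written as PLY
(ascii or binary little-endian, per-vertex uchar RGBA — the most portable
colored-mesh dialect) or OBJ (positions/faces only; OBJ cannot carry
per-vertex colors).

The static renderer is a smoke-test/documentation device: orthographic
projection with painter's-algorithm ordering, flat discs and quads, no
lighting.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from PIL import Image

from .core import ChromoglyphError, coordinates
from .encoding import Scene, resolve_view_config

#: Icosphere subdivision level for the sphere mark (162 vertices, 320 faces).
ICOSPHERE_SUBDIVISIONS = 2

#: Link prisms: number of sides, and radius as a fraction of the mean bin size.
LINK_SIDES = 8
LINK_RADIUS_FRACTION = 0.15

BACKGROUND_RGB = (255, 255, 255)


class MeshError(ChromoglyphError):
    pass


@dataclass
class Mesh:
    """Indexed triangle mesh with per-vertex RGBA colors."""

    vertices: np.ndarray       # (N, 3) float
    faces: np.ndarray          # (M, 3) int
    vertex_colors: np.ndarray  # (N, 4) uint8

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.uint8).reshape(-1, 4)
        n = len(self.vertices)
        if len(self.vertex_colors) != n:
            raise MeshError("vertex_colors length must match vertices")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise MeshError("face index out of range")
            a, b, c = self.faces.T
            if ((a == b) | (b == c) | (a == c)).any():
                raise MeshError("degenerate face (repeated vertex index)")

    @classmethod
    def empty(cls) -> "Mesh":
        return cls(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64),
                   np.empty((0, 4), dtype=np.uint8))

    @classmethod
    def concatenate(cls, meshes) -> "Mesh":
        meshes = list(meshes)
        if not meshes:
            return cls.empty()
        verts, faces, colors, offset = [], [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + offset)
            colors.append(m.vertex_colors)
            offset += len(m.vertices)
        return cls(np.concatenate(verts), np.concatenate(faces),
                   np.concatenate(colors))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _unit_icosphere(subdivisions: int = ICOSPHERE_SUBDIVISIONS):
    """Unit-radius icosphere: vertices (V, 3), faces (F, 3).

    Subdividing the icosahedron k times gives 20·4^k faces and
    10·4^k + 2 vertices (k=2: 320 faces, 162 vertices).
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [np.asarray(v, dtype=float) / np.linalg.norm(v) for v in verts]
    for _ in range(subdivisions):
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                midpoint[key] = len(verts) - 1
            return midpoint[key]

        faces = [
            tri
            for a, b, c in faces
            for tri in (
                (a, mid(a, b), mid(a, c)),
                (b, mid(b, c), mid(a, b)),
                (c, mid(a, c), mid(b, c)),
                (mid(a, b), mid(b, c), mid(a, c)),
            )
        ]
    return np.asarray(verts), np.asarray(faces, dtype=np.int64)


_CUBE_VERTS = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=float,
)
_CUBE_FACES = np.array(
    [
        (0, 1, 3), (0, 3, 2),  # -x
        (4, 6, 7), (4, 7, 5),  # +x
        (0, 4, 5), (0, 5, 1),  # -y
        (2, 3, 7), (2, 7, 6),  # +y
        (0, 2, 6), (0, 6, 4),  # -z
        (1, 5, 7), (1, 7, 3),  # +z
    ],
    dtype=np.int64,
)

#: Exact per-mark vertex/face counts (linear in bin count by construction).
MARK_GEOMETRY = {
    "sphere": (10 * 4**ICOSPHERE_SUBDIVISIONS + 2, 20 * 4**ICOSPHERE_SUBDIVISIONS),
    "box": (8, 12),
}


def _mark_mesh(mark: str, center: np.ndarray, size: float, rgba: np.ndarray) -> Mesh:
    if mark == "sphere":
        v, f = _unit_icosphere()
    elif mark == "box":
        v, f = _CUBE_VERTS, _CUBE_FACES
    else:
        raise MeshError(f"unknown mark {mark!r}")
    verts = v * float(size) + np.asarray(center, dtype=float)
    colors = np.tile(np.asarray(rgba, dtype=np.uint8), (len(verts), 1))
    return Mesh(verts, f.copy(), colors)


def _link_mesh(p0, p1, radius: float, rgba) -> Mesh:
    """Open 8-sided prism from p0 to p1 (2·LINK_SIDES vertices, 2·LINK_SIDES faces)."""
    p0, p1 = np.asarray(p0, dtype=float), np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length == 0:
        return Mesh.empty()
    w = axis / length
    up = np.array([0.0, 0.0, 1.0]) if abs(w[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(up, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    ang = 2 * np.pi * np.arange(LINK_SIDES) / LINK_SIDES
    ring = radius * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
    verts = np.concatenate([p0 + ring, p1 + ring])
    k = LINK_SIDES
    faces = []
    for i in range(k):
        j = (i + 1) % k
        faces.append((i, j, k + i))
        faces.append((j, k + j, k + i))
    colors = np.tile(np.asarray(rgba, dtype=np.uint8), (2 * k, 1))
    return Mesh(verts, np.asarray(faces, dtype=np.int64), colors)


# ---------------------------------------------------------------------------
# scene -> mesh
# ---------------------------------------------------------------------------

def build_meshes(scene: Scene) -> Mesh:
    """Materialize a scene into one concatenated triangle mesh.

    Per-structure sub-meshes are emitted in scene order with faces
    reindexed; a resolution failure names the offending entry.
    """
    parts = []
    for entry_index, (table, config) in enumerate(scene.entries):
        try:
            attrs = resolve_view_config(table, config)
        except ChromoglyphError as exc:
            raise MeshError(f"scene entry {entry_index}: {exc}") from exc
        pts = coordinates(table)
        for i in range(len(table)):
            parts.append(_mark_mesh(attrs.mark[i], pts[i], attrs.size[i], attrs.rgba[i]))
        if config.get("links", False):
            chrom = np.asarray(table["chrom"], dtype=object)
            for i in range(len(table) - 1):
                if chrom[i] != chrom[i + 1]:
                    continue
                radius = LINK_RADIUS_FRACTION * 0.5 * (attrs.size[i] + attrs.size[i + 1])
                parts.append(_link_mesh(pts[i], pts[i + 1], radius, attrs.rgba[i]))
    return Mesh.concatenate(parts)


# ---------------------------------------------------------------------------
# PLY / OBJ writers
# ---------------------------------------------------------------------------

def write_ply(mesh: Mesh, path, binary: bool = False) -> None:
    """Write PLY with per-vertex uchar RGBA (ascii or binary little-endian)."""
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        "comment written by chromoglyph\n"
        f"element vertex {len(mesh.vertices)}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "property uchar alpha\n"
        f"element face {len(mesh.faces)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            for pos, col in zip(mesh.vertices, mesh.vertex_colors):
                fh.write(struct.pack("<fff4B", *pos, *col))
            for face in mesh.faces:
                fh.write(struct.pack("<B3i", 3, *face))
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for pos, col in zip(mesh.vertices, mesh.vertex_colors):
                fh.write("%.6g %.6g %.6g %d %d %d %d\n" % (*pos, *col))
            for face in mesh.faces:
                fh.write("3 %d %d %d\n" % tuple(face))


def write_obj(mesh: Mesh, path) -> None:
    """Write OBJ (positions and faces only; OBJ drops per-vertex colors)."""
    warnings.warn(
        "OBJ cannot represent per-vertex colors; they are dropped "
        "(use write_ply to keep them)", stacklevel=2,
    )
    with open(path, "w") as fh:
        fh.write("# written by chromoglyph\n")
        fh.write("# note: per-vertex colors are not representable in OBJ "
                 "and were dropped\n")
        for pos in mesh.vertices:
            fh.write("v %.6g %.6g %.6g\n" % tuple(pos))
        for face in mesh.faces:
            fh.write("f %d %d %d\n" % tuple(face + 1))


# ---------------------------------------------------------------------------
# static raster snapshot
# ---------------------------------------------------------------------------

def _view_basis(view_direction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = np.asarray(view_direction, dtype=float)
    norm = np.linalg.norm(w)
    if not norm > 0:
        raise MeshError("view direction must be nonzero")
    w = w / norm
    up = np.array([0.0, 0.0, 1.0]) if abs(w[2]) < 0.999 else np.array([0.0, 1.0, 0.0])
    u = np.cross(up, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def render_static(scene: Scene, view_direction=(1.0, 1.0, 1.0),
                  image_size: int = 400, output=None) -> np.ndarray:
    """Render an orthographic snapshot of a scene; returns the RGB array.

    ``view_direction`` points from the viewer into the scene; marks with a
    smaller projection along it are nearer.  Marks are drawn far-to-near
    (painter's algorithm) as flat discs (sphere) or axis-aligned squares
    (box).  Deterministic for fixed inputs; ``output`` (when given)
    receives a PNG.
    """
    u, v, w = _view_basis(view_direction)
    img = np.full((image_size, image_size, 3), BACKGROUND_RGB, dtype=np.uint8)

    centers, sizes, colors, marks = [], [], [], []
    for table, config in scene.entries:
        attrs = resolve_view_config(table, config)
        pts = coordinates(table)
        centers.append(pts)
        sizes.append(attrs.size)
        colors.append(attrs.rgba)
        marks.append(attrs.mark)
    if centers:
        centers = np.concatenate(centers)
        sizes = np.concatenate(sizes)
        colors = np.concatenate(colors)
        marks = np.concatenate(marks)

        sx, sy, depth = centers @ u, centers @ v, centers @ w
        lo = min(float((sx - sizes).min()), float((sy - sizes).min()))
        hi = max(float((sx + sizes).max()), float((sy + sizes).max()))
        span = hi - lo or 1.0
        margin = 0.05 * span
        scale = image_size / (span + 2 * margin)

        px = (sx - lo + margin) * scale
        py = image_size - (sy - lo + margin) * scale  # raster y grows downward
        pr = np.maximum(sizes * scale, 1.0)

        yy, xx = np.mgrid[0:image_size, 0:image_size]
        for i in np.argsort(-depth, kind="stable"):  # far first
            if marks[i] == "box":
                inside = (np.abs(xx - px[i]) <= pr[i]) & (np.abs(yy - py[i]) <= pr[i])
            else:
                inside = (xx - px[i]) ** 2 + (yy - py[i]) ** 2 <= pr[i] ** 2
            img[inside] = colors[i, :3]

    if output is not None:
        Image.fromarray(img).save(output, format="PNG")
    return img
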