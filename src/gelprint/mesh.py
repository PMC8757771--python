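"""2-D cross-section meshes of a wood-pile scaffold unit cell.

A wood-pile lattice alternates layers of parallel strands at 0°/90°.  The
collapse analysis works on a plane-strain cross-section cut perpendicular
to the 0° strands: layers printed along the cut appear as full-width bars,
layers printed across it as rectangular strand cross-sections separated by
the inter-fiber distance.  Lateral symmetry lets a single unit cell (one
inter-fiber period wide, with half-strands on each side) represent the
infinite lattice.

Meshes are structured triangulations on a rectilinear grid whose lines are
snapped to the material boundaries, so every element lies wholly inside
one subdomain: gel, support (when the voids are filled by a sacrificial
bath), or void (dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GEL",
    "SUPPORT",
    "ScaffoldUnitCell",
    "Mesh2D",
    "build_unit_cell_mesh",
    "rectangle_mesh",
]

GEL = 0
SUPPORT = 1

# default structured-grid element sizes (m), chosen to land the element
# count in the few-hundred range typical of physics-controlled triangular
# meshes of this cell (finer without the bath, coarser with it)
DEFAULT_SIZE_GEL_ONLY = 1.35e-4
DEFAULT_SIZE_WITH_SUPPORT = 1.8e-4

_TOL = 1e-12


@dataclass(frozen=True)
class ScaffoldUnitCell:
    """Slicing-derived unit cell of a wood-pile scaffold.

    strand_width:          extruded strand width, m (the nozzle size under
                           the volumetric slicing convention)
    layer_height:          vertical pitch between layers, m; layers overlap
                           (layer_height <= strand_width) so the strand
                           cross-section is layer_height tall
    inter_fiber_distance:  centre-to-centre spacing of parallel strands, m
    n_layers:              number of deposited layers
    out_of_plane_thickness: thickness assigned to the plane-strain model, m
    """

    strand_width: float
    layer_height: float
    inter_fiber_distance: float
    n_layers: int = 6
    out_of_plane_thickness: float = 1.0e-3

    def __post_init__(self) -> None:
        for name in ("strand_width", "layer_height", "inter_fiber_distance",
                     "out_of_plane_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be at least 1")
        if self.layer_height > self.strand_width:
            raise ValueError("layer_height must not exceed strand_width (layers overlap)")

    @property
    def height(self) -> float:
        return self.n_layers * self.layer_height

    @property
    def width(self) -> float:
        return self.inter_fiber_distance


@dataclass
class Mesh2D:
    """Conforming triangle mesh with per-element subdomain labels."""

    points: np.ndarray  # (n_nodes, 2)
    triangles: np.ndarray  # (n_elements, 3), CCW
    labels: np.ndarray  # (n_elements,), GEL or SUPPORT
    thickness: float = 1.0e-3

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.triangles.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per element required")
        if np.any(self.element_areas() <= 0):
            raise ValueError("mesh contains inverted or degenerate elements")

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    # -- boundary node sets (geometric tags) --------------------------------
    def _extent(self) -> tuple[float, float, float, float]:
        x, y = self.points[:, 0], self.points[:, 1]
        return x.min(), x.max(), y.min(), y.max()

    def _tol(self) -> float:
        xmin, xmax, ymin, ymax = self._extent()
        return 1e-9 * max(xmax - xmin, ymax - ymin, 1e-12)

    def bottom_nodes(self) -> np.ndarray:
        _, _, ymin, _ = self._extent()
        return np.nonzero(self.points[:, 1] <= ymin + self._tol())[0]

    def left_nodes(self) -> np.ndarray:
        xmin, _, _, _ = self._extent()
        return np.nonzero(self.points[:, 0] <= xmin + self._tol())[0]

    def right_nodes(self) -> np.ndarray:
        _, xmax, _, _ = self._extent()
        return np.nonzero(self.points[:, 0] >= xmax - self._tol())[0]

    def top_nodes(self) -> np.ndarray:
        _, _, _, ymax = self._extent()
        return np.nonzero(self.points[:, 1] >= ymax - self._tol())[0]

    def boundary_edges(self) -> np.ndarray:
        """Edges that belong to exactly one triangle, as (n, 2) node pairs."""
        edges = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        key = np.sort(edges, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return key[idx[counts == 1]]

    def write_gmsh(self, path: str | Path) -> None:
        """Export as Gmsh 2.2 ASCII (readable by most mesh viewers)."""
        lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(self.n_nodes)]
        for i, (x, y) in enumerate(self.points, start=1):
            lines.append(f"{i} {x:.12g} {y:.12g} 0")
        lines += ["$EndNodes", "$Elements", str(self.n_elements)]
        for i, (tri, lab) in enumerate(zip(self.triangles, self.labels), start=1):
            a, b, c = (int(v) + 1 for v in tri)
            lines.append(f"{i} 2 2 {int(lab)} {int(lab)} {a} {b} {c}")
        lines.append("$EndElements")
        Path(path).write_text("\n".join(lines) + "\n")


def _refine_breakpoints(breaks: list[float], size: float) -> np.ndarray:
    """Subdivide each interval between breakpoints to ~``size`` spacing."""
    pts = [breaks[0]]
    for a, b in zip(breaks, breaks[1:]):
        n = max(1, int(round((b - a) / size)))
        pts.extend(np.linspace(a, b, n + 1)[1:].tolist())
    return np.asarray(pts)


def _grid_to_triangles(xs: np.ndarray, ys: np.ndarray):
    nx, ny = xs.size, ys.size
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([xx.ravel(), yy.ravel()])

    def node(i, j):
        return i * ny + j

    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            n00, n10 = node(i, j), node(i + 1, j)
            n01, n11 = node(i, j + 1), node(i + 1, j + 1)
            # alternate the diagonal for a symmetric union-jack-ish pattern
            if (i + j) % 2 == 0:
                tris.append((n00, n10, n11))
                tris.append((n00, n11, n01))
            else:
                tris.append((n00, n10, n01))
                tris.append((n10, n11, n01))
    return points, np.asarray(tris, dtype=np.int64)


def build_unit_cell_mesh(
    cell: ScaffoldUnitCell,
    with_support: bool = False,
    target_element_size: float | None = None,
) -> Mesh2D:
    """Mesh the unit-cell cross-section.

    Even-numbered layers (0, 2, ...) are strands running along the cut:
    full-width bars.  Odd layers run across the cut: half strand
    cross-sections sit on each lateral symmetry boundary with a void (or
    support bath, if ``with_support``) between them.
    """
    W = cell.inter_fiber_distance
    w = cell.strand_width
    h = cell.layer_height
    if w >= W:
        raise ValueError(
            "strand width must be smaller than the inter-fiber distance "
            "(otherwise adjacent strands merge and the cell is degenerate)"
        )
    if target_element_size is None:
        target_element_size = (
            DEFAULT_SIZE_WITH_SUPPORT if with_support else DEFAULT_SIZE_GEL_ONLY
        )
    x_breaks = [0.0, w / 2.0, W - w / 2.0, W]
    y_breaks = [i * h for i in range(cell.n_layers + 1)]
    xs = _refine_breakpoints(x_breaks, target_element_size)
    ys = _refine_breakpoints(y_breaks, target_element_size)
    points, tris = _grid_to_triangles(xs, ys)

    centroids = points[tris].mean(axis=1)
    layer = np.minimum((centroids[:, 1] // h).astype(int), cell.n_layers - 1)
    in_side_strand = (centroids[:, 0] < w / 2.0) | (centroids[:, 0] > W - w / 2.0)
    is_gel = (layer % 2 == 0) | in_side_strand

    if with_support:
        keep = np.ones(tris.shape[0], dtype=bool)
        labels = np.where(is_gel, GEL, SUPPORT)
    else:
        keep = is_gel
        labels = np.full(tris.shape[0], GEL)

    tris = tris[keep]
    labels = labels[keep]
    # compress node numbering to used nodes
    used = np.unique(tris)
    remap = -np.ones(points.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    return Mesh2D(points[used], remap[tris], labels, thickness=cell.out_of_plane_thickness)


def rectangle_mesh(
    width: float,
    height: float,
    nx: int = 8,
    ny: int = 24,
    thickness: float = 1.0e-3,
    label: int = GEL,
) -> Mesh2D:
    """Structured mesh of a solid rectangle (used by the analytic oracles)."""
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    points, tris = _grid_to_triangles(xs, ys)
    return Mesh2D(points, tris, np.full(tris.shape[0], label), thickness=thickness)
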