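"""Tissue geometry containers.

Two domain kinds are supported: regular 2-D sheets (quadrilateral grids) and
triangulated surface meshes.  Positions are in millimetres, per-node areas in
mm**2, and total surface area is reported in cm**2 to match the clinical
convention for atrial size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy import sparse

MM2_PER_CM2 = 100.0


@dataclass(frozen=True)
class TissueDomain:
    """A discretized piece of atrial tissue.

    Attributes
    ----------
    kind : {"sheet", "mesh"}
    positions : (n, 3) float array, node coordinates in mm.
    elements : (m, 4) int array of quads (sheet) or (m, 3) triangles (mesh).
    node_area : (n,) float array, lumped area per node in mm**2.  Sums to the
        total element area.
    boundary : (n,) bool array, True on boundary nodes.
    shape : (ny, nx) for sheets, None for meshes.
    spacing : grid spacing dx in mm for sheets, None for meshes.
    """

    kind: str
    positions: np.ndarray
    elements: np.ndarray
    node_area: np.ndarray
    boundary: np.ndarray
    shape: tuple[int, int] | None = None
    spacing: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def total_surface(self) -> float:
        """Total tissue area in cm**2."""
        return float(self.node_area.sum()) / MM2_PER_CM2

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions.min(axis=0), self.positions.max(axis=0)


def make_sheet_domain(nx: int, ny: int, dx: float) -> TissueDomain:
    """Build a regular nx-by-ny sheet with spacing ``dx`` mm.

    Nodes are indexed row-major: node (ix, iy) has flat index iy*nx + ix.
    """
    if nx < 3:
        raise ValueError(f"nx must be >= 3, got {nx}")
    if ny < 3:
        raise ValueError(f"ny must be >= 3, got {ny}")
    if dx <= 0:
        raise ValueError(f"dx must be > 0, got {dx}")

    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dx
    gx, gy = np.meshgrid(xs, ys)  # shape (ny, nx)
    positions = np.column_stack(
        [gx.ravel(), gy.ravel(), np.zeros(nx * ny)]
    ).astype(float)

    # quad elements, counter-clockwise
    i0 = (np.arange(ny - 1)[:, None] * nx + np.arange(nx - 1)[None, :]).ravel()
    elements = np.column_stack([i0, i0 + 1, i0 + nx + 1, i0 + nx]).astype(np.int64)

    node_area = np.zeros(nx * ny)
    quad_area = dx * dx
    np.add.at(node_area, elements.ravel(), quad_area / 4.0)

    boundary = np.zeros(nx * ny, dtype=bool)
    boundary.reshape(ny, nx)[[0, -1], :] = True
    boundary.reshape(ny, nx)[:, [0, -1]] = True

    return TissueDomain(
        kind="sheet",
        positions=positions,
        elements=elements,
        node_area=node_area,
        boundary=boundary,
        shape=(ny, nx),
        spacing=float(dx),
    )


def make_mesh_domain(positions: np.ndarray, triangles: np.ndarray) -> TissueDomain:
    """Build a surface-mesh domain from vertices (mm) and triangle indices.

    The mesh must be edge-manifold (no edge shared by more than two
    triangles) and all triangles must have positive area.
    """
    positions = np.asarray(positions, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array in mm")
    if triangles.ndim != 2 or triangles.shape[1] != 3:
        raise ValueError("triangles must be an (m, 3) index array")
    n = positions.shape[0]
    if triangles.min() < 0 or triangles.max() >= n:
        raise ValueError("triangle indices out of range")

    areas = triangle_areas(positions, triangles)
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise ValueError(f"triangle {bad} has non-positive area {areas[bad]:g}")

    node_area = np.zeros(n)
    np.add.at(node_area, triangles.ravel(), np.repeat(areas / 3.0, 3))

    # edge bookkeeping: boundary edges belong to exactly one triangle
    edges = np.sort(
        np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]),
        axis=1,
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise ValueError("mesh is not edge-manifold: an edge is shared by > 2 triangles")
    boundary = np.zeros(n, dtype=bool)
    boundary[uniq[counts == 1].ravel()] = True

    return TissueDomain(
        kind="mesh",
        positions=positions,
        elements=triangles,
        node_area=node_area,
        boundary=boundary,
    )


def triangle_areas(positions: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = positions[triangles[:, 0]]
    b = positions[triangles[:, 1]]
    c = positions[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def element_centroids(domain: TissueDomain) -> np.ndarray:
    return domain.positions[domain.elements].mean(axis=1)


def gaussian_smoothing_matrix(
    domain: TissueDomain, radius: float, truncate: float = 3.0
) -> sparse.csr_matrix:
    """Sparse mass-preserving Gaussian smoother over nodes.

    Row i distributes the mass at node i over its neighbours within
    ``truncate * radius`` with Gaussian weights (sigma = ``radius`` mm),
    normalized per source node so that total mass is conserved exactly.
    Apply as ``S.T @ mass`` to smear a per-node mass vector.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    tree = cKDTree(domain.positions)
    pairs = tree.query_pairs(truncate * radius, output_type="ndarray")
    n = domain.n_nodes
    ii = np.concatenate([np.arange(n), pairs[:, 0], pairs[:, 1]])
    jj = np.concatenate([np.arange(n), pairs[:, 1], pairs[:, 0]])
    d2 = np.sum(
        (domain.positions[ii] - domain.positions[jj]) ** 2, axis=1
    )
    w = np.exp(-0.5 * d2 / radius**2) * domain.node_area[jj]
    mat = sparse.csr_matrix((w, (ii, jj)), shape=(n, n))
    row_sum = np.asarray(mat.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / row_sum)
    return (inv @ mat).tocsr()
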