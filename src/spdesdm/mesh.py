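"""Triangulated meshes and the sparse Matern (SPDE) precision.

The latent Gaussian field is approximated on a triangulated mesh extending
beyond the study area by a buffer (to control boundary inflation of the
variance). Linear finite elements give a lumped mass matrix C and stiffness
matrix G; the Matern nu = 1 field with spatial range r and marginal sd s is
then the GMRF with sparse precision

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G),
    kappa = sqrt(8) / r,   tau = 1 / (sqrt(4 pi) kappa s),

so that the stationary marginal variance is s^2. Range follows the
sqrt(8 nu)/kappa convention: correlation ~= 0.13 at distance r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
import shapely


@dataclass
class Mesh:
    """Planar triangulation: vertices (n, 2) km, triangle index triplets,
    and a per-vertex flag marking the outer (convex-hull) boundary."""

    vertices: np.ndarray
    triangles: np.ndarray
    boundary: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.boundary = np.asarray(self.boundary, dtype=bool)
        areas = self.triangle_areas()
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise ValueError(f"triangle {bad} is degenerate (area {areas[bad]:.3e})")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def edges(self) -> np.ndarray:
        """Unique undirected edges as (n_edges, 2) sorted index pairs."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


def _tri_lattice(bounds, spacing: float, jitter_rng: np.random.Generator) -> np.ndarray:
    """Near-equilateral triangular lattice covering a bounding box, with a
    tiny deterministic jitter to avoid cocircular Delaunay degeneracies."""
    xmin, ymin, xmax, ymax = bounds
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = []
    y = ymin
    row = 0
    while y <= ymax + dy:
        xs = np.arange(xmin - spacing, xmax + 2 * spacing, spacing)
        if row % 2:
            xs = xs + spacing / 2.0
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row += 1
    pts = np.vstack(rows)
    return pts + jitter_rng.uniform(-1, 1, pts.shape) * spacing * 1e-3


def build_mesh(
    domain: Polygon,
    max_edge: float | tuple[float, float],
    cutoff: float | None = None,
    *,
    buffer: float | None = None,
    points: np.ndarray | None = None,
) -> Mesh:
    """Triangulate the domain plus a surrounding buffer.

    ``max_edge`` is the target interior edge length, or an (interior,
    exterior) pair; defaults mirror standard mesh guidance for this model
    family (buffer = domain-diameter / 5, cutoff = interior max_edge / 5).
    Optional seed ``points`` (e.g. observation sites) are kept as vertices;
    any points closer than ``cutoff`` are merged to one vertex.
    """
    if domain.is_empty or domain.area <= 0:
        raise ValueError("degenerate domain polygon")
    if np.isscalar(max_edge):
        interior_edge, exterior_edge = float(max_edge), 2.0 * float(max_edge)
    else:
        interior_edge, exterior_edge = map(float, max_edge)
    if cutoff is None:
        cutoff = interior_edge / 5.0
    if not (interior_edge > cutoff > 0):
        raise ValueError("require max_edge > cutoff > 0")
    xmin, ymin, xmax, ymax = domain.bounds
    diam = float(np.hypot(xmax - xmin, ymax - ymin))
    if buffer is None:
        buffer = diam / 5.0

    jrng = np.random.default_rng(0)  # jitter only; mesh is deterministic
    h_in = 0.95 * interior_edge
    fine_region = domain.buffer(1.5 * h_in)
    fine = _tri_lattice(fine_region.bounds, h_in, jrng)
    fine = fine[shapely.contains(fine_region, shapely.points(fine[:, 0], fine[:, 1]))]

    outer = domain.buffer(buffer)
    h_out = min(0.95 * exterior_edge, buffer)
    coarse = _tri_lattice(outer.bounds, h_out, jrng)
    in_outer = shapely.contains(outer, shapely.points(coarse[:, 0], coarse[:, 1]))
    not_fine = ~shapely.contains(
        domain.buffer(0.5 * h_in), shapely.points(coarse[:, 0], coarse[:, 1])
    )
    coarse = coarse[in_outer & not_fine]

    cand = [fine, coarse]
    if points is not None:
        cand.insert(0, np.asarray(points, dtype=float))
    allpts = np.vstack(cand)

    # merge clusters closer than cutoff; earlier points take precedence
    tree = cKDTree(allpts)
    keep = np.ones(len(allpts), dtype=bool)
    for i, j in sorted(tree.query_pairs(cutoff)):
        if keep[i] and keep[j]:
            keep[max(i, j)] = False
    verts = allpts[keep]

    tri = Delaunay(verts)
    areas = _areas(verts, tri.simplices)
    simplices = tri.simplices[areas > 1e-12]
    boundary = np.zeros(len(verts), dtype=bool)
    boundary[np.unique(tri.convex_hull)] = True
    return Mesh(verts, simplices, boundary)


def _areas(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = verts[tris]
    return 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )


def fem_matrices(mesh: Mesh) -> tuple[sp.csc_matrix, sp.csc_matrix]:
    """Lumped mass matrix C (diagonal) and stiffness matrix G from linear
    basis functions on the triangulation."""
    verts, tris = mesh.vertices, mesh.triangles
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise ValueError(f"triangle {bad} has zero area")
    n = mesh.n_vertices
    p = verts[tris]  # (m, 3, 2)
    # gradient of barycentric basis i: rot90 of opposite edge / 2A
    e = p[:, [2, 0, 1], :] - p[:, [1, 2, 0], :]  # edge opposite vertex i
    grads = np.stack([-e[:, :, 1], e[:, :, 0]], axis=2) / (2 * areas)[:, None, None]
    rows, cols, gvals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(tris[:, i])
            cols.append(tris[:, j])
            gvals.append(areas * np.einsum("mk,mk->m", grads[:, i], grads[:, j]))
    G = sp.coo_matrix(
        (np.concatenate(gvals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    cdiag = np.zeros(n)
    for i in range(3):
        np.add.at(cdiag, tris[:, i], areas / 3.0)
    C = sp.diags(cdiag).tocsc()
    return C, G


def spde_precision(
    C: sp.spmatrix, G: sp.spmatrix, range_km: float, sd: float
) -> sp.csc_matrix:
    """Sparse Matern (nu = 1) precision with stationary marginal sd ``sd``."""
    if range_km <= 0 or sd <= 0:
        raise ValueError("range and sd must be positive")
    kappa = np.sqrt(8.0) / range_km
    tau = 1.0 / (np.sqrt(4.0 * np.pi) * kappa * sd)
    cinv = sp.diags(1.0 / C.diagonal())
    Q = tau**2 * (kappa**4 * C + 2 * kappa**2 * G + G @ cinv @ G)
    Q = ((Q + Q.T) / 2.0).tocsc()
    return Q


@dataclass
class SPDEModel:
    """Mesh + finite-element matrices + hyperparameters + assembled precision."""

    mesh: Mesh
    C: sp.spmatrix = field(repr=False, default=None)
    G: sp.spmatrix = field(repr=False, default=None)
    range_km: float = 1.0
    sd: float = 1.0
    Q: sp.csc_matrix = field(repr=False, default=None)

    @classmethod
    def from_mesh(cls, mesh: Mesh, range_km: float, sd: float) -> "SPDEModel":
        C, G = fem_matrices(mesh)
        return cls(mesh, C, G, range_km, sd, spde_precision(C, G, range_km, sd))

    def precision(self, range_km: float, sd: float) -> sp.csc_matrix:
        return spde_precision(self.C, self.G, range_km, sd)


def projector(mesh: Mesh, points: np.ndarray) -> sp.csr_matrix:
    """Sparse barycentric projection A with A @ (vertex field) the linear
    interpolation of the field at the points. Rows sum to 1, <= 3 nonzeros."""
    pts = np.asarray(points, dtype=float)
    tri = Triangulation(
        mesh.vertices[:, 0], mesh.vertices[:, 1], triangles=mesh.triangles
    )
    finder = TrapezoidMapTriFinder(tri)
    t_idx = finder(pts[:, 0], pts[:, 1])
    outside = np.flatnonzero(t_idx < 0)
    if len(outside):
        raise ValueError(f"points outside mesh at indices {outside[:20].tolist()}")
    corners = mesh.triangles[t_idx]  # (n, 3)
    p = mesh.vertices[corners]  # (n, 3, 2)
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    d = pts - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    w1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / det
    w2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / det
    w = np.column_stack([1.0 - w1 - w2, w1, w2])
    w = np.clip(w, 0.0, 1.0)
    w /= w.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(len(pts)), 3)
    A = sp.coo_matrix(
        (w.ravel(), (rows, corners.ravel())), shape=(len(pts), mesh.n_vertices)
    )
    return A.tocsr()


@dataclass
class BackgroundSet:
    """Pseudo-absence locations: mesh vertices inside the terrestrial mask,
    supplemented by a regular grid, deduplicated."""

    coords: np.ndarray
    provenance: np.ndarray  # 'mesh-vertex' | 'grid'


def background_points(
    mesh: Mesh, mask: Polygon, spacing: float, *, tolerance: float = 1e-6
) -> BackgroundSet:
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if mask.is_empty or mask.area <= 0:
        raise ValueError("empty terrestrial mask")
    verts = mesh.vertices
    inside = shapely.contains(mask, shapely.points(verts[:, 0], verts[:, 1]))
    vpts = verts[inside]

    xmin, ymin, xmax, ymax = mask.bounds
    xs = np.arange(xmin + spacing / 2.0, xmax, spacing)
    ys = np.arange(ymin + spacing / 2.0, ymax, spacing)
    xg, yg = np.meshgrid(xs, ys)
    gpts = np.column_stack([xg.ravel(), yg.ravel()])
    gpts = gpts[shapely.contains(mask, shapely.points(gpts[:, 0], gpts[:, 1]))]

    if len(vpts) and len(gpts):
        tree = cKDTree(vpts)
        d, _ = tree.query(gpts)
        gpts = gpts[d > tolerance]
    coords = np.vstack([vpts, gpts]) if len(vpts) or len(gpts) else np.empty((0, 2))
    if len(coords) == 0:
        raise ValueError("no background points inside mask")
    prov = np.array(["mesh-vertex"] * len(vpts) + ["grid"] * len(gpts))
    return BackgroundSet(coords, prov)
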