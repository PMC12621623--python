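"""Procedural construction of the branched seta and its tetrahedral mesh.

A gecko seta is modelled as a binary tree of tapering circular branches.  The
skeleton is built from two guiding hyperbola branches ("parabolas" in the
bioadhesion literature)

    x^2/C1^2 - y^2/C2^2 = 1,   x, y > 0,

with C1 = 0.5*D0 and 1.5*D0 for the inner/outer guide and C2 = C1*tan(alpha).
At each branching height H_i the horizontal segment between the guides is
split into 2^(i-1) equidistant intervals whose midpoints are the branching
points.  Heights follow H_i = eta^(n_levels - i) * H_sp and branch widths
W_i = gamma^(n_levels + 1 - i) * R_sp, so the shaft is widest at the top
(where the driver nodes live) and the 2^n_levels terminal branches have the
spatula-shaft diameter R_sp.

The solid is the union of conical frusta swept along skeleton edges; it is
meshed by sampling structured point rings along each branch, computing one
global Delaunay tetrahedralisation, and keeping tetrahedra whose centroid
lies inside the solid.  This yields a single conforming mesh.  The top cap
above the total height H0 is removed (flat driver cross-section) and a
configurable bottom fraction of every terminal branch is removed to make
room for the particle-resolved spatula.

Axes: +Y is the substrate normal (pull direction), X points along the seta
elevation, Z is lateral.  The substrate surface is the plane y = 0.  All
lengths in nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class GeometryParams:
    """Geometric parameters of the branched seta (lengths in nm)."""

    D0_nm: float = 13.5e3
    alpha_deg: float = 30.0
    R_sp_nm: float = 50.0
    eta: float = 2.417
    #: width-scaling parameter; printed only graphically in the source
    #: material, default chosen equal to eta (gives a realistic ~4 um base
    #: shaft width at full scale) and exposed in every config.
    gamma: float = 2.417
    H_sp_nm: float = 670.0
    n_levels: int = 4
    #: target node spacing of the mesh relative to the local branch radius
    mesh_density: float = 0.9
    #: fraction of each terminal branch (measured from the tip) removed to
    #: make room for the molecular spatula
    trunc_fraction: float = 0.5
    #: fraction of the remaining terminal branch (from its cut end) whose
    #: nodes form the bridging-domain node set
    bd_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (self.eta > 1 and self.gamma > 1):
            raise ValueError("eta and gamma must exceed 1")
        if not (0 < self.alpha_deg < 90):
            raise ValueError("inclination angle must lie in (0, 90) degrees")
        if self.R_sp_nm <= 0 or self.H_sp_nm <= 0 or self.D0_nm <= 0:
            raise ValueError("lengths must be positive")
        if self.n_levels < 1:
            raise ValueError("need at least one branching level")
        if not (0 < self.trunc_fraction < 1):
            raise ValueError("trunc_fraction must lie in (0, 1)")

    @property
    def H0_nm(self) -> float:
        """Total seta height, eta^n_levels * H_sp."""
        return self.eta**self.n_levels * self.H_sp_nm

    @property
    def n_tips(self) -> int:
        return 2**self.n_levels


def parabola_x(y: float | np.ndarray, C1: float, C2: float) -> float | np.ndarray:
    """Positive-branch x of the guiding curve x^2/C1^2 - y^2/C2^2 = 1."""
    if C1 <= 0 or C2 <= 0:
        raise ValueError(f"guide parameters must be positive, got C1={C1}, C2={C2}")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("heights must be non-negative")
    out = C1 * np.sqrt(1.0 + (y / C2) ** 2)
    return float(out) if out.ndim == 0 else out


def branch_heights(params: GeometryParams) -> np.ndarray:
    """Branching heights H_i = eta^(n_levels - i) * H_sp, i = 0..n_levels."""
    i = np.arange(params.n_levels + 1)
    return params.eta ** (params.n_levels - i) * params.H_sp_nm


def branch_widths(params: GeometryParams) -> np.ndarray:
    """Branch widths W_i = gamma^(n_levels + 1 - i) * R_sp, i = 0..n_levels+1."""
    i = np.arange(params.n_levels + 2)
    return params.gamma ** (params.n_levels + 1 - i) * params.R_sp_nm


@dataclass(frozen=True)
class SetaSkeleton:
    """Branch-point tree of the seta.

    ``points[i]`` holds the (2^(i-1) or 1 for i=0) xyz coordinates at level i;
    level ``n_levels + 1`` holds the terminal tips on the substrate plane.
    ``edges`` is a list of (level, parent_index, child_index); each edge gets
    the tapering half-widths (r_top, r_bottom) from ``edge_radii``.
    """

    params: GeometryParams
    points: tuple[np.ndarray, ...]
    edges: tuple[tuple[int, int, int], ...]
    edge_radii: tuple[tuple[float, float], ...]

    def edge_endpoints(self) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
        """Per edge: (upper point, lower point, upper radius, lower radius)."""
        out = []
        for (lvl, pi, ci), (rt, rb) in zip(self.edges, self.edge_radii):
            out.append((self.points[lvl][pi], self.points[lvl + 1][ci], rt, rb))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "levels": [p.tolist() for p in self.points],
                "edges": [list(e) for e in self.edges],
                "edge_radii_nm": [list(r) for r in self.edge_radii],
                "H0_nm": self.params.H0_nm,
            }
        )


def _guide_interval(params: GeometryParams, y: float) -> tuple[float, float]:
    C1_in, C1_out = 0.5 * params.D0_nm, 1.5 * params.D0_nm
    tan_a = np.tan(np.radians(params.alpha_deg))
    x_lo = parabola_x(y, C1_in, C1_in * tan_a)
    x_hi = parabola_x(y, C1_out, C1_out * tan_a)
    return x_lo, x_hi


def _level_points(params: GeometryParams, level: int, y: float) -> np.ndarray:
    """Midpoints of the 2^(level-1) equidistant intervals at height y."""
    n = 1 if level == 0 else 2 ** (level - 1)
    x_lo, x_hi = _guide_interval(params, y)
    if not x_hi > x_lo:
        raise ValueError(f"guides do not bracket a positive segment at level {level}")
    k = np.arange(n)
    x = x_lo + (x_hi - x_lo) * (k + 0.5) / n
    pts = np.zeros((n, 3))
    pts[:, 0] = x
    pts[:, 1] = y
    return pts


def build_skeleton(params: GeometryParams) -> SetaSkeleton:
    """Build the branch-point tree from the guiding curves.

    Level i holds 2^(i-1) points (one shaft-top point at level 0); terminal
    tips sit on the substrate plane y = 0 at level n_levels + 1.  Children of
    point k at level i are points 2k and 2k+1 at level i+1.
    """
    heights = branch_heights(params)
    widths = branch_widths(params)
    points = [_level_points(params, 0, heights[0])]
    for lvl in range(1, params.n_levels + 1):
        points.append(_level_points(params, lvl, heights[lvl]))
    points.append(_level_points(params, params.n_levels + 1, 0.0))

    edges: list[tuple[int, int, int]] = []
    radii: list[tuple[float, float]] = []
    # shaft: level 0 -> level 1
    edges.append((0, 0, 0))
    radii.append((widths[0] / 2, widths[1] / 2))
    for lvl in range(1, params.n_levels + 1):
        for parent in range(len(points[lvl])):
            for child in (2 * parent, 2 * parent + 1):
                edges.append((lvl, parent, child))
                radii.append((widths[lvl] / 2, widths[lvl + 1] / 2))

    return SetaSkeleton(
        params=params,
        points=tuple(np.asarray(p) for p in points),
        edges=tuple(edges),
        edge_radii=tuple(radii),
    )


@dataclass
class SetaMesh:
    """Conforming tetrahedral mesh of the truncated seta.

    ``order`` is 1 for linear 4-node tets or 2 for quadratic 10-node tets
    (corner nodes first, then the six edge midnodes in the usual
    (01,12,20,03,13,23) order).  ``driver_nodes`` are the node indices on the
    flat top cross-section; ``bd_nodes[s]`` the bridging-domain node set of
    terminal branch s.
    """

    nodes: np.ndarray
    tets: np.ndarray
    order: int
    driver_nodes: np.ndarray
    bd_nodes: list[np.ndarray]
    #: per terminal branch: (upper point, cut point, axis unit vector down)
    branch_frames: list[tuple[np.ndarray, np.ndarray, np.ndarray]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def corner_tets(self) -> np.ndarray:
        return self.tets[:, :4]

    def volume(self) -> float:
        return float(np.sum(tet_volumes(self.nodes, self.corner_tets())))


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def _truncated_edges(skeleton: SetaSkeleton):
    """Edge list with terminal branches shortened by trunc_fraction."""
    params = skeleton.params
    out = []
    terminal = []
    n_lvl = params.n_levels
    for (lvl, _pi, _ci), (a, b, rt, rb) in zip(
        skeleton.edges, skeleton.edge_endpoints()
    ):
        if lvl == n_lvl:  # terminal branch: cut off the bottom fraction
            f = params.trunc_fraction
            cut = a + (b - a) * (1.0 - f)
            r_cut = rt + (rb - rt) * (1.0 - f)
            out.append((a, cut, rt, r_cut))
            terminal.append(len(out) - 1)
        else:
            out.append((a, b, rt, rb))
    return out, terminal


def _sample_edge_points(a, b, r_a, r_b, h, flat_top: bool = False) -> np.ndarray:
    """Structured point cloud filling one frustum: axial stations of
    concentric rings, golden-angle rotated per station to avoid degenerate
    (cospherical) Delaunay configurations.  With ``flat_top`` the first
    station's rings are laid in the horizontal plane of ``a`` so the top
    truncation cross-section (driver plane) is flat."""
    axis = b - a
    length = float(np.linalg.norm(axis))
    axis = axis / length
    # orthonormal frame
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    n_ax = max(2, int(np.ceil(length / h)) + 1)
    pts = []
    for s in range(n_ax):
        t = s / (n_ax - 1)
        c = a + axis * (t * length)
        r = r_a + (r_b - r_a) * t
        if flat_top and s == 0:
            u1, u2 = np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])
        else:
            u1, u2 = e1, e2
        n_rad = max(1, int(np.ceil(r / h)))
        pts.append(c)
        for j in range(1, n_rad + 1):
            rj = r * j / n_rad
            n_ring = max(6, int(np.ceil(2 * np.pi * rj / h)))
            phi0 = s * GOLDEN_ANGLE + j * 0.7130423
            phi = phi0 + 2 * np.pi * np.arange(n_ring) / n_ring
            ring = c + rj * (np.outer(np.cos(phi), u1) + np.outer(np.sin(phi), u2))
            pts.append(ring)
    return np.vstack([np.atleast_2d(p) for p in pts])


def _hash_jitter(keys: np.ndarray) -> np.ndarray:
    """Deterministic pseudo-random offsets in [-0.5, 0.5]^3 per integer key."""
    k = keys.astype(np.uint64)
    mix = np.empty((len(k), 3), dtype=np.uint64)
    seeds = np.array(
        [0x9E3779B97F4A7C15, 0xC2B2AE3D27D4EB4F, 0x165667B19E3779F9], dtype=np.uint64
    )
    with np.errstate(over="ignore"):
        base = (
            k[:, 0] * np.uint64(0xFF51AFD7ED558CCD)
            + k[:, 1] * np.uint64(0xC4CEB9FE1A85EC53)
            + k[:, 2] * np.uint64(0xD6E8FEB86659FD93)
        )
        for c in range(3):
            x = base + seeds[c]
            x ^= x >> np.uint64(33)
            x *= np.uint64(0xFF51AFD7ED558CCD)
            x ^= x >> np.uint64(33)
            mix[:, c] = x
    return mix.astype(np.float64) / 2.0**64 - 0.5


def _inside_solid(points: np.ndarray, edges, tol_rel: float = 0.02) -> np.ndarray:
    """True where a point lies inside the union of tapered frusta."""
    inside = np.zeros(len(points), dtype=bool)
    for a, b, r_a, r_b in edges:
        d = b - a
        L2 = float(d @ d)
        t = np.clip((points - a) @ d / L2, 0.0, 1.0)
        proj = a + t[:, None] * d
        dist = np.linalg.norm(points - proj, axis=1)
        r = r_a + (r_b - r_a) * t
        inside |= dist <= r * (1.0 + tol_rel)
    return inside


def frusta_volume(edges) -> float:
    """Sum of the analytic volumes of the tapered frusta (junction overlap
    is negligible at the default taper; used as the mesh-volume oracle)."""
    total = 0.0
    for a, b, r_a, r_b in edges:
        hgt = float(np.linalg.norm(b - a))
        total += np.pi * hgt / 3.0 * (r_a**2 + r_a * r_b + r_b**2)
    return total


def mesh_frustum(a, b, r_a, r_b, h) -> SetaMesh:
    """Mesh a single conical frustum (convex solid) with the same pipeline
    used for the full seta; useful for mesh-sanity and FEM benchmarks."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pts = _sample_edge_points(a, b, r_a, r_b, h)
    key = np.round(pts / 1e-6).astype(np.int64)
    _, uniq_idx = np.unique(key, axis=0, return_index=True)
    pts = pts[np.sort(uniq_idx)]
    pts = pts + 1e-4 * min(r_a, r_b) * _hash_jitter(
        np.round(pts / 1e-6).astype(np.int64)
    )
    tri = Delaunay(pts)
    tets = tri.simplices.copy()
    vols = tet_volumes(pts, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    return SetaMesh(nodes=pts, tets=tets, order=1,
                    driver_nodes=np.array([], dtype=np.int64),
                    bd_nodes=[], branch_frames=[])


def generate_mesh(
    skeleton: SetaSkeleton,
    mesh_density: float | None = None,
    order: int = 1,
) -> SetaMesh:
    """Tetrahedralise the truncated seta solid.

    Points are sampled per branch in skeleton-local coordinates (so a rigid
    translation of the skeleton reproduces the identical connectivity),
    deduplicated, Delaunay-triangulated, and filtered by a
    centroid-inside-solid test.  Degenerate (zero-volume) elements are
    rejected.
    """
    params = skeleton.params
    density = params.mesh_density if mesh_density is None else mesh_density
    edges, terminal_idx = _truncated_edges(skeleton)
    origin = skeleton.points[0][0].copy()

    clouds = []
    for k, (a, b, r_a, r_b) in enumerate(edges):
        h = density * min(r_a, r_b)
        clouds.append(
            _sample_edge_points(a - origin, b - origin, r_a, r_b, h, flat_top=(k == 0))
        )
    pts = np.vstack(clouds)
    # deduplicate on a fine grid; lexicographic order for determinism
    key = np.round(pts / 1e-6).astype(np.int64)
    _, uniq_idx = np.unique(key, axis=0, return_index=True)
    pts = pts[np.sort(uniq_idx)]
    order_idx = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order_idx]
    # break exact coplanarity (ring/axis points) with a deterministic,
    # translation-invariant jitter derived from the grid key
    jitter_scale = 1e-4 * min(min(r_a, r_b) for _, _, r_a, r_b in edges)
    pts = pts + jitter_scale * _hash_jitter(np.round(pts / 1e-6).astype(np.int64))

    tri = Delaunay(pts)
    tets = tri.simplices
    centroids = pts[tets].mean(axis=1)
    local_edges = [(a - origin, b - origin, ra, rb) for a, b, ra, rb in edges]
    keep = _inside_solid(centroids, local_edges)
    tets = tets[keep]
    vols = tet_volumes(pts, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    vols = np.abs(vols)
    if np.any(vols == 0):
        bad = np.nonzero(vols == 0)[0]
        raise ValueError(f"degenerate (zero-volume) elements: {bad[:10].tolist()}")
    if len(tets) == 0:
        raise ValueError("mesh generation produced no valid elements")

    # keep only referenced nodes
    used = np.unique(tets)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = pts[used] + origin
    tets = remap[tets]

    vols = tet_volumes(nodes, tets)
    if np.any(vols <= 0):
        bad = np.nonzero(vols <= 0)[0]
        raise ValueError(f"degenerate elements after filtering: {bad[:10].tolist()}")

    mesh = SetaMesh(
        nodes=nodes,
        tets=tets,
        order=1,
        driver_nodes=np.array([], dtype=np.int64),
        bd_nodes=[],
        branch_frames=[],
    )
    if order == 2:
        mesh = _promote_to_quadratic(mesh)

    _assign_node_sets(mesh, skeleton, edges, terminal_idx)
    _check_connected(mesh)
    return mesh


def _promote_to_quadratic(mesh: SetaMesh) -> SetaMesh:
    """Insert unique midside nodes, turning 4-node into 10-node tets."""
    tets = mesh.tets
    edge_local = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    pairs = np.vstack(
        [np.sort(tets[:, [i, j]], axis=1) for i, j in edge_local]
    )
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    nodes = np.vstack([mesh.nodes, mid])
    n0 = len(mesh.nodes)
    ntet = len(tets)
    new_tets = np.empty((ntet, 10), dtype=np.int64)
    new_tets[:, :4] = tets
    for k in range(6):
        new_tets[:, 4 + k] = n0 + inv[k * ntet : (k + 1) * ntet]
    return SetaMesh(
        nodes=nodes,
        tets=new_tets,
        order=2,
        driver_nodes=mesh.driver_nodes,
        bd_nodes=mesh.bd_nodes,
        branch_frames=mesh.branch_frames,
    )


def _assign_node_sets(mesh: SetaMesh, skeleton, edges, terminal_idx) -> None:
    params = skeleton.params
    # the flat top truncation plane sits at the skeleton's shaft-top height
    # (not the absolute H0: the skeleton may be rigidly translated)
    top_y = float(skeleton.points[0][0][1])
    tol = 1e-6 * params.H0_nm
    mesh.driver_nodes = np.nonzero(np.abs(mesh.nodes[:, 1] - top_y) <= tol)[0]
    if len(mesh.driver_nodes) == 0:
        raise ValueError("no driver nodes found on the top truncation plane")

    mesh.bd_nodes = []
    mesh.branch_frames = []
    for s, ei in enumerate(terminal_idx):
        a, cut, r_a, r_cut = edges[ei]
        axis = cut - a
        length = float(np.linalg.norm(axis))
        axis = axis / length
        bd_len = params.bd_fraction * length
        d = mesh.nodes - a
        t = d @ axis
        radial = np.linalg.norm(d - np.outer(t, axis), axis=1)
        r_at = r_a + (r_cut - r_a) * np.clip(t / length, 0, 1)
        sel = (
            (t >= length - bd_len - 1e-9)
            & (t <= length + 1e-9)
            & (radial <= r_at * 1.05 + 1e-9)
        )
        idx = np.nonzero(sel)[0]
        if len(idx) == 0:
            raise ValueError(f"empty bridging-domain node set for branch {s}")
        mesh.bd_nodes.append(idx)
        mesh.branch_frames.append((a.copy(), cut.copy(), axis.copy()))

    # node sets must be mutually disjoint
    all_bd = np.concatenate(mesh.bd_nodes) if mesh.bd_nodes else np.array([])
    if len(np.intersect1d(all_bd, mesh.driver_nodes)) > 0:
        raise ValueError("bridging-domain and driver node sets overlap")
    if len(np.unique(all_bd)) != len(all_bd):
        raise ValueError("bridging-domain node sets overlap each other")


def _check_connected(mesh: SetaMesh) -> None:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    tets = mesh.corner_tets()
    i = np.repeat(tets[:, 0], 3)
    j = tets[:, 1:].ravel()
    n = mesh.n_nodes if mesh.order == 1 else int(tets.max()) + 1
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError(f"mesh is not a single connected component ({ncomp})")


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Faces that belong to exactly one tetrahedron (corner connectivity)."""
    faces = np.vstack(
        [tets[:, c] for c in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))]
    )
    faces = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return uniq[counts == 1]


def surface_euler_characteristic(tets: np.ndarray) -> int:
    """V - E + F of the boundary surface (2 per spherical shell)."""
    faces = boundary_faces(tets)
    verts = np.unique(faces)
    edges = np.unique(
        np.sort(np.vstack([faces[:, (0, 1)], faces[:, (1, 2)], faces[:, (0, 2)]]), axis=1),
        axis=0,
    )
    return len(verts) - len(edges) + len(faces)


def write_vtu(mesh: SetaMesh, path, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Minimal ASCII VTU writer (linear tets; quadratic exported as corners)."""
    tets = mesh.corner_tets()
    n, m = mesh.n_nodes, len(tets)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines += [" ".join(f"{v:.9g}" for v in row) for row in mesh.nodes]
    lines += ["</DataArray>", "</Points>", "<Cells>",
              '<DataArray type="Int64" Name="connectivity" format="ascii">']
    lines += [" ".join(map(str, row)) for row in tets]
    lines += ["</DataArray>", '<DataArray type="Int64" Name="offsets" format="ascii">',
              " ".join(str(4 * (k + 1)) for k in range(m)),
              "</DataArray>", '<DataArray type="UInt8" Name="types" format="ascii">',
              " ".join("10" for _ in range(m)), "</DataArray>", "</Cells>"]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            lines.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            if arr.ndim == 1:
                lines.append(" ".join(f"{v:.9g}" for v in arr))
            else:
                lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
            lines.append("</DataArray>")
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def box_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int,
             order: int = 1) -> SetaMesh:
    """Structured tetrahedral mesh of the box [0,lx]x[0,ly]x[0,lz]
    (six Kuhn tets per cube); used for benchmarks and calibration specimens."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    kuhn = [(0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
            (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = [nid(i + a, j + b, k + d)
                     for a in (0, 1) for b in (0, 1) for d in (0, 1)]
                # corner order: bit pattern (a, b, d) -> index 4a + 2b + d
                for t in kuhn:
                    tets.append([c[v] for v in t])
    tets = np.asarray(tets, dtype=np.int64)
    vols = tet_volumes(nodes, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    mesh = SetaMesh(nodes=nodes, tets=tets, order=1,
                    driver_nodes=np.array([], dtype=np.int64),
                    bd_nodes=[], branch_frames=[])
    if order == 2:
        mesh = _promote_to_quadratic(mesh)
    return mesh


def mini_params(**overrides) -> GeometryParams:
    """Reduced two-level seta used by the miniature test systems.

    The terminal fibrils are thinned (R_sp 30 nm) and shortened (H_sp 200 nm)
    so that their bridging-domain bands match the miniature spatula shaft
    (50 nm long, 24 nm across), which physically continues the fibril.
    """
    base = dict(n_levels=2, H_sp_nm=200.0, R_sp_nm=30.0, D0_nm=2000.0,
                mesh_density=0.9)
    base.update(overrides)
    return GeometryParams(**base)
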