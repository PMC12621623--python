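import xml.etree.ElementTree as ET

import numpy as np
import pytest

from setascale.geometry import (
    GeometryParams,
    _truncated_edges,
    box_mesh,
    branch_heights,
    branch_widths,
    build_skeleton,
    frusta_volume,
    generate_mesh,
    mesh_frustum,
    mini_params,
    parabola_x,
    surface_euler_characteristic,
    tet_volumes,
    write_vtu,
)


# ---------------------------------------------------------------- parameters

def test_default_total_height_matches_recursion():
    # H_0 = eta^4 * H_sp = 2.417^4 * 0.67 um = 22.87 um (~22.8 printed)
    p = GeometryParams()
    h = branch_heights(p)
    assert h[0] == pytest.approx(p.eta**4 * 670.0)
    assert h[0] / 1000.0 == pytest.approx(22.8, rel=0.005)
    assert h[-1] == p.H_sp_nm
    assert np.all(np.diff(h) < 0)
    # consecutive ratio is eta
    assert h[:-1] / h[1:] == pytest.approx(p.eta)


def test_branch_widths_geometric_decay():
    p = GeometryParams()
    w = branch_widths(p)
    assert len(w) == p.n_levels + 2
    assert w[:-1] / w[1:] == pytest.approx(p.gamma)
    assert w[-1] == p.R_sp_nm


def test_params_validation():
    with pytest.raises(ValueError):
        GeometryParams(eta=1.0)
    with pytest.raises(ValueError):
        GeometryParams(alpha_deg=90.0)
    with pytest.raises(ValueError):
        GeometryParams(R_sp_nm=0.0)
    with pytest.raises(ValueError):
        GeometryParams(n_levels=0)
    with pytest.raises(ValueError):
        GeometryParams(trunc_fraction=1.0)


def test_parabola_x():
    # at y = 0 the guide passes through x = C1
    assert parabola_x(0.0, 2.0, 1.0) == pytest.approx(2.0)
    # monotone in y
    ys = np.linspace(0, 5, 20)
    xs = parabola_x(ys, 2.0, 1.0)
    assert np.all(np.diff(xs) > 0)
    with pytest.raises(ValueError):
        parabola_x(1.0, -2.0, 1.0)
    with pytest.raises(ValueError):
        parabola_x(-1.0, 2.0, 1.0)


# ------------------------------------------------------------------ skeleton

def test_skeleton_structure():
    p = GeometryParams(n_levels=3)
    sk = build_skeleton(p)
    # level 0 has the shaft top; level i has 2^(i-1) points; tips 2^n
    counts = [len(pts) for pts in sk.points]
    assert counts == [1, 1, 2, 4, 8]
    # tips on the substrate plane
    assert np.all(sk.points[-1][:, 1] == 0.0)
    # heights follow the recursion
    h = branch_heights(p)
    for lvl in range(p.n_levels + 1):
        assert sk.points[lvl][:, 1] == pytest.approx(h[lvl])
    # binary tree edge count: 1 shaft + sum 2^i
    assert len(sk.edges) == 1 + sum(2**i for i in range(1, p.n_levels + 1))


def test_skeleton_points_between_guides():
    p = GeometryParams(n_levels=3)
    sk = build_skeleton(p)
    tan_a = np.tan(np.radians(p.alpha_deg))
    for pts in sk.points:
        for x, y, _ in pts:
            lo = parabola_x(y, 0.5 * p.D0_nm, 0.5 * p.D0_nm * tan_a)
            hi = parabola_x(y, 1.5 * p.D0_nm, 1.5 * p.D0_nm * tan_a)
            assert lo < x < hi


# ---------------------------------------------------------------------- mesh

def test_mesh_deterministic(mini_mesh):
    mesh, geom = mini_mesh
    again = generate_mesh(build_skeleton(geom), mesh_density=geom.mesh_density)
    assert np.array_equal(mesh.nodes, again.nodes)
    assert np.array_equal(mesh.tets, again.tets)


def test_mesh_translation_invariance():
    geom = mini_params()
    sk = build_skeleton(geom)
    mesh = generate_mesh(sk, mesh_density=geom.mesh_density)
    shift = np.array([123.456, -7.89, 0.321])
    sk2 = type(sk)(
        params=sk.params,
        points=tuple(p + shift for p in sk.points),
        edges=sk.edges,
        edge_radii=sk.edge_radii,
    )
    mesh2 = generate_mesh(sk2, mesh_density=geom.mesh_density)
    assert np.array_equal(mesh.tets, mesh2.tets)
    assert mesh2.nodes == pytest.approx(mesh.nodes + shift, abs=1e-9)


def test_mesh_volume_matches_frusta_oracle(mini_mesh):
    mesh, geom = mini_mesh
    edges, _ = _truncated_edges(build_skeleton(geom))
    oracle = frusta_volume(edges)
    assert mesh.volume() == pytest.approx(oracle, rel=0.05)


def test_mesh_element_quality(mini_mesh):
    mesh, _ = mini_mesh
    vols = tet_volumes(mesh.nodes, mesh.corner_tets())
    assert np.all(vols > 0)
    # every node is referenced
    assert len(np.unique(mesh.tets)) == mesh.n_nodes


def test_mesh_node_sets(mini_mesh):
    mesh, geom = mini_mesh
    # driver nodes on the flat top truncation plane at the skeleton top
    assert len(mesh.driver_nodes) >= 3
    assert mesh.nodes[mesh.driver_nodes, 1] == pytest.approx(
        branch_heights(geom)[0], abs=1e-2)
    # one BD node set per terminal branch, all non-empty and disjoint
    assert len(mesh.bd_nodes) == geom.n_tips
    all_bd = np.concatenate(mesh.bd_nodes)
    assert all(len(b) > 0 for b in mesh.bd_nodes)
    assert len(np.unique(all_bd)) == len(all_bd)
    assert len(mesh.branch_frames) == geom.n_tips


def test_quadratic_promotion(mini_mesh):
    mesh, geom = mini_mesh
    mesh2 = generate_mesh(build_skeleton(geom), mesh_density=geom.mesh_density,
                          order=2)
    assert mesh2.order == 2
    assert mesh2.tets.shape[1] == 10
    # straight-edge P2: corner connectivity and volume are unchanged
    assert np.array_equal(mesh2.corner_tets(), mesh.tets)
    assert mesh2.volume() == pytest.approx(mesh.volume(), rel=1e-12)
    # midside nodes at edge midpoints
    t = mesh2.tets[0]
    mid01 = 0.5 * (mesh2.nodes[t[0]] + mesh2.nodes[t[1]])
    assert mesh2.nodes[t[4]] == pytest.approx(mid01, abs=1e-9)


def test_frustum_convex_oracle():
    # a single frustum is convex: closed surface (Euler = 2), analytic volume
    a = np.array([0.0, 30.0, 0.0])
    b = np.array([0.0, 0.0, 0.0])
    r_a, r_b = 10.0, 6.0
    mesh = mesh_frustum(a, b, r_a, r_b, h=2.5)
    assert surface_euler_characteristic(mesh.tets) == 2
    exact = np.pi * 30.0 / 3.0 * (r_a**2 + r_a * r_b + r_b**2)
    assert mesh.volume() == pytest.approx(exact, rel=0.05)


def test_box_mesh_volume_exact():
    mesh = box_mesh(2.0, 3.0, 4.0, 2, 3, 4)
    assert mesh.volume() == pytest.approx(24.0, rel=1e-12)
    assert surface_euler_characteristic(mesh.tets) == 2


def test_tet_volume_unit_tet():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    tets = np.array([[0, 1, 2, 3]])
    assert tet_volumes(nodes, tets)[0] == pytest.approx(1.0 / 6.0)


def test_write_vtu(tmp_path, mini_mesh):
    mesh, _ = mini_mesh
    path = tmp_path / "mesh.vtu"
    write_vtu(mesh, path)
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    assert int(piece.get("NumberOfPoints")) == mesh.n_nodes
    assert int(piece.get("NumberOfCells")) == len(mesh.tets)
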