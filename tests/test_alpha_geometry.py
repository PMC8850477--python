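"""Geometric core: triangulation, dual complex, flow, volumes, areas.

Independent oracles: brute-force empty-circumsphere Delaunay (O(n^5)),
per-simplex size/attachment evaluation against all points, rejection-
sampling volume estimates, and spherical-cap closed forms.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from alphapocket.alpha_geometry import (GeometryConfig, TriangulationError,
                                        _simplex_orthocenter,
                                        build_dual_complex,
                                        build_regular_triangulation,
                                        classify_flow, detect_pockets,
                                        extract_pockets, fibonacci_sphere,
                                        pocket_area, pocket_volume,
                                        points_in_tetrahedra, solvent_area)
from conftest import back_face_overlap, wall_residue_recall

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_delaunay(pts: np.ndarray) -> set:
    """All 4-subsets whose circumsphere is empty of the other points."""
    n = len(pts)
    tets = set()
    for quad in combinations(range(n), 4):
        p = pts[list(quad)]
        d = p[1:] - p[0]
        if abs(np.linalg.det(d)) < 1e-12:
            continue
        rhs = ((p[1:] ** 2).sum(1) - (p[0] ** 2).sum()) / 2
        c = np.linalg.solve(d, rhs)
        r2 = ((c - p[0]) ** 2).sum()
        if all(((pts[q] - c) ** 2).sum() >= r2 - 1e-9
               for q in range(n) if q not in quad):
            tets.add(tuple(sorted(quad)))
    return tets


def brute_force_membership(tri):
    """Dual-complex membership recomputed per simplex with the attachment
    test run against ALL points, then closed under faces."""
    n = tri.n_points
    tet_m = tri.sizes <= 0
    tris, edges, verts = set(), set(), set()
    for t in tri.tetra:
        s = sorted(int(x) for x in t)
        tris.update(combinations(s, 3))
        edges.update(combinations(s, 2))
        verts.update(s)

    def direct(simplex) -> bool:
        c, size = _simplex_orthocenter(tri.centers[list(simplex)],
                                       tri.weights[list(simplex)])
        if size > 0:
            return False
        return all(((tri.centers[q] - c) ** 2).sum() - tri.weights[q]
                   >= size - 1e-12
                   for q in range(n) if q not in simplex)

    tri_m = {}
    for s in tris:
        face = any(tet_m[i] and set(s) <= set(map(int, tri.tetra[i]))
                   for i in range(len(tri.tetra)))
        tri_m[s] = face or direct(s)
    edge_m = {}
    for s in edges:
        face = any(m and set(s) <= set(t) for t, m in tri_m.items())
        edge_m[s] = face or direct(s)
    vert_m = {}
    for v in verts:
        face = any(m and v in e for e, m in edge_m.items())
        vert_m[v] = face or direct((v,))
    return tet_m, tri_m, edge_m, vert_m


def rejection_volume(tet_coords, centers, radii, n_samples, seed):
    """Uniform box rejection-sampling estimate of the empty volume inside
    the tetrahedra, with a binomial standard error.

    Points are bucketed by an x-sort so each tetrahedron only inspects its
    own x-slab; the estimator itself is plain rejection sampling.
    """
    rng = np.random.default_rng(seed)
    flat = tet_coords.reshape(-1, 3)
    lo, hi = flat.min(axis=0), flat.max(axis=0)
    box = float(np.prod(hi - lo))
    edges = np.transpose(tet_coords[:, 1:] - tet_coords[:, :1], (0, 2, 1))
    good = np.abs(np.linalg.det(edges)) > 1e-12
    invs = np.linalg.inv(edges[good])
    origins = tet_coords[good, 0]
    bb_lo = tet_coords[good].min(axis=1)
    bb_hi = tet_coords[good].max(axis=1)

    hits = 0
    chunk = 500_000
    remaining = n_samples
    r2 = np.asarray(radii) ** 2
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(m, 3))
        order = np.argsort(pts[:, 0], kind="stable")
        ps = pts[order]
        inside = np.zeros(m, dtype=bool)
        for inv, o, blo, bhi in zip(invs, origins, bb_lo, bb_hi):
            i0, i1 = np.searchsorted(ps[:, 0], (blo[0], bhi[0]))
            if i0 >= i1:
                continue
            slab = ps[i0:i1]
            cand = ((slab[:, 1] >= blo[1]) & (slab[:, 1] <= bhi[1])
                    & (slab[:, 2] >= blo[2]) & (slab[:, 2] <= bhi[2])
                    & ~inside[i0:i1])
            if not cand.any():
                continue
            bary = (slab[cand] - o) @ inv.T
            ok = (bary >= -1e-9).all(axis=1) & (bary.sum(axis=1) <= 1 + 1e-9)
            idx = i0 + np.flatnonzero(cand)[ok]
            inside[idx] = True
        if inside.any():
            p = ps[inside]
            c2 = np.einsum("ij,ij->i", centers, centers)
            for s0 in range(0, len(p), 50_000):
                q = p[s0:s0 + 50_000]
                d2 = (np.einsum("ij,ij->i", q, q)[:, None]
                      + c2[None] - 2.0 * q @ centers.T)
                hits += int((d2 >= r2[None]).all(axis=1).sum())
        remaining -= m
    p_hat = hits / n_samples
    est = box * p_hat
    se = box * math.sqrt(p_hat * (1 - p_hat) / n_samples)
    return est, se


def two_sphere_exposed_area(rho: float, d: float) -> float:
    """Exposed area of one of two equal spheres of radius rho at center
    distance d < 2 rho (full sphere minus the buried cap)."""
    return 4 * math.pi * rho ** 2 - 2 * math.pi * rho * (rho - d / 2)


# ---------------------------------------------------------------------------
# regular triangulation
# ---------------------------------------------------------------------------


def test_four_points_single_tetrahedron():
    pts = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]], float)
    tri = build_regular_triangulation(pts, np.ones(4))
    assert tri.n_tetrahedra == 1
    assert set(tri.tetra[0]) == {0, 1, 2, 3}


def test_centroid_of_regular_tetrahedron_splits_into_four():
    pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float) * 3
    pts = np.vstack([pts, pts.mean(axis=0)])
    tri = build_regular_triangulation(pts, np.zeros(5))
    oracle = brute_force_delaunay(pts + 1e-7 * np.arange(15).reshape(5, 3))
    mine = {tuple(sorted(t)) for t in tri.tetra.tolist()}
    assert len(mine) == 4
    assert all(4 in t for t in mine)          # every tet uses the centroid
    assert mine == oracle or len(oracle) == 4


def test_fewer_than_four_points_rejected():
    with pytest.raises(TriangulationError):
        build_regular_triangulation(np.zeros((3, 3)), np.zeros(3))


def test_coplanar_points_rejected():
    pts = np.random.default_rng(0).uniform(0, 5, (10, 2))
    pts3 = np.column_stack([pts, np.zeros(10)])
    with pytest.raises(TriangulationError):
        build_regular_triangulation(pts3, np.zeros(10))


@pytest.mark.parametrize("trial", range(10))
def test_equal_weight_triangulation_matches_brute_force_delaunay(trial):
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(8, 13))
    pts = rng.uniform(0, 10, (n, 3))
    tri = build_regular_triangulation(pts, np.zeros(n))
    mine = {tuple(sorted(t)) for t in tri.tetra.tolist()}
    assert mine == brute_force_delaunay(pts)


@pytest.mark.parametrize("trial", range(10))
def test_tetrahedra_tile_the_convex_hull(trial):
    rng = np.random.default_rng(200 + trial)
    pts = rng.uniform(0, 10, (20, 3))
    w = rng.uniform(0, 4, 20)
    tri = build_regular_triangulation(pts, w)
    hull = ConvexHull(pts).volume
    assert tri.tet_volumes().sum() == pytest.approx(hull, rel=1e-6)
    # each interior facet shared by exactly 2 tets is enforced in build;
    # here check neighbor symmetry
    for t in range(tri.n_tetrahedra):
        for k in range(4):
            nb = tri.neighbors[t, k]
            if nb >= 0:
                assert t in tri.neighbors[nb]


def test_redundant_point_carries_no_tetrahedra():
    # a tiny ball hidden deep inside a much larger one
    pts = np.array([[0, 0, 0], [0.1, 0, 0], [10, 0, 0], [0, 10, 0],
                    [0, 0, 10], [10, 10, 10]], float)
    w = np.array([25.0, 0.01, 1, 1, 1, 1])
    tri = build_regular_triangulation(pts, w)
    assert tri.redundant[1]
    assert not any(1 in t for t in tri.tetra.tolist())


# ---------------------------------------------------------------------------
# dual complex
# ---------------------------------------------------------------------------


def _pair_edge_size(d, r):
    """Orthosphere size of an edge between two balls of radius r at
    distance d (equal weights): (d/2)^2 - r^2."""
    return (d / 2) ** 2 - r ** 2


@pytest.mark.parametrize("d,member", [(2.0, True), (4.0, False)])
def test_overlapping_balls_edge_membership(d, member):
    # two r=1.5 balls plus far-away padding to allow a triangulation
    pts = np.array([[0, 0, 0], [d, 0, 0], [30, 30, 0], [30, 0, 30],
                    [0, 30, 30]], float)
    w = np.array([1.5 ** 2, 1.5 ** 2, 0.01, 0.01, 0.01])
    tri = build_regular_triangulation(pts, w)
    labels = build_dual_complex(tri)
    i = next(i for i, e in enumerate(labels.edges.tolist()) if e == [0, 1])
    assert bool(labels.edge_member[i]) is member
    assert (_pair_edge_size(d, 1.5) <= 0) is member


@pytest.mark.parametrize("trial", range(6))
def test_membership_matches_brute_force_per_simplex_oracle(trial):
    rng = np.random.default_rng(300 + trial)
    pts = rng.uniform(0, 8, (15, 3))
    w = rng.uniform(1.0, 3.0, 15) ** 2
    tri = build_regular_triangulation(pts, w)
    labels = build_dual_complex(tri)
    tet_m, tri_m, edge_m, vert_m = brute_force_membership(tri)
    np.testing.assert_array_equal(labels.tet_member, tet_m)
    for i, row in enumerate(labels.triangles.tolist()):
        assert tri_m[tuple(row)] == bool(labels.triangle_member[i])
    for i, row in enumerate(labels.edges.tolist()):
        assert edge_m[tuple(row)] == bool(labels.edge_member[i])
    for v, m in vert_m.items():
        assert m == bool(labels.vertex_member[v])


@pytest.mark.parametrize("trial", range(6))
def test_dual_complex_closed_under_faces(trial):
    rng = np.random.default_rng(400 + trial)
    pts = rng.uniform(0, 9, (18, 3))
    w = rng.uniform(0.5, 2.5, 18) ** 2
    tri = build_regular_triangulation(pts, w)
    labels = build_dual_complex(tri)
    tri_idx = {tuple(r): i for i, r in enumerate(labels.triangles.tolist())}
    edge_idx = {tuple(r): i for i, r in enumerate(labels.edges.tolist())}
    for t in np.flatnonzero(labels.tet_member):
        for face in combinations(sorted(map(int, tri.tetra[t])), 3):
            assert labels.triangle_member[tri_idx[face]]
    for i in np.flatnonzero(labels.triangle_member):
        for e in combinations(labels.triangles[i].tolist(), 2):
            assert labels.edge_member[edge_idx[tuple(sorted(e))]]
    for i in np.flatnonzero(labels.edge_member):
        for v in labels.edges[i]:
            assert labels.vertex_member[v]


# ---------------------------------------------------------------------------
# flow and pocket taxonomy
# ---------------------------------------------------------------------------


def _flow_for(structure, config=GeometryConfig()):
    w = config.effective_weights(structure.radii)
    tri = build_regular_triangulation(structure.coords, w,
                                      jitter_seed=config.jitter_seed)
    labels = build_dual_complex(tri)
    return tri, labels, classify_flow(tri, labels)


def test_convex_blob_has_no_pockets_or_voids(blob):
    structure, _ = blob
    pockets = detect_pockets(structure, GeometryConfig(mc_samples=2000))
    assert pockets == []


def test_shallow_depression_escapes_to_infinity(shallow):
    structure, _ = shallow
    pockets = detect_pockets(structure, GeometryConfig(mc_samples=2000))
    assert pockets == []


def test_cup_yields_one_pocket_with_mouth(cup, cup_pockets):
    structure, truth = cup
    assert len(cup_pockets) == 1
    p = cup_pockets[0]
    assert p.kind == "pocket"
    assert p.n_entrances >= 1
    assert wall_residue_recall(structure, truth, p) >= 0.9
    assert back_face_overlap(structure, truth, p) == 0


def test_sealed_cavity_yields_one_void_without_mouths(cavity, fast_config):
    structure, truth = cavity
    pockets = detect_pockets(structure, fast_config)
    assert len(pockets) == 1
    assert pockets[0].kind == "void"
    assert pockets[0].n_entrances == 0
    assert wall_residue_recall(structure, truth, pockets[0]) >= 0.9


def test_flow_labels_every_empty_tetrahedron_once(cup):
    structure, _ = cup
    tri, labels, flow = _flow_for(structure)
    empty = np.flatnonzero(~labels.tet_member)
    # every empty tet is escaped or in exactly one component
    counted = np.zeros(tri.n_tetrahedra, int)
    counted[flow.status == -2] += 1
    for tets in flow.component_tets:
        counted[tets] += 1
    assert (counted[empty] == 1).all()
    assert (counted[labels.tet_member] == 0).all()


def test_flow_fixpoint_is_escape_order_independent(cup):
    """A randomized-sweep reimplementation of the escape iteration reaches
    the same fixpoint as the FIFO queue."""
    structure, _ = cup
    tri, labels, flow = _flow_for(structure)
    from alphapocket.alpha_geometry import _obtuse_facets
    obtuse = _obtuse_facets(tri)
    m = tri.n_tetrahedra
    non_dual = np.zeros((m, 4), bool)
    for t in range(m):
        for k in range(4):
            non_dual[t, k] = not labels.is_dual_triangle(
                tri.facet_triangle(t, k))
    empty = ~labels.tet_member
    escaped = np.zeros(m, bool)
    rng = np.random.default_rng(7)
    changed = True
    while changed:
        changed = False
        for t in rng.permutation(m):
            if not empty[t] or escaped[t]:
                continue
            for k in range(4):
                if obtuse[t, k] and non_dual[t, k]:
                    nb = tri.neighbors[t, k]
                    if nb == -1 or escaped[nb]:
                        escaped[t] = True
                        changed = True
                        break
    np.testing.assert_array_equal(escaped, flow.status == -2)


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------


def test_volume_of_tetrahedron_with_zero_radius_balls_is_exact():
    tet = np.array([[[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]]], float)
    mv, se = pocket_volume(tet, np.zeros((0, 3)), np.zeros(0),
                           n_samples=1000, seed=0)
    assert mv == pytest.approx(4.5, abs=1e-12)
    assert se == 0.0


def test_cup_pocket_volume_matches_rejection_oracle(cup, cup_pockets):
    structure, _ = cup
    p = cup_pockets[0]
    w = GeometryConfig().effective_weights(structure.radii)
    tri = build_regular_triangulation(structure.coords, w)
    tet_coords = tri.centers[tri.tetra[p.tetrahedra]]
    mv, se = pocket_volume(tet_coords, structure.coords, structure.radii,
                           n_samples=40_000, seed=5)
    oracle, ose = rejection_volume(tet_coords, structure.coords,
                                   structure.radii, 2_000_000, seed=6)
    assert abs(mv - oracle) <= 3 * math.hypot(se, ose)


def test_volume_monotone_in_atom_radius(cavity, fast_config):
    structure, _ = cavity
    pockets = detect_pockets(structure, fast_config)
    p = pockets[0]
    w = fast_config.effective_weights(structure.radii)
    tri = build_regular_triangulation(structure.coords, w)
    tet_coords = tri.centers[tri.tetra[p.tetrahedra]]
    mv1, _ = pocket_volume(tet_coords, structure.coords, structure.radii,
                           n_samples=30_000, seed=1)
    mv2, _ = pocket_volume(tet_coords, structure.coords,
                           structure.radii + 0.1, n_samples=30_000, seed=1)
    assert mv2 < mv1


def test_volume_deterministic_given_seed(cup, cup_pockets):
    structure, _ = cup
    p = cup_pockets[0]
    w = GeometryConfig().effective_weights(structure.radii)
    tri = build_regular_triangulation(structure.coords, w)
    tc = tri.centers[tri.tetra[p.tetrahedra]]
    a = pocket_volume(tc, structure.coords, structure.radii,
                      n_samples=5000, seed=42)
    b = pocket_volume(tc, structure.coords, structure.radii,
                      n_samples=5000, seed=42)
    assert a == b


def test_volume_rejects_bad_sample_count():
    tet = np.zeros((1, 4, 3))
    tet[0, 1, 0] = tet[0, 2, 1] = tet[0, 3, 2] = 1.0
    with pytest.raises(ValueError):
        pocket_volume(tet, np.zeros((0, 3)), np.zeros(0), n_samples=0)


# ---------------------------------------------------------------------------
# area
# ---------------------------------------------------------------------------


def test_isolated_atom_full_sphere_area():
    centers = np.array([[0.0, 0.0, 0.0]])
    area = pocket_area(np.array([0]), centers, np.array([1.6]),
                       probe=1.4, n_points=2000, tet_coords=None)
    assert area == pytest.approx(4 * math.pi * 3.0 ** 2, rel=5e-3)


@pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
def test_two_sphere_area_matches_cap_closed_form(d):
    centers = np.array([[0.0, 0, 0], [d, 0, 0]])
    radii = np.array([1.6, 1.6])
    rho = 1.6 + 1.4
    per_atom = solvent_area(centers, radii, probe=1.4, n_points=4000)
    expected = two_sphere_exposed_area(rho, d)
    np.testing.assert_allclose(per_atom, expected, rtol=0.01)


def test_buried_atom_has_zero_accessible_area():
    shell = 3.4 * fibonacci_sphere(80)
    centers = np.vstack([[[0, 0, 0]], shell])
    radii = np.full(len(centers), 1.8)
    per_atom = solvent_area(centers, radii, probe=1.4, n_points=500)
    assert per_atom[0] == 0.0


def test_solvent_area_matches_biotite_reference():
    """Per-atom SASA of a random cluster agrees with an independent
    implementation (biotite's Shrake-Rupley) to within sampling error."""
    import biotite.structure as struc
    rng = np.random.default_rng(9)
    n = 40
    coords = rng.uniform(0, 12, (n, 3))
    radii = np.full(n, 1.7)
    mine = solvent_area(coords, radii, probe=1.4, n_points=2000)
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(["C"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["ALA"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.chain_id = np.array(["A"] * n)
    ref = struc.sasa(arr, probe_radius=1.4, point_number=2000,
                     vdw_radii=radii)
    np.testing.assert_allclose(mine, ref, rtol=0.01, atol=1.0)


def test_pocket_area_converges_when_point_count_doubles(cup, cup_pockets):
    structure, _ = cup
    p = cup_pockets[0]
    w = GeometryConfig().effective_weights(structure.radii)
    tri = build_regular_triangulation(structure.coords, w)
    tc = tri.centers[tri.tetra[p.tetrahedra]]
    a1 = pocket_area(p.wall_atoms, structure.coords, structure.radii,
                     probe=1.4, n_points=256, tet_coords=tc)
    a2 = pocket_area(p.wall_atoms, structure.coords, structure.radii,
                     probe=1.4, n_points=512, tet_coords=tc)
    assert a1 > 0
    assert abs(a2 - a1) / a1 < 0.02


# ---------------------------------------------------------------------------
# rigid invariance and determinism of the full pipeline
# ---------------------------------------------------------------------------


def test_measurements_invariant_under_rigid_transform(cup):
    # high MC sampling so the comparison probes geometry, not MC noise
    structure, _ = cup
    config = GeometryConfig(mc_samples=200_000, sphere_points=2048)
    ref = detect_pockets(structure, config)[0]
    R = Rotation.from_rotvec([0.4, -1.1, 0.7]).as_matrix()
    moved = structure.with_coords(structure.coords @ R.T + [11.0, -5.0, 3.0])
    pockets = detect_pockets(moved, config)
    assert len(pockets) == 1
    assert abs(pockets[0].mv - ref.mv) / ref.mv < 0.005
    assert abs(pockets[0].saa - ref.saa) / ref.saa < 0.005


def test_detection_deterministic(cup, fast_config):
    structure, _ = cup
    a = detect_pockets(structure, fast_config)
    b = detect_pockets(structure, fast_config)
    assert len(a) == len(b)
    for pa, pb in zip(a, b):
        assert pa.mv == pb.mv
        assert pa.saa == pb.saa
        np.testing.assert_array_equal(pa.wall_atoms, pb.wall_atoms)
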