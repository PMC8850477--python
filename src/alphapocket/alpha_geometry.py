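"""Weighted alpha-shape geometry: pockets, voids and their measurement.

The geometric core of the package. Atoms are treated as weighted points
(weight = squared effective radius); their regular (power/weighted Delaunay)
triangulation is built by lifting to 4-D and taking the lower convex hull.
The dual complex at alpha = 0 marks the simplices covered by the union of
balls. Discrete flow then classifies the remaining empty tetrahedra: those
that can drain to infinity through locally widening gaps are discarded
(shallow depressions), while trapped basins become pockets (open to the
outside through one or more constricted mouths) or voids (fully sealed
cavities).

Measurements per pocket: molecular volume MV (Angstrom^3, empty space inside
the pocket tetrahedra outside the van der Waals balls, stratified Monte
Carlo) and solvent-accessible area SAA (Angstrom^2, exposed probe-expanded
sphere area of the wall atoms restricted to the pocket region,
Shrake-Rupley-style deterministic sampling).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .structure_io import Structure

__all__ = [
    "GeometryConfig",
    "RegularTriangulation",
    "DualComplexLabels",
    "FlowResult",
    "Pocket",
    "TriangulationError",
    "build_regular_triangulation",
    "build_dual_complex",
    "classify_flow",
    "extract_pockets",
    "pocket_volume",
    "pocket_area",
    "solvent_area",
    "detect_pockets",
    "fibonacci_sphere",
    "points_in_tetrahedra",
]

OUTSIDE = -1  # neighbor sentinel: facet on the convex hull boundary
ESCAPED = -2  # flow status: drains to infinity


class TriangulationError(ValueError):
    """Raised when a regular triangulation cannot be built."""


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the pocket-detection pipeline.

    probe_radius : Angstrom; added to every vdW radius in "accessible" mode
        (default 1.4, a water probe).
    mode : "accessible" builds the triangulation and flow on probe-expanded
        balls; "molecular" uses bare vdW balls.
    min_pocket_volume : Angstrom^3; pockets with smaller MV are dropped
        (suppresses sliver artifacts).
    mc_samples : Monte Carlo samples per pocket for MV.
    sphere_points : Shrake-Rupley points per atom for SAA.
    seed : base seed for the MV estimator.
    jitter_seed : seed of the deterministic symbolic-perturbation jitter.
    """

    probe_radius: float = 1.4
    mode: Literal["accessible", "molecular"] = "accessible"
    min_pocket_volume: float = 10.0
    mc_samples: int = 100_000
    sphere_points: int = 256
    seed: int = 0
    jitter_seed: int = 0

    def effective_weights(self, radii: np.ndarray) -> np.ndarray:
        if self.mode == "accessible":
            return (np.asarray(radii) + self.probe_radius) ** 2
        return np.asarray(radii, dtype=float) ** 2


# ---------------------------------------------------------------------------
# Regular triangulation
# ---------------------------------------------------------------------------

@dataclass
class RegularTriangulation:
    """Regular (weighted Delaunay) triangulation of weighted points.

    tetra : (m, 4) point indices, positively oriented.
    neighbors : (m, 4); ``neighbors[t, k]`` is the tetrahedron sharing the
        facet opposite vertex ``k`` of ``t``, or OUTSIDE (-1).
    orthocenters, sizes : per-tetrahedron orthosphere center and size
        (squared orthoradius; negative when the simplex is covered by balls).
    redundant : points hidden in the power diagram (carry no simplices).
    """

    centers: np.ndarray
    weights: np.ndarray
    tetra: np.ndarray
    neighbors: np.ndarray
    orthocenters: np.ndarray
    sizes: np.ndarray
    redundant: np.ndarray
    # caches populated by build_dual_complex
    _triangles: np.ndarray | None = field(default=None, repr=False)
    _tri_of_tet: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_points(self) -> int:
        return len(self.centers)

    @property
    def n_tetrahedra(self) -> int:
        return len(self.tetra)

    def tet_volumes(self) -> np.ndarray:
        v = self.centers[self.tetra]
        d = v[:, 1:] - v[:, :1]
        return np.abs(np.linalg.det(d)) / 6.0

    def facet_triangle(self, t: int, k: int) -> tuple[int, int, int]:
        """Sorted vertex triple of the facet of ``t`` opposite vertex ``k``."""
        verts = [int(x) for j, x in enumerate(self.tetra[t]) if j != k]
        return tuple(sorted(verts))  # type: ignore[return-value]


def _deterministic_jitter(n: int, seed: int, magnitude: float = 1e-6) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    return rng.uniform(-magnitude, magnitude, size=(n, 3))


def _simplex_orthocenter(p: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Orthocenter (in the simplex's affine hull) and size of one simplex.

    Works for any dimension 1..4 vertices: the orthocenter is the unique
    point of the affine hull with equal power distance to all vertices.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    k = len(p) - 1
    if k == 0:
        return p[0].copy(), -float(w[0])
    d = p[1:] - p[0]  # (k, 3)
    rhs = (np.einsum("ij,ij->i", p[1:], p[1:]) - w[1:]) \
        - (p[0] @ p[0] - w[0]) - 2.0 * d @ p[0]
    G = 2.0 * d @ d.T
    try:
        y = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError as exc:
        raise TriangulationError("degenerate simplex in orthocenter solve") from exc
    c = p[0] + y @ d
    size = float((c - p[0]) @ (c - p[0]) - w[0])
    return c, size


def _tet_orthocenters(centers: np.ndarray, weights: np.ndarray,
                      tetra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = centers[tetra]                       # (m, 4, 3)
    wv = weights[tetra]                      # (m, 4)
    d = v[:, 1:] - v[:, :1]                  # (m, 3, 3)
    lhs = 2.0 * d
    rhs = (np.einsum("mij,mij->mi", v[:, 1:], v[:, 1:]) - wv[:, 1:]) \
        - (np.einsum("mj,mj->m", v[:, 0], v[:, 0]) - wv[:, 0])[:, None]
    c = np.linalg.solve(lhs, rhs[..., None])[..., 0]   # (m, 3)
    diff = c - v[:, 0]
    sizes = np.einsum("mj,mj->m", diff, diff) - wv[:, 0]
    return c, sizes


def build_regular_triangulation(
    centers: np.ndarray,
    weights: np.ndarray,
    *,
    jitter_seed: int = 0,
) -> RegularTriangulation:
    """Build the regular triangulation of weighted points.

    Points are lifted to 4-D as (x, y, z, |x|^2 - w); the lower convex hull
    of the lifted set projects to the regular triangulation. Degeneracies
    (cospherical/coplanar subsets) are broken by a deterministic jitter of
    magnitude 1e-6 Angstrom derived from ``jitter_seed``. Points hidden in
    the power diagram are flagged redundant and carry no tetrahedra.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    weights = np.asarray(weights, dtype=float).reshape(-1)
    n = len(centers)
    if n < 4:
        raise TriangulationError(f"need at least 4 points, got {n}")
    if np.any(weights < 0):
        raise TriangulationError("weights must be non-negative")

    jittered = centers + _deterministic_jitter(n, jitter_seed)
    # reject (near-)coplanar inputs up front: the lifted hull would only
    # produce slivers of thickness comparable to the jitter
    sv = np.linalg.svd(jittered - jittered.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-4:     # Angstrom scale: thinner than any real atom set
        raise TriangulationError("all points coplanar after jitter")
    if n == 4:
        det = np.linalg.det(jittered[1:] - jittered[0])
        if abs(det) < 1e-9:
            raise TriangulationError("four coplanar points")
        tetra = np.array([[0, 1, 2, 3]] if det > 0 else [[0, 1, 3, 2]])
        orthocenters, sizes = _tet_orthocenters(jittered, weights, tetra)
        return RegularTriangulation(
            centers=jittered, weights=weights, tetra=tetra,
            neighbors=np.full((1, 4), OUTSIDE, dtype=int),
            orthocenters=orthocenters, sizes=sizes,
            redundant=np.zeros(4, dtype=bool))
    lifted = np.column_stack([
        jittered,
        np.einsum("ij,ij->i", jittered, jittered) - weights,
    ])
    try:
        hull = ConvexHull(lifted, qhull_options="Qt")
    except QhullError as exc:
        raise TriangulationError(
            "degenerate point set (coplanar after jitter?)") from exc

    lower = hull.equations[:, 3] < -1e-12
    tetra = hull.simplices[lower]
    if len(tetra) == 0:
        raise TriangulationError("no lower-hull facets: degenerate input")

    # enforce positive orientation in 3-D
    v = jittered[tetra]
    dets = np.linalg.det(v[:, 1:] - v[:, :1])
    flip = dets < 0
    tetra = tetra.copy()
    tetra[flip, 2], tetra[flip, 3] = tetra[flip, 3].copy(), tetra[flip, 2].copy()

    # neighbor map via shared facets (vectorized over the 4m facet slots)
    m = len(tetra)
    neighbors = np.full((m, 4), OUTSIDE, dtype=int)
    facet_rows = np.concatenate(
        [np.sort(np.delete(tetra, k, axis=1), axis=1) for k in range(4)])
    owner_t = np.tile(np.arange(m), 4)
    owner_k = np.repeat(np.arange(4), m)
    _, inverse, counts = np.unique(facet_rows, axis=0, return_inverse=True,
                                   return_counts=True)
    if counts.max() > 2:
        raise TriangulationError("facet shared by more than 2 tetrahedra")
    order = np.argsort(inverse, kind="stable")
    sorted_inv = inverse[order]
    starts = np.flatnonzero(np.r_[True, sorted_inv[1:] != sorted_inv[:-1]])
    paired = starts[counts[sorted_inv[starts]] == 2]
    a, b = order[paired], order[paired + 1]
    neighbors[owner_t[a], owner_k[a]] = owner_t[b]
    neighbors[owner_t[b], owner_k[b]] = owner_t[a]

    orthocenters, sizes = _tet_orthocenters(jittered, weights, tetra)
    used = np.zeros(n, dtype=bool)
    used[np.unique(tetra)] = True
    return RegularTriangulation(
        centers=jittered,
        weights=weights,
        tetra=tetra,
        neighbors=neighbors,
        orthocenters=orthocenters,
        sizes=sizes,
        redundant=~used,
    )


# ---------------------------------------------------------------------------
# Dual complex (alpha = 0)
# ---------------------------------------------------------------------------

@dataclass
class DualComplexLabels:
    """Membership of every simplex in the alpha complex at alpha = 0.

    A simplex belongs to the complex iff its orthosphere size is <= 0 and it
    is unattached, or it is a face of a member (closure under faces).
    """

    tet_member: np.ndarray                       # (m,) bool
    triangles: np.ndarray                        # (T, 3) sorted vertex triples
    triangle_member: np.ndarray                  # (T,) bool
    triangle_index: dict[tuple[int, int, int], int]
    edges: np.ndarray                            # (E, 2)
    edge_member: np.ndarray                      # (E,) bool
    vertex_member: np.ndarray                    # (n,) bool

    def is_dual_triangle(self, key: tuple[int, int, int]) -> bool:
        idx = self.triangle_index.get(key)
        return bool(self.triangle_member[idx]) if idx is not None else False


def _attached(c: np.ndarray, size: float, centers: np.ndarray,
              weights: np.ndarray, candidates: Iterable[int]) -> bool:
    """A simplex is attached iff some candidate point has power < size
    relative to the simplex orthosphere."""
    for q in candidates:
        d = centers[q] - c
        if float(d @ d) - weights[q] < size - 1e-12:
            return True
    return False


def _batched_sub_orthocenters(centers: np.ndarray, weights: np.ndarray,
                              simplices: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Orthocenters/sizes for a batch of k-simplices (k = 1 or 2)."""
    p = centers[simplices]                   # (S, k+1, 3)
    w = weights[simplices]                   # (S, k+1)
    d = p[:, 1:] - p[:, :1]                  # (S, k, 3)
    rhs = (np.einsum("sij,sij->si", p[:, 1:], p[:, 1:]) - w[:, 1:]) \
        - (np.einsum("sj,sj->s", p[:, 0], p[:, 0]) - w[:, 0])[:, None] \
        - 2.0 * np.einsum("skj,sj->sk", d, p[:, 0])
    G = 2.0 * np.einsum("saj,sbj->sab", d, d)
    y = np.linalg.solve(G, rhs[..., None])[..., 0]
    c = p[:, 0] + np.einsum("sk,skj->sj", y, d)
    diff = c - p[:, 0]
    sizes = np.einsum("sj,sj->s", diff, diff) - w[:, 0]
    return c, sizes


_EPS_ATTACH = 1e-12


def build_dual_complex(tri: RegularTriangulation) -> DualComplexLabels:
    """Label every simplex of the triangulation at alpha = 0."""
    centers, weights, tetra = tri.centers, tri.weights, tri.tetra
    m = len(tetra)
    tet_member = tri.sizes <= 0.0

    # --- triangles: all facets of all tets, deduplicated --------------------
    facet_rows = np.concatenate(
        [np.sort(np.delete(tetra, k, axis=1), axis=1) for k in range(4)])
    opp_vertex = np.concatenate([tetra[:, k] for k in range(4)])
    coface_tet = np.tile(np.arange(m), 4)
    triangles, inverse = np.unique(facet_rows, axis=0, return_inverse=True)
    T = len(triangles)

    tri_c, tri_size = _batched_sub_orthocenters(centers, weights, triangles)
    # attachment: candidates are the opposite vertices of cofacing tets
    dq = centers[opp_vertex] - tri_c[inverse]
    power = np.einsum("sj,sj->s", dq, dq) - weights[opp_vertex]
    occ_attached = power < tri_size[inverse] - _EPS_ATTACH
    tri_attached = np.zeros(T, dtype=bool)
    np.logical_or.at(tri_attached, inverse, occ_attached)
    # face of a member tetrahedron
    tri_face_of_member = np.zeros(T, dtype=bool)
    np.logical_or.at(tri_face_of_member, inverse, tet_member[coface_tet])
    triangle_member = tri_face_of_member | ((tri_size <= 0.0) & ~tri_attached)
    triangle_index = {tuple(int(v) for v in row): i
                      for i, row in enumerate(triangles)}

    # --- edges ---------------------------------------------------------------
    pair_idx = [(a, b) for a in range(4) for b in range(a + 1, 4)]
    edge_rows = np.concatenate(
        [np.sort(tetra[:, [a, b]], axis=1) for a, b in pair_idx])
    edge_coface_tet = np.tile(np.arange(m), 6)
    # per occurrence, the two tet vertices NOT in the edge
    other_idx = [tuple(j for j in range(4) if j not in (a, b))
                 for a, b in pair_idx]
    edge_others = np.concatenate(
        [tetra[:, list(oi)] for oi in other_idx])           # (6m, 2)
    edges, e_inverse = np.unique(edge_rows, axis=0, return_inverse=True)
    E = len(edges)

    edge_c, edge_size = _batched_sub_orthocenters(centers, weights, edges)
    dq = centers[edge_others] - edge_c[e_inverse][:, None, :]
    power = np.einsum("soj,soj->so", dq, dq) - weights[edge_others]
    occ_attached = (power < (edge_size[e_inverse] - _EPS_ATTACH)[:, None]
                    ).any(axis=1)
    edge_attached = np.zeros(E, dtype=bool)
    np.logical_or.at(edge_attached, e_inverse, occ_attached)
    # face of a member triangle: scatter member triangles' edges
    edge_key = edges[:, 0].astype(np.int64) * tri.n_points + edges[:, 1]
    key_order = np.argsort(edge_key)
    member_tris = triangles[triangle_member]
    edge_face_of_member = np.zeros(E, dtype=bool)
    if len(member_tris):
        for a, b in ((0, 1), (0, 2), (1, 2)):
            mk = member_tris[:, a].astype(np.int64) * tri.n_points \
                + member_tris[:, b]
            pos = key_order[np.searchsorted(edge_key[key_order], mk)]
            edge_face_of_member[pos] = True
    edge_member = edge_face_of_member | ((edge_size <= 0.0) & ~edge_attached)

    # --- vertices ------------------------------------------------------------
    n = tri.n_points
    both = np.concatenate([edges, edges[:, ::-1]])          # (2E, 2) v -> q
    dq = centers[both[:, 1]] - centers[both[:, 0]]
    power = np.einsum("sj,sj->s", dq, dq) - weights[both[:, 1]]
    occ_attached = power < (-weights[both[:, 0]]) - _EPS_ATTACH
    vertex_attached = np.zeros(n, dtype=bool)
    np.logical_or.at(vertex_attached, both[:, 0], occ_attached)
    vertex_face_of_member = np.zeros(n, dtype=bool)
    me = edges[edge_member]
    vertex_face_of_member[me.ravel()] = True
    vertex_member = ~tri.redundant & (vertex_face_of_member | ~vertex_attached)

    return DualComplexLabels(
        tet_member=tet_member,
        triangles=triangles,
        triangle_member=triangle_member,
        triangle_index=triangle_index,
        edges=edges,
        edge_member=edge_member,
        vertex_member=vertex_member,
    )


# ---------------------------------------------------------------------------
# Discrete flow
# ---------------------------------------------------------------------------

@dataclass
class FlowResult:
    """Classification of empty tetrahedra by discrete flow.

    status : per tetrahedron: ESCAPED (-2) for drained tetrahedra, a
        component id >= 0 for trapped ones, and -3 for dual-complex members
        (not empty space).
    component_kind : per component, "pocket" or "void".
    mouth_facets : per component, list of (tet, facet) pairs through which a
        pocket touches escaped space.
    escape_order : tetrahedron indices in the order they escaped (debugging).
    """

    status: np.ndarray
    component_tets: list[np.ndarray]
    component_kind: list[str]
    mouth_facets: list[list[tuple[int, int]]]
    escape_order: list[int]


FILLED = -3


def _obtuse_facets(tri: RegularTriangulation) -> np.ndarray:
    """(m, 4) bool: facet k of tet t is obtuse iff the orthocenter of t lies
    strictly on the far side of the facet plane from the opposite vertex."""
    m = len(tri.tetra)
    out = np.zeros((m, 4), dtype=bool)
    v = tri.centers[tri.tetra]        # (m, 4, 3)
    for k in range(4):
        idx = [j for j in range(4) if j != k]
        p0 = v[:, idx[0]]
        normal = np.cross(v[:, idx[1]] - p0, v[:, idx[2]] - p0)
        s_c = np.einsum("mj,mj->m", normal, tri.orthocenters - p0)
        s_d = np.einsum("mj,mj->m", normal, v[:, k] - p0)
        out[:, k] = (s_c * s_d) < 0.0   # strictly opposite sides
    return out


def classify_flow(tri: RegularTriangulation,
                  labels: DualComplexLabels) -> FlowResult:
    """Drain empty tetrahedra to infinity through obtuse non-dual facets;
    group the trapped remainder into pocket/void components.

    A tetrahedron escapes if it has an obtuse facet that is not a
    dual-complex triangle and that borders OUTSIDE or an already escaped
    tetrahedron; iteration runs to fixpoint (FIFO seeded at the hull
    boundary; the fixpoint is order-independent). Remaining empty
    tetrahedra form connected components via shared non-dual facets; a
    component touching escaped space (or OUTSIDE) through a non-dual facet
    is a pocket — those facets are its mouth candidates — otherwise a void.
    """
    m = len(tri.tetra)
    empty = ~labels.tet_member
    obtuse = _obtuse_facets(tri)
    # facet (t, k) -> dual-triangle membership, via the unique-triangle table
    facet_rows = np.concatenate(
        [np.sort(np.delete(tri.tetra, k, axis=1), axis=1) for k in range(4)])
    n = tri.n_points
    tri_key = (labels.triangles[:, 0].astype(np.int64) * n + labels.triangles[:, 1]
               ) * n + labels.triangles[:, 2]
    facet_key = (facet_rows[:, 0].astype(np.int64) * n + facet_rows[:, 1]
                 ) * n + facet_rows[:, 2]
    order = np.argsort(tri_key)
    pos = order[np.searchsorted(tri_key[order], facet_key)]
    non_dual = ~labels.triangle_member[pos].reshape(4, m).T

    escaped = np.zeros(m, dtype=bool)
    order: list[int] = []
    queue: deque[int] = deque()

    def try_escape(t: int) -> bool:
        for k in range(4):
            if not (obtuse[t, k] and non_dual[t, k]):
                continue
            nb = tri.neighbors[t, k]
            if nb == OUTSIDE or escaped[nb]:
                return True
        return False

    for t in range(m):
        if empty[t] and try_escape(t):
            escaped[t] = True
            queue.append(t)
            order.append(t)
    while queue:
        t = queue.popleft()
        for k in range(4):
            nb = tri.neighbors[t, k]
            if nb == OUTSIDE or escaped[nb] or not empty[nb]:
                continue
            if try_escape(nb):
                escaped[nb] = True
                queue.append(nb)
                order.append(nb)

    # connected components of trapped empty tetrahedra via non-dual facets
    status = np.full(m, FILLED, dtype=int)
    status[escaped] = ESCAPED
    comp_tets: list[np.ndarray] = []
    comp_kind: list[str] = []
    mouth_facets: list[list[tuple[int, int]]] = []
    unvisited = set(np.flatnonzero(empty & ~escaped).tolist())
    while unvisited:
        seed = min(unvisited)
        stack = [seed]
        unvisited.discard(seed)
        members = []
        mouths: list[tuple[int, int]] = []
        while stack:
            t = stack.pop()
            members.append(t)
            for k in range(4):
                if not non_dual[t, k]:
                    continue
                nb = tri.neighbors[t, k]
                if nb == OUTSIDE or escaped[nb]:
                    mouths.append((t, k))
                elif empty[nb] and nb in unvisited:
                    unvisited.discard(nb)
                    stack.append(nb)
        cid = len(comp_tets)
        members_arr = np.array(sorted(members), dtype=int)
        status[members_arr] = cid
        comp_tets.append(members_arr)
        comp_kind.append("pocket" if mouths else "void")
        mouth_facets.append(mouths)

    return FlowResult(
        status=status,
        component_tets=comp_tets,
        component_kind=comp_kind,
        mouth_facets=mouth_facets,
        escape_order=order,
    )


# ---------------------------------------------------------------------------
# Pocket extraction and measurement
# ---------------------------------------------------------------------------

@dataclass
class Pocket:
    """A classified cavity with its geometry and measurements."""

    id: int
    kind: str                                   # "pocket" or "void"
    tetrahedra: np.ndarray                      # triangulation tet indices
    wall_atoms: np.ndarray                      # atom indices
    wall_residues: list[tuple[str, int, str, str]]
    mouths: list[list[tuple[int, int]]]         # connected (tet, facet) groups
    mv: float                                   # molecular volume, A^3
    mv_se: float
    saa: float                                  # solvent-accessible area, A^2

    @property
    def n_entrances(self) -> int:
        return len(self.mouths)


def _group_mouth_facets(tri: RegularTriangulation,
                        facets: Sequence[tuple[int, int]]
                        ) -> list[list[tuple[int, int]]]:
    """Connected components of mouth triangles (connected = share an edge)."""
    if not facets:
        return []
    tri_edges = []
    for (t, k) in facets:
        verts = tri.facet_triangle(t, k)
        tri_edges.append({tuple(sorted((verts[a], verts[b])))
                          for a in range(3) for b in range(a + 1, 3)})
    n = len(facets)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if tri_edges[i] & tri_edges[j]:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, int]]] = {}
    for i, f in enumerate(facets):
        groups.setdefault(find(i), []).append(f)
    return [sorted(g) for _, g in sorted(groups.items())]


def points_in_tetrahedra(points: np.ndarray, tet_coords: np.ndarray,
                         eps: float = 1e-9) -> np.ndarray:
    """Boolean mask: which ``points`` (P, 3) lie inside any of the
    tetrahedra (T, 4, 3)."""
    points = np.asarray(points, dtype=float)
    tet_coords = np.asarray(tet_coords, dtype=float)
    inside = np.zeros(len(points), dtype=bool)
    d = np.transpose(tet_coords[:, 1:] - tet_coords[:, :1], (0, 2, 1))
    dets = np.linalg.det(d)
    good = np.abs(dets) > 1e-12
    invs = np.linalg.inv(d[good])                # (T', 3, 3)
    origins = tet_coords[good, 0]
    for inv, o in zip(invs, origins):
        rem = ~inside
        if not rem.any():
            break
        bary = (points[rem] - o) @ inv.T         # (p, 3)
        ok = (bary >= -eps).all(axis=1) & (bary.sum(axis=1) <= 1.0 + eps)
        inside[np.flatnonzero(rem)[ok]] = True
    return inside


def _outside_balls(points: np.ndarray, centers: np.ndarray,
                   radii: np.ndarray, chunk: int = 20_000) -> np.ndarray:
    """Mask of points outside every ball (center, radius)."""
    out = np.ones(len(points), dtype=bool)
    c2 = np.einsum("ij,ij->i", centers, centers)
    r2 = np.asarray(radii) ** 2
    for s in range(0, len(points), chunk):
        pts = points[s:s + chunk]
        d2 = (np.einsum("ij,ij->i", pts, pts)[:, None]
              + c2[None] - 2.0 * pts @ centers.T)
        out[s:s + chunk] = (d2 >= r2[None, :]).all(axis=1)
    return out


def pocket_volume(
    tet_coords: np.ndarray,
    ball_centers: np.ndarray,
    ball_radii: np.ndarray,
    *,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Molecular volume of the space inside the tetrahedra and outside the
    balls, by stratified Monte Carlo.

    Samples are allocated to tetrahedra proportionally to their volume
    (largest-remainder rounding, at least one per tetrahedron) and drawn
    uniformly inside each via Dirichlet barycentric weights. Returns the
    estimate and its standard error; deterministic given ``seed``.
    """
    tet_coords = np.asarray(tet_coords, dtype=float)
    if tet_coords.ndim != 3 or len(tet_coords) == 0:
        raise ValueError("tet_coords must be a non-empty (T, 4, 3) array")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    d = tet_coords[:, 1:] - tet_coords[:, :1]
    vols = np.abs(np.linalg.det(d)) / 6.0
    total = float(vols.sum())
    if total <= 0:
        return 0.0, 0.0

    quota = n_samples * vols / total
    counts = np.floor(quota).astype(int)
    short = n_samples - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    counts = np.maximum(counts, 1)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA0]))
    ball_centers = np.asarray(ball_centers, dtype=float)
    ball_radii = np.asarray(ball_radii, dtype=float)
    total_n = int(counts.sum())
    reps = np.repeat(np.arange(len(counts)), counts)
    bary = rng.standard_exponential(size=(total_n, 4))
    bary /= bary.sum(axis=1, keepdims=True)
    pts = np.einsum("pk,pkj->pj", bary, tet_coords[reps])
    if len(ball_centers):
        free = _outside_balls(pts, ball_centers, ball_radii)
    else:
        free = np.ones(total_n, dtype=bool)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    k = np.add.reduceat(free.astype(int), offsets)
    p_hat = k / counts
    est = float((vols * p_hat).sum())
    var = float((vols ** 2 * p_hat * (1.0 - p_hat) / counts).sum())
    return est, float(math.sqrt(var))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit sphere point set (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def pocket_area(
    wall_atoms: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    *,
    probe: float = 1.4,
    n_points: int = 256,
    tet_coords: np.ndarray | None = None,
) -> float:
    """Solvent-accessible area of the wall atoms, scoped to the pocket.

    Each wall atom's probe-expanded sphere is sampled with a deterministic
    Fibonacci point set; a point counts iff it lies outside every other
    expanded ball and (when ``tet_coords`` is given) inside the pocket's
    tetrahedra. Pass ``tet_coords=None`` to widen the scope to all space
    (standard per-atom SASA restricted to the chosen atoms).
    """
    centers = np.asarray(centers, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    unit = fibonacci_sphere(n_points)
    wall = np.asarray(wall_atoms, dtype=int)
    # exposure of all wall-sphere points in one pass; a point of atom i is
    # exposed iff no ball except i's own covers it
    pts_all = (centers[wall][:, None, :]
               + expanded[wall][:, None, None] * unit[None]).reshape(-1, 3)
    owner = np.repeat(wall, n_points)
    r2 = expanded ** 2
    c2 = np.einsum("ij,ij->i", centers, centers)
    keep_flat = np.empty(len(pts_all), dtype=bool)
    chunk = 20_000
    for s in range(0, len(pts_all), chunk):
        pts = pts_all[s:s + chunk]
        d2 = (np.einsum("ij,ij->i", pts, pts)[:, None]
              + c2[None] - 2.0 * pts @ centers.T)
        cover = d2 < r2[None]
        n_cover = cover.sum(axis=1)
        own = cover[np.arange(len(pts)), owner[s:s + chunk]]
        keep_flat[s:s + chunk] = (n_cover - own.astype(int)) == 0
    keep_all = keep_flat.reshape(len(wall), n_points)
    if tet_coords is not None:
        flat = np.flatnonzero(keep_all.ravel())
        in_tets = points_in_tetrahedra(pts_all[flat], tet_coords)
        mask = np.zeros(len(wall) * n_points, dtype=bool)
        mask[flat[in_tets]] = True
        keep_all &= mask.reshape(len(wall), n_points)
    per_atom = 4.0 * math.pi * expanded[wall] ** 2 \
        * keep_all.sum(axis=1) / n_points
    return float(per_atom.sum())


def solvent_area(
    centers: np.ndarray,
    radii: np.ndarray,
    *,
    probe: float = 1.4,
    n_points: int = 256,
) -> np.ndarray:
    """Whole-structure Shrake-Rupley solvent-accessible area per atom."""
    centers = np.asarray(centers, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    unit = fibonacci_sphere(n_points)
    areas = np.empty(len(centers))
    for i in range(len(centers)):
        rho = expanded[i]
        pts = centers[i] + rho * unit
        others = np.arange(len(centers)) != i
        if others.any():
            keep = _outside_balls(pts, centers[others], expanded[others])
            k = keep.sum()
        else:
            k = n_points
        areas[i] = 4.0 * math.pi * rho * rho * k / n_points
    return areas


def extract_pockets(
    tri: RegularTriangulation,
    labels: DualComplexLabels,
    flow: FlowResult,
    structure: Structure,
    *,
    config: GeometryConfig = GeometryConfig(),
) -> list[Pocket]:
    """Turn flow components into measured :class:`Pocket` records.

    One record per component, ordered by MV descending; wall atoms are the
    vertices of the component's tetrahedra; mouths are connected groups of
    non-dual boundary triangles facing escaped space. Components with
    MV below ``config.min_pocket_volume`` are dropped.
    """
    res_idx = structure.atom_residue_indices()
    res_keys = structure.residue_keys()
    pockets: list[Pocket] = []
    for cid, tets in enumerate(flow.component_tets):
        tet_coords = tri.centers[tri.tetra[tets]]
        mv, mv_se = pocket_volume(
            tet_coords, structure.coords, structure.radii,
            n_samples=config.mc_samples, seed=config.seed + cid)
        if mv < config.min_pocket_volume:
            continue
        wall = np.unique(tri.tetra[tets])
        wall_res = sorted({int(res_idx[a]) for a in wall})
        saa = pocket_area(
            wall, structure.coords, structure.radii,
            probe=config.probe_radius, n_points=config.sphere_points,
            tet_coords=tet_coords)
        pockets.append(Pocket(
            id=cid,
            kind=flow.component_kind[cid],
            tetrahedra=tets,
            wall_atoms=wall,
            wall_residues=[res_keys[r] for r in wall_res],
            mouths=_group_mouth_facets(tri, flow.mouth_facets[cid]),
            mv=mv,
            mv_se=mv_se,
            saa=saa,
        ))
    pockets.sort(key=lambda p: -p.mv)
    for new_id, p in enumerate(pockets):
        p.id = new_id
    return pockets


def detect_pockets(structure: Structure,
                   config: GeometryConfig = GeometryConfig()) -> list[Pocket]:
    """Full pipeline: triangulate, label, flow-classify and measure pockets
    of one structure (radii must be assigned)."""
    if np.any(~np.isfinite(structure.radii)):
        raise ValueError("structure has unassigned radii; call assign_radii first")
    weights = config.effective_weights(structure.radii)
    tri = build_regular_triangulation(
        structure.coords, weights, jitter_seed=config.jitter_seed)
    labels = build_dual_complex(tri)
    flow = classify_flow(tri, labels)
    return extract_pockets(tri, labels, flow, structure, config=config)
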