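"""Weighted alpha shapes via the regular (weighted Delaunay) triangulation.

A weighted point is a pair ``(p, w)`` — for an atom, ``p`` is its center and
``w = (r + probe)²`` its squared solvent-expanded radius.  The power distance
from ``x`` to ``(p, w)`` is ``|x - p|² - w``.  The regular triangulation is
the weighted analogue of the Delaunay triangulation: a tetrahedron belongs
to it iff its orthoball (the ball with zero power distance to all four
weighted vertices) has non-negative power distance to every other weighted
point.  It is computed here by the classical lifting map

    p  ↦  (p, |p|² − w)  ∈ R⁴

followed by the lower convex hull: lower-hull facets project exactly to the
regular triangulation's tetrahedra.

The alpha complex at filtration value ``alpha`` (Å²) keeps the tetrahedra
whose squared orthoradius is ≤ alpha.  ``alpha = 0`` — the default used
throughout this package — gives the "zero-shape" of the solvent-expanded
molecule, the standard alpha-shape model of a molecular surface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

__all__ = [
    "DegeneracyError", "RegularTriangulation", "AlphaComplex",
    "regular_triangulation", "weighted_alpha_complex", "surface_atoms",
    "orthoradius2", "build_alpha_complex", "brute_force_regular_tetrahedra",
]

#: Relative tolerance for power-distance predicates.
PREDICATE_RTOL = 1e-9


class DegeneracyError(ValueError):
    """Input too degenerate to triangulate (collinear/coplanar points)."""


def orthoradius2(points: np.ndarray, weights: np.ndarray) -> float:
    """Squared orthoradius of a k-simplex of weighted points.

    The orthoball is the unique ball (center in the simplex's affine hull)
    orthogonal to every weighted vertex: ``|c - p_i|² - w_i = r²`` for all i.
    For two equal-weight points at distance d this reduces to ``d²/4 - w``.
    The value may be negative (the simplex is then part of every alpha
    complex with alpha ≥ that value, including alpha = 0).
    """
    p = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.ndim != 2 or p.shape[0] < 1:
        raise ValueError("need at least one point")
    if p.shape[0] == 1:
        return float(-w[0])
    v = p[1:] - p[0]                       # (k, 3) affine basis
    # orthocenter c = p0 + v.T @ t ; orthogonality conditions give a k×k system
    g = v @ v.T
    rhs = 0.5 * ((np.sum(v * v, axis=1)) - (w[1:] - w[0]))
    try:
        t = np.linalg.solve(g, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegeneracyError("degenerate simplex (affinely dependent points)") from exc
    c = p[0] + t @ v
    return float(np.sum((c - p[0]) ** 2) - w[0])


@dataclass
class RegularTriangulation:
    """Regular triangulation of weighted points in 3D.

    ``tetrahedra`` is (M, 4) with positively oriented vertex indices;
    ``neighbors`` is (M, 4), entry j the face-adjacent tetrahedron opposite
    vertex j, or −1 on the boundary.  ``vertex_indices`` lists the input
    points that survive as vertices (redundant weighted points — those hidden
    under another point's power cell — do not).
    """

    points: np.ndarray
    weights: np.ndarray
    tetrahedra: np.ndarray
    vertex_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=int).reshape(-1, 4)
        self.vertex_indices = np.unique(self.tetrahedra)

    @cached_property
    def neighbors(self) -> np.ndarray:
        return _face_neighbors(self.tetrahedra)

    @property
    def n_tetrahedra(self) -> int:
        return self.tetrahedra.shape[0]

    @cached_property
    def orthoradii2(self) -> np.ndarray:
        """Squared orthoradius (filtration value) of each tetrahedron, Å²."""
        return _tet_orthoradius2_batch(self.points, self.weights, self.tetrahedra)


def _face_neighbors(tets: np.ndarray) -> np.ndarray:
    face_map: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
    for ti, tet in enumerate(tets):
        for j in range(4):
            face = tuple(sorted(np.delete(tet, j)))
            face_map.setdefault(face, []).append((ti, j))
    nbrs = np.full(tets.shape, -1, dtype=int)
    for owners in face_map.values():
        if len(owners) == 2:
            (t1, j1), (t2, j2) = owners
            nbrs[t1, j1] = t2
            nbrs[t2, j2] = t1
    return nbrs


def _orient_positive(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (points[tets[:, i]] for i in range(4))
    vol6 = np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a))
    flip = vol6 < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return tets


def _tet_orthoradius2_batch(points: np.ndarray, weights: np.ndarray,
                            tets: np.ndarray) -> np.ndarray:
    """Squared orthoradii; flat tetrahedra (zero volume, from cospherical
    clusters) get the limit value of their coplanar circle when the four
    weighted points admit a common orthoball, else +inf."""
    if tets.size == 0:
        return np.zeros(0)
    p = points[tets]                       # (M, 4, 3)
    w = weights[tets]                      # (M, 4)
    v = p[:, 1:, :] - p[:, :1, :]          # (M, 3, 3)
    g = np.einsum("mik,mjk->mij", v, v)
    rhs = 0.5 * (np.einsum("mik,mik->mi", v, v) - (w[:, 1:] - w[:, :1]))
    scale = float(np.abs(p).max() ** 2 + np.abs(w).max() + 1.0)
    vol6 = np.abs(np.einsum("mi,mi->m", v[:, 0], np.cross(v[:, 1], v[:, 2])))
    ok = vol6 > 1e-12 * (np.abs(p).max() + 1.0) ** 3
    r2 = np.full(tets.shape[0], np.inf)
    if np.any(ok):
        t = np.linalg.solve(g[ok], rhs[ok][..., None])[..., 0]
        c = p[ok, 0, :] + np.einsum("mi,mik->mk", t, v[ok])
        r2[ok] = np.einsum("mk,mk->m", c - p[ok, 0, :], c - p[ok, 0, :]) - w[ok, 0]
    for m in np.nonzero(~ok)[0]:
        t, *_ = np.linalg.lstsq(g[m], rhs[m], rcond=None)
        c = p[m, 0] + t @ v[m]
        power = np.einsum("ik,ik->i", c - p[m], c - p[m]) - w[m]
        if power.max() - power.min() <= 1e-6 * scale:
            r2[m] = power.mean()
    return r2


def regular_triangulation(points: np.ndarray, weights: np.ndarray, *,
                          jitter_seed: int | None = None) -> RegularTriangulation:
    """Compute the regular triangulation by lifted lower convex hull.

    Parameters
    ----------
    points, weights
        (N, 3) centers in Å and (N,) weights in Å².
    jitter_seed
        If given, coplanar/collinear degeneracies are resolved by one retry
        with seeded Gaussian jitter of 1e-6 Å; otherwise they raise
        :class:`DegeneracyError`.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if weights.shape != (points.shape[0],):
        raise ValueError("weights must be (N,)")
    n = points.shape[0]
    if n < 4:
        raise DegeneracyError(f"need ≥4 points, got {n}")
    if n == 4:  # the 4D lifted hull needs ≥5 points; a single tet is immediate
        p = points
        if abs(np.dot(p[1] - p[0], np.cross(p[2] - p[0], p[3] - p[0]))) < 1e-12:
            raise DegeneracyError("four coplanar points")
        tets = _orient_positive(points, np.arange(4, dtype=int).reshape(1, 4))
        return RegularTriangulation(points=points, weights=weights, tetrahedra=tets)
    # deterministic symbolic-perturbation-equivalent tie rule: a lexicographic
    # nudge of the lifted heights breaks every cosphericity, so the lower hull
    # is simplicial and globally conforming; membership tests below still use
    # the exact weights, so the nudge only resolves combinatorial ties
    height = np.sum(points ** 2, axis=1) - weights
    tie_eps = 1e-9 * max(1.0, float(np.abs(height).max()))
    lifted = np.column_stack([points, height - tie_eps * np.arange(1, n + 1)])
    try:
        hull = ConvexHull(lifted, qhull_options="Qt")
    except QhullError as exc:
        if _lifted_points_cohyperplanar(lifted):
            # all weighted points share one orthosphere: every triangulation
            # is regular, so the unweighted Delaunay triangulation serves
            try:
                dt = Delaunay(points)
            except QhullError:
                pass
            else:
                return RegularTriangulation(
                    points=points, weights=weights,
                    tetrahedra=_orient_positive(points, dt.simplices))
        if jitter_seed is not None:
            rng = np.random.default_rng(jitter_seed)
            jp = points + rng.normal(0.0, 1e-6, size=points.shape)
            tri = regular_triangulation(jp, weights, jitter_seed=None)
            return RegularTriangulation(points=points, weights=weights,
                                        tetrahedra=tri.tetrahedra)
        raise DegeneracyError(
            "points are affinely degenerate (coplanar/collinear); "
            "pass jitter_seed to resolve") from exc
    # lower-hull facets: outward normal points down in the lifted dimension
    lower = hull.equations[:, 3] < -PREDICATE_RTOL
    tets = hull.simplices[lower]
    if tets.size == 0:
        raise DegeneracyError("no lower-hull facets (degenerate input)")
    # zero-volume tetrahedra (cospherical+coplanar clusters) are kept: they
    # glue differently-split square faces so the face pairing stays conformal
    tets = _orient_positive(points, tets)
    return RegularTriangulation(points=points, weights=weights, tetrahedra=tets)


def _lifted_points_cohyperplanar(lifted: np.ndarray, rtol: float = 1e-9) -> bool:
    centered = lifted - lifted.mean(axis=0)
    scale = np.abs(centered).max() + 1e-300
    sv = np.linalg.svd(centered / scale, compute_uv=False)
    return sv[-1] <= rtol * sv[0]


def brute_force_regular_tetrahedra(points: np.ndarray, weights: np.ndarray,
                                   rtol: float = PREDICATE_RTOL) -> set[tuple[int, ...]]:
    """Reference oracle: enumerate all orthoball-empty tetrahedra.

    Checks every 4-subset: it belongs to the regular triangulation iff no
    other weighted point has power distance to its orthoball below the
    orthoball's own power level (orthoball emptiness).  O(n⁵); for tests on
    tiny instances only.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = points.shape[0]
    scale = float(np.max(np.abs(points)) ** 2 + np.max(np.abs(weights)) + 1.0)
    out: set[tuple[int, ...]] = set()
    for combo in itertools.combinations(range(n), 4):
        idx = np.array(combo)
        p = points[idx]
        if abs(np.dot(p[1] - p[0], np.cross(p[2] - p[0], p[3] - p[0]))) < 1e-12:
            continue
        try:
            r2 = orthoradius2(p, weights[idx])
        except DegeneracyError:
            continue
        v = p[1:] - p[0]
        g = v @ v.T
        t = np.linalg.solve(g, 0.5 * (np.sum(v * v, axis=1) - (weights[idx][1:] - weights[idx][0])))
        c = p[0] + t @ v
        others = np.setdiff1d(np.arange(n), idx)
        power = np.sum((points[others] - c) ** 2, axis=1) - weights[others]
        if np.all(power >= r2 - rtol * scale):
            out.add(tuple(sorted(combo)))
    return out


@dataclass
class AlphaComplex:
    """Classified tetrahedra of a weighted alpha shape at one alpha value.

    ``member_mask`` flags tetrahedra with squared orthoradius ≤ alpha;
    ``boundary_triangles`` are faces incident to exactly one member
    tetrahedron; ``surface_vertices`` touch a boundary triangle;
    ``singular_vertices`` are triangulation vertices with no incident member
    tetrahedron (isolated atoms or thin protrusions).  Vertices hidden from
    the triangulation (redundant weighted points) belong to neither set.
    """

    triangulation: RegularTriangulation
    alpha: float
    member_mask: np.ndarray
    boundary_triangles: np.ndarray
    surface_vertices: frozenset[int]
    singular_vertices: frozenset[int]

    @property
    def points(self) -> np.ndarray:
        return self.triangulation.points

    @property
    def member_tetrahedra(self) -> np.ndarray:
        return self.triangulation.tetrahedra[self.member_mask]

    @cached_property
    def _incidence(self) -> dict[int, np.ndarray]:
        member_ids = np.nonzero(self.member_mask)[0]
        tets = self.triangulation.tetrahedra[member_ids]
        verts = tets.ravel()
        tis = np.repeat(member_ids, 4)
        order = np.argsort(verts, kind="stable")
        verts, tis = verts[order], tis[order]
        uniq, starts = np.unique(verts, return_index=True)
        bounds = np.append(starts, verts.size)
        return {int(v): tis[bounds[i]:bounds[i + 1]]
                for i, v in enumerate(uniq)}

    def incident_member_tetrahedra(self, vertex: int) -> np.ndarray:
        """Indices (into the triangulation) of member tetrahedra at *vertex*."""
        return self._incidence.get(int(vertex), np.zeros(0, dtype=int))

    def is_vertex(self, i: int) -> bool:
        return bool(np.isin(i, self.triangulation.vertex_indices))


def weighted_alpha_complex(tri: RegularTriangulation, alpha: float = 0.0) -> AlphaComplex:
    """Alpha complex of a regular triangulation at filtration value *alpha* (Å²).

    A tetrahedron is a member iff its squared orthoradius ≤ alpha
    (``alpha = inf`` keeps everything — the convex hull).
    """
    r2 = tri.orthoradii2
    if math.isinf(alpha):
        member = np.ones(tri.n_tetrahedra, dtype=bool)
    else:
        member = r2 <= alpha + PREDICATE_RTOL * (1.0 + abs(alpha))
    mtets = tri.tetrahedra[member]
    if mtets.size:
        faces = mtets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
        faces = np.sort(faces, axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        boundary = uniq[counts == 1]
    else:
        boundary = np.zeros((0, 3), dtype=int)
    surface = frozenset(int(v) for v in np.unique(boundary)) if boundary.size else frozenset()
    member_verts = set(int(v) for v in np.unique(tri.tetrahedra[member])) if member.any() else set()
    singular = frozenset(int(v) for v in tri.vertex_indices
                         if int(v) not in member_verts)
    return AlphaComplex(triangulation=tri, alpha=alpha, member_mask=member,
                        boundary_triangles=boundary,
                        surface_vertices=surface, singular_vertices=singular)


def surface_atoms(ac: AlphaComplex) -> set[int]:
    """Vertices on the alpha-shape surface: boundary-triangle vertices plus
    singular vertices.  Atoms buried under member tetrahedra on all sides are
    excluded, as are redundant (hidden) weighted points."""
    return set(ac.surface_vertices) | set(ac.singular_vertices)


@dataclass
class _EmptyComplex(AlphaComplex):
    """Degenerate complex for <4 or affinely dependent points: no tetrahedra,
    every point a singular (hence surface) vertex."""


def build_alpha_complex(points: np.ndarray, weights: np.ndarray,
                        alpha: float = 0.0, *, jitter_seed: int = 0) -> AlphaComplex:
    """Triangulate and classify in one step, tolerating degenerate input.

    Fewer than four points, or affinely dependent points that still fail
    after seeded jitter, yield a complex with no tetrahedra in which every
    atom is singular (an isolated sphere, maximally convex).
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    try:
        tri = regular_triangulation(points, weights, jitter_seed=jitter_seed)
    except DegeneracyError:
        tri = RegularTriangulation(points=points, weights=weights,
                                   tetrahedra=np.zeros((0, 4), dtype=int))
        return _EmptyComplex(
            triangulation=tri, alpha=alpha,
            member_mask=np.zeros(0, dtype=bool),
            boundary_triangles=np.zeros((0, 3), dtype=int),
            surface_vertices=frozenset(),
            singular_vertices=frozenset(range(points.shape[0])))
    return weighted_alpha_complex(tri, alpha)


def boundary_off_mesh(ac: AlphaComplex) -> str:
    """OFF-format mesh of the boundary triangles, for visual inspection."""
    pts = ac.points
    tris = ac.boundary_triangles
    lines = ["OFF", f"{pts.shape[0]} {tris.shape[0]} 0"]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in pts]
    lines += [f"3 {a} {b} {c}" for a, b, c in tris]
    return "\n".join(lines) + "\n"
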