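"""Distance-geometry reconstruction of 3-4 labeled points from FRET peaks.

Peak efficiencies are converted to distances through the Foerster relation
r = R0 * (1/E - 1)^(1/6).  For three points the triangle is unique up to
rigid motion and reflection; for four points the six (possibly degenerate)
distances can be assigned to the edges of K4 in up to 30 dissimilar ways,
each of which is embedded in 3D.  The assignment whose edge lengths need to
change the least (RMS violation) to embed is reported as the reconstruction.

Also provided: generalized Procrustes alignment and averaging of shapes,
bootstrap uncertainty over molecules, rigid fitting to a reference structure
with a dye-linker offset, and calibration of the Foerster radius and linker
length against the B-DNA helix model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import least_squares, nnls

from .peaks import PeakSet, MultiplicityAssignment, degenerate_expansions, triangular_edge_count

K4_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_EDGE_INDEX = {e: i for i, e in enumerate(K4_EDGES)}
# action of the 24 vertex permutations on edge positions
_EDGE_PERMS = tuple(
    tuple(_EDGE_INDEX[tuple(sorted((sigma[i], sigma[j])))] for (i, j) in K4_EDGES)
    for sigma in itertools.permutations(range(4))
)
_EDGE_PERMS_NP = np.array(_EDGE_PERMS)


# ---------------------------------------------------------------------------
# Foerster model and distance sets


@dataclass(frozen=True)
class ForsterModel:
    """Foerster radius R0 (nm) and dye linker length (nm).

    Defaults: R0 = 5.4 nm (typical Cy3-Cy5) and a 1.8 nm average linker;
    both are configurable and can be calibrated with ``helix_calibrate``.
    """

    forster_radius: float = 5.4
    linker_length: float = 1.8

    def __post_init__(self):
        if self.forster_radius <= 0:
            raise ValueError("forster_radius must be > 0")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")

    def efficiency_to_distance(self, e):
        return fret_to_distance(e, self)

    def distance_to_efficiency(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ValueError("distance must be > 0")
        out = 1.0 / (1.0 + (r / self.forster_radius) ** 6)
        return float(out) if out.ndim == 0 else out


def fret_to_distance(e, model: ForsterModel):
    """Invert E = 1/(1+(r/R0)^6) to r = R0 * (1/E - 1)^(1/6)."""
    e = np.asarray(e, dtype=float)
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("efficiency must lie strictly in (0, 1)")
    r = model.forster_radius * (1.0 / e - 1.0) ** (1.0 / 6.0)
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class DistanceSet:
    """Labeled distances (nm) with integer multiplicities and uncertainties."""

    distances: tuple
    multiplicities: tuple = None
    sigmas: tuple = None

    def __post_init__(self):
        d = tuple(float(x) for x in self.distances)
        if len(d) == 0:
            raise ValueError("empty distance set")
        if any(x <= 0 for x in d):
            raise ValueError("distances must be > 0")
        object.__setattr__(self, "distances", d)
        mu = self.multiplicities
        mu = tuple(int(m) for m in mu) if mu is not None else tuple(1 for _ in d)
        if len(mu) != len(d) or any(m < 1 for m in mu):
            raise ValueError("multiplicities must align with distances and be >= 1")
        object.__setattr__(self, "multiplicities", mu)
        if self.sigmas is not None:
            object.__setattr__(self, "sigmas", tuple(float(s) for s in self.sigmas))

    @property
    def m(self) -> int:
        return sum(self.multiplicities)

    def expand(self) -> tuple:
        """Flat multiset of edge lengths, each distance repeated mu times."""
        out = []
        for d, mu in zip(self.distances, self.multiplicities):
            out.extend([d] * mu)
        return tuple(out)

    def with_multiplicities(self, mu) -> "DistanceSet":
        return DistanceSet(self.distances, tuple(mu), self.sigmas)


def peaks_to_distances(peakset: PeakSet, model: ForsterModel,
                       multiplicities=None) -> DistanceSet:
    """Convert fitted non-zero peaks to distances with delta-method errors.

    sigma_r = |dr/dE| * SEM(E), with dr/dE = -R0/(6 E^2) * (1/E - 1)^(-5/6).
    Uncertainties are reported, not used as embedding weights.
    """
    dists, sigs = [], []
    for p in peakset.peaks:
        r = fret_to_distance(p.mean, model)
        u = 1.0 / p.mean - 1.0
        drde = model.forster_radius / 6.0 * u ** (-5.0 / 6.0) / p.mean**2
        dists.append(r)
        sigs.append(abs(drde) * p.sem)
    return DistanceSet(tuple(dists), multiplicities, tuple(sigs))


# ---------------------------------------------------------------------------
# Shapes and the canonical frame


def pairwise_distances(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def distinct_distances(coords, decimals: int = 9):
    """Sorted distinct pairwise distances with their multiplicities."""
    d = pairwise_distances(coords)
    iu = np.triu_indices(len(coords), 1)
    vals, counts = np.unique(np.round(d[iu], decimals), return_counts=True)
    return vals, counts


def canonicalize(coords) -> np.ndarray:
    """Map coordinates to the canonical frame: vertex 1 at the origin,
    vertex 2 on +x, vertex 3 in the y >= 0 half of the xy-plane, vertex 4
    (if present) at z >= 0.  Idempotent; degenerate directions fall back to
    deterministic axes."""
    X = np.asarray(coords, dtype=float)
    X = X - X[0]
    n = X.shape[0]
    e1 = X[1] if n > 1 else np.array([1.0, 0.0, 0.0])
    n1 = np.linalg.norm(e1)
    e1 = e1 / n1 if n1 > 1e-12 else np.array([1.0, 0.0, 0.0])
    if n > 2:
        v = X[2] - (X[2] @ e1) * e1
    else:
        v = np.zeros(3)
    n2 = np.linalg.norm(v)
    if n2 > 1e-12:
        e2 = v / n2
    else:
        # collinear first three points: deterministic perpendicular
        trial = np.array([0.0, 1.0, 0.0]) if abs(e1[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
        e2 = trial - (trial @ e1) * e1
        e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    Y = X @ np.column_stack([e1, e2, e3])
    if n > 3 and Y[3, 2] < 0:
        Y[:, 2] = -Y[:, 2]
    Y[np.abs(Y) < 1e-12] = 0.0
    return Y


@dataclass(frozen=True)
class EdgeAssignment:
    """One assignment of six lengths to the edges of K4, stored in the order
    (0,1),(0,2),(0,3),(1,2),(1,3),(2,3) in canonical form under the 24
    vertex permutations."""

    lengths: tuple

    def __post_init__(self):
        L = tuple(float(x) for x in self.lengths)
        if len(L) != 6:
            raise ValueError("an edge assignment needs exactly 6 lengths")
        if any(x <= 0 for x in L):
            raise ValueError("edge lengths must be > 0")
        object.__setattr__(self, "lengths", L)

    def canonical_form(self) -> tuple:
        return min(tuple(self.lengths[i] for i in perm) for perm in _EDGE_PERMS)

    def distance_matrix(self) -> np.ndarray:
        d = np.zeros((4, 4))
        for (i, j), L in zip(K4_EDGES, self.lengths):
            d[i, j] = d[j, i] = L
        return d


@dataclass(frozen=True)
class ReconstructedShape:
    """Labeled 3D coordinates (nm) in the canonical frame with the RMS
    edge-length change needed to embed the target distances."""

    coords: np.ndarray
    residual: float
    assignment: EdgeAssignment | None = None
    multiplicities: tuple = None
    degenerate: bool = False

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        if self.residual < 0:
            raise ValueError("residual must be >= 0")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def realized_distances(self) -> np.ndarray:
        return pairwise_distances(self.coords)

    def sort_key(self) -> tuple:
        return tuple(np.round(self.coords.ravel(), 9))

    def mirrored(self) -> "ReconstructedShape":
        m = self.coords.copy()
        m[:, 2] = -m[:, 2]
        return ReconstructedShape(m, self.residual, self.assignment, self.multiplicities, self.degenerate)


def _edge_residual_matrix(coords, target: np.ndarray) -> float:
    realized = pairwise_distances(coords)
    n = target.shape[0]
    iu = np.triu_indices(n, 1)
    diff = realized[iu] - target[iu]
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# Triangle reconstruction


def reconstruct_triangle(d12: float, d13: float, d23: float) -> ReconstructedShape:
    """Embed three edge lengths as a planar triangle (unique up to rigid
    motion and reflection).  If the triangle inequality fails, the best
    collinear layout (least-squares over the three orderings) is returned
    with its RMS edge violation."""
    if min(d12, d13, d23) <= 0:
        raise ValueError("edge lengths must be > 0")
    target = np.zeros((3, 3))
    target[0, 1] = target[1, 0] = d12
    target[0, 2] = target[2, 0] = d13
    target[1, 2] = target[2, 1] = d23
    x3 = (d12**2 + d13**2 - d23**2) / (2.0 * d12)
    h2 = d13**2 - x3**2
    scale = max(d12, d13, d23)
    if h2 >= -1e-12 * scale**2:
        coords = np.array([[0.0, 0.0, 0.0], [d12, 0.0, 0.0], [x3, np.sqrt(max(h2, 0.0)), 0.0]])
        return ReconstructedShape(canonicalize(coords), _edge_residual_matrix(coords, target))
    # infeasible: least-violation collinear embedding; try each vertex as the
    # middle point and solve the two gaps by non-negative least squares
    best = None
    for middle in range(3):
        lo, hi = [v for v in range(3) if v != middle]
        A = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        b = np.array([target[lo, middle], target[middle, hi], target[lo, hi]])
        gaps, _ = nnls(A, b)
        pos = {lo: 0.0, middle: gaps[0], hi: gaps[0] + gaps[1]}
        coords = np.array([[pos[v], 0.0, 0.0] for v in range(3)])
        res = _edge_residual_matrix(coords, target)
        if best is None or res < best[0]:
            best = (res, coords)
    res, coords = best
    return ReconstructedShape(canonicalize(coords), res, degenerate=True)


# ---------------------------------------------------------------------------
# Quadrangle enumeration and embedding


def enumerate_assignments(lengths) -> list:
    """All dissimilar assignments of a 6-length multiset to the edges of K4.

    Assignments related by a vertex permutation are collapsed to one
    canonical representative; six distinct lengths give exactly
    6!/|Aut(K4)| = 720/24 = 30 classes.  Deterministic ascending order.
    """
    L = tuple(float(x) for x in lengths)
    if len(L) != 6:
        raise ValueError("exactly 6 lengths (with multiplicity) required")
    if any(x <= 0 for x in L):
        raise ValueError("lengths must be > 0")
    orders = np.array(sorted(set(itertools.permutations(L))))  # (N, 6)
    uniq = np.unique(orders[0])
    base = len(uniq)
    if base == 1:
        return [EdgeAssignment(tuple(orders[0]))]
    ranks = np.searchsorted(uniq, orders)  # (N, 6)
    permuted = ranks[:, _EDGE_PERMS_NP]  # (N, 24, 6)
    weights = base ** np.arange(5, -1, -1)
    codes = permuted @ weights  # (N, 24) lexicographic integer encoding
    min_idx = codes.argmin(axis=1)
    min_codes = codes[np.arange(len(orders)), min_idx]
    _, first = np.unique(min_codes, return_index=True)
    out = []
    for n in sorted(first):
        canon = tuple(orders[n][_EDGE_PERMS_NP[min_idx[n]]])
        out.append(EdgeAssignment(canon))
    out.sort(key=lambda a: a.lengths)
    return out


def _trilaterate(d: np.ndarray) -> np.ndarray:
    """Sequential placement of 4 points from a distance matrix; coordinates
    are exact when the distances are realizable in 3D, otherwise square roots
    are clamped at zero and the result is only a starting guess."""
    p = np.zeros((4, 3))
    d01 = d[0, 1]
    p[1, 0] = d01
    x2 = (d01**2 + d[0, 2] ** 2 - d[1, 2] ** 2) / (2.0 * d01)
    y2 = np.sqrt(max(d[0, 2] ** 2 - x2**2, 0.0))
    p[2] = (x2, y2, 0.0)
    x3 = (d01**2 + d[0, 3] ** 2 - d[1, 3] ** 2) / (2.0 * d01)
    if y2 > 1e-12:
        y3 = (d[0, 3] ** 2 - d[2, 3] ** 2 + x2**2 + y2**2 - 2.0 * x3 * x2) / (2.0 * y2)
    else:
        y3 = 0.0
    z3 = np.sqrt(max(d[0, 3] ** 2 - x3**2 - y3**2, 0.0))
    p[3] = (x3, y3, z3)
    return p


def _mds_start(d: np.ndarray) -> np.ndarray:
    """Classical multidimensional scaling: best rank-3 Gram approximation."""
    n = d.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:3]
    w3 = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(w3)[None, :]


def _coords_from_params(q: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, 0.0, 0.0], [q[0], 0.0, 0.0], [q[1], q[2], 0.0], [q[3], q[4], q[5]]]
    )


def _params_from_coords(p: np.ndarray) -> np.ndarray:
    c = canonicalize(p)
    return np.array([c[1, 0], c[2, 0], c[2, 1], c[3, 0], c[3, 1], c[3, 2]])


# gauge-fixed parametrization q -> coords: p0 = 0, p1 = (q0,0,0),
# p2 = (q1,q2,0), p3 = (q3,q4,q5); row = edge, col = param, entry = vertex
# coordinate the param drives (+ for i, - for j of edge (i,j))
_PARAM_VERTEX = ((1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (3, 2))


_EDGE_I = np.array([e[0] for e in K4_EDGES])
_EDGE_J = np.array([e[1] for e in K4_EDGES])
# J[k, p] = sign * u[k, axis]; precompute the sign and axis tables
_J_SIGN = np.zeros((6, 6))
_J_AXIS = np.zeros((6, 6), dtype=int)
for _k, (_i, _j) in enumerate(K4_EDGES):
    for _p, (_v, _ax) in enumerate(_PARAM_VERTEX):
        _J_AXIS[_k, _p] = _ax
        if _v == _i:
            _J_SIGN[_k, _p] = 1.0
        elif _v == _j:
            _J_SIGN[_k, _p] = -1.0
_ROWS = np.arange(6)[:, None]


def _resid_jac(q: np.ndarray, target: np.ndarray):
    p = _coords_from_params(q)
    diff = p[_EDGE_I] - p[_EDGE_J]
    r = np.sqrt((diff**2).sum(axis=1))
    f = r - target
    safe = np.where(r > 1e-12, r, 1.0)
    u = diff / safe[:, None]
    J = u[_ROWS, _J_AXIS] * _J_SIGN
    return f, J


def _lm_refine(q: np.ndarray, target: np.ndarray, max_iter: int = 60):
    """Levenberg-Marquardt stress minimization with an analytic Jacobian."""
    q = q.astype(float).copy()
    f, J = _resid_jac(q, target)
    cost = f @ f
    lam = 1e-3
    eye = np.eye(6)
    for _ in range(max_iter):
        g = J.T @ f
        if np.max(np.abs(g)) < 1e-10:
            break
        H = J.T @ J
        improved = False
        for _ in range(25):
            try:
                step = np.linalg.solve(H + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            fn, Jn = _resid_jac(q + step, target)
            cn = fn @ fn
            if cn < cost:
                gained = cost - cn
                q, f, J, cost = q + step, fn, Jn, cn
                lam = max(lam * 0.3, 1e-12)
                improved = gained > 1e-12 * (1.0 + cost)
                break
            lam *= 10.0
            if lam > 1e13:
                break
        if not improved or cost < 1e-26:
            break
    return q, float(np.sqrt(cost / 6.0))


def embed_assignment(assignment: EdgeAssignment, seed: int = 0, n_restarts: int = 10) -> ReconstructedShape:
    """Embed one edge assignment in 3D.

    Exact sequential trilateration is tried first; when the distances are
    not realizable, the coordinates minimizing the summed squared edge
    violations are found by Levenberg-Marquardt stress minimization from a
    classical-scaling start plus seeded random restarts (stopping early once
    restarts no longer improve).  The residual is the RMS difference between
    realized and target edge lengths.
    """
    d = assignment.distance_matrix()
    scale = float(np.mean(assignment.lengths))
    iu = np.triu_indices(4, 1)
    target = d[iu]

    tri = _trilaterate(d)
    res_tri = _edge_residual_matrix(tri, d)
    if res_tri <= 1e-10 * max(scale, 1.0):
        return ReconstructedShape(canonicalize(tri), res_tri, assignment)

    rng = np.random.default_rng(seed)
    q_a, res_a = _lm_refine(_params_from_coords(tri), target)
    best_q, best_res = (q_a, res_a) if res_a < res_tri else (_params_from_coords(tri), res_tri)
    if best_res > 1e-10 * max(scale, 1.0):
        q_b, res_b = _lm_refine(_params_from_coords(_mds_start(d)), target)
        if res_b < best_res - 1e-12:
            best_q, best_res = q_b, res_b
        # random restarts only when the two deterministic starts disagree
        # (for 4 points they almost always find the same minimum)
        if abs(res_a - res_b) > 1e-6 * max(best_res, 1e-30):
            stale = 0
            for _ in range(n_restarts):
                q, res = _lm_refine(rng.normal(0.0, scale, 6), target)
                if res < best_res - 1e-12:
                    best_q, best_res = q, res
                    stale = 0
                else:
                    stale += 1
                if best_res <= 1e-10 * max(scale, 1.0) or stale >= 2:
                    break
    if not np.isfinite(best_res):
        return ReconstructedShape(canonicalize(tri), float("inf"), assignment, degenerate=True)
    return ReconstructedShape(canonicalize(_coords_from_params(best_q)), best_res, assignment)


@dataclass
class ReconstructionResult:
    """Ranked embeddings; ``best`` is the minimum-violation shape and
    ``tied`` all shapes within the tie tolerance of it."""

    shapes: list
    tie_tol: float = 1e-6

    @property
    def best(self) -> ReconstructedShape:
        return self.shapes[0]

    @property
    def tied(self) -> list:
        r0 = self.shapes[0].residual
        return [s for s in self.shapes if s.residual - r0 <= self.tie_tol]


def reconstruct_best(ds: DistanceSet, n_sites: int | None = None, seed: int = 0,
                     tie_tol: float = 1e-6, n_restarts: int = 10) -> ReconstructionResult:
    """Reconstruct the minimum-violation shape from a distance set.

    With m = 3 distances the triangle is unique; with m = 6 every dissimilar
    edge assignment is embedded and ranked by residual.  When fewer distances
    than n(n-1)/2 are supplied, every multiplicity expansion from
    ``degenerate_expansions`` is searched as well.  Ties (residuals within
    ``tie_tol``) are ordered by lexicographically smallest canonical form.
    """
    if n_sites is None:
        if ds.m in (1, 3, 6):
            n_sites = {1: 2, 3: 3, 6: 4}[ds.m]
        else:
            raise ValueError("n_sites required when the distance count is not 1, 3 or 6")
    m_target = triangular_edge_count(n_sites)
    if ds.m == m_target:
        expansions = [ds.multiplicities]
    elif len(ds.distances) <= m_target and all(mu == 1 for mu in ds.multiplicities):
        expansions = [a.multiplicities for a in degenerate_expansions(len(ds.distances), n_sites)]
    else:
        raise ValueError(
            f"distance set has m={ds.m} edges but n_sites={n_sites} needs {m_target}"
        )
    shapes = []
    for mu in expansions:
        lengths = ds.with_multiplicities(mu).expand()
        if n_sites == 2:
            coords = np.array([[0.0, 0.0, 0.0], [lengths[0], 0.0, 0.0]])
            shapes.append(ReconstructedShape(coords, 0.0, multiplicities=mu))
        elif n_sites == 3:
            tri = reconstruct_triangle(*lengths)
            shapes.append(
                ReconstructedShape(tri.coords, tri.residual, multiplicities=mu, degenerate=tri.degenerate)
            )
        else:
            for a in enumerate_assignments(lengths):
                s = embed_assignment(a, seed=seed, n_restarts=n_restarts)
                shapes.append(
                    ReconstructedShape(s.coords, s.residual, a, multiplicities=mu, degenerate=s.degenerate)
                )
    shapes.sort(key=lambda s: (s.residual, s.sort_key()))
    return ReconstructionResult(shapes, tie_tol)


# ---------------------------------------------------------------------------
# Alignment, averaging, bootstrap


def _as_coords(shape) -> np.ndarray:
    return shape.coords if isinstance(shape, ReconstructedShape) else np.asarray(shape, dtype=float)


def superpose(X, Y, allow_reflection: bool = True):
    """Rigid superposition of X onto Y (optionally with reflection).

    Returns (rmsd, R, t) with X @ R + t ~= Y.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    R, _ = orthogonal_procrustes(Xc, Yc)
    if not allow_reflection and np.linalg.det(R) < 0:
        U, s, Vt = np.linalg.svd(Xc.T @ Yc)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ D @ Vt
    rmsd = float(np.sqrt(np.mean(np.sum((Xc @ R - Yc) ** 2, axis=1))))
    t = ym - xm @ R
    return rmsd, R, t


def align_and_average(shapes, allow_reflection: bool = True, max_iter: int = 100,
                      tol: float = 1e-12):
    """Generalized Procrustes analysis: translation + rotation (+ optional
    reflection), no scaling.  Returns the mean shape (canonical frame) and
    the per-shape RMSD to it."""
    coords = [_as_coords(s) for s in shapes]
    if len(coords) == 0:
        raise ValueError("need at least one shape")
    n_vert = {c.shape[0] for c in coords}
    if len(n_vert) != 1:
        raise ValueError("all shapes must have the same number of vertices")
    centered = [c - c.mean(axis=0) for c in coords]
    ref = centered[0].copy()
    aligned = centered
    for _ in range(max_iter):
        aligned = []
        for c in centered:
            _, R, _ = superpose(c, ref, allow_reflection)
            aligned.append(c @ R)
        new_ref = np.mean(aligned, axis=0)
        new_ref -= new_ref.mean(axis=0)
        if np.linalg.norm(new_ref - ref) < tol * (1.0 + np.linalg.norm(ref)):
            ref = new_ref
            break
        ref = new_ref
    aligned = []
    for c in centered:
        _, R, _ = superpose(c, ref, allow_reflection)
        aligned.append(c @ R)
    rmsds = [float(np.sqrt(np.mean(np.sum((a - ref) ** 2, axis=1)))) for a in aligned]
    mean_shape = ReconstructedShape(canonicalize(ref), 0.0)
    return mean_shape, rmsds


@dataclass
class BootstrapResult:
    mean_shape: ReconstructedShape
    vertex_sd: np.ndarray       # (n,) 3D positional SD per vertex, nm
    vertex_sd_axes: np.ndarray  # (n, 3) per-axis SD in the common frame
    n_replicates: int

    @property
    def mean_vertex_sd(self) -> float:
        return float(self.vertex_sd.mean())


def bootstrap_shape(items, B: int, seed: int = 0, n_sites: int | None = None,
                    allow_reflection: bool = True) -> BootstrapResult:
    """Bootstrap per-vertex positional uncertainty over molecules.

    ``items`` may be per-molecule DistanceSets (each is reconstructed once)
    or already-reconstructed shapes / coordinate arrays.  Molecules are
    resampled with replacement B times; each replicate's shapes are aligned
    and averaged, the replicate means are brought into a common frame, and
    the per-vertex SD over replicates is reported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(items) < 2:
        raise ValueError("need at least 2 molecules")
    shapes = []
    for it in items:
        if isinstance(it, DistanceSet):
            shapes.append(reconstruct_best(it, n_sites=n_sites).best)
        else:
            shapes.append(it)
    rng = np.random.default_rng(seed)
    n = len(shapes)
    rep_means = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        mean_b, _ = align_and_average([shapes[i] for i in idx], allow_reflection)
        rep_means.append(mean_b.coords)
    overall, _ = align_and_average(rep_means, allow_reflection)
    aligned = []
    for c in rep_means:
        cc = c - c.mean(axis=0)
        _, R, _ = superpose(cc, overall.coords - overall.coords.mean(axis=0), allow_reflection)
        aligned.append(cc @ R)
    stack = np.stack(aligned)  # (B, n_vert, 3)
    sd_axes = stack.std(axis=0)
    vertex_sd = np.sqrt((sd_axes**2).sum(axis=1))
    return BootstrapResult(overall, vertex_sd, sd_axes, B)


# ---------------------------------------------------------------------------
# Fitting to a reference structure


def expand_from_centroid(coords, offset: float) -> np.ndarray:
    """Push each point radially outward from the centroid by ``offset`` (nm),
    modeling the dye linker standing off the labeled position."""
    coords = np.asarray(coords, dtype=float)
    c = coords.mean(axis=0)
    rel = coords - c
    norms = np.linalg.norm(rel, axis=1, keepdims=True)
    unit = np.divide(rel, norms, out=np.zeros_like(rel), where=norms > 0)
    return coords + offset * unit


@dataclass
class ReferenceFit:
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    permutation: tuple
    mirrored: bool
    transformed: np.ndarray  # shape coordinates in the reference frame


def fit_to_reference(shape, reference, linker_length: float = 0.0,
                     allow_reflection: bool = True, search_permutations: bool = True) -> ReferenceFit:
    """Superpose a reconstructed shape onto linker-expanded reference points.

    The reference points (e.g. labeled atoms from a crystal structure) are
    offset outward from their centroid by the dye linker length, then the
    best rigid (+- reflection) superposition is found, searching vertex
    permutations when the correspondence is unknown.
    """
    X = _as_coords(shape)
    ref = np.asarray(reference, dtype=float)
    if X.shape != ref.shape:
        raise ValueError("shape and reference must have the same vertex count")
    ref_exp = expand_from_centroid(ref, linker_length)
    n = X.shape[0]
    perms = itertools.permutations(range(n)) if search_permutations else [tuple(range(n))]
    best = None
    for perm in perms:
        rmsd, R, t = superpose(X[list(perm)], ref_exp, allow_reflection)
        if best is None or rmsd < best.rmsd:
            best = ReferenceFit(rmsd, R, t, tuple(perm), bool(np.linalg.det(R) < 0), X[list(perm)] @ R + t)
    return best


# ---------------------------------------------------------------------------
# Helix calibration


@dataclass(frozen=True)
class HelixModel:
    """B-DNA helix geometry: 0.34 nm rise/bp, 10.5 bp/turn, 1 nm radius."""

    rise_per_bp: float = 0.34
    bp_per_turn: float = 10.5
    helix_radius: float = 1.0
    phase_deg: float = 0.0

    def __post_init__(self):
        if min(self.rise_per_bp, self.bp_per_turn, self.helix_radius) <= 0:
            raise ValueError("helix parameters must be positive")


def helix_dye_position(bp, helix: HelixModel, linker_length: float, phase_deg: float = 0.0) -> np.ndarray:
    """Dye position for an attachment at base-pair index ``bp``: the helix
    point at that base, pushed radially outward by the linker length."""
    bp = np.asarray(bp, dtype=float)
    theta = 2.0 * np.pi * bp / helix.bp_per_turn + np.deg2rad(helix.phase_deg + phase_deg)
    r = helix.helix_radius + linker_length
    return np.stack([r * np.cos(theta), r * np.sin(theta), helix.rise_per_bp * bp], axis=-1)


@dataclass(frozen=True)
class TriangleObservation:
    """Measured efficiencies for one 3-site construct with known base-pair
    attachment indices; edge order (0,1), (0,2), (1,2)."""

    bp_positions: tuple
    efficiencies: tuple

    def __post_init__(self):
        object.__setattr__(self, "bp_positions", tuple(float(b) for b in self.bp_positions))
        object.__setattr__(self, "efficiencies", tuple(float(e) for e in self.efficiencies))
        if len(self.bp_positions) != 3 or len(self.efficiencies) != 3:
            raise ValueError("a triangle observation needs 3 positions and 3 efficiencies")
        if any(not 0 < e < 1 for e in self.efficiencies):
            raise ValueError("efficiencies must lie in (0, 1)")


_TRI_EDGES = ((0, 1), (0, 2), (1, 2))


@dataclass
class CalibrationResult:
    forster_radius: float
    linker_length: float
    phase_deg: float
    rms_distance_residual: float
    per_triangle_rms: list
    mean_positional_rmsd: float


def helix_calibrate(observations, helix: HelixModel | None = None,
                    initial: ForsterModel | None = None, fit_phase: bool = False,
                    fit_linker: bool = True) -> CalibrationResult:
    """Jointly fit (R0, linker length, and optionally the attachment phase)
    to triangle data on a DNA helix by least squares between helix-model
    distances and FRET-derived distances.

    A common phase offset rotates every dye about the helix axis and leaves
    all pairwise distances unchanged, so it is a gauge freedom of this fit;
    it is excluded by default and only matters when absolute positions
    around the helix are of interest.
    """
    helix = helix or HelixModel()
    initial = initial or ForsterModel()
    if len(observations) < 2:
        raise ValueError("need at least 2 triangles")
    pairs = []
    for obs in observations:
        for (i, j), e in zip(_TRI_EDGES, obs.efficiencies):
            pairs.append((obs.bp_positions[i], obs.bp_positions[j], e))
    n_params = 1 + int(fit_linker) + int(fit_phase)
    if len(pairs) < n_params:
        raise ValueError("under-determined: fewer distances than free parameters")
    bi = np.array([p[0] for p in pairs])
    bj = np.array([p[1] for p in pairs])
    ee = np.array([p[2] for p in pairs])
    efac = (1.0 / ee - 1.0) ** (1.0 / 6.0)

    def model_dist(L, phase):
        pi = helix_dye_position(bi, helix, L, phase)
        pj = helix_dye_position(bj, helix, L, phase)
        return np.linalg.norm(pi - pj, axis=-1)

    def unpack(theta):
        r0 = theta[0]
        L = theta[1] if fit_linker else initial.linker_length
        phase = theta[-1] if fit_phase else 0.0
        return r0, L, phase

    def resid(theta):
        r0, L, phase = unpack(theta)
        return model_dist(L, phase) - r0 * efac

    x0 = [initial.forster_radius] + ([initial.linker_length] if fit_linker else []) + ([0.0] if fit_phase else [])
    lo = [1e-3] + ([0.0] if fit_linker else []) + ([-180.0] if fit_phase else [])
    hi = [np.inf] + ([np.inf] if fit_linker else []) + ([180.0] if fit_phase else [])
    sol = least_squares(resid, x0, bounds=(lo, hi))
    r0, L, phase = (float(v) for v in unpack(sol.x))
    res = resid(sol.x)
    per_tri, pos_rmsds = [], []
    k = 0
    for obs in observations:
        tri_res = res[k : k + 3]
        per_tri.append(float(np.sqrt(np.mean(tri_res**2))))
        k += 3
        d_meas = [r0 * (1.0 / e - 1.0) ** (1.0 / 6.0) for e in obs.efficiencies]
        tri = reconstruct_triangle(*d_meas)
        model_pts = helix_dye_position(np.array(obs.bp_positions), helix, L, phase)
        rmsd, _, _ = superpose(tri.coords, model_pts)
        pos_rmsds.append(rmsd)
    return CalibrationResult(
        forster_radius=r0,
        linker_length=L,
        phase_deg=phase,
        rms_distance_residual=float(np.sqrt(np.mean(res**2))),
        per_triangle_rms=per_tri,
        mean_positional_rmsd=float(np.mean(pos_rmsds)),
    )


# ---------------------------------------------------------------------------
# I/O


def write_shape_csv(shape: ReconstructedShape, path, labels=None) -> None:
    coords = shape.coords
    labels = labels or [f"V{i + 1}" for i in range(shape.n_vertices)]
    pd.DataFrame(
        {
            "vertex": labels,
            "x_nm": coords[:, 0],
            "y_nm": coords[:, 1],
            "z_nm": coords[:, 2],
            "residual_nm": shape.residual,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def write_shape_pdb(shape: ReconstructedShape, path, labels=None) -> None:
    """Write one HETATM pseudo-atom per vertex (coordinates in Angstrom)."""
    from Bio.PDB.StructureBuilder import StructureBuilder
    from Bio.PDB import PDBIO

    sb = StructureBuilder()
    sb.init_structure("shape")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for i in range(shape.n_vertices):
        sb.init_residue("DYE", "H_DYE", i + 1, " ")
        name = f"V{i + 1}"
        sb.init_atom(
            name,
            shape.coords[i] * 10.0,
            0.0,
            1.0,
            " ",
            name.ljust(4),
            i + 1,
            element="C",
        )
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def read_reference_pdb(path, to_nm: bool = True) -> np.ndarray:
    """Coordinates of every atom in a PDB file, in file order (nm by default)."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("ref", str(path))
    coords = np.array([atom.get_coord() for atom in structure.get_atoms()], dtype=float)
    if coords.size == 0:
        raise ValueError(f"no atoms found in {path}")
    return coords / 10.0 if to_nm else coords
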