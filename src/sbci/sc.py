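"""Continuous structural connectivity by spherical heat-kernel KDE.

Streamline endpoints, carried to the registration spheres, are a sparse
sample of an underlying pair density on Omega x Omega.  The density is
estimated by kernel density estimation with a product kernel

    k_h((x, y); (mu_x, mu_y)) = f_h(x, mu_x) * f_h(y, mu_y),

where f_h is the heat kernel on the 2-sphere,

    f_h(x; mu) = (4*pi)^-1 * sum_m (2m+1) exp(-m(m+1)h) P_m(<x, mu>),

with P_m the Legendre polynomials and h > 0 the bandwidth.  f_h vanishes by
convention when x and mu lie on different hemispheres, so the estimate
decomposes into left-left, left-right and right-right blocks.  Streamlines
are unordered, so each contributes half its mass to both endpoint orderings,
which makes the estimate exactly symmetric.

The Legendre series is truncated at the first order M for which the tail
bound (2M+3)*exp(-(M+1)(M+2)h) drops below a tolerance; truncation can leave
tiny negative values, which are clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .grid import HemispherePairGrid
from .mesh import SphereMesh

__all__ = [
    "HeatKernelSpec", "StreamlineEndpoints", "ContinuousSC", "heat_kernel",
    "heat_kernel_matrix", "extract_endpoints", "smooth_sc",
    "endpoint_histogram", "sparsity", "direct_connection_mask",
]

_INV_4PI = 1.0 / (4.0 * np.pi)


def _truncation_order(h: float, tail_tol: float) -> int:
    m = 0
    while (2 * m + 3) * np.exp(-(m + 1) * (m + 2) * h) >= tail_tol:
        m += 1
        if m > 100_000:
            raise ValueError(f"bandwidth h={h} too small for tail "
                             f"tolerance {tail_tol}")
    return m


@dataclass(frozen=True)
class HeatKernelSpec:
    """Heat-kernel bandwidth and series truncation.

    h is dimensionless on the unit sphere (typical connectome values lie in
    0.002-0.02).  max_degree is derived from tail_tol when omitted, as the
    smallest M whose Legendre tail bound falls below tail_tol.
    """

    h: float
    tail_tol: float = 1e-8
    max_degree: int | None = None

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("bandwidth h must be positive")
        if self.max_degree is None:
            object.__setattr__(self, "max_degree",
                               _truncation_order(self.h, self.tail_tol))
        M = self.max_degree
        if (2 * M + 3) * np.exp(-(M + 1) * (M + 2) * self.h) >= self.tail_tol:
            raise ValueError("max_degree too small for tail_tol at this h")


def heat_kernel(t_dot, spec: HeatKernelSpec) -> np.ndarray:
    """Evaluate f_h at inner products ``t_dot`` (scalar or array).

    Values are clipped at zero; the clipped magnitude is bounded by the
    truncation tolerance.
    """
    t = np.asarray(t_dot, dtype=float)
    if np.any(np.abs(t) > 1 + 1e-12):
        raise ValueError("inner products must lie in [-1, 1]")
    t = np.clip(t, -1.0, 1.0)
    M = spec.max_degree
    p_prev = np.ones_like(t)            # P_0
    acc = p_prev.copy()                 # m = 0 term
    if M >= 1:
        p = t.copy()                    # P_1
        acc = acc + 3.0 * np.exp(-2.0 * spec.h) * p
        for m in range(2, M + 1):
            p_prev, p = p, ((2 * m - 1) * t * p - (m - 1) * p_prev) / m
            acc += (2 * m + 1) * np.exp(-m * (m + 1) * spec.h) * p
    out = _INV_4PI * acc
    return np.maximum(out, 0.0) if out.ndim else max(float(out), 0.0)


def heat_kernel_matrix(x: np.ndarray, mu: np.ndarray,
                       spec: HeatKernelSpec, chunk: int = 4_000_000
                       ) -> np.ndarray:
    """f_h between every row of ``x`` and every row of ``mu`` (same sphere)."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.empty((len(x), len(mu)))
    rows_per_chunk = max(1, chunk // max(1, len(mu)))
    for lo in range(0, len(x), rows_per_chunk):
        hi = min(lo + rows_per_chunk, len(x))
        out[lo:hi] = heat_kernel(x[lo:hi] @ mu.T, spec)
    return out


@dataclass
class StreamlineEndpoints:
    """N unordered streamline endpoint pairs on the registration spheres.

    positions : (N, 2, 3) unit vectors
    hemispheres : (N, 2) int, 0 = left, 1 = right
    n_dropped : count of streamlines discarded during extraction
    """

    positions: np.ndarray
    hemispheres: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.hemispheres = np.asarray(self.hemispheres, dtype=np.int8)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (2, 3):
            raise ValueError("positions must be (N, 2, 3)")
        if self.hemispheres.shape != self.positions.shape[:2]:
            raise ValueError("hemispheres must be (N, 2)")
        if self.n == 0:
            raise ValueError("no usable endpoints")
        norms = np.linalg.norm(self.positions, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("endpoint vectors must be unit norm")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class ContinuousSC:
    """Grid-evaluated continuous SC: symmetric nonnegative density values
    (probability per steradian^2), zero diagonal."""

    values: np.ndarray
    grid: HemispherePairGrid
    h: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = self.grid.n_masked
        if v.shape != (n, n):
            raise ValueError(f"SC matrix shape {v.shape} does not match "
                             f"masked grid dimension {n}")
        if not np.allclose(v, v.T, atol=1e-9 * max(1.0, np.abs(v).max())):
            raise ValueError("SC matrix must be symmetric")
        if v.min() < 0:
            raise ValueError("SC matrix must be nonnegative")
        if np.abs(np.diag(v)).max() > 0:
            raise ValueError("SC diagonal must be exactly zero")
        self.values = v

    def quadrature_mass(self) -> float:
        """Double integral over Omega x Omega by vertex-area quadrature."""
        a = self.grid.masked_areas
        return float(a @ self.values @ a)


def extract_endpoints(streamlines, left_surface: np.ndarray,
                      right_surface: np.ndarray,
                      left_sphere: np.ndarray | None = None,
                      right_sphere: np.ndarray | None = None,
                      max_dist: float = np.inf) -> StreamlineEndpoints:
    """Snap streamline termini to surface vertices and carry them to the
    registered spherical coordinates.

    Parameters
    ----------
    streamlines : iterable of (k, 3) arrays, k >= 2
        Streamline point sequences in surface space.
    left_surface, right_surface : (n, 3) arrays
        Full-resolution surface vertex coordinates per hemisphere.
    left_sphere, right_sphere : (n, 3) unit-vector arrays, optional
        Registered spherical coordinate of each surface vertex.  Default:
        the surface vertices normalized to the unit sphere (surfaces that
        already are spheres).
    max_dist : float
        Streamlines whose terminus is farther than this from both surfaces
        are dropped; the count is recorded on the result.
    """
    left_surface = np.asarray(left_surface, dtype=float)
    right_surface = np.asarray(right_surface, dtype=float)
    if left_sphere is None:
        left_sphere = left_surface / np.linalg.norm(left_surface, axis=1,
                                                    keepdims=True)
    if right_sphere is None:
        right_sphere = right_surface / np.linalg.norm(right_surface, axis=1,
                                                      keepdims=True)
    trees = (cKDTree(left_surface), cKDTree(right_surface))
    spheres = (np.asarray(left_sphere, float), np.asarray(right_sphere, float))

    termini = []
    for sl in streamlines:
        sl = np.asarray(sl, dtype=float)
        if sl.ndim != 2 or sl.shape[0] < 2 or sl.shape[1] != 3:
            raise ValueError("each streamline needs >= 2 points in 3-D")
        termini.append((sl[0], sl[-1]))
    if not termini:
        raise ValueError("no usable endpoints")
    ends = np.array(termini)                       # (N, 2, 3)
    flat = ends.reshape(-1, 3)
    d_l, i_l = trees[0].query(flat)
    d_r, i_r = trees[1].query(flat)
    hemi = (d_r < d_l).astype(np.int8)
    dist = np.where(hemi == 0, d_l, d_r)
    pos = np.where(hemi[:, None] == 0, spheres[0][i_l], spheres[1][i_r])
    keep = (dist.reshape(-1, 2) <= max_dist).all(axis=1)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("no usable endpoints: all streamlines dropped")
    return StreamlineEndpoints(
        positions=pos.reshape(-1, 2, 3)[keep],
        hemispheres=hemi.reshape(-1, 2)[keep],
        n_dropped=n_dropped)


def _anchor_index(endpoints: StreamlineEndpoints,
                  snap_mesh: SphereMesh | None):
    """Collapse endpoints to unique anchor points with a pair-count matrix.

    If ``snap_mesh`` is given, endpoints are first binned to its nearest
    vertex (same mesh on both hemispheres); otherwise the distinct endpoint
    coordinates themselves are the anchors.  Returns per-hemisphere anchor
    coordinate arrays and a symmetric sparse count matrix over the global
    anchor index (left anchors first).
    """
    flat_pos = endpoints.positions.reshape(-1, 3)
    flat_hemi = endpoints.hemispheres.reshape(-1)
    if snap_mesh is not None:
        tree = cKDTree(snap_mesh.vertices)
        _, vidx = tree.query(flat_pos)
        keys = flat_hemi.astype(np.int64) * snap_mesh.n_vertices + vidx
        uniq, inv = np.unique(keys, return_inverse=True)
        anchor_hemi = (uniq // snap_mesh.n_vertices).astype(np.int8)
        anchor_pos = snap_mesh.vertices[uniq % snap_mesh.n_vertices]
    else:
        recs = np.concatenate([flat_hemi[:, None].astype(float), flat_pos],
                              axis=1)
        uniq, inv = np.unique(recs, axis=0, return_inverse=True)
        anchor_hemi = uniq[:, 0].astype(np.int8)
        anchor_pos = uniq[:, 1:]
        anchor_pos /= np.linalg.norm(anchor_pos, axis=1, keepdims=True)
    # reorder anchors: left block then right block
    order = np.argsort(anchor_hemi, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    anchor_hemi = anchor_hemi[order]
    anchor_pos = anchor_pos[order]
    inv = rank[inv]
    ai = inv.reshape(-1, 2)
    n_anchor = len(anchor_pos)
    counts = sparse.coo_matrix(
        (np.ones(endpoints.n), (ai[:, 0], ai[:, 1])),
        shape=(n_anchor, n_anchor)).tocsr()
    counts = (counts + counts.T) * 0.5      # half mass to each ordering
    return anchor_pos, anchor_hemi, counts


def smooth_sc(endpoints: StreamlineEndpoints, grid: HemispherePairGrid,
              spec: HeatKernelSpec,
              snap_mesh: SphereMesh | None = None) -> ContinuousSC:
    """Heat-kernel KDE of the endpoint pair density on the masked grid.

    The estimate at grid vertices (u, w) is

        C_SC(u, w) = N^-1 sum_i 0.5*[f_h(u,x_i) f_h(w,y_i)
                                     + f_h(u,y_i) f_h(w,x_i)],

    computed as two dense kernel products against the distinct endpoint
    anchors.  ``snap_mesh`` optionally bins endpoints to the vertices of a
    (full-resolution) mesh first, which bounds the number of anchors without
    materially moving the data when the mesh is fine relative to sqrt(2h).
    The diagonal is zeroed after evaluation and the matrix is not
    renormalized.
    """
    anchor_pos, anchor_hemi, counts = _anchor_index(endpoints, snap_mesh)
    gvert = grid.masked_vertices
    ghemi = grid.masked_hemisphere
    n = grid.n_masked
    values = np.zeros((n, n))
    ksub = {}
    for hemi in (0, 1):
        gs = np.flatnonzero(ghemi == hemi)
        asel = np.flatnonzero(anchor_hemi == hemi)
        if len(gs) and len(asel):
            ksub[hemi] = (gs, asel,
                          heat_kernel_matrix(gvert[gs], anchor_pos[asel],
                                             spec))
    for ha in (0, 1):
        for hb in (0, 1):
            if ha not in ksub or hb not in ksub:
                continue
            ga, aa, ka = ksub[ha]
            gb, ab, kb = ksub[hb]
            block = counts[np.ix_(aa, ab)]
            if block.nnz == 0:
                continue
            values[np.ix_(ga, gb)] += (block.T @ ka.T).T @ kb.T
    values /= endpoints.n
    values = (values + values.T) * 0.5      # remove float asymmetry
    np.fill_diagonal(values, 0.0)
    return ContinuousSC(values=values, grid=grid, h=spec.h)


def endpoint_histogram(endpoints: StreamlineEndpoints,
                       grid: HemispherePairGrid) -> ContinuousSC:
    """Unsmoothed (h = 0) endpoint pair histogram as a density on the grid.

    Each endpoint is assigned to its nearest same-hemisphere masked grid
    vertex; the pair count is symmetrized, divided by N and by the product
    of the receiving vertex areas so values are densities comparable with
    the smoothed estimate.
    """
    gvert = grid.masked_vertices
    ghemi = grid.masked_hemisphere
    n = grid.n_masked
    flat_pos = endpoints.positions.reshape(-1, 3)
    flat_hemi = endpoints.hemispheres.reshape(-1)
    assign = np.empty(len(flat_pos), dtype=np.int64)
    for hemi in (0, 1):
        gs = np.flatnonzero(ghemi == hemi)
        sel = flat_hemi == hemi
        if not sel.any():
            continue
        if len(gs) == 0:
            raise ValueError(f"no masked grid vertices on hemisphere {hemi}")
        _, j = cKDTree(gvert[gs]).query(flat_pos[sel])
        assign[sel] = gs[j]
    pairs = assign.reshape(-1, 2)
    counts = np.zeros((n, n))
    np.add.at(counts, (pairs[:, 0], pairs[:, 1]), 0.5)
    np.add.at(counts, (pairs[:, 1], pairs[:, 0]), 0.5)
    a = grid.masked_areas
    values = counts / (endpoints.n * np.outer(a, a))
    np.fill_diagonal(values, 0.0)
    return ContinuousSC(values=values, grid=grid, h=0.0)


def sparsity(matrix: np.ndarray, zero_threshold: float = 0.0) -> float:
    """Fraction of off-diagonal entries with |value| <= zero_threshold."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    off = ~np.eye(m.shape[0], dtype=bool)
    return float(np.mean(np.abs(m[off]) <= zero_threshold))


def direct_connection_mask(sc: ContinuousSC | np.ndarray,
                           threshold: float = 1e-7) -> np.ndarray:
    """Boolean matrix of node pairs with SC density above ``threshold``.

    Used to split FC values into groups with and without a direct structural
    connection; the default 1e-7 corresponds to about one expected streamline
    out of ten million.
    """
    v = sc.values if isinstance(sc, ContinuousSC) else np.asarray(sc)
    return v > threshold
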