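"""Triangulated spherical meshes: construction, geometry, quadrature.

A :class:`SphereMesh` discretizes one hemisphere's registration sphere.  All
vertices live on the unit sphere; inputs on a sphere of radius ``r`` (e.g. the
FreeSurfer convention of radius 100 mm) are rescaled with the scale recorded.
Per-vertex areas are barycentric-lumped spherical triangle areas, so they are
positive and sum to the sphere area 4*pi; they serve as quadrature weights for
fields sampled at the vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

_UNIT_TOL = 1e-9
_AREA_RTOL = 1e-6
SPHERE_AREA = 4.0 * np.pi


def geodesic_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle (arc length) distance between unit vectors, in radians.

    Accepts single vectors or broadcastable arrays with the vector axis last.
    Uses atan2 of cross/dot, which is accurate for both nearly-identical and
    nearly-antipodal pairs.

    Raises
    ------
    ValueError
        If any input vector is not unit norm (within 1e-9).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, x in (("a", a), ("b", b)):
        norms = np.linalg.norm(x, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"{name} contains non-unit vectors "
                             f"(max |norm-1| = {np.abs(norms - 1).max():.3g})")
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    dot = np.einsum("...i,...i->...", a, b)
    return np.arctan2(cross, dot)


def spherical_triangle_areas(vertices: np.ndarray,
                             triangles: np.ndarray) -> np.ndarray:
    """Solid angle of each spherical triangle (Van Oosterom-Strackee)."""
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    num = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
    den = (1.0 + np.einsum("ij,ij->i", a, b)
           + np.einsum("ij,ij->i", b, c)
           + np.einsum("ij,ij->i", a, c))
    return 2.0 * np.arctan2(num, den)


@dataclass
class SphereMesh:
    """A closed triangulated mesh on the unit 2-sphere.

    Parameters
    ----------
    vertices : (n, 3) float array
        Unit vectors.  A uniform radius != 1 is normalized away and recorded
        in ``scale``.
    triangles : (m, 3) int array
        Vertex index triples forming a closed 2-manifold.
    hemisphere : {"left", "right"}
        Which hemisphere this sphere represents.
    scale : float
        Radius of the sphere the vertices were given on (1.0 if already unit).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    hemisphere: str = "left"
    scale: float = 1.0
    vertex_areas: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', "
                             f"got {self.hemisphere!r}")
        norms = np.linalg.norm(self.vertices, axis=1)
        if norms.min() <= 0:
            raise ValueError("mesh contains a zero vertex")
        r = norms.mean()
        if abs(r - 1.0) > _UNIT_TOL:
            # input given on a radius-r sphere: rescale, remember the radius
            if norms.std() / r > 1e-4:
                raise ValueError("vertices are not on a common sphere")
            self.vertices = self.vertices / norms[:, None]
            self.scale = float(self.scale * r)
        self._check_manifold()
        self.vertex_areas = self._lumped_areas()
        total = self.vertex_areas.sum()
        if abs(total - SPHERE_AREA) / SPHERE_AREA > _AREA_RTOL:
            raise ValueError(f"vertex areas sum to {total:.8f}, "
                             f"expected {SPHERE_AREA:.8f}")

    # -- geometry ---------------------------------------------------------

    def _check_manifold(self):
        edges = np.sort(np.concatenate([self.triangles[:, [0, 1]],
                                        self.triangles[:, [1, 2]],
                                        self.triangles[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            bad = int(np.sum(counts != 2))
            raise ValueError(f"mesh is not a closed 2-manifold: {bad} edges "
                             f"not shared by exactly two triangles")

    def _lumped_areas(self) -> np.ndarray:
        tri_areas = spherical_triangle_areas(self.vertices, self.triangles)
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.triangles.ravel(), np.repeat(tri_areas / 3.0, 3))
        return va

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (n_edges, 2), sorted pairs."""
        e = np.sort(np.concatenate([self.triangles[:, [0, 1]],
                                    self.triangles[:, [1, 2]],
                                    self.triangles[:, [2, 0]]]), axis=1)
        return np.unique(e, axis=0)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric boolean vertex adjacency from the triangulation."""
        e = self.edges()
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix(
            (np.ones(len(i), dtype=bool), (i, j)),
            shape=(self.n_vertices, self.n_vertices))

    def surface_integral(self, func) -> float:
        """Integrate ``func`` over the sphere by the edge-midpoint rule.

        ``func`` maps an (n, 3) array of unit vectors to (n,) values.  The
        rule evaluates the integrand at the three (re-projected) edge
        midpoints of every spherical triangle and weights by the triangle
        solid angle; it is second-order and considerably more accurate than
        vertex lumping for smooth integrands.
        """
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        tri_areas = spherical_triangle_areas(self.vertices, self.triangles)
        acc = np.zeros(self.n_triangles)
        for p, q in ((a, b), (b, c), (c, a)):
            mid = p + q
            mid /= np.linalg.norm(mid, axis=1, keepdims=True)
            acc += np.asarray(func(mid), dtype=float)
        return float(np.sum(tri_areas * acc / 3.0))


# -- icosphere construction ------------------------------------------------

_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array([
    [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
    [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
    [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
], dtype=float)
_ICO_FACES = np.array([
    [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
    [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
    [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
    [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
], dtype=np.int64)

MAX_ICOSPHERE_LEVEL = 8


def build_icosphere(level: int, hemisphere: str = "left") -> SphereMesh:
    """Recursively subdivided icosahedron with 10*4**level + 2 vertices.

    Each subdivision splits every triangle in four at the re-projected edge
    midpoints.  Level 7 gives 163,842 vertices, the resolution of a
    full-resolution FreeSurfer registration sphere.

    Parameters
    ----------
    level : int
        Subdivision order, 0 <= level <= 8 (level 8 is ~2.6M vertices; higher
        orders are rejected).
    """
    level = int(level)
    if level < 0 or level > MAX_ICOSPHERE_LEVEL:
        raise ValueError(f"level must be in [0, {MAX_ICOSPHERE_LEVEL}], "
                         f"got {level}")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(level):
        edges = np.sort(np.concatenate([faces[:, [0, 1]],
                                        faces[:, [1, 2]],
                                        faces[:, [2, 0]]]), axis=1)
        uniq, inv = np.unique(edges, axis=0, return_inverse=True)
        mids = verts[uniq[:, 0]] + verts[uniq[:, 1]]
        mids /= np.linalg.norm(mids, axis=1, keepdims=True)
        mid_idx = len(verts) + inv.reshape(3, -1)  # rows: ab, bc, ca
        verts = np.concatenate([verts, mids])
        a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
        ab, bc, ca = mid_idx
        faces = np.concatenate([
            np.stack([a, ab, ca], axis=1),
            np.stack([b, bc, ab], axis=1),
            np.stack([c, ca, bc], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ])
    return SphereMesh(vertices=verts, triangles=faces, hemisphere=hemisphere)
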