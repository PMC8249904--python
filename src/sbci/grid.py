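"""The joint analysis grid over both hemispheres.

All continuous connectomes are evaluated on a discretization of
``Omega = S_left u S_right`` — two registration spheres, one per hemisphere.
A :class:`HemispherePairGrid` stacks the two (typically down-sampled) sphere
meshes, keeps each grid vertex's index into its full-resolution mesh, and
carries a boolean mask excluding medial-wall / corpus-callosum vertices from
analysis.  Grid vertices are indexed 0..n_left-1 (left) then
n_left..n_left+n_right-1 (right); "masked-in" refers to the mask-True subset,
which is the dimension of every connectivity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .mesh import SphereMesh

__all__ = ["HemispherePairGrid", "build_grid"]


@dataclass
class HemispherePairGrid:
    left: SphereMesh
    right: SphereMesh
    mask: np.ndarray                       # bool per grid vertex, True = in
    left_full_index: np.ndarray = None     # grid vertex -> full-res index
    right_full_index: np.ndarray = None

    def __post_init__(self):
        nl, nr = self.left.n_vertices, self.right.n_vertices
        if self.left_full_index is None:
            self.left_full_index = np.arange(nl)
        if self.right_full_index is None:
            self.right_full_index = np.arange(nr)
        self.left_full_index = np.asarray(self.left_full_index, dtype=np.int64)
        self.right_full_index = np.asarray(self.right_full_index,
                                           dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (nl + nr,):
            raise ValueError(f"mask length {self.mask.shape} does not match "
                             f"grid size {nl + nr}")
        for name, idx, n in (("left", self.left_full_index, nl),
                             ("right", self.right_full_index, nr)):
            if len(idx) != n:
                raise ValueError(f"{name} full_index_map length mismatch")
            if len(np.unique(idx)) != n:
                raise ValueError(f"{name} full_index_map has duplicates")

    # -- sizes ------------------------------------------------------------

    @property
    def n_left(self) -> int:
        return self.left.n_vertices

    @property
    def n_right(self) -> int:
        return self.right.n_vertices

    @property
    def n_total(self) -> int:
        """Grid vertices before masking."""
        return self.n_left + self.n_right

    @property
    def n_masked(self) -> int:
        """The analysis dimension: masked-in vertex count."""
        return int(self.mask.sum())

    # -- geometry over the joint grid -------------------------------------

    @property
    def vertices(self) -> np.ndarray:
        """(n_total, 3) unit vectors, left block then right block."""
        return np.concatenate([self.left.vertices, self.right.vertices])

    @property
    def hemisphere_labels(self) -> np.ndarray:
        """0 for left, 1 for right, per grid vertex."""
        return np.repeat([0, 1], [self.n_left, self.n_right])

    @property
    def vertex_areas(self) -> np.ndarray:
        return np.concatenate([self.left.vertex_areas,
                               self.right.vertex_areas])

    @property
    def masked_vertices(self) -> np.ndarray:
        return self.vertices[self.mask]

    @property
    def masked_areas(self) -> np.ndarray:
        """Quadrature weights (steradians) for the masked-in vertices."""
        return self.vertex_areas[self.mask]

    @property
    def masked_hemisphere(self) -> np.ndarray:
        return self.hemisphere_labels[self.mask]

    def masked_adjacency(self) -> sparse.csr_matrix:
        """Vertex adjacency of the masked-in grid (block-diagonal by
        hemisphere, from each mesh triangulation)."""
        joint = sparse.block_diag([self.left.adjacency(),
                                   self.right.adjacency()], format="csr")
        return joint[self.mask][:, self.mask].tocsr()

    def checksum(self) -> str:
        """Stable hex digest of the grid geometry, for sidecar validation."""
        import hashlib
        hsh = hashlib.sha256()
        for arr in (self.left.vertices, self.right.vertices, self.mask,
                    self.left_full_index, self.right_full_index):
            hsh.update(np.ascontiguousarray(arr).tobytes())
        return hsh.hexdigest()[:16]


def build_grid(left: SphereMesh, right: SphereMesh,
               mask: np.ndarray | None = None,
               left_full_index: np.ndarray | None = None,
               right_full_index: np.ndarray | None = None,
               ) -> HemispherePairGrid:
    """Assemble the two hemisphere meshes into a joint analysis grid.

    Parameters
    ----------
    mask : bool array of length n_left + n_right, optional
        True for vertices included in analysis.  Default: all included.
    left_full_index, right_full_index : int arrays, optional
        Per-grid-vertex indices into the full-resolution meshes (from
        :func:`sbci.decimate.downsample_mesh`).  Default: identity.
    """
    n = left.n_vertices + right.n_vertices
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError(f"mask has length {mask.shape[0] if mask.ndim else 0}"
                         f", expected {n}")
    return HemispherePairGrid(left=left, right=right, mask=mask,
                              left_full_index=left_full_index,
                              right_full_index=right_full_index)
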