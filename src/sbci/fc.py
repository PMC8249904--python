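"""Continuous functional connectivity.

The functional connectome is built in three steps: (1) nuisance signals
(motion parameters, WM/CSF components, global signal, ...) are regressed out
of every vertex BOLD series by ordinary least squares; (2) the residual
series are interpolated from the full-resolution surface onto the analysis
grid with a compactly supported spherical kernel (bi-weight by default); and
(3) the grid-to-grid Pearson correlation matrix is taken, with the diagonal
defined to be zero — self-interactions are not part of the connectome.

Interpolation weights depend only on geometry, so they are assembled once as
a sparse matrix and applied to all time points in a single product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .grid import HemispherePairGrid

__all__ = [
    "VertexTimeSeriesField", "ContinuousFC", "regress_nuisance",
    "interpolate_bold", "continuous_fc", "fwhm_mm_to_radians",
]


@dataclass
class VertexTimeSeriesField:
    """Per-vertex BOLD time series on the full-resolution spheres.

    series : (n_vertices, T) float array
    positions : (n_vertices, 3) unit vectors on the registration sphere
    hemisphere : (n_vertices,) int array, 0 = left, 1 = right
    """

    series: np.ndarray
    positions: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=np.int8)
        if self.series.ndim != 2:
            raise ValueError("series must be (n_vertices, T)")
        n = self.series.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError("positions shape does not match series")
        if self.hemisphere.shape != (n,):
            raise ValueError("hemisphere labels do not match series")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must be unit vectors")

    @property
    def n_vertices(self) -> int:
        return self.series.shape[0]

    @property
    def T(self) -> int:
        return self.series.shape[1]


@dataclass
class ContinuousFC:
    """Grid-evaluated continuous FC: symmetric, zero diagonal, |r| <= 1."""

    values: np.ndarray
    grid: HemispherePairGrid

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = self.grid.n_masked
        if v.shape != (n, n):
            raise ValueError(f"FC matrix shape {v.shape} does not match "
                             f"masked grid dimension {n}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if np.abs(v).max() > 1 + 1e-10:
            raise ValueError("FC entries must lie in [-1, 1]")
        if np.abs(np.diag(v)).max() > 0:
            raise ValueError("FC diagonal must be exactly zero")
        self.values = v


def regress_nuisance(field: VertexTimeSeriesField,
                     confounds: np.ndarray | None) -> VertexTimeSeriesField:
    """Residualize every vertex series on [intercept | confounds] by OLS.

    Rank-deficient confound tables are reduced to an independent column
    subset (with a warning); residuals are exactly orthogonal to every
    retained confound column and to the intercept.
    """
    T = field.T
    if confounds is None or np.size(confounds) == 0:
        X = np.ones((T, 1))
    else:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != T:
            raise ValueError(f"confounds have {confounds.shape[0]} rows, "
                             f"expected T={T}")
        if confounds.shape[1] >= T:
            raise ValueError("more confounds than time points")
        X = np.column_stack([np.ones(T), confounds])
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() or 1.0)
        if (diag < tol).any():
            warnings.warn("confound matrix is rank deficient; dropping "
                          "dependent columns", stacklevel=2)
            keep = _independent_columns(X, tol)
            X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, field.series.T, rcond=None)
    resid = field.series - (X @ beta).T
    return VertexTimeSeriesField(series=resid, positions=field.positions,
                                 hemisphere=field.hemisphere)


def _independent_columns(X: np.ndarray, tol: float) -> list[int]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol) == len(keep) + 1:
            keep.append(j)
    return keep


def fwhm_mm_to_radians(fwhm_mm: float, radius_mm: float = 100.0,
                       kernel: str = "biweight") -> float:
    """Convert a smoothing FWHM in mm on a radius-``radius_mm`` registration
    sphere (FreeSurfer uses 100 mm) to a kernel bandwidth sigma in radians.

    For the bi-weight kernel, w(d) = (1-(d/sigma)^2)^2 falls to half maximum
    at d = sigma*sqrt(1-2**-0.5), so sigma = FWHM / (2*sqrt(1-2**-0.5)).
    For the truncated Gaussian the usual FWHM = 2*sqrt(2*ln 2)*sigma applies.
    """
    arc = fwhm_mm / radius_mm
    if kernel == "biweight":
        return arc / (2.0 * np.sqrt(1.0 - 2.0 ** -0.5))
    if kernel == "gaussian":
        return arc / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    raise ValueError(f"unknown kernel {kernel!r}")


def _interp_weights(field: VertexTimeSeriesField, grid: HemispherePairGrid,
                    sigma: float, kernel: str) -> sparse.csr_matrix:
    """Sparse (n_masked_grid, n_field_vertices) normalized weight matrix."""
    gverts = grid.masked_vertices
    ghemi = grid.masked_hemisphere
    rows, cols, vals = [], [], []
    chord = 2.0 * np.sin(min(sigma, np.pi) / 2.0)   # geodesic -> chord radius
    for hemi in (0, 1):
        gsel = np.flatnonzero(ghemi == hemi)
        fsel = np.flatnonzero(field.hemisphere == hemi)
        if len(gsel) == 0:
            continue
        if len(fsel) == 0:
            raise ValueError(f"no field vertices on hemisphere {hemi}")
        tree = cKDTree(field.positions[fsel])
        neighbors = tree.query_ball_point(gverts[gsel], chord + 1e-12)
        for gi, nbrs in zip(gsel, neighbors):
            if not nbrs:
                raise ValueError(
                    f"grid vertex {gi} has no field vertex within "
                    f"sigma={sigma:.4g} rad; increase sigma or refine the "
                    f"field mesh")
            nbrs = np.asarray(nbrs)
            d = np.arccos(np.clip(
                field.positions[fsel[nbrs]] @ gverts[gi], -1.0, 1.0))
            u = np.minimum(d / sigma, 1.0)
            if kernel == "biweight":
                w = (1.0 - u ** 2) ** 2
            elif kernel == "gaussian":
                w = np.exp(-0.5 * (3.0 * u) ** 2)   # truncated at 3 sd
            else:
                raise ValueError(f"unknown kernel {kernel!r}")
            if w.sum() <= 0:            # only boundary vertices: fall back
                w = np.ones_like(w)     # to nearest-neighbor averaging
            rows.extend([gi] * len(nbrs))
            cols.extend(fsel[nbrs])
            vals.extend(w / w.sum())
    # rows currently index the masked grid in masked order
    n = grid.n_masked
    return sparse.csr_matrix((vals, (rows, cols)),
                             shape=(n, field.n_vertices))


def interpolate_bold(field: VertexTimeSeriesField, grid: HemispherePairGrid,
                     sigma: float, kernel: str = "biweight") -> np.ndarray:
    """Interpolate vertex series onto the masked grid vertices.

    Each grid point receives a convex combination of the series at the
    same-hemisphere field vertices within geodesic distance ``sigma``
    (Nadaraya-Watson: weights renormalized to sum to one, so constant
    signals are preserved exactly).

    Returns
    -------
    (n_masked, T) array of interpolated series, in masked-grid order.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    W = _interp_weights(field, grid, float(sigma), kernel)
    return W @ field.series


def continuous_fc(grid_series: np.ndarray,
                  grid: HemispherePairGrid) -> ContinuousFC:
    """Pearson correlation of interpolated grid series; diagonal forced to 0.

    Constant series produce undefined correlations; their rows/columns are
    set to zero with a warning.
    """
    s = np.asarray(grid_series, dtype=float)
    if s.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    sd = s.std(axis=1)
    constant = sd <= 1e-14 * np.maximum(1.0, np.abs(s).max())
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant grid series; their "
                      "FC rows are set to 0", stacklevel=2)
        s = s.copy()
        s[constant] += np.random.default_rng(0).normal(size=(constant.sum(),
                                                             s.shape[1]))
    c = np.corrcoef(s)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    if constant.any():
        c[constant, :] = 0.0
        c[:, constant] = 0.0
    np.fill_diagonal(c, 0.0)
    return ContinuousFC(values=c, grid=grid)
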