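"""Structure-function coupling (SFC) measures.

Three coupling measures are computed from the continuous connectomes, plus a
streamline-count baseline:

* **global** — at every grid vertex x0, the normalized inner product (an
  area-weighted cosine similarity) between the SC row and the FC row of x0
  over the whole surface;
* **local** — the same inner product restricted to the parcel containing x0;
* **discrete** — connectomes are first reduced to parcel-by-parcel matrices
  (SC as connection density per unit area squared, FC as the Fisher-z
  average correlation), then each parcel's coupling is the Pearson
  correlation between its SC and FC rows;
* **traditional** — the common atlas pipeline: SC as raw streamline counts
  per parcel pair and FC as the correlation of parcel-mean BOLD series, with
  the same row-correlation coupling.

Surface integrals are discretized with per-vertex area weights, which keeps
the measures stable under mesh refinement.  All coupling values lie in
[-1, 1] by Cauchy-Schwarz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fc import ContinuousFC
from .grid import HemispherePairGrid
from .sc import ContinuousSC

__all__ = [
    "Parcellation", "CouplingField", "DiscreteConnectome",
    "sfc_global", "sfc_local", "discrete_sc", "discrete_fc",
    "sfc_discrete", "sfc_traditional",
]

UNASSIGNED = -1
_ARTANH_CLIP = 1.0 - 1e-7


@dataclass
class Parcellation:
    """ROI labels over the masked-in grid vertices.

    labels : (n_masked,) int array; UNASSIGNED (-1) marks vertices outside
    every ROI.  ROI areas are the summed vertex areas of the members.
    """

    labels: np.ndarray
    grid: HemispherePairGrid

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.grid.n_masked,):
            raise ValueError(f"labels length {self.labels.shape} does not "
                             f"match masked grid size {self.grid.n_masked}")
        if len(self.roi_ids) == 0:
            raise ValueError("parcellation has no assigned ROI")

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != UNASSIGNED]

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def members(self, roi: int) -> np.ndarray:
        return np.flatnonzero(self.labels == roi)

    @property
    def roi_areas(self) -> np.ndarray:
        """|E| per ROI (steradians), ordered as ``roi_ids``."""
        a = self.grid.masked_areas
        return np.array([a[self.members(r)].sum() for r in self.roi_ids])

    def merge(self, mapping: dict[int, int]) -> "Parcellation":
        """Relabel ROIs (e.g. merge anatomical parcels into lobes)."""
        new = np.full_like(self.labels, UNASSIGNED)
        for old, tgt in mapping.items():
            new[self.labels == old] = tgt
        return Parcellation(labels=new, grid=self.grid)


@dataclass
class CouplingField:
    """Per-vertex (or per-ROI) SFC values with provenance.

    values may contain NaN where the measure is undefined (unassigned
    vertices, degenerate parcels, constant rows)."""

    values: np.ndarray
    kind: str                                 # global | local | discrete | traditional
    parcellation: Parcellation | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ValueError("coupling values must lie in [-1, 1]")


@dataclass
class DiscreteConnectome:
    """Parcel-level SC (density per unit area squared) and FC matrices."""

    sc: np.ndarray
    fc: np.ndarray
    parcellation: Parcellation | None = None

    def __post_init__(self):
        self.sc = np.asarray(self.sc, dtype=float)
        self.fc = np.asarray(self.fc, dtype=float)
        if self.sc.shape != self.fc.shape or self.sc.ndim != 2:
            raise ValueError("sc and fc must be square matrices of equal "
                             "shape")
        for name, m in (("sc", self.sc), ("fc", self.fc)):
            if not np.allclose(m, m.T,
                               atol=1e-9 * max(1.0, np.abs(m).max())):
                raise ValueError(f"{name} must be symmetric")


def _check_same_grid(sc: ContinuousSC, fc: ContinuousFC):
    if sc.grid is not fc.grid and sc.grid.checksum() != fc.grid.checksum():
        raise ValueError("SC and FC were computed on different grids")


def _normalized_inner(sc_rows: np.ndarray, fc_rows: np.ndarray,
                      weights: np.ndarray) -> np.ndarray:
    num = (sc_rows * fc_rows) @ weights
    n_sc = (sc_rows ** 2) @ weights
    n_fc = (fc_rows ** 2) @ weights
    den = np.sqrt(n_sc * n_fc)
    degenerate = den <= 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} vertices have a zero SC or "
                      "FC norm; their coupling is set to 0", stacklevel=3)
    out = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    return np.clip(out, -1.0, 1.0)


def sfc_global(sc: ContinuousSC, fc: ContinuousFC) -> CouplingField:
    """Whole-surface coupling: at each vertex, the area-weighted normalized
    inner product of its SC and FC rows (the point itself contributes
    nothing: both rows are zero on the diagonal by definition)."""
    _check_same_grid(sc, fc)
    a = sc.grid.masked_areas
    vals = _normalized_inner(sc.values, fc.values, a)
    return CouplingField(values=vals, kind="global")


def sfc_local(sc: ContinuousSC, fc: ContinuousFC,
              parc: Parcellation) -> CouplingField:
    """Within-parcel coupling: the global formula with the integration
    domain restricted to the parcel of each vertex.  Unassigned vertices and
    parcels with fewer than two vertices get NaN."""
    _check_same_grid(sc, fc)
    a = sc.grid.masked_areas
    out = np.full(sc.grid.n_masked, np.nan)
    for roi in parc.roi_ids:
        m = parc.members(roi)
        if len(m) < 2:
            warnings.warn(f"ROI {roi} has fewer than 2 vertices; local "
                          "coupling is undefined there", stacklevel=2)
            continue
        sub = np.ix_(m, m)
        out[m] = _normalized_inner(sc.values[sub], fc.values[sub], a[m])
    return CouplingField(values=out, kind="local", parcellation=parc)


def discrete_sc(sc: ContinuousSC, parc: Parcellation) -> np.ndarray:
    """Parcel-pair SC: the density integral over E1 x E2 divided by
    |E1||E2| — connection density per unit area squared."""
    ids = parc.roi_ids
    a = sc.grid.masked_areas
    w = np.zeros((len(ids), sc.grid.n_masked))
    for i, roi in enumerate(ids):
        m = parc.members(roi)
        w[i, m] = a[m]
    areas = w.sum(axis=1)
    return (w @ sc.values @ w.T) / np.outer(areas, areas)


def discrete_fc(fc: ContinuousFC, parc: Parcellation) -> np.ndarray:
    """Parcel-pair FC: Fisher-z transform, area-weighted average over vertex
    pairs, inverse transform.  Within-parcel entries exclude the (zero)
    diagonal pairs from the average; |r| is clipped just below 1 before
    artanh."""
    ids = parc.roi_ids
    a = fc.grid.masked_areas
    z = np.arctanh(np.clip(fc.values, -_ARTANH_CLIP, _ARTANH_CLIP))
    np.fill_diagonal(z, 0.0)
    w = np.zeros((len(ids), fc.grid.n_masked))
    for i, roi in enumerate(ids):
        m = parc.members(roi)
        w[i, m] = a[m]
    areas = w.sum(axis=1)
    num = w @ z @ w.T
    den = np.outer(areas, areas)
    # within-ROI: remove the self-pair weight a_u^2 from the normalization
    den[np.diag_indices_from(den)] -= (w ** 2).sum(axis=1)
    # a singleton parcel has no within pairs: its diagonal entry is NaN
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.tanh(num / den)


def _row_correlations(sc_rows: np.ndarray, fc_rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of matched off-diagonal rows, NaN when a row is
    constant."""
    k = sc_rows.shape[0]
    if k < 3:
        raise ValueError("need at least 3 ROIs for row correlations")
    out = np.full(k, np.nan)
    n_const = 0
    for i in range(k):
        others = np.arange(k) != i
        x, y = sc_rows[i, others], fc_rows[i, others]
        if x.std() == 0 or y.std() == 0:
            n_const += 1
            continue
        out[i] = np.corrcoef(x, y)[0, 1]
    if n_const:
        warnings.warn(f"{n_const} ROI rows are constant (disconnected ROI?);"
                      " their coupling is undefined", stacklevel=3)
    return np.clip(out, -1.0, 1.0)


def sfc_discrete(dc: DiscreteConnectome) -> CouplingField:
    """Per-parcel coupling of the discretized connectomes: correlation
    between the off-diagonal SC and FC rows of each parcel."""
    vals = _row_correlations(dc.sc, dc.fc)
    return CouplingField(values=vals, kind="discrete",
                         parcellation=dc.parcellation)


def sfc_traditional(streamline_counts: np.ndarray,
                    roi_mean_series: np.ndarray,
                    parcellation: Parcellation | None = None
                    ) -> CouplingField:
    """Atlas-pipeline baseline coupling.

    Parameters
    ----------
    streamline_counts : (k, k) symmetric array
        Raw streamline counts per parcel pair.
    roi_mean_series : (k, T) array, T >= 3
        Mean BOLD series per parcel; their Pearson correlations form the
        traditional FC.
    """
    counts = np.asarray(streamline_counts, dtype=float)
    if not np.allclose(counts, counts.T):
        raise ValueError("streamline counts must be symmetric")
    series = np.asarray(roi_mean_series, dtype=float)
    if series.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    if counts.shape[0] != series.shape[0]:
        raise ValueError("counts and series describe different ROI sets")
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(series)
    fc = np.nan_to_num(fc)
    np.fill_diagonal(fc, 0.0)
    vals = _row_correlations(counts, fc)
    return CouplingField(values=vals, kind="traditional",
                         parcellation=parcellation)
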