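"""Test-retest reliability of connectome features.

Two complementary reliability statistics are provided for a set of repeated
measurements (several subjects, several sessions each):

* the **distance-based intraclass correlation** (dICC).  With dbs2 the mean
  squared Frobenius distance between features of *different* subjects and
  dws2 the mean over repeated features of the *same* subject,

      dICC = dbs2 / (dbs2 + dws2),

  a single number per feature type in (0, 1); values near 1 mean
  within-subject repeats are far closer than different subjects.
  Uncertainty is quantified by bootstrap over subjects, reporting the
  median, the interquartile range and P(dICC < 0.5) (the probability mass
  on the "not reproducible" side).

* the classical **node-wise ICC** — a one-way random-effects ICC(1,1)
  computed independently at every matrix element or vertex from the between-
  and within-subject mean squares.

The same machinery drives KDE bandwidth selection for the structural
connectome: the bandwidth maximizing the dICC across a candidate list is
chosen (ties resolve to the smallest bandwidth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import HemispherePairGrid
from .mesh import SphereMesh
from .sc import (HeatKernelSpec, StreamlineEndpoints, endpoint_histogram,
                 smooth_sc)

__all__ = [
    "RepeatedFeatureSet", "ReliabilityReport", "pairwise_distances",
    "dicc", "bootstrap_dicc", "nodewise_icc", "select_bandwidth",
    "BandwidthSelection",
]


@dataclass
class RepeatedFeatureSet:
    """Equal-shape features with subject and session identity.

    features : list of arrays (matrices or vectors), one per measurement
    subject_ids, session_ids : parallel label sequences
    """

    features: list
    subject_ids: np.ndarray
    session_ids: np.ndarray

    def __post_init__(self):
        self.features = [np.asarray(f, dtype=float) for f in self.features]
        self.subject_ids = np.asarray(self.subject_ids)
        self.session_ids = np.asarray(self.session_ids)
        n = len(self.features)
        if len(self.subject_ids) != n or len(self.session_ids) != n:
            raise ValueError("subject/session labels must match features")
        shapes = {f.shape for f in self.features}
        if len(shapes) > 1:
            raise ValueError(f"features have mixed shapes: {shapes}")
        subjects, counts = np.unique(self.subject_ids, return_counts=True)
        if len(subjects) < 2:
            raise ValueError("need at least 2 subjects")
        if counts.max() < 2:
            raise ValueError("need at least one subject with >= 2 sessions")

    @property
    def n_measurements(self) -> int:
        return len(self.features)

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def stacked(self) -> np.ndarray:
        """(n_measurements, n_elements) flattened feature matrix."""
        return np.stack([f.ravel() for f in self.features])

    def exclude(self, subjects) -> "RepeatedFeatureSet":
        """Leave out the listed subjects (outlier removal)."""
        drop = set(np.atleast_1d(subjects).tolist())
        keep = [i for i, s in enumerate(self.subject_ids)
                if s not in drop]
        return RepeatedFeatureSet(
            features=[self.features[i] for i in keep],
            subject_ids=self.subject_ids[keep],
            session_ids=self.session_ids[keep])


@dataclass
class ReliabilityReport:
    dicc: float
    mean_sq_between: float
    mean_sq_within: float
    bootstrap_median: float | None = None
    bootstrap_iqr: float | None = None
    p_below_half: float | None = None
    n_bootstrap: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def pairwise_distances(feature_set: RepeatedFeatureSet) -> np.ndarray:
    """Symmetric matrix of Frobenius-norm distances between all features."""
    x = feature_set.stacked()
    sq = np.einsum("ij,ij->i", x, x)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def dicc(distances: np.ndarray, subject_ids) -> ReliabilityReport:
    """Distance-based ICC from a distance matrix and subject labels.

    dicc = dbs2/(dbs2 + dws2) with dws2 the mean squared distance over
    same-subject measurement pairs and dbs2 over different-subject pairs.
    """
    d = np.asarray(distances, dtype=float)
    subject_ids = np.asarray(subject_ids)
    n = len(subject_ids)
    if d.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    iu = np.triu_indices(n, k=1)
    same = subject_ids[iu[0]] == subject_ids[iu[1]]
    if not same.any():
        raise ValueError("no within-subject pairs")
    d2 = d[iu] ** 2
    dws2 = float(d2[same].mean())
    dbs2 = float(d2[~same].mean())
    total = dbs2 + dws2
    value = dbs2 / total if total > 0 else np.nan
    return ReliabilityReport(dicc=value, mean_sq_between=dbs2,
                             mean_sq_within=dws2)


def _subject_blocks(distances: np.ndarray, subject_ids):
    """Cross-subject sums of squared distances.

    G[a, b] = sum of squared distances between every session of subject a
    and every session of subject b (ordered pairs, so G[a, a] counts each
    unordered within pair twice); k[a] = session count of subject a.
    """
    subjects, inv = np.unique(subject_ids, return_inverse=True)
    ns = len(subjects)
    ind = np.zeros((ns, len(subject_ids)))
    ind[inv, np.arange(len(subject_ids))] = 1.0
    d2 = np.asarray(distances, float) ** 2
    G = ind @ d2 @ ind.T
    k = ind.sum(axis=1)
    return G, k


def bootstrap_dicc(feature_set: RepeatedFeatureSet, B: int = 10_000,
                   n_subjects: int | None = None, seed: int = 0,
                   distances: np.ndarray | None = None) -> ReliabilityReport:
    """Bootstrap the dICC by resampling subjects with replacement.

    Each replicate draws ``n_subjects`` subjects (default: the observed
    number) with replacement; sessions travel with their subject.  Reported
    are the replicate median, the IQR (75th minus 25th percentile) and
    P(dICC < 0.5).  Replicates that draw a single distinct subject have no
    between-subject pairs and are redrawn (with a warning tallying how
    many).  Results are reproducible under a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if distances is None:
        distances = pairwise_distances(feature_set)
    base = dicc(distances, feature_set.subject_ids)
    G, k = _subject_blocks(distances, feature_set.subject_ids)
    ns = len(k)
    draw = n_subjects if n_subjects is not None else ns
    rng = np.random.default_rng(seed)

    # multiplicity matrix: replicates x subjects
    M = np.zeros((B, ns))
    idx = rng.integers(0, ns, size=(B, draw))
    for b in range(B):
        np.add.at(M[b], idx[b], 1.0)
    bad = (M > 0).sum(axis=1) < 2
    n_redrawn = 0
    while bad.any():
        n_redrawn += int(bad.sum())
        idx = rng.integers(0, ns, size=(int(bad.sum()), draw))
        M[bad] = 0.0
        for r, b in enumerate(np.flatnonzero(bad)):
            np.add.at(M[b], idx[r], 1.0)
        bad = (M > 0).sum(axis=1) < 2
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} degenerate bootstrap replicates "
                      "(single distinct subject)", stacklevel=2)

    g_diag = np.diag(G)
    # within: each subject copy contributes its own session pairs
    within_sum = 0.5 * M @ g_diag
    within_cnt = M @ (k * (k - 1) / 2.0)
    # between: all session pairs across distinct subject copies
    between_sum = 0.5 * np.einsum("bi,ij,bj->b", M, G, M) - 0.5 * M @ g_diag
    mk = M @ k
    between_cnt = 0.5 * (mk ** 2 - M @ (k ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        dws2 = within_sum / within_cnt
        dbs2 = between_sum / between_cnt
        reps = dbs2 / (dbs2 + dws2)
    reps = reps[np.isfinite(reps)]
    if reps.size == 0:
        raise ValueError("all bootstrap replicates were degenerate "
                         "(no subject with repeated sessions drawn)")
    q25, q50, q75 = np.percentile(reps, [25, 50, 75])
    return ReliabilityReport(
        dicc=base.dicc, mean_sq_between=base.mean_sq_between,
        mean_sq_within=base.mean_sq_within,
        bootstrap_median=float(q50), bootstrap_iqr=float(q75 - q25),
        p_below_half=float(np.mean(reps < 0.5)),
        n_bootstrap=B, seed=seed)


def nodewise_icc(feature_set: RepeatedFeatureSet,
                 variant: str = "icc1") -> np.ndarray:
    """One-way random-effects ICC(1,1) at every feature element.

    Sessions are treated as exchangeable repeated measurements nested in
    subjects.  For subject i with k_i sessions and N = sum k_i measurements,

        MSB = sum_i k_i (m_i - m)^2 / (n - 1)
        MSW = sum_ij (x_ij - m_i)^2 / (N - n)
        ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW),

    with k0 = (N - sum k_i^2 / N)/(n - 1) the unbalanced-design session
    count.  Values are clipped to [-1, 1]; elements with zero total variance
    are NaN (reported in a warning).

    ``variant="icc1"`` is the only implemented form; the argument names the
    convention explicitly at call sites.
    """
    if variant != "icc1":
        raise ValueError(f"unsupported ICC variant {variant!r}")
    x = feature_set.stacked()                       # (N, p)
    subjects, inv = np.unique(feature_set.subject_ids, return_inverse=True)
    n = len(subjects)
    N = x.shape[0]
    if N <= n:
        raise ValueError("no repeated sessions: ICC undefined")
    ind = np.zeros((n, N))
    ind[inv, np.arange(N)] = 1.0
    k = ind.sum(axis=1)                             # sessions per subject
    m_subj = (ind @ x) / k[:, None]                 # (n, p) subject means
    m_grand = x.mean(axis=0)
    msb = (k[:, None] * (m_subj - m_grand) ** 2).sum(axis=0) / (n - 1)
    resid = x - m_subj[inv]
    msw = (resid ** 2).sum(axis=0) / (N - n)
    k0 = (N - (k ** 2).sum() / N) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msb - msw) / (msb + (k0 - 1.0) * msw)
    dead = ~np.isfinite(icc)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} elements have zero total variance;"
                      " their ICC is undefined (NaN)", stacklevel=2)
    return np.clip(icc, -1.0, 1.0)


@dataclass
class BandwidthSelection:
    chosen_h: float
    table: dict = field(default_factory=dict)   # h -> ReliabilityReport


def select_bandwidth(endpoint_sets: list[StreamlineEndpoints],
                     subject_ids, session_ids,
                     grid: HemispherePairGrid,
                     candidate_h: list[float],
                     tail_tol: float = 1e-8,
                     snap_mesh: SphereMesh | None = None
                     ) -> BandwidthSelection:
    """Choose the KDE bandwidth maximizing SC reproducibility.

    For every candidate h the continuous SC of each session is computed
    (h = 0 denotes the unsmoothed endpoint histogram) and the dICC across
    subjects is tabulated; the h with the highest dICC wins, ties going to
    the smallest h.
    """
    if len(candidate_h) == 0:
        raise ValueError("candidate_h is empty")
    subject_ids = np.asarray(subject_ids)
    session_ids = np.asarray(session_ids)
    table: dict[float, ReliabilityReport] = {}
    for h in candidate_h:
        if h < 0:
            raise ValueError("bandwidth candidates must be >= 0")
        if h == 0:
            feats = [endpoint_histogram(ep, grid).values
                     for ep in endpoint_sets]
        else:
            spec = HeatKernelSpec(h=h, tail_tol=tail_tol)
            feats = [smooth_sc(ep, grid, spec, snap_mesh=snap_mesh).values
                     for ep in endpoint_sets]
        fs = RepeatedFeatureSet(features=feats, subject_ids=subject_ids,
                                session_ids=session_ids)
        table[float(h)] = dicc(pairwise_distances(fs), subject_ids)
    best = max(sorted(table), key=lambda h: table[h].dicc)
    return BandwidthSelection(chosen_h=float(best), table=table)
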