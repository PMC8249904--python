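"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the connectome estimators
assume, while staying fully self-contained:

* parcellations by farthest-point seeding and nearest-seed assignment
  (geodesically convex, connected parcels — a stand-in for anatomical
  atlases and their lobar merges);
* BOLD fields with exact block covariance (correlation ``r_within`` inside
  a parcel, ``r_between`` across parcels, unit variances) built from a
  shared/parcel/private factor decomposition, so Pearson-correlation
  expectations are known in closed form;
* streamline endpoint pairs from mixtures of product von Mises-Fisher
  components, whose closed-form density is the oracle for KDE consistency;
* test-retest cohorts with planted between- and within-subject variance
  components, for which the distance-based and node-wise intraclass
  correlations have analytic values.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupling import Parcellation, UNASSIGNED
from .fc import VertexTimeSeriesField
from .grid import HemispherePairGrid
from .reliability import RepeatedFeatureSet
from .sc import StreamlineEndpoints

__all__ = [
    "EndpointMixture", "FixtureSpec", "Cohort",
    "sample_vmf", "vmf_density",
    "simulate_parcellation", "simulate_bold", "simulate_endpoints",
    "true_density", "simulate_feature_cohort", "simulate_endpoint_cohort",
    "simulate_cohort",
]


# -- von Mises-Fisher primitives ------------------------------------------

def sample_vmf(mu: np.ndarray, kappa: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw n points from vMF(mu, kappa) on the unit 2-sphere.

    Uses the exact inverse-CDF for the cosine of the polar angle; kappa = 0
    is the uniform distribution.
    """
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    u = rng.random(n)
    if kappa <= 0:
        w = 2.0 * u - 1.0
    else:
        # w = 1 + log(u + (1-u) e^{-2k}) / k, stable for large kappa
        w = 1.0 + np.log1p(-(1.0 - u) * -np.expm1(-2.0 * kappa)) / kappa
    phi = rng.random(n) * 2.0 * np.pi
    r = np.sqrt(np.maximum(0.0, 1.0 - w ** 2))
    local = np.column_stack([r * np.cos(phi), r * np.sin(phi), w])
    # orthonormal frame with mu as the pole
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mu @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    frame = np.stack([e1, e2, mu])
    out = local @ frame
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def vmf_density(x: np.ndarray, mu: np.ndarray, kappa: float) -> np.ndarray:
    """vMF density on the 2-sphere (probability per steradian)."""
    t = np.asarray(x, dtype=float) @ np.asarray(mu, dtype=float)
    if kappa <= 0:
        return np.full(np.shape(t), 1.0 / (4.0 * np.pi))
    # kappa / (4 pi sinh kappa) * exp(kappa t), written overflow-safe
    return kappa / (2.0 * np.pi * -np.expm1(-2.0 * kappa)) \
        * np.exp(kappa * (t - 1.0))


@dataclass
class EndpointMixture:
    """Mixture of product-vMF components for streamline endpoint pairs.

    means : (C, 2, 3) unit vectors — the two endpoint modes per component
    hemis : (C, 2) ints — hemisphere of each mode
    kappas : (C,) concentrations (>= 0; 0 = uniform)
    weights : (C,) mixing proportions summing to 1
    """

    means: np.ndarray
    hemis: np.ndarray
    kappas: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.hemis = np.asarray(self.hemis, dtype=np.int8)
        self.kappas = np.asarray(self.kappas, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        c = len(self.weights)
        if self.means.shape != (c, 2, 3) or self.hemis.shape != (c, 2) \
                or self.kappas.shape != (c,):
            raise ValueError("inconsistent mixture component shapes")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if (self.weights < 0).any() or (self.kappas < 0).any():
            raise ValueError("weights and kappas must be nonnegative")
        self.means = self.means / np.linalg.norm(self.means, axis=2,
                                                 keepdims=True)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @classmethod
    def from_parcellation(cls, parc: Parcellation, roi_pairs, kappa,
                          weights=None) -> "EndpointMixture":
        """Components centered on parcel centroids for the listed ROI-id
        pairs, all with concentration ``kappa`` (scalar or per-component)."""
        grid = parc.grid
        verts = grid.masked_vertices
        hemi = grid.masked_hemisphere
        means, hemis = [], []
        for ra, rb in roi_pairs:
            pair_m, pair_h = [], []
            for r in (ra, rb):
                m = parc.members(r)
                if len(m) == 0:
                    raise ValueError(f"ROI {r} is empty")
                c = verts[m].mean(axis=0)
                c /= np.linalg.norm(c)
                pair_m.append(c)
                pair_h.append(hemi[m[0]])
            means.append(pair_m)
            hemis.append(pair_h)
        n = len(roi_pairs)
        kappas = np.broadcast_to(np.asarray(kappa, float), (n,)).copy()
        if weights is None:
            weights = np.full(n, 1.0 / n)
        return cls(means=np.array(means), hemis=np.array(hemis),
                   kappas=kappas, weights=np.asarray(weights, float))


# -- generators ------------------------------------------------------------

def simulate_parcellation(grid: HemispherePairGrid, k: int,
                          seed: int = 0) -> Parcellation:
    """k connected parcels per hemisphere by farthest-point seeding.

    Seeds are chosen greedily to maximize the minimal geodesic distance to
    earlier seeds (first seed random); each masked vertex joins its nearest
    seed.  Nearest-seed cells on a sphere are geodesically convex, hence
    connected in the mesh adjacency.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    verts = grid.masked_vertices
    hemi = grid.masked_hemisphere
    labels = np.full(grid.n_masked, UNASSIGNED, dtype=np.int64)
    for h in (0, 1):
        sel = np.flatnonzero(hemi == h)
        if len(sel) < k:
            raise ValueError(f"k={k} exceeds the {len(sel)} masked vertices "
                             f"of hemisphere {h}")
        pts = verts[sel]
        seeds = [int(rng.integers(len(sel)))]
        min_d = np.arccos(np.clip(pts @ pts[seeds[0]], -1, 1))
        for _ in range(1, k):
            nxt = int(np.argmax(min_d))
            seeds.append(nxt)
            min_d = np.minimum(min_d,
                               np.arccos(np.clip(pts @ pts[nxt], -1, 1)))
        d = np.arccos(np.clip(pts @ pts[seeds].T, -1, 1))
        labels[sel] = d.argmin(axis=1) + h * k
    return Parcellation(labels=labels, grid=grid)


def simulate_bold(grid: HemispherePairGrid, parc: Parcellation,
                  r_within: float, r_between: float, T: int,
                  seed: int = 0) -> VertexTimeSeriesField:
    """Zero-mean Gaussian series at the masked grid vertices with exact
    block covariance: correlation ``r_within`` inside a parcel,
    ``r_between`` across parcels, unit variances.

    The covariance  r_b + (r_w - r_b) [same parcel] + (1 - r_w) I  is
    realized by a shared factor, one factor per parcel, and private noise;
    it is positive definite exactly when 0 <= r_between <= r_within < 1
    (requests outside that range are rejected with the offending
    eigenvalue).  Unassigned vertices behave as singleton parcels.
    """
    if not (0.0 <= r_between <= r_within < 1.0):
        # smallest covariance eigenvalue under the block model
        lam = min(1.0 - r_within, 1.0 - r_between)
        raise ValueError(
            f"need 0 <= r_between <= r_within < 1 for a positive definite "
            f"block covariance (offending eigenvalue {lam:.4g})")
    rng = np.random.default_rng(seed)
    labels = parc.labels
    n = grid.n_masked
    shared = rng.standard_normal(T)
    series = np.sqrt(r_between) * shared[None, :] \
        + np.sqrt(1.0 - r_within) * rng.standard_normal((n, T))
    rois = np.unique(labels)
    amp = np.sqrt(r_within - r_between)
    for roi in rois:
        m = np.flatnonzero(labels == roi)
        if roi == UNASSIGNED:
            series[m] += amp * rng.standard_normal((len(m), T))
        else:
            series[m] += amp * rng.standard_normal(T)[None, :]
    return VertexTimeSeriesField(series=series,
                                 positions=grid.masked_vertices,
                                 hemisphere=grid.masked_hemisphere)


def simulate_endpoints(mixture: EndpointMixture, N: int,
                       seed: int = 0) -> StreamlineEndpoints:
    """Draw N endpoint pairs from the product-vMF mixture, with the order
    of the two endpoints randomized per streamline."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(mixture.n_components, size=N, p=mixture.weights)
    pos = np.empty((N, 2, 3))
    hem = np.empty((N, 2), dtype=np.int8)
    for c in range(mixture.n_components):
        sel = np.flatnonzero(comp == c)
        if len(sel) == 0:
            continue
        for side in (0, 1):
            pos[sel, side] = sample_vmf(mixture.means[c, side],
                                        mixture.kappas[c], len(sel), rng)
            hem[sel, side] = mixture.hemis[c, side]
    flip = rng.random(N) < 0.5
    pos[flip] = pos[flip][:, ::-1]
    hem[flip] = hem[flip][:, ::-1]
    return StreamlineEndpoints(positions=pos, hemispheres=hem)


def true_density(mixture: EndpointMixture,
                 grid: HemispherePairGrid) -> np.ndarray:
    """The symmetrized mixture pair density evaluated at all masked grid
    vertex pairs (the oracle for KDE consistency checks)."""
    verts = grid.masked_vertices
    hemi = grid.masked_hemisphere
    n = grid.n_masked
    out = np.zeros((n, n))
    for c in range(mixture.n_components):
        f = np.empty((2, n))
        for side in (0, 1):
            f[side] = np.where(
                hemi == mixture.hemis[c, side],
                vmf_density(verts, mixture.means[c, side],
                            mixture.kappas[c]),
                0.0)
        out += mixture.weights[c] * 0.5 * (np.outer(f[0], f[1])
                                           + np.outer(f[1], f[0]))
    return out


def simulate_feature_cohort(shape, n_subjects: int, n_sessions: int,
                            sigma_between: float, sigma_within: float,
                            seed: int = 0):
    """Repeated features x_ij = b_i + e_ij with planted variance components.

    b_i ~ N(0, sigma_between^2) per subject, e_ij ~ N(0, sigma_within^2)
    per session, independently at every element.

    Returns the :class:`RepeatedFeatureSet` and a ground-truth dict with the
    analytic node-wise ICC sb^2/(sb^2+sw^2) and the analytic dICC
    (sb^2+sw^2)/(sb^2+2 sw^2) — the latter because a between-subject squared
    distance has expectation 2 sb^2 + 2 sw^2 per element while a
    within-subject one has 2 sw^2.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    feats, subs, sess = [], [], []
    for i in range(n_subjects):
        b = sigma_between * rng.standard_normal(shape)
        for j in range(n_sessions):
            feats.append(b + sigma_within * rng.standard_normal(shape))
            subs.append(i)
            sess.append(j)
    fs = RepeatedFeatureSet(features=feats, subject_ids=np.array(subs),
                            session_ids=np.array(sess))
    sb2, sw2 = sigma_between ** 2, sigma_within ** 2
    truth = {
        "analytic_icc": sb2 / (sb2 + sw2) if sb2 + sw2 > 0 else np.nan,
        "analytic_dicc": (sb2 + sw2) / (sb2 + 2.0 * sw2)
        if sb2 + 2 * sw2 > 0 else 1.0,
        "sigma_between": sigma_between,
        "sigma_within": sigma_within,
    }
    return fs, truth


def _jitter_direction(mu: np.ndarray, sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Perturb a unit vector by a tangent-plane Gaussian of sd radians."""
    if sd <= 0:
        return mu.copy()
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mu @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    v = mu + sd * (rng.standard_normal() * e1 + rng.standard_normal() * e2)
    return v / np.linalg.norm(v)


def simulate_endpoint_cohort(mixture: EndpointMixture, n_subjects: int,
                             n_sessions: int, N: int,
                             between_sd: float = 0.05, seed: int = 0):
    """Test-retest endpoint sets: each subject perturbs the base mixture
    (component means jittered by ``between_sd`` radians, weights
    redistributed), each session draws N streamlines independently.

    Returns (endpoint_sets, subject_ids, session_ids, subject_mixtures).
    """
    rng = np.random.default_rng(seed)
    sets, subs, sess, mixes = [], [], [], []
    for i in range(n_subjects):
        means = np.array([[_jitter_direction(m, between_sd, rng)
                           for m in pair] for pair in mixture.means])
        logits = np.log(mixture.weights) + between_sd * \
            rng.standard_normal(mixture.n_components)
        w = np.exp(logits - logits.max())
        w /= w.sum()
        subj_mix = EndpointMixture(means=means, hemis=mixture.hemis,
                                   kappas=mixture.kappas, weights=w)
        mixes.append(subj_mix)
        for j in range(n_sessions):
            sets.append(simulate_endpoints(
                subj_mix, N, seed=int(rng.integers(2 ** 31 - 1))))
            subs.append(i)
            sess.append(j)
    return sets, np.array(subs), np.array(sess), mixes


@dataclass
class FixtureSpec:
    """Study-scale description of a complete synthetic cohort."""

    grid_level: int = 3
    k_parcels: int = 6              # per hemisphere
    r_within: float = 0.6
    r_between: float = 0.1
    T: int = 1200
    kappa: float = 50.0
    n_components: int = 3
    n_subjects: int = 10
    n_sessions: int = 2
    n_streamlines: int = 5000
    between_sd: float = 0.05        # subject-level mixture jitter, radians
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.r_between < self.r_within < 1.0):
            raise ValueError("need 0 <= r_between < r_within < 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.n_subjects < 2:
            raise ValueError("need >= 2 subjects")


@dataclass
class Cohort:
    """A simulated test-retest study with its generating ground truth."""

    spec: FixtureSpec
    grid: HemispherePairGrid
    parcellation: Parcellation
    base_mixture: EndpointMixture
    endpoint_sets: list
    bold_fields: list
    subject_ids: np.ndarray
    session_ids: np.ndarray
    subject_mixtures: list = field(default_factory=list)


def simulate_cohort(spec: FixtureSpec) -> Cohort:
    """Generate the full synthetic study: grid, parcellation, per-session
    streamline endpoints and BOLD fields, all reproducible from the seed."""
    from .mesh import build_icosphere
    from .grid import build_grid

    rng = np.random.default_rng(spec.seed)
    grid = build_grid(build_icosphere(spec.grid_level, "left"),
                      build_icosphere(spec.grid_level, "right"))
    parc = simulate_parcellation(grid, spec.k_parcels,
                                 seed=int(rng.integers(2 ** 31 - 1)))
    roi_ids = parc.roi_ids
    pairs = [tuple(rng.choice(roi_ids, size=2, replace=False))
             for _ in range(spec.n_components)]
    mixture = EndpointMixture.from_parcellation(parc, pairs, spec.kappa)
    sets, subs, sess, mixes = simulate_endpoint_cohort(
        mixture, spec.n_subjects, spec.n_sessions, spec.n_streamlines,
        between_sd=spec.between_sd, seed=int(rng.integers(2 ** 31 - 1)))
    fields = [simulate_bold(grid, parc, spec.r_within, spec.r_between,
                            spec.T, seed=int(rng.integers(2 ** 31 - 1)))
              for _ in range(len(sets))]
    return Cohort(spec=spec, grid=grid, parcellation=parc,
                  base_mixture=mixture, endpoint_sets=sets,
                  bold_fields=fields, subject_ids=subs, session_ids=sess,
                  subject_mixtures=mixes)
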