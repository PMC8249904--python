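"""Vertex-wise two-group comparison with suprathreshold-cluster correction.

The procedure follows the nonparametric permutation framework of Nichols &
Holmes: an independent two-sample t-test is run at every grid vertex;
clusters are the connected components (mesh-edge adjacency) of vertices with
uncorrected p below the forming threshold; group labels are then permuted,
and the maximal cluster size under each relabeling builds the null
distribution.  The critical size is the smallest integer s with
P(max size >= s) <= alpha over the null set (the observed labeling is always
a member), i.e. the ceiling-adjusted (1-alpha) quantile of the permutation
maxima.  Every vertex inside a cluster at or above the critical size is
declared significant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = ["ClusterTestResult", "vertexwise_ttest",
           "suprathreshold_cluster_test"]


def vertexwise_ttest(group_a: np.ndarray, group_b: np.ndarray,
                     equal_var: bool = True):
    """Two-sided two-sample t-test at every vertex.

    Parameters
    ----------
    group_a, group_b : (n_subjects, n_vertices) arrays
    equal_var : bool
        Pooled-variance test (default) or Welch.

    Returns
    -------
    (t, p) arrays of length n_vertices.  Vertices where both groups have
    zero variance get t = 0, p = 1.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups measured on different vertex sets")
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    dead = (va == 0) & (vb == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if equal_var:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full_like(se, na + nb - 2.0)
        else:
            se = np.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (ma - mb) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(dead, 0.0, t)
    p = np.where(dead, 1.0, p)
    return t, p


@dataclass
class ClusterTestResult:
    t: np.ndarray
    p_uncorrected: np.ndarray
    cluster_labels: np.ndarray          # -1 where below forming threshold
    cluster_sizes: np.ndarray           # size per observed cluster
    cluster_p: np.ndarray               # permutation p per observed cluster
    critical_size: float
    significant: np.ndarray             # bool per vertex
    perm_maxima: np.ndarray
    n_permutations: int
    forming_p: float
    alpha: float
    seed: int | None


def _cluster_sizes(passing: np.ndarray, adjacency: sparse.csr_matrix,
                   weights: np.ndarray):
    """Connected components of the passing vertices; returns labels per
    vertex (-1 outside) and the weight sum per component."""
    idx = np.flatnonzero(passing)
    labels = np.full(len(passing), -1, dtype=np.int64)
    if len(idx) == 0:
        return labels, np.empty(0)
    sub = adjacency[idx][:, idx]
    n_comp, comp = connected_components(sub, directed=False)
    labels[idx] = comp
    sizes = np.zeros(n_comp)
    np.add.at(sizes, comp, weights[idx])
    return labels, sizes


def _label_permutations(n_total: int, n_a: int, n_perm: int,
                        rng: np.random.Generator):
    """Distinct group-A index sets: the observed labeling first, the rest
    sampled without replacement (or fully enumerated when feasible)."""
    observed = tuple(range(n_a))
    total = comb(n_total, n_a)
    if total <= n_perm:
        warnings.warn(f"only {total} distinct relabelings exist; "
                      "enumerating all of them", stacklevel=3)
        sets = [observed] + [c for c in
                             itertools.combinations(range(n_total), n_a)
                             if c != observed]
        return np.array(sets)
    seen = {observed}
    out = [observed]
    while len(out) < n_perm:
        cand = tuple(sorted(rng.choice(n_total, size=n_a, replace=False)))
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return np.array(out)


def suprathreshold_cluster_test(fields: np.ndarray, labels: np.ndarray,
                                adjacency: sparse.spmatrix,
                                forming_p: float = 0.05, alpha: float = 0.05,
                                n_perm: int = 1000, seed: int | None = 0,
                                equal_var: bool = True,
                                vertex_areas: np.ndarray | None = None,
                                block: int = 128) -> ClusterTestResult:
    """Two-group suprathreshold cluster permutation test on the surface.

    Parameters
    ----------
    fields : (n_subjects, n_vertices) array
        One coupling (or any scalar) field per subject.
    labels : (n_subjects,) array with exactly two distinct values
        Group membership.
    adjacency : sparse (n_vertices, n_vertices)
        Vertex adjacency of the analysis grid (mesh edges).
    vertex_areas : optional
        When given, cluster size is the summed area of member vertices
        instead of the vertex count.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(fields, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, found {len(groups)}")
    adjacency = sparse.csr_matrix(adjacency)
    if adjacency.shape != (x.shape[1], x.shape[1]):
        raise ValueError("adjacency does not match the vertex dimension")
    # reorder so group A occupies the leading rows; permutations are then
    # index sets into the reordered array
    order = np.concatenate([np.flatnonzero(labels == groups[0]),
                            np.flatnonzero(labels == groups[1])])
    x = x[order]
    n_a = int((labels == groups[0]).sum())
    n = x.shape[0]
    weights = (np.ones(x.shape[1]) if vertex_areas is None
               else np.asarray(vertex_areas, dtype=float))

    rng = np.random.default_rng(seed)
    perms = _label_permutations(n, n_a, n_perm, rng)
    n_perm_eff = len(perms)

    # moment sums make each permutation a couple of matrix products
    sum_all = x.sum(axis=0)
    sumsq_all = (x ** 2).sum(axis=0)
    n_b = n - n_a
    maxima = np.empty(n_perm_eff)
    obs_labels = obs_sizes = None
    t_obs = p_obs = None
    for lo in range(0, n_perm_eff, block):
        sel = perms[lo:lo + block]
        P = np.zeros((len(sel), n))
        P[np.arange(len(sel))[:, None], sel] = 1.0
        sa = P @ x
        sa2 = P @ (x ** 2)
        ma = sa / n_a
        mb = (sum_all - sa) / n_b
        va = (sa2 - sa ** 2 / n_a) / (n_a - 1)
        vb = ((sumsq_all - sa2) - (sum_all - sa) ** 2 / n_b) / (n_b - 1)
        va = np.maximum(va, 0.0)
        vb = np.maximum(vb, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            if equal_var:
                sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n - 2)
                se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
                df = np.full_like(se, float(n - 2))
            else:
                se = np.sqrt(va / n_a + vb / n_b)
                df = (va / n_a + vb / n_b) ** 2 / (
                    (va / n_a) ** 2 / (n_a - 1)
                    + (vb / n_b) ** 2 / (n_b - 1))
            t = (ma - mb) / se
            p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(se == 0, 1.0, p)
        t = np.nan_to_num(t)
        for r in range(len(sel)):
            cl, sizes = _cluster_sizes(p[r] <= forming_p, adjacency, weights)
            maxima[lo + r] = sizes.max() if sizes.size else 0.0
            if lo + r == 0:             # observed labeling
                obs_labels, obs_sizes = cl, sizes
                t_obs, p_obs = t[r].copy(), p[r].copy()

    # smallest size with null exceedance probability <= alpha
    if maxima.max() > 0:
        cand = np.unique(np.concatenate([maxima, obs_sizes,
                                         [maxima.max() + 1]]))
        exceed = np.array([np.mean(maxima >= s) for s in cand])
        critical = float(cand[np.argmax(exceed <= alpha)])
    else:
        critical = np.inf
    cluster_p = np.array([np.mean(maxima >= s) for s in obs_sizes])
    significant = np.zeros(x.shape[1], dtype=bool)
    for ci, s in enumerate(obs_sizes):
        if s >= critical:
            significant[obs_labels == ci] = True
    return ClusterTestResult(
        t=t_obs, p_uncorrected=p_obs, cluster_labels=obs_labels,
        cluster_sizes=obs_sizes, cluster_p=cluster_p,
        critical_size=critical, significant=significant,
        perm_maxima=maxima, n_permutations=n_perm_eff,
        forming_p=forming_p, alpha=alpha, seed=seed)
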