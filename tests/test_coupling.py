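import numpy as np
import pytest

from sbci import (build_grid, discrete_fc, discrete_sc, sfc_discrete,
                  sfc_global, sfc_local, sfc_traditional)
from sbci.coupling import DiscreteConnectome, Parcellation
from sbci.fc import ContinuousFC
from sbci.mesh import SphereMesh
from sbci.sc import ContinuousSC


def _tetra(hemisphere):
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                 dtype=float) / np.sqrt(3)
    t = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return SphereMesh(vertices=v, triangles=t, hemisphere=hemisphere)


@pytest.fixture(scope="module")
def toy_grid():
    """Eight grid vertices (two tetrahedra), four masked in (2 + 2)."""
    mask = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=bool)
    return build_grid(_tetra("left"), _tetra("right"), mask=mask)


def _sym_zero_diag(m):
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def _toy_pair(toy_grid, seed=0, fc_from_sc=None):
    rng = np.random.default_rng(seed)
    n = toy_grid.n_masked
    sc = _sym_zero_diag(rng.uniform(0.1, 1.0, (n, n)))
    if fc_from_sc is not None:
        fcv = fc_from_sc(sc)
    else:
        fcv = _sym_zero_diag(rng.uniform(-0.9, 0.9, (n, n)))
    return (ContinuousSC(values=sc, grid=toy_grid, h=0.01),
            ContinuousFC(values=fcv, grid=toy_grid))


class TestGlobalCoupling:
    def test_proportional_rows_give_one(self, toy_grid):
        sc, fc = _toy_pair(toy_grid, fc_from_sc=lambda s: 0.5 * s / s.max())
        out = sfc_global(sc, fc)
        assert np.allclose(out.values, 1.0)

    def test_disjoint_support_gives_zero(self, toy_grid):
        n = toy_grid.n_masked
        scv = np.zeros((n, n))
        scv[0, 1] = scv[1, 0] = 1.0
        fcv = np.zeros((n, n))
        fcv[0, 2] = fcv[2, 0] = 0.5
        sc = ContinuousSC(values=scv, grid=toy_grid, h=0.01)
        fc = ContinuousFC(values=fcv, grid=toy_grid)
        with pytest.warns(UserWarning, match="zero SC or FC norm"):
            out = sfc_global(sc, fc)
        assert out.values[0] == 0.0

    def test_matches_bruteforce_arithmetic(self, toy_grid):
        sc, fc = _toy_pair(toy_grid, seed=3)
        out = sfc_global(sc, fc)
        a = toy_grid.masked_areas
        n = toy_grid.n_masked
        for x0 in range(n):
            num = den1 = den2 = 0.0
            for s in range(n):
                num += a[s] * sc.values[x0, s] * fc.values[x0, s]
                den1 += a[s] * sc.values[x0, s] ** 2
                den2 += a[s] * fc.values[x0, s] ** 2
            expected = num / np.sqrt(den1 * den2)
            assert out.values[x0] == pytest.approx(expected, abs=1e-12)

    def test_rescaling_invariance(self, toy_grid):
        sc, fc = _toy_pair(toy_grid, seed=4)
        out1 = sfc_global(sc, fc)
        sc2 = ContinuousSC(values=37.0 * sc.values, grid=toy_grid, h=0.01)
        out2 = sfc_global(sc2, fc)
        assert np.allclose(out1.values, out2.values, atol=1e-12)

    def test_values_bounded_on_random_inputs(self, toy_grid):
        for seed in range(20):
            sc, fc = _toy_pair(toy_grid, seed=seed)
            out = sfc_global(sc, fc)
            assert np.all(np.abs(out.values) <= 1.0)


class TestLocalCoupling:
    def test_single_roi_equals_global(self, toy_grid):
        sc, fc = _toy_pair(toy_grid, seed=5)
        parc = Parcellation(labels=np.zeros(toy_grid.n_masked, dtype=int),
                            grid=toy_grid)
        loc = sfc_local(sc, fc, parc)
        glb = sfc_global(sc, fc)
        assert np.allclose(loc.values, glb.values, atol=1e-12)

    def test_proportional_rows_within_roi(self, toy_grid):
        sc, fc = _toy_pair(toy_grid, fc_from_sc=lambda s: 0.9 * s / s.max())
        parc = Parcellation(labels=np.array([0, 0, 1, 1]), grid=toy_grid)
        out = sfc_local(sc, fc, parc)
        assert np.allclose(out.values, 1.0)

    def test_unassigned_vertices_get_nan(self, toy_grid):
        sc, fc = _toy_pair(toy_grid, seed=6)
        parc = Parcellation(labels=np.array([0, 0, -1, -1]), grid=toy_grid)
        out = sfc_local(sc, fc, parc)
        assert np.isnan(out.values[2:]).all()
        assert np.isfinite(out.values[:2]).all()

    def test_planted_coupling_separates_rois(self, level3_grid,
                                             level3_parcellation):
        """FC proportional to SC inside ROI A but independent elsewhere:
        mean local coupling in A must exceed every other ROI's."""
        parc = level3_parcellation
        n = level3_grid.n_masked
        margins = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            scv = _sym_zero_diag(rng.uniform(0.0, 1.0, (n, n)))
            fcv = _sym_zero_diag(rng.uniform(-0.5, 0.5, (n, n)))
            m = parc.members(0)
            sub = np.ix_(m, m)
            fcv[sub] = 0.9 * scv[sub] / scv[sub].max()
            np.fill_diagonal(fcv, 0.0)
            sc = ContinuousSC(values=scv, grid=level3_grid, h=0.01)
            fc = ContinuousFC(values=_sym_zero_diag(fcv), grid=level3_grid)
            out = sfc_local(sc, fc, parc)
            mean_a = np.nanmean(out.values[parc.members(0)])
            mean_rest = [np.nanmean(out.values[parc.members(r)])
                         for r in parc.roi_ids if r != 0]
            margins.append(mean_a - max(mean_rest))
        assert all(m > 0 for m in margins)


class TestDiscreteConnectome:
    def test_constant_density_cancels_areas(self, toy_grid):
        n = toy_grid.n_masked
        c = 0.37
        values = np.full((n, n), c)
        np.fill_diagonal(values, 0.0)
        sc = ContinuousSC(values=values, grid=toy_grid, h=0.01)
        parc = Parcellation(labels=np.array([0, 0, 1, 1]), grid=toy_grid)
        out = discrete_sc(sc, parc)
        # within-ROI entries keep the zero diagonal pairs in the average;
        # cross-ROI entries are exactly c
        assert out[0, 1] == pytest.approx(c)
        assert out[1, 0] == pytest.approx(c)

    def test_zero_between_rois(self, toy_grid):
        n = toy_grid.n_masked
        values = np.zeros((n, n))
        values[0, 1] = values[1, 0] = 2.0
        sc = ContinuousSC(values=values, grid=toy_grid, h=0.01)
        parc = Parcellation(labels=np.array([0, 0, 1, 1]), grid=toy_grid)
        out = discrete_sc(sc, parc)
        assert out[0, 1] == 0.0

    def test_discrete_sc_matches_bruteforce(self, toy_grid):
        sc, _ = _toy_pair(toy_grid, seed=7)
        parc = Parcellation(labels=np.array([0, 1, 0, 1]), grid=toy_grid)
        out = discrete_sc(sc, parc)
        a = toy_grid.masked_areas
        for i, r1 in enumerate(parc.roi_ids):
            for j, r2 in enumerate(parc.roi_ids):
                num = 0.0
                for u in parc.members(r1):
                    for w in parc.members(r2):
                        num += a[u] * a[w] * sc.values[u, w]
                expected = num / (a[parc.members(r1)].sum()
                                  * a[parc.members(r2)].sum())
                assert out[i, j] == pytest.approx(expected, abs=1e-12)

    def test_discrete_fc_constant_r(self, toy_grid):
        n = toy_grid.n_masked
        r = 0.42
        values = np.full((n, n), r)
        np.fill_diagonal(values, 0.0)
        fc = ContinuousFC(values=values, grid=toy_grid)
        parc = Parcellation(labels=np.array([0, 0, 1, 1]), grid=toy_grid)
        out = discrete_fc(fc, parc)
        assert np.allclose(out, r)

    def test_discrete_fc_halving_identity(self, toy_grid):
        """Equal-weight blocks at r = 0.8 and r = 0 average to exactly
        tanh(artanh(0.8)/2) = 0.5."""
        values = np.zeros((4, 4))
        # ROI A = {0, 1}, ROI B = {2, 3}; tetrahedron vertices have equal
        # areas, so the four cross pairs weigh equally
        values[0, 2] = values[0, 3] = 0.8
        values[2, 0] = values[3, 0] = 0.8
        fc = ContinuousFC(values=values, grid=toy_grid)
        parc = Parcellation(labels=np.array([0, 0, 1, 1]), grid=toy_grid)
        out = discrete_fc(fc, parc)
        assert out[0, 1] == pytest.approx(0.5, abs=1e-14)
        assert np.tanh(np.arctanh(0.8) / 2) == pytest.approx(0.5, abs=1e-15)

    def test_single_pair_roi(self, toy_grid):
        values = np.zeros((4, 4))
        values[0, 2] = values[2, 0] = 0.63
        fc = ContinuousFC(values=values, grid=toy_grid)
        parc = Parcellation(labels=np.array([0, -1, 1, -1]), grid=toy_grid)
        out = discrete_fc(fc, parc)
        assert out[0, 1] == pytest.approx(0.63, abs=1e-12)


class TestDiscreteCoupling:
    def _dc(self, k=4, seed=8, fc_map=None):
        rng = np.random.default_rng(seed)
        sc = _sym_zero_diag(rng.uniform(0.1, 1.0, (k, k)))
        fc = fc_map(sc) if fc_map else _sym_zero_diag(
            rng.uniform(-0.9, 0.9, (k, k)))
        return DiscreteConnectome(sc=sc, fc=fc)

    def test_affine_rows(self):
        dc = self._dc(fc_map=lambda s: _sym_zero_diag(0.3 + 0.5 * s))
        out = sfc_discrete(dc)
        assert np.allclose(out.values, 1.0)
        dc2 = self._dc(fc_map=lambda s: _sym_zero_diag(0.3 - 0.5 * s))
        assert np.allclose(sfc_discrete(dc2).values, -1.0)

    def test_matches_direct_correlation(self):
        dc = self._dc(seed=9)
        out = sfc_discrete(dc)
        for i in range(4):
            others = np.arange(4) != i
            expected = np.corrcoef(dc.sc[i, others], dc.fc[i, others])[0, 1]
            assert out.values[i] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_reported(self):
        dc = self._dc(seed=10)
        dc.sc[1, :] = dc.sc[:, 1] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            out = sfc_discrete(DiscreteConnectome(sc=dc.sc, fc=dc.fc))
        assert np.isnan(out.values[1])


class TestTraditionalCoupling:
    def test_counts_tracking_correlations(self, rng):
        series = rng.standard_normal((5, 100))
        fc = np.corrcoef(series)
        np.fill_diagonal(fc, 0.0)
        counts = np.round(1000 * (fc + 1.5))
        np.fill_diagonal(counts, 0.0)
        counts = (counts + counts.T) / 2
        out = sfc_traditional(counts, series)
        assert np.all(out.values > 0.999)

    def test_zero_counts_everywhere_undefined(self, rng):
        series = rng.standard_normal((4, 50))
        with pytest.warns(UserWarning, match="constant"):
            out = sfc_traditional(np.zeros((4, 4)), series)
        assert np.isnan(out.values).all()

    def test_runs_alongside_discrete(self, rng):
        """Both comparators produce finite values on a shared fixture."""
        k = 6
        sc = _sym_zero_diag(rng.uniform(0.1, 1.0, (k, k)))
        fc = _sym_zero_diag(rng.uniform(-0.8, 0.8, (k, k)))
        series = rng.standard_normal((k, 120))
        counts = np.round(sc * 500)
        dct = sfc_discrete(DiscreteConnectome(sc=sc, fc=fc))
        trd = sfc_traditional(counts, series)
        assert np.isfinite(dct.values).all()
        assert np.isfinite(trd.values).all()


def test_lobar_merge(level3_grid, level3_parcellation):
    """Merging parcels into lobes yields a valid coarser parcellation."""
    parc = level3_parcellation
    mapping = {r: int(r) // 3 for r in parc.roi_ids}   # 12 ROIs -> 4 lobes
    lobes = parc.merge(mapping)
    assert lobes.n_rois == 4
    assert lobes.roi_areas.sum() == pytest.approx(parc.roi_areas.sum())
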