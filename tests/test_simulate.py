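import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from sbci import build_grid, build_icosphere, continuous_fc
from sbci.simulate import (Cohort, EndpointMixture, FixtureSpec,
                           sample_vmf, simulate_bold, simulate_cohort,
                           simulate_endpoints, simulate_feature_cohort,
                           simulate_parcellation, true_density, vmf_density)


class TestParcellation:
    def test_single_roi_covers_hemisphere(self, level3_grid):
        parc = simulate_parcellation(level3_grid, 1, seed=0)
        assert parc.n_rois == 2                     # one per hemisphere
        assert (parc.labels >= 0).all()

    def test_lobar_style_count(self, level3_grid):
        parc = simulate_parcellation(level3_grid, 6, seed=0)
        assert parc.n_rois == 12

    @pytest.mark.parametrize("seed", range(5))
    def test_every_roi_connected(self, level3_grid, seed):
        parc = simulate_parcellation(level3_grid, 8, seed=seed)
        adj = level3_grid.masked_adjacency()
        for roi in parc.roi_ids:
            m = parc.members(roi)
            n_comp, _ = connected_components(adj[m][:, m], directed=False)
            assert n_comp == 1

    def test_deterministic_under_seed(self, level3_grid):
        p1 = simulate_parcellation(level3_grid, 4, seed=3)
        p2 = simulate_parcellation(level3_grid, 4, seed=3)
        assert np.array_equal(p1.labels, p2.labels)

    def test_k_too_large_rejected(self, level2_grid):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_parcellation(level2_grid, 200, seed=0)


class TestSimulateBold:
    def test_independent_vertices(self, level2_grid):
        parc = simulate_parcellation(level2_grid, 4, seed=0)
        field = simulate_bold(level2_grid, parc, 0.0, 0.0, T=2000, seed=1)
        # r_within = r_between = 0 via the degenerate-but-valid corner:
        # need r_within < 1 and r_between <= r_within; use epsilon-free 0s
        fc = continuous_fc(field.series, level2_grid)
        off = np.abs(fc.values[~np.eye(level2_grid.n_masked, dtype=bool)])
        assert np.median(off) < 0.05

    def test_block_correlation_recovered(self, level2_grid):
        parc = simulate_parcellation(level2_grid, 4, seed=0)
        field = simulate_bold(level2_grid, parc, 0.6, 0.1, T=1200, seed=2)
        c = np.corrcoef(field.series)
        same = parc.labels[:, None] == parc.labels[None, :]
        off = ~np.eye(level2_grid.n_masked, dtype=bool)
        assert c[same & off].mean() == pytest.approx(0.6, abs=0.05)
        assert c[~same].mean() == pytest.approx(0.1, abs=0.05)

    def test_seed_determinism(self, level2_grid):
        parc = simulate_parcellation(level2_grid, 4, seed=0)
        f1 = simulate_bold(level2_grid, parc, 0.5, 0.2, T=50, seed=9)
        f2 = simulate_bold(level2_grid, parc, 0.5, 0.2, T=50, seed=9)
        assert np.array_equal(f1.series, f2.series)

    def test_invalid_correlations_rejected(self, level2_grid):
        parc = simulate_parcellation(level2_grid, 4, seed=0)
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_bold(level2_grid, parc, 0.3, 0.6, T=10, seed=0)
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_bold(level2_grid, parc, 1.0, 0.0, T=10, seed=0)


class TestVonMisesFisher:
    def test_high_concentration_collapses_to_mean(self, rng):
        mu = np.array([0.0, 0.0, 1.0])
        pts = sample_vmf(mu, 1e8, 100, rng)
        assert np.abs(pts - mu).max() < 1e-3

    def test_density_normalizes(self):
        mesh = build_icosphere(4)
        mu = np.array([1.0, 0, 0])
        for kappa in (0.0, 5.0, 50.0):
            mass = mesh.surface_integral(
                lambda p: vmf_density(p, mu, kappa))
            assert mass == pytest.approx(1.0, abs=1e-3)

    def test_empirical_moments(self, rng):
        mu = np.array([0.0, 1.0, 0.0])
        kappa = 10.0
        pts = sample_vmf(mu, kappa, 20000, rng)
        # E<x, mu> = coth(kappa) - 1/kappa
        expected = 1.0 / np.tanh(kappa) - 1.0 / kappa
        assert (pts @ mu).mean() == pytest.approx(expected, abs=0.01)


class TestSimulateEndpoints:
    def test_degenerate_weights(self, vmf_mixture):
        w = np.zeros(vmf_mixture.n_components)
        w[0] = 1.0
        mix = EndpointMixture(means=vmf_mixture.means,
                              hemis=vmf_mixture.hemis,
                              kappas=vmf_mixture.kappas, weights=w)
        eps = simulate_endpoints(mix, 500, seed=1)
        # all pairs huddle around component 0's two modes (either order)
        d0 = eps.positions @ mix.means[0].T     # (N, 2, 2)
        best = d0.max(axis=2).min(axis=1)
        assert best.min() > 0.8

    def test_component_proportions(self, vmf_mixture):
        N = 10000
        eps = simulate_endpoints(vmf_mixture, N, seed=2)
        # classify each pair by its nearest component mode pair
        score = np.zeros((N, vmf_mixture.n_components))
        for c in range(vmf_mixture.n_components):
            d = eps.positions @ vmf_mixture.means[c].T
            score[:, c] = np.maximum(d[:, 0, 0] + d[:, 1, 1],
                                     d[:, 0, 1] + d[:, 1, 0])
        counts = np.bincount(score.argmax(axis=1),
                             minlength=vmf_mixture.n_components)
        # multinomial 99% bounds around N/3
        p = 1.0 / 3.0
        bound = 2.58 * np.sqrt(N * p * (1 - p))
        assert np.abs(counts - N * p).max() < bound

    def test_seed_determinism(self, vmf_mixture):
        e1 = simulate_endpoints(vmf_mixture, 100, seed=5)
        e2 = simulate_endpoints(vmf_mixture, 100, seed=5)
        assert np.array_equal(e1.positions, e2.positions)


class TestTrueDensity:
    def test_uniform_component_is_constant(self, level2_grid):
        uni = 1.0 / (4 * np.pi)
        hemi = level2_grid.masked_hemisphere
        means = np.array([[[0, 0, 1.0], [0, 0, 1.0]]])
        # interhemispheric: each ordering carries half the mass, so the
        # cross blocks sit at (4 pi)^-2 / 2 and within blocks at 0
        mix = EndpointMixture(means=means, hemis=np.array([[0, 1]]),
                              kappas=np.array([0.0]),
                              weights=np.array([1.0]))
        td = true_density(mix, level2_grid)
        assert np.allclose(td[np.ix_(hemi == 0, hemi == 1)], uni ** 2 / 2)
        assert np.all(td[np.ix_(hemi == 0, hemi == 0)] == 0)
        # within one hemisphere both orderings coincide: exactly (4 pi)^-2
        mix_ll = EndpointMixture(means=means, hemis=np.array([[0, 0]]),
                                 kappas=np.array([0.0]),
                                 weights=np.array([1.0]))
        td_ll = true_density(mix_ll, level2_grid)
        assert np.allclose(td_ll[np.ix_(hemi == 0, hemi == 0)], uni ** 2)

    def test_symmetry_and_mass(self, level3_grid, vmf_mixture):
        td = true_density(vmf_mixture, level3_grid)
        assert np.array_equal(td, td.T)
        a = level3_grid.masked_areas
        assert a @ td @ a == pytest.approx(1.0, abs=0.02)

    def test_mass_tightens_with_resolution(self, vmf_mixture,
                                           level3_parcellation):
        """At a level-4 grid the quadrature mass is within 1%."""
        g4 = build_grid(build_icosphere(4, "left"),
                        build_icosphere(4, "right"))
        # rebuild the mixture on the finer grid via raw means
        mix = EndpointMixture(means=vmf_mixture.means,
                              hemis=vmf_mixture.hemis,
                              kappas=vmf_mixture.kappas,
                              weights=vmf_mixture.weights)
        td = true_density(mix, g4)
        a = g4.masked_areas
        assert a @ td @ a == pytest.approx(1.0, abs=0.01)


class TestCohorts:
    def test_zero_within_noise_gives_unit_dicc(self):
        from sbci import dicc, pairwise_distances

        fs, truth = simulate_feature_cohort((50,), 5, 2, 1.0, 0.0, seed=3)
        rep = dicc(pairwise_distances(fs), fs.subject_ids)
        assert rep.dicc == pytest.approx(1.0)
        assert truth["analytic_dicc"] == 1.0

    def test_full_cohort_reproducible(self):
        spec = FixtureSpec(grid_level=2, n_subjects=2, n_sessions=2,
                           n_streamlines=200, T=50, seed=4)
        c1 = simulate_cohort(spec)
        c2 = simulate_cohort(spec)
        assert isinstance(c1, Cohort)
        assert np.array_equal(c1.endpoint_sets[0].positions,
                              c2.endpoint_sets[0].positions)
        assert np.array_equal(c1.bold_fields[-1].series,
                              c2.bold_fields[-1].series)
        assert len(c1.endpoint_sets) == 4

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FixtureSpec(r_within=0.2, r_between=0.5)
        with pytest.raises(ValueError):
            FixtureSpec(n_subjects=1)
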