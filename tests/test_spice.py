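import numpy as np
import pytest

from freshcube import scene_sim as ss
from freshcube.core import (
    DegenerateDataError,
    EndmemberSet,
    InvalidParameterError,
    SpectraMatrix,
)
from freshcube.spice import (
    SpiceParams,
    abundance_feature,
    match_endmembers,
    solve_abundances,
    spice_fit,
)


def _sm(values, grid):
    return SpectraMatrix(values=np.atleast_2d(values), grid=grid)


@pytest.fixture(scope="module")
def toy_grid():
    return ss.make_wavelength_grid(6, 500.0, 10.0)


@pytest.fixture(scope="module")
def toy_endmembers(toy_grid):
    rng = np.random.default_rng(42)
    e = rng.random((3, 6)) + 0.2
    return EndmemberSet(spectra=e, grid=toy_grid)


class TestSolveAbundances:
    def test_pure_pixel(self, toy_grid, toy_endmembers):
        s = toy_endmembers.spectra[1]
        ab = solve_abundances(_sm(s, toy_grid), toy_endmembers)
        assert np.allclose(ab.values[0], [0, 1, 0], atol=1e-7)

    def test_exact_mixture(self, toy_grid, toy_endmembers):
        e = toy_endmembers.spectra
        s = 0.5 * e[0] + 0.5 * e[1]
        ab = solve_abundances(_sm(s, toy_grid), toy_endmembers)
        assert np.allclose(ab.values[0], [0.5, 0.5, 0.0], atol=1e-7)
        assert ab.residual[0] == pytest.approx(0.0, abs=1e-12)

    def test_rows_on_simplex(self, toy_grid, toy_endmembers, rng):
        x = rng.random((40, 6))
        ab = solve_abundances(_sm(x, toy_grid), toy_endmembers)
        assert np.allclose(ab.values.sum(axis=1), 1.0, atol=1e-6)
        assert ab.values.min() >= -1e-9

    def test_rank_deficient_rejected(self, toy_grid):
        e = np.array([[1.0, 1, 1, 1, 1, 1], [2.0, 2, 2, 2, 2, 2.001],
                      [3.0, 3, 3, 3, 3, 3.002]])
        ems = EndmemberSet(spectra=e, grid=toy_grid)
        with pytest.raises(DegenerateDataError):
            solve_abundances(_sm(np.ones(6), toy_grid), ems)

    def test_grid_oracle_agreement(self, toy_grid):
        """QP solution matches brute-force 0.001-step simplex search."""
        step = 0.001
        k = int(1 / step)
        ii, jj = np.meshgrid(np.arange(k + 1), np.arange(k + 1),
                             indexing="ij")
        keep = ii + jj <= k
        grid_pts = np.stack([ii[keep], jj[keep], k - ii[keep] - jj[keep]],
                            axis=1) * step
        rng = np.random.default_rng(7)
        for _ in range(10):
            e = rng.random((3, 6)) + 0.1
            s = rng.random(6)
            ems = EndmemberSet(spectra=e, grid=toy_grid)
            ab = solve_abundances(_sm(s, toy_grid), ems)
            g = e @ e.T
            c = e @ s
            vals = np.einsum("ij,jk,ik->i", grid_pts, g, grid_pts) \
                - 2.0 * grid_pts @ c
            best = grid_pts[np.argmin(vals)]
            assert np.abs(ab.values[0] - best).max() < 2e-3

    def test_sparsity_weight_shifts_solution(self, toy_grid, toy_endmembers):
        e = toy_endmembers.spectra
        s = 0.5 * e[0] + 0.5 * e[1]
        heavy = solve_abundances(_sm(s, toy_grid), toy_endmembers,
                                 sparsity_weights=np.array([10.0, 0.0, 0.0]))
        assert heavy.values[0, 0] < 0.1

    def test_negative_weights_rejected(self, toy_grid, toy_endmembers):
        with pytest.raises(InvalidParameterError):
            solve_abundances(_sm(np.ones(6), toy_grid), toy_endmembers,
                             sparsity_weights=np.array([-1.0, 0.0, 0.0]))


class TestSpiceFit:
    def test_single_material_collapses_to_one(self, working_library, rng):
        row = working_library.spectra[0]
        x = np.tile(row, (60, 1))
        sm = SpectraMatrix(values=x, grid=working_library.grid)
        fit = spice_fit(sm, SpiceParams(gamma=5.0, m0=5, seed=0))
        assert fit.endmembers.n_endmembers == 1
        angle = match_endmembers(fit.endmembers.spectra, row[None, :])[0][2]
        assert np.degrees(angle) < 0.5
        assert np.allclose(fit.abundances.values, 1.0)

    def test_noiseless_three_endmember_recovery(self, default_params):
        sm, _, lib = ss.simulate_mixture_spectra(default_params, n=5000,
                                                 alpha=0.08, noise_sd=0.0,
                                                 seed=3)
        fit = spice_fit(sm, SpiceParams(gamma=70.0, m0=20, seed=3))
        assert fit.endmembers.n_endmembers == 3
        pairs = match_endmembers(fit.endmembers.spectra, lib.spectra)
        assert all(np.degrees(a) < 2.0 for _, _, a in pairs)

    def test_fixed_two_endmember_recovery(self, default_params, rng):
        # sparsity and dispersion essentially off: pure alternating
        # constrained least squares with M fixed at 2
        lib = ss.working_endmembers(default_params)
        s = rng.beta(0.6, 0.6, size=3000)
        x = np.outer(1 - s, lib.spectra[0]) + np.outer(s, lib.spectra[1])
        sm = SpectraMatrix(values=x, grid=lib.grid)
        fit = spice_fit(sm, SpiceParams(gamma=0.5, m0=2, seed=0, mu=1e-4))
        assert fit.endmembers.n_endmembers == 2
        pairs = match_endmembers(fit.endmembers.spectra, lib.spectra[:2])
        assert all(np.degrees(a) < 2.0 for _, _, a in pairs)

    def test_objective_monotone_non_increasing(self, default_params):
        sm, _, _ = ss.simulate_mixture_spectra(default_params, n=800,
                                               noise_sd=0.005, seed=4)
        fit = spice_fit(sm, SpiceParams(gamma=10.0, m0=8, seed=4))
        h = fit.objective_history
        assert len(h) >= 2
        assert all(b <= a + 1e-7 * abs(a) for a, b in zip(h, h[1:]))

    def test_needs_more_spectra_than_m0(self, working_library, rng):
        sm = SpectraMatrix(values=rng.random((5, working_library.n_bands)),
                           grid=working_library.grid)
        with pytest.raises(InvalidParameterError):
            spice_fit(sm, SpiceParams(gamma=10.0, m0=10))

    def test_param_validation(self):
        with pytest.raises(InvalidParameterError):
            SpiceParams(gamma=0.0)
        with pytest.raises(InvalidParameterError):
            SpiceParams(m0=1)
        with pytest.raises(InvalidParameterError):
            SpiceParams(tol=0.0)

    def test_subset_rss_dominates_full_set(self, default_params):
        """Re-solved RSS over any strict endmember subset is >= full RSS."""
        sm, _, lib = ss.simulate_mixture_spectra(default_params, n=300,
                                                 noise_sd=0.01, seed=5)
        full = solve_abundances(sm, lib)
        full_rss = full.residual.sum()
        for drop in range(3):
            keep = [i for i in range(3) if i != drop]
            sub = EndmemberSet(spectra=lib.spectra[keep], grid=lib.grid)
            rss = solve_abundances(sm, sub).residual.sum()
            assert rss >= full_rss - 1e-9


@pytest.mark.slow
def test_gamma_monotone_pruning_pressure(default_params):
    """A smaller gamma never decreases the retained endmember count."""
    sm, _, _ = ss.simulate_mixture_spectra(default_params, n=5000,
                                           alpha=0.08, noise_sd=0.005,
                                           seed=7)
    counts = []
    for gamma in range(10, 151, 10):
        fit = spice_fit(sm, SpiceParams(gamma=float(gamma), m0=10, seed=7))
        counts.append(fit.endmembers.n_endmembers)
    assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestAbundanceFeature:
    def test_constant_rows(self):
        from freshcube.core import AbundanceResult

        ab = AbundanceResult(values=np.tile([0.2, 0.8], (5, 1)),
                             residual=np.zeros(5))
        feat = abundance_feature(ab)
        assert np.allclose(feat.values, [0.2, 0.8])

    def test_two_pure_pixels(self):
        from freshcube.core import AbundanceResult

        ab = AbundanceResult(values=np.array([[1.0, 0.0], [0.0, 1.0]]),
                             residual=np.zeros(2))
        assert np.allclose(abundance_feature(ab).values, [0.5, 0.5])

    def test_matches_loop_oracle(self, rng):
        from freshcube.core import AbundanceResult

        raw = rng.dirichlet(np.ones(4), size=30)
        ab = AbundanceResult(values=raw, residual=np.zeros(30))
        feat = abundance_feature(ab)
        oracle = np.zeros(4)
        for row in raw:
            oracle += row
        oracle /= 30
        assert np.allclose(feat.values, oracle, atol=1e-12)
        assert feat.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariant(self, rng):
        from freshcube.core import AbundanceResult

        raw = rng.dirichlet(np.ones(3), size=20)
        perm = rng.permutation(20)
        a = abundance_feature(AbundanceResult(values=raw,
                                              residual=np.zeros(20)))
        b = abundance_feature(AbundanceResult(values=raw[perm],
                                              residual=np.zeros(20)))
        assert np.allclose(a.values, b.values)

    def test_empty_rejected(self):
        from freshcube.core import AbundanceResult

        ab = AbundanceResult(values=np.zeros((0, 3)), residual=np.zeros(0))
        with pytest.raises(InvalidParameterError):
            abundance_feature(ab)


class TestMatchEndmembers:
    def test_identity_match(self, working_library):
        pairs = match_endmembers(working_library.spectra,
                                 working_library.spectra)
        assert {(i, j) for i, j, _ in pairs} == {(0, 0), (1, 1), (2, 2)}
        assert all(a < 1e-9 for _, _, a in pairs)

    def test_permuted_match(self, working_library):
        perm = [2, 0, 1]
        pairs = match_endmembers(working_library.spectra[perm],
                                 working_library.spectra)
        mapping = {i: j for i, j, _ in pairs}
        assert mapping == {0: 2, 1: 0, 2: 1}
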