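"""MSD samples, KDE closed forms, energy transform, NNLS decomposition."""

import numpy as np
import pytest

from arousaldyn.datatypes import EnergyLandscape, MsdSamples, ParcelTimeSeries
from arousaldyn.landscape import (
    build_landscape,
    decompose_joint,
    default_msd_grid,
    energy,
    kde_density,
    landscape_contrast,
    msd_trajectories,
)
from arousaldyn.simulate import make_parcel_grid

TR = 0.586


def _ts(data):
    return ParcelTimeSeries(data, TR, make_parcel_grid(data.shape[1]))


class TestMsdTrajectories:
    def test_constant_matrix_gives_zero(self):
        s = msd_trajectories(_ts(np.ones((30, 4))), [0, 5], max_lag=10)
        assert np.all(s.samples == 0)

    def test_unit_step_gives_unit_msd_at_all_lags(self):
        X = np.zeros((30, 4))
        X[11:] = 1.0
        s = msd_trajectories(_ts(X), [10], max_lag=10)
        assert np.allclose(s.samples, 1.0)

    def test_three_parcel_hand_example(self):
        X = np.zeros((3, 3))
        X[1] = [1.0, 2.0, 2.0]
        s = msd_trajectories(_ts(X), [0], max_lag=1)
        assert s.samples[0, 0] == pytest.approx((1 + 4 + 4) / 3)

    def test_out_of_range_onset_rejected(self):
        with pytest.raises(IndexError):
            msd_trajectories(_ts(np.zeros((20, 3))), [10], max_lag=15)

    def test_parcel_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 8))
        perm = rng.permutation(8)
        a = msd_trajectories(_ts(X), [3, 17], 10).samples
        b = msd_trajectories(_ts(X[:, perm]), [3, 17], 10).samples
        assert np.allclose(a, b)


class TestKdeDensity:
    def test_single_kernel_peak_closed_form(self):
        s = MsdSamples(np.full((1, 1), 10.0), np.array([0]), 1)
        P = kde_density(s, bandwidth=4.0, msd_grid=default_msd_grid())
        assert P.max() == pytest.approx(1.0 / (4.0 * np.sqrt(2 * np.pi)))
        assert default_msd_grid()[np.argmax(P[0])] == 10.0

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        s = MsdSamples(rng.uniform(0, 30, size=(40, 3)), np.arange(40), 3)
        wide = np.arange(-250.0, 300.0, 0.05)
        P = kde_density(s, 4.0, wide)
        for row in P:
            assert np.trapezoid(row, wide) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_of_two_sample_mixture(self):
        s = MsdSamples(np.array([[0.0], [20.0]]), np.array([0, 1]), 1)
        grid = np.arange(0.0, 20.5, 0.5)
        P = kde_density(s, 4.0, grid)[0]
        assert np.allclose(P, P[::-1], atol=1e-12)

    def test_duplication_invariance(self):
        s1 = MsdSamples(np.array([[3.0], [8.0]]), np.array([0, 1]), 1)
        s2 = MsdSamples(np.array([[3.0], [8.0], [3.0], [8.0]]), np.arange(4), 1)
        grid = default_msd_grid()
        assert np.allclose(kde_density(s1, 4.0, grid), kde_density(s2, 4.0, grid))

    def test_invalid_bandwidth_rejected(self):
        s = MsdSamples(np.ones((2, 2)), np.arange(2), 2)
        with pytest.raises(ValueError):
            kde_density(s, 0.0)


class TestEnergy:
    def test_inverse_log_pairs(self):
        E, flagged = energy(np.array([[1.0, np.exp(-2.0)]]))
        assert E[0, 0] == pytest.approx(0.0)
        assert E[0, 1] == pytest.approx(2.0)
        assert not flagged.any()

    def test_halving_probability_adds_ln2(self):
        P = np.array([[0.4, 0.2]])
        E, _ = energy(P)
        assert E[0, 1] - E[0, 0] == pytest.approx(np.log(2.0))

    def test_floor_cells_capped_and_flagged(self):
        E, flagged = energy(np.array([[0.5, 0.0]]), floor=1e-6)
        assert flagged[0, 1] and not flagged[0, 0]
        assert E[0, 1] == pytest.approx(-np.log(1e-6))

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            energy(np.array([[-0.1]]))


class TestLandscapeContrast:
    @staticmethod
    def _landscape(samples: np.ndarray) -> EnergyLandscape:
        s = MsdSamples(samples, np.arange(len(samples)), samples.shape[1])
        return build_landscape(s)

    def test_identical_landscapes_give_zero(self):
        rng = np.random.default_rng(2)
        L = self._landscape(rng.uniform(5, 30, size=(50, 15)))
        d = landscape_contrast(L, L)
        assert np.nanmax(np.abs(d)) == 0.0

    def test_wider_distribution_lowers_energy_in_tail(self):
        rng = np.random.default_rng(3)
        base = rng.gamma(4.0, 2.5, size=(400, 15))
        wide = base * 2.0
        d = landscape_contrast(self._landscape(wide), self._landscape(base))
        grid = default_msd_grid()
        sel = (grid >= 20) & (grid <= 50)
        assert np.nanmean(d[sel]) < 0

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        a = self._landscape(rng.uniform(0, 30, size=(30, 15)))
        b = build_landscape(
            MsdSamples(rng.uniform(0, 30, size=(30, 10)), np.arange(30), 10)
        )
        with pytest.raises(ValueError):
            landscape_contrast(a, b)


class TestDecomposeJoint:
    @staticmethod
    def _mk(E: np.ndarray) -> EnergyLandscape:
        grid = default_msd_grid()
        lags = np.arange(1, E.shape[0] + 1)
        return EnergyLandscape(grid, lags, np.exp(-E), E, n=100)

    def test_exact_representation(self):
        rng = np.random.default_rng(5)
        E1 = rng.uniform(1, 5, size=(15, 101))
        E2 = rng.uniform(1, 5, size=(15, 101))
        alpha, beta, resid = decompose_joint(self._mk(E1.copy()), self._mk(E1), self._mk(E2))
        assert alpha == pytest.approx(1.0, abs=1e-8)
        assert beta == pytest.approx(0.0, abs=1e-8)
        assert resid == pytest.approx(0.0, abs=1e-8)

    def test_planted_mixture_recovered(self):
        rng = np.random.default_rng(6)
        E1 = rng.uniform(1, 5, size=(15, 101))
        E2 = rng.uniform(1, 5, size=(15, 101))
        Ej = 0.3 * E1 + 0.7 * E2 + rng.normal(0, 0.01, size=E1.shape)
        alpha, beta, _ = decompose_joint(self._mk(Ej), self._mk(E1), self._mk(E2))
        assert alpha == pytest.approx(0.3, abs=0.02)
        assert beta == pytest.approx(0.7, abs=0.02)

    def test_nonnegativity_constraint_binds(self):
        rng = np.random.default_rng(7)
        E1 = rng.uniform(1, 5, size=(15, 101))
        E2 = rng.uniform(1, 5, size=(15, 101))
        Ej = 1.2 * E1 - 0.5 * E2
        alpha, beta, _ = decompose_joint(self._mk(Ej), self._mk(E1), self._mk(E2))
        assert alpha >= 0 and beta >= 0

    def test_collinear_components_warn(self):
        rng = np.random.default_rng(8)
        E1 = rng.uniform(1, 5, size=(15, 101))
        with pytest.warns(UserWarning, match="collinear"):
            decompose_joint(self._mk(E1), self._mk(E1), self._mk(E1 * 1.0000001))

    def test_sum_to_one_option(self):
        rng = np.random.default_rng(9)
        E1 = rng.uniform(1, 5, size=(15, 101))
        E2 = rng.uniform(1, 5, size=(15, 101))
        Ej = 0.2 * E1 + 0.6 * E2
        alpha, beta, _ = decompose_joint(self._mk(Ej), self._mk(E1), self._mk(E2), sum_to_one=True)
        assert alpha + beta == pytest.approx(1.0)
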