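"""MTD coupling, signed modularity (vs brute force), PC, consensus."""

import numpy as np
import pytest

from arousaldyn.datatypes import ParcelTimeSeries
from arousaldyn.network import (
    aggregate_by_network,
    hemisphere_timing_contrast,
    lagged_pc_coupling,
    louvain_consensus,
    modularity_q,
    mtd,
    participation_coefficient,
    sweep_gamma,
    time_averaged_coupling,
)
from arousaldyn.simulate import make_parcel_grid

TR = 0.586


def q_brute_force(W: np.ndarray, partition: np.ndarray, gamma: float = 1.0) -> float:
    """Literal double sum of the signed modularity definition."""
    n = len(partition)
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    vp, vn = Wp.sum(), Wn.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if partition[i] != partition[j]:
                continue
            if vp > 0:
                q += (Wp[i, j] - gamma * Wp[i].sum() * Wp[j].sum() / vp) / vp
            if vn > 0:
                q -= (Wn[i, j] - gamma * Wn[i].sum() * Wn[j].sum() / vn) / (vp + vn)
    return q


def pc_brute_force(W: np.ndarray, partition: np.ndarray) -> np.ndarray:
    Wp = np.where(W > 0, W, 0.0).copy()
    np.fill_diagonal(Wp, 0.0)
    out = np.zeros(len(partition))
    for i in range(len(partition)):
        k_i = Wp[i].sum()
        if k_i == 0:
            continue
        acc = 0.0
        for s in np.unique(partition):
            acc += (Wp[i, partition == s].sum() / k_i) ** 2
        out[i] = 1.0 - acc
    return out


def _ts(data):
    return ParcelTimeSeries(data, TR, make_parcel_grid(data.shape[1]))


class TestMtd:
    def test_identical_series_couple_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        X = np.column_stack([x, x, rng.normal(size=300)])
        net = mtd(_ts(X), w=20)
        assert np.all(np.abs(net.coupling[:, 0, 1] - 1.0) < 0.7)
        # full-run average is 1 within numerical tolerance
        W = time_averaged_coupling(_ts(X))
        assert W[0, 1] == pytest.approx(1.0, abs=1e-4)

    def test_sign_flip_for_negated_series(self):
        x = np.random.default_rng(1).normal(size=300)
        X = np.column_stack([x, -x, x])
        net = mtd(_ts(X), w=20)
        assert np.all(net.coupling[:, 0, 1] < 0)
        W = time_averaged_coupling(_ts(X))
        assert W[0, 1] == pytest.approx(-1.0, abs=1e-4)

    def test_independent_noise_couples_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 4))
        net = mtd(_ts(X), w=20)
        mean_coupling = net.coupling[:, 0, 1].mean()
        assert abs(mean_coupling) < 3 / np.sqrt(20) / np.sqrt(net.coupling.shape[0])

    def test_symmetry_per_window(self):
        rng = np.random.default_rng(3)
        net = mtd(_ts(rng.normal(size=(100, 5))), w=10)
        for k in range(net.coupling.shape[0]):
            assert np.allclose(net.coupling[k], net.coupling[k].T)

    def test_zero_variance_channel_flagged_nan(self):
        X = np.random.default_rng(4).normal(size=(100, 3))
        X[:, 2] = 5.0
        net = mtd(_ts(X), w=10)
        assert np.isnan(net.coupling[:, 2, 0]).all()

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            mtd(_ts(np.zeros((10, 3))), w=20)


class TestModularityQ:
    def test_matches_brute_force_on_random_signed_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            W = rng.normal(size=(8, 8))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            part = rng.integers(0, 3, 8)
            gamma = rng.uniform(0.5, 2.5)
            assert modularity_q(W, part, gamma) == pytest.approx(
                q_brute_force(W, part, gamma), abs=1e-12
            )

    def test_single_module_positive_graph_zero_at_unit_gamma(self):
        rng = np.random.default_rng(6)
        W = np.abs(rng.normal(size=(6, 6)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        assert modularity_q(W, np.zeros(6, dtype=int), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_matrix_rejected(self):
        W = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError):
            modularity_q(W, np.zeros(3, dtype=int))


class TestLouvainConsensus:
    @staticmethod
    def _two_cliques():
        W = np.zeros((6, 6))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        np.fill_diagonal(W, 0.0)
        return W

    def test_recovers_disconnected_cliques(self):
        part, q = louvain_consensus(self._two_cliques(), runs=25, seed=0)
        assert len(np.unique(part)) == 2
        assert (part[:3] == part[0]).all() and (part[3:] == part[3]).all()
        assert q == pytest.approx(0.5)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        W = rng.normal(size=(20, 20))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        p1, q1 = louvain_consensus(W, runs=30, seed=42)
        p2, q2 = louvain_consensus(W, runs=30, seed=42)
        assert np.array_equal(p1, p2) and q1 == q2

    def test_planted_partition_recovered(self):
        """Four planted modules (within 0.6 / between 0.05 coupling) are
        recovered with adjusted agreement > 0.9."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        n, k = 80, 4
        labels = np.arange(n) % k
        W = np.where(labels[:, None] == labels[None, :], 0.6, 0.05)
        W = W + rng.normal(0, 0.05, size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        part, _ = louvain_consensus(W, runs=50, seed=1)
        assert adjusted_rand_score(labels, part) > 0.9

    def test_consensus_beats_single_module(self):
        rng = np.random.default_rng(9)
        W = rng.normal(size=(15, 15))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        part, q = louvain_consensus(W, runs=30, seed=3)
        assert q >= modularity_q(W, np.zeros(15, dtype=int)) - 1e-12


class TestParticipationCoefficient:
    def test_all_links_within_own_module_gives_zero(self):
        W = TestLouvainConsensus._two_cliques()
        pc = participation_coefficient(W, np.array([0, 0, 0, 1, 1, 1]))
        assert np.allclose(pc, 0.0)

    def test_equal_spread_over_four_modules_gives_three_quarters(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        pc = participation_coefficient(W, np.array([0, 0, 1, 2, 3]))
        assert pc[0] == pytest.approx(0.75)

    def test_matches_brute_force_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            W = rng.normal(size=(10, 10))
            W = (W + W.T) / 2
            part = rng.integers(0, 3, 10)
            pc = participation_coefficient(W, part)
            assert np.allclose(pc, pc_brute_force(W, part), atol=1e-12)
            assert np.all((pc >= 0) & (pc <= 1))

    def test_isolated_node_gets_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        pc = participation_coefficient(W, np.array([0, 1, 0, 1]))
        assert pc[2] == 0.0 and pc[3] == 0.0


class TestLaggedPcCoupling:
    def test_shifted_copy_peaks_at_shift(self):
        rng = np.random.default_rng(11)
        T, shift = 500, 5
        contrast = rng.normal(size=T)
        centers = np.arange(50, 450)
        pc_series = contrast[centers + shift]
        pc = np.column_stack([pc_series, pc_series])
        out = lagged_pc_coupling(contrast, pc, centers, max_lag=10)
        k = np.nanargmax(out["mean"])
        assert out["lags"][k] == shift
        assert out["mean"][k] > 0.99

    def test_centers_outside_series_rejected(self):
        with pytest.raises(ValueError):
            lagged_pc_coupling(np.zeros(10), np.zeros((5, 2)), np.array([0, 2, 4, 6, 20]), 2)


class TestHemisphereContrast:
    def test_exchangeable_null_gives_p_near_half(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=200)
        hemi = np.array(["L", "R"] * 100)
        _, _, p = hemisphere_timing_contrast(vals, hemi, n_perm=2000, seed=0)
        assert 0.3 < p < 0.7

    def test_shifted_right_hemisphere_detected(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=200)
        hemi = np.array(["L"] * 100 + ["R"] * 100)
        vals[100:] += 1.0
        mean_l, mean_r, p = hemisphere_timing_contrast(vals, hemi, n_perm=2000, seed=0)
        assert mean_r > mean_l
        assert p < 0.01

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            hemisphere_timing_contrast(np.ones(10), np.array(["L", "R"] * 5))

    def test_single_hemisphere_rejected(self):
        with pytest.raises(ValueError):
            hemisphere_timing_contrast(np.arange(10.0), np.array(["L"] * 10))


class TestAggregateByNetwork:
    def test_one_label_is_identity_of_mean(self):
        pc = np.random.default_rng(14).uniform(size=(7, 5))
        frame = aggregate_by_network(pc, np.array(["a"] * 5))
        assert np.allclose(frame["a"], pc.mean(axis=1))

    def test_two_label_hand_example_and_counts(self):
        pc = np.array([[0.0, 1.0, 0.5], [0.2, 0.4, 0.6]])
        frame = aggregate_by_network(pc, np.array(["x", "y", "x"]))
        assert np.allclose(frame["x"], [0.25, 0.4])
        assert np.allclose(frame["y"], [1.0, 0.4])
        assert frame.attrs["counts"] == {"x": 2, "y": 1}
        assert sum(frame.attrs["counts"].values()) == 3

    def test_label_coverage_enforced(self):
        with pytest.raises(ValueError):
            aggregate_by_network(np.zeros((3, 4)), np.array(["a", "b"]))


class TestSweepGamma:
    def test_output_length_and_stable_plateau(self):
        rng = np.random.default_rng(15)
        n, k = 40, 4
        labels = np.arange(n) % k
        W = np.where(labels[:, None] == labels[None, :], 0.6, 0.05)
        W = W + rng.normal(0, 0.03, size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        gammas = np.array([0.5, 1.0, 1.5])
        frame = sweep_gamma(W, gammas, runs=20, seed=2)
        assert len(frame) == len(gammas)
        assert frame.attrs["best_gamma"] in gammas
        # a strongly modular graph is stable around gamma = 1
        assert frame["mean_similarity"].max() > 0.8
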