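"""Generator contracts: HRF shape, band limits, determinism, geometry."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from arousaldyn.simulate import (
    SimulationConfig,
    band_limited_noise,
    double_gamma_hrf,
    generate_cohort,
    generate_subject,
    make_parcel_grid,
    subject_seed,
)


class TestDoubleGammaHrf:
    def test_peak_near_five_seconds(self):
        h = double_gamma_hrf(0.586, 30.0)
        assert np.argmax(h) in (8, 9)  # 5 s / 0.586 s per sample

    def test_zero_at_onset_and_unit_peak(self):
        h = double_gamma_hrf(0.586, 30.0)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_undershoot_present(self):
        h = double_gamma_hrf(0.5, 30.0)
        t = np.arange(len(h)) * 0.5
        assert h[(t > 12) & (t < 20)].min() < 0

    @pytest.mark.parametrize("tr,dur", [(0.0, 30.0), (-1.0, 30.0), (0.5, 10.0)])
    def test_invalid_parameters(self, tr, dur):
        with pytest.raises(ValueError):
            double_gamma_hrf(tr, dur)


class TestBandLimitedNoise:
    def test_spectral_mass_in_band(self):
        rng = np.random.default_rng(0)
        x = band_limited_noise(rng, 2000, 0.586, (0.01, 0.15), size=4)
        for col in x.T:
            f, p = sp_signal.periodogram(col, fs=1 / 0.586)
            in_band = (f >= 0.009) & (f <= 0.151)
            assert p[in_band].sum() / p.sum() > 0.9

    def test_unit_variance(self):
        rng = np.random.default_rng(1)
        x = band_limited_noise(rng, 512, 0.586, size=3)
        assert np.allclose(x.std(axis=0), 1.0)

    def test_band_without_bins_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            band_limited_noise(rng, 50, 0.586, (0.0001, 0.0002))


class TestParcelGrid:
    def test_anterior_posterior_extent(self):
        g = make_parcel_grid(400)
        assert g["y_mm"].max() - g["y_mm"].min() == pytest.approx(140.0)
        assert len(g) == 400

    def test_hemisphere_from_x_sign(self):
        g = make_parcel_grid(100)
        assert ((g["x_mm"] < 0) == (g["hemisphere"] == "L")).all()


class TestGenerateSubject:
    def test_deterministic_under_fixed_seed(self, small_cfg):
        a = generate_subject(small_cfg, 42)
        b = generate_subject(small_cfg, 42)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1]["lc"], b[1]["lc"])
        for k in a[3].event_indices:
            assert np.array_equal(a[3].event_indices[k], b[3].event_indices[k])

    def test_distinct_seeds_distinct_noise(self, small_cfg):
        a = generate_subject(small_cfg, 1)
        b = generate_subject(small_cfg, 2)
        assert not np.array_equal(a[0].data, b[0].data)

    def test_zero_rate_gives_no_events(self):
        cfg = SimulationConfig(
            n_subjects=1, T=400, R=20, burst_rate_per_min=0.0,
            joint_burst_rate_per_min=0.0, nuisance_mix=0.0, seed=3,
        )
        _, sub, _, truth = generate_subject(cfg, 5)
        assert all(len(v) == 0 for v in truth.event_indices.values())
        # LC channel is then pure band-limited noise: unit variance, no bursts
        assert sub["lc"].std() == pytest.approx(1.0, rel=1e-6)

    def test_wave_delay_range_matches_distance_over_velocity(self, small_cfg):
        _, _, _, truth = generate_subject(small_cfg, 9)
        span_s = truth.wave_delays_s.max() - truth.wave_delays_s.min()
        assert span_s == pytest.approx(0.140 / small_cfg.wave_velocity_m_per_s, rel=1e-6)

    def test_event_separation_at_least_21_tr(self, small_cfg):
        for s in range(5):
            _, _, _, truth = generate_subject(small_cfg, s)
            alle = truth.all_event_indices()
            if len(alle) > 1:
                assert np.diff(alle).min() >= 21

    def test_events_respect_bounds(self, small_cfg):
        _, _, _, truth = generate_subject(small_cfg, 17)
        alle = truth.all_event_indices()
        assert np.all(alle >= small_cfg.boundary)
        assert np.all(alle < small_cfg.T - small_cfg.boundary)


class TestGenerateCohort:
    def test_subject_count_and_truth(self):
        cfg = SimulationConfig(n_subjects=4, T=400, R=20, seed=2)
        sids, data, truths = generate_cohort(cfg)
        assert len(sids) == 4 and set(sids) == set(data) == set(truths)

    def test_cohort_event_count_near_rate_times_duration(self):
        cfg = SimulationConfig(n_subjects=10, T=1000, R=10, seed=5, wave_amplitude_sd=0.0)
        _, _, truths = generate_cohort(cfg)
        total = sum(len(t.event_indices["lc"]) for t in truths.values())
        minutes = cfg.T * cfg.tr_seconds / 60.0 * cfg.n_subjects
        expect = cfg.burst_rate_per_min * minutes
        # thinning removes some candidates; allow 4 sigma Poisson slack downward
        assert expect - 4 * np.sqrt(expect) <= total <= expect + 4 * np.sqrt(expect)

    def test_subject_seeds_below_2_31(self):
        assert all(0 <= subject_seed(123, i) < 2**31 for i in range(20))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"T": 50},
            {"tr_seconds": 0.0},
            {"burst_amplitude_sd": -1.0},
            {"within_corr": 0.2, "between_corr_base": 0.5},
            {"between_corr_post_event": 0.9, "within_corr": 0.5},
            {"noise_band": (0.2, 0.1)},
        ],
    )
    def test_infeasible_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)
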