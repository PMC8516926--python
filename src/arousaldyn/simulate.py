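"""Synthetic resting-state cohorts with known ground truth.

The generator emulates the statistical structure the pipeline is designed
to measure, with every feature planted at a configurable, known value:

* band-limited (0.01-0.15 Hz) BOLD-like noise at TR = 0.586 s, synthesized
  in the frequency domain (power ~ 1/f^2.5 in-band, zero out-of-band) so
  band limits hold exactly without filter transients and the background
  is slow drift -- sharp transients belong to the planted bursts;
* phasic bursts in two subcortical channels (noradrenergic "LC" and
  cholinergic "BNM"), drawn from a Poisson process thinned to >= 21 TR
  separation and injected as HRF-convolved impulses;
* an anterior-to-posterior cortical travelling wave time-locked to LC-type
  bursts, with per-parcel onset delay = (distance along the wave axis) /
  velocity, evaluated at continuous (sub-TR) delays;
* windowed modular correlation structure whose between-module coupling
  rises for a fixed 10 TR window after LC-type events;
* a nuisance channel partially mixed into the LC channel, to exercise
  residualization.

Parcel coordinates sit on a regular 3-D grid spanning typical MNI extents
so the wave geometry is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .datatypes import ParcelTimeSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "double_gamma_hrf",
    "hrf_continuous",
    "band_limited_noise",
    "make_parcel_grid",
    "generate_subject",
    "generate_cohort",
]

#: minimum separation between planted bursts, TR.  Matches the 21 TR
#: analysis window so +/-10 TR event windows never overlap.
MIN_EVENT_SEPARATION_TR = 21

#: post-event window (TR) during which between-module coupling is elevated.
INTEGRATION_WINDOW_TR = 10


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the acquisition and effect scales the pipeline is
    built for: 10-minute runs at TR = 0.586 s, ~0.25 bursts per minute per
    channel, a 0.13 m/s anterior-to-posterior wave, and four cortical
    modules with within/between Pearson correlations 0.6 / 0.05 rising to
    0.30 between modules after LC bursts.
    """

    n_subjects: int = 12
    T: int = 1000
    R: int = 400
    tr_seconds: float = 0.586
    burst_rate_per_min: float = 0.25
    joint_burst_rate_per_min: float = 0.25
    burst_amplitude_sd: float = 3.0
    wave_amplitude_sd: float = 2.0
    wave_velocity_m_per_s: float = 0.13
    wave_direction: tuple[float, float, float] = (0.0, -1.0, 0.0)
    n_modules: int = 4
    within_corr: float = 0.6
    between_corr_base: float = 0.05
    between_corr_post_event: float = 0.30
    post_event_variance_scale: float = 1.0
    post_event_scale_window: int = 15
    noise_band: tuple[float, float] = (0.01, 0.15)
    spectral_exponent: float = 2.5
    nuisance_mix: float = 0.4
    boundary: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T <= 100:
            raise ValueError("T must exceed 100")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.burst_amplitude_sd < 0 or self.wave_amplitude_sd < 0:
            raise ValueError("burst amplitudes must be non-negative")
        lo, hi = self.noise_band
        if not (0 < lo < hi < 0.5 / self.tr_seconds):
            raise ValueError("noise_band must satisfy 0 < low < high < Nyquist")
        ok = 0.0 <= self.between_corr_base <= self.within_corr <= 1.0
        ok = ok and 0.0 <= self.between_corr_post_event <= self.within_corr
        if not ok:
            # latent-factor construction requires 0 <= rho_between <= rho_within <= 1
            raise ValueError(
                "infeasible correlation targets: need "
                "0 <= between <= within <= 1 in every window"
            )


@dataclass
class GroundTruth:
    """Planted structure of one synthetic subject."""

    event_indices: dict[str, np.ndarray]  # keys: lc, bnm, joint
    velocity_m_per_s: float
    module_assignments: np.ndarray  # (R,) int
    integration_level: np.ndarray  # (T,) 1 inside post-LC integration windows
    wave_delays_s: np.ndarray  # (R,) planted per-parcel onset delay

    def all_event_indices(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.event_indices.values())))


def hrf_continuous(t_seconds: np.ndarray) -> np.ndarray:
    """Canonical double-gamma haemodynamic response at arbitrary times.

    Peak near 5 s, undershoot near 15 s, zero for t <= 0; unit peak
    amplitude.
    """
    t = np.asarray(t_seconds, dtype=float)
    h = sp_stats.gamma.pdf(t, a=6.0, scale=1.0) - sp_stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    h = np.where(t > 0, h, 0.0)
    # peak of the a=6 gamma term dominates; normalize on a fine reference grid
    ref = sp_stats.gamma.pdf(5.0, a=6.0, scale=1.0) - sp_stats.gamma.pdf(5.0, a=16.0, scale=1.0) / 6.0
    return h / ref


def double_gamma_hrf(tr_seconds: float, duration_s: float = 30.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR spacing, unit peak.

    ``duration_s`` must cover the undershoot (>= 20 s).
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if duration_s < 20:
        raise ValueError("duration_s must be at least 20 s to cover the undershoot")
    t = np.arange(0.0, duration_s, tr_seconds)
    h = hrf_continuous(t)
    return h / h.max()


def band_limited_noise(
    rng: np.random.Generator,
    T: int,
    tr_seconds: float,
    band: tuple[float, float] = (0.01, 0.15),
    size: int = 1,
    exponent: float = 1.0,
) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` with a 1/f^exponent spectrum.

    Synthesized directly in the frequency domain (random phases, power
    ~ f**-exponent on in-band rfft bins, zero elsewhere), so spectral
    mass outside the band is exactly zero and no filter transients occur.
    The default exponent of 1 mimics the low-frequency-dominated spectrum
    of resting BOLD; ``exponent=0`` gives a flat in-band spectrum.
    Returns (T, size), each column unit variance.
    """
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("band contains no resolvable frequency bins")
    spec = np.zeros((len(freqs), size), dtype=complex)
    n_in = int(in_band.sum())
    amps = freqs[in_band] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_in, size))
    spec[in_band] = amps[:, None] * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=T, axis=0)
    x /= x.std(axis=0, keepdims=True)
    return x


def make_parcel_grid(R: int, n_modules: int = 4) -> pd.DataFrame:
    """Parcel metadata on a regular 3-D grid over typical MNI extents.

    x spans +/-60 mm (hemisphere from its sign), y spans -105..35 mm
    (140 mm anterior-posterior extent), z spans -40..68 mm.  Modules are
    assigned round-robin so each module samples the whole wave axis.
    """
    nx = 4
    ny = int(np.ceil(np.sqrt(R / nx)))
    nz = int(np.ceil(R / (nx * ny)))
    xs = np.linspace(-60.0, 60.0, nx)
    ys = np.linspace(-105.0, 35.0, ny)
    zs = np.linspace(-40.0, 68.0, nz)
    # y varies fastest so truncation to R keeps full anterior-posterior coverage
    pts = [(x, y, z) for z in zs for x in xs for y in ys]
    pts = np.array(pts[:R])
    modules = np.arange(R) % n_modules
    return pd.DataFrame(
        {
            "parcel_id": np.arange(R),
            "x_mm": pts[:, 0],
            "y_mm": pts[:, 1],
            "z_mm": pts[:, 2],
            "hemisphere": np.where(pts[:, 0] < 0, "L", "R"),
            "network_label": [f"module_{k + 1}" for k in modules],
        }
    )


def _draw_events(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Poisson bursts per channel, greedily thinned to >= 21 TR separation."""
    minutes = cfg.T * cfg.tr_seconds / 60.0
    lo = cfg.boundary
    hi = cfg.T - cfg.boundary - INTEGRATION_WINDOW_TR
    rates = {
        "lc": cfg.burst_rate_per_min,
        "bnm": cfg.burst_rate_per_min,
        "joint": cfg.joint_burst_rate_per_min,
    }
    candidates: list[tuple[int, str]] = []
    for etype, rate in rates.items():
        n = rng.poisson(rate * minutes)
        ts = rng.integers(lo, hi, size=n) if hi > lo else np.empty(0, dtype=int)
        candidates.extend((int(t), etype) for t in ts)
    candidates.sort()
    kept: dict[str, list[int]] = {"lc": [], "bnm": [], "joint": []}
    last = -np.inf
    for t, etype in candidates:
        if t - last >= MIN_EVENT_SEPARATION_TR:
            kept[etype].append(t)
            last = t
    return {k: np.array(v, dtype=int) for k, v in kept.items()}


def _impulse_response(
    T: int, tr: float, event_indices: np.ndarray, amplitude: float, delay_s: float = 0.0
) -> np.ndarray:
    """Sum of HRFs at ``event_indices`` with a continuous extra delay."""
    if len(event_indices) == 0 or amplitude == 0:
        return np.zeros(T)
    t_grid = np.arange(T) * tr
    out = np.zeros(T)
    for t0 in event_indices:
        out += hrf_continuous(t_grid - t0 * tr - delay_s)
    return amplitude * out


def _calibrated_channels(
    cfg: SimulationConfig,
    sub_noise: np.ndarray,
    events: dict[str, np.ndarray],
    lc_like: np.ndarray,
    bnm_like: np.ndarray,
    n_iter: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble LC/BNM channels with detector-referenced burst gains.

    The per-type injection gains are iterated so the *deterministic*
    conditioned burst response — the noise-free HRF component after
    band-passing and z-normalization, evaluated at its post-onset peak —
    reaches ``burst_amplitude_sd`` standard deviations of the contrast
    (LC, BNM events) or sum series (joint events).  Deterministic given
    the noise realization.
    """
    from .conditioning import bandpass

    T, tr = cfg.T, cfg.tr_seconds
    lo, hi = cfg.noise_band
    resp = {
        "lc": _impulse_response(T, tr, events["lc"], 1.0),
        "bnm": _impulse_response(T, tr, events["bnm"], 1.0),
        "joint": _impulse_response(T, tr, events["joint"], 1.0),
    }
    target = cfg.burst_amplitude_sd
    if target == 0 or len(np.concatenate(list(events.values()))) == 0:
        lc = sub_noise[:, 0] + target * (resp["lc"] + resp["joint"])
        return lc, sub_noise[:, 1] + target * (resp["bnm"] + resp["joint"])

    gains = {"lc": target * np.sqrt(2.0), "bnm": target * np.sqrt(2.0), "joint": target}

    def peak(det: np.ndarray, t0s: np.ndarray) -> float:
        return float(np.median([det[t + 1 : t + 15].max() for t in t0s]))

    for _ in range(n_iter):
        lc = sub_noise[:, 0] + gains["lc"] * resp["lc"] + gains["joint"] * resp["joint"]
        bnm = sub_noise[:, 1] + gains["bnm"] * resp["bnm"] + gains["joint"] * resp["joint"]
        bl, bb = bandpass(lc, lo, hi, tr), bandpass(bnm, lo, hi, tr)
        sdl, sdb = bl.std(), bb.std()
        contrast_sd = (bl / sdl - bb / sdb).std()
        sum_sd = (bl / sdl + bb / sdb).std()
        det = {
            "lc": bandpass(gains["lc"] * resp["lc"], lo, hi, tr) / sdl,
            "bnm": bandpass(gains["bnm"] * resp["bnm"], lo, hi, tr) / sdb,
            "joint": bandpass(gains["joint"] * resp["joint"], lo, hi, tr) * (1 / sdl + 1 / sdb),
        }
        for etype, norm in (("lc", contrast_sd), ("bnm", contrast_sd), ("joint", sum_sd)):
            t0s = events[etype]
            if len(t0s) == 0:
                continue
            m = peak(det[etype], t0s) / norm
            if m > 0.1:
                gains[etype] *= target / m
    lc = sub_noise[:, 0] + gains["lc"] * resp["lc"] + gains["joint"] * resp["joint"]
    bnm = sub_noise[:, 1] + gains["bnm"] * resp["bnm"] + gains["joint"] * resp["joint"]
    return lc, bnm


def generate_subject(
    cfg: SimulationConfig, subject_seed: int
) -> tuple[ParcelTimeSeries, dict[str, np.ndarray], dict[str, np.ndarray], GroundTruth]:
    """One synthetic subject: cortex, subcortical channels, nuisances, truth.

    Returns ``(cortex, subcortical, nuisance, truth)`` where ``subcortical``
    has keys ``lc``/``bnm`` and ``nuisance`` has keys ``fourth_ventricle``/
    ``pons``.  Deterministic in ``(cfg, subject_seed)``.
    """
    rng = np.random.default_rng(subject_seed)
    T, R, tr = cfg.T, cfg.R, cfg.tr_seconds
    parcels = make_parcel_grid(R, cfg.n_modules)
    modules = np.array([int(s.split("_")[1]) - 1 for s in parcels["network_label"]])

    events = _draw_events(cfg, rng)
    lc_like = np.sort(np.concatenate([events["lc"], events["joint"]]))
    bnm_like = np.sort(np.concatenate([events["bnm"], events["joint"]]))

    # subcortical channels: unit-variance band-limited noise + HRF bursts.
    # burst_amplitude_sd is defined in the units the detector thresholds:
    # s.d. of the *conditioned contrast/sum series*.  Because differencing
    # scales noise by sqrt(2), band-passing attenuates the HRF peak, and
    # the bursts themselves inflate the series s.d., the injection gains
    # are set by a deterministic fixed-point calibration against the same
    # conditioning chain the detector uses.
    sub_noise = band_limited_noise(rng, T, tr, cfg.noise_band, size=2, exponent=cfg.spectral_exponent)
    lc_clean, bnm = _calibrated_channels(cfg, sub_noise, events, lc_like, bnm_like)

    nuis = band_limited_noise(rng, T, tr, cfg.noise_band, size=2, exponent=cfg.spectral_exponent)
    fourth_ventricle, pons = nuis[:, 0], nuis[:, 1]
    lc_obs = lc_clean + cfg.nuisance_mix * fourth_ventricle

    # cortical latent factors: global + per-module + per-parcel noise,
    # with a time-varying global loading implementing the post-LC rise in
    # between-module correlation
    g = band_limited_noise(rng, T, tr, cfg.noise_band, size=1, exponent=cfg.spectral_exponent)[:, 0]
    m = band_limited_noise(rng, T, tr, cfg.noise_band, size=cfg.n_modules, exponent=cfg.spectral_exponent)
    eps = band_limited_noise(rng, T, tr, cfg.noise_band, size=R, exponent=cfg.spectral_exponent)

    rho_b = np.full(T, cfg.between_corr_base)
    integration = np.zeros(T)
    for t0 in lc_like:
        rho_b[t0 + 1 : t0 + 1 + INTEGRATION_WINDOW_TR] = cfg.between_corr_post_event
        integration[t0 + 1 : t0 + 1 + INTEGRATION_WINDOW_TR] = 1.0
    w_g = np.sqrt(rho_b)
    w_m = np.sqrt(cfg.within_corr - rho_b)
    w_e = np.sqrt(1.0 - cfg.within_corr)
    cortex = w_g[:, None] * g[:, None] + w_m[:, None] * m[:, modules] + w_e * eps

    if cfg.post_event_variance_scale != 1.0:
        scale = np.ones(T)
        for t0 in lc_like:
            scale[t0 + 1 : t0 + 1 + cfg.post_event_scale_window] = np.sqrt(
                cfg.post_event_variance_scale
            )
        cortex *= scale[:, None]

    # travelling wave locked to LC-type events, continuous per-parcel delay
    d = np.asarray(cfg.wave_direction, dtype=float)
    d /= np.linalg.norm(d)
    proj = parcels[["x_mm", "y_mm", "z_mm"]].to_numpy() @ d
    delays = (proj - proj.min()) / (cfg.wave_velocity_m_per_s * 1000.0)
    if cfg.wave_amplitude_sd != 0 and len(lc_like) > 0:
        t_grid = np.arange(T) * tr
        for t0 in lc_like:
            # (T, R) evaluation of the delayed HRF for this event
            cortex += cfg.wave_amplitude_sd * hrf_continuous(
                t_grid[:, None] - t0 * tr - delays[None, :]
            )

    truth = GroundTruth(
        event_indices=events,
        velocity_m_per_s=cfg.wave_velocity_m_per_s,
        module_assignments=modules,
        integration_level=integration,
        wave_delays_s=delays,
    )
    ts = ParcelTimeSeries(cortex, tr, parcels)
    return (
        ts,
        {"lc": lc_obs, "bnm": bnm},
        {"fourth_ventricle": fourth_ventricle, "pons": pons},
        truth,
    )


def subject_seed(cfg_seed: int, index: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    return int(np.random.SeedSequence([cfg_seed, index]).generate_state(1)[0] % (2**31))


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[str], dict[str, tuple], dict[str, GroundTruth]]:
    """Generate all subjects of a cohort in memory.

    Returns ``(subject_ids, data, truths)`` where ``data[sid]`` is the
    4-tuple from :func:`generate_subject`.  Use
    :func:`arousaldyn.io.write_cohort` to persist to a manifest layout.
    """
    subject_ids = [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)]
    data, truths = {}, {}
    for i, sid in enumerate(subject_ids):
        out = generate_subject(cfg, subject_seed(cfg.seed, i))
        data[sid] = out
        truths[sid] = out[3]
    return subject_ids, data, truths
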