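"""Core in-memory containers shared across the pipeline.

All containers are plain dataclasses over numpy arrays / pandas frames so
they serialize cleanly to the TSV + JSON sidecar layout used on disk.
Time is always indexed in TR units (0-based sample index); physical time in
seconds is obtained through ``tr_seconds``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcelTimeSeries",
    "ArousalSignals",
    "PhasicEventSet",
    "WaveFit",
    "DynamicNetwork",
    "MsdSamples",
    "EnergyLandscape",
    "NullDistribution",
    "EventLockedResponse",
]


@dataclass
class ParcelTimeSeries:
    """One subject's parcellated BOLD matrix (T time points x R parcels).

    ``parcels`` is a metadata frame with one row per parcel and columns
    ``parcel_id, x_mm, y_mm, z_mm, hemisphere, network_label`` (MNI mm,
    hemisphere in {"L", "R"}).
    """

    data: np.ndarray  # (T, R) float
    tr_seconds: float
    parcels: pd.DataFrame
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("parcel time series must be 2-D (T x R)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.parcels) != self.data.shape[1]:
            raise ValueError(
                f"parcel metadata rows ({len(self.parcels)}) do not match "
                f"matrix columns ({self.data.shape[1]})"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def coords_mm(self) -> np.ndarray:
        return self.parcels[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


@dataclass
class ArousalSignals:
    """Conditioned subcortical arousal series for one subject.

    ``tau_lc`` / ``tau_bnm`` are the noradrenergic (locus coeruleus) and
    cholinergic (basal nucleus of Meynert) BOLD series after nuisance
    residualization, band-pass filtering and z-scoring.  The contrast
    series satisfy ``contrast_bnm_minus_lc == -contrast_lc_minus_bnm``
    exactly.
    """

    tau_lc: np.ndarray
    tau_bnm: np.ndarray
    contrast_lc_minus_bnm: np.ndarray
    contrast_bnm_minus_lc: np.ndarray
    sum_lc_plus_bnm: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        lengths = {
            len(self.tau_lc),
            len(self.tau_bnm),
            len(self.contrast_lc_minus_bnm),
            len(self.contrast_bnm_minus_lc),
            len(self.sum_lc_plus_bnm),
        }
        if len(lengths) != 1:
            raise ValueError("all arousal series must share one length")

    def by_type(self, event_type: str) -> np.ndarray:
        """Return the series a given event type is detected on."""
        return {
            "lc_minus_bnm": self.contrast_lc_minus_bnm,
            "bnm_minus_lc": self.contrast_bnm_minus_lc,
            "lc_plus_bnm": self.sum_lc_plus_bnm,
        }[event_type]


EVENT_TYPES = ("lc_minus_bnm", "bnm_minus_lc", "lc_plus_bnm")


@dataclass
class PhasicEventSet:
    """Detected phasic burst onsets.

    ``events`` has columns ``subject, t0_index, type, accel_value,
    sustain_peak``; ``type`` is one of ``lc_minus_bnm | bnm_minus_lc |
    lc_plus_bnm``.
    """

    events: pd.DataFrame
    accel_sd: float = 2.0
    sustain_sd: float = 2.0
    sustain_window: int = 10
    boundary: int = 20

    COLUMNS = ("subject", "t0_index", "type", "accel_value", "sustain_peak")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        self.events = self.events.reset_index(drop=True)
        self.events["t0_index"] = self.events["t0_index"].astype(int)

    def __len__(self) -> int:
        return len(self.events)

    def of_type(self, event_type: str) -> "PhasicEventSet":
        sub = self.events[self.events["type"] == event_type]
        return PhasicEventSet(
            sub.copy(), self.accel_sd, self.sustain_sd, self.sustain_window, self.boundary
        )

    def for_subject(self, subject: str) -> np.ndarray:
        sub = self.events[self.events["subject"] == subject]
        return np.sort(sub["t0_index"].to_numpy(dtype=int))

    def counts_by_type(self) -> dict[str, int]:
        counts = self.events["type"].value_counts().to_dict()
        return {t: int(counts.get(t, 0)) for t in EVENT_TYPES}


@dataclass
class WaveFit:
    """Event-locked latency map and travelling-wave velocity estimate."""

    time_to_peak_s: np.ndarray  # per parcel, seconds
    coords_mm: np.ndarray  # (R, 3)
    velocity_m_per_s: float
    direction_sign: int  # +1 anterior-to-posterior (latency grows toward -y)
    fit_r2: float
    slope_s_per_mm: float = np.nan

    @property
    def velocity_defined(self) -> bool:
        return np.isfinite(self.velocity_m_per_s)


@dataclass
class DynamicNetwork:
    """Windowed coupling and its modular decomposition.

    ``coupling`` is (n_windows, R, R); ``window_centers`` maps each window
    to the TR index of its centre so PC time courses can be aligned with
    the arousal series.
    """

    coupling: np.ndarray
    window_centers: np.ndarray
    window_w: int
    partitions: np.ndarray | None = None  # (n_windows, R) int labels
    q_values: np.ndarray | None = None
    pc: np.ndarray | None = None  # (n_windows, R)
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.coupling.ndim != 3 or self.coupling.shape[1] != self.coupling.shape[2]:
            raise ValueError("coupling must be (windows, R, R)")
        if len(self.window_centers) != self.coupling.shape[0]:
            raise ValueError("window_centers must match number of windows")


@dataclass
class MsdSamples:
    """Per-event mean-squared-displacement trajectories.

    ``samples[i, t-1]`` is the MSD at lag ``t`` TR (t = 1..max_lag) from
    reference onset ``t0_list[i]``: the mean over parcels of the squared
    BOLD change between t0 and t0+t.
    """

    samples: np.ndarray  # (n_events, max_lag)
    t0_list: np.ndarray
    max_lag: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != self.max_lag:
            raise ValueError("samples must be (n_events, max_lag)")
        if np.any(self.samples < 0):
            raise ValueError("MSD samples must be non-negative")

    @property
    def n_events(self) -> int:
        return self.samples.shape[0]


@dataclass
class EnergyLandscape:
    """Probability surface P(MSD, lag) and its energy E = ln(1/P).

    ``P[t, m]`` is the kernel-density estimate of the MSD distribution at
    lag ``lag_grid[t]`` evaluated at ``msd_grid[m]``; ``E`` is -ln P with
    low-density cells capped and flagged in ``flagged``.
    """

    msd_grid: np.ndarray
    lag_grid: np.ndarray
    P: np.ndarray  # (n_lags, n_msd)
    E: np.ndarray
    n: int
    condition: str = ""
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.P.shape != (len(self.lag_grid), len(self.msd_grid)):
            raise ValueError("P shape must be (n_lags, n_msd)")
        if self.E.shape != self.P.shape:
            raise ValueError("E shape must match P")
        if self.flagged is None:
            self.flagged = np.zeros_like(self.P, dtype=bool)


@dataclass
class NullDistribution:
    """Resampled null distribution of a statistic with its 95% CI."""

    samples: np.ndarray
    ci_low: float
    ci_high: float
    n_perm: int
    exclusion_halfwidth: int = 10

    def __post_init__(self) -> None:
        if len(self.samples) != self.n_perm:
            raise ValueError("samples must have length n_perm")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


@dataclass
class EventLockedResponse:
    """FIR response around behavioural events, lags -L..+L TR."""

    lags: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    signal_label: str
    null_ci_low: np.ndarray | None = None
    null_ci_high: np.ndarray | None = None
    low_power: bool = False

    def __post_init__(self) -> None:
        L = (len(self.lags) - 1) // 2
        if len(self.lags) != 2 * L + 1:
            raise ValueError("lags must span -L..L")
        if len(self.mean) != len(self.lags) or len(self.sem) != len(self.lags):
            raise ValueError("mean/sem must match lags")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")
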