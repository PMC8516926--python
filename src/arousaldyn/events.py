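"""Phasic burst detection in conditioned arousal series.

A phasic burst onset is a time point whose BOLD *acceleration* (second
temporal derivative) is unusually high and that is followed by a sustained
elevation of the signal itself.  Three criteria define an onset t0:

1. accel[t0] >= mean(accel) + accel_sd * sd(accel);
2. at least one sample of the series in the following ``sustain_window``
   TRs reaches mean(series) + sustain_sd * sd(series);
3. t0 lies outside the first and last ``boundary`` TRs of the run.

Only local maxima of the acceleration are kept, so one burst yields one
event and detections stay sparse.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import EVENT_TYPES, ArousalSignals, PhasicEventSet

__all__ = ["second_derivative", "detect_phasic_events", "detect_all_types"]


def second_derivative(series: np.ndarray) -> np.ndarray:
    """Central second difference; endpoints are NaN (invalid).

    accel[t] = x[t-1] - 2 x[t] + x[t+1] for interior t.  The symmetric
    stencil preserves peak timing, which forward differences would shift.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D with length >= 3")
    accel = np.full_like(x, np.nan)
    accel[1:-1] = x[:-2] - 2 * x[1:-1] + x[2:]
    return accel


def _qualifying_mask(
    series: np.ndarray,
    accel: np.ndarray,
    accel_sd: float,
    sustain_sd: float,
    sustain_window: int,
    boundary: int,
) -> np.ndarray:
    T = len(series)
    valid = ~np.isnan(accel)
    mu_a, sd_a = accel[valid].mean(), accel[valid].std()
    mu_s, sd_s = series.mean(), series.std()
    if sd_a == 0 or sd_s == 0:
        return np.zeros(T, dtype=bool)

    accel_ok = np.zeros(T, dtype=bool)
    accel_ok[valid] = accel[valid] >= mu_a + accel_sd * sd_a

    thresh = mu_s + sustain_sd * sd_s
    sustain_ok = np.zeros(T, dtype=bool)
    for t in np.flatnonzero(accel_ok):
        seg = series[t + 1 : t + 1 + sustain_window]
        sustain_ok[t] = len(seg) > 0 and seg.max() >= thresh

    bounds_ok = np.zeros(T, dtype=bool)
    bounds_ok[boundary : T - boundary] = True
    return accel_ok & sustain_ok & bounds_ok


def detect_phasic_events(
    series: np.ndarray,
    accel_sd: float = 2.0,
    sustain_sd: float = 2.0,
    sustain_window: int = 10,
    boundary: int = 20,
    subject_id: str = "",
    event_type: str = "lc_minus_bnm",
) -> PhasicEventSet:
    """Detect phasic burst onsets in one series.

    Statistics (mean, s.d.) are computed over the full valid series of the
    subject.  A degenerate series (zero variance in signal or acceleration)
    yields an empty event set with a warning.
    """
    x = np.asarray(series, dtype=float)
    T = len(x)
    if T <= 2 * boundary + sustain_window:
        raise ValueError("series too short for the requested boundary and window")
    accel = second_derivative(x)
    if x.std() == 0 or accel[1:-1].std() == 0:
        warnings.warn("degenerate (constant) series: no events detectable", stacklevel=2)
        return _empty_set(accel_sd, sustain_sd, sustain_window, boundary)

    mask = _qualifying_mask(x, accel, accel_sd, sustain_sd, sustain_window, boundary)
    # keep only local maxima of the raw acceleration: one burst yields one
    # event, and because the peak set does not depend on the thresholds the
    # detected events nest across thresholds (counts are monotone in the
    # sweep).  Plateaus keep their left edge.
    peak = np.zeros_like(mask)
    peak[1:-1] = (accel[1:-1] >= accel[:-2]) & (accel[1:-1] > accel[2:])
    onsets = [int(t) for t in np.flatnonzero(mask & peak)]

    rows = []
    thresh_peak = lambda t: x[t + 1 : t + 1 + sustain_window].max()  # noqa: E731
    for t0 in onsets:
        rows.append((subject_id, t0, event_type, accel[t0], thresh_peak(t0)))
    table = pd.DataFrame(rows, columns=list(PhasicEventSet.COLUMNS))
    return PhasicEventSet(table, accel_sd, sustain_sd, sustain_window, boundary)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": pd.Series(dtype=str),
            "t0_index": pd.Series(dtype=int),
            "type": pd.Series(dtype=str),
            "accel_value": pd.Series(dtype=float),
            "sustain_peak": pd.Series(dtype=float),
        }
    )


def _empty_set(accel_sd, sustain_sd, sustain_window, boundary) -> PhasicEventSet:
    return PhasicEventSet(_empty_table(), accel_sd, sustain_sd, sustain_window, boundary)


def detect_all_types(
    signals: ArousalSignals,
    accel_sd: float = 2.0,
    sustain_sd: float = 2.0,
    sustain_window: int = 10,
    boundary: int = 20,
) -> PhasicEventSet:
    """Run the detector on both contrasts and the sum series.

    Each event type is detected on its own series (difference for
    lc_minus_bnm / bnm_minus_lc, sum for lc_plus_bnm), using that series'
    own mean and s.d.
    """
    parts = []
    for etype in EVENT_TYPES:
        es = detect_phasic_events(
            signals.by_type(etype),
            accel_sd,
            sustain_sd,
            sustain_window,
            boundary,
            subject_id=signals.subject_id,
            event_type=etype,
        )
        if len(es.events):
            parts.append(es.events)
    table = pd.concat(parts, ignore_index=True) if parts else _empty_table()
    return PhasicEventSet(table, accel_sd, sustain_sd, sustain_window, boundary)


def detect_cohort(
    signals_by_subject: dict[str, ArousalSignals],
    accel_sd: float = 2.0,
    sustain_sd: float = 2.0,
    sustain_window: int = 10,
    boundary: int = 20,
) -> PhasicEventSet:
    """Pool per-subject detections into one cohort-level event table."""
    parts = []
    for sid, sig in signals_by_subject.items():
        if not sig.subject_id:
            sig.subject_id = sid
        tab = detect_all_types(sig, accel_sd, sustain_sd, sustain_window, boundary).events
        if len(tab):
            parts.append(tab)
    table = pd.concat(parts, ignore_index=True) if parts else _empty_table()
    return PhasicEventSet(table, accel_sd, sustain_sd, sustain_window, boundary)
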