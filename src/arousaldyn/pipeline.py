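"""Convenience drivers chaining the pipeline stages over a cohort store."""

from __future__ import annotations

import numpy as np

from .conditioning import make_arousal_signals
from .datatypes import ArousalSignals, EnergyLandscape, ParcelTimeSeries, PhasicEventSet
from .events import detect_cohort
from .io import CohortStore
from .landscape import build_landscapes
from .nulls import sample_null_timepoints

__all__ = [
    "load_cortex_cohort",
    "condition_cohort",
    "detect_events",
    "landscapes_with_baseline",
]


def load_cortex_cohort(store: CohortStore) -> dict[str, ParcelTimeSeries]:
    return {sid: store.load_cortex(sid) for sid in store.subjects}


def condition_cohort(
    store: CohortStore, residualize: bool = True
) -> dict[str, ArousalSignals]:
    """Condition each subject's LC/BNM channels against both nuisances.

    ``residualize=False`` supports cohorts whose subcortical series were
    already residualized upstream.
    """
    out = {}
    for sid in store.subjects:
        sub = store.load_subcortical(sid)
        nuisances = [
            sub[c].to_numpy(float)
            for c in ("fourth_ventricle", "pons")
            if c in sub.columns
        ]
        out[sid] = make_arousal_signals(
            sub["lc"].to_numpy(float),
            sub["bnm"].to_numpy(float),
            nuisances,
            tr_seconds=store.tr_seconds,
            residualize=residualize,
            subject_id=sid,
        )
    return out


def detect_events(
    signals: dict[str, ArousalSignals],
    accel_sd: float = 2.0,
    sustain_sd: float = 2.0,
    sustain_window: int = 10,
    boundary: int = 20,
) -> PhasicEventSet:
    return detect_cohort(signals, accel_sd, sustain_sd, sustain_window, boundary)


def landscapes_with_baseline(
    cohort: dict[str, ParcelTimeSeries],
    events: PhasicEventSet,
    n_baseline: int = 5000,
    max_lag: int = 15,
    bandwidth: float = 4.0,
    msd_max: float = 50.0,
    seed: int = 0,
) -> dict[str, EnergyLandscape]:
    """Per-condition landscapes plus the block-resampled baseline E_A.

    Baseline onsets are random non-event time points (>= 10 TR from every
    detected event), pooled across subjects.
    """
    lengths = {sid: ts.n_timepoints for sid, ts in cohort.items()}
    null_t0s = sample_null_timepoints(
        events, lengths, n=n_baseline, max_lag=max_lag + 1, seed=seed
    )
    baseline: dict[str, list[int]] = {sid: [] for sid in cohort}
    for sid, t0 in null_t0s:
        baseline[sid].append(t0)
    conditions: dict[str, dict[str, np.ndarray]] = {
        "baseline": {sid: np.array(v, dtype=int) for sid, v in baseline.items()}
    }
    label_map = {"lc_minus_bnm": "lc", "bnm_minus_lc": "bnm", "lc_plus_bnm": "lc_plus_bnm"}
    for etype, cond in label_map.items():
        sub = events.of_type(etype)
        conditions[cond] = {sid: sub.for_subject(sid) for sid in cohort}
    from .landscape import default_msd_grid

    return build_landscapes(
        cohort, conditions, max_lag=max_lag, bandwidth=bandwidth,
        msd_grid=default_msd_grid(msd_max),
    )
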