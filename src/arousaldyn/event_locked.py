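"""FIR event-locked responses around behavioural events.

For the meditation analysis, each button press marks a shift in conscious
awareness.  The response of a signal (arousal contrast, TR-to-TR MSD,
mean participation coefficient) around the presses is recovered with a
finite-impulse-response (FIR) regression: the signal is fit on lagged
event indicators spanning -L..+L TR plus an intercept, so the
coefficients are the deconvolved event-locked response.  For isolated
(non-overlapping) events this equals the event-locked average minus the
off-event baseline mean.
"""

from __future__ import annotations

import numpy as np

from .datatypes import EventLockedResponse, ParcelTimeSeries

__all__ = ["tr_to_tr_msd", "fir_event_response", "meditation_pipeline"]


def tr_to_tr_msd(ts: ParcelTimeSeries) -> np.ndarray:
    """Mean over parcels of the squared TR-to-TR BOLD change; length T-1.

    This is lag-1 of the MSD trajectory machinery with every time point
    as its own reference.
    """
    dX = np.diff(ts.data, axis=0)
    return (dX**2).mean(axis=1)


def fir_event_response(
    signal: np.ndarray,
    event_indices: np.ndarray,
    L: int = 5,
    signal_label: str = "",
) -> EventLockedResponse:
    """FIR regression of ``signal`` on lagged event indicators.

    Builds 2L+1 indicator regressors (one per lag -L..+L) plus an
    intercept and fits by ordinary least squares.  Events without full
    +/-L context are dropped.  The standard errors come from the
    homoscedastic OLS coefficient covariance.
    """
    y = np.asarray(signal, dtype=float)
    T = len(y)
    ev = np.asarray(event_indices, dtype=int)
    ev = ev[(ev - L >= 0) & (ev + L < T)]
    if len(ev) == 0:
        raise ValueError("no events with full +/-L context")
    lags = np.arange(-L, L + 1)
    X = np.zeros((T, len(lags) + 1))
    X[:, 0] = 1.0
    for li, lag in enumerate(lags):
        X[ev + lag, li + 1] = 1.0
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular FIR design (events overlap at every lag)")
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    dof = T - X.shape[1]
    rss = float(res[0]) if len(res) else float(((y - X @ beta) ** 2).sum())
    sigma2 = rss / max(dof, 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    sem = np.sqrt(np.diag(cov)[1:])
    return EventLockedResponse(
        lags=lags,
        mean=beta[1:],
        sem=sem,
        signal_label=signal_label,
        low_power=len(ev) < 5,
    )


def _attach_null_ci(
    response: EventLockedResponse,
    signal: np.ndarray,
    null_indices: np.ndarray,
    n_events: int,
    L: int,
    n_perm: int,
    seed: int,
) -> EventLockedResponse:
    """95% CI per lag from FIR fits on resampled pseudo-event sets."""
    rng = np.random.default_rng(seed)
    pool = np.asarray(null_indices, dtype=int)
    draws = np.empty((n_perm, len(response.lags)))
    for k in range(n_perm):
        pick = rng.choice(pool, size=n_events, replace=len(pool) < n_events)
        try:
            draws[k] = fir_event_response(signal, np.unique(pick), L).mean
        except ValueError:
            draws[k] = np.nan
    lo, hi = np.nanpercentile(draws, [2.5, 97.5], axis=0)
    response.null_ci_low = lo
    response.null_ci_high = hi
    return response


def meditation_pipeline(
    contrast_by_subject: dict[str, np.ndarray],
    msd_by_subject: dict[str, np.ndarray],
    pc_by_subject: dict[str, np.ndarray],
    presses_by_subject: dict[str, np.ndarray],
    L: int = 5,
    n_perm: int = 1000,
    exclusion_halfwidth: int = 10,
    boundary: int = 5,
    seed: int = 0,
) -> dict[str, EventLockedResponse]:
    """Pooled FIR responses for the three event-locked signals.

    Per-subject signals are concatenated with press indices offset
    accordingly (presses never straddle subject boundaries because only
    presses with full +/-L context within their own subject are kept).
    The null CI re-evaluates the FIR at block-resampled non-press onsets.
    Keys of the result: ``tau_contrast``, ``msd_tr``, ``mean_pc``.
    """
    from .nulls import eligible_null_indices

    signals = {
        "tau_contrast": contrast_by_subject,
        "msd_tr": msd_by_subject,
        "mean_pc": pc_by_subject,
    }
    out: dict[str, EventLockedResponse] = {}
    for label, per_subject in signals.items():
        concat, events, null_pool = [], [], []
        offset = 0
        for sid, sig in per_subject.items():
            sig = np.asarray(sig, dtype=float)
            presses = np.asarray(presses_by_subject.get(sid, ()), dtype=int)
            presses = presses[(presses - L >= 0) & (presses + L < len(sig))]
            concat.append(sig)
            events.extend(presses + offset)
            idx = eligible_null_indices(
                presses, len(sig), exclusion_halfwidth, boundary=max(boundary, L)
            )
            null_pool.extend(idx + offset)
            offset += len(sig)
        y = np.concatenate(concat)
        resp = fir_event_response(y, np.asarray(events), L, signal_label=label)
        if null_pool:
            resp = _attach_null_ci(
                resp, y, np.asarray(null_pool), len(events), L, n_perm, seed
            )
        out[label] = resp
    return out
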