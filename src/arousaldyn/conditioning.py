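"""Nuisance residualization, band-pass filtering and arousal contrasts.

The subcortical arousal series (locus coeruleus, basal nucleus of Meynert)
are contaminated by non-neural fluctuations from nearby structures (fourth
ventricle CSF, adjacent pontine grey matter).  Conditioning proceeds as:
ordinary-least-squares residualization against the nuisance series, then
zero-phase band-pass filtering to the resting-state BOLD band, then
z-scoring.  The analysis quantities are the contrast series
tau_LC-BNM = z(tau_LC) - z(tau_BNM) (and its negation) and the sum
tau_LC+BNM = z(tau_LC) + z(tau_BNM).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .datatypes import ArousalSignals

__all__ = ["regress_out", "bandpass", "zscore", "make_arousal_signals"]


def regress_out(signal: np.ndarray, nuisances: Sequence[np.ndarray]) -> np.ndarray:
    """OLS residual of ``signal`` on ``nuisances`` plus an intercept.

    The residual is orthogonal to every nuisance regressor and has zero
    mean.  With no nuisances this reduces to demeaning.

    Raises
    ------
    ValueError
        On length mismatch or a rank-deficient design matrix.
    """
    y = np.asarray(signal, dtype=float)
    cols = [np.ones_like(y)]
    for nui in nuisances:
        nui = np.asarray(nui, dtype=float)
        if nui.shape != y.shape:
            raise ValueError("nuisance length does not match signal length")
        cols.append(nui)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient nuisance design (collinear regressors)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def bandpass(
    series: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
    tr_seconds: float = 0.586,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    Applied forward-backward (``sosfiltfilt``) so event timing is not
    shifted, which the lag-based analyses downstream depend on.  Output
    length equals input length.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({nyquist:.3f} Hz)")
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(series, dtype=float))


def zscore(series: np.ndarray) -> np.ndarray:
    """Z-score; an exactly constant series maps to zeros."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def make_arousal_signals(
    lc_raw: np.ndarray,
    bnm_raw: np.ndarray,
    nuisances: Sequence[np.ndarray] = (),
    tr_seconds: float = 0.586,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
    residualize: bool = True,
    standardize: bool = True,
    subject_id: str = "",
) -> ArousalSignals:
    """Condition both arousal channels and form contrast / sum series.

    Order of operations: residualize -> band-pass -> z-score, then
    difference and sum.  ``residualize=False`` accepts series that were
    already residualized upstream; ``standardize=False`` skips z-scoring
    (thresholds downstream are in s.d. units, so detection is unaffected,
    but absolute contrast amplitudes then keep the input units).
    """
    lc = np.asarray(lc_raw, dtype=float)
    bnm = np.asarray(bnm_raw, dtype=float)
    if lc.shape != bnm.shape:
        raise ValueError("LC and BNM series must have the same length")

    def _condition(x: np.ndarray) -> np.ndarray:
        if residualize and len(nuisances) > 0:
            x = regress_out(x, nuisances)
        x = bandpass(x, low_hz, high_hz, tr_seconds)
        if standardize:
            x = zscore(x)
        return x

    tau_lc = _condition(lc)
    tau_bnm = _condition(bnm)
    contrast = tau_lc - tau_bnm
    return ArousalSignals(
        tau_lc=tau_lc,
        tau_bnm=tau_bnm,
        contrast_lc_minus_bnm=contrast,
        contrast_bnm_minus_lc=-contrast,
        sum_lc_plus_bnm=tau_lc + tau_bnm,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
    )
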