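"""MSD energy landscape of BOLD dynamics.

The low-dimensional coordinate is the mean-squared displacement (MSD):
the mean over parcels of the squared change in BOLD between a reference
onset t0 and lag t.  Pooling MSD samples over onsets gives, per lag, a
probability density P(MSD, t) via Gaussian kernel density estimation, and
the landscape is its Boltzmann energy E = ln(1/P) with temperature and
partition function set to 1 (so E is defined up to an additive constant,
and only contrasts between landscapes are interpreted).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize as sp_optimize

from .datatypes import EnergyLandscape, MsdSamples, ParcelTimeSeries

__all__ = [
    "msd_trajectories",
    "kde_density",
    "energy",
    "build_landscape",
    "build_landscapes",
    "landscape_contrast",
    "decompose_joint",
    "default_msd_grid",
    "default_lag_grid",
]

GAUSS_NORM = 1.0 / np.sqrt(2.0 * np.pi)


def default_msd_grid(msd_max: float = 50.0, step: float = 0.5) -> np.ndarray:
    return np.arange(0.0, msd_max + step / 2, step)


def default_lag_grid(max_lag: int = 15) -> np.ndarray:
    return np.arange(1, max_lag + 1)


def msd_trajectories(
    ts: ParcelTimeSeries, t0_list: np.ndarray, max_lag: int = 15
) -> MsdSamples:
    """MSD from each onset: samples[i, t-1] = <(x[t0+t] - x[t0])^2>_parcels."""
    X = ts.data
    t0s = np.asarray(t0_list, dtype=int)
    if len(t0s) == 0:
        raise ValueError("t0_list is empty")
    if np.any(t0s < 0) or np.any(t0s + max_lag >= X.shape[0]):
        raise IndexError("t0 + max_lag exceeds series length")
    lags = np.arange(1, max_lag + 1)
    # (n_events, max_lag, R) displacements
    disp = X[t0s[:, None] + lags[None, :], :] - X[t0s][:, None, :]
    samples = (disp**2).mean(axis=2)
    return MsdSamples(samples=samples, t0_list=t0s, max_lag=max_lag)


def kde_density(
    samples: MsdSamples,
    bandwidth: float = 4.0,
    msd_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-lag Gaussian KDE of the MSD samples on ``msd_grid``.

    P(m, t) = (1/(n h)) sum_i phi((m - MSD_{t,i})/h) with phi the standard
    normal density, so each per-lag density integrates to 1 over the real
    line (the truncated display grid holds less than unit mass).
    """
    if msd_grid is None:
        msd_grid = default_msd_grid()
    S = samples.samples
    n = S.shape[0]
    if n < 1:
        raise ValueError("no MSD samples")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    # (lags, grid): sum kernels over events
    u = (msd_grid[None, None, :] - S.T[:, :, None]) / bandwidth
    P = GAUSS_NORM * np.exp(-0.5 * u**2)
    return P.sum(axis=1) / (n * bandwidth)


def energy(P: np.ndarray, floor: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann energy E = -ln(P) with a density floor.

    Cells with P <= floor are capped at -ln(floor) and flagged; flagged
    cells are excluded from contrasts and decomposition downstream.
    Returns ``(E, flagged)``.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("P must be non-negative")
    if floor is None:
        floor = max(P.max(), np.finfo(float).tiny) * 1e-12
    flagged = P <= floor
    E = np.where(flagged, -np.log(floor), -np.log(np.where(flagged, 1.0, P)))
    return E, flagged


def build_landscape(
    samples: MsdSamples,
    bandwidth: float = 4.0,
    msd_grid: np.ndarray | None = None,
    condition: str = "",
    floor_scale: float = 0.01,
) -> EnergyLandscape:
    """KDE + energy transform for one pooled sample set.

    The density floor is ``floor_scale / (n * bandwidth)`` — the height a
    single kernel contributes at ~3 bandwidths — so sparsely sampled tails
    are flagged rather than assigned spuriously precise energies.
    """
    if msd_grid is None:
        msd_grid = default_msd_grid()
    P = kde_density(samples, bandwidth, msd_grid)
    floor = floor_scale / (samples.n_events * bandwidth)
    E, flagged = energy(P, floor=floor)
    return EnergyLandscape(
        msd_grid=np.asarray(msd_grid, dtype=float),
        lag_grid=np.arange(1, samples.max_lag + 1),
        P=P,
        E=E,
        n=samples.n_events,
        condition=condition,
        flagged=flagged,
    )


#: reference per-parcel BOLD amplitude (s.d. units) that subjects are
#: standardized to before displacement.  Unit-variance parcels bound the
#: MSD near 4, which would leave the canonical 0-50 display grid empty;
#: sigma = 4 places typical resting displacements mid-grid while keeping
#: the cross-subject pooling scale-free.
REFERENCE_BOLD_SD = 4.0


def _pool_samples(
    cohort: dict[str, ParcelTimeSeries],
    t0s_by_subject: dict[str, np.ndarray],
    max_lag: int,
    reference_sd: float = REFERENCE_BOLD_SD,
) -> MsdSamples | None:
    blocks = []
    t0_all = []
    for sid, ts in cohort.items():
        t0s = np.asarray(t0s_by_subject.get(sid, ()), dtype=int)
        if len(t0s) == 0:
            continue
        X = ts.data
        if reference_sd is not None:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd * reference_sd
            ts = ParcelTimeSeries(X, ts.tr_seconds, ts.parcels, ts.subject_id)
        blocks.append(msd_trajectories(ts, t0s, max_lag).samples)
        t0_all.append(t0s)
    if not blocks:
        return None
    return MsdSamples(
        samples=np.vstack(blocks), t0_list=np.concatenate(t0_all), max_lag=max_lag
    )


def build_landscapes(
    cohort: dict[str, ParcelTimeSeries],
    events_by_condition: dict[str, dict[str, np.ndarray]],
    max_lag: int = 15,
    bandwidth: float = 4.0,
    msd_grid: np.ndarray | None = None,
    reference_sd: float = REFERENCE_BOLD_SD,
) -> dict[str, EnergyLandscape]:
    """One pooled landscape per condition across subjects.

    ``events_by_condition`` maps a condition label (e.g. ``baseline``,
    ``lc``, ``bnm``, ``lc_plus_bnm``) to per-subject onset arrays.  Each
    subject's cortical matrix is standardized (z-scored per parcel, then
    scaled to ``reference_sd``) before displacement so subjects pool on a
    common scale that fills the canonical MSD grid.  Conditions with no
    events are skipped with a warning.
    """
    out: dict[str, EnergyLandscape] = {}
    for cond, t0s_by_subject in events_by_condition.items():
        pooled = _pool_samples(cohort, t0s_by_subject, max_lag, reference_sd)
        if pooled is None:
            warnings.warn(f"condition '{cond}' has no events; skipped", stacklevel=2)
            continue
        out[cond] = build_landscape(pooled, bandwidth, msd_grid, condition=cond)
    return out


def landscape_contrast(
    E_event: EnergyLandscape,
    E_base: EnergyLandscape,
    lag_range: tuple[int, int] = (10, 15),
) -> np.ndarray:
    """Mean energy difference (event - baseline) per MSD bin over ``lag_range``.

    Cells flagged as below the density floor in either landscape are
    excluded from the per-bin average (NaN where no lag survives).
    """
    if not np.array_equal(E_event.msd_grid, E_base.msd_grid) or not np.array_equal(
        E_event.lag_grid, E_base.lag_grid
    ):
        raise ValueError("landscape grids do not match")
    lo, hi = lag_range
    sel = (E_event.lag_grid >= lo) & (E_event.lag_grid <= hi)
    diff = E_event.E[sel] - E_base.E[sel]
    bad = E_event.flagged[sel] | E_base.flagged[sel]
    diff = np.where(bad, np.nan, diff)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(diff, axis=0)


def decompose_joint(
    E_joint: EnergyLandscape,
    E_lc: EnergyLandscape,
    E_bnm: EnergyLandscape,
    sum_to_one: bool = False,
) -> tuple[float, float, float]:
    """Non-negative decomposition E_joint ~ alpha E_lc + beta E_bnm.

    Solved by non-negative least squares over all grid cells finite (not
    floor-flagged) in all three landscapes.  ``sum_to_one`` renormalizes
    (alpha, beta) to unit sum after the fit.  Returns
    ``(alpha, beta, residual_norm)``.
    """
    for other in (E_lc, E_bnm):
        if not np.array_equal(E_joint.msd_grid, other.msd_grid) or not np.array_equal(
            E_joint.lag_grid, other.lag_grid
        ):
            raise ValueError("landscape grids do not match")
    ok = ~(E_joint.flagged | E_lc.flagged | E_bnm.flagged)
    if ok.sum() < 2:
        raise ValueError("too few jointly finite cells for decomposition")
    A = np.column_stack([E_lc.E[ok], E_bnm.E[ok]])
    b = E_joint.E[ok]
    corr = np.corrcoef(A[:, 0], A[:, 1])[0, 1]
    if abs(corr) > 0.999:
        warnings.warn("E_lc and E_bnm are nearly collinear; decomposition is ill-conditioned", stacklevel=2)
    coef, resid = sp_optimize.nnls(A, b)
    alpha, beta = float(coef[0]), float(coef[1])
    if sum_to_one and alpha + beta > 0:
        alpha, beta = alpha / (alpha + beta), beta / (alpha + beta)
    return alpha, beta, float(resid)
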