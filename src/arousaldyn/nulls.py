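"""Block-resampling null models and permutation tests.

Significance throughout the pipeline is assessed against statistics
recomputed at random non-event time points.  Because the statistic is
always evaluated on contiguous windows around the resampled onsets, the
characteristic temporal autocorrelation of BOLD is preserved under the
null — the point of block resampling, as opposed to sample shuffling.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np

from .datatypes import NullDistribution, PhasicEventSet

__all__ = [
    "sample_null_timepoints",
    "null_distribution",
    "permutation_test_one_sided",
]


def eligible_null_indices(
    event_t0s: np.ndarray,
    T: int,
    exclusion_halfwidth: int = 10,
    boundary: int = 20,
    max_lag: int = 0,
) -> np.ndarray:
    """Indices satisfying the boundary constraint and >= halfwidth from events.

    ``max_lag`` further trims the tail so downstream lag windows fit.
    """
    lo = boundary
    hi = T - max(boundary, max_lag)
    if hi <= lo:
        return np.empty(0, dtype=int)
    ok = np.ones(T, dtype=bool)
    ok[:lo] = False
    ok[hi:] = False
    for t0 in np.asarray(event_t0s, dtype=int):
        ok[max(0, t0 - exclusion_halfwidth) : t0 + exclusion_halfwidth + 1] = False
    return np.flatnonzero(ok)


def sample_null_timepoints(
    event_set: PhasicEventSet,
    series_lengths: dict[str, int],
    n: int = 5000,
    exclusion_halfwidth: int = 10,
    boundary: int = 20,
    max_lag: int = 0,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Random non-event onsets, uniform over the pooled eligible indices.

    Draws respect per-subject boundaries (never cross subjects), the edge
    exclusion, and a minimum distance of ``exclusion_halfwidth`` TR from
    every detected event of any type.  If the eligible pool is smaller
    than ``n`` the draws are taken with replacement and a warning is
    raised; an empty pool is an error.
    """
    rng = np.random.default_rng(seed)
    pool: list[tuple[str, int]] = []
    for sid, T in series_lengths.items():
        t0s = event_set.events.loc[event_set.events["subject"] == sid, "t0_index"].to_numpy()
        idx = eligible_null_indices(t0s, T, exclusion_halfwidth, boundary, max_lag)
        pool.extend((sid, int(t)) for t in idx)
    if not pool:
        raise ValueError("no eligible null time points (events cover every index)")
    replace = len(pool) < n
    if replace:
        warnings.warn(
            f"eligible null pool ({len(pool)}) smaller than n ({n}); sampling with replacement",
            stacklevel=2,
        )
    chosen = rng.choice(len(pool), size=n, replace=replace)
    return [pool[i] for i in chosen]


def null_distribution(
    statistic: Callable[[Sequence[tuple[str, int]]], float],
    null_t0s: Sequence[tuple[str, int]],
    n_events: int,
    n_perm: int = 5000,
    seed: int = 0,
    exclusion_halfwidth: int = 10,
) -> NullDistribution:
    """Null distribution of a statistic over resampled pseudo-event sets.

    Each permutation draws ``n_events`` onsets (the observed event count,
    so sampling variability matches) from the null pool and evaluates
    ``statistic`` on them.  The 2.5th/97.5th percentiles give the 95% CI.
    """
    rng = np.random.default_rng(seed)
    null_t0s = list(null_t0s)
    samples = np.empty(n_perm)
    for k in range(n_perm):
        pick = rng.choice(len(null_t0s), size=n_events, replace=len(null_t0s) < n_events)
        samples[k] = statistic([null_t0s[i] for i in pick])
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return NullDistribution(
        samples=samples,
        ci_low=float(lo),
        ci_high=float(hi),
        n_perm=n_perm,
        exclusion_halfwidth=exclusion_halfwidth,
    )


def permutation_test_one_sided(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> float:
    """One-sided permutation p for mean(a) > mean(b).

    Labels are shuffled ``n_perm`` times; p = (1 + #{permuted diff >
    observed}) / (n_perm + 1).  The +1 smoothing keeps p above zero and
    the strict inequality lets a perfectly separated contrast reach the
    1/(n_perm+1) floor (re-drawing the observed labelling does not count
    as evidence against it).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[: len(a)].mean() - perm[len(a) :].mean()
        if diff > observed:
            count += 1
    return (1 + count) / (n_perm + 1)
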