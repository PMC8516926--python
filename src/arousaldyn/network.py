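"""Time-resolved connectivity, signed modularity, and participation.

Coupling is estimated with the multiplication of temporal derivatives
(MTD): the point-wise product of the first differences of two parcel
series, normalized by the standard deviation of each derivative and
averaged over a sliding window.  Community structure is found by a
Louvain-style greedy optimization of the signed modularity

    Q = (1/v+) sum_ij (w+_ij - gamma e+_ij) delta(M_i, M_j)
      - (1/(v+ + v-)) sum_ij (w-_ij - gamma e-_ij) delta(M_i, M_j)

where the positive and negative layers carry their own strength-product
null e_ij = s_i s_j / v and the resolution parameter gamma scales both
null terms.  Integration is summarized by the participation coefficient
computed on positive weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DynamicNetwork, ParcelTimeSeries

__all__ = [
    "mtd",
    "time_averaged_coupling",
    "modularity_q",
    "louvain_consensus",
    "participation_coefficient",
    "lagged_pc_coupling",
    "hemisphere_timing_contrast",
    "aggregate_by_network",
    "sweep_gamma",
]


# ---------------------------------------------------------------------------
# coupling


def mtd(ts: ParcelTimeSeries, w: int = 20, step: int = 1) -> DynamicNetwork:
    """Multiplication-of-temporal-derivatives coupling tensor.

    Derivatives are first differences; each channel's derivative is
    normalized by its own standard deviation over the full run, so the
    coupling of two identical series is ~1.  Window k averages the
    normalized products over ``w`` consecutive derivative samples starting
    at ``k * step``; its centre is reported in TR units of the original
    series.  A zero-variance derivative channel yields NaN couplings for
    that parcel.
    """
    X = ts.data
    T = X.shape[0]
    if T <= w + 1:
        raise ValueError("need T > w + 1 for at least one window")
    dX = np.diff(X, axis=0)
    sd = dX.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dXn = dX / sd
    dXn[:, sd == 0] = np.nan

    n_win = (dX.shape[0] - w) // step + 1
    R = X.shape[1]
    coupling = np.empty((n_win, R, R))
    centers = np.empty(n_win)
    for k in range(n_win):
        seg = dXn[k * step : k * step + w]
        coupling[k] = seg.T @ seg / w
        # derivative sample t sits between TR t and t+1
        centers[k] = k * step + (w - 1) / 2.0 + 0.5
    return DynamicNetwork(coupling=coupling, window_centers=centers, window_w=w)


def time_averaged_coupling(ts: ParcelTimeSeries) -> np.ndarray:
    """MTD averaged over the whole run, diagonal zeroed."""
    dX = np.diff(ts.data, axis=0)
    sd = dX.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dXn = dX / sd
    W = dXn.T @ dXn / dX.shape[0]
    np.fill_diagonal(W, 0.0)
    return W


# ---------------------------------------------------------------------------
# signed modularity


def _signed_modularity_matrix(W: np.ndarray, gamma: float) -> np.ndarray:
    """Matrix B with Q(partition) = sum of B over same-module pairs."""
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    vp = Wp.sum()
    vn = Wn.sum()
    B = np.zeros_like(W, dtype=float)
    if vp > 0:
        sp = Wp.sum(axis=1)
        B += (Wp - gamma * np.outer(sp, sp) / vp) / vp
    if vn > 0:
        sn = Wn.sum(axis=1)
        B -= (Wn - gamma * np.outer(sn, sn) / vn) / (vp + vn)
    return B


def modularity_q(W: np.ndarray, partition: np.ndarray, gamma: float = 1.0) -> float:
    """Signed modularity of ``partition`` on weight matrix ``W``.

    Positive and negative layers are normalized asymmetrically (positive
    by v+, negative by v+ + v-) and each layer uses its own
    strength-product null, scaled by ``gamma``.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    labels = np.asarray(partition)
    if len(labels) != W.shape[0]:
        raise ValueError("partition must cover all nodes")
    B = _signed_modularity_matrix(W, gamma)
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _greedy_phase(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One Louvain phase: sweep nodes, moving each to its best community."""
    n = B.shape[0]
    improved = False
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            w_ic = np.bincount(labels, weights=B[i], minlength=labels.max() + 1)
            own = labels[i]
            # Q gain of moving i to c (halved): w_ic - w_i,own + B_ii; staying = 0
            gains = w_ic - w_ic[own] + B[i, i]
            gains[own] = 0.0
            best = int(np.argmax(gains))
            if best != own and gains[best] > 1e-12:
                labels[i] = best
                moved = True
                improved = True
    return improved


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _louvain_matrix(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy Louvain (move + aggregate) on a generic modularity matrix."""
    n = B.shape[0]
    assignment = np.arange(n)  # node -> community in original indexing
    Bc = B.copy()
    while True:
        labels = np.arange(Bc.shape[0])
        improved = _greedy_phase(Bc, labels, rng)
        labels = _relabel(labels)
        if not improved or labels.max() == Bc.shape[0] - 1:
            break
        assignment = labels[assignment]
        # aggregate communities into super-nodes
        k = labels.max() + 1
        S = np.zeros((Bc.shape[0], k))
        S[np.arange(Bc.shape[0]), labels] = 1.0
        Bc = S.T @ Bc @ S
    return _relabel(assignment)


def louvain_consensus(
    W: np.ndarray,
    gamma: float = 1.0,
    runs: int = 500,
    seed: int = 0,
    consensus_tau: float = 0.5,
    max_iter: int = 20,
) -> tuple[np.ndarray, float]:
    """Consensus community structure over repeated Louvain runs.

    The Louvain heuristic is run ``runs`` times with distinct sub-seeds;
    the co-assignment (module-allegiance) matrix is thresholded at
    ``consensus_tau`` and reclustered iteratively until every run returns
    the same partition.  Returns the consensus partition and its signed
    modularity on ``W``.
    """
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("W must be finite")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    rng = np.random.default_rng(seed)
    B = _signed_modularity_matrix(W, gamma)
    parts = np.stack([_louvain_matrix(B, rng) for _ in range(runs)])

    n_recluster = min(runs, 50)
    for _ in range(max_iter):
        if all((p == parts[0]).all() for p in parts):
            break
        agree = _agreement_matrix(parts)
        Bc = agree - consensus_tau
        np.fill_diagonal(Bc, 0.0)
        parts = np.stack([_louvain_matrix(Bc, rng) for _ in range(n_recluster)])
    partition = _relabel(parts[0])
    return partition, modularity_q(W, partition, gamma)


def _agreement_matrix(parts: np.ndarray) -> np.ndarray:
    """Fraction of runs assigning each node pair to the same module."""
    runs, n = parts.shape
    agree = np.zeros((n, n))
    for p in parts:
        agree += p[:, None] == p[None, :]
    return agree / runs


# ---------------------------------------------------------------------------
# participation


def participation_coefficient(W: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Participation coefficient on positive weights.

    PC_i = 1 - sum_s (kappa_is / kappa_i)^2 with kappa_is the positive
    strength of node i into module s.  Negative weights are discarded;
    self-connections are ignored; an isolated node (kappa_i = 0) gets 0.
    """
    W = np.asarray(W, dtype=float)
    labels = _relabel(np.asarray(partition))
    Wp = np.where(W > 0, W, 0.0)
    np.fill_diagonal(Wp, 0.0)
    k = labels.max() + 1
    S = np.zeros((W.shape[0], k))
    S[np.arange(W.shape[0]), labels] = 1.0
    kappa_is = Wp @ S  # (n, modules)
    kappa_i = kappa_is.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = kappa_is / kappa_i[:, None]
    pc = 1.0 - np.nansum(frac**2, axis=1)
    pc[kappa_i == 0] = 0.0
    return np.clip(pc, 0.0, 1.0)


def network_pipeline(
    ts: ParcelTimeSeries,
    w: int = 20,
    step: int = 1,
    gamma: float = 1.0,
    runs: int = 100,
    seed: int = 0,
) -> DynamicNetwork:
    """Windowed MTD -> per-window consensus partition, Q and PC."""
    net = mtd(ts, w=w, step=step)
    n_win, R, _ = net.coupling.shape
    partitions = np.empty((n_win, R), dtype=int)
    q_values = np.empty(n_win)
    pc = np.empty((n_win, R))
    for k in range(n_win):
        Wk = net.coupling[k].copy()
        np.fill_diagonal(Wk, 0.0)
        part, q = louvain_consensus(Wk, gamma=gamma, runs=runs, seed=seed + k)
        partitions[k] = part
        q_values[k] = q
        pc[k] = participation_coefficient(Wk, part)
    net.partitions = partitions
    net.q_values = q_values
    net.pc = pc
    net.gamma = gamma
    return net


# ---------------------------------------------------------------------------
# event-locked topology


def lagged_pc_coupling(
    contrast: np.ndarray,
    pc: np.ndarray,
    window_centers: np.ndarray,
    max_lag: int = 10,
) -> dict:
    """Lagged correlation between the arousal contrast and PC.

    PC time courses (windows x parcels) are aligned to the contrast by
    their window centres (rounded to the nearest TR).  Positive lag means
    PC follows the contrast.  Returns per-parcel curves, the curve of the
    parcel-mean PC, and the lag grid.
    """
    x = np.asarray(contrast, dtype=float)
    centers = np.rint(np.asarray(window_centers)).astype(int)
    if np.any(centers < 0) or np.any(centers >= len(x)):
        raise ValueError("window centers fall outside the contrast series")
    n_win, R = pc.shape
    lags = np.arange(-max_lag, max_lag + 1)
    per_parcel = np.full((len(lags), R), np.nan)
    mean_curve = np.full(len(lags), np.nan)
    mean_pc = pc.mean(axis=1)
    for li, lag in enumerate(lags):
        tgt = centers + lag
        ok = (tgt >= 0) & (tgt < len(x))
        if ok.sum() < 3:
            continue
        xs = x[tgt[ok]]
        per_parcel[li] = _corr_columns(xs, pc[ok])
        mean_curve[li] = _corr_columns(xs, mean_pc[ok, None])[0]
    return {"lags": lags, "per_parcel": per_parcel, "mean": mean_curve}


def _corr_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc @ Yc) / denom


def hemisphere_timing_contrast(
    values: np.ndarray,
    hemispheres: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """One-sided permutation test of right > left hemisphere means.

    Returns (mean_left, mean_right, p).  Degenerate (zero-variance) input
    raises ``ValueError``.
    """
    from .nulls import permutation_test_one_sided

    values = np.asarray(values, dtype=float)
    hemispheres = np.asarray(hemispheres)
    left = values[hemispheres == "L"]
    right = values[hemispheres == "R"]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("both hemispheres must be represented")
    if values.std() == 0:
        raise ValueError("degenerate input: zero variance across parcels")
    p = permutation_test_one_sided(right, left, n_perm=n_perm, seed=seed)
    return float(left.mean()), float(right.mean()), p


def aggregate_by_network(pc: np.ndarray, network_labels: np.ndarray) -> pd.DataFrame:
    """Per-network mean PC time courses.

    ``pc`` is (windows x parcels); returns a frame indexed by window with
    one column per network label, plus a ``counts`` attribute-style row
    accessible via ``DataFrame.attrs['counts']``.
    """
    labels = np.asarray(network_labels)
    if len(labels) != pc.shape[1]:
        raise ValueError("network labels must cover all parcels")
    out = {}
    counts = {}
    for lab in pd.unique(labels):
        mask = labels == lab
        out[lab] = pc[:, mask].mean(axis=1)
        counts[lab] = int(mask.sum())
    frame = pd.DataFrame(out)
    frame.attrs["counts"] = counts
    return frame


def sweep_gamma(
    W: np.ndarray,
    gammas: np.ndarray | None = None,
    runs: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Partition stability across resolution parameters.

    For each gamma a consensus partition is computed; similarity between
    gammas is the Pearson correlation of their off-diagonal co-assignment
    indicators.  The frame carries per-gamma partitions, mean similarity
    to the other gammas, and ``attrs['best_gamma']`` (most stable).
    """
    if gammas is None:
        gammas = np.arange(0.5, 2.51, 0.25)
    gammas = np.asarray(gammas, dtype=float)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    parts, coassign = [], []
    for i, g in enumerate(gammas):
        part, _ = louvain_consensus(W, gamma=g, runs=runs, seed=seed + i)
        parts.append(part)
        coassign.append((part[:, None] == part[None, :])[iu].astype(float))
    sim = np.ones((len(gammas), len(gammas)))
    for i in range(len(gammas)):
        for j in range(i + 1, len(gammas)):
            a, b = coassign[i], coassign[j]
            if a.std() == 0 or b.std() == 0:
                r = 1.0 if np.array_equal(a, b) else 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            sim[i, j] = sim[j, i] = r
    mean_sim = (sim.sum(axis=1) - 1.0) / max(len(gammas) - 1, 1)
    frame = pd.DataFrame(
        {
            "gamma": gammas,
            "n_modules": [p.max() + 1 for p in parts],
            "mean_similarity": mean_sim,
        }
    )
    frame.attrs["partitions"] = np.stack(parts)
    frame.attrs["similarity"] = sim
    frame.attrs["best_gamma"] = float(gammas[int(np.argmax(mean_sim))])
    return frame
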