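"""Cooperation statistics on discrete action matrices and trajectories.

All statistics follow the study's definitions:

* **success rate** -- fraction of decision time points (rows with at least
  one active player) whose group step reduced the cursor-target distance by
  more than ``delta``;
* **correct response rate** R_i -- fraction of player i's spikes that would
  have reduced the distance had the player acted alone (counterfactual
  single 10 px step along the player's true direction);
* **event synchronization** ES -- near-coincidence count between two spike
  trains within an adaptive half-inter-spike-interval neighborhood,
  normalized by sqrt(m_i * m_j);
* **action-time correlation** C_ij -- Pearson correlation of the binary
  activity columns (equal to Spearman on binary data);
* **cooperation measure** zeta -- sample covariance, over the 28 unordered
  player pairs, between C_ij and the pairwise success probability. Positive
  zeta: pairs that co-activate also tend to produce successful steps.

Undefined statistics (no spikes, constant columns, no co-active steps)
propagate as NaN, never silently as zero.
"""

from __future__ import annotations

import math

import numpy as np

from ._circular import signed_circ_diff
from .engine import BatchRecord, SessionData

_EPS = 1e-9


def _distance_drop(pos, pos_next, target):
    d0 = np.hypot(*(np.asarray(target) - pos).T)
    d1 = np.hypot(*(np.asarray(target) - pos_next).T)
    return d0 - d1


def success_rate(actions, pos, pos_next, target, delta: float = 0.0) -> float:
    """Group success rate over decision time points (rows with >=1 spike).

    A step succeeds when the distance to the target drops strictly more
    than ``delta``. NaN when there are no decision time points.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    actions = np.asarray(actions)
    active = actions.any(axis=1)
    if not active.any():
        return float("nan")
    ok = _distance_drop(pos, pos_next, target) > delta
    return float(ok[active].mean())


def pairwise_success(actions, pos, pos_next, target, delta: float, i: int, j: int) -> float:
    """Success probability restricted to steps where players i and j were
    both active. NaN when the pair never co-activated."""
    actions = np.asarray(actions)
    co = (actions[:, i] == 1) & (actions[:, j] == 1)
    if not co.any():
        return float("nan")
    ok = _distance_drop(pos, pos_next, target) > delta
    return float(ok[co].mean())


def success_matrix(actions, pos, pos_next, target, delta: float = 0.0) -> np.ndarray:
    """All pairwise success probabilities (symmetric; diagonal i == j is the
    player's own conditional success)."""
    actions = np.asarray(actions)
    n = actions.shape[1]
    ok = _distance_drop(pos, pos_next, target) > delta
    a = actions.astype(float)
    co_counts = a.T @ a
    ok_counts = (a * ok[:, None]).T @ a
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(co_counts > 0, ok_counts / co_counts, np.nan)


def correct_response_rate(actions, pos, target, mu_i: float, i: int,
                          step_length: float = 10.0) -> float:
    """Counterfactual single-player improvement rate at player i's spikes."""
    actions = np.asarray(actions)
    spikes = actions[:, i] == 1
    if not spikes.any():
        return float("nan")
    p = np.asarray(pos)[spikes]
    t = np.asarray(target)[spikes] if np.ndim(target) == 2 else np.asarray(target)[None, :]
    solo = p + step_length * np.array([math.cos(mu_i), math.sin(mu_i)])
    d0 = np.hypot(*(t - p).T)
    d1 = np.hypot(*(t - solo).T)
    return float((d0 > d1).mean())


# ---------------------------------------------------------------------------
# event synchronization
# ---------------------------------------------------------------------------


def _half_min_isi(times: np.ndarray) -> np.ndarray:
    """Half of the smaller surrounding inter-spike interval per spike;
    missing boundary intervals count as +inf."""
    isi = np.diff(times)
    prev = np.concatenate(([np.inf], isi))
    nxt = np.concatenate((isi, [np.inf]))
    return 0.5 * np.minimum(prev, nxt)


def _directed_coincidences(ti, tj, half_i, half_j) -> int:
    """Count pairs (k, l) with 0 < ti[k] - tj[l] <= min(half_i[k], half_j[l])."""
    lo = np.searchsorted(tj, ti - half_i)  # tj >= ti - half_i
    hi = np.searchsorted(tj, ti, side="left")  # tj < ti
    n_cand = hi - lo
    if n_cand.sum() == 0:
        return 0
    ks = np.repeat(np.arange(len(ti)), n_cand)
    offs = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
    gap = ti[ks] - tj[offs]
    tau = np.minimum(half_i[ks], half_j[offs])
    return int(((gap > 0) & (gap <= tau + _EPS)).sum())


def event_synchronization(train_i, train_j) -> float:
    """ES in [0, 1]: 1 for identical trains, 0 for trains with no spikes in
    each other's adaptive neighborhoods."""
    ti = np.asarray(train_i, dtype=float)
    tj = np.asarray(train_j, dtype=float)
    if ti.size == 0 or tj.size == 0:
        raise ValueError("event synchronization needs non-empty spike trains")
    if np.any(np.diff(ti) <= 0) or np.any(np.diff(tj) <= 0):
        raise ValueError("spike trains must be strictly increasing")
    hi_, hj_ = _half_min_isi(ti), _half_min_isi(tj)
    n_fwd = _directed_coincidences(ti, tj, hi_, hj_)
    n_bwd = _directed_coincidences(tj, ti, hj_, hi_)
    n_eq = np.intersect1d(ti, tj).size  # each equal pair contributes 1/2 + 1/2
    return float((n_fwd + n_bwd + n_eq) / math.sqrt(ti.size * tj.size))


def synchronization_matrix(actions) -> np.ndarray:
    """Pairwise ES matrix from the binary action matrix (diagonal = 1);
    NaN where a player never spiked."""
    actions = np.asarray(actions)
    n = actions.shape[1]
    trains = [np.flatnonzero(actions[:, i]).astype(float) for i in range(n)]
    es = np.full((n, n), np.nan)
    for i in range(n):
        if trains[i].size == 0:
            continue
        es[i, i] = 1.0
        for j in range(i + 1, n):
            if trains[j].size == 0:
                continue
            es[i, j] = es[j, i] = event_synchronization(trains[i], trains[j])
    return es


# ---------------------------------------------------------------------------
# correlation and the cooperation measure
# ---------------------------------------------------------------------------


def action_time_correlation(actions, i: int, j: int) -> float:
    """Pearson correlation of the binary activity columns of players i, j.

    On binary data this equals the Spearman rank correlation (phi
    coefficient). NaN when either column is constant.
    """
    a = np.asarray(actions, dtype=float)
    x, y = a[:, i], a[:, j]
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx < _EPS or sy < _EPS:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).sum() / ((len(x) - 1) * sx * sy))


def correlation_matrix(actions) -> np.ndarray:
    a = np.asarray(actions, dtype=float)
    n = a.shape[1]
    c = np.full((n, n), np.nan)
    sd = a.std(axis=0, ddof=1)
    ok = sd >= _EPS
    if ok.any():
        with np.errstate(invalid="ignore"):
            sub = np.corrcoef(a[:, ok], rowvar=False)
        c[np.ix_(ok, ok)] = np.atleast_2d(sub)
    return c


def cooperation_measure(corr: np.ndarray, succ: np.ndarray) -> float:
    """zeta: sample covariance (divisor N_p - 1) of the strict upper-triangle
    entries of the correlation and pairwise-success matrices."""
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    c, s = corr[iu], succ[iu]
    bad = np.flatnonzero(~(np.isfinite(c) & np.isfinite(s)))
    if bad.size:
        pairs = [(int(iu[0][b]), int(iu[1][b])) for b in bad]
        raise ValueError(f"undefined pair entries for pairs {pairs}")
    return float(np.cov(c, s, ddof=1)[0, 1])


def synchronization_by_distance(es: np.ndarray, mu: np.ndarray) -> dict:
    """Mean ES bucketed by the signed circular distance between the two
    players' true directions (multiples of pi/4; +-pi share one bucket)."""
    n = es.shape[0]
    buckets: dict[float, list] = {}
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(es[i, j]):
                continue
            d = float(signed_circ_diff(mu[j], mu[i]))
            key = round(d / (math.pi / 4)) * (math.pi / 4)
            if key == -math.pi:
                key = math.pi
            buckets.setdefault(key, []).append(es[i, j])
    return {k: float(np.mean(v)) for k, v in sorted(buckets.items())}


# ---------------------------------------------------------------------------
# session-level report
# ---------------------------------------------------------------------------


def batch_metrics(batch: BatchRecord, delta: float = 0.0) -> dict:
    """All cooperation statistics of one batch."""
    corr = correlation_matrix(batch.actions)
    succ = success_matrix(batch.actions, batch.pos, batch.pos_next, batch.target, delta)
    es = synchronization_matrix(batch.actions)
    iu = np.triu_indices(batch.n_players, k=1)
    defined = np.isfinite(corr[iu]) & np.isfinite(succ[iu])
    zeta = cooperation_measure(corr, succ) if defined.all() else float("nan")
    return {
        "success_rate": success_rate(batch.actions, batch.pos, batch.pos_next,
                                     batch.target, delta),
        "correlation": corr,
        "pairwise_success": succ,
        "event_synchronization": es,
        "zeta": zeta,
        "es_by_distance": synchronization_by_distance(es, batch.mu),
        "correct_response": np.array([
            correct_response_rate(batch.actions, batch.pos, batch.target,
                                  batch.mu[i], i, 10.0)
            for i in range(batch.n_players)
        ]),
    }


def session_metrics(session: SessionData, delta: float = 0.0) -> dict:
    """Pooled cooperation report for a session.

    Success and correct-response rates pool counts over all batches. The
    correlation, pairwise-success and synchronization matrices are averaged
    across batches with the players re-ordered by direction rank (direction
    assignments are batch-local; averaging in neighborhood order preserves
    the systematic structure), and zeta is the covariance of the averaged
    matrices over the 28 pairs. The per-batch-then-averaged zeta -- which
    additionally picks up the positively correlated within-batch sampling
    noise of the two matrices -- is reported as ``zeta_per_batch``.
    """
    step_len = session.config.step_length
    n = session.config.n_players
    succ_num = succ_den = 0
    resp_num = np.zeros(n)
    resp_den = np.zeros(n)
    zetas_pb = []
    corr_stack, succ_stack = [], []
    es_profiles: dict[float, list] = {}
    for b in session.batches:
        active = b.actions.any(axis=1)
        drop = _distance_drop(b.pos, b.pos_next, b.target)
        succ_num += int(((drop > delta) & active).sum())
        succ_den += int(active.sum())
        solo = np.stack([b.pos + step_len * np.array([math.cos(m), math.sin(m)])
                         for m in b.mu], axis=1)  # (N, n, 2)
        d0 = np.hypot(*(b.target - b.pos).T)
        d1 = np.hypot(*np.moveaxis(b.target[:, None, :] - solo, -1, 0))
        correct = (d0[:, None] > d1) & (b.actions == 1)
        resp_num += correct.sum(axis=0)
        resp_den += b.actions.sum(axis=0)
        m = batch_metrics(b, delta)
        if np.isfinite(m["zeta"]):
            zetas_pb.append(m["zeta"])
        order = np.argsort(b.mu)
        corr_stack.append(m["correlation"][np.ix_(order, order)])
        succ_stack.append(m["pairwise_success"][np.ix_(order, order)])
        for k, v in m["es_by_distance"].items():
            es_profiles.setdefault(k, []).append(v)
    group_rate = succ_num / succ_den if succ_den else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        resp = np.where(resp_den > 0, resp_num / resp_den, np.nan)
    mean_resp = float(np.nanmean(resp))
    with np.errstate(invalid="ignore"):
        corr_avg = np.nanmean(corr_stack, axis=0)
        succ_avg = np.nanmean(succ_stack, axis=0)
    iu = np.triu_indices(n, k=1)
    if np.all(np.isfinite(corr_avg[iu])) and np.all(np.isfinite(succ_avg[iu])):
        zeta = cooperation_measure(corr_avg, succ_avg)
    else:
        zeta = float("nan")
    return {
        "model": session.model,
        "seed": session.seed,
        "delta": delta,
        "group_success_rate": float(group_rate),
        "correct_response_rates": resp,
        "mean_correct_response_rate": mean_resp,
        "synergy_gap": float(group_rate - mean_resp),
        "zeta": zeta,
        "zeta_per_batch": float(np.mean(zetas_pb)) if zetas_pb else float("nan"),
        "zeta_batches_defined": len(zetas_pb),
        "correlation_avg": corr_avg,
        "pairwise_success_avg": succ_avg,
        "es_by_distance": {k: float(np.mean(v)) for k, v in sorted(es_profiles.items())},
        "n_decision_points": succ_den,
    }


def delta_sweep(session: SessionData, deltas, normalize_by: str = "width") -> "object":
    """Success rate as a function of the improvement threshold delta.

    ``deltas`` are dimensionless fractions of display size; ``normalize_by``
    chooses the size convention ("width" or "diagonal").
    """
    import pandas as pd

    cfg = session.config
    if normalize_by == "width":
        scale = cfg.screen_width
    elif normalize_by == "diagonal":
        scale = math.hypot(cfg.screen_width, cfg.screen_height)
    else:
        raise ValueError("normalize_by must be 'width' or 'diagonal'")
    rows = []
    for frac in deltas:
        delta_px = frac * scale
        num = den = 0
        for b in session.batches:
            active = b.actions.any(axis=1)
            drop = _distance_drop(b.pos, b.pos_next, b.target)
            num += int(((drop > delta_px) & active).sum())
            den += int(active.sum())
        rows.append({"delta_fraction": frac, "delta_px": delta_px,
                     "success_rate": num / den if den else float("nan")})
    return pd.DataFrame(rows)
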