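"""Learning-progress analyses: spike-triggered statistics, learning
duration, population-vector decoding error and learning-curve fits.

The stimulus of a spike is the noiseless target-difference angle visible on
the screen at that time point (the agents' private noisy observations are
not an analysis-side quantity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._circular import TWO_PI, circ_dist
from .engine import BatchRecord, SessionData


# ---------------------------------------------------------------------------
# spike-triggered average and variance
# ---------------------------------------------------------------------------


def _spike_sums(actions_i, stimuli, t):
    a = np.asarray(actions_i)[: t + 1].astype(bool)
    ang = np.asarray(stimuli)[: t + 1][a]
    if ang.size == 0:
        return None
    return np.sin(ang).mean(), np.cos(ang).mean(), ang.size


def spike_triggered_average(actions_i, stimuli, t) -> float:
    """Circular mean of the stimulus angles at player i's spikes up to time t.

    NaN (undefined) with no spikes or a vanishing resultant.
    """
    s = _spike_sums(actions_i, stimuli, t)
    if s is None:
        return float("nan")
    sy, cx, _ = s
    if math.hypot(sy, cx) < 1e-12:
        return float("nan")
    return math.atan2(sy, cx) % TWO_PI


def spike_triggered_variance(actions_i, stimuli, t) -> float:
    """1 - resultant length of the spike-conditioned angles: the circular
    variance of the unit's effective receptive field, in [0, 1]."""
    s = _spike_sums(actions_i, stimuli, t)
    if s is None:
        return float("nan")
    sy, cx, _ = s
    return 1.0 - math.hypot(sy, cx)


@dataclass
class STASeries:
    """Running STA/STV of one unit over its spike ordinals (1-based)."""

    angles: np.ndarray  # STA after spike k (NaN where resultant vanishes)
    variances: np.ndarray  # STV after spike k

    @property
    def n_spikes(self) -> int:
        return len(self.angles)


def sta_series(spike_angles) -> STASeries:
    """Running spike-triggered statistics over the ordinal spike number."""
    ang = np.asarray(spike_angles, dtype=float)
    k = np.arange(1, ang.size + 1)
    s = np.cumsum(np.sin(ang)) / k
    c = np.cumsum(np.cos(ang)) / k
    r = np.hypot(s, c)
    with np.errstate(invalid="ignore"):
        sta = np.where(r >= 1e-12, np.mod(np.arctan2(s, c), TWO_PI), np.nan)
    return STASeries(angles=sta, variances=1.0 - r)


def learning_duration(series: STASeries, mu_i: float) -> int | None:
    """Smallest spike ordinal T* from which the running STA stays within
    pi/2 of the true direction for every later spike; None if censored
    (never permanently inside the neighborhood within the batch)."""
    if series.n_spikes == 0:
        return None
    with np.errstate(invalid="ignore"):
        ok = circ_dist(series.angles, mu_i) <= math.pi / 2
    ok &= np.isfinite(series.angles)
    if not ok[-1]:
        return None
    # scan from the right: first index after the last violation
    bad = np.flatnonzero(~ok)
    return int(bad[-1]) + 2 if bad.size else 1  # 1-based ordinals


# ---------------------------------------------------------------------------
# population-vector decoding
# ---------------------------------------------------------------------------


def population_decode(v_t, sta_angles) -> np.ndarray:
    """Population vector sum_i <v, e_i> e_i with unit axes e_i at the STAs."""
    sta = np.asarray(sta_angles, dtype=float)
    if np.any(~np.isfinite(sta)):
        raise ValueError("all STA angles must be defined for decoding")
    e = np.stack([np.cos(sta), np.sin(sta)], axis=1)
    return e.T @ (e @ np.asarray(v_t, dtype=float))


def decoding_error(pos, target, sta_angles) -> float:
    """Mean circular distance between the decoded population-vector angle
    and the true target-difference angle over the given time points.

    A zero-length population vector contributes pi/2 (chance level for the
    angular half-error).
    """
    sta = np.asarray(sta_angles, dtype=float)
    e = np.stack([np.cos(sta), np.sin(sta)], axis=1)  # (n, 2)
    v = np.asarray(target) - np.asarray(pos)  # (N, 2)
    vpop = (v @ e.T) @ e  # (N, 2)
    ang_v = np.arctan2(v[:, 1], v[:, 0])
    ang_p = np.arctan2(vpop[:, 1], vpop[:, 0])
    err = circ_dist(ang_p, ang_v)
    degenerate = np.hypot(vpop[:, 0], vpop[:, 1]) < 1e-12
    err = np.where(degenerate, math.pi / 2, err)
    return float(err.mean())


# ---------------------------------------------------------------------------
# learning-curve fit
# ---------------------------------------------------------------------------


@dataclass
class LearningCurveFit:
    rate: float
    n_used: int
    n_censored: int
    at_boundary: bool


def fit_learning_curve(durations, censored=None) -> LearningCurveFit:
    """Least-squares fit of the cumulative exponential F(k) = 1 - exp(-r k)
    to the empirical fraction of unit-batches with learning duration <= k.

    Censored durations are excluded from the fit (but counted). Degenerate
    all-equal data put the rate at the optimizer boundary, flagged.
    """
    durations = np.asarray(durations, dtype=float)
    if censored is None:
        censored = np.zeros(durations.shape, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    d = durations[~censored]
    if d.size < 5:
        raise ValueError("need at least 5 uncensored durations")
    ks = np.arange(1, int(d.max()) + 1, dtype=float)
    emp = (d[None, :] <= ks[:, None]).mean(axis=1)
    upper = 50.0
    (rate,), _ = curve_fit(lambda k, r: 1.0 - np.exp(-r * k), ks, emp,
                           p0=[1.0 / max(d.mean(), 1.0)], bounds=(1e-8, upper))
    degenerate = bool(d.min() == d.max())
    return LearningCurveFit(rate=float(rate), n_used=int(d.size),
                            n_censored=int(censored.sum()),
                            at_boundary=degenerate or bool(
                                rate > 0.98 * upper or rate < 2e-8))


# ---------------------------------------------------------------------------
# session-level report
# ---------------------------------------------------------------------------


def batch_learning(batch: BatchRecord) -> dict:
    """Per-unit learning statistics of one batch: running STA/STV series,
    learning durations, and the whole-batch decoding error."""
    n = batch.n_players
    series, durations, cens, whole_sta = [], [], [], []
    for i in range(n):
        spikes = batch.actions[:, i] == 1
        s = sta_series(batch.psi[spikes])
        series.append(s)
        t_star = learning_duration(s, batch.mu[i])
        durations.append(t_star if t_star is not None else s.n_spikes)
        cens.append(t_star is None)
        whole_sta.append(s.angles[-1] if s.n_spikes else float("nan"))
    whole_sta = np.asarray(whole_sta)
    if np.all(np.isfinite(whole_sta)):
        err = decoding_error(batch.pos, batch.target, whole_sta)
    else:
        err = float("nan")
    return {
        "sta_series": series,
        "durations": np.asarray(durations, dtype=float),
        "censored": np.asarray(cens, dtype=bool),
        "whole_batch_sta": whole_sta,
        "decoding_error": err,
    }


def session_learning(session: SessionData, duration_threshold: int = 50) -> dict:
    """Learning report for a session.

    * fraction of unit-batches with a defined learning duration (censored
      unit-batches never enter the cumulative duration curve, which is
      fitted by a distribution with asymptote 1) that learned within
      ``duration_threshold`` spikes; the censored fraction is reported
      separately;
    * cumulative-exponential rate fitted to the uncensored durations;
    * decoding error via the whole-batch STA, averaged over batches where all
      units spiked;
    * batch-averaged STV at matched spike ordinals.
    """
    durations, censored, errors = [], [], []
    stv_acc: dict[int, list] = {}
    for b in session.batches:
        r = batch_learning(b)
        has_spikes = r["durations"] > 0
        durations.extend(r["durations"][has_spikes])
        censored.extend(r["censored"][has_spikes])
        if np.isfinite(r["decoding_error"]):
            errors.append(r["decoding_error"])
        for s in r["sta_series"]:
            for k in range(s.n_spikes):
                stv_acc.setdefault(k + 1, []).append(s.variances[k])
    durations = np.asarray(durations)
    censored = np.asarray(censored, dtype=bool)
    learned = durations[~censored]
    frac = float((learned <= duration_threshold).mean()) if learned.size else float("nan")
    try:
        fit = fit_learning_curve(durations, censored)
    except ValueError:
        fit = None
    return {
        "model": session.model,
        "seed": session.seed,
        "fraction_learned_within": frac,
        "fraction_censored": float(censored.mean()) if durations.size else float("nan"),
        "duration_threshold": duration_threshold,
        "learning_rate_fit": fit,
        "decoding_error": float(np.mean(errors)) if errors else float("nan"),
        "decoding_batches_used": len(errors),
        "stv_by_ordinal": {k: float(np.mean(v)) for k, v in sorted(stv_acc.items())},
        "n_unit_batches": int(durations.size),
    }
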