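"""Game environment: trial geometry, direction assignment, the step rule,
batch/session orchestration, event logging and time discretization.

Coordinate convention: mathematical axes (x right, y up, origin bottom left);
angles via atan2 in [0, 2*pi).

A *trial* steers the cursor from a random start to a random target 840 px
away; a *batch* is ten consecutive trials sharing one hidden assignment of
eight equiangular movement directions; units learn within a batch and are
reset between batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._circular import TWO_PI
from .agent_core import subsystem_rng
from .config import GameConfig

#: simulated pause between trials (countdown in the original task), ms
TRIAL_PAUSE_MS = 3000.0


# ---------------------------------------------------------------------------
# geometry and directions
# ---------------------------------------------------------------------------


def sample_trial_geometry(rng, config: GameConfig, max_attempts: int = 10_000):
    """Rejection-sample a (start, target) pair.

    Start position and direction are uniform; the target lies exactly
    ``target_distance`` away. Both points must avoid the 10% brim of the
    screen, otherwise the pair is rejected and redrawn.
    """
    w, h, b = config.screen_width, config.screen_height, config.brim_fraction
    lo = np.array([b * w, b * h])
    hi = np.array([(1 - b) * w, (1 - b) * h])
    for _ in range(max_attempts):
        start = rng.uniform(lo, hi)
        theta = rng.uniform(0.0, TWO_PI)
        target = start + config.target_distance * np.array(
            [math.cos(theta), math.sin(theta)]
        )
        if np.all(target >= lo) and np.all(target <= hi):
            return start, target
    raise RuntimeError(
        "could not place trial geometry inside the brim; "
        "target_distance is too large for this screen"
    )


def assign_directions(rng, n_players: int = 8) -> np.ndarray:
    """Random rotated wind rose: one uniform rotation in [0, 2*pi/n), the n
    equiangular directions randomly permuted over players."""
    omega = rng.uniform(0.0, TWO_PI / n_players)
    mu = (omega + np.arange(n_players) * TWO_PI / n_players) % TWO_PI
    return mu[rng.permutation(n_players)]


@dataclass
class GameState:
    cursor: np.ndarray
    target: np.ndarray
    trial_index: int = 0
    batch_index: int = 0
    step_index: int = 0


def step(state: GameState, actions, mu: np.ndarray, config: GameConfig) -> GameState:
    """Advance the cursor by the vector sum of the active players' unit steps."""
    a = np.asarray(actions)
    disp = config.step_length * np.array(
        [np.dot(a, np.cos(mu)), np.dot(a, np.sin(mu))]
    )
    return GameState(
        cursor=state.cursor + disp,
        target=state.target,
        trial_index=state.trial_index,
        batch_index=state.batch_index,
        step_index=state.step_index + 1,
    )


# ---------------------------------------------------------------------------
# recorded data
# ---------------------------------------------------------------------------


@dataclass
class BatchRecord:
    """Discrete-time record of one batch.

    Rows are discrete time points, concatenated over the batch's trials.
    ``pos`` is the cursor before the step, ``pos_next`` after it; ``target``
    and ``trial_index`` are per-row; ``psi`` is the noiseless target-difference
    angle seen on the screen (the analysis-side stimulus).
    """

    mu: np.ndarray
    actions: np.ndarray  # (N, n_players) uint8
    pos: np.ndarray  # (N, 2)
    pos_next: np.ndarray  # (N, 2)
    target: np.ndarray  # (N, 2)
    psi: np.ndarray  # (N,)
    trial_index: np.ndarray  # (N,)
    trial_reached: list = field(default_factory=list)  # per trial: reached target?

    @property
    def n_steps(self) -> int:
        return self.actions.shape[0]

    @property
    def n_players(self) -> int:
        return self.actions.shape[1]


@dataclass
class SessionData:
    """All batches of one simulated session plus provenance."""

    config: GameConfig
    model: str
    seed: int
    batches: list

    @property
    def n_steps(self) -> int:
        return sum(b.n_steps for b in self.batches)


# ---------------------------------------------------------------------------
# simulation loop
# ---------------------------------------------------------------------------


def run_trial(agents, mu, start, target, config: GameConfig, out: dict) -> bool:
    """Play one trial, appending rows to the ``out`` buffers.

    Returns True if the target was reached within the step cap.
    """
    n = len(agents)
    cmu = np.cos(mu) * config.step_length
    smu = np.sin(mu) * config.step_length
    sx, sy = float(start[0]), float(start[1])
    tx, ty = float(target[0]), float(target[1])
    radius = config.target_radius
    rows_a, rows_p, rows_pn, rows_psi = out["a"], out["p"], out["pn"], out["psi"]
    reached = False
    for _ in range(config.max_steps_per_trial):
        psi = math.atan2(ty - sy, tx - sx) % TWO_PI
        a = [ag.act(psi) for ag in agents]
        dx = dy = 0.0
        for i in range(n):
            if a[i]:
                dx += cmu[i]
                dy += smu[i]
        nx, ny = sx + dx, sy + dy
        d0 = math.hypot(tx - sx, ty - sy)
        d1 = math.hypot(tx - nx, ty - ny)
        r = 1 if d0 > d1 else (-1 if d0 < d1 else 0)
        disp = (dx, dy)
        for ag in agents:
            ag.observe_outcome(disp, r)
        rows_a.append(a)
        rows_p.append((sx, sy))
        rows_pn.append((nx, ny))
        rows_psi.append(psi)
        sx, sy = nx, ny
        if d1 <= radius:
            reached = True
            break
    for ag in agents:
        ag.end_trial()
    out["end_pos"] = (sx, sy)
    return reached


def run_batch(agents, config: GameConfig, rng) -> BatchRecord:
    """Play ``trials_per_batch`` trials under one fresh direction assignment.

    Units are reset at the start of the batch and keep their learning state
    across the batch's trials.
    """
    mu = assign_directions(rng, config.n_players)
    for ag in agents:
        ag.reset()
    out = {"a": [], "p": [], "pn": [], "psi": []}
    tgt_rows = []
    trial_rows = []
    reached_flags = []
    for k in range(config.trials_per_batch):
        start, target = sample_trial_geometry(rng, config)
        n_before = len(out["a"])
        reached = run_trial(agents, mu, start, target, config, out)
        reached_flags.append(reached)
        n_new = len(out["a"]) - n_before
        tgt_rows.extend([tuple(target)] * n_new)
        trial_rows.extend([k] * n_new)
    return BatchRecord(
        mu=mu,
        actions=np.array(out["a"], dtype=np.uint8),
        pos=np.array(out["p"]),
        pos_next=np.array(out["pn"]),
        target=np.array(tgt_rows),
        psi=np.array(out["psi"]),
        trial_index=np.array(trial_rows, dtype=np.int64),
        trial_reached=reached_flags,
    )


def run_session(agents, config: GameConfig, seed: int | None = None,
                model: str = "custom", n_batches: int | None = None) -> SessionData:
    """Play a full session (default 40 batches of 10 trials)."""
    seed = config.seed if seed is None else seed
    rng = subsystem_rng(seed, 0)
    n_batches = config.n_batches if n_batches is None else n_batches
    batches = [run_batch(agents, config, rng) for _ in range(n_batches)]
    return SessionData(config=config, model=model, seed=seed, batches=batches)


def simulate(model: str, config: GameConfig | None = None, seed: int | None = None,
             hyper=None, n_batches: int | None = None, **model_kwargs) -> SessionData:
    """Convenience front end: build agents for ``model`` and run a session.

    With ``hyper=None`` the shipped calibration profile supplies both the
    pipeline hyperparameters and the model-specific ones (explicit keyword
    arguments still win).
    """
    from .agent_models import make_agents

    config = config or GameConfig()
    seed = config.seed if seed is None else seed
    if hyper is None:
        from .calibration import hyperparams_for

        hyper, cal_kwargs = hyperparams_for(model)
        model_kwargs = {**cal_kwargs, **model_kwargs}
    agents = make_agents(model, hyper, seed, config.n_players, **model_kwargs)
    session = run_session(agents, config, seed=seed, model=model, n_batches=n_batches)
    return session


# ---------------------------------------------------------------------------
# event logs and time discretization
# ---------------------------------------------------------------------------


@dataclass
class EventLog:
    """Millisecond-stamped recording in the format of the original task:
    per-player press times, cursor trajectory samples, per-batch direction
    assignments and trial boundaries."""

    presses: list = field(default_factory=list)  # (player, t_ms)
    trajectory: list = field(default_factory=list)  # (t_ms, x, y)
    batch_marks: list = field(default_factory=list)  # (t_ms, [mu...])
    trial_marks: list = field(default_factory=list)  # (t_ms, start, target)

    def validate(self) -> None:
        for seq, pos in ((self.presses, 1), (self.trajectory, 0)):
            ts = [rec[pos] for rec in seq]
            if any(b < a for a, b in zip(ts, ts[1:])):
                raise ValueError("timestamps must be nondecreasing")


def session_to_event_log(session: SessionData) -> EventLog:
    """Render a simulated session in the human recording format.

    Steps are stamped ``k * dt_ms`` within each trial (dt defaults to 130 ms,
    the typical discretization interval of the original recordings) with a
    3 s pause between trials, so discretizing the log recovers the
    simulator's internal matrices exactly.
    """
    dt = session.config.dt_ms
    log = EventLog()
    t = 0.0
    for batch in session.batches:
        log.batch_marks.append((t, [float(m) for m in batch.mu]))
        for k in range(int(batch.trial_index.max()) + 1 if batch.n_steps else 0):
            rows = np.flatnonzero(batch.trial_index == k)
            if rows.size == 0:
                continue
            start = batch.pos[rows[0]]
            target = batch.target[rows[0]]
            log.trial_marks.append((t, (float(start[0]), float(start[1])),
                                    (float(target[0]), float(target[1]))))
            for step_i, row in enumerate(rows):
                tt = t + step_i * dt
                log.trajectory.append((tt, float(batch.pos[row, 0]), float(batch.pos[row, 1])))
                for p in np.flatnonzero(batch.actions[row]):
                    log.presses.append((int(p), tt))
            t_end = t + rows.size * dt
            log.trajectory.append((t_end, float(batch.pos_next[rows[-1], 0]),
                                   float(batch.pos_next[rows[-1], 1])))
            t = t_end + TRIAL_PAUSE_MS
    log.presses.sort(key=lambda r: r[1])
    return log


def discretization_bin_width(log: EventLog) -> float:
    """Bin width: the minimum over players of their minimum inter-press
    interval -- the largest width guaranteeing that no player ever appears
    twice within one bin."""
    if not log.presses:
        raise ValueError("empty event log")
    by_player: dict[int, list[float]] = {}
    for p, t in log.presses:
        by_player.setdefault(p, []).append(t)
    isis = [
        min(b - a for a, b in zip(ts, ts[1:]))
        for ts in by_player.values()
        if len(ts) >= 2
    ]
    if not isis:
        raise ValueError("need at least one player with two or more presses")
    width = min(isis)
    if width <= 0:
        raise ValueError("a player pressed twice at the same instant")
    return width


def discretize_time(log: EventLog, n_players: int | None = None):
    """Bin a continuous log into an action matrix and resampled trajectory.

    Bins of the adaptive width start at the first trajectory sample; events
    in the same bin count as simultaneous. The trajectory is forward-filled
    at bin starts. Returns ``(A, S, bin_width_ms)``.
    """
    width = discretization_bin_width(log)
    if not log.trajectory:
        raise ValueError("log has no trajectory samples")
    t0 = min(log.trajectory[0][0], log.presses[0][1])
    t_last = max(log.trajectory[-1][0], log.presses[-1][1])
    n_bins = int(math.floor((t_last - t0) / width)) + 1
    if n_players is None:
        n_players = max(p for p, _ in log.presses) + 1
    a = np.zeros((n_bins, n_players), dtype=np.uint8)
    for p, t in log.presses:
        b = int(math.floor((t - t0) / width + 1e-9))
        if a[b, p]:
            raise AssertionError(
                "double press within one bin: contradicts the bin-width rule"
            )
        a[b, p] = 1
    traj = np.asarray(log.trajectory, dtype=float)
    edges = t0 + width * np.arange(n_bins)
    idx = np.searchsorted(traj[:, 0], edges + 1e-9) - 1
    idx = np.clip(idx, 0, len(traj) - 1)
    s = traj[idx, 1:3]
    return a, s, width


def records_from_log(log: EventLog) -> list[BatchRecord]:
    """Reconstruct per-batch discrete records from a human-format log.

    Each trial is binned on its own grid (anchored at its start) with the
    global adaptive bin width; inter-trial pauses never produce rows.
    """
    width = discretization_bin_width(log)
    traj = np.asarray(sorted(log.trajectory), dtype=float)
    press_t = np.asarray([t for _, t in log.presses])
    press_p = np.asarray([p for p, _ in log.presses], dtype=int)
    n_players = len(log.batch_marks[0][1]) if log.batch_marks else int(press_p.max()) + 1

    batch_times = [t for t, _ in log.batch_marks] + [math.inf]
    trial_times = [t for t, _, _ in log.trial_marks] + [math.inf]
    records = []
    for bi, (bt, mu) in enumerate(log.batch_marks):
        b_end = batch_times[bi + 1]
        rows_a, rows_p, rows_pn, rows_tgt, rows_psi, rows_trial = [], [], [], [], [], []
        t_idx = -1
        for ti, (tt, start, target) in enumerate(log.trial_marks):
            if not (bt <= tt < b_end):
                continue
            t_idx += 1
            span_end = min(trial_times[ti + 1], b_end)
            in_trial = (traj[:, 0] >= tt - 1e-9) & (traj[:, 0] < span_end)
            tr = traj[in_trial]
            if len(tr) < 2:
                continue
            t_fin = tr[-1, 0]
            n_bins = max(int(round((t_fin - tt) / width)), 1)
            edges = tt + width * np.arange(n_bins + 1)
            fill = np.clip(np.searchsorted(tr[:, 0], edges + 1e-9) - 1, 0, len(tr) - 1)
            pos = tr[fill, 1:3]
            a = np.zeros((n_bins, n_players), dtype=np.uint8)
            sel = (press_t >= tt - 1e-9) & (press_t < edges[-1] - 1e-9)
            for p, t in zip(press_p[sel], press_t[sel]):
                a[int(math.floor((t - tt) / width + 1e-9)), p] = 1
            d = np.asarray(target) - pos[:-1]
            rows_a.append(a)
            rows_p.append(pos[:-1])
            rows_pn.append(pos[1:])
            rows_tgt.append(np.tile(target, (n_bins, 1)))
            rows_psi.append(np.mod(np.arctan2(d[:, 1], d[:, 0]), TWO_PI))
            rows_trial.append(np.full(n_bins, t_idx, dtype=np.int64))
        if not rows_a:
            continue
        records.append(
            BatchRecord(
                mu=np.asarray(mu, dtype=float),
                actions=np.concatenate(rows_a),
                pos=np.concatenate(rows_p),
                pos_next=np.concatenate(rows_pn),
                target=np.concatenate(rows_tgt),
                psi=np.concatenate(rows_psi),
                trial_index=np.concatenate(rows_trial),
            )
        )
    return records
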