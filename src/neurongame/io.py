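"""File formats and run orchestration.

Event logs are JSON-Lines (one record per event) in the schema of the
original recordings: millisecond press times per player, cursor trajectory
samples, per-batch direction assignments and trial boundaries. Discrete
matrices go to CSV; run manifests to JSON. A fixture generator produces
synthetic human-format logs (tuned point-process players) to exercise every
analysis path without any deposited human data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._circular import TWO_PI
from .config import GameConfig, save_config
from .engine import (
    EventLog,
    SessionData,
    TRIAL_PAUSE_MS,
    assign_directions,
    sample_trial_geometry,
    session_to_event_log,
)

PACKAGE_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# event logs on disk (JSONL)
# ---------------------------------------------------------------------------


def write_event_log(log: EventLog, path) -> None:
    """Write a time-ordered JSONL stream of press/pos/batch/trial records."""
    events = (
        [("press", t, {"player": p, "t_ms": t}) for p, t in log.presses]
        + [("pos", t, {"t_ms": t, "x": x, "y": y}) for t, x, y in log.trajectory]
        + [("batch", t, {"t_ms": t, "mu": list(mu)}) for t, mu in log.batch_marks]
        + [("trial", t, {"t_ms": t, "start": list(s), "target": list(tg)})
           for t, s, tg in log.trial_marks]
    )
    order = {"batch": 0, "trial": 1, "pos": 2, "press": 3}
    events.sort(key=lambda e: (e[1], order[e[0]]))
    with open(path, "w") as fh:
        for kind, _, rec in events:
            fh.write(json.dumps({"kind": kind, **rec}) + "\n")


def read_event_log(path) -> EventLog:
    log = EventLog()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            kind = rec["kind"]
            if kind == "press":
                log.presses.append((int(rec["player"]), float(rec["t_ms"])))
            elif kind == "pos":
                log.trajectory.append((float(rec["t_ms"]), float(rec["x"]), float(rec["y"])))
            elif kind == "batch":
                log.batch_marks.append((float(rec["t_ms"]), [float(v) for v in rec["mu"]]))
            elif kind == "trial":
                log.trial_marks.append((float(rec["t_ms"]), tuple(rec["start"]),
                                        tuple(rec["target"])))
            else:
                raise ValueError(f"unknown event kind {kind!r}")
    log.presses.sort(key=lambda r: r[1])
    log.trajectory.sort(key=lambda r: r[0])
    return log


# ---------------------------------------------------------------------------
# discrete matrices on disk (CSV)
# ---------------------------------------------------------------------------


def batch_to_frame(batch) -> pd.DataFrame:
    """One row per discrete time point: t, a1..aP, x, y, tx, ty."""
    n = batch.n_players
    cols = {"t": np.arange(batch.n_steps)}
    for i in range(n):
        cols[f"a{i + 1}"] = batch.actions[:, i]
    cols.update(x=batch.pos[:, 0], y=batch.pos[:, 1],
                tx=batch.target[:, 0], ty=batch.target[:, 1])
    return pd.DataFrame(cols)


def write_run(session: SessionData, out_dir, write_log: bool = True) -> dict:
    """Persist a session: per-batch CSV, event log JSONL, config and manifest.

    Returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, batch in enumerate(session.batches):
        p = out / f"batch_{k:03d}.csv"
        batch_to_frame(batch).to_csv(p, index=False)
        paths.append(p.name)
    if write_log:
        write_event_log(session_to_event_log(session), out / "events.jsonl")
    save_config(session.config, out / "config.yaml")
    manifest = {
        "package_version": PACKAGE_VERSION,
        "model": session.model,
        "seed": session.seed,
        "config": session.config.to_dict(),
        "batch_files": paths,
        "event_log": "events.jsonl" if write_log else None,
        "mu_per_batch": [list(map(float, b.mu)) for b in session.batches],
        "trials_reached": [list(map(bool, b.trial_reached)) for b in session.batches],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_run(run_dir) -> list:
    """Reconstruct per-batch records from a run directory's event log."""
    from .engine import records_from_log

    run = Path(run_dir)
    return records_from_log(read_event_log(run / "events.jsonl"))


# ---------------------------------------------------------------------------
# synthetic human-format fixtures
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Synthetic stand-in for a human recording (no human data exist).

    Each player is a direction-tuned point process: its press rate peaks when
    the current target-difference angle is near the player's direction, with
    von Mises-shaped tuning of the given width (``None`` = untuned, constant
    rate -- the null model for the cooperation measure) on top of a constant
    floor rate. Each press displaces the cursor by one 10 px step at its own
    timestamp (tick start plus a uniform jitter in [0, jitter)), and the
    trajectory is sampled at every tick and after every press, so the
    adaptive binning of the analysis attributes each displacement to the
    bin of the press that caused it.
    """

    tuning_width: float | None = 1.0  # rad
    base_rate: float = 2.0  # spikes / s at the tuning peak
    floor_rate: float = 0.3  # spikes / s far from the preferred direction
    timing_jitter_ms: float = 20.0
    n_trials: int = 10
    n_batches: int = 1
    mu: np.ndarray | None = None
    tick_ms: float = 130.0
    config: GameConfig | None = None

    def __post_init__(self):
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not (0 <= self.floor_rate <= self.base_rate):
            raise ValueError("floor_rate must lie in [0, base_rate]")
        if self.tuning_width is not None and not (0 < self.tuning_width <= math.pi):
            raise ValueError("tuning_width must lie in (0, pi]")
        if not (0 <= self.timing_jitter_ms < self.tick_ms / 2):
            raise ValueError("jitter must stay below half a tick")


def generate_fixture(spec: FixtureSpec, rng) -> EventLog:
    """Simulate tuned point-process players and emit a human-format log."""
    cfg = spec.config or GameConfig()
    n = cfg.n_players
    dt_s = spec.tick_ms / 1000.0
    kappa = 0.0 if spec.tuning_width is None else 2.0 / spec.tuning_width**2
    log = EventLog()
    t = 0.0
    for _ in range(spec.n_batches):
        mu = np.asarray(spec.mu, dtype=float) if spec.mu is not None \
            else assign_directions(rng, n)
        log.batch_marks.append((t, [float(m) for m in mu]))
        for _ in range(spec.n_trials):
            start, target = sample_trial_geometry(rng, cfg)
            log.trial_marks.append((t, (float(start[0]), float(start[1])),
                                    (float(target[0]), float(target[1]))))
            s = start.astype(float).copy()
            presses_buf = []
            k = 0
            for k in range(cfg.max_steps_per_trial):
                tk = t + k * spec.tick_ms
                log.trajectory.append((tk, float(s[0]), float(s[1])))
                psi = math.atan2(target[1] - s[1], target[0] - s[0]) % TWO_PI
                rate = spec.floor_rate + (spec.base_rate - spec.floor_rate) * np.exp(
                    kappa * (np.cos(psi - mu) - 1.0)
                )
                p = np.minimum(rate * dt_s, 1.0)
                act = np.flatnonzero(rng.random(n) < p)
                jit = np.sort(rng.uniform(0.0, spec.timing_jitter_ms, act.size)) \
                    if spec.timing_jitter_ms > 0 else np.zeros(act.size)
                for i, tj in zip(act, tk + jit):
                    presses_buf.append((int(i), float(tj)))
                    s += cfg.step_length * np.array([math.cos(mu[i]), math.sin(mu[i])])
                    log.trajectory.append((float(tj) + 1e-6, float(s[0]), float(s[1])))
                if math.hypot(*(target - s)) <= cfg.target_radius:
                    break
            t_end = t + (k + 1) * spec.tick_ms
            log.trajectory.append((t_end, float(s[0]), float(s[1])))
            log.presses.extend(presses_buf)
            t = t_end + TRIAL_PAUSE_MS
    log.presses.sort(key=lambda r: r[1])
    return log
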