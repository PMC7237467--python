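"""Shared decision pipeline for all simulated units.

Every unit, regardless of its learning model, runs the same loop at each
discrete time point:

1. the target-difference angle ``psi`` on the screen is observed through
   Gaussian angular noise with variance ``beta3``, giving ``phi``;
2. ``phi`` is encoded as a binary tile-coding feature vector built from
   ``m`` shifted tilings of ``n`` tiles each (exactly one active tile per
   tiling, so ``m`` ones out of ``n*m`` entries);
3. the model-specific activation level ``g`` is squashed through the soft
   activation ``sigma(x) = atan(gain*x)/pi + 1/2``;
4. the unit presses with probability ``(1-q) * (eps/2 + (1-eps)*sigma(g))``
   where ``q`` forces idleness (a refractory surrogate matching the human
   coincidence statistics) and ``eps = max(beta2, epsilon_base**c)`` is an
   exploration rate decaying with the unit's spike count ``c``;
5. learning updates are applied only with probability ``beta1``
   (inattention / forgetting).

Units see only the shared screen: the noisy angle and the realized group
displacement. No unit ever receives another unit's action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._circular import TWO_PI, wrap_angle


@dataclass
class AgentHyperParams:
    """Hyperparameters shared by every decision-unit model.

    beta1   -- probability that a learning update is actually applied
    beta2   -- lower bound on the exploration rate
    beta3   -- variance (rad^2) of the Gaussian observation noise on the angle
    gain    -- slope of the arctan soft activation
    q       -- per-step probability of being forced idle (refractory surrogate)
    epsilon_base -- per-spike decay base of the exploration rate
    n_tiles, n_tilings -- tile-coding resolution (feature length = n*m)
    """

    beta1: float = 0.9
    beta2: float = 0.05
    beta3: float = 0.01
    gain: float = 5.0
    q: float = 0.1939
    epsilon_base: float = 0.85
    n_tiles: int = 8
    n_tilings: int = 45

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "q", "epsilon_base"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.q >= 1.0:
            raise ValueError("q must be < 1")
        if self.beta3 < 0 or self.gain <= 0:
            raise ValueError("beta3 must be >= 0 and gain > 0")

    @property
    def n_features(self) -> int:
        return self.n_tiles * self.n_tilings


class Stimulus(NamedTuple):
    """True and noise-contaminated target-difference angle, both in [0, 2*pi)."""

    psi: float
    phi: float


def observe(target, cursor, params: AgentHyperParams, rng) -> Stimulus:
    """Noisy observation of the target-difference angle.

    ``psi = atan2(ty - sy, tx - sx) mod 2pi`` and ``phi = (psi + eta) mod 2pi``
    with ``eta ~ Normal(0, beta3)``. Raises when target and cursor coincide
    (the angle is undefined there).
    """
    dx = float(target[0]) - float(cursor[0])
    dy = float(target[1]) - float(cursor[1])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("target equals cursor: target-difference angle undefined")
    psi = math.atan2(dy, dx) % TWO_PI
    eta = rng.normal(0.0, math.sqrt(params.beta3)) if params.beta3 > 0 else 0.0
    return Stimulus(psi=psi, phi=(psi + eta) % TWO_PI)


_TILE_TABLES: dict = {}


def _tile_table(n: int, m: int) -> np.ndarray:
    """(n*m, m) table: active feature indices for every intersection cell.

    The m tilings jointly partition the circle into n*m cells of width
    2*pi/(n*m); the encoding is constant on each cell, so it is precomputed
    once per (n, m).
    """
    key = (n, m)
    tab = _TILE_TABLES.get(key)
    if tab is None:
        j = np.arange(1, m + 1)
        xs = (np.arange(n * m) + 0.5) / (n * m)  # cell centers in [0, 1)
        tile = np.floor(n * xs[:, None] - j / m).astype(np.int64) % n
        tab = (j - 1) * n + tile
        tab.setflags(write=False)
        _TILE_TABLES[key] = tab
    return tab


def active_tile_indices(phi: float, n: int, m: int) -> np.ndarray:
    """Indices of the m active features for angle ``phi``.

    Tiling ``j`` (1-based) activates tile ``i`` when ``phi/2pi`` falls in
    ``[(i-1+j/m)/n, (i+j/m)/n)`` wrapped mod 1; the flat layout is
    tiling-major: ``(j-1)*n + i``.
    """
    cell = int(((phi / TWO_PI) % 1.0) * n * m) % (n * m)
    return _tile_table(n, m)[cell]


def encode(phi: float, params: AgentHyperParams) -> np.ndarray:
    """Binary tile-coding feature vector of length n*m with exactly m ones."""
    f = np.zeros(params.n_features, dtype=np.uint8)
    f[active_tile_indices(phi, params.n_tiles, params.n_tilings)] = 1
    return f


def cell_index(phi: float, n: int, m: int) -> int:
    """Index of the width-2pi/(nm) intersection cell containing ``phi``.

    The m active tiles of the encoding intersect in exactly one such cell;
    all angles inside it share the same feature vector.
    """
    return int(math.floor(((phi / TWO_PI) % 1.0) * n * m)) % (n * m)


def cell_center(phi: float, n: int, m: int) -> float:
    """Center angle of the intersection cell containing ``phi``.

    Equals the circular mean of the m active tile centers.
    """
    w = TWO_PI / (n * m)
    return (cell_index(phi, n, m) + 0.5) * w


def exploration_rate(c: int, params: AgentHyperParams) -> float:
    """Exploration rate after c spikes: max(beta2, epsilon_base**c)."""
    if c < 0:
        raise ValueError("spike count must be nonnegative")
    return max(params.beta2, params.epsilon_base**c)


def soft_activation(g: float, gain: float) -> float:
    """sigma(x) = atan(gain*x)/pi + 1/2, a sigmoid onto (0, 1)."""
    return math.atan(gain * g) / math.pi + 0.5


def action_probability(g: float, c: int, params: AgentHyperParams) -> float:
    """P(a=1): (1-q) * (eps/2 + (1-eps) * sigma(g))."""
    eps = exploration_rate(c, params)
    return (1.0 - params.q) * (
        0.5 * eps + (1.0 - eps) * soft_activation(g, params.gain)
    )


class Outcome(NamedTuple):
    """What every unit sees after a group step: the realized group
    displacement vector and the sign of the change in target distance."""

    displacement: tuple
    reward: int


def maybe_update(unit, observation: Outcome, rng, params: AgentHyperParams):
    """Apply the unit's model-specific update with probability beta1."""
    if params.beta1 >= 1.0 or rng.random() < params.beta1:
        unit.apply_update(observation)
    return unit


class DecisionUnit:
    """Base class implementing the shared decision pipeline.

    Subclasses provide ``_activation()`` (reading ``self._phi``) and
    ``apply_update(outcome)``; they may override ``reset`` / ``_on_spike``.
    The unit keeps no cross-unit state: its only inputs are the shared
    noiseless angle (which it privately corrupts) and the realized group
    displacement.
    """

    def __init__(self, params: AgentHyperParams, rng):
        self.params = params
        self.rng = rng
        self.spikes = 0
        self._phi: float = 0.0
        self._last_action = 0

    # -- interface ---------------------------------------------------------
    def act(self, psi: float) -> int:
        p = self.params
        rng = self.rng
        forced_idle = rng.random() < p.q
        eta = rng.normal(0.0, math.sqrt(p.beta3)) if p.beta3 > 0 else 0.0
        self._phi = (psi + eta) % TWO_PI
        self._prepare()
        if forced_idle:
            a = 0
        else:
            eps = max(p.beta2, p.epsilon_base**self.spikes)
            g = self._activation()
            prob = 0.5 * eps + (1.0 - eps) * soft_activation(g, p.gain)
            a = 1 if rng.random() < prob else 0
        if a:
            self.spikes += 1
        self._last_action = a
        return a

    def observe_outcome(self, displacement, reward: int) -> None:
        """Feed back the realized group displacement for this step.

        Units learn only from steps on which they themselves spiked, and
        even then the update is skipped with probability 1 - beta1.
        """
        if self._last_action != 1:
            return
        maybe_update(self, Outcome(displacement, reward), self.rng, self.params)

    def reset(self) -> None:
        """Forget everything learned (called between batches)."""
        self.spikes = 0
        self._last_action = 0

    def end_trial(self) -> None:
        """Hook for episode boundaries within a batch (default: nothing)."""

    # -- subclass hooks ----------------------------------------------------
    def _prepare(self) -> None:
        """Cache per-step derived quantities of self._phi (optional)."""

    def _activation(self) -> float:
        raise NotImplementedError

    def apply_update(self, outcome: Outcome) -> None:
        raise NotImplementedError


def unit_rng(seed: int, unit_index: int) -> np.random.Generator:
    """Independent per-unit stream: adding a unit never perturbs others."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, unit_index)))


def subsystem_rng(seed: int, subsystem: int) -> np.random.Generator:
    """Independent stream for a non-unit subsystem (0 = engine geometry)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, subsystem)))
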