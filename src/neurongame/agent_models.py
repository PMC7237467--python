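"""The four decision-unit models: Bayes, Thompson, SARSA(lambda), perceptron.

All four share the pipeline of :mod:`neurongame.agent_core` and differ only
in the activation level ``g`` and the learning rule.

* **Bayes** -- keeps a conjugate-style belief ``(R0, Phi, c)`` over its hidden
  displacement direction (a von Mises posterior with an unknown concentration
  integrated out numerically) and sets ``g`` to the expected utility of
  pressing, where the utility of pressing is ``pi/2`` minus the circular
  distance between the observed angle and the displacement direction.
* **Thompson** -- same belief, but ``g`` is a single posterior sample of the
  utility: a draw of the displacement direction and of the angle compatible
  with the current feature vector.
* **SARSA(lambda)** -- model-free on-policy TD learning over the tile-coded
  features with replacing eligibility traces and the reward
  ``sign(d_t - d_{t+1})`` of the realized group step.
* **Perceptron** -- a single-layer threshold unit trained by a punitive
  rule from the binary signal "did the group step reduce the distance".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ive

from ._circular import TWO_PI, circ_dist, circ_mean_resultant, wrap_angle
from .agent_core import (
    AgentHyperParams,
    DecisionUnit,
    Outcome,
    active_tile_indices,
    cell_center,
)

# Numerical grids for the Bayes/Thompson belief machinery. The concentration
# kappa has an improper flat prior; truncating it to a logarithmic grid on
# (1e-2, 500] (50 points) makes it proper while resolving the pi/180 tile
# width. The direction nu is handled on a 360-point grid (quadrature) or
# exactly (conditional sampling).
KAPPA_GRID: np.ndarray = np.geomspace(1e-2, 500.0, 50)
NU_GRID_SIZE: int = 360
PHI_QUAD_POINTS: int = 16


def _log_i0(x):
    """log of the modified Bessel function I0, overflow-safe via ive."""
    x = np.asarray(x, dtype=float)
    return x + np.log(ive(0, x))


# ---------------------------------------------------------------------------
# utility and the feature-conditional angle density
# ---------------------------------------------------------------------------


def utility(a: int, phi: float, nu: float) -> float:
    """Utility of action ``a`` given observed angle ``phi`` and displacement
    direction ``nu``: zero for staying idle, ``pi/2 - d_C(phi, nu)`` for
    pressing (positive iff pressing moves the cursor closer)."""
    if a == 0:
        return 0.0
    return math.pi / 2.0 - float(circ_dist(phi, nu))


@dataclass(frozen=True)
class PhiDensity:
    """Uniform density of angles compatible with one feature vector.

    The m active tiles intersect in a single cell of width ``2*pi/(n*m)``
    centered at the circular mean of the active tile centers; the density is
    ``n*m/(2*pi)`` there and zero elsewhere.
    """

    center: float
    n_features: int

    @property
    def half_width(self) -> float:
        return math.pi / self.n_features

    @property
    def height(self) -> float:
        return self.n_features / TWO_PI

    def __call__(self, phi) -> np.ndarray:
        inside = circ_dist(phi, self.center) < self.half_width
        return np.where(inside, self.height, 0.0)

    def quadrature_points(self, k: int = PHI_QUAD_POINTS) -> np.ndarray:
        """Midpoint quadrature nodes spanning the support."""
        w = 2.0 * self.half_width
        offs = (np.arange(k) + 0.5) / k * w - self.half_width
        return wrap_angle(self.center + offs)

    def sample(self, rng) -> float:
        return wrap_angle(self.center + rng.uniform(-self.half_width, self.half_width))


def phi_density_given_f(f: np.ndarray, params: AgentHyperParams) -> PhiDensity:
    """Build the feature-conditional angle density from a feature vector."""
    f = np.asarray(f)
    idx = np.flatnonzero(f)
    n, m = params.n_tiles, params.n_tilings
    if idx.size != m or np.any(np.bincount(idx // n, minlength=m) != 1):
        raise ValueError("feature vector must have exactly one active tile per tiling")
    tile = idx % n
    j = idx // n + 1  # 1-based tiling number
    centers = (tile + 0.5 + j / m) / n * TWO_PI  # tile spans [(i-1+j/m)/n, (i+j/m)/n)
    mean, rbar = circ_mean_resultant(wrap_angle(centers))
    if rbar <= 0:
        raise ValueError("degenerate feature vector: tile centers have no mean")
    return PhiDensity(center=mean, n_features=n * m)


# ---------------------------------------------------------------------------
# Bayesian belief over the hidden displacement direction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BayesBelief:
    """Sufficient statistics of the direction belief.

    r0  -- length of the resultant of all observed displacement angles
    phi -- direction of that resultant (NaN while r0 == 0)
    c   -- number of observations absorbed so far
    """

    r0: float = 0.0
    phi: float = float("nan")
    c: int = 0

    def __post_init__(self):
        if self.r0 < 0 or self.c < 0:
            raise ValueError("r0 and c must be nonnegative")
        if self.r0 > self.c + 1e-9:
            raise ValueError("resultant length cannot exceed observation count")


def belief_update(belief: BayesBelief, angles) -> BayesBelief:
    """Absorb observed displacement angles by vector-adding their unit
    vectors to the resultant and incrementing the count."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        return belief
    s = np.sin(angles).sum()
    c_ = np.cos(angles).sum()
    if belief.r0 > 0 and math.isfinite(belief.phi):
        s += belief.r0 * math.sin(belief.phi)
        c_ += belief.r0 * math.cos(belief.phi)
    r0 = float(np.hypot(s, c_))
    if r0 <= 1e-12:  # vanishing resultant: direction ill-defined
        r0, phi = 0.0, float("nan")
    else:
        phi = float(np.arctan2(s, c_)) % TWO_PI
    return BayesBelief(r0=min(r0, belief.c + angles.size), phi=phi, c=belief.c + angles.size)


def _kappa_weights(belief: BayesBelief, kappa_grid: np.ndarray) -> np.ndarray:
    """Posterior weights of the concentration grid points.

    Marginalizing the direction analytically gives
    ``p(kappa) propto I0(r0*kappa) / I0(kappa)^c`` on the grid.
    """
    logw = _log_i0(belief.r0 * kappa_grid) - belief.c * _log_i0(kappa_grid)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def belief_density(
    belief: BayesBelief,
    nu_grid: np.ndarray | None = None,
    kappa_grid: np.ndarray | None = None,
):
    """Joint belief density on a (nu, kappa) grid.

    Returns ``(nu, kappa, P)`` where ``P[i, j]`` is the density at
    ``(nu[i], kappa[j])``, normalized so that ``sum(P * cell_area) == 1``
    with trapezoidal kappa cell widths.
    """
    if nu_grid is None:
        nu_grid = TWO_PI * np.arange(NU_GRID_SIZE) / NU_GRID_SIZE
    if kappa_grid is None:
        kappa_grid = KAPPA_GRID
    if belief.r0 > 0 and math.isnan(belief.phi):
        raise ValueError("belief has positive resultant but undefined direction")
    cosd = np.cos(nu_grid - belief.phi)[:, None] if belief.r0 > 0 else np.zeros((len(nu_grid), 1))
    logp = belief.r0 * kappa_grid[None, :] * cosd - belief.c * _log_i0(kappa_grid)[None, :]
    logp -= logp.max()
    p = np.exp(logp)
    dnu = TWO_PI / len(nu_grid)
    dk = np.gradient(kappa_grid)
    p /= (p * dnu * dk[None, :]).sum()
    return nu_grid, kappa_grid, p


def expected_distance_profile(
    belief: BayesBelief, grid_size: int = NU_GRID_SIZE, kappa_grid: np.ndarray | None = None
) -> np.ndarray:
    """E[d_C(phi, nu)] under the belief, tabulated over a grid of offsets
    ``phi - Phi`` (grid_size points around the circle).

    Computed by mixing the exact von Mises conditionals ``nu | kappa`` over
    the kappa grid and circularly convolving with the distance kernel.
    """
    if kappa_grid is None:
        kappa_grid = KAPPA_GRID
    g = grid_size
    offsets = TWO_PI * np.arange(g) / g
    if belief.c == 0 or belief.r0 < 1e-12:
        dens = np.full(g, 1.0 / TWO_PI)
    else:
        w = _kappa_weights(belief, kappa_grid)
        kr = kappa_grid * belief.r0
        # von Mises density at each offset for each kappa, overflow-safe
        dens = (w / (TWO_PI * ive(0, kr))) @ np.exp(np.outer(kr, np.cos(offsets) - 1.0))
    mass = dens * (TWO_PI / g)
    mass /= mass.sum()
    kernel = np.minimum(np.arange(g), g - np.arange(g)) * (TWO_PI / g)
    return np.fft.irfft(np.fft.rfft(mass) * np.fft.rfft(kernel), g)


def _interp_profile(profile: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Circular linear interpolation of a profile tabulated on a uniform grid."""
    g = len(profile)
    x = np.mod(offset, TWO_PI) / (TWO_PI / g)
    i0 = np.floor(x).astype(int) % g
    frac = x - np.floor(x)
    return profile[i0] * (1.0 - frac) + profile[(i0 + 1) % g] * frac


def bayes_activation(
    belief: BayesBelief,
    f: np.ndarray | PhiDensity,
    params: AgentHyperParams,
    grid_size: int = NU_GRID_SIZE,
    phi_points: int = PHI_QUAD_POINTS,
    kappa_grid: np.ndarray | None = None,
    _profile: np.ndarray | None = None,
) -> float:
    """Expected utility of pressing: the triple integral of
    ``p(nu, kappa) * p(phi | f) * U(1, phi, nu)`` by numerical quadrature.

    The uninformed belief (c = 0) gives exactly 0 by symmetry.
    """
    if belief.c == 0 or belief.r0 < 1e-12:
        return 0.0
    dens = f if isinstance(f, PhiDensity) else phi_density_given_f(f, params)
    profile = _profile
    if profile is None:
        profile = expected_distance_profile(belief, grid_size, kappa_grid)
    phis = dens.quadrature_points(phi_points)
    e = _interp_profile(profile, phis - belief.phi).mean()
    if not np.isfinite(e):
        raise FloatingPointError("non-finite quadrature in Bayes activation")
    return float(math.pi / 2.0 - e)


def thompson_activation(
    belief: BayesBelief,
    f: np.ndarray | PhiDensity,
    rng,
    params: AgentHyperParams,
    kappa_grid: np.ndarray | None = None,
    _kappa_cdf: np.ndarray | None = None,
) -> float:
    """One posterior sample of the expected utility of pressing."""
    if kappa_grid is None:
        kappa_grid = KAPPA_GRID
    dens = f if isinstance(f, PhiDensity) else phi_density_given_f(f, params)
    phi = dens.sample(rng)
    if belief.c == 0 or belief.r0 < 1e-12:
        nu = rng.uniform(0.0, TWO_PI)
    else:
        cdf = _kappa_cdf if _kappa_cdf is not None else np.cumsum(_kappa_weights(belief, kappa_grid))
        k = kappa_grid[np.searchsorted(cdf, rng.random())]
        nu = wrap_angle(belief.phi + rng.vonmises(0.0, k * belief.r0))
    return utility(1, phi, nu)


# ---------------------------------------------------------------------------
# SARSA(lambda) with tile coding
# ---------------------------------------------------------------------------


def reward(s_t, s_t1, target) -> int:
    """sign(d(target, s_t) - d(target, s_{t+1})): +1 closer, -1 farther, 0 tie."""
    d0 = math.hypot(target[0] - s_t[0], target[1] - s_t[1])
    d1 = math.hypot(target[0] - s_t1[0], target[1] - s_t1[1])
    return int(np.sign(d0 - d1))


@dataclass
class RLState:
    """Weights and replacing eligibility trace for the two-action learner.

    ``w`` stacks the idle-action block before the press-action block,
    each of length n*m.
    """

    n_features: int
    alpha: float = 0.1
    gamma: float = 0.9
    lam: float = 0.8
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    z: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.w is None:
            self.w = np.zeros(2 * self.n_features)
        if self.z is None:
            self.z = np.zeros(2 * self.n_features)


def rl_activation(state: RLState, f: np.ndarray) -> float:
    """g = Q(f, press) - Q(f, idle) with linear Q over augmented features."""
    idx = np.flatnonzero(f)
    nf = state.n_features
    return float(state.w[idx + nf].sum() - state.w[idx].sum())


def _sarsa_step(state: RLState, idx_t: np.ndarray, a_t: int, r: float,
                idx_t1: np.ndarray | None, a_t1: int) -> None:
    """In-place SARSA(lambda) update: replace trace, TD update, decay trace.

    ``idx_t1 = None`` marks a terminal transition (no bootstrap).
    """
    nf = state.n_features
    fa = idx_t + a_t * nf
    state.z[fa] = np.maximum(state.z[fa], 1.0)
    q_sa = state.w[fa].sum()
    q_next = state.w[idx_t1 + a_t1 * nf].sum() if idx_t1 is not None else 0.0
    delta = r - q_sa + state.gamma * q_next
    state.w += state.alpha * delta * state.z
    state.z *= state.gamma * state.lam


def sarsa_update(state: RLState, f_t: np.ndarray, a_t: int, r: float,
                 f_t1: np.ndarray, a_t1: int) -> RLState:
    """Functional SARSA(lambda) update on full feature vectors.

    Order follows the published rule literally: the trace is *replaced*
    before the weight update and *decayed* after it.
    """
    f_t = np.asarray(f_t)
    f_t1 = np.asarray(f_t1)
    if f_t.size != state.n_features or f_t1.size != state.n_features:
        raise ValueError("feature length does not match state")
    out = RLState(state.n_features, state.alpha, state.gamma, state.lam,
                  state.w.copy(), state.z.copy())
    _sarsa_step(out, np.flatnonzero(f_t), a_t, r, np.flatnonzero(f_t1), a_t1)
    return out


# ---------------------------------------------------------------------------
# Perceptron
# ---------------------------------------------------------------------------


@dataclass
class PerceptronState:
    """Single-layer perceptron weights.

    ``variant`` selects the update rule applied when the unit spiked and the
    training signal T (distance decreased?) disagreed with the response:

    * ``"feature_based"`` (default): ``w <- w + alpha*(T-1)*f``,
      ``b <- b + alpha*(T-1)`` -- punishes the active features.
    * ``"as_printed"``: ``w <- w + alpha*(T-1)*w``, ``b <- b + alpha*(T-1)*b``
      -- the multiplicative form, retained for fidelity; with the stated
      zero initialization it never leaves the origin.
    """

    n_features: int
    alpha: float = 0.1
    variant: str = "feature_based"
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    b: float = 0.0

    def __post_init__(self):
        if self.variant not in ("feature_based", "as_printed"):
            raise ValueError(f"unknown perceptron variant: {self.variant}")
        if self.w is None:
            self.w = np.zeros(self.n_features)


def perceptron_activation(state: PerceptronState, f: np.ndarray) -> float:
    """g = w . f + b."""
    return float(state.w[np.flatnonzero(f)].sum() + state.b)


def perceptron_update(state: PerceptronState, f: np.ndarray, spiked: int,
                      training_signal: int) -> PerceptronState:
    """Update after a spiked step (no update when idle or when T == 1)."""
    if spiked != 1 or training_signal == 1:
        return state
    out = PerceptronState(state.n_features, state.alpha, state.variant,
                          state.w.copy(), state.b)
    step = state.alpha * (training_signal - 1)
    if state.variant == "as_printed":
        out.w += step * state.w
        out.b += step * state.b
    else:
        out.w += step * np.asarray(f, dtype=float)
        out.b += step
    return out


# ---------------------------------------------------------------------------
# Agent classes plugging the models into the shared pipeline
# ---------------------------------------------------------------------------


class _BeliefAgent(DecisionUnit):
    """Common machinery of the Bayes and Thompson units.

    The unit keeps track of the average displacement it has experienced over
    its active steps; each accepted update feeds the angle of that running
    average displacement vector into the belief. (Averaging first is what
    keeps the estimate stable against the group's own coordinated drift;
    the angle of a single step's group displacement mostly reflects where
    the already-coordinated group is heading.)
    """

    def __init__(self, params: AgentHyperParams, rng):
        super().__init__(params, rng)
        self.belief = BayesBelief()
        self._cell = 0.0
        self._disp_sum = np.zeros(2)

    def _prepare(self) -> None:
        self._cell = cell_center(self._phi, self.params.n_tiles, self.params.n_tilings)

    def apply_update(self, outcome: Outcome) -> None:
        dx, dy = outcome.displacement
        self._disp_sum[0] += dx
        self._disp_sum[1] += dy
        if self._disp_sum[0] == 0.0 and self._disp_sum[1] == 0.0:
            return  # zero average displacement carries no direction information
        angle = math.atan2(self._disp_sum[1], self._disp_sum[0]) % TWO_PI
        self.belief = belief_update(self.belief, angle)
        self._invalidate()

    def reset(self) -> None:
        super().reset()
        self.belief = BayesBelief()
        self._disp_sum = np.zeros(2)
        self._invalidate()

    def _invalidate(self) -> None:
        raise NotImplementedError

    def snapshot(self) -> dict:
        return {"r0": self.belief.r0, "phi": self.belief.phi, "c": self.belief.c,
                "spikes": self.spikes}


class BayesAgent(_BeliefAgent):
    """Expected-utility unit: g is the quadrature of U over the belief."""

    def __init__(self, params: AgentHyperParams, rng,
                 grid_size: int = NU_GRID_SIZE, phi_points: int = PHI_QUAD_POINTS):
        self.grid_size = grid_size
        self.phi_points = phi_points
        self._profile = None
        super().__init__(params, rng)

    def _invalidate(self) -> None:
        self._profile = None

    def _activation(self) -> float:
        if self.belief.c == 0 or self.belief.r0 < 1e-12:
            return 0.0
        if self._profile is None:
            self._profile = expected_distance_profile(self.belief, self.grid_size)
        dens = PhiDensity(self._cell, self.params.n_features)
        return bayes_activation(self.belief, dens, self.params,
                                self.grid_size, self.phi_points, _profile=self._profile)


class ThompsonAgent(_BeliefAgent):
    """Posterior-sampling unit: g is one sampled utility."""

    def __init__(self, params: AgentHyperParams, rng):
        self._kappa_cdf = None
        super().__init__(params, rng)

    def _invalidate(self) -> None:
        self._kappa_cdf = None

    def _activation(self) -> float:
        if self.belief.c > 0 and self.belief.r0 >= 1e-12 and self._kappa_cdf is None:
            self._kappa_cdf = np.cumsum(_kappa_weights(self.belief, KAPPA_GRID))
        dens = PhiDensity(self._cell, self.params.n_features)
        return thompson_activation(self.belief, dens, self.rng, self.params,
                                   _kappa_cdf=self._kappa_cdf)


class SarsaAgent(DecisionUnit):
    """SARSA(lambda) unit over tile-coded features.

    Weights persist across trials within a batch; the eligibility trace and
    the pending transition are episodic and reset at trial boundaries.
    Updates happen only for steps on which the unit spiked.
    """

    def __init__(self, params: AgentHyperParams, rng,
                 alpha: float = 0.1, gamma: float = 0.9, lam: float = 0.8):
        super().__init__(params, rng)
        self.state = RLState(params.n_features, alpha, gamma, lam)
        self._idx = None
        self._ready = None  # (idx_t, a_t, r) awaiting the next state-action

    def _prepare(self) -> None:
        self._idx = active_tile_indices(self._phi, self.params.n_tiles,
                                        self.params.n_tilings)

    def act(self, psi: float) -> int:
        a = super().act(psi)
        if self._ready is not None:
            idx_t, a_t, r = self._ready
            _sarsa_step(self.state, idx_t, a_t, r, self._idx, a)
            self._ready = None
        return a

    def _activation(self) -> float:
        nf = self.params.n_features
        return float(self.state.w[self._idx + nf].sum() - self.state.w[self._idx].sum())

    def apply_update(self, outcome: Outcome) -> None:
        self._ready = (self._idx, 1, float(outcome.reward))

    def end_trial(self) -> None:
        if self._ready is not None:  # terminal: no bootstrap
            idx_t, a_t, r = self._ready
            _sarsa_step(self.state, idx_t, a_t, r, None, 0)
            self._ready = None
        self.state.z[:] = 0.0

    def reset(self) -> None:
        super().reset()
        self.state.w[:] = 0.0
        self.state.z[:] = 0.0
        self._ready = None

    def snapshot(self) -> dict:
        return {"w": self.state.w.tolist(), "spikes": self.spikes}


class PerceptronAgent(DecisionUnit):
    """Single-layer perceptron unit with the punitive update rule."""

    def __init__(self, params: AgentHyperParams, rng,
                 alpha: float = 0.1, variant: str = "feature_based"):
        super().__init__(params, rng)
        self.state = PerceptronState(params.n_features, alpha, variant)
        self._idx = None

    def _prepare(self) -> None:
        self._idx = active_tile_indices(self._phi, self.params.n_tiles,
                                        self.params.n_tilings)

    def _activation(self) -> float:
        return float(self.state.w[self._idx].sum() + self.state.b)

    def apply_update(self, outcome: Outcome) -> None:
        t_signal = 1 if outcome.reward > 0 else 0
        if t_signal == 1:
            return
        step = self.state.alpha * (t_signal - 1)
        if self.state.variant == "as_printed":
            self.state.w += step * self.state.w
            self.state.b += step * self.state.b
        else:
            self.state.w[self._idx] += step
            self.state.b += step

    def reset(self) -> None:
        super().reset()
        self.state.w[:] = 0.0
        self.state.b = 0.0

    def snapshot(self) -> dict:
        return {"w": self.state.w.tolist(), "b": self.state.b, "spikes": self.spikes}


class ScriptedAgent:
    """Omniscient oracle that knows its true direction: presses iff the
    target-difference angle lies strictly within pi/2 of it. Used as a
    closed-loop sanity check of the engine, not as a behavioral model."""

    def __init__(self, mu: float):
        self.mu = mu

    def act(self, psi: float) -> int:
        return 1 if circ_dist(psi, self.mu) < math.pi / 2 else 0

    def observe_outcome(self, displacement, reward) -> None:
        pass

    def reset(self) -> None:
        pass

    def end_trial(self) -> None:
        pass


MODEL_NAMES = ("bayes", "thompson", "rl", "ann")


def make_agents(model: str, params: AgentHyperParams, seed: int, n_players: int,
                **model_kwargs):
    """Build one unit per player with independent RNG streams."""
    from .agent_core import unit_rng

    cls = {"bayes": BayesAgent, "thompson": ThompsonAgent,
           "rl": SarsaAgent, "ann": PerceptronAgent}.get(model)
    if cls is None:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    return [cls(params, unit_rng(seed, i), **model_kwargs) for i in range(n_players)]
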