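"""Hyperparameter calibration harness.

The behavioral models were originally tuned so that simulated group
performance matches human group performance; the tuned values themselves are
not published. This module ships (a) a coarse grid-search harness that
scores candidate hyperparameters by the distance of the simulated group
statistics to the published model-level statistics, and (b) the calibration
profile produced by that harness (``data/calibration.yaml``), which the rest
of the package uses by default.
"""

from __future__ import annotations

import itertools
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .agent_core import AgentHyperParams
from .config import GameConfig

#: Published model-level group statistics used as the calibration objective
#: (percent): group success rate and mean individual correct-response rate.
REFERENCE_STATS = {
    "bayes": {"success": 84.0, "correct_response": 75.0},
    "thompson": {"success": 84.0, "correct_response": 75.0},
    "rl": {"success": 73.0, "correct_response": 66.0},
    "ann": {"success": 58.0, "correct_response": 55.0},
}

_SHARED_KEYS = ("beta1", "beta2", "beta3", "gain", "q", "epsilon_base")
_MODEL_KEYS = {"rl": ("alpha", "gamma", "lam"), "ann": ("alpha", "variant")}


def load_calibration(path=None) -> dict:
    """Load a calibration profile (default: the packaged one)."""
    if path is None:
        text = resources.files("neurongame").joinpath("data/calibration.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def hyperparams_for(model: str, calibration: dict | None = None):
    """Split a model's calibrated block into shared pipeline hyperparameters
    and model-specific constructor keywords."""
    calibration = calibration or load_calibration()
    block = dict(calibration["models"][model])
    shared = {k: block.pop(k) for k in list(block) if k in _SHARED_KEYS}
    kwargs = {k: block.pop(k) for k in list(block) if k in _MODEL_KEYS.get(model, ())}
    return AgentHyperParams(**shared), kwargs


def score_candidate(model: str, params: AgentHyperParams, model_kwargs: dict,
                    seeds, n_batches: int, config: GameConfig | None = None) -> dict:
    """Simulate reduced sessions and measure the distance (in percentage
    points, summed over statistics and averaged over seeds) to the published
    model-level statistics."""
    from .engine import simulate
    from .group_metrics import session_metrics

    config = config or GameConfig()
    ref = REFERENCE_STATS[model]
    succ, resp = [], []
    for seed in seeds:
        session = simulate(model, config, seed=seed, hyper=params,
                           n_batches=n_batches, **model_kwargs)
        m = session_metrics(session)
        succ.append(100 * m["group_success_rate"])
        resp.append(100 * m["mean_correct_response_rate"])
    succ_m, resp_m = float(np.mean(succ)), float(np.mean(resp))
    return {
        "success": succ_m,
        "correct_response": resp_m,
        "score": abs(succ_m - ref["success"]) + abs(resp_m - ref["correct_response"]),
    }


def grid_search(model: str, grid: dict, seeds=(0, 1), n_batches: int = 8,
                base: dict | None = None, config: GameConfig | None = None,
                progress=None) -> list:
    """Coarse grid search over hyperparameter candidates.

    ``grid`` maps parameter names (shared or model-specific) to candidate
    lists; ``base`` supplies the fixed values. Returns all evaluated
    candidates sorted by score (best first).
    """
    base = dict(base or {})
    names = sorted(grid)
    results = []
    for combo in itertools.product(*(grid[k] for k in names)):
        cand = {**base, **dict(zip(names, combo))}
        shared = {k: v for k, v in cand.items() if k in _SHARED_KEYS}
        kwargs = {k: v for k, v in cand.items() if k in _MODEL_KEYS.get(model, ())}
        res = score_candidate(model, AgentHyperParams(**shared), kwargs,
                              seeds, n_batches, config)
        results.append({"params": cand, **res})
        if progress is not None:
            progress(results[-1])
    results.sort(key=lambda r: r["score"])
    return results


def write_calibration(profile: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(profile, sort_keys=False))
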