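"""Small circular-statistics helpers shared across modules.

Angles are radians; canonical range is [0, 2*pi). The circular distance
``circ_dist`` is the geodesic distance on the circle, in [0, pi].
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angle(s) into [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


def circ_dist(a, b):
    """Circular (geodesic) distance between angles, in [0, pi]."""
    d = np.abs(np.mod(a - b, TWO_PI))
    return np.minimum(d, TWO_PI - d)


def signed_circ_diff(a, b):
    """Signed circular difference a - b, wrapped into (-pi, pi]."""
    d = np.mod(a - b, TWO_PI)
    return np.where(d > np.pi, d - TWO_PI, d)


def circ_mean_resultant(angles, weights=None):
    """Mean direction and mean resultant length of a sample of angles.

    Returns ``(mean_angle, rbar)``. When the resultant vanishes the mean
    direction is ill-defined; callers must check ``rbar``.
    """
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        s = np.sin(angles).mean()
        c = np.cos(angles).mean()
    else:
        weights = np.asarray(weights, dtype=float)
        w = weights.sum()
        s = np.dot(weights, np.sin(angles)) / w
        c = np.dot(weights, np.cos(angles)) / w
    rbar = float(np.hypot(s, c))
    return float(np.arctan2(s, c)) % TWO_PI, rbar
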