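"""Synthetic MT anchoring-site angles: von Mises mixtures on the circle.

Emulates traced anchoring-site positions around cell centroids; a bimodal
mixture at 0 and 180 degrees reproduces the proximal-distal boundary
concentration seen by EM.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidParameterError


def make_anchoring_angles(
    n: int = 200,
    modes_deg: list[float] | tuple[float, ...] = (0.0, 180.0),
    kappa: float = 4.0,
    weights: list[float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n`` angles (degrees in [0, 360)) from a von Mises mixture.

    ``kappa = 0`` gives the uniform circular distribution regardless of
    modes.  Mixture components are equally weighted unless ``weights`` is
    given.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    modes = np.asarray(modes_deg, dtype=float)
    if modes.size == 0:
        raise InvalidParameterError("need at least one mode")
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    if weights is None:
        w = np.full(modes.size, 1.0 / modes.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != modes.shape or np.any(w < 0) or w.sum() <= 0:
            raise InvalidParameterError("weights must be non-negative and match modes")
        w = w / w.sum()
    if kappa == 0:
        return rng.uniform(0.0, 360.0, size=n)
    comp = rng.choice(modes.size, size=n, p=w)
    angles = rng.vonmises(np.deg2rad(modes[comp]), kappa)
    return np.degrees(angles) % 360.0
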