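"""Synthetic vesicle-track mixtures with per-track ground-truth labels.

Three motion modes, emulating the trafficking patterns seen in live
imaging at 5-second frame intervals:

* transcytotic — persistent, highly linear drift along the P-D axis with
  small lateral noise; distal with probability ``p_distal``;
* wandering   — unbiased random walk with frequent pause frames;
* stuck       — no change in location in any frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError
from ..tracks import Track


@dataclass(frozen=True)
class TrackMixtureTruth:
    tracks: list[Track]
    labels: list[str]               # per-track mode
    distal_truth: list[bool | None]  # transcytotic tracks: drifted distally?
    p_distal: float
    frame_interval_s: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.tracks) != len(self.labels):
            raise InvalidParameterError("labels and tracks must align")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr, lab in zip(self.tracks, self.labels):
            for k in range(tr.n_frames):
                rows.append(
                    {
                        "track_id": tr.track_id,
                        "frame": k,
                        "t_seconds": tr.t[k],
                        "x": tr.x[k],
                        "y": tr.y[k],
                        "truth_label": lab,
                    }
                )
        return pd.DataFrame(rows)


def make_track_mixture(
    n: int = 1192,
    f_trans: float = 0.75,
    f_wander: float = 0.10,
    f_stuck: float = 0.15,
    p_distal: float = 0.58,
    step_px: float = 3.0,
    n_frames: int = 10,
    frame_interval_s: float = 5.0,
    lateral_sd_frac: float = 0.15,
    pause_prob: float = 0.4,
    arena_px: float = 200.0,
    seed: int = 0,
) -> TrackMixtureTruth:
    """Sample ``n`` tracks from the three-mode mixture.

    Fractions must sum to 1 (tolerance 1e-9); ``n_frames >= 2`` so every
    track is visible in at least two consecutive frames.  Mode counts are
    the rounded expectations (deterministic composition); per-track
    randomness (start points, drift direction, steps) comes from ``seed``.
    """
    if abs(f_trans + f_wander + f_stuck - 1.0) > 1e-9:
        raise InvalidParameterError("mode fractions must sum to 1")
    if min(f_trans, f_wander, f_stuck) < 0:
        raise InvalidParameterError("mode fractions must be >= 0")
    if n_frames < 2:
        raise InvalidParameterError("tracks need at least two frames")
    if not (0.0 <= p_distal <= 1.0):
        raise InvalidParameterError("p_distal must be a probability")
    if frame_interval_s <= 0 or step_px <= 0:
        raise InvalidParameterError("frame interval and step must be > 0")
    rng = np.random.default_rng(seed)

    n_trans = int(round(n * f_trans))
    n_wander = int(round(n * f_wander))
    n_stuck = n - n_trans - n_wander
    if n_stuck < 0:
        raise InvalidParameterError("rounded mode counts exceed n")
    modes = ["transcytotic"] * n_trans + ["wandering"] * n_wander + ["stuck"] * n_stuck

    t = np.arange(n_frames) * frame_interval_s
    tracks: list[Track] = []
    labels: list[str] = []
    distal_truth: list[bool | None] = []
    for tid, mode in enumerate(modes):
        x0, y0 = rng.uniform(0, arena_px, size=2)
        if mode == "transcytotic":
            distal = bool(rng.random() < p_distal)
            sign = 1.0 if distal else -1.0
            dx = sign * step_px * (1.0 + 0.1 * rng.standard_normal(n_frames - 1))
            dy = lateral_sd_frac * step_px * rng.standard_normal(n_frames - 1)
            x = x0 + np.concatenate([[0.0], np.cumsum(dx)])
            y = y0 + np.concatenate([[0.0], np.cumsum(dy)])
            distal_truth.append(distal)
        elif mode == "wandering":
            steps = 0.5 * step_px * rng.standard_normal((n_frames - 1, 2))
            paused = rng.random(n_frames - 1) < pause_prob
            steps[paused] = 0.0
            x = x0 + np.concatenate([[0.0], np.cumsum(steps[:, 0])])
            y = y0 + np.concatenate([[0.0], np.cumsum(steps[:, 1])])
            distal_truth.append(None)
        else:
            x = np.full(n_frames, x0)
            y = np.full(n_frames, y0)
            distal_truth.append(None)
        tracks.append(Track(track_id=tid, t=t, x=x, y=y))
        labels.append(mode)
    return TrackMixtureTruth(
        tracks=tracks, labels=labels, distal_truth=distal_truth,
        p_distal=p_distal, frame_interval_s=frame_interval_s, seed=seed,
    )
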