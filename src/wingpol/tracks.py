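"""Vesicle-track quantification: filtering, net-direction and motion-mode
classification, and the proximal-vs-distal binomial test.

A track is scored by the vector between its first and last points: if the
axial (x) component dominates, the vesicle moved proximally or distally;
otherwise anteriorly or posteriorly.  A vesicle with no change in location
between any two consecutive frames is "stuck".  The headline statistics are
the fraction of tracks moving along the P-D axis and an exact binomial test
of distal vs proximal counts against 0.5.

Axis convention: x rightward = distal, y downward = posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

CATEGORIES = ("proximal", "distal", "anterior", "posterior", "stuck")
MOTION_MODES = ("transcytotic", "wandering")


@dataclass(frozen=True)
class Track:
    """Time-stamped 2D point sequence for one vesicle."""

    track_id: int
    t: np.ndarray              # seconds, strictly increasing
    x: np.ndarray              # pixels
    y: np.ndarray              # pixels
    apical: np.ndarray | None = None   # per-frame in-plane flag

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise InvalidParameterError("t, x, y must be 1-D and equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise InvalidParameterError(
                f"track {self.track_id}: timestamps must be strictly increasing"
            )
        apical = self.apical
        if apical is None:
            apical = np.ones(t.size, dtype=bool)
        else:
            apical = np.asarray(apical, dtype=bool)
            if apical.shape != t.shape:
                raise InvalidParameterError("apical flags must match frames")
        for name, arr in (("t", t), ("x", x), ("y", y), ("apical", apical)):
            object.__setattr__(self, name, arr)
            arr.setflags(write=False)

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    def steps(self) -> np.ndarray:
        """Per-interval displacement magnitudes, shape (n_frames - 1,)."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def net_vector(self) -> np.ndarray:
        return np.array([self.x[-1] - self.x[0], self.y[-1] - self.y[0]])


def filter_tracks(
    tracks: Iterable[Track],
    min_frames: int = 2,
    require_apical: bool = True,
) -> list[Track]:
    """Keep tracks visible in >= ``min_frames`` consecutive frames.

    With ``require_apical`` the consecutive-frame run must lie in the
    apical (adherens-junction) plane; the track is trimmed to its longest
    apical run before the length test.
    """
    out = []
    for tr in tracks:
        if require_apical:
            best = _longest_true_run(tr.apical)
            if best is None:
                continue
            lo, hi = best
            if hi - lo < min_frames:
                continue
            sl = slice(lo, hi)
            tr = Track(tr.track_id, tr.t[sl], tr.x[sl], tr.y[sl], tr.apical[sl])
        elif tr.n_frames < min_frames:
            continue
        if tr.n_frames >= min_frames:
            out.append(tr)
    return out


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    best = None
    start = None
    for i, v in enumerate(list(mask) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return best


def classify_net_direction(track: Track, stuck_eps: float = 0.0) -> str:
    """Net-direction category of one (filtered) track.

    Stuck: every consecutive displacement <= ``stuck_eps``.  Otherwise the
    first-to-last vector ``v`` decides: axial (|v_x| >= |v_y|, ties axial)
    gives distal (v_x > 0) or proximal, else posterior (v_y > 0) or
    anterior.  A zero net vector with super-threshold wiggling counts as
    axial/proximal-distal by the v_x sign rule with v_x = 0 -> proximal
    (declared tie rule, logged in the summary).
    """
    if track.n_frames < 2:
        raise InvalidParameterError("cannot classify a single-frame track")
    if np.all(track.steps() <= stuck_eps):
        return "stuck"
    vx, vy = track.net_vector()
    if abs(vx) >= abs(vy):
        return "distal" if vx > 0 else "proximal"
    return "posterior" if vy > 0 else "anterior"


def binomial_p(k: int, n: int, alternative: str = "two-sided") -> float:
    """Exact binomial test p-value for ``k`` successes of ``n`` at p=0.5."""
    if n == 0:
        return float("nan")
    return float(stats.binomtest(k, n, 0.5, alternative=alternative).pvalue)


@dataclass
class DirectionSummary:
    """Category counts plus the axial fraction and the distal-vs-proximal test."""

    counts: dict[str, int]
    n_total: int
    axial_fraction: float
    axial_fraction_moving: float
    distal_vs_proximal_p: float
    significant: bool | None
    tie_rule: str = "axial on |v_x| == |v_y|; v_x == 0 counts proximal"

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_total": self.n_total,
            "axial_fraction": self.axial_fraction,
            "axial_fraction_moving": self.axial_fraction_moving,
            "distal_vs_proximal_p": self.distal_vs_proximal_p,
            "significant": self.significant,
            "tie_rule": self.tie_rule,
        }


def direction_summary(
    tracks: Iterable[Track],
    stuck_eps: float = 0.0,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> DirectionSummary:
    """Classify all tracks and summarize.

    ``axial_fraction`` uses all analyzed tracks (stuck included) as the
    denominator; ``axial_fraction_moving`` excludes stuck tracks — both are
    reported because published percentages rarely state the denominator.
    The distal-vs-proximal p-value is the exact binomial test against 0.5
    over axially moving tracks, two-sided by default; it is NaN (and
    ``significant`` None) when no tracks move axially.
    """
    counts = {c: 0 for c in CATEGORIES}
    for tr in tracks:
        counts[classify_net_direction(tr, stuck_eps)] += 1
    n_total = sum(counts.values())
    if n_total == 0:
        raise InvalidParameterError("no tracks to summarize")
    axial = counts["proximal"] + counts["distal"]
    moving = n_total - counts["stuck"]
    p = binomial_p(counts["distal"], axial, alternative) if axial else float("nan")
    return DirectionSummary(
        counts=counts,
        n_total=n_total,
        axial_fraction=axial / n_total,
        axial_fraction_moving=axial / moving if moving else float("nan"),
        distal_vs_proximal_p=p,
        significant=(p <= alpha) if axial else None,
    )


def classify_motion_mode(
    track: Track,
    straightness_min: float = 0.8,
    pause_frac_max: float = 0.2,
    stuck_eps: float = 0.0,
) -> str | None:
    """Transcytotic vs wandering classification of a moving track.

    Straightness = |net vector| / path length; pause fraction = fraction
    of consecutive steps <= ``stuck_eps``.  Transcytotic movement is
    highly linear and processive (straightness >= ``straightness_min``
    and pause fraction <= ``pause_frac_max``); anything else wandering.
    Returns None (not classifiable) for tracks with < 3 frames or zero
    path length.
    """
    if track.n_frames < 3:
        return None
    steps = track.steps()
    path = steps.sum()
    if path <= 0:
        return None
    straightness = float(np.linalg.norm(track.net_vector())) / path
    pause_frac = float(np.mean(steps <= stuck_eps))
    if straightness >= straightness_min and pause_frac <= pause_frac_max:
        return "transcytotic"
    return "wandering"


def transcytosis_table(
    tracks_by_age: dict[str, list[Track]],
    **mode_kwargs,
) -> pd.DataFrame:
    """Per-age transcytosis ratios (as for staged pupal wings).

    ``tracks_by_age`` maps an age label (e.g. "24 hAPF") to its tracks;
    returns one row per age with counts and the transcytotic ratio among
    classifiable moving tracks.
    """
    rows = []
    for age, tracks in tracks_by_age.items():
        labels = [classify_motion_mode(t, **mode_kwargs) for t in tracks]
        n_trans = sum(1 for l in labels if l == "transcytotic")
        n_wander = sum(1 for l in labels if l == "wandering")
        n_cls = n_trans + n_wander
        rows.append(
            {
                "age": age,
                "n_tracks": len(tracks),
                "n_classifiable": n_cls,
                "n_transcytotic": n_trans,
                "n_wandering": n_wander,
                "transcytotic_ratio": n_trans / n_cls if n_cls else float("nan"),
            }
        )
    return pd.DataFrame(rows)
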