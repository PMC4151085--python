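"""Tissue-level expression gradients along the proximal-distal axis.

Ds and Fj levels in the wing are graded along the P-D axis; the model takes
them as per-column inputs on the cell grid.  Profiles emulate the
experimentally motivated shapes: a roughly linear larval-disc gradient, a
pupal step-like gradient, a steep proximal ramp flattening distally, and a
steep ramp that falls to exactly zero distally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

KINDS = ("linear", "step", "steep_flat", "zero_distal", "uniform", "custom")


@dataclass(frozen=True)
class GradientSpec:
    """Per-column level of one species (Ds or Fj) along the P-D axis.

    ``values[0]`` is the most proximal column; all levels are >= 0.
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise InvalidParameterError("gradient values must be a 1-D array")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise InvalidParameterError("gradient values must be finite and >= 0")
        if self.kind not in KINDS:
            raise InvalidParameterError(f"unknown gradient kind {self.kind!r}")
        object.__setattr__(self, "values", vals)
        vals.setflags(write=False)

    @property
    def n_columns(self) -> int:
        return int(self.values.size)

    def mirrored(self) -> "GradientSpec":
        """The same profile with the P-D axis reversed."""
        return GradientSpec("custom", self.values[::-1].copy())


def make_gradient(
    kind: str,
    columns: int,
    *,
    high: float = 1.0,
    low: float = 0.0,
    step_column: int = 8,
    ramp_columns: int = 8,
) -> GradientSpec:
    """Build a named gradient profile over ``columns`` cell columns.

    Parameters
    ----------
    kind
        ``linear``: affine ramp from ``high`` (proximal) to ``low`` (distal).
        ``step``: ``high`` for columns < ``step_column``, then ``low``.
        ``steep_flat``: linear drop from ``high`` to ``low`` over the first
        ``ramp_columns`` columns, then constant ``low``.
        ``zero_distal``: as ``steep_flat`` but the flat level is exactly 0.
        ``uniform``: constant ``high``.
    columns
        Number of cell columns (>= 2).
    """
    if columns < 2:
        raise InvalidParameterError("a gradient needs at least 2 columns")
    if high < 0 or low < 0:
        raise InvalidParameterError("gradient levels must be >= 0")
    x = np.arange(columns, dtype=float)
    if kind == "linear":
        vals = high + (low - high) * x / (columns - 1)
    elif kind == "step":
        if not (0 < step_column < columns):
            raise InvalidParameterError("step_column must be inside the grid")
        vals = np.where(x < step_column, high, low).astype(float)
    elif kind in ("steep_flat", "zero_distal"):
        flat = 0.0 if kind == "zero_distal" else low
        if not (1 <= ramp_columns < columns):
            raise InvalidParameterError("ramp_columns must be in [1, columns)")
        vals = np.where(
            x < ramp_columns,
            high + (flat - high) * x / ramp_columns,
            flat,
        ).astype(float)
    elif kind == "uniform":
        vals = np.full(columns, float(high))
    else:
        raise InvalidParameterError(f"unknown gradient kind {kind!r}")
    return GradientSpec(kind, vals)
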