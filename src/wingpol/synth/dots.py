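"""Paired dot (tubulin-like) and membrane (Dsh-like) synthetic channels.

Cells are pointy-top hexagons on a pixel lattice; the membrane channel
draws each cell outline, the dot channel places one Gaussian punctum per
cell displaced by a known offset along the negative axis direction
(proximal for axis 0).  The geometric truth — apothem (centre-to-membrane
distance along the axis) and imposed offset — predicts the shift-
correlation peaks: |A| = apothem - offset (proximal), |B| = apothem +
offset (distal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line_aa

from ..errors import InvalidParameterError


@dataclass(frozen=True)
class DotMembraneTruth:
    dots: np.ndarray
    membrane: np.ndarray
    offset_px: float
    axis_deg: float
    apothem_px: float
    centers: np.ndarray
    seed: int

    def to_truth_dict(self) -> dict:
        return {
            "offset_px": self.offset_px,
            "axis_deg": self.axis_deg,
            "apothem_px": self.apothem_px,
            "expected_A": -(self.apothem_px - self.offset_px),
            "expected_B": self.apothem_px + self.offset_px,
            "seed": self.seed,
        }


def make_dot_membrane_pair(
    offset_px: float = 4.0,
    axis_deg: float = 0.0,
    apothem_px: float = 12.0,
    n_rows: int = 8,
    n_cols: int = 10,
    dot_sigma: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DotMembraneTruth:
    """Render the two channels on a hexagonal cell mosaic.

    ``offset_px`` displaces each dot by that distance along the *negative*
    axis direction (proximal when the axis is the P-D axis at 0 degrees).
    Must be smaller than the apothem (half the cell diameter across
    flats).  Two seeds with the same parameters share the cell geometry
    and differ only in noise.
    """
    if abs(offset_px) >= apothem_px:
        raise InvalidParameterError("offset must be smaller than the cell apothem")
    if apothem_px <= 2 or n_rows < 2 or n_cols < 2:
        raise InvalidParameterError("degenerate mosaic geometry")
    rng = np.random.default_rng(seed)

    # pointy-top hexagon: flat left/right sides at distance = apothem
    r_vertex = apothem_px / np.cos(np.pi / 6.0)
    dx = 2.0 * apothem_px          # column pitch
    dy = 1.5 * r_vertex            # row pitch
    pad = int(np.ceil(2 * r_vertex))
    width = int(np.ceil(n_cols * dx + 2 * pad))
    height = int(np.ceil(n_rows * dy + 2 * pad))
    membrane = np.zeros((height, width), dtype=float)
    dots = np.zeros((height, width), dtype=float)

    centers = []
    vertex_angles = np.deg2rad(30 + 60 * np.arange(6))
    off = np.array([-np.cos(np.deg2rad(axis_deg)), -np.sin(np.deg2rad(axis_deg))])
    for r in range(n_rows):
        for c in range(n_cols):
            cx = pad + c * dx + (apothem_px if r % 2 else 0.0)
            cy = pad + r * dy
            centers.append((cx, cy))
            verts = [
                (cx + r_vertex * np.cos(a), cy + r_vertex * np.sin(a))
                for a in vertex_angles
            ]
            for (x0, y0), (x1, y1) in zip(verts, verts[1:] + verts[:1]):
                rr, cc, val = line_aa(
                    int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
                )
                keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
                np.maximum.at(membrane, (rr[keep], cc[keep]), val[keep])
            px = cx + offset_px * off[0]
            py = cy + offset_px * off[1]
            iy, ix = int(round(py)), int(round(px))
            if 0 <= iy < height and 0 <= ix < width:
                dots[iy, ix] += 1.0

    dots = ndimage.gaussian_filter(dots, dot_sigma, mode="constant")
    membrane = ndimage.gaussian_filter(membrane, 0.8, mode="constant")
    if noise_sd > 0:
        dots = np.clip(dots + noise_sd * rng.standard_normal(dots.shape), 0, None)
        membrane = np.clip(membrane + noise_sd * rng.standard_normal(membrane.shape), 0, None)
    return DotMembraneTruth(
        dots=dots, membrane=membrane, offset_px=float(offset_px),
        axis_deg=float(axis_deg), apothem_px=float(apothem_px),
        centers=np.asarray(centers), seed=seed,
    )
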