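"""Synthetic fiber (microtubule-like) images with known axial orientations.

Fibers are anti-aliased line segments whose axial angles follow a von
Mises distribution on doubled angles (the axial analogue of the von Mises;
kappa = 0 gives the uniform axial distribution).  The rendered image is
Gaussian-blurred and carries optional Gaussian read noise; the sampled
angles are recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line_aa

from ..errors import InvalidParameterError


@dataclass(frozen=True)
class FiberImageTruth:
    image: np.ndarray
    fiber_angles_deg: np.ndarray   # axial, in [0, 180)
    mu_deg: float
    kappa: float
    seed: int

    def to_truth_dict(self) -> dict:
        return {
            "mu_deg": self.mu_deg,
            "kappa": self.kappa,
            "seed": self.seed,
            "fiber_angles_deg": self.fiber_angles_deg.tolist(),
        }


def sample_axial_von_mises(
    n: int, mu_deg: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Axial angles in [0, 180): theta = vonmises(2*mu, kappa) / 2."""
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa, size=n)
    return (np.degrees(doubled) / 2.0) % 180.0


def make_fiber_image(
    n_fibers: int = 120,
    mu_deg: float = 0.0,
    kappa: float = 8.0,
    size: int = 256,
    noise_sd: float = 0.02,
    seed: int = 0,
    fiber_length: float | None = None,
    blur_sigma: float = 1.0,
) -> FiberImageTruth:
    """Render a fiber field with axial angles ~ von Mises (doubled angles).

    Angle convention matches the orientation module: theta is the fiber
    tangent from +x, y downward.  The image is non-negative; identical
    parameters and seed give a bit-identical image.
    """
    if size < 64:
        raise InvalidParameterError("size must be >= 64")
    if n_fibers < 1:
        raise InvalidParameterError("n_fibers must be >= 1")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    angles = sample_axial_von_mises(n_fibers, mu_deg, kappa, rng)
    if fiber_length is None:
        fiber_length = 0.5 * size
    img = np.zeros((size, size), dtype=float)
    centers = rng.uniform(0, size, size=(n_fibers, 2))  # (y, x)
    half = fiber_length / 2.0
    for (cy, cx), theta in zip(centers, angles):
        dx = np.cos(np.deg2rad(theta))
        dy = np.sin(np.deg2rad(theta))
        y0, x0 = cy - half * dy, cx - half * dx
        y1, x1 = cy + half * dy, cx + half * dx
        y0, x0, y1, x1 = (int(round(v)) for v in (y0, x0, y1, x1))
        rr, cc, val = line_aa(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        np.add.at(img, (rr[keep], cc[keep]), val[keep])
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma, mode="reflect")
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, None)
    return FiberImageTruth(
        image=img, fiber_angles_deg=angles, mu_deg=mu_deg % 180.0,
        kappa=kappa, seed=seed,
    )
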