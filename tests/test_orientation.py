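import numpy as np
import pytest
from scipy import ndimage

from wingpol.errors import EmptyHistogramError, InvalidParameterError
from wingpol.orientation import (
    OrientationHistogram, align_to_axis, circular_order,
    orientation_histogram, structure_tensor_orientation,
)
from wingpol.synth import make_fiber_image


def grating(theta_deg, size=128, wavelength=8.0):
    """Stripes whose tangent direction is theta (image coords, y down)."""
    y, x = np.mgrid[0:size, 0:size].astype(float)
    th = np.deg2rad(theta_deg)
    phase = (-x * np.sin(th) + y * np.cos(th)) * 2 * np.pi / wavelength
    return np.cos(phase)


@pytest.mark.parametrize("theta", [0.0, 30.0, 77.5, 120.0, 179.0])
def test_grating_orientation_recovered(theta):
    field = structure_tensor_orientation(grating(theta), 1.0, 4.0)
    good = field.coherence > 0.9
    assert good.mean() > 0.5
    est = np.median(field.theta[good])
    diff = min(abs(est - theta), 180 - abs(est - theta))
    assert diff < 0.5


def test_rotation_by_90_shifts_theta_by_90():
    img = grating(30.0)
    rot = np.rot90(img, k=-1)   # 90 deg clockwise in (y down) display
    f0 = structure_tensor_orientation(img, 1.0, 4.0)
    f1 = structure_tensor_orientation(rot, 1.0, 4.0)
    inner = (slice(20, -20), slice(20, -20))
    good = (f0.coherence[inner] > 0.9)
    d = (f1.theta[inner][good] - f0.theta[inner][good]) % 180
    assert np.median(np.abs(d - 90)) < 1.0


def test_white_noise_has_low_mean_coherence(rng):
    img = rng.standard_normal((128, 128))
    field = structure_tensor_orientation(img, 1.0, 4.0)
    assert field.coherence.mean() < 0.25


def test_constant_image_coherence_zero_no_error():
    field = structure_tensor_orientation(np.ones((64, 64)), 1.0, 4.0)
    assert np.all(field.coherence == 0.0)


def test_histogram_mass_in_single_bin_for_grating():
    field = structure_tensor_orientation(grating(30.0), 1.0, 4.0)
    hist = orientation_histogram(field, n_bins=36)
    assert np.isclose(hist.weights.sum(), 1.0)
    # mode within one bin of the true 30-degree orientation
    assert hist.weights.argmax() in (5, 6)
    assert hist.weights.max() > 0.4


def test_uniform_field_histogram_flat(rng):
    from wingpol.orientation import OrientationField
    n = 200
    theta = rng.uniform(0, 180, size=(n, n))
    field = OrientationField(theta=theta, coherence=np.ones((n, n)),
                             energy=np.ones((n, n)))
    hist = orientation_histogram(field, n_bins=36, weighting="none", min_coherence=0.0)
    assert hist.weights.max() <= 2.0 / 36


def test_empty_histogram_raises():
    field = structure_tensor_orientation(np.ones((64, 64)), 1.0, 4.0)
    with pytest.raises(EmptyHistogramError):
        orientation_histogram(field, min_coherence=0.5)


def test_align_to_axis_identity_and_cyclic_shift():
    w = np.zeros(36)
    w[6] = 1.0   # 30-35 deg
    hist = OrientationHistogram(weights=w, bin_width=5.0)
    assert np.array_equal(align_to_axis(hist, 0.0).weights, hist.weights)
    shifted = align_to_axis(hist, 90.0)
    assert shifted.weights.argmax() == (6 - 18) % 36
    assert shifted.axis_offset_deg == 90.0


class TestCircularOrder:
    def test_all_equal_angles_give_R_one(self):
        mean, R = circular_order([42.0] * 10)
        assert np.isclose(R, 1.0)
        assert np.isclose(mean, 42.0)

    def test_two_orthogonal_masses_give_R_zero(self):
        # doubled angles are antipodal: closed-form R = 0
        mean, R = circular_order([0.0, 90.0])
        assert np.isclose(R, 0.0, atol=1e-12)

    def test_uniform_R_shrinks_with_n(self, rng):
        _, R = circular_order(rng.uniform(0, 180, size=20000))
        assert R < 0.03

    def test_empty_raises(self):
        with pytest.raises(InvalidParameterError):
            circular_order([])


@pytest.mark.parametrize("kappa", [8.0, 32.0])
def test_fiber_image_mean_angle_recovered_within_2_degrees(kappa):
    truth = make_fiber_image(n_fibers=150, mu_deg=40.0, kappa=kappa,
                             size=256, noise_sd=0.02, seed=7)
    field = structure_tensor_orientation(truth.image, 1.0, 4.0)
    hist = orientation_histogram(field, n_bins=36)
    est = hist.mean_axial_deg()
    diff = min(abs(est - 40.0), 180 - abs(est - 40.0))
    assert diff < 2.0


def test_resultant_monotone_in_concentration():
    Rs = []
    for kappa in (2.0, 8.0, 32.0):
        truth = make_fiber_image(n_fibers=150, mu_deg=40.0, kappa=kappa,
                                 size=256, noise_sd=0.02, seed=11)
        field = structure_tensor_orientation(truth.image, 1.0, 4.0)
        hist = orientation_histogram(field, n_bins=36)
        Rs.append(hist.resultant())
    assert Rs[0] < Rs[1] < Rs[2]


def test_image_rotation_preserves_resultant():
    truth = make_fiber_image(n_fibers=150, mu_deg=10.0, kappa=16.0,
                             size=256, noise_sd=0.0, seed=3)
    f0 = structure_tensor_orientation(truth.image, 1.0, 4.0)
    f1 = structure_tensor_orientation(np.rot90(truth.image), 1.0, 4.0)
    h0 = orientation_histogram(f0, n_bins=36)
    h1 = orientation_histogram(f1, n_bins=36)
    assert abs(h0.resultant() - h1.resultant()) < 0.05
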