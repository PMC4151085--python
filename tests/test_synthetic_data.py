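import cmath

import numpy as np
import pytest

from wingpol.errors import InvalidParameterError
from wingpol.gradients import GradientSpec, make_gradient
from wingpol.synth import make_fiber_image, make_track_mixture


def independent_circular_mean_axial(angles_deg):
    """Doubled-angle circular mean, written with cmath only."""
    z = sum(cmath.exp(2j * cmath.pi * a / 180.0) for a in angles_deg)
    return (cmath.phase(z) * 180.0 / cmath.pi / 2.0) % 180.0


class TestFiberImages:
    def test_seed_reproducibility_bit_identical(self):
        a = make_fiber_image(seed=4)
        b = make_fiber_image(seed=4)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.fiber_angles_deg, b.fiber_angles_deg)

    def test_truth_mean_matches_requested_direction(self):
        truth = make_fiber_image(n_fibers=400, mu_deg=30.0, kappa=20.0,
                                 noise_sd=0.0, seed=1)
        est = independent_circular_mean_axial(truth.fiber_angles_deg)
        diff = min(abs(est - 30.0), 180.0 - abs(est - 30.0))
        # sampling error at kappa=20, n=400: sd ~ 0.65 deg
        assert diff < 2.0

    def test_kappa_zero_angles_roughly_uniform(self):
        truth = make_fiber_image(n_fibers=2000, kappa=0.0, seed=2, size=64)
        h, _ = np.histogram(truth.fiber_angles_deg, bins=18, range=(0, 180))
        assert h.min() > 0
        assert h.max() / h.mean() < 1.5

    def test_image_non_negative_and_angles_in_range(self):
        truth = make_fiber_image(noise_sd=0.2, seed=3)
        assert truth.image.min() >= 0.0
        assert np.all((truth.fiber_angles_deg >= 0) & (truth.fiber_angles_deg < 180))

    @pytest.mark.parametrize("kwargs", [
        dict(size=32), dict(noise_sd=-0.1), dict(n_fibers=0), dict(kappa=-1.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            make_fiber_image(**kwargs)


class TestTrackGenerator:
    def test_deterministic_for_seed(self):
        a = make_track_mixture(n=60, seed=8)
        b = make_track_mixture(n=60, seed=8)
        for ta, tb in zip(a.tracks, b.tracks):
            assert np.array_equal(ta.x, tb.x) and np.array_equal(ta.y, tb.y)

    def test_frame_interval_is_five_seconds(self):
        truth = make_track_mixture(n=5, seed=0)
        assert np.allclose(np.diff(truth.tracks[0].t), 5.0)

    def test_labels_align_with_tracks(self):
        truth = make_track_mixture(n=100, seed=0)
        assert len(truth.labels) == len(truth.tracks) == 100
        assert truth.labels.count("stuck") == 15

    def test_stuck_tracks_never_move(self):
        truth = make_track_mixture(n=50, f_trans=0.0, f_wander=0.0, f_stuck=1.0, seed=1)
        for tr in truth.tracks:
            assert np.all(tr.steps() == 0.0)

    def test_distal_probability_controls_drift(self):
        truth = make_track_mixture(n=400, f_trans=1.0, f_wander=0.0, f_stuck=0.0,
                                   p_distal=1.0, seed=2)
        for tr in truth.tracks:
            assert tr.net_vector()[0] > 0

    def test_min_frames_enforced(self):
        with pytest.raises(InvalidParameterError):
            make_track_mixture(n=5, n_frames=1)

    def test_truth_csv_round_trip(self, tmp_path):
        from wingpol.io import read_tracks, write_tracks
        truth = make_track_mixture(n=20, seed=3)
        path = tmp_path / "tracks.csv"
        write_tracks(path, truth.to_frame())
        back = read_tracks(path)
        assert len(back) == 20
        orig = {t.track_id: t for t in truth.tracks}
        for tr in back:
            assert np.allclose(tr.x, orig[tr.track_id].x)
            assert np.allclose(tr.t, orig[tr.track_id].t)


class TestGradients:
    def test_linear_strictly_monotone(self):
        g = make_gradient("linear", 30, high=1.0, low=0.0)
        assert np.all(np.diff(g.values) < 0)

    def test_step_has_exactly_two_levels(self):
        g = make_gradient("step", 30, high=1.0, low=0.1, step_column=8)
        assert set(np.round(g.values, 12)) == {1.0, 0.1}
        assert g.values[7] == 1.0 and g.values[8] == 0.1

    def test_zero_distal_is_exactly_zero_beyond_ramp(self):
        g = make_gradient("zero_distal", 30, high=1.0, ramp_columns=8)
        assert np.all(g.values[8:] == 0.0)
        assert g.values[0] == 1.0

    def test_steep_flat_constant_after_ramp(self):
        g = make_gradient("steep_flat", 30, high=1.0, low=0.1, ramp_columns=8)
        assert np.allclose(g.values[8:], 0.1)

    def test_mirror_reverses_values(self):
        g = make_gradient("linear", 10, high=2.0, low=0.0)
        assert np.allclose(g.mirrored().values, g.values[::-1])

    @pytest.mark.parametrize("kwargs", [
        dict(kind="nope", columns=10),
        dict(kind="linear", columns=1),
        dict(kind="step", columns=10, step_column=0),
        dict(kind="linear", columns=10, high=-1.0),
    ])
    def test_invalid_gradients_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            make_gradient(**kwargs)

    def test_negative_values_rejected_in_spec(self):
        with pytest.raises(InvalidParameterError):
            GradientSpec("custom", np.array([1.0, -0.5]))
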