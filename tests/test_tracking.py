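"""Streamline propagation, retention rules and FA computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tractconn.phantoms import PhantomSpec, make_tensor_phantom
from tractconn.tracking import (
    TensorVolume,
    TrackingParams,
    fa_of_tensor,
    streamline_length,
    track_from_seed,
    track_streamlines,
)


class TestFaOfTensor:
    @pytest.mark.parametrize(
        "eigs, expected",
        [
            ((1, 1, 1), 0.0),  # isotropy
            ((1, 0, 0), 1.0),  # degenerate stick
            ((3, 2, 1), 0.4629100498862757),  # hand evaluation of the closed form
        ],
    )
    def test_known_eigenvalues(self, eigs, expected):
        assert fa_of_tensor(np.diag(eigs)) == pytest.approx(expected, abs=1e-12)

    def test_zero_tensor_is_zero_by_convention(self):
        assert fa_of_tensor(np.zeros((3, 3))) == 0.0

    def test_rejects_asymmetric(self):
        t = np.eye(3)
        t[0, 1] = 0.5
        with pytest.raises(ValueError):
            fa_of_tensor(t)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 10.0), min_size=3, max_size=3), st.integers(0, 10**6))
    def test_fa_in_unit_interval_and_rotation_invariant(self, eigs, seed):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = q @ np.diag(eigs) @ q.T
        t = (t + t.T) / 2
        fa = fa_of_tensor(t)
        assert 0.0 <= fa <= 1.0 + 1e-12
        assert fa == pytest.approx(fa_of_tensor(np.diag(eigs)), abs=1e-8)


class TestStreamlineLength:
    def test_three_four_five(self):
        assert streamline_length([(0, 0, 0), (3, 4, 0)]) == pytest.approx(5.0)

    def test_collinear_additivity(self):
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0)]
        assert streamline_length(pts) == pytest.approx(2.0)

    def test_quarter_arc_polyline(self):
        theta = np.linspace(0, np.pi / 2, 100)
        pts = np.c_[20 * np.cos(theta), 20 * np.sin(theta), np.zeros_like(theta)]
        assert streamline_length(pts) == pytest.approx(np.pi / 2 * 20, rel=1e-3)

    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            streamline_length([(0, 0, 0)])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_length_is_translation_invariant_and_scales(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3))
        base = streamline_length(pts)
        assert streamline_length(pts + 5.0) == pytest.approx(base, rel=1e-9)
        assert streamline_length(3.0 * pts) == pytest.approx(3 * base, rel=1e-9)


class TestSlabTracking:
    def test_interior_seed_is_straight_and_spans_thickness(self, slab_volume):
        sl = track_from_seed(slab_volume, (12.0, 6.0, 6.0))
        assert sl.retained
        # straight line: y and z constant along the slab axis
        assert np.ptp(sl.points[:, 1]) == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(sl.points[:, 2]) == pytest.approx(0.0, abs=1e-9)
        assert abs(sl.length - 16.0) <= 2 * 0.5  # within 2 step sizes

    def test_seed_outside_white_mask_is_an_error(self, slab_volume):
        with pytest.raises(ValueError):
            track_from_seed(slab_volume, (0.5, 0.5, 0.5))

    def test_four_streamlines_per_white_voxel(self, slab_volume, slab_tractogram):
        assert len(slab_tractogram) == 4 * int(slab_volume.white_mask.sum())

    def test_interior_retention_and_length_window(self, slab_volume, slab_tractogram):
        retained = slab_tractogram.retained
        assert len(retained) / len(slab_tractogram) > 0.9
        for sl in retained:
            assert 3.0 <= sl.length <= 1000.0
            for endpoint in (sl.points[0], sl.points[-1]):
                assert slab_volume.grey_mask[slab_volume.voxel_of(endpoint)]

    def test_thin_slab_below_min_length_not_retained(self):
        spec = PhantomSpec(
            shape=(12, 8, 8),
            geometry="straight_slab",
            geometry_params={"thickness": 2.0, "half_width": 2.0},
            fa_target=0.7,
        )
        vol = make_tensor_phantom(spec)
        tg = track_streamlines(vol)
        assert len(tg) > 0
        assert len(tg.retained) == 0  # every fiber is shorter than 3 mm

    def test_determinism(self, slab_volume):
        a = track_streamlines(slab_volume)
        b = track_streamlines(slab_volume)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.points, sb.points)
            assert sa.retained == sb.retained

    def test_global_eigenvector_sign_flip_is_irrelevant(self, slab_volume):
        flipped = TensorVolume(
            tensors=slab_volume.tensors.copy(),
            white_mask=slab_volume.white_mask,
            grey_mask=slab_volume.grey_mask,
            voxel_size=slab_volume.voxel_size,
        )
        flipped._prepare_fields()
        flipped.principal_dir = -flipped.principal_dir
        a = track_from_seed(slab_volume, (12.0, 6.0, 6.0))
        b = track_from_seed(flipped, (12.0, 6.0, 6.0))
        assert a.retained == b.retained
        assert a.length == pytest.approx(b.length)
        # same point set up to traversal direction
        assert np.allclose(sorted(map(tuple, a.points)), sorted(map(tuple, b.points)))


class TestTerminationRules:
    def test_ninety_degree_crossing_terminates_at_interface(self):
        spec = PhantomSpec(
            shape=(24, 24, 8),
            geometry="crossing_interface",
            geometry_params={"thickness": 16.0, "half_width": 8.0},
            fa_target=0.7,
        )
        vol = make_tensor_phantom(spec)
        # seed in the x-oriented half; the 90 degree turn exceeds max_angle 60
        sl = track_from_seed(vol, (6.0, 12.0, 4.0))
        assert not sl.retained
        interface_x = 12.0
        assert sl.points[:, 0].max() <= interface_x + 1.0

    def test_isotropic_volume_yields_no_retained_fibers(self):
        spec = PhantomSpec(shape=(8, 8, 8), geometry="straight_slab", fa_target=0.0)
        vol = make_tensor_phantom(spec)
        tg = track_streamlines(vol)
        assert len(tg.retained) == 0

    def test_max_length_cap_terminates_growth(self, slab_volume):
        params = TrackingParams(max_length=10.0, min_length=1.0)
        sl = track_from_seed(slab_volume, (12.0, 6.0, 6.0), params)
        assert sl.length <= 10.0
        assert not sl.retained  # capped before reaching the grey caps

    def test_empty_white_mask_warns_and_returns_empty(self):
        vol = TensorVolume(
            tensors=np.zeros((4, 4, 4, 3, 3)),
            white_mask=np.zeros((4, 4, 4), bool),
            grey_mask=np.zeros((4, 4, 4), bool),
        )
        with pytest.warns(UserWarning):
            tg = track_streamlines(vol)
        assert len(tg) == 0


def test_quarter_arc_length_matches_analytic_arc():
    spec = PhantomSpec(
        shape=(30, 30, 12),
        geometry="quarter_arc",
        geometry_params={"radius": 12.0, "tube_radius": 2.0},
        fa_target=0.7,
    )
    vol = make_tensor_phantom(spec)
    tg = track_streamlines(vol)
    lengths = [s.length for s in tg.retained]
    assert len(lengths) > 50
    assert np.mean(lengths) == pytest.approx(np.pi / 2 * 12.0, rel=0.05)
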