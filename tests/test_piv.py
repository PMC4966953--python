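import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cytostream.piv import (
    FLAG_FLAT,
    FLAG_RANGE,
    FLAG_SINGULAR,
    ImageStack,
    average_fields,
    integer_displacement,
    piv_field,
    subpixel_displacement,
)


@pytest.fixture(scope="module")
def texture():
    rng = np.random.default_rng(0)
    return gaussian_filter(rng.uniform(0, 1, (1, 128, 128)), (0, 1.5, 1.5))


@pytest.fixture(scope="module")
def texture3d():
    rng = np.random.default_rng(1)
    return gaussian_filter(rng.uniform(0, 1, (9, 96, 96)), (0.8, 1.5, 1.5))


class TestIntegerDisplacement:
    def test_no_motion(self, texture):
        s, flags = integer_displacement(ImageStack(texture), ImageStack(texture), (64, 64, 0))
        assert tuple(s) == (0, 0, 0)
        assert flags == 0

    @pytest.mark.parametrize("dx,dy", [(3, -2), (-4, 4), (1, 0), (0, 5)])
    def test_constructed_translation(self, texture, dx, dy):
        moved = np.roll(np.roll(texture, dy, axis=1), dx, axis=2)
        s, flags = integer_displacement(ImageStack(texture), ImageStack(moved), (64, 64, 0))
        assert (s.x, s.y, s.z) == (dx, dy, 0)

    def test_axial_shift_in_3d(self, texture3d):
        moved = np.roll(np.roll(texture3d, 1, axis=0), 3, axis=2)
        s, _ = integer_displacement(ImageStack(texture3d), ImageStack(moved), (48, 48, 4))
        assert (s.x, s.y, s.z) == (3, 0, 1)

    def test_out_of_reach_shift_clips_and_flags(self):
        # cumulative search reach is 5+2+1 = 8 px; a 10 px shift of a
        # single blob walks to the boundary of the reach and is flagged
        y, x = np.mgrid[0:128, 0:128]
        blob = np.exp(-(((x - 64.0) ** 2 + (y - 64.0) ** 2) / (2 * 6.0**2)))
        moved = np.exp(-(((x - 74.0) ** 2 + (y - 64.0) ** 2) / (2 * 6.0**2)))
        s, flags = integer_displacement(
            ImageStack(blob[None]), ImageStack(moved[None]), (64, 64, 0)
        )
        assert s.x == 8 and s.y == 0
        assert flags & FLAG_RANGE

    def test_flat_window_flagged(self):
        flat = np.ones((1, 128, 128))
        s, flags = integer_displacement(ImageStack(flat), ImageStack(flat), (64, 64, 0))
        assert flags & FLAG_FLAT
        assert tuple(s) == (0, 0, 0)

    def test_window_out_of_bounds_rejected(self, texture):
        with pytest.raises(ValueError):
            integer_displacement(ImageStack(texture), ImageStack(texture), (5, 64, 0))

    def test_reverse_pair_antisymmetry(self, texture):
        moved = np.roll(np.roll(texture, -2, axis=1), 3, axis=2)
        s_fwd, _ = integer_displacement(ImageStack(texture), ImageStack(moved), (64, 64, 0))
        s_rev, _ = integer_displacement(ImageStack(moved), ImageStack(texture), (64, 64, 0))
        assert (s_rev.x, s_rev.y, s_rev.z) == (-s_fwd.x, -s_fwd.y, -s_fwd.z)

    def test_translation_equivariance(self, texture):
        # translating BOTH stacks identically leaves the displacement field
        # unchanged
        moved = np.roll(texture, 2, axis=2)
        shift_both = lambda a: np.roll(a, 5, axis=1)
        s1, _ = integer_displacement(ImageStack(texture), ImageStack(moved), (64, 64, 0))
        s2, _ = integer_displacement(
            ImageStack(shift_both(texture)), ImageStack(shift_both(moved)), (64, 64, 0)
        )
        assert tuple(s1) == tuple(s2)


class TestSubpixel:
    def test_identical_windows_zero(self, texture):
        d, flags = subpixel_displacement(texture[0, :33, :33], texture[0, :33, :33])
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        assert not flags & FLAG_SINGULAR

    def test_gaussian_blob_fractional_shift(self):
        y, x = np.mgrid[0:33, 0:33]
        blob = np.exp(-(((x - 16.0) ** 2 + (y - 16.0) ** 2) / (2 * 3.0**2)))
        moved = np.exp(-(((x - 16.4) ** 2 + (y - 16.0) ** 2) / (2 * 3.0**2)))
        d, flags = subpixel_displacement(blob, moved)
        assert d[0] == pytest.approx(0.4, abs=0.1)
        assert abs(d[1]) < 0.05 and d[2] == 0.0

    def test_aperture_problem_flagged_but_resolved_direction_ok(self):
        ramp = np.tile(np.linspace(0, 1, 33), (33, 1))
        d, flags = subpixel_displacement(ramp, ramp - 0.5 / 32)
        assert flags & FLAG_SINGULAR
        assert d[0] == pytest.approx(0.5, abs=0.05)
        assert d[1] == 0.0 and d[2] == 0.0


class TestPivField:
    def test_uniform_translation_and_um_conversion(self, texture):
        # 2 px at 0.26 um/px over 5 s -> 0.104 um/s along x
        f = piv_field(
            ImageStack(texture), ImageStack(np.roll(texture, 2, axis=2), time=5.0)
        )
        assert f.valid.all()
        np.testing.assert_allclose(f.displacement[:, 0], 2.0, atol=0.05)
        np.testing.assert_allclose(f.velocity[:, 0], 0.104, atol=0.003)
        np.testing.assert_allclose(f.velocity[:, 2], 0.0, atol=1e-12)

    def test_zero_motion_zero_field(self, texture):
        f = piv_field(ImageStack(texture), ImageStack(texture, time=1.0))
        np.testing.assert_allclose(f.displacement, 0.0, atol=1e-9)

    def test_2d_input_collapses_axial_component(self, texture):
        f = piv_field(ImageStack(texture), ImageStack(np.roll(texture, 1, axis=1), time=1.0))
        np.testing.assert_allclose(f.displacement[:, 2], 0.0)

    def test_mismatched_shapes_rejected(self, texture):
        with pytest.raises(ValueError):
            piv_field(ImageStack(texture), ImageStack(texture[:, :64, :]), dt=1.0)

    def test_nonpositive_dt_rejected(self, texture):
        with pytest.raises(ValueError):
            piv_field(ImageStack(texture), ImageStack(texture), dt=0.0)


class TestAverageFields:
    def _uniform_field(self, texture, px, dt=1.0):
        return piv_field(
            ImageStack(texture), ImageStack(np.roll(texture, px, axis=2), time=dt)
        )

    def test_identical_fields_unchanged(self, texture):
        f = self._uniform_field(texture, 2)
        avg = average_fields([f, f, f])
        np.testing.assert_allclose(avg.velocity, f.velocity)

    def test_field_plus_negation_cancels(self, texture):
        f1 = self._uniform_field(texture, 2)
        f2 = self._uniform_field(texture, -2)
        avg = average_fields([f1, f2])
        np.testing.assert_allclose(avg.velocity[:, 0], 0.0, atol=0.01)

    def test_noise_averages_down_as_clt(self, texture):
        rng = np.random.default_rng(2)
        base = self._uniform_field(texture, 2)
        sigma = 0.05
        fields = []
        for _ in range(50):
            f = piv_field(
                ImageStack(texture), ImageStack(np.roll(texture, 2, axis=2), time=1.0)
            )
            f.velocity = f.velocity + sigma * rng.standard_normal(f.velocity.shape)
            fields.append(f)
        avg = average_fields(fields)
        resid = avg.velocity - base.velocity
        assert np.abs(resid).std() < 3 * sigma / np.sqrt(50)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_fields([])

    def test_mismatched_grids_rejected(self, texture):
        f1 = self._uniform_field(texture, 1)
        f2 = piv_field(
            ImageStack(texture), ImageStack(texture, time=1.0), grid_spacing=17
        )
        with pytest.raises(ValueError):
            average_fields([f1, f2])


def test_image_stack_validation():
    with pytest.raises(ValueError):
        ImageStack(-np.ones((4, 4)))
    with pytest.raises(ValueError):
        ImageStack(np.ones((4, 4)), voxel_size=(0.26, 0.0, 1.0))
    with pytest.raises(ValueError):
        ImageStack(np.ones(4))


def test_tiff_roundtrip(tmp_path, texture):
    stack = ImageStack(texture)
    path = tmp_path / "stack.tif"
    stack.to_tiff(path)
    back = ImageStack.from_tiff(path)
    np.testing.assert_allclose(back.intensities, texture, rtol=1e-6)
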