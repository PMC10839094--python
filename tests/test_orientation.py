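"""Structure tensor, lesion ellipse, ring ROIs, and the alignment index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from retglia import orientation as ori
from retglia import synthetic_data as sd


def _line_image(angle_deg, size=256, half_len=100):
    """A thin bright line through the image center at a Cartesian angle."""
    img = np.zeros((size, size))
    t = np.linspace(-half_len, half_len, 8 * half_len + 1)
    xs = np.round(size / 2 + t * math.cos(math.radians(angle_deg))).astype(int)
    ys = np.round(size / 2 - t * math.sin(math.radians(angle_deg))).astype(int)
    img[ys, xs] = 255.0
    return gaussian_filter(img, 1.0)


def _fourier_orientation(img):
    """Independent spectral oracle: the axial orientation of a line is
    perpendicular to the principal axis of its power spectrum."""
    f = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean()))) ** 2
    n = img.shape[0]
    yy, xx = np.mgrid[0:n, 0:n]
    u = xx - n // 2
    v = -(yy - n // 2)  # Cartesian frequency coordinates
    keep = (u**2 + v**2) > 4  # drop the DC neighbourhood
    w = f * keep
    # axial mean of the doubled spectral angle
    ang = 2 * np.arctan2(v, u)
    c = float(np.sum(w * np.cos(ang)))
    s = float(np.sum(w * np.sin(ang)))
    spec_axis = math.degrees(0.5 * math.atan2(s, c))
    return (spec_axis + 90.0) % 180.0


class TestStructureTensor:
    def test_vertical_grating_is_90_degrees_and_coherent(self):
        x = np.arange(256)
        img = 120 + 100 * np.sin(2 * np.pi * x / 16)[None, :] * np.ones((256, 1))
        f = ori.structure_tensor_field(img, 2, 10)
        inner = (slice(30, -30),) * 2
        assert np.median(f.orientation_deg[inner]) == pytest.approx(90.0, abs=0.5)
        assert np.mean(f.coherency[inner]) > 0.95

    def test_isotropic_noise_has_low_coherency(self):
        rng = np.random.default_rng(0)
        f = ori.structure_tensor_field(rng.normal(100, 20, (256, 256)), 2, 20)
        assert np.mean(f.coherency[30:-30, 30:-30]) < 0.1

    @pytest.mark.parametrize("angle", [10.0, 30.0, 75.0, 120.0, 160.0])
    def test_line_orientation_matches_fourier_oracle(self, angle):
        img = _line_image(angle)
        f = ori.structure_tensor_field(img, 2, 10)
        strong = f.energy > 0.1 * f.energy.max()
        ang = np.radians(2 * f.orientation_deg[strong])
        measured = math.degrees(
            0.5 * math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        ) % 180.0
        oracle = _fourier_orientation(img)
        d = abs(measured - oracle) % 180
        assert min(d, 180 - d) < 1.0
        d2 = abs(measured - angle) % 180
        assert min(d2, 180 - d2) < 1.0

    def test_coherency_bounds(self):
        rng = np.random.default_rng(1)
        f = ori.structure_tensor_field(rng.uniform(0, 255, (64, 64)), 1, 4)
        assert f.coherency.min() >= 0.0 and f.coherency.max() <= 1.0

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            ori.structure_tensor_field(np.zeros(10), 2, 10)


class TestLesionEllipse:
    def test_disc_moments(self):
        yy, xx = np.mgrid[0:512, 0:512]
        mask = np.hypot(xx - 255.5, yy - 255.5) <= 200.0
        e = ori.fit_lesion_ellipse(mask)
        assert e.a == pytest.approx(200.0, rel=0.01)
        assert e.b == pytest.approx(200.0, rel=0.01)
        assert e.center == pytest.approx((255.5, 255.5), abs=0.1)

    def test_axis_aligned_ellipse(self):
        yy, xx = np.mgrid[0:700, 0:700]
        mask = ((xx - 349.5) / 300.0) ** 2 + ((yy - 349.5) / 200.0) ** 2 <= 1.0
        e = ori.fit_lesion_ellipse(mask)
        assert e.a == pytest.approx(300.0, rel=0.01)
        assert e.b == pytest.approx(200.0, rel=0.01)
        assert min(e.tilt_deg, 180 - e.tilt_deg) < 2.0

    def test_ellipse_area_equals_mask_area(self):
        yy, xx = np.mgrid[0:300, 0:300]
        mask = ((xx - 149.5) / 90.0) ** 2 + ((yy - 149.5) / 50.0) ** 2 <= 1.0
        e = ori.fit_lesion_ellipse(mask)
        assert math.pi * e.a * e.b == pytest.approx(mask.sum(), rel=1e-6)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            ori.fit_lesion_ellipse(np.zeros((10, 10), dtype=bool))
        single = np.zeros((10, 10), dtype=bool)
        single[5, 5] = True
        with pytest.raises(ValueError):
            ori.fit_lesion_ellipse(single)


class TestRingRois:
    def test_circle_four_rois_at_cardinal_points(self):
        e = ori.Ellipse(center=(0.0, 0.0), a=100.0, b=100.0, tilt_deg=0.0)
        ring = ori.place_ring_rois(e, n_rois=4)
        expected = np.array([[100, 0], [0, -100], [-100, 0], [0, 100]], dtype=float)
        assert np.allclose(ring.centers, expected, atol=1e-9)

    def test_chord_spacing_on_circle(self):
        e = ori.Ellipse(center=(5.0, -3.0), a=80.0, b=80.0, tilt_deg=30.0)
        ring = ori.place_ring_rois(e, n_rois=8)
        d = np.linalg.norm(np.diff(np.vstack([ring.centers, ring.centers[:1]]), axis=0), axis=1)
        assert np.allclose(d, 2 * 80.0 * math.sin(math.pi / 8))

    def test_centers_satisfy_ellipse_equation(self):
        e = ori.Ellipse(center=(10.0, 20.0), a=200.0, b=100.0, tilt_deg=25.0)
        ring = ori.place_ring_rois(e, n_rois=12)
        t = math.radians(e.tilt_deg)
        for cx, cy in ring.centers:
            dx, dy = cx - e.center[0], cy - e.center[1]
            # rotate back into the ellipse frame (Cartesian tilt, y down)
            u = dx * math.cos(t) - dy * math.sin(t)
            v = dx * math.sin(t) + dy * math.cos(t)
            assert (u / e.a) ** 2 + (v / e.b) ** 2 == pytest.approx(1.0, abs=1e-9)


class TestRoiOrientation:
    def test_single_orientation_full_coherency(self):
        x = np.arange(256)
        img = 120 + 100 * np.sin(2 * np.pi * x / 16)[None, :] * np.ones((256, 1))
        f = ori.structure_tensor_field(img, 2, 10)
        o, c = ori.roi_orientation(f, (128.0, 128.0), 100.0)
        assert o == pytest.approx(90.0, abs=1.0)
        assert c > 0.95

    def test_orthogonal_populations_cancel(self):
        """Two equal-energy fully coherent orthogonal populations in one
        ROI have zero aggregate coherency."""
        n = 64
        field = ori.OrientationField(
            orientation_deg=np.where(np.arange(n)[:, None] < n // 2, 0.0, 90.0)
            * np.ones((1, n)),
            coherency=np.ones((n, n)),
            energy=np.ones((n, n)),
            grad_sigma_um=2.0,
            tensor_sigma_um=10.0,
        )
        _, c = ori.roi_orientation(field, (31.5, 31.5), 40.0)
        assert c == pytest.approx(0.0, abs=0.05)

    def test_drawn_cell_truth_recovered(self):
        """Drawn orientation recovered within 3 deg and coherency within
        0.1 over 50 seeded single-cell fields."""
        errs_o, errs_c = [], []
        for s in range(50):
            spec = sd.MicrogliaFieldSpec(
                n_cells=1, coherency_range=(0.7, 0.7), lesion_radius_um=60.0,
                placement_band_um=(10.0, 40.0), field_size_um=400.0,
                angular_jitter_deg=180.0, render_core_debris=False, seed=s,
            )
            mf = sd.generate_microglia_field(spec)
            cell = mf.cells.iloc[0]
            f = ori.structure_tensor_field(mf.image.astype(float), 2, 10)
            o, c = ori.roi_orientation(f, (cell.x_um, cell.y_um), 100.0)
            d = abs(o - cell.orientation_deg) % 180
            errs_o.append(min(d, 180 - d))
            errs_c.append(abs(c - 0.7))
        assert np.median(errs_o) < 3.0
        assert np.median(errs_c) < 0.1

    def test_roi_outside_image_rejected(self):
        f = ori.structure_tensor_field(np.zeros((64, 64)), 2, 4)
        with pytest.raises(ValueError):
            ori.roi_orientation(f, (60.0, 32.0), 20.0)


class TestAlignmentIndex:
    def test_perfectly_radial_scores_one(self):
        rois = []
        for k in range(8):
            phi = 2 * math.pi * k / 8
            center = (100 * math.cos(phi), -100 * math.sin(phi))
            radial = math.degrees(phi) % 180.0
            rois.append((radial, 1.0, center))
        res = ori.alignment_index(rois, (0.0, 0.0))
        assert res.index == pytest.approx(1.0, abs=1e-12)

    def test_perfectly_tangential_scores_zero(self):
        rois = []
        for k in range(8):
            phi = 2 * math.pi * k / 8
            center = (100 * math.cos(phi), -100 * math.sin(phi))
            tangential = (math.degrees(phi) + 90.0) % 180.0
            rois.append((tangential, 1.0, center))
        res = ori.alignment_index(rois, (0.0, 0.0))
        assert res.index == pytest.approx(0.0, abs=1e-12)

    def test_weighted_mixture_hand_value(self):
        """(dtheta 0, c 0.8) with (dtheta 90, c 0.2) gives 0.8."""
        rois = [
            (0.0, 0.8, (-100.0, 0.0)),  # radial direction is 0 deg
            (90.0, 0.2, (-50.0, 0.0)),
        ]
        res = ori.alignment_index(rois, (0.0, 0.0))
        assert res.index == pytest.approx(0.8)

    def test_uniform_orientations_average_half(self):
        """Many uniformly oriented ROIs average to the 0.5 random baseline."""
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(400):
            rois = [
                (float(rng.uniform(0, 180)), 1.0, (100.0, 0.0)),
            ]
            vals.append(ori.alignment_index(rois, (0.0, 0.0)).index)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.04)

    def test_zero_coherency_everywhere_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            ori.alignment_index([(10.0, 0.0, (1.0, 0.0))], (0.0, 0.0))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0, 180), st.floats(0.01, 1)), min_size=1, max_size=12),
           st.floats(-180, 180))
    def test_index_bounded_and_rotation_invariant(self, oris, rot_deg):
        """The index stays in [0, 1] and is unchanged when the whole zone
        (orientations and geometry) rotates about the lesion center."""
        rois = []
        rois_rot = []
        rot = math.radians(rot_deg)
        for k, (o, c) in enumerate(oris):
            phi = 2 * math.pi * k / len(oris)
            center = (80 * math.cos(phi), -80 * math.sin(phi))
            rois.append((o, c, center))
            phi2 = phi + rot
            center2 = (80 * math.cos(phi2), -80 * math.sin(phi2))
            rois_rot.append(((o + rot_deg) % 180.0, c, center2))
        a = ori.alignment_index(rois, (0.0, 0.0)).index
        b = ori.alignment_index(rois_rot, (0.0, 0.0)).index
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(b, abs=1e-9)


class TestZonePipeline:
    def test_radial_zones_score_high_and_monotone_in_kappa(self):
        means = []
        for kappa in (0.0, 4.0, 100.0):
            vals = []
            for s in range(8):
                mf = sd.generate_microglia_field(
                    sd.MicrogliaFieldSpec(alignment_model="radial_von_mises",
                                          kappa=kappa, seed=500 + s)
                )
                vals.append(ori.score_zone(mf.image, mf.lesion_mask).index)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert means[2] > 0.9

    def test_max_projection_of_stack_accepted(self):
        mf = sd.generate_microglia_field(sd.MicrogliaFieldSpec(seed=1))
        stack = np.stack([mf.image, np.zeros_like(mf.image)])
        res = ori.score_zone(stack, mf.lesion_mask)
        assert 0.0 <= res.index <= 1.0


class TestTimecourse:
    @staticmethod
    def _groups(shift):
        rng = np.random.default_rng(0)
        base = np.clip(rng.normal(0.5, 0.05, 5), 0, 1)
        return {
            0.0: list(base),
            0.5: list(np.clip(base + shift + rng.normal(0, 0.02, 5), 0, 1)),
            1.0: list(np.clip(base + shift + rng.normal(0, 0.02, 5), 0, 1)),
        }

    def test_identical_groups_not_significant(self):
        groups = {0.0: [0.5, 0.52, 0.48], 1.0: [0.5, 0.52, 0.48]}
        table = ori.orientation_timecourse(groups)
        assert not table.loc[table.timepoint_h == 1.0, "significant"].item()

    def test_shifted_groups_significant(self):
        table = ori.orientation_timecourse(self._groups(0.25))
        later = table[table.timepoint_h > 0]
        assert later["significant"].all()
        assert (later["mean_index"] > 0.7).all()

    def test_unequal_groups_fall_back_to_welch(self):
        groups = {0.0: [0.5, 0.45, 0.55, 0.5], 2.0: [0.8, 0.75, 0.82]}
        table = ori.orientation_timecourse(groups)
        assert table.loc[table.timepoint_h == 2.0, "test"].item() == "welch"

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            ori.orientation_timecourse({1.0: [0.5, 0.6]})

    def test_single_zone_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            ori.orientation_timecourse({0.0: [0.5, 0.6], 1.0: [0.9]})
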