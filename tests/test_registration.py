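"""Fiducial detection, affine estimation, resampling, stack registration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slicerecon as sr
from slicerecon.registration import RegistrationError
from slicerecon.phantom import FIDUCIAL_LEVEL

from conftest import stack_spec


TRIANGLE = np.array([[10.0, 12.0], [60.0, 15.0], [20.0, 55.0]])


class TestAffine2D:
    def test_compose_with_inverse_is_identity(self):
        t = sr.Affine2D.translation(3.2, -1.7) @ sr.Affine2D.rotation(0.3, (10, 20))
        assert np.abs((t @ t.inverse()).matrix - np.eye(3)).max() < 1e-9

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(RegistrationError, match="invertible"):
            sr.Affine2D(np.array([[1, 1, 0], [2, 2, 0], [0, 0, 1.0]]))
        with pytest.raises(RegistrationError, match="last row"):
            sr.Affine2D(np.array([[1, 0, 0], [0, 1, 0], [0, 0, 2.0]]))

    def test_json_roundtrip(self):
        t = sr.Affine2D.rotation(0.2, (5, 5))
        assert np.array_equal(sr.Affine2D.from_json(t.to_json()).matrix, t.matrix)


class TestEstimateAffine:
    def test_identity_and_translation(self):
        src = sr.FiducialSet(TRIANGLE)
        assert sr.estimate_affine(src, sr.FiducialSet(TRIANGLE)).is_identity()
        t = sr.estimate_affine(src, sr.FiducialSet(TRIANGLE + [3.0, -2.0]))
        expected = np.eye(3)
        expected[:2, 2] = (3.0, -2.0)
        assert np.abs(t.matrix - expected).max() < 1e-9
        assert t.residual_rms < 1e-12

    def test_exact_recovery_of_shear_scale(self):
        a = sr.Affine2D(np.array([[1.3, 0.4, -5.0], [0.1, 0.8, 2.0], [0, 0, 1.0]]))
        t = sr.estimate_affine(sr.FiducialSet(TRIANGLE), sr.FiducialSet(a.apply(TRIANGLE)))
        assert np.abs(t.matrix - a.matrix).max() < 1e-9

    def test_degenerate_inputs_rejected(self):
        collinear = np.array([[0.0, 0.0], [10.0, 10.0], [20.0, 20.0]])
        with pytest.raises(RegistrationError, match="collinear"):
            sr.FiducialSet(collinear)
        four = np.vstack([TRIANGLE, [40.0, 40.0]])
        with pytest.raises(RegistrationError, match="mismatch"):
            sr.estimate_affine(sr.FiducialSet(TRIANGLE), sr.FiducialSet(four))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-0.5, 0.5),
        tx=st.floats(-20, 20),
        ty=st.floats(-20, 20),
        sx=st.floats(0.7, 1.4),
        shear=st.floats(-0.3, 0.3),
    )
    def test_estimation_consistency_property(self, angle, tx, ty, sx, shear):
        """estimate(T(P) -> P) composed with T is the identity (1e-9)."""
        m = np.array([[sx * np.cos(angle), -np.sin(angle) + shear, tx],
                      [np.sin(angle), np.cos(angle), ty],
                      [0, 0, 1.0]])
        t_true = sr.Affine2D(m)
        est = sr.estimate_affine(
            sr.FiducialSet(t_true.apply(TRIANGLE)), sr.FiducialSet(TRIANGLE)
        )
        assert np.abs((est @ t_true).matrix - np.eye(3)).max() < 1e-9


class TestResample:
    def test_identity_is_exact(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (20, 24))
        out = sr.resample_slice(img, sr.Affine2D.identity())
        assert np.array_equal(out, img)

    def test_integer_translation_shifts_and_fills(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (16, 16))
        out = sr.resample_slice(img, sr.Affine2D.translation(5.0, 0.0), fill_value=-1.0)
        assert np.array_equal(out[:, 5:], img[:, :-5])
        assert np.all(out[:, :5] == -1.0)

    def test_roundtrip_loss_bounded_on_smooth_image(self):
        ys, xs = np.mgrid[0:64, 0:64]
        smooth = 120 + 80 * np.sin(xs / 9.0) * np.cos(ys / 11.0)
        t = sr.Affine2D.translation(1.6, -2.3) @ sr.Affine2D.rotation(0.05, (32, 32))
        back = sr.resample_slice(sr.resample_slice(smooth, t), t.inverse())
        interior = (slice(8, -8), slice(8, -8))
        assert np.abs(back[interior] - smooth[interior]).max() < 2.0


class TestDetection:
    def test_noiseless_centroids_within_half_pixel(self):
        stack, truth = sr.generate_slice_stack(stack_spec())
        pts = sr.detect_fiducials(stack.images[0]).points
        true_sorted = truth.base_centers_px[
            np.lexsort((truth.base_centers_px[:, 0], truth.base_centers_px[:, 1]))
        ]
        assert np.linalg.norm(pts - true_sorted, axis=1).max() < 0.5

    def test_blank_slice_reports_found_count(self):
        with pytest.raises(RegistrationError, match="found 0 of 3"):
            sr.detect_fiducials(np.zeros((32, 32)))

    def test_noisy_centroids_within_one_pixel(self):
        stack, truth = sr.generate_slice_stack(stack_spec(noise_sigma=5.0, seed=9))
        true_sorted = truth.base_centers_px[
            np.lexsort((truth.base_centers_px[:, 0], truth.base_centers_px[:, 1]))
        ]
        for img in stack.images[:5]:
            pts = sr.detect_fiducials(img).points
            assert np.linalg.norm(pts - true_sorted, axis=1).max() < 1.0

    def test_tiny_specks_ignored(self):
        img = np.zeros((64, 64))
        img[5, 5] = FIDUCIAL_LEVEL  # below the 4 px component floor
        for cx, cy in [(20, 10), (50, 30), (15, 50)]:
            img[cy : cy + 3, cx : cx + 3] = FIDUCIAL_LEVEL
        pts = sr.detect_fiducials(img).points
        assert len(pts) == 3
        assert not np.any(np.all(np.isclose(pts, [5, 5], atol=1.5), axis=1))


class TestRegisterStack:
    def test_jitter_free_yields_identity(self):
        stack, _ = sr.generate_slice_stack(stack_spec())
        _, transforms = sr.register_stack(stack)
        for t in transforms:
            assert np.abs(t.matrix - np.eye(3)).max() < 1e-6

    def test_known_jitter_recovered(self, rigid_jitter):
        stack, truth = sr.generate_slice_stack(stack_spec(jitter=rigid_jitter))
        _, transforms = sr.register_stack(stack, reference_index=0)
        for t, j in zip(transforms, truth.transforms):
            assert sr.transform_mean_displacement(t, j.inverse(), stack.shape) < 0.1

    def test_registration_reduces_fiducial_scatter(self, rigid_jitter):
        stack, _ = sr.generate_slice_stack(stack_spec(jitter=rigid_jitter, noise_sigma=5.0, seed=4))
        registered, _ = sr.register_stack(stack)
        pre = np.array([sr.detect_fiducials(im).points for im in stack.images]).std(axis=0)
        post = np.array(
            [sr.detect_fiducials(im).points for im in registered.images]
        ).std(axis=0)
        assert post.max() <= pre.max()

    def test_single_slice_stack_rejected(self):
        with pytest.raises(Exception, match=">= 2"):
            sr.SliceStack(images=[np.zeros((8, 8))])

    def test_failed_detection_names_slice(self):
        stack, _ = sr.generate_slice_stack(stack_spec())
        images = [im.copy() for im in stack.images]
        images[3][:] = 0.0
        broken = sr.SliceStack(images, stack.pixel_size, stack.slice_spacing)
        with pytest.raises(RegistrationError, match="slice_0003"):
            sr.register_stack(broken)
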