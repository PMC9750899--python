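"""Affine optical flow: ROI weights, per-ROI and pooled fits, propagation."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import ndimage

from laatrack import (
    AffineParams,
    Contour,
    TrackerConfig,
    estimate_global_affine,
    estimate_roi_affine,
    gaussian_roi_weights,
    propagation_plan,
    synth_speckle_texture,
    track_pair,
)

SPACING = 0.2  # mm/px used throughout


@pytest.fixture(scope="module")
def speckle():
    return synth_speckle_texture(128, seed=11)


class TestRoiWeights:
    def test_stated_window_size(self):
        w = gaussian_roi_weights(6.0, 0.4, 0.25, SPACING)
        assert w.shape == (61, 61)
        assert w.sum() == pytest.approx(1.0)

    def test_flat_kernel_limit_is_uniform(self):
        w = gaussian_roi_weights(3.0, 1e6, 1.0, SPACING)
        nz = w[w > 0]
        assert np.allclose(nz, nz[0], rtol=1e-6)

    def test_matches_truncated_gaussian_formula(self):
        radius, sigma, frac = 4.0, 0.7, 0.5
        w = gaussian_roi_weights(radius, sigma, frac, SPACING)
        half = w.shape[0] // 2
        expected = np.zeros_like(w)
        for r in range(w.shape[0]):
            for c in range(w.shape[1]):
                d = math.hypot(r - half, c - half) * SPACING
                if d <= frac * radius:
                    expected[r, c] = math.exp(-0.5 * (d / sigma) ** 2)
        expected /= expected.sum()
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError, match="3 px"):
            gaussian_roi_weights(0.1, 0.4, 0.25, SPACING)


def ssd_integer_shift_search(frame_a, frame_b, center_px, weights, max_shift=5):
    """Brute-force oracle: best integer translation by weighted SSD."""
    half = weights.shape[0] // 2
    cy, cx = int(center_px[1]), int(center_px[0])
    patch_a = frame_a[cy - half:cy + half + 1, cx - half:cx + half + 1]
    best, best_ssd = None, np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            patch_b = frame_b[
                cy + dy - half:cy + dy + half + 1, cx + dx - half:cx + dx + half + 1
            ]
            ssd = float((weights * (patch_b - patch_a) ** 2).sum())
            if ssd < best_ssd:
                best, best_ssd = (dx, dy), ssd
    return np.array(best, dtype=float)


class TestRoiAffine:
    def test_identical_frames_fixed_point(self, speckle):
        w = gaussian_roi_weights(6.0, 0.4, 0.25, SPACING)
        p = estimate_roi_affine(speckle, speckle, np.array([12.8, 12.8]), w, SPACING)
        np.testing.assert_allclose(p.A, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(p.b, 0, atol=1e-10)

    @pytest.mark.parametrize("shift_px", [(2, 0), (0, -2), (2, 1)])
    def test_integer_translation_matches_ssd_oracle(self, speckle, shift_px):
        dx, dy = shift_px
        shifted = np.roll(speckle, (dy, dx), axis=(0, 1))
        w = gaussian_roi_weights(6.0, 0.4, 0.25, SPACING)
        center = np.array([64, 64]) * SPACING
        p = estimate_roi_affine(speckle, shifted, center, w, SPACING)
        oracle = ssd_integer_shift_search(speckle, shifted, center / SPACING, w)
        np.testing.assert_allclose(oracle, [dx, dy])  # sanity of the oracle
        assert np.abs(p.b / SPACING - oracle).max() < 0.1
        np.testing.assert_allclose(p.A, np.eye(2), atol=0.02)

    def test_known_small_affine_recovered(self, speckle):
        # warp: 1% scaling + 1 degree rotation about the ROI centre
        th = math.radians(1.0)
        A = 1.01 * np.array([[math.cos(th), -math.sin(th)],
                             [math.sin(th), math.cos(th)]])
        b_px = np.array([0.4, -0.3])
        center_px = np.array([64.0, 64.0])
        cols, rows = np.meshgrid(np.arange(128), np.arange(128))
        pos = np.stack([cols, rows], axis=-1).astype(float)
        Ainv = np.linalg.inv(A)
        src = center_px + (pos - center_px - b_px) @ Ainv.T
        warped = ndimage.map_coordinates(
            speckle, [src[..., 1], src[..., 0]], order=3, mode="nearest"
        )
        # a full-support mask: the linear part is barely observable inside a
        # tightly truncated kernel (1% scale moves a 7 px offset by 0.07 px)
        w = gaussian_roi_weights(6.0, 2.0, 1.0, SPACING)
        p = estimate_roi_affine(speckle, warped, center_px * SPACING, w, SPACING)
        assert np.abs(p.A - A).max() < 1e-2
        assert np.abs(p.b / SPACING - b_px).max() < 1e-1

    def test_flat_image_degenerate_returns_init(self):
        flat = np.full((64, 64), 0.5)
        w = gaussian_roi_weights(3.0, 0.4, 0.25, SPACING)
        init = AffineParams.identity()
        with pytest.warns(UserWarning, match="degenerate"):
            p = estimate_roi_affine(flat, flat, np.array([6.4, 6.4]), w, SPACING, init)
        np.testing.assert_array_equal(p.A, init.A)

    def test_nonfinite_intensities_rejected(self, speckle):
        bad = speckle.copy()
        bad[0, 0] = np.nan
        w = gaussian_roi_weights(3.0, 0.4, 0.25, SPACING)
        with pytest.raises(ValueError, match="non-finite"):
            estimate_roi_affine(bad, speckle, np.array([6.4, 6.4]), w, SPACING)


@pytest.fixture(scope="module")
def arc_contour():
    th = np.linspace(0.5, np.pi * 1.5, 30)
    pts = np.array([64, 64]) * SPACING + 6.0 * np.column_stack(
        [np.cos(th), np.sin(th)]
    )
    return Contour(pts, "constant")


class TestGlobalAffine:
    def test_identical_frames_identity(self, speckle, arc_contour):
        g = estimate_global_affine(speckle, speckle, arc_contour, TrackerConfig(), SPACING)
        np.testing.assert_allclose(g.A, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(g.b, 0, atol=1e-10)

    def test_global_translation_recovered(self, speckle, arc_contour):
        shifted = np.roll(speckle, (1, 2), axis=(0, 1))
        g = estimate_global_affine(speckle, shifted, arc_contour, TrackerConfig(), SPACING)
        np.testing.assert_allclose(g.b / SPACING, [2, 1], atol=0.05)
        np.testing.assert_allclose(g.A, np.eye(2), atol=0.01)

    def test_pooled_fit_agrees_with_single_roi_on_shared_translation(self, speckle):
        shifted = np.roll(speckle, (0, 2), axis=(0, 1))
        cfg = TrackerConfig()
        w = gaussian_roi_weights(6.0, 0.4, 0.25, SPACING)
        # two well separated ROIs consistent with the same translation
        c1, c2 = np.array([40.0, 40.0]) * SPACING, np.array([88.0, 88.0]) * SPACING
        contour = Contour(np.array([c1, (c1 + c2) / 2, c2]), "constant")
        pooled = estimate_global_affine(speckle, shifted, contour, cfg, SPACING)
        for c in (c1, c2):
            single = estimate_roi_affine(speckle, shifted, c, w, SPACING)
            np.testing.assert_allclose(pooled.b, single.b, atol=0.05 * SPACING)


class TestTrackPair:
    def test_static_pair_exact(self, speckle, arc_contour):
        c_b, field = track_pair(speckle, speckle, arc_contour, TrackerConfig(), SPACING)
        np.testing.assert_array_equal(c_b.points, arc_contour.points)
        np.testing.assert_array_equal(field.vectors, 0 * field.vectors)

    def test_pure_translation_uniform_vectors(self, speckle, arc_contour):
        shifted = np.roll(speckle, (2, 1), axis=(0, 1))  # (dx, dy) = (1, 2) px
        c_b, field = track_pair(speckle, shifted, arc_contour, TrackerConfig(), SPACING)
        v_px = field.vectors / SPACING
        np.testing.assert_allclose(v_px[:, 0], 1.0, atol=0.1)
        np.testing.assert_allclose(v_px[:, 1], 2.0, atol=0.1)
        assert np.abs(v_px - v_px.mean(axis=0)).max() < 0.1

    def test_translation_equivariance(self, speckle, arc_contour):
        """Shifting frames and contour by the same integer offset leaves
        the displacement field unchanged (to solver tolerance)."""
        shifted = np.roll(speckle, (1, 1), axis=(0, 1))
        _, f0 = track_pair(speckle, shifted, arc_contour, TrackerConfig(), SPACING)
        off_px = (6, -4)  # (dx, dy)
        a2 = np.roll(speckle, (off_px[1], off_px[0]), axis=(0, 1))
        b2 = np.roll(shifted, (off_px[1], off_px[0]), axis=(0, 1))
        moved = arc_contour.translated(np.array(off_px) * SPACING)
        _, f1 = track_pair(a2, b2, moved, TrackerConfig(), SPACING)
        assert np.abs((f1.vectors - f0.vectors) / SPACING).max() < 0.05

    def test_out_of_view_point_keeps_global_stage(self, speckle):
        # one contour point near the border drifts out after the global stage
        pts = np.array([[2.0, 12.8], [6.0, 12.8], [12.8, 12.8]])
        contour = Contour(pts, "constant")
        shifted = np.roll(speckle, (0, -15), axis=(0, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c_b, _ = track_pair(speckle, shifted, contour, TrackerConfig(), SPACING)
        assert np.all(np.isfinite(c_b.points))


class TestPropagationPlan:
    def test_stated_example(self):
        plan = propagation_plan(10, 0)
        fwd = [tgt for _, tgt in plan[:5]]
        bwd = [tgt for _, tgt in plan[5:]]
        assert fwd == [1, 2, 3, 4, 5]
        assert bwd == [9, 8, 7, 6]

    def test_two_frames(self):
        assert propagation_plan(2, 0) == [(0, 1)]

    def test_exhaustive_cover_property(self):
        for T in range(2, 13):
            for ref in range(T):
                plan = propagation_plan(T, ref)
                targets = [tgt for _, tgt in plan]
                assert sorted(targets) == sorted(set(range(T)) - {ref})
                # chains are contiguous: each source is the ref or a prior target
                seen = {ref}
                for src, tgt in plan:
                    assert src in seen
                    seen.add(tgt)
                # accumulated depth is bounded by ceil((T-1)/2)
                n_fwd = math.ceil((T - 1) / 2)
                assert len(plan[:n_fwd]) == n_fwd

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            propagation_plan(1, 0)
        with pytest.raises(ValueError):
            propagation_plan(5, 5)


class TestConfig:
    def test_json_roundtrip(self):
        cfg = TrackerConfig(laa_window_radius_mm=5.0)
        assert TrackerConfig.from_json(cfg.to_json()) == cfg

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TrackerConfig(support_fraction=0.0)
        with pytest.raises(ValueError):
            TrackerConfig(kernel_sigma_mm=-1)
        with pytest.raises(NotImplementedError):
            TrackerConfig(oov_regularization=True)
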