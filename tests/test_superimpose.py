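"""Centroid size, side reflection, GPA and tangent projection."""

import numpy as np
import pytest

import valveshape as vs
from valveshape.superimpose import DegenerateShapeError, optimal_rotation

SQUARE = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])


def random_similarity(rng, coords):
    theta = rng.uniform(-np.pi, np.pi)
    s = rng.uniform(0.2, 5.0)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return s * coords @ R.T + rng.uniform(-10, 10, 2)


class TestCentroidSize:
    def test_unit_square(self):
        assert vs.centroid_size(SQUARE) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_linear_scaling(self):
        assert vs.centroid_size(3 * SQUARE) == pytest.approx(3 * np.sqrt(2), abs=1e-12)

    def test_matches_pairwise_distance_identity(self, rng):
        """CS^2 equals the sum of squared pairwise distances divided by k
        (an algebraically independent route to the same quantity)."""
        coords = rng.normal(size=(48, 2))
        k = len(coords)
        ss_pairs = 0.0
        for i in range(k):
            for j in range(k):
                ss_pairs += ((coords[i] - coords[j]) ** 2).sum()
        assert vs.centroid_size(coords) ** 2 == pytest.approx(
            ss_pairs / (2 * k), rel=1e-12
        )

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateShapeError):
            vs.centroid_size(np.ones((5, 2)))


class TestReflectSide:
    def test_double_reflection_is_identity(self, rng):
        cfg = vs.LandmarkConfiguration("S1", rng.normal(size=(10, 2)), side="left")
        once = vs.reflect_side(cfg, "left")
        twice = once.with_coords(
            vs.reflect_side(once, "left").coords
        )
        np.testing.assert_allclose(
            vs.reflect_side(vs.reflect_side(cfg, "left"), "left").coords,
            cfg.coords,
            atol=1e-12,
        )

    def test_vertical_axis_negates_x_about_centroid(self):
        coords = np.array([[1.0, 2], [-1, -2], [0, 0]])  # centred
        cfg = vs.LandmarkConfiguration("S1", coords, side="left")
        out = vs.reflect_side(cfg, "left", axis="vertical")
        np.testing.assert_allclose(out.coords[0], [-1, 2], atol=1e-12)

    def test_other_side_untouched(self):
        cfg = vs.LandmarkConfiguration("S1", SQUARE, side="right")
        assert vs.reflect_side(cfg, "left") is cfg

    def test_mirror_pair_superimposes(self, rng):
        """A perfectly symmetric individual: the mirrored left valve lands
        exactly on the right valve after superimposition."""
        right = vs.bean_template() + 0.01 * rng.standard_normal((48, 2))
        left_coords = right.copy()
        left_coords[:, 0] = -left_coords[:, 0]
        left_coords = random_similarity(rng, left_coords)
        left = vs.LandmarkConfiguration("S1", left_coords, side="left")
        reflected = vs.reflect_side(left, "left")
        aligned = vs.gpa([vs.LandmarkConfiguration("S1b", right, side="right"), reflected])
        assert np.linalg.norm(aligned.shapes[0] - aligned.shapes[1]) < 1e-9


class TestGPA:
    def test_identical_configs(self):
        aligned = vs.gpa([vs.LandmarkConfiguration("a", SQUARE),
                          vs.LandmarkConfiguration("b", SQUARE, side="left")])
        assert np.linalg.norm(aligned.shapes[0] - aligned.shapes[1]) < 1e-12
        np.testing.assert_allclose(aligned.consensus, aligned.shapes[0], atol=1e-12)

    def test_similarity_transformed_copy(self, rng):
        base = vs.bean_template()
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = 2.5 * base @ R.T + np.array([5.0, -2.0])
        aligned = vs.gpa(np.stack([base, moved]))
        assert np.linalg.norm(aligned.shapes[0] - aligned.shapes[1]) < 1e-10

    def test_two_shape_rotation_matches_closed_form(self, rng):
        """The fitted rotation equals the closed-form optimum
        theta* = atan2(sum(x_i ^ y_i), sum(x_i . y_i)) from the 2x2
        cross-covariance of centred, unit-size shapes."""
        A = rng.normal(size=(20, 2))
        B = rng.normal(size=(20, 2))
        A -= A.mean(0); B -= B.mean(0)
        A /= np.linalg.norm(A); B /= np.linalg.norm(B)
        R = optimal_rotation(A, B)
        # maximize tr(R' M) with M = A'B: theta* = atan2(M10 - M01, M00 + M11)
        M = A.T @ B
        theta_star = np.arctan2(M[1, 0] - M[0, 1], M[0, 0] + M[1, 1])
        R_star = np.array(
            [[np.cos(theta_star), -np.sin(theta_star)],
             [np.sin(theta_star), np.cos(theta_star)]]
        )
        np.testing.assert_allclose(A @ R, A @ R_star, atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_output_invariants(self, small_aligned, rng):
        _, aligned = small_aligned
        pts = aligned.shapes.reshape(aligned.n, -1, 2)
        assert np.abs(pts.mean(axis=1)).max() < 1e-9  # centred
        # unit centroid size holds on a raw GPA fit (tangent projection
        # then perturbs sizes only at O(rho^2))
        raw = vs.gpa(np.stack([vs.bean_template() + 0.01 * rng.standard_normal((48, 2))
                               for _ in range(5)]))
        norms = np.linalg.norm(raw.shapes, axis=1)
        assert np.abs(norms - 1).max() < 1e-9
        np.testing.assert_allclose(raw.consensus, raw.shapes.mean(axis=0), atol=1e-12)

    def test_invariance_under_input_similarity_transforms(self, rng):
        base = [vs.bean_template() + 0.02 * rng.standard_normal((48, 2))
                for _ in range(6)]
        a1 = vs.gpa(np.stack(base))
        a2 = vs.gpa(np.stack([random_similarity(rng, c) for c in base]))
        assert np.abs(a1.shapes - a2.shapes).max() < 1e-9

    def test_residual_ss_not_worse_than_first_iteration(self, rng):
        """Iterating to convergence cannot leave a larger residual sum of
        squares around the consensus than a single alignment pass."""
        shapes = np.stack([vs.bean_template() + 0.05 * rng.standard_normal((48, 2))
                           for _ in range(8)])
        one = vs.gpa(shapes, max_iter=1)
        full = vs.gpa(shapes)
        ss = lambda a: float((a.procrustes_distances() ** 2).sum())
        assert ss(full) <= ss(one) + 1e-12

    def test_degenerate_config_rejected(self):
        with pytest.raises(DegenerateShapeError):
            vs.gpa(np.stack([SQUARE, np.ones((4, 2))]))

    def test_single_config_rejected(self):
        with pytest.raises(ValueError):
            vs.gpa(np.stack([SQUARE]))


class TestTangentProjection:
    def test_consensus_fixed_and_idempotent(self, small_aligned):
        _, aligned = small_aligned
        again = vs.tangent_project(aligned)
        assert np.abs(again.shapes - aligned.shapes).max() < 1e-12

    def test_small_shapes_move_little(self, rng):
        shapes = np.stack([vs.bean_template() + 0.004 * rng.standard_normal((48, 2))
                           for _ in range(10)])
        aligned = vs.gpa(shapes)
        assert aligned.procrustes_distances().max() < 0.05
        proj = vs.tangent_project(aligned)
        assert np.abs(proj.shapes - aligned.shapes).max() < 1e-4


class TestResampleOutline:
    @staticmethod
    def circle(n=3600):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([np.cos(t), np.sin(t)])

    def test_circle_midpoints(self):
        pts = self.circle()
        i_ant = int(np.argmin(np.abs(pts[:, 0] + 1) + np.abs(pts[:, 1])))
        out = vs.resample_outline(pts, (i_ant, 0), n_dorsal=1, n_ventral=1)
        # anchors at (-1,0) and (1,0); single interior point per semicircle
        # falls at the arc midpoints (0, +/-1)
        np.testing.assert_allclose(out[0], [-1, 0], atol=1e-6)
        np.testing.assert_allclose(out[1], [1, 0], atol=1e-6)
        np.testing.assert_allclose(np.abs(out[2:, 1]), [1, 1], atol=1e-5)
        assert out[2:, 0] == pytest.approx([0, 0], abs=1e-5)

    def test_equidistance_on_dense_circle(self):
        pts = self.circle()
        i_ant = int(np.argmin(np.abs(pts[:, 0] + 1) + np.abs(pts[:, 1])))
        out = vs.resample_outline(pts, (i_ant, 0), n_dorsal=28, n_ventral=18)
        # on a circle, equal arc length = equal central angle
        dorsal = np.unwrap(np.concatenate([[np.pi], np.arctan2(out[2:30, 1], out[2:30, 0]), [0]]))
        gaps = np.abs(np.diff(dorsal))
        assert np.ptp(gaps) < 1e-4  # equal within dense-polygon resolution

    def test_k_is_48_for_default_counts(self):
        pts = self.circle(500)
        out = vs.resample_outline(pts, (125, 0), 28, 18)
        assert out.shape == (48, 2)

    def test_equal_anchors_rejected(self):
        with pytest.raises(ValueError):
            vs.resample_outline(self.circle(100), (3, 3))


class TestSemilandmarkSliding:
    def test_slider_runs_and_preserves_validity(self, rng):
        """Optional minimum-bending-energy sliding: output stays a valid
        aligned sample close to the fixed-landmark fit (sliding is OFF in
        the default pipeline)."""
        from valveshape.superimpose import slide_semilandmarks

        shapes = np.stack([vs.bean_template() + 0.01 * rng.standard_normal((48, 2))
                           for _ in range(5)])
        aligned = vs.gpa(shapes)
        slid = slide_semilandmarks(aligned, sliding_indices=range(2, 48),
                                   max_iter=2)
        assert slid.shapes.shape == aligned.shapes.shape
        assert np.isfinite(slid.shapes).all()
        assert np.abs(slid.shapes - aligned.shapes).max() < 0.1
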