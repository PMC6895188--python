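"""Geometric morphometrics: superimposition, ordination and warping."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

from cerebrotype import (LandmarkSet, average_replicates, between_group_pca,
                         centroid_size, find_mean_spec, gpa,
                         group_confidence_ellipse, group_mean_deviation_map,
                         procrustes_distance, shape_pca, tps_warp)


def random_landmark_set(rng, n=8, k=12, spread=0.15):
    """Specimens sharing a base shape with individual variation, the
    regime landmark data lives in (GPA assumes roughly similar shapes)."""
    base = rng.normal(size=(k, 3))
    coords = base + rng.normal(scale=spread, size=(n, k, 3))
    names = [f"s{i}" for i in range(n)]
    return LandmarkSet(coords, names, names)


class TestAverageReplicates:
    def test_identical_sessions_are_a_fixed_point(self, rng):
        lm = random_landmark_set(rng)
        out = average_replicates([lm, lm])
        np.testing.assert_allclose(out.coords, lm.coords)

    def test_midpoint_of_offset_sessions(self, rng):
        lm = random_landmark_set(rng)
        delta = rng.normal(size=lm.coords.shape)
        shifted = LandmarkSet(lm.coords + 2 * delta, lm.specimens, lm.species)
        out = average_replicates([lm, shifted])
        np.testing.assert_allclose(out.coords, lm.coords + delta)

    def test_three_sessions_match_stacked_mean(self, rng):
        sessions = [random_landmark_set(np.random.default_rng(s))
                    for s in (1, 2, 3)]
        for s in sessions[1:]:
            s.specimens = sessions[0].specimens
        out = average_replicates(sessions)
        brute = np.stack([s.coords for s in sessions]).mean(axis=0)
        np.testing.assert_allclose(out.coords, brute)

    def test_mismatched_sessions_rejected(self, rng):
        a = random_landmark_set(rng)
        b = random_landmark_set(rng, k=13)
        with pytest.raises(ValueError, match="session 2"):
            average_replicates([a, b])


class TestCentroidSize:
    def test_single_point_is_zero(self):
        assert centroid_size(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_unit_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        assert centroid_size(corners) == pytest.approx(np.sqrt(6.0))

    def test_matches_longhand_formula(self, rng):
        config = rng.normal(size=(66, 3))
        c = config.mean(axis=0)
        longhand = np.sqrt(sum(np.sum((p - c) ** 2) for p in config))
        assert centroid_size(config) == pytest.approx(longhand, rel=1e-12)

    def test_similarity_behaviour(self, rng):
        config = rng.normal(size=(10, 3))
        cs = centroid_size(config)
        R = Rotation.random(random_state=3).as_matrix()
        assert centroid_size(config @ R + 5.0) == pytest.approx(cs)
        assert centroid_size(2.5 * config) == pytest.approx(2.5 * cs)


class TestGPA:
    def test_identical_configs_have_zero_distance(self, rng):
        base = rng.normal(size=(9, 3))
        lm = LandmarkSet(np.stack([base, base]), ["a", "b"], ["a", "b"])
        aligned = gpa(lm)
        assert procrustes_distance(aligned.coords[0],
                                   aligned.coords[1]) < 1e-12

    def test_similarity_transformed_copy_aligns_exactly(self, rng):
        base = rng.normal(size=(9, 3))
        R = Rotation.random(random_state=1).as_matrix()
        if np.linalg.det(R) < 0:  # similarity only, no reflection
            R = -R
        copy = 1.7 * base @ R + np.array([3.0, -2.0, 0.5])
        lm = LandmarkSet(np.stack([base, copy]), ["a", "b"], ["a", "b"])
        aligned = gpa(lm)
        assert procrustes_distance(aligned.coords[0],
                                   aligned.coords[1]) < 1e-8

    def test_two_specimen_gpa_equals_closed_form_opa(self, rng):
        """Oracle: centre/scale both, one SVD rotation (scipy's
        orthogonal_procrustes), then the residual norm is the two-shape
        Procrustes distance GPA must reproduce."""
        A = rng.normal(size=(4, 3))
        B = rng.normal(size=(4, 3))

        def unit(X):
            X = X - X.mean(axis=0)
            return X / np.sqrt(np.sum(X ** 2))

        a, b = unit(A), unit(B)
        R, _ = orthogonal_procrustes(a, b)
        if np.linalg.det(R) < 0:
            U, s, Vt = np.linalg.svd(a.T @ b)
            s_signs = np.ones(3)
            s_signs[-1] = -1
            R = (U * s_signs) @ Vt
        oracle = np.sqrt(np.sum((a @ R - b) ** 2))

        lm = LandmarkSet(np.stack([A, B]), ["a", "b"], ["a", "b"])
        aligned = gpa(lm)
        d = procrustes_distance(aligned.coords[0], aligned.coords[1])
        assert d == pytest.approx(oracle, abs=1e-10)

    def test_idempotence(self, rng):
        lm = random_landmark_set(rng, n=7)
        first = gpa(lm)
        again = gpa(LandmarkSet(first.coords, first.specimens, first.species))
        np.testing.assert_allclose(again.coords, first.coords, atol=1e-8)

    def test_pairwise_distances_invariant_to_input_pose(self, rng):
        lm = random_landmark_set(rng, n=6)
        d0 = _pairwise(gpa(lm))
        moved = lm.coords.copy()
        for i in range(moved.shape[0]):
            R = Rotation.random(random_state=10 + i).as_matrix()
            moved[i] = (0.5 + i) * moved[i] @ R + i
        d1 = _pairwise(gpa(LandmarkSet(moved, lm.specimens, lm.species)))
        np.testing.assert_allclose(d0, d1, atol=1e-8)

    def test_centroids_at_origin_and_sizes_kept(self, rng):
        lm = random_landmark_set(rng)
        sizes = [centroid_size(c) for c in lm.coords]
        aligned = gpa(lm)
        np.testing.assert_allclose(aligned.centroid_sizes, sizes)
        np.testing.assert_allclose(aligned.coords.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(aligned.mean_shape.mean(axis=0), 0,
                                   atol=1e-12)

    def test_degenerate_specimen_named(self):
        coords = np.stack([np.zeros((5, 3)), np.random.default_rng(0).normal(
            size=(5, 3))])
        with pytest.raises(ValueError, match="flatfish"):
            gpa(LandmarkSet(coords, ["flatfish", "ok"], ["a", "b"]))


def _pairwise(aligned):
    n = aligned.n_specimens
    return np.array([[procrustes_distance(aligned.coords[i],
                                          aligned.coords[j])
                      for j in range(n)] for i in range(n)])


class TestProcrustesDistance:
    def test_metric_properties(self, rng):
        a, b, c = rng.normal(size=(3, 8, 3))
        assert procrustes_distance(a, a) == 0.0
        assert procrustes_distance(a, b) == procrustes_distance(b, a)
        for _ in range(100):
            x, y, z = rng.normal(size=(3, 8, 3))
            assert (procrustes_distance(x, z) <=
                    procrustes_distance(x, y) + procrustes_distance(y, z)
                    + 1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            procrustes_distance(rng.normal(size=(5, 3)),
                                rng.normal(size=(6, 3)))


class TestShapePCA:
    def test_collinear_data_loads_on_one_axis(self, rng):
        from cerebrotype import AlignedShapes

        base = rng.normal(size=(6, 3))
        base -= base.mean(axis=0)
        direction = rng.normal(size=(6, 3))
        direction -= direction.mean(axis=0)
        coords = np.stack([base + t * direction for t in
                           np.linspace(-1, 1, 7)])
        names = [f"s{i}" for i in range(7)]
        shapes = AlignedShapes(coords, np.ones(7), base, names, names)
        space = shape_pca(shapes)
        assert space.percent_variance[0] > 100 - 1e-9

    def test_percent_variance_sums_to_100(self, rng):
        space = shape_pca(gpa(random_landmark_set(rng)))
        assert space.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(space.scores.mean(axis=0), 0, atol=1e-9)

    def test_score_distances_reproduce_shape_distances(self, rng):
        aligned = gpa(random_landmark_set(rng, n=9))
        space = shape_pca(aligned)
        d_shape = _pairwise(aligned)
        d_score = np.linalg.norm(space.scores[:, None] - space.scores[None],
                                 axis=2)
        np.testing.assert_allclose(d_score, d_shape, atol=1e-8)

    def test_total_variance_matches_coordinate_variances(self, rng):
        aligned = gpa(random_landmark_set(rng, n=9))
        space = shape_pca(aligned)
        per_coord = aligned.flat().var(axis=0, ddof=1).sum()
        assert space.eigenvalues.sum() == pytest.approx(per_coord, rel=1e-9)

    def test_needs_three_specimens(self, rng):
        lm = random_landmark_set(rng, n=2)
        with pytest.raises(ValueError):
            shape_pca(gpa(lm))


class TestBetweenGroupPCA:
    def test_two_groups_span_one_axis(self, rng):
        aligned = gpa(random_landmark_set(rng, n=8))
        groups = ["A"] * 4 + ["B"] * 4
        space = between_group_pca(aligned, groups)
        assert space.eigenvalues.shape == (1,)

    def test_identical_group_means_have_no_spread(self, rng):
        base = rng.normal(size=(6, 3))
        coords = np.stack([base, base, base, base])
        lm = LandmarkSet(coords, list("abcd"), list("abcd"))
        space = between_group_pca(gpa(lm), ["A", "A", "B", "B"])
        assert space.eigenvalues.sum() == pytest.approx(0.0)

    def test_separated_groups_recovered_by_nearest_mean(self, rng):
        base = rng.normal(size=(10, 3))
        offsets = {g: rng.normal(scale=0.8, size=(10, 3))
                   for g in "ABC"}
        coords, labels = [], []
        for g in "ABC":
            for _ in range(5):
                coords.append(base + offsets[g]
                              + rng.normal(scale=0.02, size=(10, 3)))
                labels.append(g)
        names = [f"s{i}" for i in range(len(coords))]
        aligned = gpa(LandmarkSet(np.stack(coords), names, names))
        space = between_group_pca(aligned, labels)
        labels = np.asarray(labels)
        means = {g: space.scores[labels == g].mean(axis=0) for g in "ABC"}
        for i, g in enumerate(labels):
            nearest = min(means, key=lambda m:
                          np.linalg.norm(space.scores[i] - means[m]))
            assert nearest == g

    def test_empty_group_rejected(self, rng):
        aligned = gpa(random_landmark_set(rng, n=4))
        with pytest.raises(ValueError):
            between_group_pca(aligned, ["A", "A", "A", "A"])


class TestConfidenceEllipse:
    def test_zero_variance_group_degenerates_to_point(self):
        scores = np.tile([2.0, -1.0], (5, 1))
        ell = group_confidence_ellipse(scores, np.arange(5), seed=0,
                                       replicates=200)
        np.testing.assert_allclose(ell.center, [2.0, -1.0])
        np.testing.assert_allclose(ell.semi_axes, 0.0, atol=1e-12)

    def test_isotropic_group_gives_near_circular_ellipse(self, rng):
        pts = rng.normal(size=(4000, 2))
        ell = group_confidence_ellipse(pts, np.arange(4000), seed=1,
                                       replicates=2000)
        ratio = ell.semi_axes[0] / ell.semi_axes[1]
        assert ratio < 1.1

    def test_seed_reproducibility(self, rng):
        pts = rng.normal(size=(20, 2))
        a = group_confidence_ellipse(pts, np.arange(20), seed=42)
        b = group_confidence_ellipse(pts, np.arange(20), seed=42)
        np.testing.assert_array_equal(a.semi_axes, b.semi_axes)
        assert a.orientation == b.orientation

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_confidence_ellipse(rng.normal(size=(5, 2)), [0, 1], seed=0)


class TestFindMeanSpec:
    def test_single_specimen(self, rng):
        lm = random_landmark_set(rng, n=2)
        aligned = gpa(lm)
        aligned.coords = aligned.coords[:1]
        aligned.specimens = aligned.specimens[:1]
        assert find_mean_spec(aligned) == "s0"

    def test_matches_exhaustive_scan(self, rng):
        aligned = gpa(random_landmark_set(rng, n=11))
        d = [procrustes_distance(aligned.coords[i], aligned.mean_shape)
             for i in range(11)]
        assert find_mean_spec(aligned) == aligned.specimens[int(np.argmin(d))]


class TestTPS:
    def test_identity_map(self, rng):
        src = rng.normal(size=(8, 3))
        verts = rng.normal(size=(50, 3))
        np.testing.assert_allclose(tps_warp(src, src, verts), verts,
                                   atol=1e-9)

    def test_translation_is_reproduced_exactly(self, rng):
        src = rng.normal(size=(8, 3))
        shift = np.array([1.5, -0.3, 2.0])
        verts = rng.normal(size=(50, 3))
        np.testing.assert_allclose(tps_warp(src, src + shift, verts),
                                   verts + shift, atol=1e-8)

    def test_general_affine_reproduced_exactly(self, rng):
        src = rng.normal(size=(10, 3))
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        b = rng.normal(size=3)
        verts = rng.normal(size=(40, 3))
        np.testing.assert_allclose(tps_warp(src, src @ A + b, verts),
                                   verts @ A + b, atol=1e-7)

    def test_exact_interpolation_at_landmarks(self, rng):
        src = rng.normal(size=(12, 3))
        tgt = src + rng.normal(scale=0.3, size=(12, 3))
        np.testing.assert_allclose(tps_warp(src, tgt, src), tgt, atol=1e-8)

    def test_coincident_landmarks_rejected(self, rng):
        src = np.zeros((6, 3))
        with pytest.raises(ValueError):
            tps_warp(src, src + 1, rng.normal(size=(5, 3)))


class TestDeviationMap:
    def test_group_equal_to_mean_gives_zero_field(self, rng):
        base = rng.normal(size=(8, 3))
        # two mirror-balanced specimens per group, same group means
        coords = np.stack([base, base, base, base])
        lm = LandmarkSet(coords, list("abcd"), list("abcd"))
        aligned = gpa(lm)
        verts = rng.normal(size=(30, 3))
        fields = group_mean_deviation_map(aligned, ["G", "G", "H", "H"],
                                          verts)
        for field in fields.values():
            np.testing.assert_allclose(field, 0.0, atol=1e-9)

    def test_field_nonnegative_and_localised(self, rng):
        from scipy.stats import spearmanr

        base = rng.normal(scale=2.0, size=(25, 3))
        displaced = base.copy()
        displaced[0] += np.array([1.5, 0, 0])
        coords = np.stack([base, base, displaced, displaced])
        lm = LandmarkSet(coords, list("abcd"), list("abcd"))
        aligned = gpa(lm)
        verts = aligned.mean_shape
        fields = group_mean_deviation_map(aligned, ["G", "G", "H", "H"],
                                          verts)
        for field in fields.values():
            assert np.all(field >= 0)
        # displacement field peaks at the moved landmark and decays with
        # distance from it (rank correlation over mean-shape vertices)
        field = fields["H"]
        assert int(np.argmax(field)) == 0
        dist_to_moved = np.linalg.norm(verts - verts[0], axis=1)
        rho = spearmanr(dist_to_moved[1:], field[1:]).statistic
        assert rho < 0
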