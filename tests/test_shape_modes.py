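"""Contour processing, registration, and the shape-mode model."""

import numpy as np
import pandas as pd
import pytest

from _oracles import kmeans_exhaustive_inertia
from conftest import raster_disk
from gliamorph import shape_modes as sm
from gliamorph import synthetic as syn


def star_mask(rng):
    cls = syn.ShapeClass("star4", (6, 8), (4, 4), (16, 20), (2.5, 3))
    return syn.generate_cell_shape(cls, rng)


def rotate_contour(contour, degrees):
    th = np.deg2rad(degrees)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    center = contour.mean(axis=0)
    return (contour - center) @ rot.T + center


class TestContour:
    def test_disk_contour_length_near_circumference(self):
        contour = sm.extract_contour(raster_disk(50))
        assert sm.contour_length(contour) == pytest.approx(
            2 * np.pi * 50, rel=0.03)

    def test_square_shoelace_area(self):
        sq = np.zeros((14, 14), dtype=bool)
        sq[2:12, 2:12] = True
        contour = sm.extract_contour(sq)
        assert sm.contour_area(contour) == pytest.approx(100, rel=0.05)

    def test_hole_is_ignored(self):
        yy, xx = np.mgrid[0:41, 0:41]
        r2 = (yy - 20) ** 2 + (xx - 20) ** 2
        ring = (r2 <= 15**2) & (r2 >= 6**2)
        solid = r2 <= 15**2
        assert np.allclose(sm.extract_contour(ring), sm.extract_contour(solid))

    def test_too_small_object_rejected(self):
        tiny = np.zeros((5, 5), dtype=bool)
        tiny[2, 2] = True
        with pytest.raises(sm.ParameterError):
            sm.extract_contour(tiny)


class TestResample:
    def test_unit_square_eight_points_hits_corners_and_midpoints(self):
        square = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], dtype=float)
        out = sm.resample_contour(square, 8)
        expected = {(0, 0), (0, 0.5), (0, 1), (0.5, 1), (1, 1), (1, 0.5),
                    (1, 0), (0.5, 0)}
        got = {tuple(np.round(p, 6)) for p in out}
        assert got == expected

    def test_idempotent_on_equispaced_contour(self):
        contour = sm.resample_contour(sm.extract_contour(raster_disk(30)), 40)
        again = sm.resample_contour(contour, 40)
        assert np.allclose(contour, again, atol=1e-6)

    def test_spacing_is_uniform(self, rng):
        contour = sm.extract_contour(star_mask(rng))
        out = sm.resample_contour(contour, 50)
        closed = np.vstack([out, out[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        assert seg.std() / seg.mean() < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(sm.ParameterError):
            sm.resample_contour(np.eye(3), 2)


class TestRegister:
    def test_translation_and_scale_removed(self, rng):
        contour = sm.resample_contour(sm.extract_contour(star_mask(rng)), 50)
        v0 = sm.register(contour)
        assert np.allclose(v0, sm.register(contour + [31.0, -8.0]), atol=1e-9)
        assert np.allclose(v0, sm.register(contour * 2.0), atol=1e-9)
        # unit RMS radius after registration
        assert np.sqrt(np.mean(v0[:50] ** 2 + v0[50:] ** 2)) == pytest.approx(1)

    def test_rotation_removed_for_elongated_shape(self):
        canvas = np.zeros((160, 160), dtype=bool)
        yy, xx = np.mgrid[0:160, 0:160]
        canvas[((yy - 80) / 20.0) ** 2 + ((xx - 80) / 55.0) ** 2 <= 1] = True
        # add an asymmetric bump so the 180-degree flip is determined
        canvas[70:78, 120:135] = True
        contour = sm.resample_contour(sm.extract_contour(canvas), 200)
        v0 = sm.register(contour)
        v33 = sm.register(sm.resample_contour(rotate_contour(contour, 33), 200))
        assert np.allclose(v0, v33, atol=1e-2)
        # after Procrustes alignment agreement is tight
        assert np.allclose(v0, sm.align_to_reference(v33, v0), atol=1e-3)

    def test_zero_radius_rejected(self):
        with pytest.raises(sm.ParameterError):
            sm.register(np.zeros((10, 2)))


def make_population(rng, n, classes):
    contours, labels, areas = [], [], []
    for i in range(n):
        j = i % len(classes)
        mask = syn.generate_cell_shape(classes[j], rng)
        contours.append(sm.extract_contour(mask))
        labels.append(j)
        areas.append(int(mask.sum()))
    return contours, np.array(labels), areas


class TestFit:
    def test_two_class_recovery(self, rng, disk_class, star4_class):
        contours, truth, areas = make_population(rng, 200,
                                                 [disk_class, star4_class])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=2).fit(seed=1)
        modes = res.assignments["shape_mode"].to_numpy() - 1
        agreement = max((modes == truth).mean(), (modes != truth).mean())
        assert agreement >= 0.95

    def test_k1_single_mode_centroid_is_score_mean(self, rng, disk_class):
        contours, _, areas = make_population(rng, 30, [disk_class])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=1,
                                   train_fraction=1.0).fit(seed=0)
        assert (res.assignments["shape_mode"] == 1).all()
        scores = (res.registered_vectors - res.model.mean_shape) @ res.model.basis.T
        assert np.allclose(res.model.centroids[0], scores.mean(axis=0),
                           atol=1e-8)

    def test_refit_is_deterministic(self, rng, disk_class, star4_class):
        contours, _, areas = make_population(rng, 60,
                                             [disk_class, star4_class])
        a = sm.ShapeModeAnalysis(contours, areas=areas, k=2).fit(seed=9)
        b = sm.ShapeModeAnalysis(contours, areas=areas, k=2).fit(seed=9)
        assert np.array_equal(a.model.centroids, b.model.centroids)
        assert a.assignments["shape_mode"].equals(b.assignments["shape_mode"])

    def test_fewer_cells_than_modes_rejected(self, rng, disk_class):
        contours, _, areas = make_population(rng, 3, [disk_class])
        with pytest.raises(sm.ParameterError):
            sm.ShapeModeAnalysis(contours, areas=areas, k=5).fit(seed=0)

    def test_modes_numbered_by_decreasing_median_area(self, rng,
                                                      disk_class, star4_class):
        contours, truth, areas = make_population(rng, 100,
                                                 [disk_class, star4_class])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=2).fit(seed=2)
        areas = np.asarray(areas)
        modes = res.assignments["shape_mode"].to_numpy()
        med1 = np.median(areas[modes == 1])
        med2 = np.median(areas[modes == 2])
        assert med1 >= med2

    def test_split_stability_on_homogeneous_population(self, rng, disk_class):
        contours, _, areas = make_population(rng, 1000, [disk_class])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=3).fit(seed=4)
        df = res.assignments
        for mode in range(1, 4):
            freqs = []
            for split in ("train", "test"):
                sub = df[df["split"] == split]
                freqs.append(100.0 * (sub["shape_mode"] == mode).mean())
            assert abs(freqs[0] - freqs[1]) < 10.0


@pytest.fixture(scope="module")
def fitted(disk_class, star4_class):
    rng = np.random.default_rng(77)
    contours, _, areas = make_population(rng, 80, [disk_class, star4_class])
    res = sm.ShapeModeAnalysis(contours, areas=areas, k=2).fit(seed=3)
    return contours, res


class TestAssign:
    def test_training_cell_keeps_its_label(self, fitted):
        contours, res = fitted
        for idx in (0, 1, 10, 11):
            mode, _ = res.model.assign(contours[idx])
            assert mode == res.assignments["shape_mode"].iloc[idx]

    def test_centroid_preimage_maps_to_its_mode_with_near_zero_distance(self, fitted):
        _, res = fitted
        model = res.model
        separation = np.linalg.norm(model.centroids[0] - model.centroids[1])
        for j in range(model.k):
            vec = model.mean_shape + model.centroids[j] @ model.basis
            mode, dist = model.assign_vector(vec)
            assert mode == j + 1
            # re-alignment of the reconstruction perturbs it only slightly
            assert dist < 0.02 * separation

    def test_exactly_equidistant_point_takes_lower_mode_index(self):
        # hand-built model where the two centroid distances are bitwise
        # identical: the tie must resolve to the lower mode index
        n = 4
        vec = np.zeros(2 * n)
        vec[0] = 0.5
        basis = np.zeros((2, 2 * n))
        basis[0, 0] = basis[1, 1] = 1.0
        model = sm.ShapeModeModel(
            n_points=n, n_components=2, k=2, mean_shape=np.zeros(2 * n),
            alignment_reference=vec.copy(), basis=basis,
            explained_variance=np.ones(2),
            explained_variance_ratio=np.full(2, 0.5),
            centroids=np.array([[0.2, 0.3], [0.2, -0.3]]),
            linkage=np.zeros((1, 4)), train_fraction=1.0, seed=0)
        mode, dist = model.assign_vector(vec)
        assert mode == 1
        assert dist == pytest.approx(np.hypot(0.3, 0.3))

    def test_serialization_round_trip(self, fitted, tmp_path):
        contours, res = fitted
        path = tmp_path / "model.json"
        res.model.to_json(path)
        loaded = sm.ShapeModeModel.from_json(path)
        for c in contours[:10]:
            mode_a, dist_a = res.model.assign(c)
            mode_b, dist_b = loaded.assign(c)
            assert mode_a == mode_b
            assert dist_a == pytest.approx(dist_b, rel=1e-9)


class TestPCAKMeansOracles:
    def test_full_dimension_basis_reconstructs_exactly(self, rng, disk_class,
                                                       star4_class):
        contours, _, areas = make_population(rng, 40,
                                             [disk_class, star4_class])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=2, n_points=30,
                                   n_components=60,
                                   train_fraction=1.0).fit(seed=0)
        assert res.reconstruction_rms() < 1e-8

    def test_reconstruction_error_nonincreasing_in_components(self, rng,
                                                              star4_class):
        contours, _, areas = make_population(rng, 40, [star4_class])
        errors = []
        for n_comp in (2, 5, 10, 20):
            res = sm.ShapeModeAnalysis(contours, areas=areas, k=2,
                                       n_components=n_comp,
                                       train_fraction=1.0).fit(seed=0)
            errors.append(res.reconstruction_rms())
        assert errors == sorted(errors, reverse=True)

    def test_basis_rows_orthonormal(self, rng, disk_class, star4_class):
        contours, _, areas = make_population(rng, 50,
                                             [disk_class, star4_class])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=2).fit(seed=0)
        basis = res.model.basis
        assert np.allclose(basis @ basis.T, np.eye(len(basis)), atol=1e-8)

    def test_kmeans_partition_matches_exhaustive_optimum(self, rng,
                                                         disk_class,
                                                         star4_class):
        contours, _, areas = make_population(rng, 8,
                                             [disk_class, star4_class])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=2, n_components=2,
                                   train_fraction=1.0).fit(seed=0)
        scores = (res.registered_vectors - res.model.mean_shape) @ res.model.basis.T
        modes = res.assignments["shape_mode"].to_numpy()
        inertia = sum(((scores[modes == j]
                        - scores[modes == j].mean(axis=0)) ** 2).sum()
                      for j in np.unique(modes))
        assert inertia == pytest.approx(
            kmeans_exhaustive_inertia(scores, 2), rel=1e-9)


class TestDendrogram:
    def test_k2_single_merge(self, rng, disk_class, star4_class):
        contours, _, areas = make_population(rng, 40,
                                             [disk_class, star4_class])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=2).fit(seed=0)
        link, leaves = res.model.dendrogram()
        assert link.shape == (1, 4)
        assert sorted(leaves) == [1, 2]

    def test_first_merge_joins_closest_centroid_pair(self, rng, disk_class,
                                                     star4_class):
        contours, _, areas = make_population(
            rng, 120, [disk_class, star4_class,
                       syn.ShapeClass("e", (8, 10), (0, 0), (0, 0), (0, 0),
                                      (3.2, 3.8))])
        res = sm.ShapeModeAnalysis(contours, areas=areas, k=3).fit(seed=0)
        link, _ = res.model.dendrogram()
        c = res.model.centroids
        dists = {(i, j): np.linalg.norm(c[i] - c[j])
                 for i in range(3) for j in range(i + 1, 3)}
        closest = min(dists, key=dists.get)
        assert {int(link[0, 0]), int(link[0, 1])} == set(closest)


class TestOverlay:
    def test_colors_conserve_cell_areas(self):
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[2:10, 2:10] = 1
        mask[15:25, 15:25] = 2
        overlay = sm.render_mode_overlay(mask, {1: 1, 2: 1}, k=2)
        foreground = (overlay.sum(axis=2) > 0)
        assert foreground.sum() == (mask > 0).sum()
        colors = {tuple(v) for v in overlay[foreground]}
        assert len(colors) == 1  # both cells share one mode color

    def test_background_stays_black_and_unassigned_is_gray(self):
        mask = np.zeros((16, 16), dtype=np.int32)
        mask[4:8, 4:8] = 1
        overlay = sm.render_mode_overlay(mask, {}, k=3)
        assert (overlay[mask == 0] == 0).all()
        assert (overlay[mask == 1] == 128).all()
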