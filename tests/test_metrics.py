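"""Jaccard / RMSE / Hausdorff metrics, LOO harness, paired comparison."""

import numpy as np
import pytest
import trimesh

from footshape.geometry import GeometryError, TriangleMesh, mirror
from footshape.metrics import (
    ValidationRecord,
    hausdorff,
    jaccard_index,
    left_right_similarity,
    loo_cross_validate,
    records_to_frame,
    rmse_surface,
    summarize_and_compare,
)
from footshape.registration import CorrespondedSet


def box(extent, translate):
    b = trimesh.creation.box(extents=extent)
    b.apply_translation(translate)
    return TriangleMesh(np.asarray(b.vertices), np.asarray(b.faces))


class TestJaccard:
    def test_self_similarity_is_one(self, sphere5):
        assert jaccard_index(sphere5, sphere5, 0.5) == 1.0

    def test_half_overlapping_unit_cubes(self):
        a = box([1, 1, 1], [0.5, 0.5, 0.5])
        b = box([1, 1, 1], [1.0, 0.5, 0.5])
        j = jaccard_index(a, b, voxel_size=0.1)
        # analytic 0.5 / 1.5 = 1/3, within one voxel layer of tolerance
        assert abs(j - 1.0 / 3.0) < 0.1 * 3 / 1.5

    def test_disjoint_solids(self):
        a = box([1, 1, 1], [0, 0, 0])
        b = box([1, 1, 1], [5, 0, 0])
        assert jaccard_index(a, b, voxel_size=0.2) == 0.0

    def test_symmetric(self, sphere5, unit_cube):
        assert jaccard_index(sphere5, unit_cube, 0.5) == pytest.approx(
            jaccard_index(unit_cube, sphere5, 0.5)
        )

    def test_non_watertight_rejected(self, unit_cube):
        holey = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(GeometryError):
            jaccard_index(unit_cube, holey, 0.5)


class TestSurfaceDistances:
    def test_self_distances_zero(self, random_cloud):
        cloud = random_cloud(60)
        assert rmse_surface(cloud, cloud) == 0.0
        assert hausdorff(cloud, cloud) == 0.0

    def test_hausdorff_three_four_five(self):
        a = np.array([[0.0, 0, 0]] * 4)
        b = np.array([[3.0, 4, 0]] * 4)
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_translated_flat_grid_rmse_is_offset(self):
        g = np.stack(np.meshgrid(np.linspace(0, 50, 51), np.linspace(0, 50, 51)),
                     axis=-1).reshape(-1, 2)
        a = np.column_stack([g, np.zeros(len(g))])
        b = a + [0, 0, 1.0]  # 1 mm off-plane shift of a dense flat grid
        assert abs(rmse_surface(a, b) - 1.0) < 1e-9

    def test_rmse_matches_brute_force(self, random_cloud):
        a = random_cloud(100, seed=21).points
        b = random_cloud(100, seed=22).points
        d_ab = np.linalg.norm(a[:, None] - b[None], axis=2).min(axis=1)
        d_ba = np.linalg.norm(b[:, None] - a[None], axis=2).min(axis=1)
        oracle = np.sqrt(np.mean(np.concatenate([d_ab, d_ba]) ** 2))
        assert abs(rmse_surface(a, b) - oracle) < 1e-12

    def test_hausdorff_matches_brute_force(self, random_cloud):
        a = random_cloud(200, seed=23).points
        b = random_cloud(200, seed=24).points
        dmat = np.linalg.norm(a[:, None] - b[None], axis=2)
        oracle = max(dmat.min(axis=1).max(), dmat.min(axis=0).max())
        assert hausdorff(a, b) == oracle

    def test_hausdorff_dominates_rmse(self, random_cloud):
        a = random_cloud(80, seed=25).points
        b = random_cloud(90, seed=26).points
        assert hausdorff(a, b) >= rmse_surface(a, b)

    def test_hausdorff_triangle_inequality_spot_check(self, random_cloud):
        a = random_cloud(50, seed=27).points
        b = random_cloud(50, seed=28).points
        c = random_cloud(50, seed=29).points
        assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-12


class TestLeftRightSimilarity:
    def test_exact_mirror_is_identical(self, bone_template):
        tpl, _ = bone_template
        right = tpl
        left = mirror(tpl, "z")
        assert left_right_similarity(left, right, voxel_size=0.8) > 0.97

    def test_inflated_mirror_is_lower_but_overlapping(self, sphere5):
        s = trimesh.creation.icosphere(subdivisions=3, radius=6.0)
        inflated = TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))
        j = left_right_similarity(mirror(sphere5, "z"), inflated,
                                  voxel_size=0.5)
        # convex solids, 1 mm inflation of a 5 mm sphere: (5/6)^3 ~ 0.58
        assert 0.5 < j < 1.0

    def test_unrelated_solids_near_zero(self, unit_cube):
        far = box([10, 10, 10], [200, 5, 5])
        assert left_right_similarity(unit_cube, far, voxel_size=1.0) < 1.0


class TestValidationRecord:
    def test_rmse_cannot_exceed_hausdorff(self):
        with pytest.raises(GeometryError):
            ValidationRecord("S", "seg", "full", 0.9, rmse=2.0, hausdorff=1.0)

    def test_jaccard_bounds(self):
        with pytest.raises(GeometryError):
            ValidationRecord("S", "seg", "full", 1.2, rmse=0.1, hausdorff=0.2)


class TestLooCrossValidate:
    def test_identical_population_scores_perfectly(self, bone_template):
        tpl, lmk = bone_template
        shapes = np.repeat(tpl.vertices[None], 5, axis=0)
        corr = CorrespondedSet(template=tpl.as_cloud(), shapes=shapes,
                               fit_rmse=np.zeros(5), faces=tpl.faces)
        recs = loo_cross_validate(corr, "full", landmark_indices=lmk,
                                  segment="synthetic", voxel_size=0.8)
        assert len(recs) == 5
        for r in recs:
            assert r.jaccard > 0.99
            assert r.rmse < 1e-6
            assert r.hausdorff < 1e-6

    def test_record_count_matches_population(self, clean_population):
        corr, _, lmk = clean_population
        sub = CorrespondedSet(template=corr.template, shapes=corr.shapes[:6],
                              fit_rmse=corr.fit_rmse[:6], faces=corr.faces)
        recs = loo_cross_validate(sub, "full", landmark_indices=lmk,
                                  segment="synthetic", voxel_size=0.8)
        assert len(recs) == 6
        assert {r.mode for r in recs} == {"full"}

    def test_accuracy_improves_with_k_then_plateaus(self, clean_population):
        """Mean LOO surface error decreases as modes are added up to the
        generating count (3) and plateaus beyond it."""
        corr, _, lmk = clean_population
        sub = CorrespondedSet(template=corr.template, shapes=corr.shapes[:8],
                              fit_rmse=corr.fit_rmse[:8], faces=corr.faces)
        means = []
        for k in (1, 2, 3, 4):
            recs = loo_cross_validate(sub, "full", k_override=k,
                                      landmark_indices=lmk,
                                      segment="synthetic", voxel_size=0.8)
            means.append(records_to_frame(recs).rmse.mean())
        assert means[1] < means[0]
        assert means[2] < means[1]
        assert abs(means[3] - means[2]) < 0.25 * means[2] + 0.05

    def test_sparse_talus_rejected(self, clean_population):
        from footshape.fitting import UnsupportedSegmentError

        corr, _, lmk = clean_population
        with pytest.raises(UnsupportedSegmentError):
            loo_cross_validate(corr, "sparse", landmark_indices=lmk,
                               segment="talus")

    def test_too_few_shapes_rejected(self, bone_template):
        tpl, lmk = bone_template
        shapes = np.repeat(tpl.vertices[None], 3, axis=0)
        corr = CorrespondedSet(template=tpl.as_cloud(), shapes=shapes,
                               fit_rmse=np.zeros(3))
        with pytest.raises(GeometryError):
            loo_cross_validate(corr, "full")


class TestSummarizeAndCompare:
    def _records(self, mode, jac, rmse, haus):
        return [
            ValidationRecord(f"S{i:02d}", "synthetic", mode, j, r, h)
            for i, (j, r, h) in enumerate(zip(jac, rmse, haus))
        ]

    def test_identical_pairs_flagged_with_p_one(self):
        jac = [0.8] * 6
        rmse = [1.0] * 6
        haus = [2.0] * 6
        full = self._records("full", jac, rmse, haus)
        sparse = self._records("sparse", jac, rmse, haus)
        summary = summarize_and_compare(full, sparse)
        assert all(p == 1.0 for p in summary.p_values.values())
        assert all(summary.all_zero_differences.values())

    def test_one_signed_differences_exact_p(self, rng):
        n = 10
        jac_f = 0.9 + rng.uniform(0.0, 0.01, n)
        jac_s = jac_f - rng.uniform(0.01, 0.05, n)  # full wins every pair
        rmse_f = rng.uniform(0.5, 0.6, n)
        haus_f = rmse_f + 1.0
        full = self._records("full", jac_f, rmse_f, haus_f)
        sparse = self._records("sparse", jac_s, rmse_f + 0.3, haus_f + 0.3)
        summary = summarize_and_compare(full, sparse)
        assert summary.p_values["jaccard"] == pytest.approx(2 / 1024)

    def test_means_and_sds_match_direct_recomputation(self, rng):
        jac = rng.uniform(0.6, 0.9, 8)
        rmse = rng.uniform(0.5, 2.0, 8)
        haus = rmse + rng.uniform(0.5, 3.0, 8)
        full = self._records("full", jac, rmse, haus)
        sparse = self._records("sparse", jac - 0.05, rmse + 0.2, haus + 0.2)
        summary = summarize_and_compare(full, sparse)
        assert summary.table.loc["full", "jaccard_mean"] == pytest.approx(
            jac.mean(), abs=1e-12
        )
        assert summary.table.loc["full", "rmse_sd"] == pytest.approx(
            rmse.std(ddof=1), abs=1e-12
        )
        assert summary.table.loc["sparse", "hausdorff_mean"] == pytest.approx(
            (haus + 0.2).mean(), abs=1e-12
        )
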