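"""Voxel grid, study selection and activation-map construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imgx.meta_map import (
    StudyDatabase,
    StudyRecord,
    VoxelGrid,
    build_activation_map,
    build_association_map,
    load_study_database,
    select_studies,
    study_activation_mask,
    study_site_activation_matrix,
    write_study_database,
)


def study(sid, terms, foci):
    return StudyRecord(study_id=sid, terms=frozenset(terms), foci=np.asarray(foci))


class TestVoxelGrid:
    def test_mni_shapes(self):
        assert VoxelGrid.mni(4.0).shape == (46, 55, 46)
        assert VoxelGrid.mni(2.0).shape == (91, 109, 91)

    def test_mm_voxel_roundtrip_at_centers(self, rng):
        g = VoxelGrid.mni(4.0)
        idx = np.column_stack(
            [rng.integers(0, s, size=200) for s in g.shape]
        )
        assert np.array_equal(g.mm_to_voxel(g.voxel_to_mm(idx)), idx)

    def test_affine_matches_mapping(self):
        g = VoxelGrid.mni(4.0)
        hom = np.array([3, 5, 7, 1.0])
        assert np.allclose((g.affine @ hom)[:3], g.voxel_to_mm([[3, 5, 7]])[0])

    @pytest.mark.parametrize("spacing", [-1.0, 0.0])
    def test_bad_spacing(self, spacing):
        with pytest.raises(ValueError):
            VoxelGrid(shape=(5, 5, 5), spacing=spacing)


class TestSelectStudies:
    @pytest.fixture
    def db(self):
        return StudyDatabase(
            [
                study("s1", {"navigation"}, [[0, 0, 0]]),
                study("s2", {"navigation", "memory"}, [[4, 0, 0]]),
                study("s3", {"memory", "spatial"}, [[8, 0, 0]]),
                study("s4", {"spatial"}, [[0, 4, 0]]),
            ]
        )

    def test_single_term(self, db):
        assert [s.study_id for s in select_studies(db, "navigation")] == ["s1", "s2"]

    def test_pair_matches_brute_force(self, db):
        got = {s.study_id for s in select_studies(db, ("memory", "spatial"))}
        brute = {
            s.study_id
            for s in db.studies
            if "memory" in s.terms and "spatial" in s.terms
        }
        assert got == brute == {"s3"}

    def test_disjoint_pair_empty(self, db):
        assert select_studies(db, ("navigation", "spatial")) == []

    def test_unknown_label_warns_and_returns_empty(self, db):
        with pytest.warns(UserWarning, match="not found"):
            assert select_studies(db, "unknownterm") == []

    def test_uppercase_label_rejected(self, db):
        with pytest.raises(ValueError, match="lowercase"):
            select_studies(db, "Navigation")

    def test_synthetic_term_count(self, world):
        cfg, db, _, _ = world
        assert len(select_studies(db, cfg.term)) == cfg.n_term_studies


class TestActivationMask:
    def test_radius_zero_single_voxel(self, small_grid):
        center = small_grid.voxel_to_mm([[10, 10, 10]])[0]
        mask = study_activation_mask(study("s", {"t"}, [center]), small_grid, 0.0)
        assert mask.sum() == 1 and mask[10, 10, 10]

    def test_no_foci_all_zero(self, small_grid):
        mask = study_activation_mask(
            study("s", {"t"}, np.empty((0, 3))), small_grid, 10.0
        )
        assert not mask.any()

    def test_two_distant_foci_double_the_count(self, small_grid):
        f1 = np.array([-14.0, 0.0, 0.0])
        f2 = f1 + [30.0, 0, 0]
        m1 = study_activation_mask(study("a", {"t"}, [f1]), small_grid, 10.0)
        m2 = study_activation_mask(study("b", {"t"}, [f1, f2]), small_grid, 10.0)
        assert m2.sum() == 2 * m1.sum()
        # exhaustive check against all voxel centers
        centers = small_grid.voxel_to_mm(
            np.column_stack(np.unravel_index(np.arange(small_grid.n_voxels), small_grid.shape))
        )
        d = np.minimum(
            np.linalg.norm(centers - f1, axis=1), np.linalg.norm(centers - f2, axis=1)
        )
        assert np.array_equal(m2.ravel(), d <= 10.0)

    def test_focus_outside_grid_contributes_inside_only(self, small_grid):
        mask = study_activation_mask(
            study("s", {"t"}, [[200.0, 0.0, 0.0]]), small_grid, 10.0
        )
        assert not mask.any()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        r1=st.floats(0, 12),
        r2=st.floats(0, 12),
        seed=st.integers(0, 10_000),
    )
    def test_monotone_in_radius(self, r1, r2, seed):
        grid = VoxelGrid(shape=(12, 12, 12), spacing=4.0, origin=(-22.0, -22.0, -22.0))
        rng = np.random.default_rng(seed)
        s = study("s", {"t"}, rng.uniform(-20, 20, size=(4, 3)))
        lo, hi = sorted([r1, r2])
        m_lo = study_activation_mask(s, grid, lo)
        m_hi = study_activation_mask(s, grid, hi)
        assert not np.any(m_lo & ~m_hi)


class TestBuildMap:
    def test_single_study_binary(self, small_grid):
        amap = build_activation_map([study("s", {"t"}, [[0, 0, 0]])], small_grid, 8.0)
        assert set(np.unique(amap.values)) <= {0.0, 1.0}

    def test_duplicated_study_same_map(self, small_grid):
        s = study("s", {"t"}, [[0, 0, 0], [10, 0, 0]])
        one = build_activation_map([s], small_grid, 8.0)
        many = build_activation_map([s] * 5, small_grid, 8.0)
        assert np.array_equal(one.values, many.values)

    def test_disjoint_studies_half_values(self, small_grid):
        a = study("a", {"t"}, [[-20.0, 0, 0]])
        b = study("b", {"t"}, [[20.0, 0, 0]])
        amap = build_activation_map([a, b], small_grid, 6.0)
        assert set(np.unique(amap.values)) == {0.0, 0.5}

    def test_empty_list_error(self, small_grid):
        with pytest.raises(ValueError, match="no studies"):
            build_activation_map([], small_grid, 8.0)

    def test_permutation_invariance(self, small_grid, rng):
        studies = [
            study(f"s{i}", {"t"}, rng.uniform(-30, 30, size=(3, 3)))
            for i in range(6)
        ]
        fwd = build_activation_map(studies, small_grid, 10.0)
        rev = build_activation_map(studies[::-1], small_grid, 10.0)
        assert np.array_equal(fwd.values, rev.values)

    def test_likelihood_bounds_and_integer_incidences(self, small_grid, rng):
        studies = [
            study(f"s{i}", {"t"}, rng.uniform(-30, 30, size=(4, 3)))
            for i in range(7)
        ]
        amap = build_activation_map(studies, small_grid, 10.0)
        assert amap.values.min() >= 0 and amap.values.max() <= 1
        total = amap.values.sum() * amap.n_studies
        assert abs(total - round(total)) < 1e-9

    def test_association_map_signs(self, small_grid):
        term = [study("t1", {"t"}, [[0, 0, 0]]), study("t2", {"t"}, [[0, 0, 0]])]
        bg = [study(f"b{i}", {"b"}, [[30.0, 30, 30]]) for i in range(4)]
        amap = build_association_map(term, bg, small_grid, 6.0)
        center = amap.values[tuple(small_grid.mm_to_voxel([[0, 0, 0]])[0])]
        far = amap.values[tuple(small_grid.mm_to_voxel([[30, 30, 30]])[0])]
        assert center > 0 and far < 0
        assert amap.mode == "association"


class TestSiteMatrix:
    def test_column_means_equal_full_map_sampling(self, small_grid, rng):
        studies = [
            study(f"s{i}", {"t"}, rng.uniform(-30, 30, size=(5, 3)))
            for i in range(9)
        ]
        flat = rng.choice(small_grid.n_voxels, size=40, replace=False)
        M = study_site_activation_matrix(studies, small_grid, 10.0, flat)
        amap = build_activation_map(studies, small_grid, 10.0)
        assert np.array_equal(
            M.astype(float).mean(axis=0), amap.values.ravel()[flat]
        )


class TestIO:
    def test_nifti_roundtrip(self, small_grid, tmp_path, rng):
        import nibabel as nib

        amap = build_activation_map(
            [study("s", {"t"}, rng.uniform(-30, 30, size=(4, 3)))], small_grid, 10.0
        )
        path = tmp_path / "map.nii"
        amap.save(path)
        img = nib.load(path)
        assert np.allclose(img.affine, small_grid.affine)
        assert np.array_equal(np.asarray(img.dataobj), amap.values.astype(np.float32))

    def test_study_csv_roundtrip(self, tmp_path, world):
        _, db, _, _ = world
        write_study_database(db, tmp_path / "studies.csv", tmp_path / "foci.csv")
        back = load_study_database(tmp_path / "studies.csv", tmp_path / "foci.csv")
        assert len(back) == len(db)
        for a, b in zip(db.studies, back.studies):
            assert a.study_id == b.study_id and a.terms == b.terms
            assert np.allclose(a.foci, b.foci)
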