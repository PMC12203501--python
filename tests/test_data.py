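"""Volume cropping, z-projection, splits and annotation I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subloc3d import (
    DatasetTable,
    VolumeSample,
    crop_single_cells,
    normalize_volume,
    project_z,
    read_annotations,
    split_by_protein,
    stratified_protein_split,
    write_annotations,
)
from subloc3d.data import read_volume, write_volume


def _multicell(shape=(4, 40, 40), seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, 100, size=(2,) + shape)


class TestCropping:
    def test_output_size_matches_out_xy(self):
        vol = _multicell()
        out = crop_single_cells(vol, [(2, 20, 20)], crop_xy=16, out_xy=128)
        assert out[0].volume.shape == (2, 4, 128, 128)

    def test_identity_crop_is_exact_subarray(self):
        vol = _multicell()
        out = crop_single_cells(vol, [(2, 20, 20)], crop_xy=8, out_xy=8)
        assert np.array_equal(out[0].volume, vol[:, :, 16:24, 16:24])

    def test_corner_center_zero_pads_three_quadrants(self):
        vol = np.zeros((2, 2, 6, 6))
        vol[1, :, 0, 0] = 5.0  # one bright voxel at the corner
        out = crop_single_cells(vol, [(0, 0, 0)], crop_xy=4, out_xy=4)
        crop = out[0].volume[1]
        # window spans [-2, 2): only the lower-right quadrant is in-bounds
        assert crop[:, 2, 2].max() == 5.0
        assert crop[:, :2, :].sum() == 0
        assert crop[:, :, :2].sum() == 0

    def test_interior_crop_conserves_intensity(self):
        vol = _multicell()
        out = crop_single_cells(vol, [(2, 20, 20)], crop_xy=10, out_xy=10)
        assert np.isclose(out[0].volume[1].sum(),
                          vol[1, :, 15:25, 15:25].sum())

    def test_center_outside_bounds_names_the_center(self):
        vol = _multicell()
        with pytest.raises(ValueError, match=r"\(2, 99, 20\)"):
            crop_single_cells(vol, [(2, 99, 20)], crop_xy=8, out_xy=8)

    def test_empty_center_list_gives_empty_result(self):
        assert crop_single_cells(_multicell(), [], 8, 8) == []


class TestProjection:
    def test_constant_volume_projects_to_constant(self):
        vol = np.full((3, 5, 5), 2.5)
        assert np.array_equal(project_z(vol), np.full((5, 5), 2.5))

    def test_single_bright_voxel_projects_to_its_xy(self):
        vol = np.zeros((4, 6, 6))
        vol[2, 3, 4] = 7.0
        img = project_z(vol)
        assert img[3, 4] == 7.0 and img.sum() == 7.0

    def test_max_vs_mean_operator(self):
        vol = np.zeros((3, 1, 1))
        vol[:, 0, 0] = [1.0, 5.0, 3.0]
        assert project_z(vol)[0, 0] == 5.0
        assert project_z(vol, operator="mean")[0, 0] == 3.0

    def test_zero_z_axis_is_rejected(self):
        with pytest.raises(ValueError):
            project_z(np.zeros((0, 4, 4)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_max_projection_commutes_with_monotone_rescale(self, seed, scale):
        vol = np.random.default_rng(seed).uniform(0, 1, size=(3, 4, 4))
        assert np.allclose(project_z(vol * scale), project_z(vol) * scale)


def _table(n_proteins, cells_per_protein=2):
    samples = [
        VolumeSample(cell_id=f"p{i}_c{j}", protein_id=f"p{i}",
                     labels={"membrane"}, grades={"membrane": 3})
        for i in range(n_proteins) for j in range(cells_per_protein)
    ]
    return DatasetTable(samples=samples, class_vocabulary=["membrane"])


class TestSplits:
    def test_counts_70_15_15_for_100_proteins(self):
        table = _table(100)
        sa = split_by_protein(table, (0.70, 0.15, 0.15), seed=5)
        counts = {s: sum(1 for v in sa.assignment.values() if v == s)
                  for s in ("train", "val", "test")}
        assert counts == {"train": 70, "val": 15, "test": 15}

    def test_all_train_when_fraction_one(self):
        table = _table(10)
        sa = split_by_protein(table, (1.0, 0.0, 0.0), seed=0)
        assert set(sa.assignment.values()) == {"train"}

    def test_deterministic_per_seed_and_varies_across_seeds(self):
        table = _table(50)
        a = split_by_protein(table, seed=3).assignment
        b = split_by_protein(table, seed=3).assignment
        c = split_by_protein(table, seed=4).assignment
        assert a == b
        assert a != c

    def test_cells_inherit_protein_split_without_leakage(self):
        table = _table(20, cells_per_protein=3)
        split_by_protein(table, seed=1)
        per_protein = {}
        for s in table.samples:
            per_protein.setdefault(s.protein_id, set()).add(s.split)
        assert all(len(v) == 1 for v in per_protein.values())

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError):
            split_by_protein(_table(2), (0.7, 0.15, 0.15), seed=0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            split_by_protein(_table(10), (0.5, 0.2, 0.2), seed=0)

    def test_cell_level_mode_splits_cells_not_proteins(self):
        table = _table(4, cells_per_protein=10)
        split_by_protein(table, seed=2, level="cell")
        splits_of_p0 = {s.split for s in table.samples
                        if s.protein_id == "p0"}
        assert len(splits_of_p0) > 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_split_partition_is_disjoint_and_complete(self, seed):
        table = _table(17)
        sa = split_by_protein(table, seed=seed)
        assert sorted(sa.assignment) == sorted(table.protein_index)
        assert set(sa.assignment.values()) <= {"train", "val", "test"}

    def test_stratified_split_covers_combos_in_every_split(self, tiny_dataset):
        table, _ = tiny_dataset
        stratified_protein_split(table, seed=9)
        combos = {}
        for s in table.samples:
            combos.setdefault(s.labels, set()).add(s.split)
        for labels, splits in combos.items():
            n_prot = len({x.protein_id for x in table.samples
                          if x.labels == labels})
            if n_prot >= 3:
                assert {"train", "test"} <= splits


def test_split_assignment_csv_round_trip(tmp_path):
    from subloc3d import SplitAssignment

    table = _table(9)
    sa = split_by_protein(table, seed=2)
    path = tmp_path / "splits.csv"
    sa.write_csv(path)
    back = SplitAssignment.read_csv(path)
    assert back.assignment == sa.assignment


class TestAnnotations:
    def test_parse_pipe_separated_row(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("cell_id,protein_id,volume_path,labels,grades\n"
                     "c1,p1,v.tif,membrane|vesicles,3|1\n")
        table = read_annotations(p)
        s = table.samples[0]
        assert s.labels == frozenset({"membrane", "vesicles"})
        assert s.grades == {"membrane": 3, "vesicles": 1}

    def test_round_trip_preserves_fields(self, tmp_path, tiny_dataset):
        table, _ = tiny_dataset
        path = tmp_path / "ann.csv"
        write_annotations(table, path)
        back = read_annotations(path)
        observed = sorted(set().union(*(s.labels for s in table.samples)))
        assert back.class_vocabulary == observed
        for a, b in zip(table.samples, back.samples):
            assert (a.cell_id, a.protein_id, a.labels, a.grades) == \
                   (b.cell_id, b.protein_id, b.labels, b.grades)

    def test_grade_outside_1_3_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cell_id,protein_id,volume_path,labels,grades\n"
                     "c1,p1,v.tif,membrane,4\n")
        with pytest.raises(ValueError, match="grade"):
            read_annotations(p)

    def test_label_grade_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cell_id,protein_id,volume_path,labels,grades\n"
                     "c1,p1,v.tif,membrane|vesicles,3\n")
        with pytest.raises(ValueError, match="labels"):
            read_annotations(p)


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".tif", ".npz"])
    def test_write_read_round_trip(self, tmp_path, suffix):
        vol = np.random.default_rng(0).uniform(0, 10, (2, 3, 5, 5))
        path = tmp_path / f"v{suffix}"
        write_volume(vol, path)
        back = read_volume(path)
        assert back.shape == vol.shape
        assert np.allclose(back, vol, atol=1e-5)


def test_normalize_volume_is_per_channel_minmax():
    vol = np.stack([np.linspace(2, 6, 8).reshape(2, 2, 2),
                    np.full((2, 2, 2), 3.0)])
    out = normalize_volume(vol)
    assert out[0].min() == 0.0 and out[0].max() == 1.0
    assert np.all(out[1] == 0.0)  # constant channel maps to zero


def test_sample_invariants_enforced():
    with pytest.raises(ValueError, match="non-empty"):
        VolumeSample(cell_id="c", protein_id="p", labels=set(), grades={})
    with pytest.raises(ValueError, match="grades"):
        VolumeSample(cell_id="c", protein_id="p", labels={"membrane"},
                     grades={"vesicles": 3})
    with pytest.raises(ValueError, match="2, z, y, x"):
        VolumeSample(cell_id="c", protein_id="p", labels={"membrane"},
                     grades={"membrane": 3}, volume=np.zeros((3, 2, 2, 2)))
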