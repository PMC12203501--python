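"""Synthetic cell renderer, dataset generator and GO-style graph."""

import numpy as np
import pytest

from subloc3d import SimConfig, simulate_cell, simulate_dataset, simulate_kg
from subloc3d.simulate import (
    CLASS_VOCABULARY,
    cell_geometry,
    class_support_mask,
    _dropout_multipliers,
)

NOISE_OFF = dict(background=0.0, background_jitter=0.0, shot_noise=False)


class TestRenderers:
    @pytest.mark.parametrize("cls", CLASS_VOCABULARY)
    def test_protein_mass_lies_in_class_support(self, cls):
        cfg = SimConfig(shape=(10, 24, 24), classes=(cls,), **NOISE_OFF)
        rng = np.random.default_rng(42)
        geo_rng = np.random.default_rng(42)
        geo = cell_geometry(cfg.shape, geo_rng)  # same draw as simulate_cell
        sample, _ = simulate_cell({cls}, cfg, rng)
        mask = class_support_mask(cls, geo)
        prot = sample.volume[1]
        assert prot.sum() > 0
        assert prot[mask].sum() / prot.sum() >= 0.95

    def test_membrane_pattern_absent_from_nucleus(self):
        cfg = SimConfig(shape=(10, 24, 24), classes=("membrane",),
                        **NOISE_OFF)
        sample, _ = simulate_cell({"membrane"}, cfg,
                                  np.random.default_rng(3))
        nucleus = sample.volume[0] > 0.5
        assert sample.volume[1][nucleus].sum() == 0.0

    def test_nucleoplasm_mass_concentrated_in_nucleus(self):
        cfg = SimConfig(shape=(10, 24, 24), classes=("nucleoplasm",),
                        **NOISE_OFF)
        sample, _ = simulate_cell({"nucleoplasm"}, cfg,
                                  np.random.default_rng(4))
        nucleus = sample.volume[0] > 0.5
        prot = sample.volume[1]
        assert prot[nucleus].sum() / prot.sum() > 0.99

    def test_same_rng_seed_gives_bit_identical_volume(self):
        cfg = SimConfig(shape=(8, 16, 16))
        a, _ = simulate_cell({"vesicles"}, cfg, np.random.default_rng(11))
        b, _ = simulate_cell({"vesicles"}, cfg, np.random.default_rng(11))
        assert np.array_equal(a.volume, b.volume)

    def test_unknown_class_lists_vocabulary(self):
        cfg = SimConfig(shape=(8, 16, 16))
        with pytest.raises(ValueError, match="nucleoplasm"):
            simulate_cell({"mitochondria"}, cfg, np.random.default_rng(0))


class TestDataset:
    def test_sample_count_is_proteins_times_cells(self):
        cfg = SimConfig(shape=(8, 16, 16), n_proteins=30,
                        cells_per_protein=20, seed=0)
        table, _ = simulate_dataset(cfg)
        assert len(table.samples) == 600

    def test_zero_weak_annotation_keeps_all_patterns(self, tiny_dataset):
        table, truth = tiny_dataset
        for s in table.samples:
            assert truth.records[s.cell_id].realized == s.labels

    def test_dataset_deterministic_under_fixed_seed(self):
        cfg = SimConfig(shape=(8, 16, 16), n_proteins=4,
                        cells_per_protein=2, seed=5)
        t1, _ = simulate_dataset(cfg)
        t2, _ = simulate_dataset(cfg)
        for a, b in zip(t1.samples, t2.samples):
            assert a.labels == b.labels
            assert np.array_equal(a.volume, b.volume)

    def test_weak_annotation_rate_recovered_empirically(self):
        rate = 0.2
        cfg = SimConfig(shape=(8, 16, 16), n_proteins=60,
                        cells_per_protein=20, weight_range=(0.2, 1.0),
                        weak_annotation_rate=rate, seed=21, **NOISE_OFF)
        table, truth = simulate_dataset(cfg)
        # dropout probabilities are shared within a (protein, class)
        # cluster, so estimate the standard error from cluster means
        clusters: dict[tuple, list[int]] = {}
        total = 0
        for rec in truth.records.values():
            for cls in rec.labels:
                key = (rec.protein_id, cls)
                clusters.setdefault(key, []).append(
                    int(cls not in rec.realized))
                total += 1
        means = np.array([np.mean(v) for v in clusters.values()])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert total > 1000
        assert abs(means.mean() - rate) < 3 * se

    def test_grades_follow_weight_bands(self, tiny_dataset):
        table, truth = tiny_dataset
        cfg = SimConfig(shape=(8, 16, 16))
        for rec in truth.records.values():
            for cls, w in rec.weights.items():
                assert rec.grades[cls] == cfg.grade_for_weight(w)

    def test_concentrated_frequency_dominates_label_share(self):
        freqs = {c: (0.8 if c == "membrane" else 0.2 / 5)
                 for c in SimConfig().classes}
        cfg = SimConfig(shape=(8, 16, 16), n_proteins=100,
                        cells_per_protein=1, multilabel_rate=0.0,
                        class_frequencies=freqs, seed=2, **NOISE_OFF)
        table, _ = simulate_dataset(cfg)
        share = np.mean([("membrane" in s.labels) for s in table.samples])
        assert 0.70 <= share <= 0.90

    def test_dropout_multipliers_have_unit_marginal_mean(self):
        for wr in [(0.2, 1.0), (0.5, 1.0), (0.35, 0.9)]:
            cfg = SimConfig(shape=(8, 16, 16), weight_range=wr)
            mult = _dropout_multipliers(cfg)
            lo, hi = wr
            ws = np.linspace(lo, hi, 20001)[:-1] + (hi - lo) / 40000
            mean = np.mean([mult[cfg.grade_for_weight(w)] for w in ws])
            assert abs(mean - 1.0) < 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            SimConfig(shape=(4, 16, 16))
        with pytest.raises(ValueError, match="rate"):
            SimConfig(multilabel_rate=1.5)
        with pytest.raises(ValueError, match="frequencies"):
            SimConfig(class_frequencies={c: 0.0 for c in SimConfig().classes})
        with pytest.raises(ValueError, match="unknown"):
            SimConfig(classes=("lysosome",))


class TestKnowledgeGraphGeneration:
    def test_located_in_triples_match_labels_without_corruption(
            self, tiny_dataset, tiny_graph):
        table, _ = tiny_dataset
        labels_of = {s.protein_id: s.labels for s in table.samples}
        for pid, labels in labels_of.items():
            cc_tails = {t for h, r, t in tiny_graph.triples
                        if h == pid and r == "located_in"}
            assert cc_tails == {f"GO:CC:{c}" for c in labels}

    def test_graph_carries_categories_and_texts(self, tiny_graph):
        cats = set(tiny_graph.entities.values())
        assert cats == {"protein", "CC", "MF", "BP"}
        for e, cat in tiny_graph.entities.items():
            if cat != "protein":
                assert len(tiny_graph.go_texts[e]) > 10

    def test_fixed_seed_gives_identical_triple_set(self, tiny_dataset,
                                                   tiny_config, tiny_graph):
        table, _ = tiny_dataset
        again = simulate_kg(table, tiny_config)
        assert again.triples == tiny_graph.triples

    def test_corruption_rewires_some_cc_triples(self, tiny_dataset):
        table, _ = tiny_dataset
        cfg = SimConfig(shape=(8, 16, 16), n_proteins=8, cells_per_protein=4,
                        seed=7, kg_corruption_rate=0.5)
        corrupted = simulate_kg(table, cfg)
        labels_of = {s.protein_id: s.labels for s in table.samples}
        mismatches = 0
        for pid, labels in labels_of.items():
            cc_tails = {t for h, r, t in corrupted.triples
                        if h == pid and r == "located_in"}
            mismatches += cc_tails != {f"GO:CC:{c}" for c in labels}
        assert mismatches > 0
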