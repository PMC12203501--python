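"""Designed desk-scale experiments exercising the method end to end.

Each experiment fixes its own study conditions (dataset size, class set,
noise regime, training schedule) and reports per-seed results, so the
qualitative claims of the method — learnability of localization patterns
from 3-D volumes, the benefit of GO-derived knowledge for visually
confusable classes, the robustness value of the asymmetric
confidence-weighted loss under weak annotation, and the feature
aggregation effect of the protein-ID loss — can be checked on a single
CPU in minutes.  Sizes are deliberately small (tens of proteins, volumes
of (12, 32, 32)); the conditions each experiment uses are documented in
docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .data import stratified_protein_split
from .metrics import evaluate
from .simulate import (
    CLASS_VOCABULARY,
    SimConfig,
    simulate_dataset,
    simulate_kg,
)
from .trainer import LocalizationClassifier

__all__ = [
    "end_to_end_experiment",
    "knowledge_enhancement_experiment",
    "weak_annotation_experiment",
    "pida_experiment",
    "within_protein_cosine",
]


def _spread(base_seed: int, n: int) -> list[int]:
    """n distinct sub-seeds derived from one base seed, all below 2^31."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(1, 2**31 - 1, size=n)]

#: model-init replicates averaged per arm in paired comparisons; two
#: inits halve training-trajectory noise at twice the cost
N_REPLICATES = 2


def _arm_score(fit_and_score, seed: int, n_replicates: int = N_REPLICATES
               ) -> float:
    """Mean score of one experimental arm over model-init replicates."""
    scores = [fit_and_score((seed + 1_000_003 * rep) % (2**31 - 1))
              for rep in range(n_replicates)]
    return float(np.mean(scores))


def end_to_end_experiment(base_seed: int = 0, n_seeds: int = 5,
                          epochs: int = 10) -> dict:
    """Image-only training on the default synthetic screen.

    30 proteins x 20 cells, six classes, volumes (12, 32, 32), stratified
    protein-level 70/15/15 split; reports held-out-protein macro-MCC at
    the cell and source-image level for each seed.
    """
    cell_scores, image_scores = [], []
    for seed in _spread(base_seed, n_seeds):
        cfg = SimConfig(seed=seed)
        table, _ = simulate_dataset(cfg)
        stratified_protein_split(table, seed=seed)
        test = table.subset("test")
        yt = table.label_matrix(test)
        est = LocalizationClassifier(kge_method=None, epochs=epochs, seed=seed)
        est.fit(table)
        probs = est.predict_proba(test)
        cell_scores.append(
            evaluate(probs, yt, est.classes_).macro["mMCC"]
        )
        image_scores.append(
            evaluate(probs, yt, est.classes_, level="image",
                     image_ids=[s.image_id for s in test]).macro["mMCC"]
        )
    return {
        "cell_mmcc": cell_scores,
        "image_mmcc": image_scores,
        "n_pass": sum(m >= 0.8 for m in cell_scores),
        "n_seeds": n_seeds,
    }


def knowledge_enhancement_experiment(base_seed: int = 0, n_seeds: int = 5,
                                     epochs: int = 10) -> dict:
    """Full model (PairRE) vs image-only on confusable classes.

    Nucleolus is rendered with the nucleoplasm pattern, so the two
    classes are visually near-identical; their GO cellular-component
    triples still differ and are available for held-out proteins, so the
    knowledge pathway is the only route that can separate them.  The
    graph carries clean located_in triples only (no MF/BP distractors):
    the experiment isolates whether compartment triples disambiguate
    confusable classes, not robustness to annotation noise.
    """
    classes = ("nucleoplasm", "nucleolus", "cytoplasm", "membrane")
    # weight the class draw toward the confusable pair so the macro-MCC
    # comparison is dominated by the manipulated factor
    freqs = {"nucleoplasm": 0.35, "nucleolus": 0.35,
             "cytoplasm": 0.15, "membrane": 0.15}
    img_scores, kg_scores = [], []
    for seed in _spread(base_seed, n_seeds):
        cfg = SimConfig(seed=seed, classes=classes, cells_per_protein=10,
                        class_frequencies=freqs,
                        pattern_overrides={"nucleolus": "nucleoplasm"},
                        kg_extra_triples_per_protein=0)
        table, _ = simulate_dataset(cfg)
        graph = simulate_kg(table, cfg)
        stratified_protein_split(table, seed=seed)
        test = table.subset("test")
        yt = table.label_matrix(test)
        for scores, method in ((img_scores, None), (kg_scores, "pairre")):
            def run(model_seed, method=method):
                est = LocalizationClassifier(kge_method=method,
                                             epochs=epochs,
                                             seed=model_seed)
                est.fit(table, graph if method else None)
                rep = evaluate(est.predict_proba(test), yt, est.classes_)
                return rep.macro["mMCC"]

            scores.append(_arm_score(run, seed))
    wins = [k > i for k, i in zip(kg_scores, img_scores)]
    return {
        "image_only_mmcc": img_scores,
        "knowledge_mmcc": kg_scores,
        "n_wins": sum(wins),
        "n_seeds": n_seeds,
    }


#: fixed screen roster for the weak-annotation experiment: severely
#: imbalanced nine-class composition (rare classes down to one or two
#: proteins) with graded mixing-weight ladders, so every seed contains
#: grade-1 ("subtle and weak") annotations in both train and test.
#: Entries: (labels-with-weights, split).
_WEAK_ROSTER: tuple = (
    ({"nucleoplasm": 0.85}, "train"), ({"nucleoplasm": 0.60}, "train"),
    ({"nucleoplasm": 0.45}, "train"), ({"nucleoplasm": 0.30}, "val"),
    ({"nucleoplasm": 0.70}, "test"),
    ({"cytoplasm": 0.80}, "train"), ({"cytoplasm": 0.55}, "train"),
    ({"cytoplasm": 0.90}, "train"), ({"cytoplasm": 0.65}, "val"),
    ({"cytoplasm": 0.75}, "test"),
    ({"nucleoplasm": 0.80, "nucleolus": 0.30}, "train"),
    ({"nucleoplasm": 0.55, "nucleolus": 0.60}, "train"),
    ({"nucleoplasm": 0.70, "nucleolus": 0.25}, "test"),
    ({"cytoplasm": 0.75, "vesicles": 0.25}, "train"),
    ({"cytoplasm": 0.85, "vesicles": 0.50}, "train"),
    ({"cytoplasm": 0.80, "vesicles": 0.30}, "test"),
    ({"membrane": 0.80}, "train"), ({"membrane": 0.60}, "test"),
    ({"nucleolus": 0.75}, "train"), ({"nucleolus": 0.50}, "train"),
    ({"nucleolus": 0.60}, "test"),
    ({"er": 0.25, "nucleoplasm": 0.75}, "train"),
    ({"er": 0.50, "nucleoplasm": 0.60}, "train"),
    ({"er": 0.30, "nucleoplasm": 0.80}, "test"),
    ({"membrane": 0.75, "cell_contact": 0.35}, "train"),
    ({"membrane": 0.70, "cell_contact": 0.45}, "test"),
    ({"vesicles": 0.85}, "train"), ({"vesicles": 0.65}, "test"),
    ({"golgi": 0.60, "er": 0.40}, "train"),
    ({"golgi": 0.55, "er": 0.50}, "test"),
    ({"focal_adhesions": 0.45, "cytoplasm": 0.80}, "train"),
    ({"focal_adhesions": 0.55, "cytoplasm": 0.70}, "test"),
    ({"nucleoplasm": 0.60, "cytoplasm": 0.70}, "train"),
    ({"nucleoplasm": 0.35, "cytoplasm": 0.90}, "train"),
    ({"nucleoplasm": 0.55, "cytoplasm": 0.65}, "test"),
    ({"golgi": 0.70}, "train"),
)


def _roster_config(roster, seed: int, **kw) -> tuple[SimConfig, list[str]]:
    specs = tuple((frozenset(w), dict(w)) for w, _ in roster)
    cfg = SimConfig(seed=seed, classes=CLASS_VOCABULARY,
                    n_proteins=len(specs), protein_specs=specs, **kw)
    return cfg, [split for _, split in roster]


def weak_annotation_experiment(base_seed: int = 0, n_seeds: int = 5,
                               epochs: int = 8,
                               weak_annotation_rate: float = 0.2) -> dict:
    """ASL + confidence weights vs plain BCE under weak annotation.

    A designed stress test in the regime the loss was built for: a fixed
    nine-class roster with severe imbalance and graded mixing weights
    (grade-1 annotations present in train and test; their patterns are
    absent from most cells at the 20% marginal dropout rate), fixed
    protein-level splits, and randomness confined to rendering, dropout
    realization and training.  Models are compared on clean-truth
    (realized-pattern) macro-MCC over held-out proteins, each arm
    averaged over model-init replicates.
    """
    asl_scores, bce_scores = [], []
    for seed in _spread(base_seed, n_seeds):
        cfg, splits = _roster_config(
            _WEAK_ROSTER, seed, cells_per_protein=10,
            weak_annotation_rate=weak_annotation_rate,
        )
        table, truth = simulate_dataset(cfg)
        ordered = sorted(table.protein_index, key=table.protein_index.get)
        assignment = dict(zip(ordered, splits))
        for s in table.samples:
            s.split = assignment[s.protein_id]
        test = table.subset("test")
        yt_clean = truth.realized_matrix(test, table.class_vocabulary)
        for scores, kw in (
            (asl_scores, {}),
            (bce_scores, dict(r=0.0, m=0.0, use_confidence_weights=False)),
        ):
            def run(model_seed, kw=kw):
                est = LocalizationClassifier(kge_method=None, epochs=epochs,
                                             seed=model_seed, **kw)
                est.fit(table)
                rep = evaluate(est.predict_proba(test), yt_clean,
                               est.classes_)
                return rep.macro["mMCC"]

            scores.append(_arm_score(run, seed))
    wins = [a > b for a, b in zip(asl_scores, bce_scores)]
    return {
        "asl_ccw_mmcc": asl_scores,
        "plain_bce_mmcc": bce_scores,
        "n_wins": sum(wins),
        "n_seeds": n_seeds,
    }


def pida_experiment(base_seed: int = 0, n_seeds: int = 5,
                    epochs: int = 8) -> dict:
    """Protein-ID aggregation effect on within-protein feature cohesion.

    Measured in the knowledge-enhanced configuration the ID loss was
    designed to support (protein entities are image-derived there, so
    per-protein feature consistency is what makes the embedding loss
    meaningful): PairRE joint training on the default screen with
    heterogeneous cells (weak-annotation dropout 0.3, full mixing-weight
    range).  The mean within-protein cosine similarity of fused features
    (mean-centered) is compared between otherwise identical trainings
    with and without the ID loss, each arm averaged over three
    model-init replicates.
    """
    with_scores, without_scores = [], []
    for seed in _spread(base_seed, n_seeds):
        cfg = SimConfig(seed=seed, cells_per_protein=10,
                        weak_annotation_rate=0.3, weight_range=(0.2, 1.0))
        table, _ = simulate_dataset(cfg)
        graph = simulate_kg(table, cfg)
        stratified_protein_split(table, seed=seed)
        train = table.subset("train")
        pids = [s.protein_id for s in train]
        for scores, wid in ((with_scores, 0.1), (without_scores, 0.0)):
            def run(model_seed, wid=wid):
                est = LocalizationClassifier(kge_method="pairre",
                                             epochs=epochs,
                                             w_id=wid, seed=model_seed,
                                             validate_each_epoch=False)
                est.fit(table, graph)
                return within_protein_cosine(est.fused_features(train),
                                             pids)

            scores.append(_arm_score(run, seed, n_replicates=3))
    wins = [a > b for a, b in zip(with_scores, without_scores)]
    return {
        "with_pida_cosine": with_scores,
        "without_pida_cosine": without_scores,
        "n_wins": sum(wins),
        "n_seeds": n_seeds,
    }


def within_protein_cosine(features: np.ndarray, protein_ids) -> float:
    """Mean pairwise cosine similarity of cells within each protein.

    Features are mean-centered first: the raw fused features share a
    dominant direction that saturates cosines near 1 and would mask any
    clustering structure.
    """
    F = np.asarray(features, dtype=np.float64)
    F = F - F.mean(axis=0, keepdims=True)
    F = F / np.maximum(np.linalg.norm(F, axis=1, keepdims=True), 1e-12)
    pids = np.asarray(protein_ids)
    vals = []
    for p in np.unique(pids):
        idx = np.flatnonzero(pids == p)
        n = len(idx)
        if n < 2:
            continue
        g = F[idx] @ F[idx].T
        vals.append((g.sum() - n) / (n * (n - 1)))
    if not vals:
        raise ValueError("need at least one protein with two or more cells")
    return float(np.mean(vals))
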