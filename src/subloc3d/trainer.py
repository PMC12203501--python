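"""Joint training of the encoder, heads and knowledge-graph embeddings.

The public surface is :class:`LocalizationClassifier`, a scikit-learn
style estimator: hyperparameters in ``__init__`` (so ``get_params`` /
``set_params`` and cloning work), ``fit`` on a :class:`~subloc3d.data.
DatasetTable` (plus an optional knowledge graph), ``predict_proba`` /
``predict`` on new samples, and fitted state in trailing-underscore
attributes.  The module-level :func:`train` and :func:`predict` functions
are thin wrappers.

Per optimisation step the model runs the dual-branch forward pass, the
confidence-weighted asymmetric classification loss, the protein-ID
aggregation loss, and — when a graph is supplied — the contrastive
knowledge-embedding loss in which the head entity of each sampled
protein-GO triple is the *current cell's* adapted fused feature, so
image gradients carry protein knowledge.  Prediction is self-contained
for proteins unseen during training: their knowledge features are
recovered from their triples alone by head inversion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .autodiff import Tensor, no_grad
from .data import DatasetTable, VolumeSample, normalize_volume
from .knowledge import KGEModel, KnowledgeGraph, knowledge_feature
from .layers import Adam
from .losses import LossConfig, alpha_from_grades, ke_loss, slc_loss, total_loss
from .losses import _asymmetric_terms
from .metrics import evaluate
from .network import DualBranchNet, EncoderConfig

__all__ = ["LocalizationClassifier", "TrainReport", "train", "predict"]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainReport:
    history: pd.DataFrame
    best_epoch: int
    best_metric: float
    seeds: dict[str, int] = field(default_factory=dict)
    checkpoint_path: str | None = None


class LocalizationClassifier(BaseEstimator):
    """Multi-label localization classifier over 3-D single-cell volumes.

    Parameters mirror the encoder, loss and optimisation knobs; the
    defaults are desk-scale (volumes around (12, 32, 32), minutes of CPU
    training).  ``kge_method`` selects the knowledge-embedding scoring
    function ('transe', 'rotate', 'pairre', 'complex'); with ``None`` or
    no graph passed to :meth:`fit`, the model is the image-only ablation.
    """

    def __init__(self, *, n_blocks=3, base_channels=4, fused_dim=128,
                 knowledge_dim=64, entity_dim=32, kge_method="pairre",
                 gamma=6.0, n_negatives=8, k_triples=4, go_go_per_step=4,
                 epochs=10, batch_size=16, lr=1e-3,
                 r=4.0, m=0.05, r_id=4.0, m_id=0.1,
                 use_confidence_weights=True,
                 w_slc=1.0, w_ke=0.1, w_id=0.1,
                 threshold=0.5, validate_each_epoch=True, augment=True,
                 modality_dropout=0.4, protein_rep="batch",
                 ema_momentum=0.9, seed=0):
        self.n_blocks = n_blocks
        self.base_channels = base_channels
        self.fused_dim = fused_dim
        self.knowledge_dim = knowledge_dim
        self.entity_dim = entity_dim
        self.kge_method = kge_method
        self.gamma = gamma
        self.n_negatives = n_negatives
        self.k_triples = k_triples
        self.go_go_per_step = go_go_per_step
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.r = r
        self.m = m
        self.r_id = r_id
        self.m_id = m_id
        self.use_confidence_weights = use_confidence_weights
        self.w_slc = w_slc
        self.w_ke = w_ke
        self.w_id = w_id
        self.threshold = threshold
        self.validate_each_epoch = validate_each_epoch
        self.augment = augment
        self.modality_dropout = modality_dropout
        self.protein_rep = protein_rep
        self.ema_momentum = ema_momentum
        self.seed = seed

    # -- helpers ------------------------------------------------------------
    def _loss_config(self) -> LossConfig:
        cfg = LossConfig(r=self.r, m=self.m, r_id=self.r_id, m_id=self.m_id,
                         w_slc=self.w_slc, w_ke=self.w_ke, w_id=self.w_id)
        if not self.use_confidence_weights:
            cfg.alpha_by_grade = {1: 1.0, 2: 1.0, 3: 1.0}
        return cfg

    def _prepare(self, samples: list[VolumeSample]) -> np.ndarray:
        vols = []
        for s in samples:
            if s.volume is None:
                raise ValueError(f"sample {s.cell_id} has no volume loaded")
            vols.append(normalize_volume(s.volume))
        return np.stack(vols)

    def _knowledge_rows(self, protein_ids: list[str]) -> np.ndarray:
        """Per-cell knowledge features from the current embeddings.

        Features are L2-normalized per protein (zero stays zero for the
        no-triples fallback) so their scale is comparable across proteins
        and scoring methods before the knowledge adapter.
        """
        rows = np.zeros((len(protein_ids), self.entity_dim))
        flags = np.zeros(len(protein_ids), dtype=bool)
        cache: dict[str, tuple[np.ndarray, bool]] = {}
        for i, pid in enumerate(protein_ids):
            if pid not in cache:
                vec, ok = knowledge_feature(self.kge_, pid, self.graph_)
                norm = np.linalg.norm(vec)
                if norm > 0:
                    vec = vec / norm
                cache[pid] = (vec, ok)
            rows[i], flags[i] = cache[pid]
        return rows, flags

    # -- fitting ------------------------------------------------------------
    def fit(self, table: DatasetTable, graph: KnowledgeGraph | None = None):
        rng = np.random.default_rng(self.seed)
        # knowledge-path randomness (triple/negative sampling, modality
        # dropout) draws from its own stream so that runs with and
        # without a graph see identical batch shuffling and augmentation
        kg_rng = np.random.default_rng(np.random.SeedSequence(
            [self.seed, 0x6B67]))
        train_samples = table.subset("train") or list(table.samples)
        val_samples = table.subset("val")
        self.classes_ = list(table.class_vocabulary)
        self.protein_index_ = dict(table.protein_index)
        self.encoder_config_ = EncoderConfig(
            n_classes=len(self.classes_),
            n_proteins=len(self.protein_index_),
            n_blocks=self.n_blocks,
            base_channels=self.base_channels,
            fused_dim=self.fused_dim,
            knowledge_dim=self.knowledge_dim,
            knowledge_in_dim=self.entity_dim,
        )
        self.net_ = DualBranchNet(self.encoder_config_, seed=self.seed)
        # k_triples == 0 or w_ke == 0 switches the knowledge path off
        # entirely, making the run identical to the graph-absent
        # (image-only) ablation, gradients included
        use_kg = (graph is not None and self.kge_method is not None
                  and self.k_triples > 0 and self.w_ke > 0)
        self.kge_ = None
        self.graph_ = None
        if use_kg:
            self.kge_ = KGEModel(
                self.kge_method, graph, entity_dim=self.entity_dim,
                fused_dim=self.fused_dim, gamma=self.gamma,
                n_negatives=self.n_negatives, seed=self.seed,
            )
            self.graph_ = graph

        cfg = self._loss_config()
        X = self._prepare(train_samples)
        y = table.label_matrix(train_samples)
        alpha = (alpha_from_grades(y, [s.grades for s in train_samples],
                                   self.classes_, cfg)
                 if self.use_confidence_weights else np.ones_like(y, float))
        pid_ids = np.array([self.protein_index_[s.protein_id]
                            for s in train_samples])
        pida_gate = np.array(
            [bool(s.labels & cfg.pida_classes) for s in train_samples],
            dtype=np.float64,
        )
        protein_names = [s.protein_id for s in train_samples]

        params = self.net_.parameters()
        if self.kge_ is not None:
            params = params + self.kge_.parameters()
        opt = Adam(params, lr=self.lr)

        triples_by_protein = {}
        go_go = []
        if self.graph_ is not None:
            for pid in self.protein_index_:
                trs = self.graph_.triples_for_protein(pid)
                triples_by_protein[pid] = [
                    (self.kge_.relation_index[r], self.kge_.go_index[t])
                    for _, r, t in trs
                ]
            go_go = [
                (self.kge_.go_index[h], self.kge_.relation_index[r],
                 self.kge_.go_index[t])
                for h, r, t in self.graph_.go_go_triples()
            ]
            self._warned_proteins = set()
            self._ema_bank = np.zeros((len(self.protein_index_),
                                       self.entity_dim))
            self._ema_seen = np.zeros(len(self.protein_index_), dtype=bool)

        n = len(train_samples)
        rows = []
        step_rows = []
        step = 0
        best = (-np.inf, 0, None)
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            ep = {"l_slc": 0.0, "l_ke": 0.0, "l_id": 0.0, "total": 0.0}
            n_batches = 0
            self.net_.train()
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xv = X[idx]
                if self.augment:
                    xv = _augment_batch(xv, rng)
                xb = Tensor(xv)
                kb = None
                fmask = None
                if self.kge_ is not None:
                    krows, _ = self._knowledge_rows(
                        [protein_names[i] for i in idx]
                    )
                    kb = Tensor(krows)
                    if self.modality_dropout > 0:
                        fmask = (kg_rng.random(len(idx))
                                 >= self.modality_dropout).astype(float)
                out = self.net_.forward(xb, kb, fused_mask=fmask)
                l_slc = slc_loss(out.class_probs, y[idx], alpha[idx], cfg)
                l_id = self._pida_batch(out.id_probs, pid_ids[idx],
                                        pida_gate[idx], cfg) \
                    if self.w_id > 0 else Tensor(np.zeros(()))
                l_ke = self._ke_batch(out.fused, [protein_names[i] for i in idx],
                                      triples_by_protein, go_go, kg_rng) \
                    if (self.kge_ is not None and self.w_ke > 0
                        and self.k_triples > 0) else Tensor(np.zeros(()))
                loss = total_loss(l_slc, l_ke, l_id, cfg)
                opt.zero_grad()
                loss.backward()
                opt.step()
                step += 1
                step_row = {
                    "step": step,
                    "l_slc": l_slc.item(),
                    "l_ke": l_ke.item() if isinstance(l_ke, Tensor) else l_ke,
                    "l_id": l_id.item() if isinstance(l_id, Tensor) else l_id,
                    "total": loss.item(),
                }
                step_rows.append(step_row)
                for key in ("l_slc", "l_ke", "l_id", "total"):
                    ep[key] += step_row[key]
                n_batches += 1
            row = {k: v / n_batches for k, v in ep.items()}
            row["epoch"] = epoch
            if self.validate_each_epoch and val_samples:
                probs, _, _ = self._forward_samples(val_samples)
                try:
                    rep = evaluate(probs, table.label_matrix(val_samples),
                                   self.classes_, threshold=self.threshold)
                except ValueError:
                    # degenerate validation split (no discriminable class)
                    rep = None
                if rep is not None:
                    row["val_mMCC"] = rep.macro["mMCC"]
                    if rep.macro["mMCC"] > best[0]:
                        best = (rep.macro["mMCC"], epoch,
                                self._snapshot_state())
            rows.append(row)
        self.history_ = pd.DataFrame(rows)
        self.step_log_ = pd.DataFrame(step_rows)
        if best[2] is not None:
            self.best_epoch_ = best[1]
            self.best_val_mmcc_ = best[0]
            self._restore_state(best[2])
        else:
            self.best_epoch_ = self.epochs
            self.best_val_mmcc_ = float("nan")
        self.net_.eval()
        return self

    def _pida_batch(self, id_probs: Tensor, true_ids: np.ndarray,
                    gate: np.ndarray, cfg: LossConfig) -> Tensor:
        n_prot = id_probs.shape[-1]
        y = np.zeros((len(true_ids), n_prot))
        y[np.arange(len(true_ids)), true_ids] = 1.0
        terms = _asymmetric_terms(id_probs, y, np.ones_like(y), cfg.r_id,
                                  cfg.m_id)
        per_sample = terms.mean(axis=1)
        return (per_sample * gate).mean()

    def _ke_batch(self, fused: Tensor, protein_ids: list[str],
                  triples_by_protein, go_go, rng) -> Tensor:
        """Knowledge-embedding loss for one batch.

        With ``protein_rep='batch'`` (default) the head entity of each
        sampled protein-GO triple is the current cell's adapted fused
        feature, so gradients reach the encoder.  With ``'ema'`` heads
        come from an exponential-moving-average memory bank of adapted
        features instead: the embedding loss then trains only the KGE
        parameters, and image features drift more slowly into the bank.
        """
        kge = self.kge_
        h_rows, rel_idx, tail_idx = [], [], []
        for i, pid in enumerate(protein_ids):
            trs = triples_by_protein.get(pid, [])
            if not trs:
                if pid not in self._warned_proteins:
                    warnings.warn(f"protein {pid} has no knowledge triples; "
                                  "it contributes no embedding loss")
                    self._warned_proteins.add(pid)
                continue
            take = rng.choice(len(trs), size=min(self.k_triples, len(trs)),
                              replace=False)
            for j in take:
                h_rows.append(i)
                rel_idx.append(trs[j][0])
                tail_idx.append(trs[j][1])
        if not h_rows:
            return Tensor(np.zeros(()))
        if self.protein_rep == "ema":
            adapted = kge.protein_adapter(fused.detach()).data
            m = self.ema_momentum
            for i, pid in enumerate(protein_ids):
                j = self.protein_index_[pid]
                if self._ema_seen[j]:
                    self._ema_bank[j] = m * self._ema_bank[j] \
                        + (1 - m) * adapted[i]
                else:
                    self._ema_bank[j] = adapted[i]
                    self._ema_seen[j] = True
            bank_rows = np.array([
                self.protein_index_[protein_ids[i]] for i in h_rows
            ])
            h = Tensor(self._ema_bank[bank_rows])
        elif self.protein_rep == "batch":
            h = kge.protein_adapter(fused.take_rows(np.array(h_rows)))
        else:
            raise ValueError(
                f"unknown protein_rep {self.protein_rep!r}; choose "
                "'batch' or 'ema'"
            )
        rel_idx = np.array(rel_idx)
        tail_idx = np.array(tail_idx)
        n_neg = kge.n_negatives
        neg_tails = self._negative_tails(tail_idx, n_neg, rng)

        if go_go and self.go_go_per_step > 0:
            picks = rng.integers(0, len(go_go), size=self.go_go_per_step)
            gg = [go_go[int(p)] for p in picks]
            gg_h = np.array([x[0] for x in gg])
            gg_r = np.array([x[1] for x in gg])
            gg_t = np.array([x[2] for x in gg])
            h = _stack_rows(h, kge.go_embeddings.take_rows(gg_h))
            rel_idx = np.concatenate([rel_idx, gg_r])
            tail_idx = np.concatenate([tail_idx, gg_t])
            neg_tails = np.concatenate(
                [neg_tails, self._negative_tails(gg_t, n_neg, rng)]
            )

        m = len(tail_idx)
        t = kge.go_embeddings.take_rows(tail_idx)
        d_pos = kge.score_rows(h, rel_idx, t)
        h_rep = h.take_rows(np.repeat(np.arange(m), n_neg))
        t_neg = kge.go_embeddings.take_rows(neg_tails.reshape(-1))
        d_neg = kge.score_rows(h_rep, np.repeat(rel_idx, n_neg), t_neg)
        pos_term = -(self.gamma - d_pos).sigmoid().clip_min(1e-12).log()
        neg_term = -(d_neg - self.gamma).sigmoid().clip_min(1e-12).log()
        return pos_term.mean() + neg_term.reshape(m, n_neg).mean(axis=1).mean()

    def _negative_tails(self, tail_idx: np.ndarray, n_neg: int,
                        rng: np.random.Generator) -> np.ndarray:
        """Knowledge-aware corruption: same-category tails, never the truth."""
        kge = self.kge_
        out = np.empty((len(tail_idx), n_neg), dtype=np.intp)
        for i, ti in enumerate(tail_idx):
            cat = kge.go_categories[ti]
            members = np.flatnonzero(kge.go_categories == cat)
            members = members[members != ti]
            if len(members) == 0:
                raise ValueError(
                    f"GO category {cat!r} has a single member; cannot "
                    "sample negatives"
                )
            out[i] = members[rng.integers(0, len(members), size=n_neg)]
        return out

    def _snapshot_state(self):
        state = {"net": self.net_.state_dict()}
        if self.kge_ is not None:
            state["kge"] = self.kge_.state_dict()
        return state

    def _restore_state(self, state):
        self.net_.load_state_dict(state["net"])
        if self.kge_ is not None and "kge" in state:
            self.kge_.load_state_dict(state["kge"])

    # -- inference ----------------------------------------------------------
    def _forward_samples(self, samples: list[VolumeSample],
                         batch_size: int = 64):
        X = self._prepare(samples)
        self.net_.eval()
        probs = []
        fused = []
        flags = np.zeros(len(samples), dtype=bool)
        with no_grad():
            for start in range(0, len(samples), batch_size):
                sl = slice(start, start + batch_size)
                kb = None
                if self.kge_ is not None and self.graph_ is not None:
                    krows, f = self._knowledge_rows(
                        [s.protein_id for s in samples[sl]]
                    )
                    kb = Tensor(krows)
                    flags[sl] = f
                out = self.net_.forward(Tensor(X[sl]), kb)
                probs.append(out.class_probs.data)
                fused.append(out.fused.data)
        return np.concatenate(probs), np.concatenate(fused), flags

    def predict_proba(self, samples: list[VolumeSample]) -> np.ndarray:
        probs, _, _ = self._forward_samples(samples)
        return probs

    def predict(self, samples: list[VolumeSample]) -> np.ndarray:
        return (self.predict_proba(samples) >= self.threshold).astype(np.int64)

    def fused_features(self, samples: list[VolumeSample]) -> np.ndarray:
        _, fused, _ = self._forward_samples(samples)
        return fused

    def knowledge_flags(self, samples: list[VolumeSample]) -> np.ndarray:
        """True where the non-fallback knowledge path was used."""
        _, _, flags = self._forward_samples(samples)
        return flags

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "classes": self.classes_,
            "protein_index": self.protein_index_,
            "has_kge": self.kge_ is not None,
        }
        arrays = {f"net::{k}": v for k, v in self.net_.state_dict().items()}
        if self.kge_ is not None:
            arrays.update(
                {f"kge::{k}": v for k, v in self.kge_.state_dict().items()}
            )
        np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, graph: KnowledgeGraph | None = None
             ) -> "LocalizationClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"checkpoint format {meta['format_version']} not supported"
            )
        est = cls(**meta["params"])
        est.classes_ = meta["classes"]
        est.protein_index_ = meta["protein_index"]
        est.encoder_config_ = EncoderConfig(
            n_classes=len(est.classes_), n_proteins=len(est.protein_index_),
            n_blocks=est.n_blocks, base_channels=est.base_channels,
            fused_dim=est.fused_dim, knowledge_dim=est.knowledge_dim,
            knowledge_in_dim=est.entity_dim,
        )
        est.net_ = DualBranchNet(est.encoder_config_, seed=est.seed)
        est.net_.load_state_dict(
            {k.split("::", 1)[1]: v for k, v in arrays.items()
             if k.startswith("net::")}
        )
        est.net_.eval()
        est.kge_ = None
        est.graph_ = None
        if meta["has_kge"]:
            if graph is None:
                raise ValueError(
                    "checkpoint was trained with a knowledge graph; pass it "
                    "to load()"
                )
            est.kge_ = KGEModel(
                est.kge_method, graph, entity_dim=est.entity_dim,
                fused_dim=est.fused_dim, gamma=est.gamma,
                n_negatives=est.n_negatives, seed=est.seed,
            )
            est.kge_.load_state_dict(
                {k.split("::", 1)[1]: v for k, v in arrays.items()
                 if k.startswith("kge::")}
            )
            est.graph_ = graph
        est.history_ = pd.DataFrame()
        return est


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random y/x flips and y-x transposition (square volumes only)."""
    out = x
    if rng.random() < 0.5:
        out = out[..., ::-1, :]
    if rng.random() < 0.5:
        out = out[..., :, ::-1]
    if out.shape[-1] == out.shape[-2] and rng.random() < 0.5:
        out = np.swapaxes(out, -1, -2)
    return np.ascontiguousarray(out)


def _stack_rows(a: Tensor, b: Tensor) -> Tensor:
    from .autodiff import concat

    return concat([a.reshape(a.shape[0], -1), b.reshape(b.shape[0], -1)],
                  axis=0)


# -- functional wrappers ------------------------------------------------------


def train(table: DatasetTable, graph: KnowledgeGraph | None = None,
          **params) -> tuple[LocalizationClassifier, TrainReport]:
    """Fit a classifier and return it with its training report."""
    est = LocalizationClassifier(**params)
    est.fit(table, graph)
    report = TrainReport(
        history=est.history_,
        best_epoch=est.best_epoch_,
        best_metric=est.best_val_mmcc_,
        seeds={"seed": est.seed},
    )
    return est, report


def predict(model: LocalizationClassifier, samples: list[VolumeSample],
            graph: KnowledgeGraph | None = None) -> dict[str, np.ndarray]:
    """Class probabilities, hard calls, fused features and knowledge flags."""
    if graph is not None:
        model.graph_ = graph
    probs, fused, flags = model._forward_samples(samples)
    return {
        "probabilities": probs,
        "calls": (probs >= model.threshold).astype(np.int64),
        "fused_features": fused,
        "knowledge_used": flags,
    }
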