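"""The three training losses and their weighted combination.

* ``slc_loss`` — multi-label subcellular-localization classification loss:
  asymmetric loss (ASL) with focusing parameter r and probability margin m
  on the negative term, times per-class confidence weights alpha derived
  from annotation grades (grade 3 -> 1.0, 2 -> 0.5, 1 -> 0.1; negatives
  always weigh 1).
* ``ke_loss`` — margin-based contrastive knowledge-embedding loss over one
  positive triple distance and n negative-sample distances.
* ``pida_loss`` — protein-ID aggregation: asymmetric single-label loss on
  the softmax protein-ID head, active only for cells whose labels touch
  the nine low-variability localization classes.

All logarithms are natural; probabilities are clamped with eps = 1e-12
inside logs so every loss is finite on the closed interval [0, 1].
Functions accept plain arrays (returning floats) or autodiff Tensors
(returning Tensors), so the same code defines both the reported values
and the training gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = ["LossConfig", "slc_loss", "ke_loss", "pida_loss", "total_loss",
           "alpha_from_grades", "PIDA_CLASSES"]

EPS = 1e-12

#: the nine low-variability localization classes the ID-aggregation loss
#: is restricted to
PIDA_CLASSES = frozenset({
    "cytoplasm", "nucleoplasm", "nucleolus", "focal_adhesions",
    "cell_contact", "membrane", "er", "vesicles", "golgi",
})


@dataclass
class LossConfig:
    r: float = 4.0
    m: float = 0.05
    alpha_by_grade: dict[int, float] = field(
        default_factory=lambda: {3: 1.0, 2: 0.5, 1: 0.1}
    )
    r_id: float = 4.0
    m_id: float = 0.1
    pida_classes: frozenset[str] = PIDA_CLASSES
    w_slc: float = 1.0
    w_ke: float = 0.1
    w_id: float = 0.1

    def __post_init__(self):
        if self.r < 0 or self.r_id < 0:
            raise ValueError("focusing parameters r, r_id must be >= 0")
        if not (0 <= self.m < 1 and 0 <= self.m_id < 1):
            raise ValueError("margins m, m_id must be in [0, 1)")
        if any(a <= 0 for a in self.alpha_by_grade.values()):
            raise ValueError("confidence weights must be positive")
        if min(self.w_slc, self.w_ke, self.w_id) < 0:
            raise ValueError("loss weights must be non-negative")


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def alpha_from_grades(labels: np.ndarray, grades_rows: list[dict[str, int]],
                      class_vocabulary: list[str], config: LossConfig
                      ) -> np.ndarray:
    """Per-class confidence weights: alpha_by_grade on positives, 1 on negatives."""
    alpha = np.ones_like(np.asarray(labels, dtype=np.float64))
    for i, grades in enumerate(grades_rows):
        for cls, g in grades.items():
            j = class_vocabulary.index(cls)
            alpha[i, j] = config.alpha_by_grade[g]
    return alpha


def _asymmetric_terms(probs: Tensor, y: np.ndarray, alpha: np.ndarray,
                      r: float, m: float) -> Tensor:
    """alpha * [-y ln p - (1-y) (p-)^r ln(1 - p-)], elementwise."""
    y = np.asarray(y, dtype=np.float64)
    pos = (-y) * probs.clip_min(EPS).log()
    shifted = (probs - m).clip_min(0.0)
    neg = (-(1.0 - y)) * shifted**r * (1.0 - shifted).clip_min(EPS).log()
    return (pos + neg) * alpha


def slc_loss(class_probs, labels, alpha=None, config: LossConfig | None = None):
    """Confidence-weighted asymmetric multi-label classification loss.

    ``class_probs`` and ``labels`` are (C,) or (B, C); per-sample losses
    average over classes, and a batch averages over samples.
    """
    config = config or LossConfig()
    probs, was_tensor = _as_tensor(class_probs)
    if np.isnan(probs.data).any():
        raise ValueError("class probabilities contain NaN")
    y = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    p = probs if probs.ndim == 2 else probs.reshape(1, -1)
    if alpha is None:
        alpha = np.ones_like(y)
    alpha = np.atleast_2d(np.asarray(alpha, dtype=np.float64))
    terms = _asymmetric_terms(p, y, alpha, config.r, config.m)
    out = terms.mean(axis=1).mean()
    return out if was_tensor else out.item()


def ke_loss(d_pos, d_negs, gamma: float):
    """-ln sigma(gamma - d_pos) - (1/n) sum ln sigma(d_neg - gamma)."""
    dn, negs_tensor = _as_tensor(d_negs)
    if dn.data.size == 0:
        raise ValueError("ke_loss requires at least one negative sample")
    dp, pos_tensor = _as_tensor(d_pos)
    pos_term = -(gamma - dp).sigmoid().clip_min(EPS).log()
    neg_term = -((dn - gamma).sigmoid().clip_min(EPS).log()).mean()
    out = pos_term.sum() + neg_term  # d_pos is scalar or size-1
    return out if (negs_tensor or pos_tensor) else out.item()


def pida_loss(id_probs, true_id: int, sample_labels, config: LossConfig | None = None):
    """Asymmetric single-label protein-ID loss, gated on the nine classes."""
    config = config or LossConfig()
    probs, was_tensor = _as_tensor(id_probs)
    n = probs.shape[-1]
    if not 0 <= true_id < n:
        raise ValueError(f"true_id {true_id} outside 0..{n - 1}")
    if not set(sample_labels) & set(config.pida_classes):
        zero = Tensor(np.zeros(()))
        return zero if was_tensor else 0.0
    y = np.zeros(n)
    y[true_id] = 1.0
    p = probs.reshape(1, -1)
    terms = _asymmetric_terms(p, y[None], np.ones((1, n)), config.r_id,
                              config.m_id)
    out = terms.mean(axis=1).mean()
    return out if was_tensor else out.item()


def total_loss(l_slc, l_ke, l_id, config: LossConfig | None = None):
    """Weighted sum, default 1.0 * slc + 0.1 * ke + 0.1 * id."""
    config = config or LossConfig()
    return config.w_slc * l_slc + config.w_ke * l_ke + config.w_id * l_id
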