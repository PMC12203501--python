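"""Dual-branch residual encoder with adaptive-gating fusion and heads.

A 3-D residual stack consumes the two-channel single-cell volume and a
parallel 2-D stack consumes its maximum-intensity z-projection; both end
in global average pooling.  The branch features are combined by an
adaptive gate — an elementwise sigmoid gate computed from the
concatenated branches — and a fully connected layer maps the gated
mixture to the fused image feature (default 768-d).  The classification
head concatenates the fused feature with the protein knowledge feature
and applies independent per-class sigmoids (multi-label); the protein-ID
head is a softmax over training proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .data import normalize_volume, project_z
from .layers import (
    Linear,
    Module,
    ResidualBlock,
    global_average_pool,
    global_max_pool,
)

__all__ = ["EncoderConfig", "ForwardOutput", "DualBranchNet"]


@dataclass
class EncoderConfig:
    n_classes: int
    n_proteins: int
    n_blocks: int = 6
    base_channels: int = 8
    channel_schedule: tuple[int, ...] | None = None
    fused_dim: int = 768
    knowledge_dim: int = 32
    knowledge_in_dim: int = 16  # entity_dim of the KGE model
    in_channels: int = 2
    projection: str = "max"

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.fused_dim <= 0:
            raise ValueError("fused_dim must be positive")
        if self.channel_schedule is None:
            cap = 8 * self.base_channels
            self.channel_schedule = tuple(
                min(self.base_channels * 2**i, cap) for i in range(self.n_blocks)
            )
        if len(self.channel_schedule) != self.n_blocks:
            raise ValueError("channel_schedule length must equal n_blocks")


@dataclass
class ForwardOutput:
    f3d: Tensor
    f2d: Tensor
    fused: Tensor
    class_probs: Tensor
    id_probs: Tensor


class DualBranchNet(Module):
    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        chans = config.channel_schedule
        self.blocks3d = [
            ResidualBlock(3, config.in_channels if i == 0 else chans[i - 1],
                          chans[i], rng, stride=2)
            for i in range(config.n_blocks)
        ]
        self.blocks2d = [
            ResidualBlock(2, config.in_channels if i == 0 else chans[i - 1],
                          chans[i], rng, stride=2)
            for i in range(config.n_blocks)
        ]
        feat = chans[-1]
        self.gate = Linear(2 * feat, feat, rng)
        self.fuse = Linear(feat, config.fused_dim, rng)
        self.knowledge_adapter = Linear(config.knowledge_in_dim,
                                        config.knowledge_dim, rng)
        self.classifier = Linear(config.fused_dim + config.knowledge_dim,
                                 config.n_classes, rng)
        self.id_head = Linear(config.fused_dim, config.n_proteins, rng)

    # -- pieces -------------------------------------------------------------
    def _check_spatial(self, spatial: tuple[int, ...]) -> None:
        need = 2 ** (self.config.n_blocks - 1)
        if min(spatial) < need:
            raise ValueError(
                f"spatial size {spatial} too small for "
                f"{self.config.n_blocks} downsampling blocks (needs every "
                f"axis >= {need}); use fewer blocks"
            )

    def branch_features(self, volumes: Tensor) -> tuple[Tensor, Tensor]:
        """(B, 2, z, y, x) -> pooled (B, F) features of both branches."""
        self._check_spatial(tuple(volumes.shape[2:]))
        h3 = volumes
        for blk in self.blocks3d:
            h3 = blk(h3)
        f3d = global_average_pool(h3)
        if volumes.requires_grad:
            h2 = _project_z_max_t(volumes) if self.config.projection == "max" \
                else volumes.mean(axis=2)
        else:
            op = np.max if self.config.projection == "max" else np.mean
            h2 = Tensor(op(volumes.data, axis=2))
        for blk in self.blocks2d:
            h2 = blk(h2)
        f2d = global_average_pool(h2)
        return f3d, f2d

    def fuse_gated(self, f3d: Tensor, f2d: Tensor,
                   gate: np.ndarray | None = None) -> Tensor:
        """g = sigmoid(W [f3d; f2d]); fused = FC(g * f3d + (1 - g) * f2d)."""
        if f3d.shape != f2d.shape:
            raise ValueError(
                f"branch feature dims differ: {f3d.shape} vs {f2d.shape}"
            )
        g = (self.gate(concat([f3d, f2d], axis=-1))).sigmoid() \
            if gate is None else Tensor(np.asarray(gate, dtype=np.float64))
        pre = g * f3d + (1.0 - g) * f2d
        return self.fuse(pre)

    def classify(self, fused: Tensor, knowledge: Tensor | None) -> Tensor:
        if knowledge is None:
            knowledge = Tensor(np.zeros(fused.shape[:-1]
                                        + (self.config.knowledge_in_dim,)))
        k = self.knowledge_adapter(knowledge)
        return self.classifier(concat([fused, k], axis=-1)).sigmoid()

    def protein_id_head(self, fused: Tensor) -> Tensor:
        return self.id_head(fused).softmax(axis=-1)

    # -- full forward -------------------------------------------------------
    def forward(self, volumes, knowledge=None,
                fused_mask: np.ndarray | None = None) -> ForwardOutput:
        """Full forward pass.

        ``fused_mask`` (B,) optionally zeroes the fused image feature in
        the *classifier* input only (modality dropout during training:
        keeps the knowledge pathway load-bearing when both are present);
        the ID head always sees the full fused feature.
        """
        x = volumes if isinstance(volumes, Tensor) else Tensor(
            np.asarray(volumes, dtype=np.float64)
        )
        k = None
        if knowledge is not None:
            k = knowledge if isinstance(knowledge, Tensor) else Tensor(
                np.asarray(knowledge, dtype=np.float64)
            )
        f3d, f2d = self.branch_features(x)
        fused = self.fuse_gated(f3d, f2d)
        fused_cls = fused
        if fused_mask is not None:
            fused_cls = fused * Tensor(
                np.asarray(fused_mask, dtype=np.float64)[:, None]
            )
        return ForwardOutput(
            f3d=f3d,
            f2d=f2d,
            fused=fused,
            class_probs=self.classify(fused_cls, k),
            id_probs=self.protein_id_head(fused),
        )

    __call__ = forward

    def encode(self, sample, knowledge=None) -> ForwardOutput:
        """Inference on one sample: normalize, add batch axis, eval mode."""
        was_training = self.training
        self.eval()
        try:
            vol = normalize_volume(sample.volume if hasattr(sample, "volume")
                                   else sample)
            with no_grad():
                out = self.forward(vol[None],
                                   None if knowledge is None else knowledge[None])
        finally:
            if was_training:
                self.train()
        return out


def _project_z_max_t(volumes: Tensor) -> Tensor:
    """Differentiable max-projection along z for (B, C, z, y, x) tensors."""
    data = volumes.data
    out_data = data.max(axis=2)
    argmax = data.argmax(axis=2)

    def backward(g):
        if volumes.requires_grad:
            full = np.zeros_like(data)
            np.put_along_axis(
                full, argmax[:, :, None], g[:, :, None], axis=2
            )
            volumes._accumulate(full)

    return Tensor._make(out_data, (volumes,), backward)
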