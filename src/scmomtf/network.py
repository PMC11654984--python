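"""The multitask network: modality encoders, cell encoder, decoders,
discriminators and classifier head.

Architecture (shallow by design, to keep feature attribution tractable):

* modality encoder m:  v_m -> hidden -> modality_embed_dim (default 150)
* cell encoder:        2 x modality_embed_dim -> hidden -> cell_embed_dim (64)
* decoder m:           cell_embed_dim -> hidden -> v_m (mirrors the encoder)
* discriminator m:     v_m -> hidden -> hidden/4 -> 1 with a sigmoid output,
                       the probability the input is real rather than generated
* classifier:          one affine layer on the cell embedding + softmax

All sub-networks use Linear -> LayerNorm -> Tanh blocks; layer normalization
is per-sample, so inference is a deterministic row-wise map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data_io import ValidationError
from .nn import Adam, Sequential, mlp, softmax


@dataclass
class ModelConfig:
    v1: int
    v2: int
    n_classes: int
    modality_embed_dim: int = 150
    cell_embed_dim: int = 64
    hidden_dim: int = 256
    label_smoothing_alpha: float = 0.1
    classification_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("v1", "v2", "n_classes", "modality_embed_dim", "cell_embed_dim", "hidden_dim"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.label_smoothing_alpha < 1.0:
            raise ValidationError("label_smoothing_alpha must lie in [0, 1)")
        if self.classification_weight < 0:
            raise ValidationError("classification_weight must be nonnegative")


@dataclass
class CellEmbedding:
    """Joint embedding z plus the per-modality embeddings it was built from."""

    z: np.ndarray
    h1: np.ndarray
    h2: np.ndarray


@dataclass
class ModelState:
    """All sub-network parameters plus bookkeeping.

    ``feature_ids`` records the training feature space per modality so task
    entry points can verify that query data matches.
    """

    config: ModelConfig
    enc1: Sequential
    enc2: Sequential
    cell_enc: Sequential
    dec1: Sequential
    dec2: Sequential
    dis1: Sequential
    dis2: Sequential
    classifier: Sequential
    step: int = 0
    feature_ids: tuple[list[str], list[str]] | None = None
    classes: list[str] | None = None

    def generator_modules(self) -> list[Sequential]:
        return [self.enc1, self.enc2, self.cell_enc, self.dec1, self.dec2, self.classifier]

    def discriminator_modules(self) -> list[Sequential]:
        return [self.dis1, self.dis2]

    def all_modules(self) -> list[Sequential]:
        return self.generator_modules() + self.discriminator_modules()


def init_model(cfg: ModelConfig) -> ModelState:
    """Seeded initialization; two calls with the same config are identical."""
    rng = np.random.default_rng(cfg.seed)
    h = max(cfg.hidden_dim, cfg.modality_embed_dim)
    e = cfg.modality_embed_dim
    z = cfg.cell_embed_dim
    return ModelState(
        config=cfg,
        enc1=mlp([cfg.v1, h, e], rng),
        enc2=mlp([cfg.v2, h, e], rng),
        cell_enc=mlp([2 * e, cfg.hidden_dim, z], rng),
        dec1=mlp([z, h, cfg.v1], rng),
        dec2=mlp([z, h, cfg.v2], rng),
        dis1=mlp([cfg.v1, cfg.hidden_dim, cfg.hidden_dim // 4, 1], rng, final_sigmoid=True),
        dis2=mlp([cfg.v2, cfg.hidden_dim, cfg.hidden_dim // 4, 1], rng, final_sigmoid=True),
        classifier=mlp([z, cfg.n_classes], rng),
    )


def encode(state: ModelState, x1: np.ndarray, x2: np.ndarray) -> CellEmbedding:
    """Map paired inputs to modality embeddings h1, h2 and cell embedding z."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    cfg = state.config
    if x1.shape[1] != cfg.v1 or x2.shape[1] != cfg.v2:
        raise ValidationError(
            f"input widths ({x1.shape[1]}, {x2.shape[1]}) do not match model ({cfg.v1}, {cfg.v2})"
        )
    if x1.shape[0] != x2.shape[0]:
        raise ValidationError("modalities must be row-aligned")
    h1 = state.enc1.forward(x1)
    h2 = state.enc2.forward(x2)
    z = state.cell_enc.forward(np.concatenate([h1, h2], axis=1))
    return CellEmbedding(z=z, h1=h1, h2=h2)


def decode(state: ModelState, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != state.config.cell_embed_dim:
        raise ValidationError(f"z width {z.shape[1]} != cell_embed_dim {state.config.cell_embed_dim}")
    return state.dec1.forward(z), state.dec2.forward(z)


def discriminate(state: ModelState, x: np.ndarray, modality: int) -> np.ndarray:
    """Per-row probability that ``x`` comes from real data (modality 1 or 2)."""
    if modality not in (1, 2):
        raise ValidationError("modality must be 1 or 2")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dis = state.dis1 if modality == 1 else state.dis2
    expected = state.config.v1 if modality == 1 else state.config.v2
    if x.shape[1] != expected:
        raise ValidationError(f"input width {x.shape[1]} != modality-{modality} width {expected}")
    return dis.forward(x)[:, 0]


def classify(state: ModelState, z: np.ndarray) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) from cell embeddings."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != state.config.cell_embed_dim:
        raise ValidationError(f"z width {z.shape[1]} != cell_embed_dim {state.config.cell_embed_dim}")
    return softmax(state.classifier.forward(z))


# ---------------------------------------------------------------------------
# checkpoint serialization: single .npz with a JSON config header
# ---------------------------------------------------------------------------

_MODULE_NAMES = ("enc1", "enc2", "cell_enc", "dec1", "dec2", "dis1", "dis2", "classifier")


def save_model(state: ModelState, path) -> None:
    header = {
        "config": vars(state.config),
        "step": state.step,
        "classes": state.classes,
        "feature_ids": state.feature_ids,
    }
    arrays = {"__header__": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for name in _MODULE_NAMES:
        for i, p in enumerate(getattr(state, name).params()):
            arrays[f"{name}:{i}"] = p
    np.savez_compressed(path, **arrays)


def load_model(path) -> ModelState:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        state = init_model(ModelConfig(**header["config"]))
        for name in _MODULE_NAMES:
            for i, p in enumerate(getattr(state, name).params()):
                p[...] = data[f"{name}:{i}"]
    state.step = header["step"]
    state.classes = header["classes"]
    if header["feature_ids"] is not None:
        state.feature_ids = (header["feature_ids"][0], header["feature_ids"][1])
    return state


def make_optimizers(
    state: ModelState, lr_gen: float, lr_dis: float, weight_decay: float = 0.0
) -> tuple[Adam, Adam]:
    gen_params = [p for m in state.generator_modules() for p in m.params()]
    gen_grads = [g for m in state.generator_modules() for g in m.grads()]
    dis_params = [p for m in state.discriminator_modules() for p in m.params()]
    dis_grads = [g for m in state.discriminator_modules() for g in m.grads()]
    # decay applies to 2-D weight matrices only, not biases or norm scales
    gen_mask = [p.ndim == 2 for p in gen_params]
    return (
        Adam(gen_params, gen_grads, lr=lr_gen, weight_decay=weight_decay, decay_mask=gen_mask),
        Adam(dis_params, dis_grads, lr=lr_dis),
    )
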