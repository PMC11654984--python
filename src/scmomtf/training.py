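"""Joint adversarial multitask training.

Each minibatch takes two alternating steps:

* step A — the two discriminators minimize the least-squares discriminator
  loss on reconstructions (fake) and real data, with the generator frozen;
* step B — encoders, decoders and classifier minimize
  ``L_res + gamma * L_cls + L_gen`` with the discriminators frozen (their
  parameters still carry gradients through to the reconstructions, but are
  not updated).

Epoch-mean loss components are recorded in a training log; ``L_cls`` is
logged raw while the total includes ``gamma * L_cls``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import LabelCodec, PairedDataset, ValidationError
from .losses import (
    classification_loss,
    discriminator_loss,
    generator_loss,
    one_hot,
    reconstruction_loss,
    smooth_labels,
    total_loss,
)
from .network import ModelConfig, ModelState, init_model, make_optimizers
from .nn import softmax

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings.

    ``input_noise_sd`` adds seeded Gaussian noise to the encoder inputs during
    training only (a denoising-autoencoder regularizer on the normalized log
    scale); reconstruction targets stay clean and inference is unaffected.
    """

    epochs: int = 100
    batch_size: int = 256
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-4
    input_noise_sd: float = 0.3
    batch_shift_aug_sd: float = 0.0
    weight_decay: float = 0.0
    class_balance: str = "oversample"  # "oversample" | "weight" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("epochs and batch_size must be positive")
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValidationError("learning rates must be positive")
        if self.input_noise_sd < 0 or self.batch_shift_aug_sd < 0:
            raise ValidationError("augmentation scales must be nonnegative")
        if self.class_balance not in ("oversample", "weight", "none"):
            raise ValidationError("class_balance must be oversample, weight or none")


def _zero_all(state: ModelState) -> None:
    for m in state.all_modules():
        m.zero_grad()


def _train_batch(
    state: ModelState,
    x1: np.ndarray,
    x2: np.ndarray,
    x1_in: np.ndarray,
    x2_in: np.ndarray,
    y_ls: np.ndarray,
    cell_weights: np.ndarray,
    opt_gen,
    opt_dis,
) -> tuple[float, float, float, float]:
    cfg = state.config
    n = x1.shape[0]
    M = 2

    # ---- step A: discriminators (generator frozen) -----------------------
    h1 = state.enc1.forward(x1_in)
    h2 = state.enc2.forward(x2_in)
    z = state.cell_enc.forward(np.concatenate([h1, h2], axis=1))
    xh1 = state.dec1.forward(z)
    xh2 = state.dec2.forward(z)

    _zero_all(state)
    d_fake, d_real = [], []
    for dis, fake, real in ((state.dis1, xh1, x1), (state.dis2, xh2, x2)):
        df = dis.forward(fake)
        dis.backward(2.0 * df / (n * M))           # d/d(out) of out^2 / (nM)
        d_fake.append(df[:, 0].copy())
        dr = dis.forward(real)
        dis.backward(2.0 * (dr - 1.0) / (n * M))   # d/d(out) of (out-1)^2 / (nM)
        d_real.append(dr[:, 0].copy())
    opt_dis.step()
    L_dis = discriminator_loss(d_fake, d_real)

    # ---- step B: generator + classifier (discriminators frozen) ----------
    h1 = state.enc1.forward(x1_in)
    h2 = state.enc2.forward(x2_in)
    z = state.cell_enc.forward(np.concatenate([h1, h2], axis=1))
    xh1 = state.dec1.forward(z)
    xh2 = state.dec2.forward(z)
    logits = state.classifier.forward(z)
    probs = softmax(logits)

    _zero_all(state)
    gz = np.zeros_like(z)
    d_gen = []
    for dis, dec, xh, x in (
        (state.dis1, state.dec1, xh1, x1),
        (state.dis2, state.dec2, xh2, x2),
    ):
        d = dis.forward(xh)
        d_gen.append(d[:, 0].copy())
        g_xh = 2.0 * (xh - x) / (n * M)                       # reconstruction
        g_xh = g_xh + dis.backward(2.0 * (d - 1.0) / (n * M))  # adversarial
        gz += dec.backward(g_xh)
    gz += state.classifier.backward(
        cfg.classification_weight * cell_weights[:, None] * (probs - y_ls) / n
    )
    gh = state.cell_enc.backward(gz)
    e = cfg.modality_embed_dim
    state.enc1.backward(gh[:, :e])
    state.enc2.backward(gh[:, e:])
    # discriminator grads were only a conduit for the generator signal
    for dis in state.discriminator_modules():
        dis.zero_grad()
    opt_gen.step()

    L_res = reconstruction_loss([x1, x2], [xh1, xh2])
    if np.allclose(cell_weights, 1.0):
        L_cls = classification_loss(y_ls, probs)
    else:  # weighted mean of the per-cell cross-entropies
        per_cell = -(y_ls * np.log(np.maximum(probs, 1e-8))).sum(axis=1)
        L_cls = float((cell_weights * per_cell).mean())
    L_gen = generator_loss(d_gen)
    state.step += 1
    return L_res, L_cls, L_gen, L_dis


def train(
    ds: PairedDataset,
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
    log_path: str | Path | None = None,
) -> tuple[ModelState, pd.DataFrame]:
    """Train on a preprocessed (normalized, feature-selected) labeled dataset.

    Returns the trained state and a per-epoch loss log with columns
    ``epoch, L_res, L_cls, L_gen, L_dis, L_total``.  Fully seeded: the same
    dataset and configs give bit-identical parameters on CPU.
    """
    if ds.cell_labels is None:
        raise ValidationError(
            "training requires cell labels (the classification head is supervised)"
        )
    tcfg = tcfg or TrainConfig()
    codec = LabelCodec.from_labels(ds.cell_labels)
    if mcfg is None:
        mcfg = ModelConfig(
            v1=ds.modality_1.n_features,
            v2=ds.modality_2.n_features,
            n_classes=codec.n_classes,
            seed=tcfg.seed,
        )
    if mcfg.n_classes != codec.n_classes:
        raise ValidationError(
            f"model expects {mcfg.n_classes} classes, labels contain {codec.n_classes}"
        )
    state = init_model(mcfg)
    state.feature_ids = (list(ds.modality_1.feature_ids), list(ds.modality_2.feature_ids))
    state.classes = codec.classes
    opt_gen, opt_dis = make_optimizers(
        state, tcfg.lr_generator, tcfg.lr_discriminator, tcfg.weight_decay
    )

    x1_all = np.asarray(ds.modality_1.values, dtype=np.float64)
    x2_all = np.asarray(ds.modality_2.values, dtype=np.float64)
    y_codes = codec.encode(ds.cell_labels)
    y_ls_all = smooth_labels(
        one_hot(y_codes, codec.n_classes), mcfg.label_smoothing_alpha, codec.n_classes
    )

    # rare cell types carry almost no classification gradient under a plain
    # minibatch mean; "weight" scales the per-cell gradient by inverse class
    # frequency (mean 1), "oversample" resamples minibatch indices with those
    # probabilities so rare cells are seen often, each time with fresh input
    # noise (an augmentation, not a repetition, when input_noise_sd > 0)
    weights_all = np.ones(ds.n_cells)
    sample_p = None
    if tcfg.class_balance != "none":
        counts = np.bincount(y_codes, minlength=codec.n_classes).astype(float)
        w_class = 1.0 / counts
        w = w_class[y_codes]
        if tcfg.class_balance == "weight":
            weights_all = w * (len(y_codes) / w.sum())
        else:
            sample_p = w / w.sum()

    rng = np.random.default_rng(tcfg.seed)
    n = ds.n_cells
    rows = []
    for epoch in range(tcfg.epochs):
        if sample_p is None:
            order = rng.permutation(n)
        else:
            order = rng.choice(n, size=n, replace=True, p=sample_p)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            x1, x2 = x1_all[idx], x2_all[idx]
            x1_in, x2_in = x1, x2
            if tcfg.input_noise_sd > 0:
                x1_in = x1_in + tcfg.input_noise_sd * rng.standard_normal(x1.shape)
                x2_in = x2_in + tcfg.input_noise_sd * rng.standard_normal(x2.shape)
            if tcfg.batch_shift_aug_sd > 0:
                # one coherent per-feature offset per minibatch: teaches the
                # encoders invariance to additive batch effects
                x1_in = x1_in + tcfg.batch_shift_aug_sd * rng.standard_normal(x1.shape[1])
                x2_in = x2_in + tcfg.batch_shift_aug_sd * rng.standard_normal(x2.shape[1])
            parts = _train_batch(
                state, x1, x2, x1_in, x2_in, y_ls_all[idx], weights_all[idx],
                opt_gen, opt_dis,
            )
            if not all(np.isfinite(parts)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"L_res={parts[0]:.4g} L_cls={parts[1]:.4g} "
                    f"L_gen={parts[2]:.4g} L_dis={parts[3]:.4g}"
                )
            sums += parts
            n_batches += 1
        L_res, L_cls, L_gen, L_dis = sums / n_batches
        bundle = total_loss(L_res, L_cls, L_gen, L_dis, mcfg.classification_weight)
        rows.append(
            {
                "epoch": epoch,
                "L_res": bundle.L_res,
                "L_cls": bundle.L_cls,
                "L_gen": bundle.L_gen,
                "L_dis": bundle.L_dis,
                "L_total": bundle.L_total,
            }
        )
        if epoch == 0 or (epoch + 1) % 20 == 0:
            logger.info(
                "epoch %d: L_res=%.4f L_cls=%.4f L_gen=%.4f L_dis=%.4f",
                epoch, L_res, L_cls, L_gen, L_dis,
            )
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return state, log
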