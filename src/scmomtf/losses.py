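"""Training objectives: reconstruction, label-smoothed cross-entropy,
least-squares generator/discriminator losses, and their weighted total.

All batch losses are means over the minibatch: the reconstruction and
adversarial terms divide by n*M (cells times modalities), the classification
term by n.  The total is

    L_total = L_res + gamma * L_cls + L_gen + L_dis
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import ValidationError

#: probability floor inside the classification log
EPS = 1e-8


@dataclass
class LossBundle:
    L_res: float
    L_cls: float
    L_gen: float
    L_dis: float
    L_total: float
    gamma: float = 1.0


def reconstruction_loss(
    xs: Sequence[np.ndarray], x_hats: Sequence[np.ndarray]
) -> float:
    """Mean squared Euclidean distance over cells and modalities.

    ``(1 / (n M)) sum_i sum_m || x_hat_i^(m) - x_i^(m) ||^2``
    """
    if len(xs) != len(x_hats):
        raise ValidationError("modality count mismatch between x and x_hat")
    n = xs[0].shape[0]
    M = len(xs)
    total = 0.0
    for x, xh in zip(xs, x_hats):
        if x.shape != xh.shape:
            raise ValidationError(f"shape mismatch {x.shape} vs {xh.shape}")
        total += float(np.sum((xh - x) ** 2))
    return total / (n * M)


def smooth_labels(y_real: np.ndarray, alpha: float, n_classes: int) -> np.ndarray:
    """Label-smoothing regularization: ``(1 - alpha) * y + alpha / C``."""
    if not 0.0 <= alpha < 1.0:
        raise ValidationError("alpha must lie in [0, 1)")
    y_real = np.asarray(y_real, dtype=float)
    if y_real.shape[1] != n_classes:
        raise ValidationError("y_real width must equal n_classes")
    return (1.0 - alpha) * y_real + alpha / n_classes


def one_hot(codes: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(codes), n_classes))
    out[np.arange(len(codes)), np.asarray(codes, dtype=int)] = 1.0
    return out


def classification_loss(y_ls: np.ndarray, y_pred: np.ndarray) -> float:
    """Cross entropy against smoothed targets, mean over cells.

    Predicted probabilities are floored at ``EPS`` inside the log.
    """
    y_ls = np.asarray(y_ls, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_ls.shape != y_pred.shape:
        raise ValidationError("target / prediction shape mismatch")
    if (y_pred < 0).any():
        raise ValidationError("predicted probabilities must be nonnegative")
    return float(-(y_ls * np.log(np.maximum(y_pred, EPS))).sum(axis=1).mean())


def generator_loss(dis_outputs_on_fake: Sequence[np.ndarray]) -> float:
    """LSGAN generator term: ``(1/(nM)) sum (Dis(x_hat) - 1)^2``."""
    n = len(np.asarray(dis_outputs_on_fake[0]))
    M = len(dis_outputs_on_fake)
    total = sum(float(np.sum((np.asarray(d) - 1.0) ** 2)) for d in dis_outputs_on_fake)
    return total / (n * M)


def discriminator_loss(
    dis_on_fake: Sequence[np.ndarray], dis_on_real: Sequence[np.ndarray]
) -> float:
    """LSGAN discriminator term: fake pushed to 0, real pushed to 1.

    ``(1/(nM)) sum Dis(x_hat)^2 + (1/(nM)) sum (Dis(x) - 1)^2``
    """
    n = len(np.asarray(dis_on_fake[0]))
    M = len(dis_on_fake)
    fake = sum(float(np.sum(np.asarray(d) ** 2)) for d in dis_on_fake)
    real = sum(float(np.sum((np.asarray(d) - 1.0) ** 2)) for d in dis_on_real)
    return fake / (n * M) + real / (n * M)


def total_loss(
    L_res: float, L_cls: float, L_gen: float, L_dis: float, gamma: float
) -> LossBundle:
    """Combine the four objectives; gamma scales only the classification term."""
    if gamma < 0:
        raise ValidationError("gamma must be nonnegative")
    total = L_res + gamma * L_cls + L_gen + L_dis
    return LossBundle(L_res, L_cls, L_gen, L_dis, total, gamma)
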