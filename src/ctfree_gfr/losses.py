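"""Segmentation training losses on per-voxel class probabilities.

Both losses consume a one-hot target ``y`` and a probability map ``y_hat``
shaped ``(n_classes, *spatial)`` (a leading batch axis is fine too — voxels
are voxels).

CCE here is the per-class binary cross-entropy averaged over the ``n``
classes and over voxels,

    CCE = -(1/n) * mean_voxels sum_i [ y_i log(yhat_i) + (1-y_i) log(1-yhat_i) ]

and the generalized Dice loss is

    GDSC = 1 - 2 sum_i w_i [y_i yhat_i] / ( sum_i w_i [y_i] + sum_i w_i [yhat_i] )

with ``[.]`` a sum over voxels and per-class weights ``w_i`` defaulting to the
inverse squared class volume, which rebalances the tiny kidney classes against
the vast background.
"""

from __future__ import annotations

import numpy as np

__all__ = ["class_weights", "cce_loss", "gdsc_loss"]

_EPS_PROB = 1e-7
_EPS_WEIGHT = 1e-6


def class_weights(y: np.ndarray, eps: float = _EPS_WEIGHT) -> np.ndarray:
    """Inverse-squared-volume class weights, w_i = 1 / ((sum_vox y_i)^2 + eps).

    The stabilizer keeps weights finite for classes absent from the target
    (e.g. the resected kidney after total nephrectomy).
    """
    y = np.asarray(y, dtype=np.float64)
    vol = y.reshape(y.shape[0], -1).sum(axis=1)
    return 1.0 / (vol**2 + eps)


def _check_pair(y: np.ndarray, y_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"target shape {y.shape} != prediction shape {y_hat.shape}")
    return y, y_hat


def cce_loss(y: np.ndarray, y_hat: np.ndarray, eps: float = _EPS_PROB) -> float:
    """Cross-entropy loss; 0 only for a perfect, fully confident prediction."""
    y, y_hat = _check_pair(y, y_hat)
    n_classes = y.shape[0]
    p = np.clip(y_hat, eps, 1.0 - eps)
    per_voxel = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum(axis=0) / n_classes
    return float(per_voxel.mean())


def gdsc_loss(
    y: np.ndarray, y_hat: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Generalized Dice loss in [0, 1]; 0 for perfect overlap.

    When every weighted class is empty in both target and prediction the loss
    is defined as 0 (perfect agreement on absence).
    """
    y, y_hat = _check_pair(y, y_hat)
    if weights is None:
        weights = class_weights(y)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (y.shape[0],):
        raise ValueError(f"expected {y.shape[0]} class weights, got shape {w.shape}")

    yf = y.reshape(y.shape[0], -1)
    pf = y_hat.reshape(y_hat.shape[0], -1)
    intersect = float((w * (yf * pf).sum(axis=1)).sum())
    denom = float((w * yf.sum(axis=1)).sum() + (w * pf.sum(axis=1)).sum())
    if denom == 0.0:
        return 0.0
    return 1.0 - 2.0 * intersect / denom
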