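"""Image normalization, filtering, cropping and label cleanup.

Covers the preprocessing used by the two networks: logarithmic maximum
normalization of the input SPECT windows for the u-map generator, maximum or
windowing-maximum normalization of u-maps for the segmenter, a 3D Butterworth
low-pass for statistical noise reduction of the scatter window, the training
crop, and morphological closing of label maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LEFT_KIDNEY, RIGHT_KIDNEY, LabelMap, Volume3D

__all__ = [
    "NormalizationSpec",
    "ButterworthSpec",
    "normalize",
    "butterworth_lowpass",
    "crop_for_training",
    "pad_back",
    "close_labels",
    "KidneyCropWarning",
]

DEFAULT_CROP_SHAPE = (64, 64, 96)


class KidneyCropWarning(UserWarning):
    """A training crop discarded kidney-labelled voxels."""


@dataclass(frozen=True)
class NormalizationSpec:
    """Intensity normalization recipe, fixed per trained model.

    method:
        ``maximum``            v / max(v)
        ``log_maximum``        log(1+v) / log(1+max(v))
        ``windowing_maximum``  clip(v, 0, w) then maximum normalization
    window_upper:
        The window ceiling w (only for ``windowing_maximum``; default 0.5,
        the ceiling that performed best for attenuation maps, whose values
        top out at bone).
    """

    method: str = "maximum"
    window_upper: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("maximum", "log_maximum", "windowing_maximum"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.window_upper <= 0:
            raise ValueError("window_upper must be positive")


@dataclass(frozen=True)
class ButterworthSpec:
    """3D radial Butterworth low-pass: order 10, cutoff 0.48 cycles/cm."""

    order: int = 10
    cutoff_cycles_per_cm: float = 0.48

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff_cycles_per_cm <= 0:
            raise ValueError("cutoff must be positive")


def normalize(volume: Volume3D, spec: NormalizationSpec) -> Volume3D:
    """Normalize intensities into [0, 1] per ``spec``.

    Raises for an all-zero (or all-nonpositive, for window methods) volume,
    which cannot be scaled.
    """
    v = np.asarray(volume.data, dtype=np.float64)
    if spec.method == "maximum":
        vmax = v.max()
        if vmax <= 0:
            raise ValueError("cannot maximum-normalize a volume with max <= 0")
        out = v / vmax
    elif spec.method == "log_maximum":
        if v.min() < 0:
            raise ValueError("log_maximum normalization requires non-negative input")
        vmax = v.max()
        if vmax <= 0:
            raise ValueError("cannot log-maximum-normalize a volume with max <= 0")
        out = np.log1p(v) / np.log1p(vmax)
    else:  # windowing_maximum
        clipped = np.clip(v, 0.0, spec.window_upper)
        cmax = clipped.max()
        if cmax <= 0:
            raise ValueError("windowed volume is identically zero; cannot normalize")
        # after clipping at w the observed max may fall below w; divide by the
        # observed post-clip maximum so the output always reaches 1
        out = clipped / cmax
    return volume.with_data(out)


def butterworth_lowpass(volume: Volume3D, spec: ButterworthSpec | None = None) -> Volume3D:
    """Apply a 3D radial-frequency Butterworth low-pass filter.

    The transfer function is H(f) = 1 / sqrt(1 + (f/fc)^(2n)) on the 3D radial
    spatial-frequency grid in cycles/cm, so DC passes with gain 1 and the gain
    at f = fc is exactly 1/sqrt(2).  Requires isotropic voxels so the cutoff is
    well-defined in cycles/cm.
    """
    spec = spec or ButterworthSpec()
    voxel_cm = volume.require_isotropic() / 10.0
    nyquist = 1.0 / (2.0 * voxel_cm)
    if spec.cutoff_cycles_per_cm >= nyquist:
        warnings.warn(
            f"Butterworth cutoff {spec.cutoff_cycles_per_cm} cycles/cm is at or above "
            f"Nyquist ({nyquist:.3f}); the filter is nearly transparent",
            stacklevel=2,
        )
    freqs = [np.fft.fftfreq(n, d=voxel_cm) for n in volume.shape]
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f = np.sqrt(fz**2 + fy**2 + fx**2)
    h = 1.0 / np.sqrt(1.0 + (f / spec.cutoff_cycles_per_cm) ** (2 * spec.order))
    filtered = np.fft.ifftn(np.fft.fftn(volume.data) * h).real
    return volume.with_data(filtered)


def _crop_slices(
    shape: tuple[int, int, int],
    target_shape: tuple[int, int, int],
    center_offset: tuple[int, int, int],
) -> tuple[slice, slice, slice]:
    slices = []
    for n, t, off in zip(shape, target_shape, center_offset):
        if t > n:
            raise ValueError(f"crop target {target_shape} exceeds source {shape}")
        start = (n - t) // 2 + off
        if start < 0 or start + t > n:
            raise ValueError(
                f"crop offset {center_offset} pushes the window out of bounds for "
                f"source {shape} and target {target_shape}"
            )
        slices.append(slice(start, start + t))
    return tuple(slices)


def crop_for_training(
    volume: Volume3D,
    target_shape: tuple[int, int, int] = DEFAULT_CROP_SHAPE,
    center_offset: tuple[int, int, int] = (0, 0, 0),
) -> Volume3D:
    """Centered crop (configurable offset) to the training matrix size.

    Cropping a :class:`LabelMap` that loses kidney voxels emits a
    :class:`KidneyCropWarning` — the crop silently truncating ground truth is
    a training-data quality problem worth surfacing.
    """
    sl = _crop_slices(volume.shape, tuple(target_shape), tuple(center_offset))
    cropped = volume.data[sl]
    if isinstance(volume, LabelMap):
        lost = int(np.count_nonzero(volume.data)) - int(np.count_nonzero(cropped))
        if lost > 0:
            warnings.warn(
                f"training crop discards {lost} kidney-labelled voxels",
                KidneyCropWarning,
                stacklevel=2,
            )
    return volume.with_data(cropped.copy())


def pad_back(
    volume: Volume3D,
    original_shape: tuple[int, int, int],
    center_offset: tuple[int, int, int] = (0, 0, 0),
) -> Volume3D:
    """Inverse of :func:`crop_for_training`: zero-pad to the original grid."""
    sl = _crop_slices(tuple(original_shape), volume.shape, tuple(center_offset))
    out = np.zeros(original_shape, dtype=volume.data.dtype)
    out[sl] = volume.data
    return volume.with_data(out)


def close_labels(labels: LabelMap, structuring_radius_vox: int = 1) -> LabelMap:
    """Morphological closing of a kidney label map, per class.

    Each kidney class is closed independently with a cubic structuring element
    of edge ``2*radius + 1`` (default 3x3x3), then recombined with
    right-kidney priority where the closed masks overlap.  Closing never
    removes voxels, so per-class counts never decrease.
    """
    if structuring_radius_vox < 1:
        raise ValueError("structuring_radius_vox must be >= 1")
    size = 2 * structuring_radius_vox + 1
    structure = np.ones((size, size, size), dtype=bool)
    out = labels.data.copy()
    # original voxels are never reassigned (counts cannot decrease); closing
    # only fills background, and the right kidney claims contested fill voxels
    for cls in (RIGHT_KIDNEY, LEFT_KIDNEY):
        mask = labels.class_mask(cls)
        if not mask.any():
            continue
        closed = ndimage.binary_closing(mask, structure=structure)
        out[closed & (out == 0)] = cls
    return LabelMap(data=out, spacing_mm=labels.spacing_mm)
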