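"""Deterministic image conditioning: center crop and integer quantization.

MRI volumes are center-cropped to a fixed region around the joint and then
compressed to a small number of integer intensity levels (14 by default).
The compression is a per-volume min-max rescale to ``[0, n_levels - 1]``
followed by round-half-away-from-zero, so a volume with a well-populated
intensity range maps onto exactly ``n_levels`` distinct values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PreprocessConfig", "center_crop", "normalize_quantize", "preprocess_volume"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Crop target and quantization depth.

    ``crop_shape`` is the voxel count per axis after cropping (e.g.
    ``(120, 320, 320)`` for full-scale sagittal MRI, ``(24, 48, 48)`` at desk
    scale); ``n_levels`` is the number of integer intensity levels.
    """

    crop_shape: tuple[int, ...]
    n_levels: int = 14

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")
        if any(s < 1 for s in self.crop_shape):
            raise ValueError(f"crop_shape entries must be >= 1, got {self.crop_shape}")


def center_crop(volume: np.ndarray, crop_shape: tuple[int, ...]) -> np.ndarray:
    """Crop ``volume`` to ``crop_shape``, centered on every axis.

    When the margin on an axis is odd the smaller half goes on the low-index
    side (margin 5 -> offsets 2 low / 3 high).
    """
    volume = np.asarray(volume)
    if volume.ndim != len(crop_shape):
        raise ValueError(
            f"crop_shape has {len(crop_shape)} axes but volume has {volume.ndim}"
        )
    slices = []
    for axis, (size, target) in enumerate(zip(volume.shape, crop_shape)):
        if target > size:
            raise ValueError(
                f"crop size {target} exceeds input size {size} on axis {axis}"
            )
        low = (size - target) // 2
        slices.append(slice(low, low + target))
    return volume[tuple(slices)]


def _round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    # np.round rounds half-to-even; the pipeline uses half-away-from-zero so
    # level boundaries are platform-independent.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_quantize(volume: np.ndarray, n_levels: int = 14) -> np.ndarray:
    """Min-max normalize and quantize to integers ``0 .. n_levels - 1``.

    Mapping: ``v -> round((v - min) / (max - min) * (n_levels - 1))`` with
    half-away-from-zero rounding. A constant volume maps to all zeros.
    Idempotent: integer volumes already on ``0 .. n_levels - 1`` are fixed
    points.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite intensities")
    vmin = volume.min()
    vmax = volume.max()
    if vmax == vmin:
        return np.zeros_like(volume)
    scaled = (volume - vmin) / (vmax - vmin) * (n_levels - 1)
    return _round_half_away_from_zero(scaled)


def preprocess_volume(volume: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Apply the full conditioning chain: center crop then quantize."""
    return normalize_quantize(center_crop(volume, config.crop_shape), config.n_levels)
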