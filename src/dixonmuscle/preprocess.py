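"""Mid-sagittal splitting, left-right mirroring, slab sampling, augmentation.

The network always sees single-leg images: a two-leg volume is split along
the mid-sagittal plane and the left half is mirrored so that both halves
look like a right leg.  Training patches are slabs of consecutive axial
slices at full in-plane extent, randomly positioned along the
inferior-superior axis, carried as a 2-channel (out-of-phase, in-phase)
array plus the identically-cut label window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "Patch",
    "AugmentParams",
    "split_midsagittal",
    "concat_halves",
    "mirror_lr",
    "sample_patch",
    "cut_patch",
    "augment",
]


def _lr_axis(arr: np.ndarray) -> int:
    # left-right axis: axis 0 for (X, Y, Z) arrays, axis 1 for (C, X, Y, Z)
    if arr.ndim == 3:
        return 0
    if arr.ndim == 4:
        return 1
    raise ValueError(f"expected a 3-D or channels-first 4-D array, got {arr.ndim}-D")


def split_midsagittal(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a two-leg array into (right_half, left_half) along the LR axis.

    The left half occupies the lower column indices, the right half the
    upper ones; ``concat_halves`` restores the original.  The LR extent
    must be even.
    """
    ax = _lr_axis(arr)
    n = arr.shape[ax]
    if n % 2 != 0:
        raise ValueError(f"mid-sagittal split needs an even LR extent, got {n}")
    left = np.take(arr, range(0, n // 2), axis=ax)
    right = np.take(arr, range(n // 2, n), axis=ax)
    return right, left


def concat_halves(right: np.ndarray, left: np.ndarray) -> np.ndarray:
    """Inverse of :func:`split_midsagittal`."""
    ax = _lr_axis(right)
    return np.concatenate([left, right], axis=ax)


def mirror_lr(arr: np.ndarray) -> np.ndarray:
    """Reverse the left-right axis (column x -> W-1-x).  An involution;
    label values are unchanged since the scheme has no left/right ids."""
    return np.flip(arr, axis=_lr_axis(arr)).copy()


@dataclass
class Patch:
    """A single-leg training/inference window.

    ``channels`` is ``(2, W, Y, S)`` with channel 0 the out-of-phase and
    channel 1 the in-phase image; ``labels`` the identically-cut label
    window (may be None at inference); ``z_start`` the slab position;
    ``side`` "right" or "left" (left patches are already mirrored).
    """

    channels: np.ndarray
    labels: Optional[np.ndarray]
    z_start: int
    side: str = "right"

    def __post_init__(self) -> None:
        if self.channels.ndim != 4 or self.channels.shape[0] != 2:
            raise ValueError("patch channels must be (2, W, Y, S)")
        if self.labels is not None and self.labels.shape != self.channels.shape[1:]:
            raise ValueError("label window must match the channel window")


def cut_patch(
    channels: np.ndarray, labels: Optional[np.ndarray], z_start: int, patch_slices: int, side: str = "right"
) -> Patch:
    z = channels.shape[-1]
    if not 0 <= z_start <= z - patch_slices:
        raise ValueError(f"z_start {z_start} out of range for Z={z}, S={patch_slices}")
    sl = slice(z_start, z_start + patch_slices)
    return Patch(
        channels=np.ascontiguousarray(channels[..., sl]),
        labels=None if labels is None else np.ascontiguousarray(labels[..., sl]),
        z_start=z_start,
        side=side,
    )


def sample_patch(
    channels: np.ndarray,
    labels: Optional[np.ndarray],
    patch_slices: int,
    rng: np.random.Generator,
    side: str = "right",
) -> Patch:
    """Cut a slab of ``patch_slices`` consecutive slices at a uniformly random
    inferior-superior position.  Volumes shorter than the patch are an error:
    no padding is applied."""
    z = channels.shape[-1]
    if z < patch_slices:
        raise ValueError(f"volume has {z} slices < patch length {patch_slices}; no padding is applied")
    z_start = int(rng.integers(0, z - patch_slices + 1))
    return cut_patch(channels, labels, z_start, patch_slices, side)


@dataclass(frozen=True)
class AugmentParams:
    """Ranges of the training-time augmentation, symmetric about identity.

    ``rotation_deg``: max in-plane rotation; ``scale``: max relative
    isotropic in-plane scale change; ``translation_vox``: max in-plane
    shift; ``noise_sigma_aug``: sd of additive Gaussian intensity noise in
    signal units (channels only, never labels).
    """

    rotation_deg: float = 10.0
    scale: float = 0.1
    translation_vox: float = 5.0
    noise_sigma_aug: float = 10.0

    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0
            and self.scale == 0
            and self.translation_vox == 0
            and self.noise_sigma_aug == 0
        )


def augment(patch: Patch, params: AugmentParams, rng: np.random.Generator) -> Patch:
    """Apply one shared random affine to channels (linear interpolation) and
    labels (nearest neighbour), then additive Gaussian noise to channels.

    Identity parameter ranges return the patch unchanged, bit for bit.
    """
    if params.is_identity():
        return patch

    angle = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg))
    scale = 1.0 + rng.uniform(-params.scale, params.scale)
    shift = rng.uniform(-params.translation_vox, params.translation_vox, size=2)

    # output -> input coordinate map, rotating/scaling in-plane about the
    # patch centre; the slice axis is untouched
    c, sn = np.cos(angle), np.sin(angle)
    m = np.eye(3)
    m[0, 0], m[0, 1] = c * scale, -sn * scale
    m[1, 0], m[1, 1] = sn * scale, c * scale
    centre = (np.asarray(patch.channels.shape[1:], dtype=np.float64) - 1) / 2.0
    offset = centre - m @ centre + np.array([shift[0], shift[1], 0.0])

    channels = np.empty_like(patch.channels)
    for ch in range(patch.channels.shape[0]):
        channels[ch] = ndimage.affine_transform(
            patch.channels[ch], m, offset=offset, order=1, mode="constant", cval=0.0
        )
    labels = None
    if patch.labels is not None:
        labels = ndimage.affine_transform(
            patch.labels, m, offset=offset, order=0, mode="constant", cval=0
        )
    if params.noise_sigma_aug > 0:
        channels = channels + rng.normal(0.0, params.noise_sigma_aug, channels.shape)
        channels = np.clip(channels, 0.0, None).astype(np.float32)
    return Patch(channels=channels, labels=labels, z_start=patch.z_start, side=patch.side)
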