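"""Label-map cleanup and ground-truth preparation utilities.

Prediction cleanup keeps, per muscle, only the two largest 26-connected
components (one per leg) and then fills enclosed background cavities.
Ground-truth preparation mirrors manual-delineation practice: a 1-pixel
in-plane boundary erosion (excluding fascia and vessels from the muscle
mask) and slice sparsification with nearest-neighbour fill (delineating
only every k-th slice).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .imgvol import LabelVolume

__all__ = ["filter_components", "fill_holes", "erode_boundary", "sparsify_gt"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)

# in-plane 4-connected cross, extended with a singleton slice axis so that
# scipy erodes every axial slice independently
_CROSS_2D = np.zeros((3, 3, 1), dtype=bool)
_CROSS_2D[1, :, 0] = True
_CROSS_2D[:, 1, 0] = True


def filter_components(labels: LabelVolume) -> LabelVolume:
    """Retain only the two largest 26-connected components per muscle
    (the left- and right-leg bodies), erasing smaller blobs to background.

    A size tie at rank 2 is broken toward the component with the lowest
    centroid x, so the result is deterministic.  Muscles with at most two
    components pass through unchanged.  Idempotent.
    """
    out = labels.values.copy()
    for m in labels.scheme.ids:
        mask = labels.values == m
        if not mask.any():
            continue
        comp, n_comp = ndimage.label(mask, structure=_STRUCT_26)
        if n_comp <= 2:
            continue
        sizes = np.bincount(comp.ravel())[1:]  # component ids 1..n_comp
        cx = ndimage.center_of_mass(mask, comp, index=range(1, n_comp + 1))
        cx = np.asarray(cx)[:, 0]
        order = sorted(range(n_comp), key=lambda i: (-sizes[i], cx[i]))
        drop = [i + 1 for i in order[2:]]
        out[np.isin(comp, drop)] = 0
    return LabelVolume(out, labels.scheme, labels.spacing_mm)


def fill_holes(labels: LabelVolume) -> LabelVolume:
    """Fill background cavities enclosed inside a single muscle.

    A cavity is a 6-connected component of background voxels that does not
    reach the volume border and whose foreground neighbours all carry one
    and the same muscle id; it is relabelled to that muscle.  Cavities
    bordering several muscles are inter-muscle space and are left alone.
    Foreground voxels are never modified.  Idempotent.
    """
    vals = labels.values
    bg = vals == 0
    comp, n_comp = ndimage.label(bg, structure=_STRUCT_6)
    if n_comp == 0:
        return LabelVolume(vals.copy(), labels.scheme, labels.spacing_mm)

    border_ids: set[int] = set()
    for axis in range(3):
        for face in (0, -1):
            border_ids.update(np.unique(np.take(comp, face, axis=axis)))
    border_ids.discard(0)

    # neighbour labels of each background component via the six axis shifts
    neighbour: dict[int, set[int]] = {}
    for axis in range(3):
        for sign in (1, -1):
            shifted = np.roll(vals, sign, axis=axis)
            edge = np.take(np.arange(vals.shape[axis]), 0 if sign == 1 else -1)
            sl = [slice(None)] * 3
            sl[axis] = edge
            shifted[tuple(sl)] = 0  # rolled-in face: treat as background
            touch = bg & (shifted > 0)
            pairs = np.stack([comp[touch], shifted[touch]])
            for cid, lab in np.unique(pairs, axis=1).T:
                neighbour.setdefault(int(cid), set()).add(int(lab))

    out = vals.copy()
    for cid, labs in neighbour.items():
        if cid in border_ids or len(labs) != 1:
            continue
        out[comp == cid] = labs.pop()
    return LabelVolume(out, labels.scheme, labels.spacing_mm)


def erode_boundary(labels: LabelVolume, width: int = 1) -> LabelVolume:
    """Erode a ``width``-pixel layer from every muscle boundary, slice by
    slice in-plane (4-connected cross element).

    Used to prepare ground truth so fascia and vessels at muscle borders
    are excluded from quantification; not applied to predictions.  The
    volume outside counts as background, so muscles touching the image
    edge are eroded there too.  ``width=0`` is the identity.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    if width == 0:
        return LabelVolume(labels.values.copy(), labels.scheme, labels.spacing_mm)
    out = np.zeros_like(labels.values)
    for m in labels.scheme.ids:
        mask = labels.values == m
        if not mask.any():
            continue
        eroded = ndimage.binary_erosion(mask, structure=_CROSS_2D, iterations=width)
        out[eroded] = m
    return LabelVolume(out, labels.scheme, labels.spacing_mm)


def sparsify_gt(labels: LabelVolume, stride: int) -> LabelVolume:
    """Emulate sparse manual annotation: keep every ``stride``-th slice and
    replace each other slice by its nearest kept slice (nearest-neighbour
    fill along the slice axis; equidistant ties go to the inferior slice).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    z = labels.shape[2]
    if stride >= z:
        warnings.warn(
            f"stride {stride} >= {z} slices: only slice 0 is kept", stacklevel=2
        )
    if stride == 1:
        return LabelVolume(labels.values.copy(), labels.scheme, labels.spacing_mm)
    zs = np.arange(z)
    q, r = np.divmod(zs, stride)
    lower = q * stride
    upper = (q + 1) * stride
    last_kept = ((z - 1) // stride) * stride
    nearest = np.where(2 * r <= stride, lower, np.minimum(upper, last_kept))
    return LabelVolume(labels.values[:, :, nearest].copy(), labels.scheme, labels.spacing_mm)
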