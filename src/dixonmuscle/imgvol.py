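"""Core image-volume data model, NIfTI I/O, fat-fraction maps and stack stitching.

Conventions used throughout the package:

* volumes are 3-D arrays indexed ``(x, y, z)`` with axis 0 the left-right
  (mid-sagittal split) axis, axis 1 anterior-posterior and axis 2 the slice
  (inferior -> superior) axis;
* indices are 0-based and ranges half-open;
* physical voxel spacing is given in mm as ``(sx, sy, sz)``;
* intensity channels are stored as 32-bit float, label maps as unsigned 8-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "DixonVolume",
    "FFMap",
    "LabelVolume",
    "MuscleScheme",
    "Stack",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "compute_ff_map",
    "derive_ip_op",
    "stitch_stacks",
]

#: Abbreviation / full-name pairs of the 18 proximal-leg muscles, in the
#: conventional reading order.  Label ids are 1-based into this tuple;
#: 0 is background.
MUSCLES_18: tuple[tuple[str, str], ...] = (
    ("RF", "Rectus femoris"),
    ("VL", "Vastus lateralis"),
    ("VM", "Vastus medialis"),
    ("VI", "Vastus intermedius"),
    ("PC", "Pectineus"),
    ("AB", "Adductor brevis"),
    ("AL", "Adductor longus"),
    ("AM", "Adductor magnus"),
    ("BFL", "Biceps femoris caput longus"),
    ("BFB", "Biceps femoris caput brevis"),
    ("ST", "Semitendinosus"),
    ("SM", "Semimembranosus"),
    ("SR", "Sartorius"),
    ("TFL", "Tensor fascia lata"),
    ("GC", "Gracilis"),
    ("Gma", "Gluteus maximus"),
    ("Gme", "Gluteus medius"),
    ("Gmi", "Gluteus minimus"),
)


@dataclass(frozen=True)
class MuscleScheme:
    """Mapping of integer label ids to muscle abbreviations and full names.

    Ids are contiguous starting at 1; 0 is always background.
    """

    names: tuple[tuple[str, str], ...] = MUSCLES_18

    def __post_init__(self) -> None:
        abbrevs = [a for a, _ in self.names]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("muscle abbreviations must be unique")
        if not 1 <= len(self.names) <= 18:
            raise ValueError("scheme must contain between 1 and 18 muscles")

    @classmethod
    def first(cls, n: int) -> "MuscleScheme":
        """Scheme restricted to the first ``n`` muscles of the 18-muscle list."""
        return cls(names=MUSCLES_18[:n])

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.names) + 1))

    def abbreviation(self, muscle_id: int) -> str:
        return self.names[self._check(muscle_id)][0]

    def full_name(self, muscle_id: int) -> str:
        return self.names[self._check(muscle_id)][1]

    def _check(self, muscle_id: int) -> int:
        if not 1 <= muscle_id <= len(self.names):
            raise KeyError(f"muscle id {muscle_id} not in scheme (1..{len(self.names)})")
        return muscle_id - 1

    def __len__(self) -> int:
        return len(self.names)


def _check_spacing(spacing_mm: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing_mm}")
    return spacing


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular anisotropic grid.

    ``z_offset`` locates the first slice in a common stitched frame; it is 0
    for whole volumes and positive for stacks cropped from a longer axis.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 2.0)
    z_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got {self.values.ndim}-D")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if self.z_offset < 0:
            raise ValueError("z_offset must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_mm, other.spacing_mm)


def _require_same_grid(a: ImageVolume, b: ImageVolume, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm):
        raise ValueError(f"{what}: spacing mismatch {a.spacing_mm} vs {b.spacing_mm}")


@dataclass
class DixonVolume:
    """The four co-registered Dixon channels on one voxel grid.

    ``water`` and ``fat`` are the water-only and fat-only reconstructions;
    ``ip`` (in-phase) and ``op`` (out-of-phase) follow the two-point Dixon
    identities ip = water + fat, op = \\|water - fat\\|.
    """

    water: ImageVolume
    fat: ImageVolume
    ip: ImageVolume
    op: ImageVolume

    def __post_init__(self) -> None:
        for name in ("fat", "ip", "op"):
            _require_same_grid(self.water, getattr(self, name), f"Dixon channel {name}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.water.shape

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.water.spacing_mm

    @property
    def z_offset(self) -> int:
        return self.water.z_offset

    def channels(self) -> dict[str, ImageVolume]:
        return {"water": self.water, "fat": self.fat, "ip": self.ip, "op": self.op}


@dataclass
class FFMap:
    """Per-voxel proton-density fat fraction, in percent.

    ``valid`` marks voxels with any Dixon signal (fat + water > 0); the fat
    fraction is undefined elsewhere and stored as 0 with ``valid`` False.
    """

    values: np.ndarray
    valid: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 2.0)

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("FF values and validity mask must share a shape")
        self.spacing_mm = _check_spacing(self.spacing_mm)


@dataclass
class LabelVolume:
    """Integer muscle label map: 0 = background, ids per :class:`MuscleScheme`."""

    values: np.ndarray
    scheme: MuscleScheme
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 2.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"label map must be 3-D, got {self.values.ndim}-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("label map must be integer-typed")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        present = np.unique(self.values)
        allowed = {0, *self.scheme.ids}
        stray = set(int(v) for v in present) - allowed
        if stray:
            raise ValueError(f"label values {sorted(stray)} not in scheme")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def mask(self, muscle_id: int) -> np.ndarray:
        self.scheme._check(muscle_id)
        return self.values == muscle_id


@dataclass
class Stack:
    """A Dixon sub-volume of consecutive axial slices plus its slice offset
    in the stitched frame."""

    dixon: DixonVolume
    z_offset: int

    def __post_init__(self) -> None:
        if self.z_offset < 0:
            raise ValueError("z_offset must be >= 0")

    @property
    def n_slices(self) -> int:
        return self.dixon.shape[2]

    @property
    def z_end(self) -> int:
        return self.z_offset + self.n_slices


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_from_spacing(spacing_mm: Sequence[float]) -> np.ndarray:
    """RAS affine for a volume whose axes align with the scanner axes."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_volume(volume: ImageVolume, path: str | Path, dtype=np.float32) -> Path:
    """Write a scalar volume as NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(volume.values, dtype=dtype), _affine_from_spacing(volume.spacing_mm)
    )
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3-D NIfTI volume.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the payload is not 3-D or the voxel spacing is not positive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises its own hierarchy
        raise ValueError(f"{path.name}: not a readable NIfTI file ({e})") from e
    if img.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D NIfTI volume, got {img.ndim}-D data")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    values = np.asarray(img.dataobj)
    return ImageVolume(values=values, spacing_mm=_check_spacing(spacing))


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write a label map as unsigned 8-bit NIfTI."""
    vol = ImageVolume(labels.values.astype(np.uint8), labels.spacing_mm)
    return write_volume(vol, path, dtype=np.uint8)


def read_labels(path: str | Path, scheme: MuscleScheme) -> LabelVolume:
    vol = read_volume(path)
    return LabelVolume(
        values=np.asarray(vol.values).astype(np.uint8), scheme=scheme, spacing_mm=vol.spacing_mm
    )


#: File-name suffixes for the Dixon channels and the label map.
CHANNEL_SUFFIXES = {"water": "_W", "fat": "_F", "ip": "_IP", "op": "_OP", "labels": "_labels"}


def write_dixon(dixon: DixonVolume, directory: str | Path, stem: str) -> dict[str, Path]:
    """Write the four Dixon channels as ``<stem>_W/_F/_IP/_OP.nii.gz``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, vol in dixon.channels().items():
        out[name] = write_volume(vol, directory / f"{stem}{CHANNEL_SUFFIXES[name]}.nii.gz")
    return out


def read_dixon(directory: str | Path, stem: str) -> DixonVolume:
    directory = Path(directory)
    vols = {
        name: read_volume(directory / f"{stem}{CHANNEL_SUFFIXES[name]}.nii.gz")
        for name in ("water", "fat", "ip", "op")
    }
    return DixonVolume(**vols)


# ---------------------------------------------------------------------------
# Dixon arithmetic
# ---------------------------------------------------------------------------

def compute_ff_map(fat: ImageVolume, water: ImageVolume) -> FFMap:
    """Proton-density fat-fraction map: 100 * fat / (fat + water), in percent.

    Voxels with ``fat + water == 0`` carry no Dixon signal; they are marked
    invalid and set to 0 so that downstream per-muscle means can exclude them.
    """
    _require_same_grid(fat, water, "compute_ff_map")
    f = np.asarray(fat.values, dtype=np.float64)
    w = np.asarray(water.values, dtype=np.float64)
    if (f < 0).any() or (w < 0).any():
        raise ValueError("compute_ff_map: channel values must be non-negative")
    total = f + w
    valid = total > 0
    ff = np.zeros_like(f)
    np.divide(f, total, out=ff, where=valid)
    return FFMap(values=100.0 * ff, valid=valid, spacing_mm=fat.spacing_mm)


def derive_ip_op(water: ImageVolume, fat: ImageVolume) -> tuple[ImageVolume, ImageVolume]:
    """In-phase and out-of-phase channels from the two-point Dixon identities."""
    _require_same_grid(water, fat, "derive_ip_op")
    ip = ImageVolume(water.values + fat.values, water.spacing_mm, water.z_offset)
    op = ImageVolume(np.abs(water.values - fat.values), water.spacing_mm, water.z_offset)
    return ip, op


def dixon_from_water_fat(water: ImageVolume, fat: ImageVolume) -> DixonVolume:
    ip, op = derive_ip_op(water, fat)
    return DixonVolume(water=water, fat=fat, ip=ip, op=op)


# ---------------------------------------------------------------------------
# Stack stitching
# ---------------------------------------------------------------------------

def _tent_weights(n: int) -> np.ndarray:
    # weight grows linearly with distance to the nearer stack end, so in an
    # overlap the stack whose interior is nearer dominates
    i = np.arange(n, dtype=np.float64)
    return np.minimum(i + 1.0, n - i)


def stitch_stacks(stacks: Sequence[Stack]) -> DixonVolume:
    """Fuse partially overlapping axial stacks into one volume.

    Slices covered by a single stack are copied verbatim.  In overlap
    regions each channel is blended with linear-ramp weights favouring the
    stack whose interior is nearer, which reproduces the source exactly when
    the overlapping values agree.

    Raises
    ------
    ValueError
        If stacks are unsorted, leave an axial gap, or differ in-plane.
    """
    if not stacks:
        raise ValueError("stitch_stacks: no stacks given")
    offsets = [s.z_offset for s in stacks]
    if offsets != sorted(offsets):
        raise ValueError("stitch_stacks: stacks must be sorted by z_offset")
    shape_xy = stacks[0].dixon.shape[:2]
    spacing = stacks[0].dixon.spacing_mm
    for s in stacks[1:]:
        if s.dixon.shape[:2] != shape_xy:
            raise ValueError(
                f"stitch_stacks: in-plane shape mismatch {s.dixon.shape[:2]} vs {shape_xy}"
            )
        if not np.allclose(s.dixon.spacing_mm, spacing):
            raise ValueError("stitch_stacks: spacing mismatch between stacks")
    for prev, nxt in zip(stacks, stacks[1:]):
        if nxt.z_offset > prev.z_end:
            raise ValueError(
                f"stitch_stacks: gap between slices {prev.z_end} and {nxt.z_offset}"
            )

    z0 = stacks[0].z_offset
    z_total = max(s.z_end for s in stacks) - z0
    out_shape = (*shape_xy, z_total)
    acc = {name: np.zeros(out_shape, dtype=np.float64) for name in ("water", "fat", "ip", "op")}
    wsum = np.zeros(z_total, dtype=np.float64)
    for s in stacks:
        w = _tent_weights(s.n_slices)
        sl = slice(s.z_offset - z0, s.z_end - z0)
        wsum[sl] += w
        for name, vol in s.dixon.channels().items():
            acc[name][:, :, sl] += vol.values * w[None, None, :]
    channels = {}
    for name in acc:
        vals = (acc[name] / wsum[None, None, :]).astype(np.float32)
        channels[name] = ImageVolume(vals, spacing, z_offset=0)
    return DixonVolume(**channels)
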