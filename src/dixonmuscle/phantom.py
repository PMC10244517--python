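"""Synthetic Dixon leg phantom with known per-muscle fat infiltration.

The phantom emulates the statistical structure of proximal-leg Dixon MRI —
two mirror-symmetric legs, a subcutaneous fat rind, a femur with fatty
marrow, and a configurable number of muscle compartments with per-muscle
fat replacement — so the full segmentation and quantification pipeline can
be exercised with exactly known ground truth.  It makes no claim of MR
physics fidelity: channels follow the ideal two-point Dixon forward model
(water/fat mixtures at a single global signal amplitude) with optional
additive Gaussian noise.

Geometry model, per leg and axial slice: an outer ellipse bounds the leg;
an inner concentric ellipse separates the subcutaneous fat rind from the
muscle region; a femur disk (signal-free cortex around fatty marrow) sits
at the centre; the muscle region is divided into angular wedges around the
femur, one per muscle, each with its own outer elliptical-radius factor so
compartments differ in shape.  In-plane size tapers linearly along the
slice axis, mimicking the proximodistal change of thigh cross-sections.
The left leg is the exact mirror image of the right leg, so label maps are
mirror-symmetric about the mid-sagittal plane by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .imgvol import (
    DixonVolume,
    ImageVolume,
    LabelVolume,
    MuscleScheme,
    Stack,
    dixon_from_water_fat,
    write_dixon,
    write_labels,
)

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "acquire_stacks", "make_cohort"]

#: Global signal amplitude, arbitrary units.  The acquisition model has no
#: absolute intensity scale; one consistent amplitude is used throughout.
SIGNAL_AMPLITUDE = 1000.0


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic Dixon leg scan.

    ``infiltration`` holds one fat-infiltration fraction in [0, 1] per
    muscle; the designed per-muscle FF%% is 100x that fraction.
    ``shape_jitter`` scales random anatomical variation (ellipse axes, leg
    position, wedge rotation) between subjects; 0 gives the canonical
    geometry.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 48)
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 2.0)
    n_muscles_per_leg: int = 6
    infiltration: tuple[float, ...] = (0.05, 0.20, 0.40, 0.60, 0.80, 0.95)
    noise_sigma: float = 0.02
    n_stacks: int = 1
    stack_len: int | None = None
    stack_overlap: int = 0
    seed: int = 0
    shape_jitter: float = 0.0
    signal: float = SIGNAL_AMPLITUDE

    def __post_init__(self) -> None:
        X, Y, Z = self.grid_shape
        if X % 2 != 0:
            raise ValueError("grid X extent must be even (mid-sagittal split)")
        if X // 2 < 32 or Y < 32:
            raise ValueError(
                "grid too small to host the leg geometry: need >= 32 in-plane "
                f"voxels per leg, got half-width {X // 2} and depth {Y}"
            )
        if Z < 4:
            raise ValueError("grid Z extent must be >= 4 slices")
        if not 1 <= self.n_muscles_per_leg <= 18:
            raise ValueError("n_muscles_per_leg must be in [1, 18]")
        if len(self.infiltration) != self.n_muscles_per_leg:
            raise ValueError(
                f"need {self.n_muscles_per_leg} infiltration fractions, "
                f"got {len(self.infiltration)}"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.infiltration):
            raise ValueError("infiltration fractions must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 1 <= self.n_stacks <= 3:
            raise ValueError("n_stacks must be 1, 2 or 3")
        sl = self.stack_len if self.stack_len is not None else Z
        if self.n_stacks > 1:
            if self.stack_overlap >= sl:
                raise ValueError("stack_overlap must be smaller than stack_len")
            covered = self.n_stacks * sl - (self.n_stacks - 1) * self.stack_overlap
            if covered < Z:
                raise ValueError(
                    f"stack layout covers {covered} < {Z} slices; increase "
                    "stack_len or reduce stack_overlap"
                )
        if sl > Z:
            raise ValueError("stack_len cannot exceed grid Z extent")

    @property
    def scheme(self) -> MuscleScheme:
        return MuscleScheme.first(self.n_muscles_per_leg)

    @property
    def effective_stack_len(self) -> int:
        return self.stack_len if self.stack_len is not None else self.grid_shape[2]


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom scan: the label map plus the
    designed per-muscle FF%% and true volumes."""

    labels: LabelVolume
    designed_ff_pct: dict[int, float]
    true_volume_ml: dict[int, float]

    def as_frame(self) -> pd.DataFrame:
        scheme = self.labels.scheme
        rows = [
            {
                "muscle_id": m,
                "muscle_name": scheme.abbreviation(m),
                "designed_ff_pct": self.designed_ff_pct[m],
                "volume_ml": self.true_volume_ml[m],
            }
            for m in scheme.ids
        ]
        return pd.DataFrame(rows)


def _leg_half(config: PhantomConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build water/fat/label arrays for one leg on a half-width grid.

    Returns arrays of shape (X/2, Y, Z); the full phantom is this half plus
    its mirror image.
    """
    X, Y, Z = config.grid_shape
    W = X // 2
    n = config.n_muscles_per_leg
    S = config.signal
    j = config.shape_jitter

    # subject-level anatomy jitter (applied identically to both legs)
    jx = 1.0 + j * rng.uniform(-1.0, 1.0)
    jy = 1.0 + j * rng.uniform(-1.0, 1.0)
    cx = W / 2.0 + j * W * 0.2 * rng.uniform(-1.0, 1.0)
    cy = Y / 2.0 + j * Y * 0.2 * rng.uniform(-1.0, 1.0)
    rot = j * rng.uniform(-0.5, 0.5) * (2.0 * np.pi / n)

    r0 = 0.42 * min(W, Y)
    ax, ay = r0 * jx, r0 * jy
    rind = 0.82          # inner-ellipse fraction: muscle region boundary
    femur_frac = 0.20    # femur radius as fraction of r0
    marrow_frac = 0.60   # marrow radius as fraction of femur radius
    taper = 0.25         # linear in-plane shrinkage from z=0 to z=Z-1

    # per-muscle outer-radius factors: fixed deterministic pattern plus jitter
    rho = 0.90 + 0.08 * ((np.arange(n) * 7) % n) / max(n - 1, 1)
    if j > 0:
        rho = np.clip(rho + 0.03 * rng.uniform(-1.0, 1.0, size=n), 0.85, 1.0)

    x = np.arange(W, dtype=np.float64)[:, None] - cx
    y = np.arange(Y, dtype=np.float64)[None, :] - cy
    theta = np.arctan2(y, x)  # broadcast to (W, Y)
    wedge = np.floor(((theta + np.pi + rot) / (2.0 * np.pi / n))).astype(np.int64) % n

    water = np.zeros((W, Y, Z), dtype=np.float32)
    fat = np.zeros((W, Y, Z), dtype=np.float32)
    labels = np.zeros((W, Y, Z), dtype=np.uint8)
    infil = np.asarray(config.infiltration, dtype=np.float64)

    for z in range(Z):
        t = 1.0 - taper * (z / max(Z - 1, 1))
        r_ell = np.sqrt((x / (ax * t)) ** 2 + (y / (ay * t)) ** 2)  # (W, Y)
        r_abs = np.sqrt(x**2 + y**2)
        leg = r_ell <= 1.0
        muscle_region = r_ell <= rind
        femur = r_abs <= femur_frac * r0 * t
        marrow = r_abs <= marrow_frac * femur_frac * r0 * t

        # subcutaneous fat rind and fatty marrow: pure fat signal
        fat_like = (leg & ~muscle_region) | marrow
        fat[:, :, z][fat_like] = S
        # femur cortex between marrow and femur radius: signal-free (bone)

        core = muscle_region & ~femur
        for m in range(n):
            inside = core & (wedge == m) & (r_ell <= rind * rho[m])
            labels[:, :, z][inside] = m + 1
            water[:, :, z][inside] = (1.0 - infil[m]) * S
            fat[:, :, z][inside] = infil[m] * S
        # wedge voxels beyond the muscle's own radius: intermuscular fat
        gaps = core & (labels[:, :, z] == 0)
        fat[:, :, z][gaps] = S

    return water, fat, labels


def generate_phantom(config: PhantomConfig) -> tuple[DixonVolume, PhantomTruth]:
    """Generate one two-legged Dixon phantom scan and its ground truth.

    The right-leg half is synthesised and mirrored onto the left half, so
    the noise-free geometry is exactly mirror-symmetric.  Zero-mean Gaussian
    noise (sd = ``noise_sigma`` x signal amplitude, clipped at 0) is added
    to the water and fat channels independently; in-phase and out-of-phase
    channels are derived afterwards so all four stay consistent.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    water_h, fat_h, labels_h = _leg_half(config, rng)

    def mirror_concat(a: np.ndarray) -> np.ndarray:
        return np.concatenate([a[::-1], a], axis=0)  # left half = mirrored right

    water = mirror_concat(water_h)
    fat = mirror_concat(fat_h)
    labels = mirror_concat(labels_h)

    if config.noise_sigma > 0:
        sd = config.noise_sigma * config.signal
        water = np.clip(water + rng.normal(0.0, sd, water.shape), 0.0, None)
        fat = np.clip(fat + rng.normal(0.0, sd, fat.shape), 0.0, None)
    water = water.astype(np.float32)
    fat = fat.astype(np.float32)

    dixon = dixon_from_water_fat(
        ImageVolume(water, config.spacing_mm), ImageVolume(fat, config.spacing_mm)
    )
    label_vol = LabelVolume(labels, config.scheme, config.spacing_mm)
    voxel_ml = np.prod(config.spacing_mm) / 1000.0
    truth = PhantomTruth(
        labels=label_vol,
        designed_ff_pct={m: 100.0 * config.infiltration[m - 1] for m in config.scheme.ids},
        true_volume_ml={
            m: float(np.count_nonzero(labels == m)) * voxel_ml for m in config.scheme.ids
        },
    )
    return dixon, truth


def acquire_stacks(volume: DixonVolume, config: PhantomConfig) -> list[Stack]:
    """Crop a stitched-frame volume into 1-3 partially overlapping axial stacks.

    Consecutive stacks overlap by ``stack_overlap`` slices; the union of the
    slice ranges covers the full axis.  Noise is part of the source volume,
    so overlap regions are bit-identical between stacks.
    """
    Z = volume.shape[2]
    sl = config.effective_stack_len
    if config.n_stacks > 1 and config.stack_overlap >= sl:
        raise ValueError("stack_overlap must be smaller than stack_len")
    stride = sl - config.stack_overlap
    stacks = []
    for i in range(config.n_stacks):
        z0 = min(i * stride, Z - sl)
        crop = {
            name: ImageVolume(vol.values[:, :, z0 : z0 + sl], vol.spacing_mm, z_offset=z0)
            for name, vol in volume.channels().items()
        }
        stacks.append(Stack(dixon=DixonVolume(**crop), z_offset=z0))
    covered = set()
    for s in stacks:
        covered.update(range(s.z_offset, s.z_end))
    if covered != set(range(Z)):
        raise ValueError("stack layout does not cover the full slice range")
    return stacks


def make_cohort(
    n_subjects: int,
    infiltration_range: tuple[float, float],
    base_config: PhantomConfig,
    seed: int,
    shape_jitter: float = 0.08,
) -> list[tuple[DixonVolume, PhantomTruth]]:
    """Generate a cohort of phantom subjects with random per-muscle infiltration.

    Per subject, each muscle's infiltration fraction is drawn uniformly from
    ``infiltration_range`` and the anatomy is jittered (ellipse axes, leg
    position, wedge rotation) so subjects differ in shape as well as in fat
    load.  Reproducible under ``seed``; subjects are sub-seeded
    independently.
    """
    lo, hi = infiltration_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError(f"infiltration_range must satisfy 0 <= lo <= hi <= 1, got {lo, hi}")
    out = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_subjects):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        infil = tuple(rng.uniform(lo, hi, size=base_config.n_muscles_per_leg).tolist())
        cfg = replace(
            base_config, infiltration=infil, seed=sub_seed, shape_jitter=shape_jitter
        )
        out.append(generate_phantom(cfg))
    return out


def save_subject(
    dixon: DixonVolume, truth: PhantomTruth, directory: str | Path, stem: str
) -> None:
    """Write a phantom subject as NIfTI channels, a label map and a truth CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_dixon(dixon, directory, stem)
    write_labels(truth.labels, directory / f"{stem}_labels.nii.gz")
    truth.as_frame().to_csv(directory / f"{stem}_truth.csv", index=False)
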