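"""3-D U-Net segmentation model, training protocol and whole-volume prediction.

The network is an encoder-decoder with 3x3x3 kernels everywhere, including
the strided down-sampling convolutions and the channel-reducing convolutions
that precede nearest-neighbour up-sampling; the deepest level holds 4
convolutional layers.  Skip connections are additive.  Instance
normalisation follows every convolution (the batch size is fixed at 1).
Channel widths double per level from ``base_filters``.

Training follows a fixed protocol: per epoch, 2 slab patches are randomly
sampled from every single-leg training image (batch size 1), optionally
augmented, and optimised with Adam under voxel-wise cross-entropy starting
from learning rate 1e-4.  The learning rate halves when the validation
loss has not improved over the last 25 epochs; training stops at
``max_epochs`` or, when configured, after ``early_stop_patience``
non-improving epochs.  The parameters with the best validation loss are
returned.  Validation loss is measured on a fixed tiling of patches so the
schedule is not driven by sampling noise.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .imgvol import DixonVolume, LabelVolume, MuscleScheme
from .preprocess import AugmentParams, Patch, augment, cut_patch, mirror_lr, sample_patch, split_midsagittal, concat_halves

__all__ = [
    "SegModelSpec",
    "TrainConfig",
    "FoldSplit",
    "ProbabilityVolume",
    "TrainingScan",
    "UNet3D",
    "build_model",
    "make_folds",
    "train",
    "finetune",
    "predict_volume",
    "ensemble_vote",
    "segment_subject",
    "lr_schedule_trace",
    "scans_from_subject",
    "tile_starts",
]


@dataclass(frozen=True)
class SegModelSpec:
    """Architecture of the segmentation U-Net.

    ``n_classes`` counts background plus one class per muscle.  Spatial
    input extents must be divisible by ``2**(depth-1)``.  ``input_scale``
    is a fixed global intensity scaling (the model applies no per-image
    normalisation).
    """

    depth: int = 3
    base_filters: int = 8
    n_classes: int = 7
    in_channels: int = 2
    growth: int = 2
    convs_per_level: int = 1
    deepest_convs: int = 4
    norm: str = "instance"
    input_scale: float = 1e-3

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.norm not in ("instance", "none"):
            raise ValueError("norm must be 'instance' or 'none'")
        if self.deepest_convs < 1 or self.convs_per_level < 1:
            raise ValueError("conv counts must be >= 1")

    def channels_at(self, level: int) -> int:
        return self.base_filters * self.growth**level


def _conv_block(cin: int, cout: int, rng, spec: SegModelSpec, stride: int = 1) -> list:
    layers: list = [nn.Conv3x3(cin, cout, rng, stride=stride)]
    if spec.norm == "instance":
        layers.append(nn.InstanceNorm(cout))
    layers.append(nn.ReLU())
    return layers


class UNet3D:
    """The segmentation network with explicit forward/backward passes."""

    def __init__(self, spec: SegModelSpec, rng: np.random.Generator):
        self.spec = spec
        self.meta: dict = {}
        d = spec.depth
        ch = [spec.channels_at(l) for l in range(d)]

        # encoder: level 0 entry conv, then strided down-convs; the deepest
        # level holds `deepest_convs` conv layers in total (down conv included)
        self.enc_blocks: list[list] = []
        for l in range(d):
            layers: list = []
            if l == 0:
                layers += _conv_block(spec.in_channels, ch[0], rng, spec)
                extra = spec.convs_per_level - 1
            else:
                layers += _conv_block(ch[l - 1], ch[l], rng, spec, stride=2)
                extra = (spec.deepest_convs if l == d - 1 else spec.convs_per_level) - 1
            for _ in range(extra):
                layers += _conv_block(ch[l], ch[l], rng, spec)
            self.enc_blocks.append(layers)

        # decoder: reduce channels, nearest-neighbour upsample, add skip,
        # then refine
        self.dec_blocks: list[dict] = []
        for l in range(d - 2, -1, -1):
            up = _conv_block(ch[l + 1], ch[l], rng, spec)
            refine: list = []
            for _ in range(spec.convs_per_level):
                refine += _conv_block(ch[l], ch[l], rng, spec)
            self.dec_blocks.append({"level": l, "up": up, "upsample": nn.Upsample2x(), "refine": refine})

        self.head = nn.Head1x1(ch[0], spec.n_classes, rng)
        self.model_id = f"{int(rng.integers(2**62)):016x}"

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for block in self.enc_blocks:
            for layer in block:
                out += layer.params()
        for dec in self.dec_blocks:
            for layer in [*dec["up"], *dec["refine"]]:
                out += layer.params()
        out += self.head.params()
        return out

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the parameter list")
        for p, w in zip(params, weights):
            p.value[...] = w

    def clone(self) -> "UNet3D":
        return copy.deepcopy(self)

    # -- passes -------------------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.spec.in_channels:
            raise ValueError(f"expected ({self.spec.in_channels}, X, Y, S) input, got {x.shape}")
        div = 2 ** (self.spec.depth - 1)
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"spatial shape {x.shape[1:]} not divisible by {div} "
                f"(depth {self.spec.depth})"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a 2-channel patch to per-voxel class logits of the same
        spatial shape."""
        self._check_shape(x)
        h = np.ascontiguousarray(x, dtype=np.float32) * np.float32(self.spec.input_scale)
        skips = []
        for block in self.enc_blocks:
            for layer in block:
                h = layer.forward(h)
            skips.append(h)
        h = skips[-1]
        for dec in self.dec_blocks:
            for layer in dec["up"]:
                h = layer.forward(h)
            h = dec["upsample"].forward(h)
            h = h + skips[dec["level"]]
            for layer in dec["refine"]:
                h = layer.forward(h)
        return self.head.forward(h)

    def forward_probs(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities (softmax over the class axis)."""
        return nn.softmax(self.forward(x), axis=0)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        for dec in reversed(self.dec_blocks):
            for layer in reversed(dec["refine"]):
                d = layer.backward(d)
            dskips[dec["level"]] = d.copy()  # additive skip: gradient forks
            d = dec["upsample"].backward(d)
            for layer in reversed(dec["up"]):
                d = layer.backward(d)
        # accumulate decoder-path gradient into the deepest encoder output
        for l in range(self.spec.depth - 1, -1, -1):
            if l == self.spec.depth - 1:
                dh = d
            else:
                dh = dh + dskips[l]
            for layer in reversed(self.enc_blocks[l]):
                dh = layer.backward(dh)

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {f"param_{i:04d}": p.value for i, p in enumerate(self.params())}
        header = json.dumps({"spec": asdict(self.spec), "meta": self.meta, "model_id": self.model_id})
        np.savez_compressed(path, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            model = cls(SegModelSpec(**header["spec"]), np.random.default_rng(0))
            model.meta = header["meta"]
            model.model_id = header["model_id"]
            keys = sorted(k for k in data.files if k.startswith("param_"))
            model.set_weights([data[k] for k in keys])
        return model


def build_model(spec: SegModelSpec, seed: int | np.random.Generator = 0) -> UNet3D:
    """Build a U-Net with reproducible seeded He initialisation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return UNet3D(spec, rng)


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """The training protocol.  Loss is voxel-wise cross-entropy and the
    optimizer Adam; both are fixed.  ``patch_slices`` None means the full
    slab length min(81, Z)."""

    lr0: float = 1e-4
    plateau_patience: int = 25
    lr_factor: float = 0.5
    batch_size: int = 1
    patches_per_image: int = 2
    max_epochs: int = 160
    early_stop_patience: Optional[int] = None
    min_improvement: float = 1e-6
    patch_slices: Optional[int] = None
    augment: Optional[AugmentParams] = field(default_factory=AugmentParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("the protocol fixes batch_size at 1")
        if self.lr0 <= 0 or not 0 < self.lr_factor < 1:
            raise ValueError("invalid learning-rate settings")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")

    def effective_patch_slices(self, z: int) -> int:
        return self.patch_slices if self.patch_slices is not None else min(81, z)


class PlateauSchedule:
    """Reduce-on-plateau learning rate with strict-improvement tolerance.

    A validation loss counts as an improvement when it is more than ``tol``
    below the best seen so far.  After ``patience`` consecutive
    non-improving epochs the rate is multiplied by ``factor`` and the
    plateau counter restarts; the best-loss bookmark is kept.
    """

    def __init__(self, lr0: float, factor: float, patience: int, tol: float = 1e-6):
        self.lr = lr0
        self.factor = factor
        self.patience = patience
        self.tol = tol
        self.best = np.inf
        self.plateau = 0

    def update(self, val_loss: float) -> float:
        if val_loss < self.best - self.tol:
            self.best = val_loss
            self.plateau = 0
        else:
            self.plateau += 1
            if self.plateau >= self.patience:
                self.lr *= self.factor
                self.plateau = 0
        return self.lr


def lr_schedule_trace(
    val_losses: Sequence[float],
    lr0: float = 1e-4,
    factor: float = 0.5,
    patience: int = 25,
    tol: float = 1e-6,
) -> list[float]:
    """Learning rate after each epoch, as a pure function of the
    validation-loss sequence."""
    sched = PlateauSchedule(lr0, factor, patience, tol)
    return [sched.update(v) for v in val_losses]


@dataclass
class TrainingScan:
    """A single-leg image ready for the network: 2-channel (OP, IP) array
    plus labels, with left legs already mirrored to right-leg orientation."""

    channels: np.ndarray
    labels: np.ndarray
    subject_id: str
    scan_id: str

    def __post_init__(self) -> None:
        if self.channels.ndim != 4 or self.channels.shape[0] != 2:
            raise ValueError("scan channels must be (2, W, Y, Z)")
        if self.labels.shape != self.channels.shape[1:]:
            raise ValueError("scan labels must match the channel grid")


def scans_from_subject(
    dixon: DixonVolume, labels: LabelVolume, subject_id: str, scan_id: str = "scan0"
) -> list[TrainingScan]:
    """Split a two-leg scan into its two single-leg training images (the
    left half mirrored), doubling the data per subject."""
    channels = np.stack([dixon.op.values, dixon.ip.values]).astype(np.float32)
    right_c, left_c = split_midsagittal(channels)
    right_l, left_l = split_midsagittal(labels.values)
    return [
        TrainingScan(right_c, right_l, subject_id, f"{scan_id}_R"),
        TrainingScan(mirror_lr(left_c), mirror_lr(left_l), subject_id, f"{scan_id}_L"),
    ]


@dataclass
class FoldSplit:
    """Subject-grouped k-fold partition: every scan of a subject lands in
    exactly one fold."""

    folds: list[list[str]]
    scans_by_subject: dict[str, list[str]]

    def subjects(self) -> list[str]:
        return [s for fold in self.folds for s in fold]

    def train_subjects(self, fold_idx: int) -> list[str]:
        return [s for i, fold in enumerate(self.folds) if i != fold_idx for s in fold]

    def val_subjects(self, fold_idx: int) -> list[str]:
        return list(self.folds[fold_idx])


def make_folds(
    subjects: Sequence[tuple[str, Sequence[str]]], k: int, seed: int = 0
) -> FoldSplit:
    """Deal shuffled subjects round-robin into k folds; scans follow their
    subject so the partition is grouped at subject level."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} available subjects")
    ids = [s for s, _ in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    order = np.random.default_rng(seed).permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return FoldSplit(folds=folds, scans_by_subject={s: list(sc) for s, sc in subjects})


def _validation_patches(scans: Sequence[TrainingScan], patch_slices: int) -> list[Patch]:
    """Fixed minimal-coverage tiling used for the validation loss each epoch."""
    patches = []
    for scan in scans:
        z = scan.channels.shape[-1]
        for start in tile_starts(z, patch_slices, overlap_frac=0.0):
            patches.append(cut_patch(scan.channels, scan.labels, start, patch_slices))
    return patches


def train(
    model: UNet3D,
    train_scans: Sequence[TrainingScan],
    val_scans: Sequence[TrainingScan],
    config: TrainConfig,
) -> tuple[UNet3D, pd.DataFrame]:
    """Train in place under the fixed protocol; returns the model carrying
    its best-validation-loss parameters plus the per-epoch history
    (epoch, train_loss, val_loss, lr)."""
    if not train_scans:
        raise ValueError("empty training set")
    if not val_scans:
        raise ValueError("empty validation set")
    z = train_scans[0].channels.shape[-1]
    patch_slices = config.effective_patch_slices(z)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.lr0)
    sched = PlateauSchedule(config.lr0, config.lr_factor, config.plateau_patience, config.min_improvement)
    val_patches = _validation_patches(val_scans, patch_slices)

    best_val = np.inf
    best_weights = model.get_weights()
    since_improve = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_scans))
        losses = []
        for idx in order:
            scan = train_scans[idx]
            for _ in range(config.patches_per_image):
                patch = sample_patch(scan.channels, scan.labels, patch_slices, rng)
                if config.augment is not None:
                    patch = augment(patch, config.augment, rng)
                logits = model.forward(patch.channels)
                loss, dlogits = nn.cross_entropy(logits, patch.labels)
                model.backward(dlogits)
                opt.lr = sched.lr
                opt.step()
                losses.append(loss)
        val_loss = float(
            np.mean([nn.cross_entropy(model.forward(p.channels), p.labels)[0] for p in val_patches])
        )
        lr_after = sched.update(val_loss)
        if val_loss < best_val - config.min_improvement:
            best_val = val_loss
            best_weights = model.get_weights()
            since_improve = 0
        else:
            since_improve += 1
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss, "lr": lr_after}
        )
        if config.early_stop_patience is not None and since_improve >= config.early_stop_patience:
            break
    model.set_weights(best_weights)
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss", "lr"])
    model.meta.setdefault("history_epochs", 0)
    model.meta["history_epochs"] += len(history)
    return model, history


def finetune(
    model: UNet3D,
    train_scans: Sequence[TrainingScan],
    val_scans: Sequence[TrainingScan],
    config: TrainConfig,
) -> tuple[UNet3D, pd.DataFrame]:
    """Continue training from the given parameters on a new set of scans
    (e.g. a low-infiltration model refined on high-infiltration cases).
    The parent model id is recorded; 0 epochs leaves parameters unchanged."""
    tuned = model.clone()
    tuned.meta["parent"] = model.model_id
    rng = np.random.default_rng(int(model.model_id, 16) % (2**31))
    tuned.model_id = f"{int(rng.integers(2**62)):016x}"
    if config.max_epochs == 0:
        return tuned, pd.DataFrame(columns=["epoch", "train_loss", "val_loss", "lr"])
    return train(tuned, train_scans, val_scans, config)


# ---------------------------------------------------------------------------
# whole-volume prediction
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities plus the number of patches that
    contributed to each voxel."""

    probs: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.ndim != 4:
            raise ValueError("probs must be (n_classes, X, Y, Z)")
        if self.coverage.shape != self.probs.shape[1:]:
            raise ValueError("coverage must match the spatial grid")

    def argmax_labels(self) -> np.ndarray:
        # ties resolve to the lowest class id (np.argmax convention)
        return np.argmax(self.probs, axis=0).astype(np.uint8)


def tile_starts(z: int, patch_slices: int, overlap_frac: float = 0.5) -> list[int]:
    """Deterministic slab starts covering [0, z) with roughly the requested
    fractional overlap; the final slab is flush with the end."""
    if patch_slices > z:
        raise ValueError(f"patch length {patch_slices} exceeds {z} slices")
    step = max(1, int(round(patch_slices * (1.0 - overlap_frac))))
    starts = list(range(0, z - patch_slices + 1, step))
    if starts[-1] != z - patch_slices:
        starts.append(z - patch_slices)
    return starts


def predict_volume(
    model: UNet3D,
    channels: np.ndarray,
    patch_slices: Optional[int] = None,
    policy: str = "tile",
    overlap_frac: float = 0.5,
    n_random: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    starts: Optional[Sequence[int]] = None,
) -> ProbabilityVolume:
    """Predict a whole single-leg volume from overlapping slab patches.

    Per-voxel probabilities are the coverage-weighted mean over all patches
    containing the voxel, renormalised to the probability simplex.  The
    default policy tiles the slice axis deterministically with >= 50%
    overlap; ``policy="random"`` samples random slabs (at least enough for
    full coverage).  Explicit ``starts`` must cover every slice.
    """
    if channels.ndim != 4:
        raise ValueError("channels must be (2, W, Y, Z)")
    z = channels.shape[-1]
    s = patch_slices if patch_slices is not None else min(81, z)
    if starts is not None:
        starts = sorted(int(v) for v in starts)
    elif policy == "tile":
        starts = tile_starts(z, s, overlap_frac)
    elif policy == "random":
        rng = rng or np.random.default_rng(0)
        n_min = n_random if n_random is not None else max(2, 2 * len(tile_starts(z, s, 0.0)))
        starts = [int(rng.integers(0, z - s + 1)) for _ in range(n_min)]
        # keep sampling until every slice is covered
        cov = np.zeros(z, dtype=bool)
        for st in starts:
            cov[st : st + s] = True
        while not cov.all():
            first_gap = int(np.flatnonzero(~cov)[0])
            lo = max(0, first_gap - s + 1)
            hi = min(first_gap, z - s)
            st = int(rng.integers(lo, hi + 1))
            starts.append(st)
            cov[st : st + s] = True
        starts = sorted(starts)
    else:
        raise ValueError(f"unknown patch policy {policy!r}")

    covered = np.zeros(z, dtype=np.int64)
    for st in starts:
        if not 0 <= st <= z - s:
            raise ValueError(f"patch start {st} out of range for Z={z}, S={s}")
        covered[st : st + s] += 1
    if (covered == 0).any():
        missing = np.flatnonzero(covered == 0)
        raise ValueError(f"patch starts leave slices uncovered: {missing.tolist()}")

    acc = np.zeros((model.spec.n_classes, *channels.shape[1:]), dtype=np.float64)
    for st in starts:
        probs = model.forward_probs(np.ascontiguousarray(channels[..., st : st + s]))
        acc[..., st : st + s] += probs
    acc /= covered[None, None, None, :]
    acc /= acc.sum(axis=0, keepdims=True)
    coverage = np.broadcast_to(covered, channels.shape[1:]).copy()
    return ProbabilityVolume(probs=acc.astype(np.float32), coverage=coverage)


def ensemble_vote(
    label_volumes: Sequence[LabelVolume],
    prob_volumes: Optional[Sequence[np.ndarray]] = None,
) -> LabelVolume:
    """Majority vote over label maps from several models.

    Ties are broken by the highest mean class probability when probability
    volumes are supplied, otherwise by the lowest label id; the result is
    deterministic either way.
    """
    if len(label_volumes) < 2:
        raise ValueError("ensemble needs at least 2 label volumes")
    scheme = label_volumes[0].scheme
    shape = label_volumes[0].shape
    for lv in label_volumes[1:]:
        if lv.shape != shape or len(lv.scheme) != len(scheme):
            raise ValueError("ensemble inputs must share grid and scheme")
    n_classes = len(scheme) + 1
    counts = np.zeros((n_classes, *shape), dtype=np.int16)
    for lv in label_volumes:
        for c in range(n_classes):
            counts[c] += lv.values == c
    top = counts.max(axis=0)
    is_top = counts == top[None]
    n_top = is_top.sum(axis=0)
    if prob_volumes is not None:
        if len(prob_volumes) != len(label_volumes):
            raise ValueError("need one probability volume per label volume")
        mean_probs = np.mean([np.asarray(p, dtype=np.float64) for p in prob_volumes], axis=0)
        score = np.where(is_top, mean_probs, -1.0)
        winner = score.argmax(axis=0)
        # argmax also resolves residual exact-probability ties to lowest id
    else:
        winner = is_top.argmax(axis=0)  # lowest tied id
    majority = counts.argmax(axis=0)
    out = np.where(n_top > 1, winner, majority).astype(np.uint8)
    return LabelVolume(out, scheme, label_volumes[0].spacing_mm)


def segment_subject(
    models: UNet3D | Sequence[UNet3D],
    dixon: DixonVolume,
    scheme: MuscleScheme,
    patch_slices: Optional[int] = None,
    overlap_frac: float = 0.5,
) -> LabelVolume:
    """Segment a full two-leg Dixon scan.

    Pipeline: mid-sagittal split -> mirror the left half -> patch-based
    prediction of both halves -> argmax -> mirror the left prediction back
    -> concatenate.  With several models, their stitched label maps are
    fused by majority vote (probability tie-break).  The result is ready
    for postprocessing.
    """
    model_list = [models] if isinstance(models, UNet3D) else list(models)
    channels = np.stack([dixon.op.values, dixon.ip.values]).astype(np.float32)
    right_c, left_c = split_midsagittal(channels)
    left_m = mirror_lr(left_c)

    full_labels, full_probs = [], []
    for model in model_list:
        if model.spec.n_classes != len(scheme) + 1:
            raise ValueError("model class count does not match the muscle scheme")
        pv_r = predict_volume(model, right_c, patch_slices, overlap_frac=overlap_frac)
        pv_l = predict_volume(model, left_m, patch_slices, overlap_frac=overlap_frac)
        labels = concat_halves(pv_r.argmax_labels(), mirror_lr(pv_l.argmax_labels()))
        probs = concat_halves(pv_r.probs, mirror_lr(pv_l.probs))
        full_labels.append(LabelVolume(labels, scheme, dixon.spacing_mm))
        full_probs.append(probs)
    if len(full_labels) == 1:
        return full_labels[0]
    return ensemble_vote(full_labels, full_probs)
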