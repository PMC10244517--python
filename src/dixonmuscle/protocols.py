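"""Desk-scale study protocols: fixed conditions for phantom experiments.

These functions pin down the miniature counterpart of the clinical study
so that experiments are reproducible and comparable: an 8-subject phantom
cohort on a 96x96x48 grid with 6 muscles per leg, a depth-3/8-filter
U-Net on 24-slice patches, 40 training epochs with 2 patches per image at
batch size 1, and subject-grouped fold splits.  The learning rate is the
one deliberate departure from the clinical protocol: with roughly two
orders of magnitude fewer optimizer steps than a clinical-scale run, the
Adam step size is scaled up tenfold (1e-3) so that the total parameter
displacement is comparable; every other protocol constant carries over.

The low-infiltration (LI) cohort draws per-muscle infiltration uniformly
from [0, 0.2]; the high-infiltration (HI) cohort from [0.4, 0.8],
mirroring the two clinical severity groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imgvol import DixonVolume, LabelVolume
from .metrics import evaluate_segmentation
from .phantom import PhantomConfig, PhantomTruth, make_cohort
from .postprocess import fill_holes, filter_components, sparsify_gt
from .preprocess import AugmentParams
from .segnet import (
    SegModelSpec,
    TrainConfig,
    UNet3D,
    build_model,
    finetune,
    make_folds,
    scans_from_subject,
    segment_subject,
    train,
)

__all__ = [
    "mini_unet_spec",
    "mini_train_config",
    "desk_base_config",
    "desk_cohort",
    "MiniStudyResult",
    "run_mini_study",
    "evaluate_model_on_cohort",
    "finetune_on_cohort",
]

#: Desk-scale study constants.
N_SUBJECTS = 8
N_MUSCLES = 6
GRID = (96, 96, 48)
PATCH_SLICES = 24
MAX_EPOCHS = 40
LI_RANGE = (0.0, 0.2)
HI_RANGE = (0.4, 0.8)
MINI_LR = 1e-3


def mini_unet_spec(n_muscles: int = N_MUSCLES) -> SegModelSpec:
    """The miniature U-Net: depth 3, 8 base filters, 2 input channels."""
    return SegModelSpec(depth=3, base_filters=8, n_classes=n_muscles + 1)


def mini_train_config(seed: int, max_epochs: int = MAX_EPOCHS, lr0: float = MINI_LR) -> TrainConfig:
    """Desk-scale training protocol; augmentation kept mild to match the
    phantom's modest anatomical variability."""
    return TrainConfig(
        lr0=lr0,
        max_epochs=max_epochs,
        patch_slices=PATCH_SLICES,
        augment=AugmentParams(rotation_deg=5, scale=0.05, translation_vox=2, noise_sigma_aug=10),
        seed=seed,
    )


def desk_base_config() -> PhantomConfig:
    return PhantomConfig(
        grid_shape=GRID,
        n_muscles_per_leg=N_MUSCLES,
        infiltration=(0.0,) * N_MUSCLES,
        noise_sigma=0.02,
    )


def desk_cohort(
    seed: int, infiltration_range: tuple[float, float] = LI_RANGE, n_subjects: int = N_SUBJECTS
) -> list[tuple[DixonVolume, PhantomTruth]]:
    return make_cohort(n_subjects, infiltration_range, desk_base_config(), seed=seed)


@dataclass
class MiniStudyResult:
    """One desk-scale training run and its held-out evaluation."""

    model: UNet3D
    history: pd.DataFrame
    held_out: list[str]
    per_subject: pd.DataFrame
    mean_gdsc_pct: float
    cohort: list = field(repr=False, default_factory=list)


def _postprocessed_prediction(model, dixon, scheme) -> LabelVolume:
    pred = segment_subject(model, dixon, scheme, patch_slices=PATCH_SLICES)
    return fill_holes(filter_components(pred))


def evaluate_model_on_cohort(
    model: UNet3D,
    cohort: Sequence[tuple[DixonVolume, PhantomTruth]],
    subject_ids: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Segment, postprocess and score each requested cohort subject;
    returns one row per subject with the generalized DSC."""
    rows = []
    ids = subject_ids if subject_ids is not None else range(len(cohort))
    for i in ids:
        dixon, truth = cohort[i]
        pred = _postprocessed_prediction(model, dixon, truth.labels.scheme)
        report = evaluate_segmentation(pred, truth.labels)
        rows.append({"subject": f"s{i}", "gdsc_pct": report.gdsc_pct})
    return pd.DataFrame(rows)


def run_mini_study(
    seed: int,
    cohort: Optional[list] = None,
    gt_stride: int = 1,
    max_epochs: int = MAX_EPOCHS,
) -> MiniStudyResult:
    """Train the mini U-Net on a subject-grouped split of an 8-subject LI
    cohort and evaluate on the held-out fold.

    The cohort is split into two grouped folds; fold 0 (4 subjects) is
    held out, and of the remaining subjects the last provides the
    validation scans.  ``gt_stride`` > 1 trains on sparsified ground truth
    (every k-th slice, nearest-neighbour fill) while evaluation always
    uses the full truth.
    """
    cohort = cohort if cohort is not None else desk_cohort(seed)
    subjects = [(f"s{i}", [f"s{i}"]) for i in range(len(cohort))]
    folds = make_folds(subjects, k=2, seed=seed)
    held = folds.val_subjects(0)
    train_ids = folds.train_subjects(0)
    val_ids, fit_ids = train_ids[-1:], train_ids[:-1]

    def training_labels(truth: PhantomTruth) -> LabelVolume:
        return truth.labels if gt_stride == 1 else sparsify_gt(truth.labels, gt_stride)

    scans = {
        f"s{i}": scans_from_subject(dixon, training_labels(truth), f"s{i}")
        for i, (dixon, truth) in enumerate(cohort)
    }
    train_scans = [s for sid in fit_ids for s in scans[sid]]
    val_scans = [s for sid in val_ids for s in scans[sid]]

    model = build_model(mini_unet_spec(), seed)
    model, history = train(model, train_scans, val_scans, mini_train_config(seed, max_epochs))
    per_subject = evaluate_model_on_cohort(
        model, cohort, [int(s[1:]) for s in held]
    )
    return MiniStudyResult(
        model=model,
        history=history,
        held_out=held,
        per_subject=per_subject,
        mean_gdsc_pct=float(per_subject["gdsc_pct"].mean()),
        cohort=cohort,
    )


def finetune_on_cohort(
    model: UNet3D,
    cohort: Sequence[tuple[DixonVolume, PhantomTruth]],
    seed: int,
    max_epochs: int = 15,
) -> tuple[UNet3D, pd.DataFrame, list[int]]:
    """Continue training a model on the training half of a new cohort
    (e.g. LI model -> HI cohort); returns the tuned model, its history and
    the held-out subject indices of that cohort."""
    subjects = [(f"s{i}", [f"s{i}"]) for i in range(len(cohort))]
    folds = make_folds(subjects, k=2, seed=seed)
    held = [int(s[1:]) for s in folds.val_subjects(0)]
    train_ids = folds.train_subjects(0)
    scans = {
        f"s{i}": scans_from_subject(dixon, truth.labels, f"s{i}")
        for i, (dixon, truth) in enumerate(cohort)
    }
    train_scans = [s for sid in train_ids[:-1] for s in scans[sid]]
    val_scans = [s for sid in train_ids[-1:] for s in scans[sid]]
    config = mini_train_config(seed, max_epochs)
    tuned, history = finetune(model, train_scans, val_scans, config)
    return tuned, history, held
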