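"""The fully automatic two-stage flow: detect bone slices, then segment.

A raw scan is border-cropped and normalized, every slice is resized to
the detection resolution and classified as bone/no-bone by the
detection network (a slice is positive when its output map has at
least ``min_area`` pixels above threshold — an all-black output means
"no bone here"), and the slices that survive detection are segmented
at full resolution.  Slices the detector rejects carry empty masks, so
segmentation output is causally gated by detection.  The three
compartment predictions combine into a whole-knee mask by voxelwise
union.  The ablation mode replaces the detection network with the
ground-truth presence vector, isolating the segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .metrics import ConfusionCounts, EvalReport, bone_volume, confusion_from_presence, pool_overlap
from .volumes import MaskSequence, MRISequence, crop_borders, normalize_intensity, resize

__all__ = [
    "SliceModel",
    "IntensityThresholdModel",
    "SlicePresence",
    "PipelineModels",
    "detect_bone_slices",
    "select_slices",
    "segment_slices",
    "combine_compartments",
    "run_full",
    "evaluate_pipeline",
]


class SliceModel(Protocol):
    """Anything that maps an NCHW batch to per-pixel probabilities."""

    def predict_proba(self, x: np.ndarray) -> np.ndarray: ...


class IntensityThresholdModel:
    """Analytic reference segmenter: probability = 1 where intensity > cut.

    On noise-free phantoms with the default intensities this recovers
    the ground truth exactly, which makes it the oracle for pipeline
    plumbing tests and a no-training baseline for the CLI.
    """

    def __init__(self, cut: float = 0.5):
        self.cut = float(cut)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) > self.cut).astype(np.float32)


@dataclass
class SlicePresence:
    """Per-slice bone/no-bone decisions with the first/last positive index."""

    flags: np.ndarray  # (n_slices,) bool

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ValueError("flags must be a 1D boolean vector")

    @property
    def first_index(self) -> int | None:
        pos = np.flatnonzero(self.flags)
        return int(pos[0]) if pos.size else None

    @property
    def last_index(self) -> int | None:
        pos = np.flatnonzero(self.flags)
        return int(pos[-1]) if pos.size else None


@dataclass
class PipelineModels:
    """The trained detection/segmentation networks for one pipeline run.

    ``segmenters`` maps compartment name (femur/tibia/patella or
    ``whole``) to its segmentation model; ``detectors`` likewise (a
    single ``whole`` detector may serve every compartment).  Detection
    runs at a coarse resolution, segmentation at full cropped
    resolution.
    """

    detectors: dict[str, SliceModel]
    segmenters: dict[str, SliceModel]
    detection_size: int = 128
    segmentation_size: int = 352

    @classmethod
    def from_estimators(cls, detectors: dict, segmenters: dict) -> "PipelineModels":
        """Build from fitted SliceDetector/BoneSegmenter estimators."""
        det_models = {c: est.model_ for c, est in detectors.items()}
        seg_models = {c: est.model_ for c, est in segmenters.items()}
        det_size = next(iter(detectors.values())).input_size
        seg_size = next(iter(segmenters.values())).input_size
        return cls(det_models, seg_models, detection_size=det_size, segmentation_size=seg_size)

    def detector_for(self, compartment: str) -> SliceModel:
        if compartment in self.detectors:
            return self.detectors[compartment]
        if "whole" in self.detectors:
            return self.detectors["whole"]
        raise KeyError(f"no detector for compartment {compartment!r}")


def detect_bone_slices(
    model: SliceModel,
    seq: MRISequence,
    prob_threshold: float = 0.5,
    min_area: int = 1,
    input_size: int | None = None,
    batch: int = 16,
) -> SlicePresence:
    """Classify every slice as bone/no-bone via the detection network.

    Slices are resized to the detection resolution; a slice is positive
    iff at least ``min_area`` output pixels reach ``prob_threshold``.
    """
    if not 0.0 < prob_threshold < 1.0:
        raise ValueError("prob_threshold must be in (0, 1)")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    size = input_size or getattr(getattr(model, "spec", None), "input_size", None)
    if size is None:
        raise ValueError("input_size not given and model has no spec.input_size")
    if seq.slices.shape[1] == size and seq.slices.shape[2] == size:
        small = seq.slices.astype(np.float32)
    else:
        small = np.stack([resize(sl, size, "intensity") for sl in seq.slices]).astype(np.float32)
    flags = np.zeros(len(seq), dtype=bool)
    for lo in range(0, len(seq), batch):
        p = model.predict_proba(small[lo : lo + batch, None])
        counts = (p >= prob_threshold).sum(axis=(1, 2, 3))
        flags[lo : lo + batch] = counts >= min_area
    return SlicePresence(flags=flags)


def select_slices(presence: SlicePresence, mode: str = "per_slice") -> set[int]:
    """Indices to segment: the positive slices, or the filled [first, last] range."""
    if mode == "per_slice":
        return {int(i) for i in np.flatnonzero(presence.flags)}
    if mode == "fill_range":
        if presence.first_index is None:
            return set()
        return set(range(presence.first_index, presence.last_index + 1))
    raise ValueError(f"unknown selection mode: {mode!r}")


def segment_slices(
    model: SliceModel,
    seq: MRISequence,
    indices,
    prob_threshold: float = 0.5,
    compartment: str = "whole",
    batch: int = 8,
) -> MaskSequence:
    """Segment the selected slices at full resolution.

    Unselected slices are emitted as all-zero masks (a discarded slice
    carries no bone).  The output stack always has the input's length.
    """
    indices = sorted(int(i) for i in indices)
    if indices and (indices[0] < 0 or indices[-1] >= len(seq)):
        raise IndexError(f"slice index out of range for sequence of {len(seq)}")
    out = np.zeros(seq.slices.shape, dtype=np.uint8)
    sel = np.asarray(indices, dtype=int)
    for lo in range(0, sel.size, batch):
        idx = sel[lo : lo + batch]
        p = model.predict_proba(seq.slices[idx][:, None].astype(np.float32))
        out[idx] = (p[:, 0] >= prob_threshold).astype(np.uint8)
    return MaskSequence(case_id=seq.case_id, compartment=compartment, slices=out)


def combine_compartments(
    masks: dict[str, MaskSequence],
    rule: str = "union",
    probs: dict[str, np.ndarray] | None = None,
    return_labels: bool = False,
):
    """Whole-knee mask as the voxelwise union of the compartment masks.

    With ``return_labels`` a label map is also produced (0 background,
    then 1-based compartment labels in the fixed order femur, tibia,
    patella); overlapping predictions resolve to the highest model
    probability when ``probs`` maps are supplied, else to the fixed
    order.
    """
    if rule != "union":
        raise ValueError(f"unknown combination rule: {rule!r}")
    order = [c for c in ("femur", "tibia", "patella") if c in masks]
    if not order:
        order = sorted(masks)
    shapes = {masks[c].slices.shape for c in order}
    if len(shapes) != 1:
        raise ValueError(f"misaligned compartment stacks: {shapes}")
    union = np.zeros(next(iter(shapes)), dtype=np.uint8)
    for c in order:
        union |= masks[c].slices
    whole = MaskSequence(case_id=masks[order[0]].case_id, compartment="whole", slices=union)
    if not return_labels:
        return whole
    labels = np.zeros(union.shape, dtype=np.uint8)
    best = np.zeros(union.shape, dtype=np.float32)
    for rank, c in enumerate(order, start=1):
        on = masks[c].slices.astype(bool)
        score = probs[c].astype(np.float32) if probs and c in probs else np.ones(union.shape, np.float32)
        take = on & ((labels == 0) | (score > best))
        labels[take] = rank
        best[take] = score[take]
    return whole, labels


def _preprocess(seq: MRISequence, segmentation_size: int, crop_margin: int = 16) -> MRISequence:
    """Crop raw-size input to the segmentation resolution, then normalize."""
    h = seq.slices.shape[1]
    if h == segmentation_size + 2 * crop_margin:
        seq = MRISequence(seq.case_id, crop_borders(seq.slices, crop_margin), seq.spacing)
    elif h != segmentation_size:
        raise ValueError(
            f"sequence height {h} is neither raw ({segmentation_size + 2 * crop_margin}) "
            f"nor cropped ({segmentation_size})"
        )
    return normalize_intensity(seq)


def run_full(
    models: PipelineModels,
    seq: MRISequence,
    prob_threshold: float = 0.5,
    min_area: int = 1,
    select_mode: str = "per_slice",
    crop_margin: int = 16,
) -> dict[str, MaskSequence]:
    """The fully automatic method on one raw or pre-cropped sequence.

    crop -> normalize -> detect -> select -> segment, per compartment;
    no human input anywhere.  Returns a mask per configured segmenter.
    """
    pre = _preprocess(seq, models.segmentation_size, crop_margin)
    out: dict[str, MaskSequence] = {}
    for comp, seg in models.segmenters.items():
        presence = detect_bone_slices(
            models.detector_for(comp), pre, prob_threshold, min_area, models.detection_size
        )
        chosen = select_slices(presence, select_mode)
        out[comp] = segment_slices(seg, pre, chosen, prob_threshold, compartment=comp)
    return out


def evaluate_pipeline(
    dataset,
    models: PipelineModels,
    detection_source: str = "automatic",
    prob_threshold: float = 0.5,
    min_area: int = 1,
    select_mode: str = "per_slice",
    crop_margin: int = 16,
) -> tuple[EvalReport, dict[str, ConfusionCounts] | None]:
    """Score the pipeline on (sequence, ground-truth masks) cases.

    ``detection_source="automatic"`` runs the full flow and also returns
    per-compartment slice-detection confusion counts;  ``"manual"``
    feeds the ground-truth presence vectors to the selection stage
    instead (the ablation), so results are independent of any detection
    model and the confusion counts are None.
    """
    if detection_source not in {"automatic", "manual"}:
        raise ValueError(f"unknown detection_source: {detection_source!r}")
    report = EvalReport()
    confusion: dict[str, ConfusionCounts] = {c: ConfusionCounts() for c in models.segmenters}
    for seq, gt_masks in dataset:
        pre = _preprocess(seq, models.segmentation_size, crop_margin)
        for comp, seg in models.segmenters.items():
            if comp not in gt_masks:
                raise ValueError(f"case {seq.case_id} lacks ground truth for {comp!r}")
            gt = gt_masks[comp]
            gt_pre = MaskSequence(
                case_id=gt.case_id,
                compartment=comp,
                slices=crop_borders(gt.slices, crop_margin)
                if gt.slices.shape[1] != pre.slices.shape[1]
                else gt.slices,
            )
            truth_presence = gt_pre.presence()
            if detection_source == "automatic":
                presence = detect_bone_slices(
                    models.detector_for(comp), pre, prob_threshold, min_area, models.detection_size
                )
                confusion[comp] = confusion[comp] + confusion_from_presence(presence.flags, truth_presence)
            else:
                presence = SlicePresence(flags=truth_presence)
            chosen = select_slices(presence, select_mode)
            pred = segment_slices(seg, pre, chosen, prob_threshold, compartment=comp)
            overlap = pool_overlap(gt_pre, pred)
            report.add_case(
                seq.case_id,
                comp,
                overlap,
                volume_gt=bone_volume(gt_pre, seq.spacing),
                volume_pred=bone_volume(pred, seq.spacing),
            )
    return report, (confusion if detection_source == "automatic" else None)
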