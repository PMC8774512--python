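"""Evaluation metrics for slice detection and 3D case-level segmentation.

Detection is scored per slice with the usual confusion-matrix rates
(a true negative is a slice where both the ground truth and the model
output are all-black).  Segmentation is scored at the case level: the
pixel sets of the ground truth (Sg) and the model (Sm) are pooled over
every slice of the scan, treating each compartment as one 3D object,
and the overlap ratios are

    DICE = 2|Sg n Sm| / (|Sg| + |Sm|)      SI  = |Sg n Sm| / |Sg u Sm|
    TPR  = |Sg n Sm| / |Sg|                FPR = (|Sg u Sm| - |Sg|) / |Sg|
    FNR  = 1 - TPR

Undefined ratios (zero denominators) return ``None`` rather than
raising; the empty-ground-truth/empty-prediction case scores DICE and
SI as 1 by convention (a perfect match of two empty sets) and is
flagged in reports.

Bone volume is positive-voxel count times voxel size; agreement between
manual and automatic volumes is summarized by an OLS fit and squared
Pearson correlation, and paired per-case scores are compared with a
two-tailed paired t-test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import MaskSequence

__all__ = [
    "ConfusionCounts",
    "OverlapCounts",
    "EvalReport",
    "confusion_from_presence",
    "recall",
    "precision",
    "accuracy",
    "pool_overlap",
    "dice",
    "similarity",
    "tpr",
    "fpr",
    "fnr",
    "bone_volume",
    "volume_agreement",
    "paired_t_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Slice-level detection tallies; tp+tn+fp+fn = slices evaluated."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class OverlapCounts:
    """Pixel-set sizes pooled over every slice of one case."""

    n_g: int  # |Sg|
    n_m: int  # |Sm|
    n_inter: int  # |Sg n Sm|

    def __post_init__(self):
        if min(self.n_g, self.n_m, self.n_inter) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_inter > min(self.n_g, self.n_m):
            raise ValueError("intersection cannot exceed either set")

    @property
    def n_union(self) -> int:
        return self.n_g + self.n_m - self.n_inter

    @property
    def empty_empty(self) -> bool:
        return self.n_g == 0 and self.n_m == 0


def confusion_from_presence(pred, truth) -> ConfusionCounts:
    """Tally per-slice detection decisions against ground-truth presence."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def recall(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when no positive slices exist."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def precision(c: ConfusionCounts) -> float | None:
    """TP / (TP + FP); None when nothing was predicted positive."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def accuracy(c: ConfusionCounts) -> float | None:
    """Percentage of correctly classified slices."""
    return 100.0 * (c.tp + c.tn) / c.total if c.total else None


def pool_overlap(gt: MaskSequence, pred: MaskSequence) -> OverlapCounts:
    """Pool ground-truth and predicted pixel sets over the whole sequence."""
    if gt.slices.shape != pred.slices.shape:
        raise ValueError(f"misaligned stacks: {gt.slices.shape} vs {pred.slices.shape}")
    g = gt.slices.astype(bool)
    m = pred.slices.astype(bool)
    return OverlapCounts(n_g=int(g.sum()), n_m=int(m.sum()), n_inter=int((g & m).sum()))


def dice(o: OverlapCounts) -> float:
    if o.empty_empty:
        return 1.0
    return 2.0 * o.n_inter / (o.n_g + o.n_m)


def similarity(o: OverlapCounts) -> float:
    """Jaccard index; relates to DICE by D = 2J / (1 + J)."""
    if o.empty_empty:
        return 1.0
    return o.n_inter / o.n_union


def tpr(o: OverlapCounts) -> float | None:
    return o.n_inter / o.n_g if o.n_g else None


def fpr(o: OverlapCounts) -> float | None:
    return (o.n_union - o.n_g) / o.n_g if o.n_g else None


def fnr(o: OverlapCounts) -> float | None:
    t = tpr(o)
    return None if t is None else 1.0 - t


def bone_volume(mask: MaskSequence, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Positive-voxel count times voxel volume, in mm^3."""
    if min(spacing) <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return float(mask.slices.sum(dtype=np.int64)) * spacing[0] * spacing[1] * spacing[2]


def volume_agreement(gt_volumes, pred_volumes) -> tuple[float, float, float] | None:
    """OLS of predicted on ground-truth volumes: (slope, intercept, R^2).

    R^2 is the squared Pearson correlation.  Returns None when the
    ground-truth volumes have no variance.
    """
    x = np.asarray(gt_volumes, dtype=float)
    y = np.asarray(pred_volumes, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0:
        return None
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def paired_t_test(a, b) -> tuple[float, float] | None:
    """Two-tailed paired t-test on per-case score differences.

    Returns (t, p) with n-1 degrees of freedom, or None when the
    differences have zero variance (the test is degenerate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    d = a - b
    # zero variance up to float rounding of the inputs
    if np.std(d) <= 1e-12 * max(1.0, float(np.abs(d).max(initial=0.0))):
        return None
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


class EvalReport:
    """Per-case, per-compartment segmentation scores with aggregate means.

    Ratios are stored unrounded; display rounding (percentages to two
    decimals, ratios to three) happens only at serialization time.
    """

    COLUMNS = [
        "case_id",
        "compartment",
        "tpr",
        "fpr",
        "fnr",
        "si",
        "dice",
        "volume_gt_mm3",
        "volume_pred_mm3",
        "empty_empty",
    ]

    def __init__(self):
        self._rows: list[dict] = []

    def add_case(
        self,
        case_id: str,
        compartment: str,
        overlap: OverlapCounts,
        volume_gt: float,
        volume_pred: float,
    ) -> None:
        self._rows.append(
            {
                "case_id": case_id,
                "compartment": compartment,
                "tpr": tpr(overlap),
                "fpr": fpr(overlap),
                "fnr": fnr(overlap),
                "si": similarity(overlap),
                "dice": dice(overlap),
                "volume_gt_mm3": volume_gt,
                "volume_pred_mm3": volume_pred,
                "empty_empty": overlap.empty_empty,
            }
        )

    @property
    def per_case(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self.COLUMNS)

    def aggregate(self) -> pd.DataFrame:
        """Unweighted mean of per-case scores, one row per compartment."""
        df = self.per_case
        return df.groupby("compartment", sort=False)[["tpr", "fpr", "fnr", "si", "dice"]].mean()

    def scores(self, compartment: str, metric: str = "dice") -> np.ndarray:
        df = self.per_case
        return df.loc[df["compartment"] == compartment, metric].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)

    def summary_json(self, path=None) -> str:
        agg = self.aggregate()
        payload = {
            comp: {
                "tpr_pct": round(100 * row["tpr"], 2),
                "fpr_pct": round(100 * row["fpr"], 2),
                "fnr_pct": round(100 * row["fnr"], 2),
                "si_pct": round(100 * row["si"], 2),
                "dice_pct": round(100 * row["dice"], 2),
            }
            for comp, row in agg.iterrows()
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text
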