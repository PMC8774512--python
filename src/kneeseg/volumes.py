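"""Slice-stack containers, format I/O and the preprocessing steps.

A knee MRI scan is an ordered stack of 2D slices (one ``MRISequence``
per case); its manual segmentation is a ``MaskSequence`` per bone
compartment (femur, tibia, patella, or their union ``whole``).
Supported on-disk forms: a DICOM series directory (read-only), NIfTI,
a directory of numbered PNGs, and a single NPZ bundle.

Preprocessing mirrors the pipeline's data preparation: per-case min-max
intensity normalization, a fixed border crop (the manual labels do not
reach the image edge, so 16 px are removed from every side, taking
384x384 to 352x352), bilinear/nearest resizing, and a case-level
train/validation/test split so that all slices of a scan stay together.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "MRISequence",
    "MaskSequence",
    "CaseSplit",
    "FormatError",
    "COMPARTMENTS",
    "read_sequence",
    "write_sequence",
    "read_masks",
    "write_masks",
    "normalize_intensity",
    "crop_borders",
    "resize",
    "split_cases",
]

COMPARTMENTS = ("femur", "tibia", "patella", "whole")


class FormatError(ValueError):
    """A file or directory does not match the declared format."""


@dataclass
class MRISequence:
    """One case: ordered 2D intensity slices plus voxel spacing in mm."""

    case_id: str
    slices: np.ndarray  # (n_slices, height, width) float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError(f"slices must be a non-empty (n, h, w) stack, got {self.slices.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    def __len__(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.slices.shape


@dataclass
class MaskSequence:
    """Binary mask stack for one compartment, aligned to its MRISequence."""

    case_id: str
    compartment: str
    slices: np.ndarray  # (n_slices, height, width) in {0, 1}

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError(f"slices must be a non-empty (n, h, w) stack, got {self.slices.shape}")
        vals = np.unique(self.slices)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be binary {0, 1}")
        self.slices = self.slices.astype(np.uint8)

    def __len__(self) -> int:
        return self.slices.shape[0]

    def presence(self) -> np.ndarray:
        """Per-slice boolean: does the compartment appear in that slice?"""
        return self.slices.any(axis=(1, 2))


@dataclass
class CaseSplit:
    train_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split groups must be pairwise disjoint")


# ---------------------------------------------------------------------------
# readers / writers

_PNG_NUM = re.compile(r"(\d+)")


def _png_sort_key(p: Path):
    m = _PNG_NUM.findall(p.stem)
    if not m:
        raise FormatError(f"PNG stack file {p} has no numeric index in its name")
    return int(m[-1])


def read_sequence(path, format: str) -> MRISequence:
    """Read one case from disk.

    ``format`` is one of ``dicom_dir``, ``nifti``, ``png_stack``, ``npz``.
    Slices are ordered by DICOM InstanceNumber or by the numeric part of
    the filename; spacing comes from metadata where available, else 1 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if format == "npz":
        with np.load(path, allow_pickle=False) as data:
            return MRISequence(
                case_id=str(data["case_id"]) if "case_id" in data else path.stem,
                slices=data["slices"],
                spacing=tuple(float(v) for v in data["spacing"]) if "spacing" in data else (1.0, 1.0, 1.0),
            )
    if format == "png_stack":
        files = sorted(path.glob("*.png"), key=_png_sort_key)
        if not files:
            raise FormatError(f"no PNG files under {path}")
        slices = []
        shape = None
        for f in files:
            img = np.asarray(iio.imread(f), dtype=np.float64)
            if img.ndim == 3:  # collapse any grayscale-as-RGB
                img = img[..., 0]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(f"slice shape mismatch in {f}: {img.shape} != {shape}")
            slices.append(img / 65535.0 if img.max() > 255 else img / 255.0)
        return MRISequence(case_id=path.name, slices=np.stack(slices))
    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise FormatError(f"expected a 3D NIfTI volume, got shape {arr.shape}")
        zooms = img.header.get_zooms()[:3]
        # stored (row, col, slice); stack slice-major
        slices = np.transpose(arr, (2, 0, 1)).astype(np.float64)
        case_id = path.name.removesuffix(".gz").removesuffix(".nii")
        return MRISequence(case_id=case_id, slices=slices, spacing=(float(zooms[0]), float(zooms[1]), float(zooms[2])))
    if format == "dicom_dir":
        import pydicom

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima", ""} and p.is_file())
        if not files:
            raise FormatError(f"no DICOM files under {path}")
        ordered = []
        for f in files:
            try:
                ds = pydicom.dcmread(str(f))
            except Exception as exc:  # noqa: BLE001 - name the offending file
                raise FormatError(f"unreadable DICOM file {f}: {exc}") from exc
            if not hasattr(ds, "InstanceNumber"):
                raise FormatError(f"DICOM file {f} lacks InstanceNumber ordering metadata")
            ordered.append((int(ds.InstanceNumber), ds.pixel_array.astype(np.float64), ds))
        ordered.sort(key=lambda t: t[0])
        shapes = {arr.shape for _, arr, _ in ordered}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent slice shapes in {path}: {shapes}")
        ds0 = ordered[0][2]
        px = getattr(ds0, "PixelSpacing", [1.0, 1.0])
        dz = float(getattr(ds0, "SpacingBetweenSlices", getattr(ds0, "SliceThickness", 1.0)))
        return MRISequence(
            case_id=path.name,
            slices=np.stack([arr for _, arr, _ in ordered]),
            spacing=(float(px[0]), float(px[1]), dz),
        )
    raise FormatError(f"unsupported format token: {format!r}")


def write_sequence(seq: MRISequence, path, format: str) -> None:
    """Write intensities to disk; npz and nifti round-trip losslessly."""
    path = Path(path)
    if format == "npz":
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, slices=seq.slices, spacing=np.asarray(seq.spacing), case_id=seq.case_id)
        return
    if format == "png_stack":
        path.mkdir(parents=True, exist_ok=True)
        lo, hi = float(seq.slices.min()), float(seq.slices.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        for i, sl in enumerate(seq.slices):
            arr = ((sl - lo) * scale).round().astype(np.uint16)
            iio.imwrite(path / f"slice_{i:04d}.png", arr)
        return
    if format == "nifti":
        import nibabel as nib

        path.parent.mkdir(parents=True, exist_ok=True)
        affine = np.diag([seq.spacing[0], seq.spacing[1], seq.spacing[2], 1.0])
        nib.save(nib.Nifti1Image(np.transpose(seq.slices, (1, 2, 0)), affine), str(path))
        return
    raise FormatError(f"unsupported format token: {format!r}")


def write_masks(mask: MaskSequence, path, format: str) -> None:
    """Write a binary mask stack (PNG stacks store 0/255, re-binarized on read)."""
    path = Path(path)
    if format == "npz":
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path, slices=mask.slices, case_id=mask.case_id, compartment=mask.compartment
        )
        return
    if format == "png_stack":
        path.mkdir(parents=True, exist_ok=True)
        for i, sl in enumerate(mask.slices):
            iio.imwrite(path / f"slice_{i:04d}.png", (sl * 255).astype(np.uint8))
        return
    if format == "nifti":
        import nibabel as nib

        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(np.transpose(mask.slices, (1, 2, 0)).astype(np.uint8), np.eye(4)), str(path))
        return
    raise FormatError(f"unsupported format token: {format!r}")


def read_masks(path, format: str, compartment: str | None = None) -> MaskSequence:
    path = Path(path)
    if format == "npz":
        with np.load(path, allow_pickle=False) as data:
            return MaskSequence(
                case_id=str(data["case_id"]) if "case_id" in data else path.stem,
                compartment=str(data["compartment"]) if "compartment" in data else (compartment or "whole"),
                slices=data["slices"],
            )
    if format in {"png_stack", "nifti"}:
        seq = read_sequence(path, format)
        return MaskSequence(
            case_id=seq.case_id,
            compartment=compartment or "whole",
            slices=(seq.slices > 0.5).astype(np.uint8),
        )
    raise FormatError(f"unsupported format token: {format!r}")


# ---------------------------------------------------------------------------
# preprocessing

def normalize_intensity(seq: MRISequence) -> MRISequence:
    """Per-case min-max scaling to [0, 1]; a constant case maps to zeros."""
    lo, hi = float(seq.slices.min()), float(seq.slices.max())
    if hi > lo:
        scaled = (seq.slices - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(seq.slices, dtype=np.float64)
    return MRISequence(case_id=seq.case_id, slices=scaled, spacing=seq.spacing)


def crop_borders(grid: np.ndarray, margin: int) -> np.ndarray:
    """Remove ``margin`` pixels from every side of a 2D grid (or of every
    slice of a 3D stack)."""
    grid = np.asarray(grid)
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin == 0:
        return grid
    h, w = grid.shape[-2:]
    if 2 * margin >= min(h, w):
        raise ValueError(f"margin {margin} too large for grid of size {h}x{w}")
    return grid[..., margin : h - margin, margin : w - margin]


def resize(grid: np.ndarray, size: int, kind: str = "intensity") -> np.ndarray:
    """Resize a 2D grid to size x size.

    Intensities are bilinearly interpolated; masks use nearest-neighbor
    and are re-binarized at 0.5 so the output stays in {0, 1}.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    grid = np.asarray(grid)
    if kind == "intensity":
        return _sk_resize(grid.astype(np.float64), (size, size), order=1, anti_aliasing=False, preserve_range=True)
    if kind == "mask":
        out = _sk_resize(grid.astype(np.float64), (size, size), order=0, anti_aliasing=False, preserve_range=True)
        return (out >= 0.5).astype(np.uint8)
    raise ValueError(f"unknown resize kind: {kind!r}")


def split_cases(case_ids, fractions: tuple[float, float, float], seed: int) -> CaseSplit:
    """Case-level random split.

    Validation and test sizes are round-half-up of n*fraction; training
    takes the remainder, which reproduces 99 -> 69/15/15 at
    (0.70, 0.15, 0.15).  All slices of a case travel together because
    only the case ids are partitioned.
    """
    ids = list(case_ids)
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0:
        raise ValueError("all fractions must be positive")
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 cases to form three non-empty groups, got {n}")
    n_val = int(np.floor(n * f_val + 0.5))
    n_test = int(np.floor(n * f_test + 0.5))
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    val = order[:n_val]
    test = order[n_val : n_val + n_test]
    train = order[n_val + n_test :]
    return CaseSplit(train_ids=train, val_ids=val, test_ids=test)
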