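"""Synthetic knee-like MRI phantoms with exact ground truth.

Each phantom case mimics the statistical structure the two-stage
pipeline relies on, without any MRI physics: every bone compartment
appears on one contiguous slice interval of the stack (in a real DESS
scan the femur may run from roughly slice 22 to 134 of 160, the tibia
30-136, the patella 50-115, with case-to-case variation), is brighter
than the background, and occupies a compartment-specific region of the
image so that the three masks are disjoint and the whole-knee mask is
their union.

Per slice a compartment is a filled ellipse whose center drifts
smoothly along the stack and whose radii taper toward the ends of the
interval, so bones appear, grow, shrink and vanish the way a 3D body
does in cross-section.  Corruption is additive Gaussian noise clipped
to [0, 1]; with the default intensities (bone 0.9, background 0.2,
noise sd 0.05) a mid-intensity threshold separates bone from background
essentially perfectly, which gives the whole pipeline an analytic
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volumes import MRISequence, MaskSequence, write_masks, write_sequence

__all__ = ["CompartmentSpec", "PhantomConfig", "generate_case", "generate_dataset", "load_dataset"]

# reference anatomy: slice intervals quoted for a 160-slice scan; regions as
# (row_lo, row_hi, col_lo, col_hi) fractions of the image, pairwise disjoint
_REFERENCE_SLICES = 160
_DEFAULT_COMPARTMENTS = {
    "femur": dict(start=(18, 26), end=(130, 138), region=(0.08, 0.46, 0.28, 0.92)),
    "tibia": dict(start=(26, 34), end=(132, 140), region=(0.54, 0.92, 0.28, 0.92)),
    "patella": dict(start=(46, 54), end=(111, 119), region=(0.30, 0.70, 0.02, 0.24)),
}


@dataclass(frozen=True)
class CompartmentSpec:
    """Slice-interval ranges and geometry for one bone compartment."""

    start_range: tuple[int, int]  # inclusive range the start slice is drawn from
    end_range: tuple[int, int]  # inclusive range the end slice is drawn from
    region: tuple[float, float, float, float]  # (row_lo, row_hi, col_lo, col_hi) fractions
    peak_radius_frac: float = 0.75  # peak semi-axes as fraction of region half-extents
    drift_frac: float = 0.15  # center drift amplitude as fraction of region extent


@dataclass(frozen=True)
class PhantomConfig:
    n_cases: int
    n_slices: int = 160
    image_size: int = 384
    compartments: dict[str, CompartmentSpec] = field(default_factory=dict)
    noise_sd: float = 0.05
    bone_intensity: float = 0.9
    background_intensity: float = 0.2
    seed: int = 0
    allow_low_contrast: bool = False

    @classmethod
    def default(cls, n_cases: int, n_slices: int = 160, image_size: int = 384, **kwargs) -> "PhantomConfig":
        """Default three-compartment anatomy, slice ranges scaled to n_slices."""
        scale = n_slices / _REFERENCE_SLICES
        comps = {}
        for name, d in _DEFAULT_COMPARTMENTS.items():
            comps[name] = CompartmentSpec(
                start_range=(int(round(d["start"][0] * scale)), int(round(d["start"][1] * scale))),
                end_range=(int(round(d["end"][0] * scale)), int(round(d["end"][1] * scale))),
                region=d["region"],
            )
        return cls(n_cases=n_cases, n_slices=n_slices, image_size=image_size, compartments=comps, **kwargs)

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_slices < 1 or self.image_size < 8:
            raise ValueError("n_cases must be >= 0, n_slices >= 1, image_size >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.compartments:
            raise ValueError("at least one compartment must be configured")
        for name, c in self.compartments.items():
            if not (0 <= c.start_range[0] <= c.start_range[1]):
                raise ValueError(f"{name}: bad start_range {c.start_range}")
            if not (c.end_range[0] <= c.end_range[1] < self.n_slices):
                raise ValueError(f"{name}: bad end_range {c.end_range} for {self.n_slices} slices")
            if c.start_range[1] >= c.end_range[0]:
                raise ValueError(f"{name}: start range {c.start_range} must lie before end range {c.end_range}")
        contrast = self.bone_intensity - self.background_intensity
        if contrast <= 3 * self.noise_sd and not self.allow_low_contrast:
            raise ValueError(
                f"bone/background contrast {contrast:.3f} <= 3*noise_sd {3 * self.noise_sd:.3f}; "
                "set allow_low_contrast=True to override the separability guarantee"
            )


def _ellipse_mask(size: int, cr: float, cc: float, rr: float, rc: float) -> np.ndarray:
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    return (((rows - cr) / rr) ** 2 + ((cols - cc) / rc) ** 2) <= 1.0


def _compartment_stack(config: PhantomConfig, comp: CompartmentSpec, rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
    size = config.image_size
    n = config.n_slices
    start = int(rng.integers(comp.start_range[0], comp.start_range[1] + 1))
    end = int(rng.integers(comp.end_range[0], comp.end_range[1] + 1))

    r0, r1, c0, c1 = (f * size for f in comp.region)
    half_h, half_w = (r1 - r0) / 2.0, (c1 - c0) / 2.0
    center_r, center_c = (r0 + r1) / 2.0, (c0 + c1) / 2.0

    # smooth per-case center drift inside the region
    phase_r, phase_c = rng.uniform(0, 2 * np.pi, size=2)
    amp_r = comp.drift_frac * half_h
    amp_c = comp.drift_frac * half_w
    # peak semi-axes leave room for the drift so the ellipse stays in-region
    peak_rr = comp.peak_radius_frac * (half_h - amp_r)
    peak_rc = comp.peak_radius_frac * (half_w - amp_c)
    r_min = max(1.5, 0.03 * size)  # keeps every in-interval slice non-empty

    stack = np.zeros((n, size, size), dtype=np.uint8)
    mid = (start + end) / 2.0
    half_span = max((end - start) / 2.0, 0.5)
    for s in range(start, end + 1):
        u = (s - mid) / half_span
        taper = np.sqrt(max(0.0, 1.0 - u * u))
        rr = max(r_min, peak_rr * taper)
        rc = max(r_min, peak_rc * taper)
        phi = 2 * np.pi * s / n
        cr = center_r + amp_r * np.sin(phi + phase_r)
        cc = center_c + amp_c * np.sin(phi + phase_c)
        stack[s] = _ellipse_mask(size, cr, cc, rr, rc)
    return stack, start, end


def generate_case(config: PhantomConfig, case_index: int) -> tuple[MRISequence, dict[str, MaskSequence]]:
    """Generate one phantom case, deterministic given (config.seed, case_index).

    Returns the intensity sequence and a mask per compartment plus the
    ``whole`` union mask.  Each compartment is non-empty exactly on its
    drawn contiguous [start, end] slice interval.
    """
    config.validate()
    if not 0 <= case_index < max(config.n_cases, 1):
        raise ValueError(f"case_index {case_index} out of range for {config.n_cases} cases")
    rng = np.random.default_rng(config.seed + case_index)
    case_id = f"case_{case_index:03d}"

    masks: dict[str, MaskSequence] = {}
    union = np.zeros((config.n_slices, config.image_size, config.image_size), dtype=np.uint8)
    for name, comp in config.compartments.items():
        stack, _, _ = _compartment_stack(config, comp, rng)
        masks[name] = MaskSequence(case_id=case_id, compartment=name, slices=stack)
        union |= stack
    masks["whole"] = MaskSequence(case_id=case_id, compartment="whole", slices=union)

    img = np.full(union.shape, config.background_intensity, dtype=np.float64)
    img[union.astype(bool)] = config.bone_intensity
    if config.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, config.noise_sd, size=img.shape), 0.0, 1.0)
    return MRISequence(case_id=case_id, slices=img), masks


def generate_dataset(
    config: PhantomConfig,
    out_dir=None,
    format: str = "npz",
) -> list[tuple[MRISequence, dict[str, MaskSequence]]]:
    """Generate all cases; optionally write them plus a plain-text manifest.

    On disk each case gets its own directory with ``image`` and
    ``mask_<compartment>`` entries in the requested format; the manifest
    lists one line per case: id, slice count, and each compartment's
    0-based start-end slice interval.
    """
    config.validate()
    cases = [generate_case(config, i) for i in range(config.n_cases)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lines = []
        ext = ".npz" if format == "npz" else (".nii.gz" if format == "nifti" else "")
        for seq, masks in cases:
            case_dir = out_dir / seq.case_id
            case_dir.mkdir(exist_ok=True)
            write_sequence(seq, case_dir / f"image{ext}", format)
            spans = []
            for name, mask in masks.items():
                write_masks(mask, case_dir / f"mask_{name}{ext}", format)
                present = np.flatnonzero(mask.presence())
                spans.append(f"{name}:{present[0]}-{present[-1]}" if present.size else f"{name}:-")
            lines.append(f"{seq.case_id} {len(seq)} " + " ".join(spans))
        (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
    return cases


def load_dataset(out_dir, format: str = "npz") -> list[tuple[MRISequence, dict[str, MaskSequence]]]:
    """Read back a dataset written by :func:`generate_dataset`."""
    from .volumes import read_masks, read_sequence

    out_dir = Path(out_dir)
    manifest = out_dir / "manifest.txt"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.txt under {out_dir}")
    ext = ".npz" if format == "npz" else (".nii.gz" if format == "nifti" else "")
    cases = []
    for line in manifest.read_text().splitlines():
        if not line.strip():
            continue
        case_id = line.split()[0]
        comp_names = [tok.split(":")[0] for tok in line.split()[2:]]
        case_dir = out_dir / case_id
        seq = read_sequence(case_dir / f"image{ext}", format)
        masks = {
            name: read_masks(case_dir / f"mask_{name}{ext}", format, compartment=name)
            for name in comp_names
        }
        cases.append((seq, masks))
    return cases
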