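"""I/O round-trips, preprocessing arithmetic and the case-level split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneeseg.volumes import (
    FormatError,
    MaskSequence,
    MRISequence,
    crop_borders,
    normalize_intensity,
    read_masks,
    read_sequence,
    resize,
    split_cases,
    write_masks,
    write_sequence,
)


# -- containers ---------------------------------------------------------------

def test_mask_rejects_nonbinary_values():
    with pytest.raises(ValueError):
        MaskSequence("c", "femur", np.full((2, 4, 4), 2))


def test_sequence_rejects_bad_spacing_and_shape():
    with pytest.raises(ValueError):
        MRISequence("c", np.zeros((2, 4, 4)), spacing=(1, 0, 1))
    with pytest.raises(ValueError):
        MRISequence("c", np.zeros((4, 4)))


# -- preprocessing ------------------------------------------------------------

def test_crop_384_to_352():
    grid = np.arange(384 * 384, dtype=float).reshape(384, 384)
    out = crop_borders(grid, 16)
    assert out.shape == (352, 352)
    assert np.array_equal(out, grid[16:368, 16:368])


def test_crop_margin_zero_identity_and_too_large():
    grid = np.ones((10, 10))
    assert crop_borders(grid, 0) is grid
    with pytest.raises(ValueError):
        crop_borders(grid, 5)


def test_crop_composes_additively(rng):
    grid = rng.random((40, 40))
    ab = crop_borders(crop_borders(grid, 3), 4)
    assert np.array_equal(ab, crop_borders(grid, 7))


def test_normalize_scales_to_unit_range():
    seq = MRISequence("c", np.linspace(0, 4095, 2 * 8 * 8).reshape(2, 8, 8))
    out = normalize_intensity(seq)
    assert out.slices.min() == 0.0 and out.slices.max() == 1.0
    # idempotent on normalized input
    again = normalize_intensity(out)
    assert np.allclose(again.slices, out.slices)


def test_normalize_constant_case_maps_to_zero():
    out = normalize_intensity(MRISequence("c", np.full((2, 4, 4), 7.0)))
    assert np.all(out.slices == 0.0)


def test_resize_mask_stays_binary():
    mask = np.zeros((352, 352))
    mask[100:250, 80:300] = 1
    out = resize(mask, 128, "mask")
    assert out.shape == (128, 128)
    assert set(np.unique(out)) <= {0, 1}
    assert out.sum() > 0


def test_resize_constant_field_is_constant():
    assert np.allclose(resize(np.ones((40, 40)), 17, "intensity"), 1.0)
    assert np.all(resize(np.ones((40, 40)), 17, "mask") == 1)


def test_resize_same_size_mask_identity(rng):
    mask = (rng.random((32, 32)) > 0.5).astype(np.uint8)
    assert np.array_equal(resize(mask, 32, "mask"), mask)


# -- split --------------------------------------------------------------------

def test_split_99_cases_gives_69_15_15():
    ids = [f"case_{i:03d}" for i in range(99)]
    split = split_cases(ids, (0.70, 0.15, 0.15), seed=0)
    assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (69, 15, 15)
    # with 160 slices per case this is the 11040/2400/2400 slice budget
    assert len(split.train_ids) * 160 == 11040


def test_split_10_cases_rounding():
    split = split_cases([str(i) for i in range(10)], (0.70, 0.15, 0.15), seed=1)
    assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (6, 2, 2)


@settings(deadline=None, max_examples=30)
@given(n=st.integers(3, 200), seed=st.integers(0, 2**31 - 1))
def test_split_partitions_input(n, seed):
    ids = [f"c{i}" for i in range(n)]
    split = split_cases(ids, (0.70, 0.15, 0.15), seed=seed)
    groups = [set(split.train_ids), set(split.val_ids), set(split.test_ids)]
    assert sum(len(g) for g in groups) == n
    assert groups[0] | groups[1] | groups[2] == set(ids)


def test_split_rejects_bad_fractions_and_tiny_sets():
    with pytest.raises(ValueError):
        split_cases(["a", "b", "c"], (0.5, 0.2, 0.2), seed=0)
    with pytest.raises(ValueError):
        split_cases(["a", "b"], (0.70, 0.15, 0.15), seed=0)


def test_split_deterministic_given_seed():
    ids = [f"c{i}" for i in range(30)]
    assert split_cases(ids, (0.7, 0.15, 0.15), 7).train_ids == split_cases(ids, (0.7, 0.15, 0.15), 7).train_ids


# -- I/O round-trips ----------------------------------------------------------

def test_npz_sequence_roundtrip_bit_identical(tmp_path, rng):
    seq = MRISequence("caseX", rng.random((5, 16, 16)), spacing=(0.5, 0.5, 1.5))
    write_sequence(seq, tmp_path / "x.npz", "npz")
    back = read_sequence(tmp_path / "x.npz", "npz")
    assert back.case_id == "caseX"
    assert np.array_equal(back.slices, seq.slices)
    assert back.spacing == seq.spacing


@pytest.mark.parametrize("fmt", ["npz", "png_stack", "nifti"])
def test_mask_roundtrip_identity(tmp_path, rng, fmt):
    mask = MaskSequence("c", "tibia", (rng.random((4, 12, 12)) > 0.6).astype(np.uint8))
    ext = {"npz": "m.npz", "png_stack": "m_dir", "nifti": "m.nii.gz"}[fmt]
    write_masks(mask, tmp_path / ext, fmt)
    back = read_masks(tmp_path / ext, fmt, compartment="tibia")
    assert np.array_equal(back.slices, mask.slices)


def test_png_stack_reads_160_slices_in_order(tmp_path):
    seq = MRISequence("c", np.stack([np.full((8, 8), i / 160) for i in range(160)]))
    write_sequence(seq, tmp_path / "stack", "png_stack")
    back = read_sequence(tmp_path / "stack", "png_stack")
    assert len(back) == 160
    means = back.slices.mean(axis=(1, 2))
    assert np.all(np.diff(means) >= 0), "slices must come back in index order"


def test_nifti_roundtrip_and_spacing(tmp_path, rng):
    seq = MRISequence("c", rng.random((6, 10, 10)), spacing=(0.7, 0.7, 1.4))
    write_sequence(seq, tmp_path / "v.nii.gz", "nifti")
    back = read_sequence(tmp_path / "v.nii.gz", "nifti")
    assert np.allclose(back.slices, seq.slices)
    assert np.allclose(back.spacing, seq.spacing)


def test_dicom_series_read_orders_by_instance_number(tmp_path, rng):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    order = [3, 1, 2]  # written out of order on purpose
    for inst in order:
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = inst
        ds.PixelSpacing = [0.4, 0.4]
        ds.SliceThickness = 0.7
        ds.Rows = ds.Columns = 8
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.full((8, 8), 100 * inst, np.uint16).tobytes()
        ds.save_as(tmp_path / f"slice_{inst}.dcm", enforce_file_format=True)
    seq = read_sequence(tmp_path, "dicom_dir")
    assert len(seq) == 3
    assert [int(s[0, 0]) for s in seq.slices] == [100, 200, 300]
    assert seq.spacing == (0.4, 0.4, 0.7)


def test_shape_mismatch_in_png_stack_names_offender(tmp_path):
    import imageio.v3 as iio

    d = tmp_path / "stack"
    d.mkdir()
    iio.imwrite(d / "slice_0000.png", np.zeros((8, 8), np.uint8))
    iio.imwrite(d / "slice_0001.png", np.zeros((6, 6), np.uint8))
    with pytest.raises(FormatError, match="slice_0001"):
        read_sequence(d, "png_stack")


def test_unsupported_format_token(tmp_path):
    with pytest.raises(FormatError):
        write_sequence(MRISequence("c", np.zeros((1, 4, 4))), tmp_path / "x", "tiff")
    with pytest.raises(FormatError):
        read_sequence(tmp_path, "bogus")


def test_missing_path_is_format_error(tmp_path):
    with pytest.raises(FormatError):
        read_sequence(tmp_path / "nope.npz", "npz")
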