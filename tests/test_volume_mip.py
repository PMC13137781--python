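"""Volume IO, bone segmentation, orientation and projection."""

import numpy as np
import pydicom
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ctoam.synthetic_patella import generate_patella_volume
from ctoam.volume_mip import (BoneMask, CtVolume, DensityWindow, FormatError,
                              MipImage, OrientationError, SegmentationError,
                              compute_mip, mirror_ml, read_dicom_series,
                              read_nifti, render_grayscale,
                              restore_anatomical_orientation, segment_bone,
                              standardize_orientation, write_dicom_series,
                              write_nifti)


def _toy_volume(voxels, side="right", status="non-operated"):
    return CtVolume(np.asarray(voxels, float), (1.0, 1.0, 1.0), "T", side, status)


# ---------------------------------------------------------------------------
# readers / writers


def test_nifti_round_trip(tmp_path, noise_free_config):
    vol = generate_patella_volume(noise_free_config, "right", "non-operated", 0)
    path = tmp_path / "p.nii.gz"
    write_nifti(vol, path)
    back = read_nifti(path, side="right")
    np.testing.assert_array_equal(back.voxels, vol.voxels)
    assert back.spacing_mm == pytest.approx(vol.spacing_mm)


def test_nifti_missing_file_and_4d(tmp_path):
    import nibabel as nib

    with pytest.raises(Exception):
        read_nifti(tmp_path / "nope.nii.gz")
    nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4)),
             str(tmp_path / "fourd.nii.gz"))
    with pytest.raises(FormatError):
        read_nifti(tmp_path / "fourd.nii.gz")


def test_nifti_preserves_anisotropic_spacing(tmp_path):
    vol = CtVolume(np.full((8, 8, 8), 300.0), (0.7, 0.4, 0.3), "T", "right",
                   "non-operated")
    write_nifti(vol, tmp_path / "a.nii.gz")
    back = read_nifti(tmp_path / "a.nii.gz")
    assert back.spacing_mm == pytest.approx((0.7, 0.4, 0.3))


def test_dicom_round_trip(tmp_path, noise_free_config):
    vol = generate_patella_volume(noise_free_config, "left", "operated", 1)
    write_dicom_series(vol, tmp_path / "series")
    back = read_dicom_series(tmp_path / "series", side="left", status="operated")
    np.testing.assert_array_equal(back.voxels, vol.voxels)
    assert back.spacing_mm == pytest.approx(vol.spacing_mm)


def _minimal_slice(tmp_path, name, *, slope, intercept, stored, series_uid, z):
    ds = pydicom.Dataset()
    ds.SOPClassUID = pydicom.uid.CTImageStorage
    ds.SOPInstanceUID = pydicom.uid.generate_uid()
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = "1.2.3"
    ds.Modality = "CT"
    ds.InstanceNumber = z + 1
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.PixelSpacing = [1.0, 1.0]
    ds.SliceThickness = 1.0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    arr = np.full((2, 2), stored, dtype=np.uint16)
    ds.Rows, ds.Columns = arr.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = arr.tobytes()
    ds.file_meta = pydicom.dataset.FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = ds.SOPClassUID
    ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    ds.save_as(str(tmp_path / name), enforce_file_format=True)


def test_dicom_rescale_applied(tmp_path):
    """Stored 612 with slope 2 and intercept -1024 converts to 200 HU."""
    uid = pydicom.uid.generate_uid()
    _minimal_slice(tmp_path, "s0.dcm", slope=2, intercept=-1024, stored=612,
                   series_uid=uid, z=0)
    vol = read_dicom_series(tmp_path)
    assert np.all(vol.voxels == 200.0)


def test_dicom_mixed_series_rejected(tmp_path):
    _minimal_slice(tmp_path, "a.dcm", slope=1, intercept=0, stored=100,
                   series_uid=pydicom.uid.generate_uid(), z=0)
    _minimal_slice(tmp_path, "b.dcm", slope=1, intercept=0, stored=100,
                   series_uid=pydicom.uid.generate_uid(), z=1)
    with pytest.raises(FormatError, match="series"):
        read_dicom_series(tmp_path)


def test_dicom_nonuniform_spacing_rejected(tmp_path):
    uid = pydicom.uid.generate_uid()
    for z in (0, 1, 5):
        _minimal_slice(tmp_path, f"s{z}.dcm", slope=1, intercept=0, stored=100,
                       series_uid=uid, z=z)
    with pytest.raises(FormatError, match="spacing"):
        read_dicom_series(tmp_path)


# ---------------------------------------------------------------------------
# segmentation


def test_segment_bone_matches_phantom_support(noise_free_config):
    vol = generate_patella_volume(noise_free_config, "right", "non-operated", 0)
    mask = segment_bone(vol, 200.0)
    np.testing.assert_array_equal(mask.mask, vol.voxels >= 200.0)


def test_segment_bone_drops_disconnected_speck(noise_free_config):
    vol = generate_patella_volume(noise_free_config, "right", "non-operated", 0)
    vol.voxels[0, 0, 0] = 1500.0  # isolated high-HU speck far from the bone
    mask = segment_bone(vol, 200.0)
    assert not mask.mask[0, 0, 0]
    assert mask.mask.sum() > 0


def test_segment_bone_all_air_errors():
    with pytest.raises(SegmentationError):
        segment_bone(_toy_volume(np.full((8, 8, 8), -1000.0)))


# ---------------------------------------------------------------------------
# orientation


def test_standardize_left_matches_right_twin(noise_free_config):
    """A mirrored left phantom reproduces the right-sided construction."""
    left = generate_patella_volume(noise_free_config, "left", "non-operated", 0)
    right = generate_patella_volume(noise_free_config, "right", "non-operated", 0)
    std, _ = standardize_orientation(left, segment_bone(left))
    np.testing.assert_array_equal(std.voxels, right.voxels)
    assert std.orientation == "standardized-right"


def test_standardize_right_is_identity(noise_free_config):
    right = generate_patella_volume(noise_free_config, "right", "operated", 0)
    std, _ = standardize_orientation(right, segment_bone(right))
    np.testing.assert_array_equal(std.voxels, right.voxels)


def test_mirror_is_involution(rng):
    v = rng.normal(size=(5, 6, 7))
    np.testing.assert_array_equal(mirror_ml(mirror_ml(v)), v)


# ---------------------------------------------------------------------------
# projection and rendering


def test_mip_toy_example():
    vox = np.zeros((2, 2, 2))
    vox[0, :, 0] = [1000, 900]
    vox[0, :, 1] = [400, 300]
    vox[1, :, 0] = [250, 100]
    vox[1, :, 1] = [1200, 1150]
    vol = _toy_volume(vox)
    mip = compute_mip(vol, BoneMask(np.ones_like(vox, bool)))
    np.testing.assert_array_equal(mip.pixels_hu, [[1000, 400], [250, 1200]])


def test_mip_empty_mask_errors(noise_free_config):
    vol = generate_patella_volume(noise_free_config, "right", "non-operated", 0)
    with pytest.raises(SegmentationError):
        compute_mip(vol, BoneMask(np.zeros_like(vol.voxels, bool)))


@given(hnp.arrays(float, (4, 5, 6), elements=st.floats(-1000, 2000)),
       hnp.arrays(bool, (4, 5, 6)))
def test_mip_equals_exhaustive_maximum(vox, mask):
    """MIP equals a per-pixel loop over masked voxels; empty columns get the
    background sentinel."""
    vol = _toy_volume(vox)
    window = DensityWindow()
    if not mask.any():
        return
    mip = compute_mip(vol, BoneMask(mask), window)
    for i in range(4):
        for j in range(6):
            col = [vox[i, y, j] for y in range(5) if mask[i, y, j]]
            expected = max(col) if col else window.background_hu
            assert mip.pixels_hu[i, j] == expected


def test_masking_out_max_voxel_drops_to_second_largest():
    vox = np.zeros((1, 3, 1))
    vox[0, :, 0] = [500, 1100, 900]
    mask = np.ones_like(vox, bool)
    mask[0, 1, 0] = False
    mip = compute_mip(_toy_volume(vox), BoneMask(mask))
    assert mip.pixels_hu[0, 0] == 900


def test_mip_unchanged_by_extra_background(noise_free_config):
    vol = generate_patella_volume(noise_free_config, "right", "non-operated", 0)
    mask = segment_bone(vol)
    mip = compute_mip(vol, mask)
    padded = np.pad(vol.voxels, ((0, 0), (0, 3), (0, 0)), constant_values=-1000.0)
    pmask = np.pad(mask.mask, ((0, 0), (0, 3), (0, 0)), constant_values=False)
    vol2 = _toy_volume(padded)
    mip2 = compute_mip(vol2, BoneMask(pmask))
    np.testing.assert_array_equal(mip.pixels_hu, mip2.pixels_hu)


@pytest.mark.parametrize("hu,gray", [
    (1000.0, 204),  # the threshold used to define HDA
    (200.0, 0),
    (1200.0, 255),
    (700.0, 128),   # 127.5 rounds half up
    (-500.0, 0),    # saturates below the window
    (3000.0, 255),  # saturates above
])
def test_grayscale_rendering(hu, gray):
    mip = MipImage(np.array([[hu]]), DensityWindow(), "right", "standardized-right")
    assert render_grayscale(mip).gray8[0, 0] == gray


@given(st.floats(-2000, 3000), st.floats(-2000, 3000))
def test_rendering_monotone(a, b):
    window = DensityWindow()
    img = MipImage(np.array([[a, b]]), window, "right", "standardized-right")
    g = render_grayscale(img).gray8
    if a <= b:
        assert g[0, 0] <= g[0, 1]
    else:
        assert g[0, 0] >= g[0, 1]


def test_restore_anatomical_flips_left_and_rejects_double():
    img = np.array([[1000.0, 300.0]])
    mip = MipImage(img, DensityWindow(), "left", "standardized-right")
    back = restore_anatomical_orientation(mip)
    np.testing.assert_array_equal(back.pixels_hu, [[300.0, 1000.0]])
    assert back.orientation == "anatomical"
    with pytest.raises(OrientationError):
        restore_anatomical_orientation(back)


def test_restore_anatomical_right_identity():
    img = np.array([[1000.0, 300.0]])
    mip = MipImage(img, DensityWindow(), "right", "standardized-right")
    back = restore_anatomical_orientation(mip)
    np.testing.assert_array_equal(back.pixels_hu, img)
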