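"""CT volumes, bone segmentation, orientation handling and maximum-intensity projections.

The analysis operates on Hounsfield-unit (HU) calibrated CT volumes of the
patella.  Array axes follow the convention ``(superior->inferior,
anterior->posterior, medial->lateral)``: axis 0 maps to image rows, axis 2 to
image columns, and axis 1 is the anterior--posterior projection axis.  In the
*standardized-right* orientation the medial side sits at the low-column end;
left-sided patellae are temporarily mirrored along the medial--lateral axis so
that one set of column-wise region definitions applies to every knee, and
flipped back afterwards so that regional labels refer to anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

__all__ = [
    "CtVolume",
    "BoneMask",
    "DensityWindow",
    "MipImage",
    "FormatError",
    "SegmentationError",
    "OrientationError",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "write_dicom_series",
    "segment_bone",
    "standardize_orientation",
    "compute_mip",
    "render_grayscale",
    "restore_anatomical_orientation",
    "mirror_ml",
]

#: Medial--lateral (column) axis of the voxel array.
ML_AXIS = 2
#: Anterior--posterior (projection) axis of the voxel array.
AP_AXIS = 1


class FormatError(ValueError):
    """Raised when an input volume violates the expected format."""


class SegmentationError(ValueError):
    """Raised when bone segmentation finds no foreground."""


class OrientationError(ValueError):
    """Raised on an invalid orientation-state transition."""


@dataclass(frozen=True)
class DensityWindow:
    """HU display window; the default 200--1200 HU excludes soft tissue and
    spans the mineralization range of subchondral bone."""

    lo_hu: float = 200.0
    hi_hu: float = 1200.0

    def __post_init__(self) -> None:
        if not self.lo_hu < self.hi_hu:
            raise ValueError(f"window requires lo < hi, got {self.lo_hu}..{self.hi_hu}")

    @property
    def background_hu(self) -> float:
        """Sentinel for projection pixels with no bone: just below the window
        floor, so it renders to gray 0 and can never be counted as bone."""
        return self.lo_hu - 1.0


@dataclass
class CtVolume:
    """A 3D HU grid with voxel spacing and per-patella metadata."""

    voxels: np.ndarray  # 3D, HU
    spacing_mm: tuple[float, float, float]
    patient_id: str
    side: str  # "left" | "right"
    status: str  # "operated" | "non-operated"
    orientation: str = "anatomical"  # "anatomical" | "standardized-right"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite HU values")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise FormatError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.status not in ("operated", "non-operated"):
            raise ValueError(f"invalid status {self.status!r}")


@dataclass
class BoneMask:
    """Boolean bone support congruent with a volume; one connected component."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class MipImage:
    """Anterior--posterior maximum-intensity projection of a patella.

    ``pixels_hu`` keeps the lossless HU maxima (background sentinel where no
    bone projects); ``gray8`` holds the 8-bit rendering of the density window
    once :func:`render_grayscale` has run.
    """

    pixels_hu: np.ndarray  # 2D HU
    window: DensityWindow
    side: str
    orientation: str  # "standardized-right" | "anatomical"
    gray8: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels_hu = np.asarray(self.pixels_hu, dtype=float)
        if self.pixels_hu.ndim != 2:
            raise ValueError("MIP must be 2D")


# ---------------------------------------------------------------------------
# readers / writers


def read_nifti(path: str | Path, *, patient_id: str = "", side: str = "right",
               status: str = "non-operated") -> CtVolume:
    """Read a 3D NIfTI volume whose values are already in HU."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return CtVolume(data.astype(float), tuple(float(z) for z in zooms),
                    patient_id, side, status)


def write_nifti(volume: CtVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with spacing in the header affine."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float64), affine), str(path))


def read_dicom_series(path: str | Path, *, patient_id: str | None = None,
                      side: str = "right", status: str = "non-operated",
                      spacing_tol_mm: float = 1e-3) -> CtVolume:
    """Read one axial CT series (one file per slice) into HU.

    Slices are sorted by their position along the slice axis; stored values
    are converted to HU via RescaleSlope/RescaleIntercept.  A directory
    holding more than one series, missing rescale tags, or non-uniform slice
    spacing beyond ``spacing_tol_mm`` is a format error.
    """
    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"directory contains {len(uids)} series, expected one")

    def position(ds: pydicom.Dataset) -> float:
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(ds.get("InstanceNumber", 0))

    datasets.sort(key=position)

    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise FormatError("missing RescaleSlope/RescaleIntercept tags")
        slices.append(ds.pixel_array.astype(float) * float(ds.RescaleSlope)
                      + float(ds.RescaleIntercept))

    positions = np.array([position(ds) for ds in datasets])
    if len(positions) > 1:
        increments = np.diff(positions)
        dz = float(np.median(increments))
        if np.any(np.abs(increments - dz) > spacing_tol_mm):
            raise FormatError("non-uniform slice spacing beyond tolerance")
    else:
        dz = float(datasets[0].get("SliceThickness", 1.0))

    row_mm, col_mm = (float(v) for v in datasets[0].PixelSpacing)
    voxels = np.stack(slices, axis=0)  # (slice, row, col) = (sup-inf, AP, ML)
    pid = patient_id if patient_id is not None else str(datasets[0].get("PatientID", ""))
    return CtVolume(voxels, (abs(dz), row_mm, col_mm), pid, side, status)


def write_dicom_series(volume: CtVolume, out_dir: str | Path) -> list[Path]:
    """Write a minimal single-series axial DICOM stack (one file per slice).

    Stored values are ``HU + 1024`` as unsigned 16-bit with RescaleSlope 1 and
    RescaleIntercept -1024, so readers recover HU exactly (values are rounded
    to integers, adequate for phantoms built on integer-valued HU noise
    realizations at the fidelity the HDA statistic needs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    dz, row_mm, col_mm = volume.spacing_mm
    paths: list[Path] = []
    for k in range(volume.voxels.shape[0]):
        stored = np.round(volume.voxels[k] + 1024.0)
        if stored.min() < 0 or stored.max() > 65535:
            raise FormatError("HU out of storable range for 16-bit DICOM")
        ds = pydicom.Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [row_mm, col_mm]
        ds.SliceThickness = dz
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.astype(np.uint16).tobytes()
        ds.file_meta = pydicom.dataset.FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = ds.SOPClassUID
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        p = out / f"slice_{k:04d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# segmentation / orientation / projection


def segment_bone(volume: CtVolume, bone_threshold_hu: float = 200.0) -> BoneMask:
    """Threshold at ``bone_threshold_hu`` and keep the largest 26-connected
    component.  The default threshold equals the density-window floor."""
    fg = volume.voxels >= bone_threshold_hu
    if not fg.any():
        raise SegmentationError(
            f"no voxel reaches the bone threshold of {bone_threshold_hu} HU")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        return BoneMask(labels == keep)
    return BoneMask(fg)


def mirror_ml(voxels: np.ndarray) -> np.ndarray:
    """Mirror a volume (or mask) along the medial--lateral axis."""
    return np.flip(voxels, axis=ML_AXIS).copy()


def standardize_orientation(volume: CtVolume, mask: BoneMask) -> tuple[CtVolume, BoneMask]:
    """Mirror left-sided volumes along the medial--lateral axis so every
    patella is analysed in a right-sided frame; right volumes pass through."""
    if not mask.mask.any():
        raise SegmentationError("empty bone mask")
    if volume.orientation == "standardized-right":
        return volume, mask
    if volume.side == "left":
        vol = replace(volume, voxels=mirror_ml(volume.voxels),
                      orientation="standardized-right")
        return vol, BoneMask(mirror_ml(mask.mask))
    return replace(volume, orientation="standardized-right"), mask


def compute_mip(volume: CtVolume, mask: BoneMask,
                window: DensityWindow | None = None) -> MipImage:
    """Maximum-intensity projection along the anterior--posterior axis.

    Each output pixel holds the maximum HU over masked voxels in its
    projection column; columns containing no bone get the background sentinel
    (one HU below the window floor).
    """
    if window is None:
        window = DensityWindow()
    if not mask.mask.any():
        raise SegmentationError("cannot project an empty mask")
    masked = np.where(mask.mask, volume.voxels, -np.inf)
    mip = masked.max(axis=AP_AXIS)
    has_bone = mask.mask.any(axis=AP_AXIS)
    mip = np.where(has_bone, mip, window.background_hu)
    return MipImage(mip, window, volume.side, volume.orientation)


def render_grayscale(mip: MipImage) -> MipImage:
    """Populate the 8-bit rendering: the density window maps linearly onto
    0--255 with round-half-up, saturating outside the window."""
    lo, hi = mip.window.lo_hu, mip.window.hi_hu
    clipped = np.clip(mip.pixels_hu, lo, hi)
    scaled = (clipped - lo) / (hi - lo) * 255.0
    mip.gray8 = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return mip


def restore_anatomical_orientation(mip: MipImage) -> MipImage:
    """Flip left-sided MIPs back so columns follow anatomy; a second
    application is an orientation-state error."""
    if mip.orientation != "standardized-right":
        raise OrientationError(
            f"expected standardized-right orientation, got {mip.orientation!r}")
    if mip.side == "left":
        pixels = np.flip(mip.pixels_hu, axis=1).copy()
        gray = None if mip.gray8 is None else np.flip(mip.gray8, axis=1).copy()
    else:
        pixels, gray = mip.pixels_hu, mip.gray8
    return MipImage(pixels, mip.window, mip.side, "anatomical", gray)
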