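"""Reading and writing CT volumes, masks and measurement tables.

Everything the pipeline touches is normalized into :class:`CTVolume`: a
3D grid of Hounsfield units (float32 in memory) with per-axis voxel
spacing in mm.  The in-memory axis order is ``(x, y, z)`` with the slice
(z) axis last and the z index increasing from the lung base toward the
apex; slice indices are 0-based.

Supported on-disk formats:

* Analyze 7.5 ``.hdr``/``.img`` pairs (via nibabel) -- the scanner
  export format this pipeline was built around;
* DICOM series directories (via pydicom), with RescaleSlope/Intercept
  applied so voxel values are calibrated HU;
* multi-page TIFF stacks (via tifffile), which carry no spacing --
  spacing must then be supplied by the caller and defaults to the
  scanner's 0.107 mm isotropic geometry with a logged warning;
* NIfTI-1 for volume/mask export (via nibabel).

Values below -1024 HU are legal (int16 padding such as -32768 denotes
deep air, not missing data) but their presence is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import tifffile
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

logger = logging.getLogger(__name__)

#: Scanner geometry fallback used when a format carries no spacing (mm).
DEFAULT_SPACING_MM: float = 0.107

#: Fixed measurement-table schema (CSV header row).
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "volume_id", "slice", "bin_label", "voxel_count", "measure_mm", "fraction",
)

TOTAL_LABEL = "TOTAL"


class FormatError(ValueError):
    """A file could not be parsed as the requested format."""


class GeometryError(ValueError):
    """Inconsistent or invalid geometry metadata."""


@dataclass
class CTVolume:
    """A calibrated CT volume: HU voxel grid plus geometry metadata."""

    voxels: np.ndarray                      # (nx, ny, nz) float32 HU
    spacing: tuple[float, float, float]     # mm per voxel edge, (x, y, z)
    axis_convention: str = "z_last_base_to_apex"
    source: str = "<memory>"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3D grid, got shape {self.voxels.shape}")
        if self.voxels.dtype != np.float32:
            self.voxels = self.voxels.astype(np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("voxel values must be finite")
        if np.any(self.voxels < -1024):
            logger.info(
                "%s: %d voxels below -1024 HU (int16 padding / deep air)",
                self.source, int(np.sum(self.voxels < -1024)),
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[0] * self.spacing[1]


def spacing_from_fov(fov_mm, matrix) -> tuple[float, ...]:
    """Per-axis voxel spacing (mm) from a field of view and matrix size.

    E.g. a 54.85 x 54.85 x 82.27 mm field of view reconstructed on a
    512 x 512 x 768 grid gives ~0.107 mm (107 um) isotropic voxels.
    """
    fov = np.asarray(fov_mm, dtype=float)
    mat = np.asarray(matrix, dtype=float)
    if fov.shape != mat.shape or np.any(fov <= 0) or np.any(mat <= 0):
        raise GeometryError("field of view and matrix must be positive and same length")
    return tuple(fov / mat)


# ---------------------------------------------------------------------------
# readers

def read_volume(path, format_hint: str = "auto", spacing=None) -> CTVolume:
    """Read a CT volume from Analyze, NIfTI, a DICOM directory or a TIFF stack.

    ``format_hint`` is one of ``{"analyze", "nifti", "dicom_dir",
    "tiff_stack", "auto"}``.  ``spacing`` overrides/provides voxel
    spacing (required semantics for TIFF, which stores none).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    fmt = _sniff_format(path) if format_hint == "auto" else format_hint
    if fmt == "analyze" or fmt == "nifti":
        return _read_nib(path, fmt, spacing)
    if fmt == "dicom_dir":
        return _read_dicom_dir(path)
    if fmt == "tiff_stack":
        return _read_tiff(path, spacing)
    raise FormatError(f"unknown format {fmt!r}")


def _sniff_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    suf = "".join(path.suffixes).lower()
    if suf.endswith((".hdr", ".img")):
        return "analyze"
    if suf.endswith((".nii", ".nii.gz")):
        return "nifti"
    if suf.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise FormatError(f"cannot infer format of {path}")


def _read_nib(path: Path, fmt: str, spacing=None) -> CTVolume:
    if fmt == "analyze":
        stem = path.with_suffix("")
        for ext in (".hdr", ".img"):
            if not stem.with_suffix(ext).exists():
                raise FormatError(f"Analyze pair incomplete: missing {stem.with_suffix(ext)}")
    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path}: {e}") from e
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if spacing is None:
        spacing = zooms
    return CTVolume(voxels=data.astype(np.float32), spacing=tuple(spacing),
                    source=f"{path}:{fmt}")


def _read_dicom_dir(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise FormatError(f"no DICOM slices found in {path}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as e:
            raise FormatError(f"cannot parse DICOM file {f}: {e}") from e
    for required in ("PixelSpacing", "PixelData"):
        missing = [f for ds, f in zip(slices, files) if required not in ds]
        if missing:
            raise FormatError(f"DICOM slice {missing[0]} lacks required field {required}")

    def z_of(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    px = [tuple(float(v) for v in ds.PixelSpacing) for ds in slices]
    if any(p != px[0] for p in px):
        raise GeometryError("DICOM slices disagree on in-plane PixelSpacing")
    zs = np.array([z_of(ds) for ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise GeometryError("DICOM slice positions not strictly increasing")
        if (dz.max() - dz.min()) > 0.01 * dz.mean():
            raise GeometryError(
                f"inconsistent DICOM slice spacing (range {dz.min():g}..{dz.max():g} mm)")
        z_spacing = float(dz.mean())
    else:
        z_spacing = float(getattr(slices[0], "SliceThickness", DEFAULT_SPACING_MM))
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    vox = np.stack(planes, axis=-1)           # (rows, cols, z) = (y, x, z)
    vox = np.transpose(vox, (1, 0, 2))        # -> (x, y, z)
    # PixelSpacing is (row spacing, col spacing) = (y, x)
    spacing = (px[0][1], px[0][0], z_spacing)
    return CTVolume(voxels=vox, spacing=spacing, source=f"{path}:dicom_dir")


def _read_tiff(path: Path, spacing=None) -> CTVolume:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 2D/3D TIFF stack, got shape {data.shape}")
    vox = np.transpose(data.astype(np.float32), (2, 1, 0))  # (pages, y, x) -> (x, y, z)
    if spacing is None:
        logger.warning(
            "TIFF stacks carry no voxel spacing; assuming %g mm isotropic",
            DEFAULT_SPACING_MM,
        )
        spacing = (DEFAULT_SPACING_MM,) * 3
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    return CTVolume(voxels=vox, spacing=tuple(spacing), source=f"{path}:tiff_stack")


# ---------------------------------------------------------------------------
# writers

def write_volume(volume: CTVolume, path, format: str = "auto") -> None:
    """Persist a CTVolume as analyze, nifti, tiff_stack or dicom_dir."""
    path = Path(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt in ("analyze", "nifti"):
        affine = np.diag(list(volume.spacing) + [1.0])
        cls = nib.AnalyzeImage if fmt == "analyze" else nib.Nifti1Image
        img = cls(volume.voxels.astype(np.float32), affine)
        img.header.set_zooms(volume.spacing)
        img.to_filename(str(path))
    elif fmt == "tiff_stack":
        pages = np.transpose(volume.voxels, (2, 1, 0))  # (z, y, x)
        tifffile.imwrite(str(path), pages.astype(np.float32), photometric="minisblack")
    elif fmt == "dicom_dir":
        _write_dicom_dir(volume, path)
    else:
        raise FormatError(f"unknown volume format {fmt!r}")


def _write_dicom_dir(volume: CTVolume, path: Path) -> None:
    """Write an int16 CT series, one file per slice, RescaleIntercept 0.

    HU values are rounded to the nearest integer on disk; a volume whose
    values are already integral round-trips exactly.
    """
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    sx, sy, sz = volume.spacing
    nx, ny, nz = volume.dims
    stored = np.rint(volume.voxels).astype(np.int16)
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * sz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sy, sx]            # (row, col) = (y, x)
        ds.SliceThickness = sz
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1            # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()  # (y, x)
        pydicom.dcmwrite(str(path / f"slice_{k:04d}.dcm"), ds, enforce_file_format=True)


def write_mask(mask, path, format: str = "auto", spacing=None) -> None:
    """Persist a binary mask (LungMask or boolean grid) as nifti or tiff_stack."""
    arr = np.asarray(getattr(mask, "mask", mask)).astype(np.uint8)
    if spacing is None:
        spacing = getattr(mask, "spacing", (1.0, 1.0, 1.0))
    path = Path(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "nifti":
        img = nib.Nifti1Image(arr, np.diag(list(spacing) + [1.0]))
        img.header.set_zooms(spacing)
        img.to_filename(str(path))
    elif fmt == "tiff_stack":
        tifffile.imwrite(str(path), np.transpose(arr, (2, 1, 0)), photometric="minisblack")
    else:
        raise FormatError(f"unknown mask format {fmt!r}")


def read_mask(path, format: str = "auto") -> np.ndarray:
    """Read a binary mask written by :func:`write_mask`."""
    vol = read_volume(path, format_hint="auto" if format == "auto" else format,
                      spacing=(1.0, 1.0, 1.0))
    return vol.voxels > 0


# ---------------------------------------------------------------------------
# measurement tables

def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    if list(table.columns) != list(MEASUREMENT_COLUMNS):
        raise FormatError(
            f"measurement table columns must be {list(MEASUREMENT_COLUMNS)}, "
            f"got {list(table.columns)}")
    if len(table) == 0:
        raise FormatError("measurement table is empty")
    return table


def write_measurements(table: pd.DataFrame, path) -> None:
    """Write a measurement table as RFC-4180 CSV with a fixed header row.

    Floats carry 9 significant digits so a re-parse reproduces values.
    """
    validate_measurements(table)
    table.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def read_measurements(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"volume_id": str, "slice": str, "bin_label": str})
    return validate_measurements(table)
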