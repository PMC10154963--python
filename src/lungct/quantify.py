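"""Per-HU-bin measurement inside a lung mask or a per-slice ROI.

The mask (3D) or ROI (2D) selects voxels; each selected voxel is
assigned to an HU bin and the per-bin voxel counts are converted to
physical measure -- mm^3 for volumetric measurement, mm^2 for a single
slice.  An OUT_OF_RANGE row keeps the accounting conservative: counts
over all bins plus OUT_OF_RANGE always equal the number of selected
voxels, and fractions sum to 1.

The semi-manual workflow measures a hand-drawn per-slice ROI and then
"interpolates" it: the same 2D outline is re-applied to neighboring
slices (default offsets -5 and +5) as a data-augmentation step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .hu import OUT_OF_RANGE, OUT_OF_RANGE_LABEL, HUBinScheme, assign_bins
from .segment import LungMask
from .volume_io import MEASUREMENT_COLUMNS, TOTAL_LABEL, CTVolume, GeometryError

logger = logging.getLogger(__name__)

#: Default ROI interpolation offsets: two additional slices at +/-5.
DEFAULT_AUGMENT_OFFSETS: tuple[int, ...] = (-5, 5)


@dataclass
class SliceROI:
    """A 2D region of interest on one slice, e.g. a manual lung outline."""

    slice_index: int
    mask2d: np.ndarray
    analyst_id: str = "analyst"

    def __post_init__(self):
        self.mask2d = np.asarray(self.mask2d, dtype=bool)
        if self.mask2d.ndim != 2:
            raise GeometryError(f"ROI mask must be 2D, got shape {self.mask2d.shape}")

    @property
    def area_voxels(self) -> int:
        return int(np.count_nonzero(self.mask2d))


def _bin_rows(hu_values: np.ndarray, scheme: HUBinScheme, unit_measure: float,
              volume_id: str, slice_label: str) -> pd.DataFrame:
    """Shared counting core: one row per bin, plus OUT_OF_RANGE and TOTAL."""
    idx = assign_bins(hu_values, scheme)
    # shift so OUT_OF_RANGE (-1) lands in slot 0
    counts = np.bincount(idx.ravel() + 1, minlength=scheme.n_bins + 1)
    oor = int(counts[0])
    per_bin = counts[1:]
    total = int(per_bin.sum()) + oor
    denom = total if total else 1
    rows = []
    for label, c in zip(scheme.labels, per_bin):
        rows.append((volume_id, slice_label, label, int(c), c * unit_measure, c / denom))
    rows.append((volume_id, slice_label, OUT_OF_RANGE_LABEL, oor, oor * unit_measure,
                 oor / denom))
    in_range = int(per_bin.sum())
    rows.append((volume_id, slice_label, TOTAL_LABEL, in_range,
                 in_range * unit_measure, in_range / denom))
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def measure_bins(volume: CTVolume, mask: Union[LungMask, np.ndarray],
                 scheme: HUBinScheme, volume_id: str = "volume") -> pd.DataFrame:
    """Per-bin voxel counts and volumes (mm^3) inside a 3D mask.

    Returns one row per bin plus an OUT_OF_RANGE row and a TOTAL row
    (TOTAL = in-range bins only, the "total lung tissue volume").
    """
    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if arr.shape != volume.dims:
        raise GeometryError(f"mask dims {arr.shape} != volume dims {volume.dims}")
    return _bin_rows(volume.voxels[arr], scheme, volume.voxel_volume_mm3,
                     volume_id, "ALL")


def total_tissue_volume(table: pd.DataFrame) -> float:
    """Total lung tissue volume (mm^3): sum of in-range bin volumes.

    OUT_OF_RANGE is excluded -- only voxels inside the scheme's HU span
    count as measured lung tissue.
    """
    bins = table[~table["bin_label"].isin([OUT_OF_RANGE_LABEL, TOTAL_LABEL])]
    return float(bins["measure_mm"].sum())


def measure_slice_roi(volume: CTVolume, roi: SliceROI,
                      scheme: HUBinScheme) -> pd.DataFrame:
    """Per-bin counts and areas (mm^2) for voxels inside a 2D ROI on one slice."""
    if not 0 <= roi.slice_index < volume.n_slices:
        raise ValueError(
            f"ROI slice {roi.slice_index} outside stack of {volume.n_slices} slices")
    if roi.mask2d.shape != volume.dims[:2]:
        raise GeometryError(
            f"ROI dims {roi.mask2d.shape} != in-plane volume dims {volume.dims[:2]}")
    plane = volume.voxels[:, :, roi.slice_index]
    return _bin_rows(plane[roi.mask2d], scheme, volume.pixel_area_mm2,
                     roi.analyst_id, str(roi.slice_index))


def augment_roi(roi: SliceROI, offsets: Sequence[int] = DEFAULT_AUGMENT_OFFSETS,
                n_slices: Optional[int] = None) -> list[SliceROI]:
    """Re-anchor a manual ROI on offset slices (the interpolation step).

    Returns the additional ROIs only (the original is not included);
    offsets that fall outside the stack are dropped with a warning.
    """
    out = []
    for off in offsets:
        target = roi.slice_index + int(off)
        if n_slices is not None and not 0 <= target < n_slices:
            logger.warning("augment_roi: offset %+d from slice %d falls outside "
                           "stack of %d slices; dropped", off, roi.slice_index, n_slices)
            continue
        if n_slices is None and target < 0:
            logger.warning("augment_roi: offset %+d from slice %d is negative; dropped",
                           off, roi.slice_index)
            continue
        out.append(SliceROI(slice_index=target, mask2d=roi.mask2d.copy(),
                            analyst_id=roi.analyst_id))
    return out


def roi_from_polygon(slice_index: int, vertices: Sequence[Sequence[float]],
                     shape: tuple[int, int], analyst_id: str = "analyst") -> SliceROI:
    """Rasterize an (x, y) polygon to a filled 2D ROI (even-odd rule)."""
    from PIL import Image, ImageDraw

    img = Image.new("1", (shape[1], shape[0]), 0)  # PIL is (width, height) = (y, x)
    draw = ImageDraw.Draw(img)
    draw.polygon([(float(y), float(x)) for x, y in vertices], fill=1, outline=1)
    mask = np.asarray(img, dtype=bool).T
    return SliceROI(slice_index=slice_index, mask2d=mask, analyst_id=analyst_id)


def load_roi(path, slice_index: Optional[int] = None, shape=None,
             analyst_id: str = "analyst") -> SliceROI:
    """Load a ROI from a 2D binary PNG/TIFF or a JSON polygon file.

    JSON schema: ``{"slice": int, "vertices": [[x, y], ...]}``.
    """
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() == ".json":
        spec = json.loads(path.read_text())
        if shape is None:
            raise ValueError("polygon ROI needs the in-plane volume shape")
        return roi_from_polygon(int(spec["slice"]), spec["vertices"], shape, analyst_id)
    if path.suffix.lower() in (".png", ".tif", ".tiff"):
        from PIL import Image

        arr = np.asarray(Image.open(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
        if slice_index is None:
            raise ValueError("image ROI needs an explicit slice index")
        return SliceROI(slice_index=slice_index, mask2d=arr.T > 0, analyst_id=analyst_id)
    raise ValueError(f"unsupported ROI file type: {path.suffix!r}")
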