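"""Synthetic mouse-thorax micro-CT phantom with exact ground truth.

The phantom emulates the kind of whole-body mouse scan the pipeline was
designed for: a default 128 x 128 x 192 grid (a 1/4 linear-scale analog
of the scanner's 512 x 512 x 768 reconstruction) at 0.107 mm isotropic
spacing.  Geometry is a simple body ellipsoid containing:

* a chest wall / bone shell (~ +300 HU),
* heart and connective soft tissue (~ -100 HU),
* a two-lobed ellipsoidal lung of aerated parenchyma (~ -650 HU,
  clipped to [-1000, -300]) with an embedded cylindrical airway lumen
  (~ -950 HU) and a spherical cardiac notch,
* an optional sub-base "decoy" gas pocket below the diaphragm that a
  naive threshold would pick up -- it exists to exercise the base-slice
  crop,
* exterior air at -1000 HU.

Voxel noise is independent Gaussian per tissue class; a Gaussian blur
then mimics partial-volume averaging, which is what spreads lung voxels
across neighboring HU bins as in real scans.  The ground-truth lung
mask is the exact pre-blur voxel set of parenchyma plus intra-lung
airway, so every downstream stage can be scored against it.

A "fibrotic" preset shifts the parenchyma mean from -650 to -450 HU and
shrinks the lung axes by 15 %: the qualitative signature of
bleomycin-type injury (smaller aerated lung, right-shifted HU
histogram).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .quantify import SliceROI
from .segment import LungMask
from .volume_io import CTVolume

EXTERIOR, WALL, SOFT, PARENCHYMA, AIRWAY, GAS = range(6)

#: (mean HU, HU standard deviation) per tissue class.
CLASS_HU: dict[int, tuple[float, float]] = {
    EXTERIOR: (-1000.0, 10.0),
    WALL: (300.0, 150.0),
    SOFT: (-100.0, 60.0),
    PARENCHYMA: (-650.0, 120.0),
    AIRWAY: (-950.0, 20.0),
    GAS: (-800.0, 30.0),
}

#: Parenchyma HU values are clipped to this physical range before blur.
PARENCHYMA_CLIP: tuple[float, float] = (-1000.0, -300.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic thorax; defaults give the healthy mouse."""

    dims: tuple[int, int, int] = (128, 128, 192)
    spacing_mm: float = 0.107
    parenchyma_mean_hu: float = -650.0
    parenchyma_sd_hu: float = 120.0
    lung_scale: float = 1.0            # linear scale factor on the lung semi-axes
    noise_scale: float = 1.0           # multiplier on all class HU noise SDs
    blur_sigma: float = 0.6            # partial-volume Gaussian width (voxels)
    include_decoy: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.dims) < 32:
            raise ValueError("phantom needs at least 32 voxels per axis")
        if not 0.2 <= self.lung_scale <= 1.2:
            raise ValueError("lung_scale outside the range the geometry can fit")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.spacing_mm,) * 3

    @property
    def default_base_slice(self) -> int:
        """A base-of-lung slice below the lung and above the decoy pocket."""
        return int(round(0.28 * self.dims[2]))


def fibrotic_spec(**overrides) -> PhantomSpec:
    """The injured-lung preset: denser parenchyma, 15 % smaller lung."""
    base = dict(parenchyma_mean_hu=-450.0, lung_scale=0.85)
    base.update(overrides)
    return PhantomSpec(**base)


def _ellipsoid(grids, center, semi) -> np.ndarray:
    x, y, z = grids
    return ((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2 \
        + ((z - center[2]) / semi[2]) ** 2 <= 1.0


def _class_grid(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.dims
    x, y, z = (np.arange(nx).reshape(-1, 1, 1) / nx,
               np.arange(ny).reshape(1, -1, 1) / ny,
               np.arange(nz).reshape(1, 1, -1) / nz)
    grids = (x, y, z)
    cls = np.full(spec.dims, EXTERIOR, dtype=np.uint8)
    body = _ellipsoid(grids, (0.5, 0.5, 0.5), (0.42, 0.42, 0.45))
    inner = _ellipsoid(grids, (0.5, 0.5, 0.5), (0.42 * 0.88, 0.42 * 0.88, 0.45 * 0.88))
    cls[body] = WALL
    cls[inner] = SOFT
    s = spec.lung_scale
    lung = np.zeros(spec.dims, dtype=bool)
    for cx in (0.36, 0.64):
        lung |= _ellipsoid(grids, (cx, 0.5, 0.58), (0.20 * s, 0.26 * s, 0.22 * s))
    lung &= inner
    cls[lung] = PARENCHYMA
    notch = _ellipsoid(grids, (0.5, 0.58, 0.52), (0.11, 0.11, 0.11))
    cls[notch & inner] = SOFT
    lung_now = cls == PARENCHYMA
    airway = (((x - 0.5) * nx) ** 2 + ((y - 0.46) * ny) ** 2
              <= (0.035 * nx) ** 2) & (z >= 0.40) & (z <= 0.72)
    cls[airway & lung_now] = AIRWAY
    if spec.include_decoy:
        decoy = _ellipsoid(grids, (0.5, 0.5, 0.16), (0.07, 0.07, 0.07 * nx / nz))
        cls[decoy & inner] = GAS
    return cls


def generate_phantom(spec: Optional[PhantomSpec] = None,
                     ) -> tuple[CTVolume, LungMask, float]:
    """Build the noisy/blurred HU volume, its exact lung mask and true volume.

    Fully deterministic given ``spec.seed``.  The ground-truth mask is
    the pre-blur parenchyma + intra-lung airway voxel set; the returned
    volume is what the segmentation pipeline sees.
    """
    spec = spec or PhantomSpec()
    cls = _class_grid(spec)
    truth = (cls == PARENCHYMA) | (cls == AIRWAY)
    if not truth.any():
        raise ValueError("phantom geometry produced no lung voxels for these dims")

    rng = np.random.default_rng(spec.seed)
    mean = np.empty(spec.dims, dtype=np.float32)
    sd = np.empty(spec.dims, dtype=np.float32)
    for c, (m, s) in CLASS_HU.items():
        if c == PARENCHYMA:
            m, s = spec.parenchyma_mean_hu, spec.parenchyma_sd_hu
        sel = cls == c
        mean[sel] = m
        sd[sel] = s * spec.noise_scale
    hu = mean + sd * rng.standard_normal(spec.dims).astype(np.float32)
    par = cls == PARENCHYMA
    hu[par] = np.clip(hu[par], *PARENCHYMA_CLIP)
    if spec.blur_sigma > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.blur_sigma)

    volume = CTVolume(voxels=hu, spacing=spec.spacing, source=f"phantom(seed={spec.seed})")
    true_volume = float(truth.sum()) * volume.voxel_volume_mm3
    mask = LungMask(
        mask=truth, spacing=spec.spacing, selected_label=0,
        base_slice=0, refine_params={}, source="phantom:ground_truth",
    )
    return volume, mask, true_volume


def simulate_manual_roi(truth: Union[LungMask, np.ndarray], slice_index: int,
                        reader_noise: int = 1,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None,
                        analyst_id: str = "reader") -> SliceROI:
    """Perturb a ground-truth slice to emulate one reader's manual outline.

    A random morphological jitter -- erosion or dilation by up to
    ``reader_noise`` voxels -- stands in for reader-to-reader boundary
    variability.  ``reader_noise=0`` returns the truth slice exactly.
    """
    arr = np.asarray(getattr(truth, "mask", truth), dtype=bool)
    plane = arr[:, :, slice_index]
    if not plane.any():
        raise ValueError(f"slice {slice_index} does not intersect the lung mask")
    rng = rng if rng is not None else np.random.default_rng(seed)
    k = int(rng.integers(-reader_noise, reader_noise + 1)) if reader_noise else 0
    st = ndimage.generate_binary_structure(2, 1)
    if k > 0:
        plane = ndimage.binary_dilation(plane, structure=st, iterations=k)
    elif k < 0:
        eroded = ndimage.binary_erosion(plane, structure=st, iterations=-k)
        if eroded.any():
            plane = eroded
    return SliceROI(slice_index=slice_index, mask2d=plane, analyst_id=analyst_id)
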