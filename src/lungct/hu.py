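"""Hounsfield-unit calibration semantics and radiodensity bin schemes.

CT radiodensity is expressed in Hounsfield units (HU), a linear scale
anchored by a two-point calibration: air maps to -1000 HU and water to
0 HU.  In aerated lung the voxel value is, to first order, a linear mix
of the two references, so -500 HU corresponds to a 50/50 air/tissue
ratio.  Quantification proceeds by partitioning the HU axis into
contiguous bins and counting lung voxels per bin.

Three bin schemes are provided:

``default``
    ``[-1000, -600, -500, -400, -300, -200, 0]`` -- six bins spanning
    aerated parenchyma up to connective tissue.
``mod``
    As ``default`` but with the most aerated range split into
    ``[-1000, -700)``, ``[-700, -600)`` and ``[-600, -500)`` for better
    specificity in the air-dominated range.
``range``
    User-defined uniform bins between a min and max with a fixed width.

Bins are half-open ``[lo, hi)``; the final bin is closed at its upper
edge so the printed lists form a true partition and boundary voxels are
counted exactly once.  Voxels outside the scheme map to the sentinel
:data:`OUT_OF_RANGE`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel bin index for voxels outside the scheme's [first, last] span.
OUT_OF_RANGE: int = -1

#: Row label used for the out-of-range sentinel in measurement tables.
OUT_OF_RANGE_LABEL: str = "OUT_OF_RANGE"

DEFAULT_EDGES: tuple[float, ...] = (-1000.0, -600.0, -500.0, -400.0, -300.0, -200.0, 0.0)
MOD_EDGES: tuple[float, ...] = (-1000.0, -700.0, -600.0, -500.0, -400.0, -300.0, -200.0, 0.0)


class BinSchemeError(ValueError):
    """Invalid bin-scheme parameters."""


def _fmt_hu(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def _interval_labels(edges: np.ndarray) -> list[str]:
    labels = []
    n = len(edges) - 1
    for i in range(n):
        close = "]" if i == n - 1 else ")"
        labels.append(f"[{_fmt_hu(edges[i])}, {_fmt_hu(edges[i + 1])}{close}")
    return labels


@dataclass(frozen=True)
class HUBinScheme:
    """An ordered partition of the HU axis into contiguous bins."""

    mode: str
    edges: tuple[float, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if len(edges) < 2:
            raise BinSchemeError("a bin scheme needs at least 2 edges")
        if not np.all(np.diff(edges) > 0):
            raise BinSchemeError("bin edges must be strictly increasing")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(_interval_labels(edges)))
        if len(self.labels) != len(edges) - 1:
            raise BinSchemeError("number of labels must equal number of bins")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def to_json(self) -> str:
        return json.dumps({"mode": self.mode, "edges": list(self.edges)})

    @classmethod
    def from_json(cls, text: str) -> "HUBinScheme":
        d = json.loads(text)
        return cls(mode=d["mode"], edges=tuple(float(e) for e in d["edges"]))


@dataclass(frozen=True)
class CalibrationModel:
    """Two-point linear air/water HU calibration.

    ``air_hu`` is the reference value of pure air (-1000 by definition of
    the HU scale) and ``water_hu`` of pure water/soft tissue (0).  The
    model is affine between the anchors; no beam-hardening correction.
    """

    air_hu: float = -1000.0
    water_hu: float = 0.0

    def __post_init__(self):
        if not self.air_hu < self.water_hu:
            raise ValueError("air_hu must be below water_hu")


def make_bin_scheme(
    mode: str,
    min_hu: float | None = None,
    max_hu: float | None = None,
    width: float | None = None,
) -> HUBinScheme:
    """Build a bin scheme in ``default``, ``mod`` or ``range`` mode.

    ``default`` and ``mod`` take no further parameters and return the
    fixed edge lists.  ``range`` builds uniform bins ``min, min+width,
    ...`` capped at ``max``; if the width does not divide the span the
    final bin is truncated at ``max`` (logged).
    """
    if mode in ("default", "mod"):
        if any(v is not None for v in (min_hu, max_hu, width)):
            raise BinSchemeError(f"min/max/width are not accepted in {mode!r} mode")
        return HUBinScheme(mode=mode, edges=DEFAULT_EDGES if mode == "default" else MOD_EDGES)
    if mode != "range":
        raise BinSchemeError(f"unknown bin-scheme mode {mode!r}")
    if min_hu is None or max_hu is None or width is None:
        raise BinSchemeError("range mode requires min_hu, max_hu and width")
    if width <= 0:
        raise BinSchemeError("range mode requires width > 0")
    if min_hu >= max_hu:
        raise BinSchemeError("range mode requires min_hu < max_hu")
    edges = list(np.arange(min_hu, max_hu, width, dtype=float))
    if not np.isclose(edges[-1] + width, max_hu):
        logger.warning(
            "bin width %g does not divide span [%g, %g]; final bin truncated at %g",
            width, min_hu, max_hu, max_hu,
        )
    edges.append(float(max_hu))
    return HUBinScheme(mode="range", edges=tuple(edges))


def assign_bins(hu: np.ndarray, scheme: HUBinScheme) -> np.ndarray:
    """Map each HU value to its bin index, or :data:`OUT_OF_RANGE`.

    Bin ``i`` owns ``edges[i] <= hu < edges[i+1]``; the final bin is
    closed at its top edge.  Accepts any array shape (typically the 3D
    voxel grid); returns an int grid of the same shape.
    """
    v = np.asarray(hu)
    edges = np.asarray(scheme.edges, dtype=float)
    idx = np.searchsorted(edges, v, side="right") - 1
    idx = idx.astype(np.int64, copy=False)
    idx[np.asarray(v == edges[-1])] = scheme.n_bins - 1
    idx[np.asarray((v < edges[0]) | (v > edges[-1]))] = OUT_OF_RANGE
    return idx


def air_fraction(hu, cal: CalibrationModel | None = None):
    """Percent air content (0-100) of a voxel under the linear calibration.

    ``air_hu`` maps to 100 % air, ``water_hu`` to 0 % air, affine in
    between; -500 HU under the standard anchors is a 50/50 air/tissue
    mix.  Values outside the anchors are clamped first (logged).
    """
    cal = cal or CalibrationModel()
    v = np.asarray(hu, dtype=float)
    if np.any(v < cal.air_hu) or np.any(v > cal.water_hu):
        logger.info("air_fraction: values clamped to [%g, %g]", cal.air_hu, cal.water_hu)
        v = np.clip(v, cal.air_hu, cal.water_hu)
    frac = 100.0 * (cal.water_hu - v) / (cal.water_hu - cal.air_hu)
    return float(frac) if np.isscalar(hu) else frac
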