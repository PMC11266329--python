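"""Attenuation-map construction at 511 keV.

Converts HU volumes (CT-like, synthetic-CT-like) or MRAC class volumes to
linear-attenuation-coefficient (LAC, cm^-1) maps, and applies the map
preparation rules used for a common-support comparison: crop every map to one
reference external contour, replace missing tissue inside the contour with
water, and set internal air pockets to water.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .phantoms import MR_AIR, MR_FAT, MR_SOFT_TISSUE

#: Water LAC at 511 keV, cm^-1.
WATER_LAC = 0.096

#: Threshold separating residual air from tissue inside the body contour.
MISSING_TISSUE_LAC_CUT = 0.02


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear HU -> LAC transform, clamped outside the breakpoints.

    The default is a standard bilinear curve anchored at air (-1000 HU, 0),
    water (0 HU, 0.096 cm^-1) and a reduced bone slope (1000 HU, 0.130 cm^-1);
    the scanner vendor's proprietary curve is not published, so the anchors
    are configurable.
    """

    breakpoints: tuple[float, ...]
    lac_values: tuple[float, ...]

    def validate(self) -> None:
        if len(self.breakpoints) == 0 or len(self.breakpoints) != len(self.lac_values):
            raise ConfigurationError("calibration curve is empty or ragged")
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.lac_values, dtype=float)
        if not np.all(np.diff(bp) > 0):
            raise ConfigurationError("breakpoints must be strictly increasing")
        if np.any(lv < 0) or not np.all(np.diff(lv) >= 0):
            raise ConfigurationError("lac_values must be non-negative and non-decreasing")


def default_calibration_curve() -> CalibrationCurve:
    return CalibrationCurve((-1000.0, 0.0, 1000.0), (0.0, WATER_LAC, 0.130))


#: Population bulk LACs for the Dixon-style classes (pelvic FOV, no lung).
DEFAULT_CLASS_LACS: dict[int, float] = {
    MR_AIR: 0.0,
    MR_FAT: 0.086,
    MR_SOFT_TISSUE: WATER_LAC,
}


@dataclass
class AttenuationMap:
    """511 keV LAC volume (cm^-1) with provenance tag."""

    lac_volume: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    provenance: str  # "CTAC" | "sCTAC" | "MRAC"
    prepared: bool = False

    def validate(self) -> None:
        if self.provenance not in ("CTAC", "sCTAC", "MRAC"):
            raise ConfigurationError(f"unknown provenance {self.provenance!r}")
        if np.any(self.lac_volume < 0):
            raise ValueError("LAC must be non-negative")


def hu_to_lac(hu_volume: np.ndarray, curve: CalibrationCurve | None = None) -> np.ndarray:
    """Elementwise piecewise-linear HU -> LAC conversion (cm^-1)."""
    if curve is None:
        curve = default_calibration_curve()
    curve.validate()
    return np.interp(
        np.asarray(hu_volume, dtype=float),
        np.asarray(curve.breakpoints, dtype=float),
        np.asarray(curve.lac_values, dtype=float),
    )


def mrac_assign(
    class_volume: np.ndarray, class_lacs: Mapping[int, float] | None = None
) -> np.ndarray:
    """Assign one bulk LAC per tissue class (pure lookup)."""
    if class_lacs is None:
        class_lacs = DEFAULT_CLASS_LACS
    classes = np.unique(class_volume)
    missing = [int(c) for c in classes if int(c) not in class_lacs]
    if missing:
        raise ConfigurationError(f"no LAC assigned for class(es) {missing}")
    lut = np.zeros(int(classes.max()) + 1, dtype=float)
    for c, v in class_lacs.items():
        if c <= classes.max():
            lut[c] = v
    return lut[np.asarray(class_volume, dtype=np.intp)]


def prepare_map(
    lac: np.ndarray,
    reference_body_mask: np.ndarray,
    internal_air_pockets: np.ndarray | None,
    water_lac: float = WATER_LAC,
    *,
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    provenance: str = "CTAC",
    air_cut: float = MISSING_TISSUE_LAC_CUT,
) -> AttenuationMap:
    """Apply the common-support preparation rules.

    Voxels outside the reference external contour are zeroed; voxels inside
    the contour whose LAC falls below ``air_cut`` (missing tissue) are set to
    water; internal air pockets are set to water.  Idempotent.
    """
    mask = np.asarray(reference_body_mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("reference body mask is empty")
    out = np.array(lac, dtype=float, copy=True)
    if np.any(out < 0):
        raise ValueError("LAC must be non-negative")
    out[~mask] = 0.0
    out[mask & (out < air_cut)] = water_lac
    if internal_air_pockets is not None:
        out[np.asarray(internal_air_pockets, dtype=bool) & mask] = water_lac
    amap = AttenuationMap(out, tuple(voxel_spacing_mm), provenance, prepared=True)
    amap.validate()
    return amap
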