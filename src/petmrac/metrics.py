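"""Image- and contour-level comparison metrics.

Implements the evaluation layer of the attenuation-correction comparison:
external-contour restriction, per-voxel percentage SUV differences and their
cohort histogram (400 bins over +/-100%), bone-region analysis, 40%-of-SUVmax
tumour delineation, Dice overlap, symmetric surface distances and the
per-lesion metric bundle comparing each candidate map against CTAC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import AnalysisError
from .simulate import SuvImage

HIST_RANGE = (-100.0, 100.0)
N_BINS = 400

PROVENANCES = ("CTAC", "sCTAC", "MRAC")


def _suv_array(img) -> np.ndarray:
    return img.suv if isinstance(img, SuvImage) else np.asarray(img, dtype=float)


# --------------------------------------------------------------------------
# External contour and percentage-difference maps
# --------------------------------------------------------------------------


def external_contour(ref_suv, threshold: float = 0.05) -> np.ndarray:
    """Threshold the reference (CTAC) SUV image at ``threshold`` (SUV, i.e.
    g/ml-equivalent) and keep the largest connected component.

    The same contour is applied unchanged to every provenance of the patient.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = _suv_array(ref_suv)
    mask = arr >= threshold
    if not np.any(mask):
        raise AnalysisError("external contour is empty at this threshold")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (int(np.argmax(sizes)) + 1)
    return mask


@dataclass
class PercentDiffResult:
    """Per-voxel percentage differences inside a contour.

    ``values`` holds 100*(eval-ref)/ref at in-contour voxels with ref > 0;
    voxels with ref = 0 are excluded from the division and counted.
    """

    values: np.ndarray  # 1D
    n_in_contour: int
    n_excluded_zero_ref: int

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def percent_diff_map(eval_suv, ref_suv, contour: np.ndarray) -> PercentDiffResult:
    ev, rf = _suv_array(eval_suv), _suv_array(ref_suv)
    if ev.shape != rf.shape or ev.shape != contour.shape:
        raise ValueError("images and contour must share one grid")
    contour = np.asarray(contour, dtype=bool)
    if not np.any(contour):
        raise ValueError("contour is empty")
    ref_in = rf[contour]
    ev_in = ev[contour]
    ok = ref_in > 0
    values = 100.0 * (ev_in[ok] - ref_in[ok]) / ref_in[ok]
    return PercentDiffResult(
        values=values,
        n_in_contour=int(contour.sum()),
        n_excluded_zero_ref=int((~ok).sum()),
    )


@dataclass
class DifferenceHistogram:
    """Cohort histogram of percentage differences: 400 bins over +/-100%.

    Per patient, each bin holds the percentage of that patient's in-contour
    voxels falling in the bin; the cohort curve is the per-bin mean across
    patients with +/- one standard error.
    """

    bin_edges: np.ndarray  # 401 edges
    per_patient_fraction: np.ndarray  # (n_patients, 400), percent
    mean_per_bin: np.ndarray
    se_per_bin: np.ndarray
    n_excluded: np.ndarray  # per patient: zero-ref + out-of-range voxels
    se_defined: bool  # False for a single-patient cohort

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def bin_histogram(
    diff_maps: Sequence[PercentDiffResult | np.ndarray],
) -> DifferenceHistogram:
    """Bin per-patient difference maps and average the fractions across the
    cohort.  Bins are half-open [lo, hi) with the last bin closed; values
    outside +/-100% are excluded and counted."""
    if len(diff_maps) == 0:
        raise ValueError("at least one patient required")
    edges = np.linspace(HIST_RANGE[0], HIST_RANGE[1], N_BINS + 1)
    fracs, excluded = [], []
    for dm in diff_maps:
        if isinstance(dm, PercentDiffResult):
            vals, n_total, n_zero = dm.values, dm.n_in_contour, dm.n_excluded_zero_ref
        else:
            vals = np.asarray(dm, dtype=float).ravel()
            n_total, n_zero = vals.size, 0
        counts, _ = np.histogram(vals, bins=edges)
        out_of_range = vals.size - int(counts.sum())
        fracs.append(100.0 * counts / n_total)
        excluded.append(n_zero + out_of_range)
    fr = np.asarray(fracs)
    n = fr.shape[0]
    mean = fr.mean(axis=0)
    if n > 1:
        se = fr.std(axis=0, ddof=1) / np.sqrt(n)
        se_defined = True
    else:
        se = np.zeros(N_BINS)
        se_defined = False
    return DifferenceHistogram(edges, fr, mean, se, np.asarray(excluded), se_defined)


# --------------------------------------------------------------------------
# Bone region
# --------------------------------------------------------------------------


def bone_mask(
    hu_volume: np.ndarray,
    hu_threshold: float = 200.0,
    min_component_voxels: int = 50,
) -> np.ndarray:
    """Bone ROI delineated on the CT HU volume: threshold plus removal of
    connected components below ``min_component_voxels``."""
    mask = np.asarray(hu_volume, dtype=float) >= hu_threshold
    lab, n = ndimage.label(mask)
    if n > 0:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_voxels) + 1
        mask = np.isin(lab, keep)
    if not np.any(mask):
        warnings.warn("bone mask is empty", stacklevel=2)
    return mask


# --------------------------------------------------------------------------
# Tumour delineation
# --------------------------------------------------------------------------


def threshold_gtv(
    suv, manual_volume: np.ndarray, fraction: float = 0.4
) -> np.ndarray:
    """GTV = voxels inside the manual tumour volume with SUV >= fraction of
    the maximum SUV found inside that manual volume.  No connectivity
    filtering: every qualifying voxel is kept."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    manual = np.asarray(manual_volume, dtype=bool)
    if not np.any(manual):
        raise ValueError("manual volume is empty")
    arr = _suv_array(suv)
    suv_max = float(arr[manual].max())
    if suv_max <= 0:
        raise AnalysisError("SUV is zero everywhere inside the manual volume")
    return manual & (arr >= fraction * suv_max)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Volumetric Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise AnalysisError("Dice is undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Surface voxels: mask minus its 6-connected erosion (4-connected per
    slice for a single-slice input)."""
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=struct, border_value=0)


def distance_to_agreement(
    a: np.ndarray,
    b: np.ndarray,
    spacing_mm: Sequence[float],
    directed: bool = False,
) -> tuple[float, float]:
    """Surface-distance summary between two masks in mm.

    Default (symmetric): distances from every boundary voxel of ``a`` to the
    nearest boundary voxel of ``b`` and vice versa are pooled; returns
    (mean, max) where max is the symmetric Hausdorff distance.  With
    ``directed`` only the a-to-b direction is used.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not np.any(a) or not np.any(b):
        raise AnalysisError("distance to agreement requires two non-empty masks")
    spacing = tuple(float(s) for s in spacing_mm[: a.ndim])
    ba, bb = _boundary(a), _boundary(b)
    dt_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    d_ab = dt_to_b[ba]
    if directed:
        pooled = d_ab
    else:
        dt_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
        pooled = np.concatenate([d_ab, dt_to_a[bb]])
    return float(pooled.mean()), float(pooled.max())


# --------------------------------------------------------------------------
# Per-lesion metric bundle
# --------------------------------------------------------------------------


@dataclass
class GtvResult:
    """Delineation and metabolic-parameter comparison for one lesion.

    Dictionaries are keyed by provenance; comparison metrics (DSC, DTA,
    volume %) compare each candidate GTV against the CTAC GTV, while SUVmax
    and SUVmean are measured inside each provenance's own GTV with percentage
    differences relative to CTAC.
    """

    kind: str
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    dsc: dict[str, float] = field(default_factory=dict)
    dta_mean_mm: dict[str, float] = field(default_factory=dict)
    dta_max_mm: dict[str, float] = field(default_factory=dict)
    volume_pct_diff: dict[str, float] = field(default_factory=dict)
    suv_max: dict[str, float] = field(default_factory=dict)
    suv_mean: dict[str, float] = field(default_factory=dict)
    suv_max_pct_diff: dict[str, float] = field(default_factory=dict)
    suv_mean_pct_diff: dict[str, float] = field(default_factory=dict)


def gtv_metrics(
    suv_by_provenance: Mapping[str, SuvImage | np.ndarray],
    manual_volume: np.ndarray,
    spacing_mm: Sequence[float],
    kind: str = "primary",
    fraction: float = 0.4,
) -> GtvResult:
    """Threshold each provenance independently at 40% of its own SUVmax and
    compare the candidate GTVs against the CTAC GTV.

    Sign convention: a candidate larger / hotter than CTAC gives a positive
    percentage difference.
    """
    for p in PROVENANCES:
        if p not in suv_by_provenance:
            raise ValueError(f"missing provenance {p!r}")
    res = GtvResult(kind=kind)
    for p in PROVENANCES:
        arr = _suv_array(suv_by_provenance[p])
        gtv = threshold_gtv(arr, manual_volume, fraction)
        res.masks[p] = gtv
        res.suv_max[p] = float(arr[gtv].max())
        res.suv_mean[p] = float(arr[gtv].mean())
    ref = res.masks["CTAC"]
    ref_vol = int(ref.sum())
    for p in ("sCTAC", "MRAC"):
        res.dsc[p] = dice(res.masks[p], ref)
        dmean, dmax = distance_to_agreement(res.masks[p], ref, spacing_mm)
        res.dta_mean_mm[p] = dmean
        res.dta_max_mm[p] = dmax
        res.volume_pct_diff[p] = 100.0 * (int(res.masks[p].sum()) - ref_vol) / ref_vol
        res.suv_max_pct_diff[p] = (
            100.0 * (res.suv_max[p] - res.suv_max["CTAC"]) / res.suv_max["CTAC"]
        )
        res.suv_mean_pct_diff[p] = (
            100.0 * (res.suv_mean[p] - res.suv_mean["CTAC"]) / res.suv_mean["CTAC"]
        )
    return res
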