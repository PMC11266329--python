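"""Desk-scale PET acquisition simulation and OSEM reconstruction.

A 2D parallel-beam model applied slice by slice: line integrals are computed
with a Joseph-style ray tracer (bilinear interpolation at unit-pixel steps
along each ray) and the backprojector is the exact adjoint of that gather,
so the EM forward/back pair is matched.  One sinogram per patient is
simulated from the activity truth attenuated by the physical (CTAC) mu-map;
each candidate attenuation map then enters reconstruction only through its
attenuation-factor sinogram, exactly as in an attenuation-correction
comparison: same data, same geometry, different correction.

Deliberately not modelled: scatter, randoms, detector normalisation, decay,
point-spread-function resolution modelling and time of flight.  These are
orthogonal to how mu-map errors propagate into SUV errors, which is the
quantity this simulator exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

MM_PER_CM = 10.0
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam sampling: angles over 180 deg, radial bins across the FOV."""

    n_angles: int = 96
    n_radial_bins: int = 192
    radial_spacing_mm: float = 3.0

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles


@dataclass(frozen=True)
class ReconSettings:
    iterations: int = 4
    subsets: int = 16
    postfilter_fwhm_mm: float = 5.0
    epsilon: float = 1e-10

    def validate(self, geometry: ScanGeometry) -> None:
        if self.iterations < 1 or self.subsets < 1:
            raise ValueError("iterations and subsets must be >= 1")
        if geometry.n_angles % self.subsets != 0:
            raise ValueError(
                f"subsets ({self.subsets}) must divide n_angles ({geometry.n_angles})"
            )
        if self.postfilter_fwhm_mm < 0:
            raise ValueError("postfilter FWHM must be non-negative")


@dataclass
class Sinogram:
    """Projection-domain counts, shape (n_slices, n_angles, n_radial_bins)."""

    counts: np.ndarray
    count_scale: float
    noisy: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("sinogram counts must be finite and non-negative")


@dataclass
class SuvImage:
    """Reconstructed, post-filtered image in SUV units."""

    suv: np.ndarray
    provenance: str
    patient_id: str
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)


# --------------------------------------------------------------------------
# Matched Joseph-style projector pair
# --------------------------------------------------------------------------


class _Projector:
    """Precomputed ray sample coordinates for one (geometry, grid) pairing.

    Rays march in unit-pixel steps; the forward projection is a bilinear
    gather summed along each ray and scaled to image-units x cm, and the
    backprojection is its exact transpose (bilinear scatter-add).
    """

    def __init__(self, geometry: ScanGeometry, nx: int, ny: int, pixel_mm: float):
        diag_mm = float(np.hypot(nx, ny)) * pixel_mm
        if geometry.n_radial_bins * geometry.radial_spacing_mm < diag_mm:
            raise ValueError(
                "radial bins do not cover the image diagonal: "
                f"{geometry.n_radial_bins} x {geometry.radial_spacing_mm} mm "
                f"< {diag_mm:.0f} mm"
            )
        self.nx, self.ny = nx, ny
        self.pixel_mm = pixel_mm
        self.geometry = geometry
        n_steps = int(np.ceil(np.hypot(nx, ny))) + 1
        step = 1.0  # pixel units
        r = (
            (np.arange(geometry.n_radial_bins) - (geometry.n_radial_bins - 1) / 2.0)
            * geometry.radial_spacing_mm
            / pixel_mm
        )
        t = (np.arange(n_steps) - (n_steps - 1) / 2.0) * step
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        th = geometry.angles_rad
        # coords[a] has shape (n_bins, n_steps)
        cos, sin = np.cos(th), np.sin(th)
        self.xs = (
            cx
            + cos[:, None, None] * r[None, :, None]
            - sin[:, None, None] * t[None, None, :]
        ).astype(np.float64)
        self.ys = (
            cy
            + sin[:, None, None] * r[None, :, None]
            + cos[:, None, None] * t[None, None, :]
        ).astype(np.float64)
        self.integral_scale = step * pixel_mm / MM_PER_CM  # cm per sample
        self._weights_cache: dict[tuple[int, ...], tuple] = {}

    def _weights(self, angle_idx: tuple[int, ...]):
        """Bilinear corner indices/weights for the selected angles (cached)."""
        key = angle_idx
        if key in self._weights_cache:
            return self._weights_cache[key]
        sel = list(angle_idx)
        xs = self.xs[sel]
        ys = self.ys[sel]
        nx, ny = self.nx, self.ny
        inside = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
        x0 = np.clip(np.floor(xs).astype(np.intp), 0, nx - 2)
        y0 = np.clip(np.floor(ys).astype(np.intp), 0, ny - 2)
        fx = np.clip(xs - x0, 0.0, 1.0)
        fy = np.clip(ys - y0, 0.0, 1.0)
        w00 = (1 - fx) * (1 - fy) * inside
        w01 = (1 - fx) * fy * inside
        w10 = fx * (1 - fy) * inside
        w11 = fx * fy * inside
        base = x0 * ny + y0
        idx = (base, base + 1, base + ny, base + ny + 1)
        weights = (w00, w01, w10, w11)
        out = (idx, weights)
        if len(self._weights_cache) < 64:
            self._weights_cache[key] = out
        return out

    def forward(self, image2d: np.ndarray, angle_idx: Sequence[int] | None = None):
        """Line integrals, shape (n_selected_angles, n_radial_bins), units x cm."""
        if angle_idx is None:
            angle_idx = range(self.geometry.n_angles)
        idx, weights = self._weights(tuple(angle_idx))
        flat = np.ascontiguousarray(image2d, dtype=np.float64).ravel()
        acc = np.zeros(idx[0].shape, dtype=np.float64)
        for i, w in zip(idx, weights):
            acc += w * flat[i]
        return acc.sum(axis=2) * self.integral_scale

    def back(self, sino2d: np.ndarray, angle_idx: Sequence[int] | None = None):
        """Exact adjoint of :meth:`forward`; input (n_selected_angles, n_bins)."""
        if angle_idx is None:
            angle_idx = range(self.geometry.n_angles)
        idx, weights = self._weights(tuple(angle_idx))
        vals = np.asarray(sino2d, dtype=np.float64)[:, :, None]
        out = np.zeros(self.nx * self.ny, dtype=np.float64)
        for i, w in zip(idx, weights):
            out += np.bincount(
                i.ravel(), weights=(w * vals).ravel(), minlength=self.nx * self.ny
            )
        return out.reshape(self.nx, self.ny) * self.integral_scale


_projector_cache: dict[tuple, _Projector] = {}


def get_projector(geometry: ScanGeometry, nx: int, ny: int, pixel_mm: float) -> _Projector:
    key = (geometry.n_angles, geometry.n_radial_bins, geometry.radial_spacing_mm,
           nx, ny, float(pixel_mm))
    if key not in _projector_cache:
        _projector_cache[key] = _Projector(geometry, nx, ny, pixel_mm)
    return _projector_cache[key]


def _as_slices(volume: np.ndarray) -> np.ndarray:
    """Accept (nx, ny) or (nx, ny, nz); return a view iterable over z."""
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if vol.ndim != 3:
        raise ValueError("expected a 2D slice or a 3D (x, y, z) volume")
    return vol


def forward_project(
    image: np.ndarray, geometry: ScanGeometry, pixel_mm: float | None = None
) -> np.ndarray:
    """Parallel-beam line integrals per slice.

    Returns shape (n_slices, n_angles, n_radial_bins) in image-units x cm.
    """
    vol = _as_slices(image)
    if not np.all(np.isfinite(vol)):
        raise ValueError("image must be finite")
    if pixel_mm is None:
        pixel_mm = geometry.radial_spacing_mm
    proj = get_projector(geometry, vol.shape[0], vol.shape[1], pixel_mm)
    return np.stack([proj.forward(vol[:, :, k]) for k in range(vol.shape[2])])


def attenuation_sinogram(amap, geometry: ScanGeometry) -> np.ndarray:
    """Attenuation factors exp(-integral of mu dl) per (slice, angle, bin)."""
    if not amap.prepared:
        raise ValueError("attenuation map must be prepared before projection")
    if np.any(amap.lac_volume < 0):
        raise ValueError("LAC must be non-negative")
    line = forward_project(amap.lac_volume, geometry, amap.voxel_spacing_mm[0])
    return np.exp(-line)


def simulate_scan(
    activity: np.ndarray,
    true_map,
    geometry: ScanGeometry,
    count_scale: float = 50.0,
    noise: bool = True,
    seed: int = 0,
) -> Sinogram:
    """Simulate one attenuated acquisition from the activity truth.

    The expected sinogram is ``count_scale * att(true_map) * P(activity)``;
    with ``noise`` the counts are a Poisson draw under ``seed``.  The physical
    truth must be the CTAC map — degraded maps enter only at reconstruction.
    """
    if count_scale <= 0:
        raise ValueError("count_scale must be positive")
    if true_map.provenance != "CTAC":
        raise ValueError("the physical attenuation truth must be the CTAC map")
    att = attenuation_sinogram(true_map, geometry)
    mean = count_scale * att * forward_project(
        activity, geometry, true_map.voxel_spacing_mm[0]
    )
    if noise:
        counts = np.random.default_rng(seed).poisson(mean).astype(np.float64)
    else:
        counts = mean
    sino = Sinogram(counts, count_scale, noisy=noise, seed=seed if noise else None)
    sino.validate()
    return sino


def osem_reconstruct(
    sino: Sinogram,
    correction_map,
    geometry: ScanGeometry,
    settings: ReconSettings | None = None,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Ordered-subset EM with the correction map's attenuation factors folded
    into the system model.

    Subset k takes angles congruent to k modulo the subset count.  The image
    is initialised uniform positive wherever the total sensitivity is
    positive (or from ``initial`` if given); zero-sensitivity voxels are
    frozen at 0.  Exactly ``iterations x subsets`` multiplicative sub-updates
    are applied.
    """
    if settings is None:
        settings = ReconSettings()
    settings.validate(geometry)
    sino.validate()
    att = attenuation_sinogram(correction_map, geometry)
    counts = np.asarray(sino.counts, dtype=np.float64)
    if counts.ndim == 2:
        counts = counts[None]
    nx, ny, _ = _as_slices(correction_map.lac_volume).shape
    n_slices = counts.shape[0]
    proj = get_projector(geometry, nx, ny, correction_map.voxel_spacing_mm[0])
    subsets = [
        tuple(range(k, geometry.n_angles, settings.subsets))
        for k in range(settings.subsets)
    ]
    eps = settings.epsilon

    recon = np.zeros((nx, ny, n_slices), dtype=np.float64)
    for z in range(n_slices):
        att_z = att[z]
        y_z = counts[z]
        sens = [proj.back(att_z[list(s)], s) for s in subsets]
        total_sens = np.sum(sens, axis=0)
        alive = total_sens > 0
        if initial is not None:
            x = np.asarray(initial, dtype=np.float64)
            x = (x[:, :, z] if x.ndim == 3 else x).copy()
            x[~alive] = 0.0
        else:
            x = np.where(alive, 1.0, 0.0)
        for _ in range(settings.iterations):
            for s, sens_s in zip(subsets, sens):
                a = att_z[list(s)]
                ybar = a * proj.forward(x, s) + eps
                corr = proj.back(a * (y_z[list(s)] / ybar), s)
                upd = sens_s > 0
                x[upd] *= corr[upd] / sens_s[upd]
        x[~alive] = 0.0
        recon[:, :, z] = x
    return recon


def postfilter(
    volume: np.ndarray,
    fwhm_mm: float,
    spacing_mm: Sequence[float] = (3.0, 3.0, 3.0),
) -> np.ndarray:
    """Gaussian post-reconstruction filter, sigma = FWHM / 2.3548 per axis."""
    from scipy import ndimage

    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    vol = np.asarray(volume, dtype=np.float64)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / s for s in spacing_mm[: vol.ndim]]
    return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0)


def to_suv(
    recon: np.ndarray,
    count_scale: float,
    weight_kg: float,
    injected_dose_MBq: float,
    provenance: str = "CTAC",
    patient_id: str = "p00",
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> SuvImage:
    """Scale the reconstruction back to SUV units.

    The pipeline expresses the activity truth directly in SUV and folds the
    acquisition scale into ``count_scale``, so the SUV conversion (activity
    concentration x body mass / injected dose) reduces to dividing the
    count scale back out; weight and dose are validated as metadata.
    """
    if count_scale <= 0:
        raise ValueError("count_scale must be positive")
    if weight_kg <= 0 or injected_dose_MBq <= 0:
        raise ValueError("weight and injected dose must be positive")
    return SuvImage(
        np.asarray(recon, dtype=np.float64) / count_scale,
        provenance,
        patient_id,
        voxel_spacing_mm,
    )
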