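"""End-to-end study replica.

Orchestrates: seeded cohort generation -> three attenuation maps per patient
(CTAC ground truth, sCTAC with controlled bone errors, MRAC with bone
removed) -> one simulated acquisition per patient (attenuated by the CTAC
map) -> three OSEM reconstructions differing only in the correction map ->
whole-image / bone-region percentage-difference analysis, 40%-of-SUVmax GTV
delineation metrics, and the eight paired TOST equivalence comparisons
(2 candidate maps x 2 GTV kinds x {SUVmax, SUVmean}).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import attenuation, equivalence, metrics, phantoms, simulate
from .attenuation import AttenuationMap
from .phantoms import DigitalPatient
from .simulate import ReconSettings, ScanGeometry, SuvImage

log = logging.getLogger("petmrac")

CANDIDATES = ("sCTAC", "MRAC")
GTV_KINDS = ("primary", "nodal")
SUV_METRICS = ("suv_max", "suv_mean")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class CohortConfig:
    n_patients: int = 10
    n_primary: int = 9
    n_nodal: int = 5
    grid_shape: tuple[int, int, int] = (128, 128, 9)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    background_suv: float = 1.0
    hu_noise_sd: float = 10.0
    #: uniform scale on all anatomy (body axes, bone/lesion/pocket geometry);
    #: < 1 shrinks the phantom onto smaller grids for quick runs
    body_scale: float = 1.0


@dataclass
class SctErrorConfig:
    bone_hu_bias: float = -30.0
    bone_boundary_shift_mm: float = 0.0


@dataclass
class AcquisitionConfig:
    n_angles: int = 96
    n_radial_bins: int = 192
    radial_spacing_mm: float = 3.0
    count_scale: float = 50.0
    noise: bool = True
    iterations: int = 4
    subsets: int = 16
    postfilter_fwhm_mm: float = 5.0


@dataclass
class MetricsConfig:
    external_contour_suv: float = 0.05
    gtv_fraction: float = 0.4
    bone_hu_threshold: float = 200.0
    bone_min_component_voxels: int = 50


@dataclass
class StatsConfig:
    delta_petct: float = 12.0
    allowed_increase: float = 0.5
    base_alpha: float = 0.05
    n_tests: int = 8


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sct_error: SctErrorConfig = field(default_factory=SctErrorConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 1
    outdir: str = "petmrac_out"

    def validate(self) -> None:
        geo = self.geometry()
        self.recon_settings().validate(geo)
        if self.cohort.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.acquisition.count_scale <= 0:
            raise ValueError("count_scale must be positive")
        if not 0 < self.metrics.gtv_fraction < 1:
            raise ValueError("gtv_fraction must lie in (0, 1)")
        if self.stats.n_tests < 2:
            raise ValueError("n_tests must be >= 2")

    def geometry(self) -> ScanGeometry:
        a = self.acquisition
        return ScanGeometry(a.n_angles, a.n_radial_bins, a.radial_spacing_mm)

    def recon_settings(self) -> ReconSettings:
        a = self.acquisition
        return ReconSettings(a.iterations, a.subsets, a.postfilter_fwhm_mm)

    def phantom_spec(self) -> phantoms.PhantomSpec:
        c = self.cohort
        spec = phantoms.default_spec()
        s = float(c.body_scale)
        if s != 1.0:
            g = spec.body_geometry
            spec = dataclasses.replace(
                spec,
                body_geometry=dataclasses.replace(
                    g,
                    semi_axis_x_mm=g.semi_axis_x_mm * s,
                    semi_axis_y_mm=g.semi_axis_y_mm * s,
                    fat_thickness_mm=g.fat_thickness_mm * s,
                ),
                bone_sites=tuple(
                    dataclasses.replace(
                        b,
                        center_mm=(b.center_mm[0] * s, b.center_mm[1] * s),
                        radius_mm=b.radius_mm * s,
                    )
                    for b in spec.bone_sites
                ),
                lesion_specs=tuple(
                    dataclasses.replace(
                        l,
                        center_mm=tuple(x * s for x in l.center_mm),
                        diameter_mm=l.diameter_mm * s,
                    )
                    for l in spec.lesion_specs
                ),
                air_pockets=tuple(
                    dataclasses.replace(
                        p,
                        center_mm=tuple(x * s for x in p.center_mm),
                        radius_mm=p.radius_mm * s,
                    )
                    for p in spec.air_pockets
                ),
            )
        return dataclasses.replace(
            spec,
            grid_shape=tuple(c.grid_shape),
            voxel_spacing_mm=tuple(c.voxel_spacing_mm),
            background_suv=c.background_suv,
            hu_noise_sd=c.hu_noise_sd,
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in (sub or {}).items():
                if k not in fields:
                    raise ValueError(f"unknown config key {k!r} for {klass.__name__}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return klass(**kwargs)

        return cls(
            cohort=build(CohortConfig, d.get("cohort")),
            sct_error=build(SctErrorConfig, d.get("sct_error")),
            acquisition=build(AcquisitionConfig, d.get("acquisition")),
            metrics=build(MetricsConfig, d.get("metrics")),
            stats=build(StatsConfig, d.get("stats")),
            seed=int(d.get("seed", 1)),
            outdir=str(d.get("outdir", "petmrac_out")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# --------------------------------------------------------------------------
# Per-patient processing
# --------------------------------------------------------------------------


def build_attenuation_maps(
    patient: DigitalPatient,
    sct_error: SctErrorConfig,
    curve: attenuation.CalibrationCurve | None = None,
) -> dict[str, AttenuationMap]:
    """CTAC, sCTAC and MRAC maps for one patient, all prepared on the
    patient's own body contour with air pockets set to water."""
    pockets = patient.tissue_labels == phantoms.AIR_POCKET
    spacing = patient.voxel_spacing_mm

    def prep(lac, provenance):
        return attenuation.prepare_map(
            lac,
            patient.body_mask,
            pockets,
            voxel_spacing_mm=spacing,
            provenance=provenance,
        )

    ct_lac = attenuation.hu_to_lac(patient.hu_volume, curve)
    sct_hu = phantoms.make_sct_hu(
        patient,
        bone_hu_bias=sct_error.bone_hu_bias,
        bone_boundary_shift_mm=sct_error.bone_boundary_shift_mm,
        seed=(patient.seed + 1) % 2**31,
    )
    sct_lac = attenuation.hu_to_lac(sct_hu, curve)
    mrac_lac = attenuation.mrac_assign(phantoms.degrade_to_mrac_labels(patient))
    return {
        "CTAC": prep(ct_lac, "CTAC"),
        "sCTAC": prep(sct_lac, "sCTAC"),
        "MRAC": prep(mrac_lac, "MRAC"),
    }


def reconstruct_patient(
    patient: DigitalPatient,
    maps: dict[str, AttenuationMap],
    config: RunConfig,
) -> dict[str, SuvImage]:
    """Simulate one acquisition (CTAC truth) and reconstruct it once per
    candidate correction map; identical data, geometry and settings."""
    geo = config.geometry()
    settings = config.recon_settings()
    acq = config.acquisition
    sino = simulate.simulate_scan(
        patient.activity_truth,
        maps["CTAC"],
        geo,
        count_scale=acq.count_scale,
        noise=acq.noise,
        seed=(patient.seed + 2) % 2**31,
    )
    suvs: dict[str, SuvImage] = {}
    for prov in ("CTAC",) + CANDIDATES:
        recon = simulate.osem_reconstruct(sino, maps[prov], geo, settings)
        filtered = simulate.postfilter(
            recon, settings.postfilter_fwhm_mm, patient.voxel_spacing_mm
        )
        suvs[prov] = simulate.to_suv(
            filtered,
            acq.count_scale,
            patient.weight_kg,
            patient.injected_dose_MBq,
            provenance=prov,
            patient_id=patient.patient_id,
            voxel_spacing_mm=patient.voxel_spacing_mm,
        )
    return suvs


# --------------------------------------------------------------------------
# Study report
# --------------------------------------------------------------------------


@dataclass
class StudyReport:
    config: RunConfig
    gtv_table: pd.DataFrame  # one row per (patient, lesion)
    histograms: dict[tuple[str, str], metrics.DifferenceHistogram]
    region_mean_diff: dict[tuple[str, str], float]  # (region, candidate) -> %
    equivalence: list[equivalence.EquivalenceResult]
    warnings: list[str]
    config_hash: str = ""
    seed: int = 0

    def equivalence_table(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(e) for e in self.equivalence]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "region_mean_diff": {
                f"{region}/{cand}": v
                for (region, cand), v in self.region_mean_diff.items()
            },
            "equivalence": [dataclasses.asdict(e) for e in self.equivalence],
            "gtv_metrics": self.gtv_table.to_dict(orient="records"),
            "warnings": self.warnings,
        }


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full replica and collect every analysis output."""
    config.validate()
    t0 = time.time()
    cohort_cfg = config.cohort
    spec = config.phantom_spec()
    patients = phantoms.generate_cohort(
        spec,
        cohort_cfg.n_patients,
        cohort_cfg.n_primary,
        cohort_cfg.n_nodal,
        config.seed,
    )
    log.info("generated %d patients in %.1f s", len(patients), time.time() - t0)

    gtv_rows = []
    diff_maps: dict[tuple[str, str], list[metrics.PercentDiffResult]] = {
        (region, cand): [] for region in ("whole", "bone") for cand in CANDIDATES
    }
    warn_log: list[str] = []

    for patient in patients:
        t1 = time.time()
        stage = "maps"
        try:
            maps = build_attenuation_maps(patient, config.sct_error)
            stage = "reconstruction"
            suvs = reconstruct_patient(patient, maps, config)
            stage = "evaluation"
            contour = metrics.external_contour(
                suvs["CTAC"], config.metrics.external_contour_suv
            )
            bmask = metrics.bone_mask(
                patient.hu_volume,
                config.metrics.bone_hu_threshold,
                config.metrics.bone_min_component_voxels,
            )
            if not np.any(bmask):
                warn_log.append(f"{patient.patient_id}: empty bone mask")
            for cand in CANDIDATES:
                diff_maps[("whole", cand)].append(
                    metrics.percent_diff_map(suvs[cand], suvs["CTAC"], contour)
                )
                bone_in = bmask & contour
                if np.any(bone_in):
                    diff_maps[("bone", cand)].append(
                        metrics.percent_diff_map(suvs[cand], suvs["CTAC"], bone_in)
                    )
            for manual, kind in patient.manual_volumes:
                res = metrics.gtv_metrics(
                    suvs,
                    manual,
                    patient.voxel_spacing_mm,
                    kind=kind,
                    fraction=config.metrics.gtv_fraction,
                )
                for cand in CANDIDATES:
                    gtv_rows.append(
                        {
                            "patient_id": patient.patient_id,
                            "kind": kind,
                            "method": cand,
                            "dsc": res.dsc[cand],
                            "dta_mean_mm": res.dta_mean_mm[cand],
                            "dta_max_mm": res.dta_max_mm[cand],
                            "volume_pct_diff": res.volume_pct_diff[cand],
                            "suv_max": res.suv_max[cand],
                            "suv_mean": res.suv_mean[cand],
                            "suv_max_ctac": res.suv_max["CTAC"],
                            "suv_mean_ctac": res.suv_mean["CTAC"],
                            "suv_max_pct_diff": res.suv_max_pct_diff[cand],
                            "suv_mean_pct_diff": res.suv_mean_pct_diff[cand],
                        }
                    )
        except Exception as exc:
            raise RuntimeError(
                f"study aborted at stage {stage!r} for patient "
                f"{patient.patient_id}: {exc}"
            ) from exc
        log.info("patient %s done in %.1f s", patient.patient_id, time.time() - t1)

    gtv_table = pd.DataFrame(gtv_rows)

    histograms = {
        key: metrics.bin_histogram(maps_)
        for key, maps_ in diff_maps.items()
        if maps_
    }
    region_mean = {
        key: float(np.mean([dm.mean for dm in maps_]))
        for key, maps_ in diff_maps.items()
        if maps_
    }

    # TOST equivalence: 2 candidates x 2 GTV kinds x {SUVmax, SUVmean}
    st = config.stats
    margin = equivalence.derive_margin(st.delta_petct, st.allowed_increase)
    _, alpha_exact = equivalence.corrected_alpha(st.n_tests, st.base_alpha)
    eq_results = []
    for cand in CANDIDATES:
        for kind in GTV_KINDS:
            sub = gtv_table[
                (gtv_table["method"] == cand) & (gtv_table["kind"] == kind)
            ]
            for metric_name in SUV_METRICS:
                label = f"{cand}/{kind}/{metric_name}"
                diffs = sub[f"{metric_name}_pct_diff"].to_numpy()
                if diffs.size < 2:
                    warn_log.append(f"{label}: fewer than 2 lesions, TOST skipped")
                    continue
                res = equivalence.tost_paired(diffs, margin, alpha_exact, label)
                if res.degenerate_se:
                    warn_log.append(f"{label}: degenerate SE = 0")
                eq_results.append(res)

    log.info("study complete in %.1f s", time.time() - t0)
    return StudyReport(
        config=config,
        gtv_table=gtv_table,
        histograms=histograms,
        region_mean_diff=region_mean,
        equivalence=eq_results,
        warnings=warn_log,
        config_hash=config.config_hash(),
        seed=config.seed,
    )


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _delineation_summary(gtv_table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE (min, max) per metric per GTV kind per method."""
    rows = []
    for metric_name in ("dsc", "dta_mean_mm", "dta_max_mm", "volume_pct_diff"):
        for kind in GTV_KINDS:
            for method in CANDIDATES:
                sub = gtv_table[
                    (gtv_table["kind"] == kind) & (gtv_table["method"] == method)
                ][metric_name]
                if sub.empty:
                    rows.append(
                        {"metric": metric_name, "kind": kind, "method": method,
                         "n": 0, "mean": np.nan, "se": np.nan,
                         "min": np.nan, "max": np.nan, "absent": True}
                    )
                    continue
                n = len(sub)
                rows.append(
                    {
                        "metric": metric_name,
                        "kind": kind,
                        "method": method,
                        "n": n,
                        "mean": float(sub.mean()),
                        "se": float(sub.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                        "min": float(sub.min()),
                        "max": float(sub.max()),
                        "absent": False,
                    }
                )
    return pd.DataFrame(rows)


def render_tables(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write the study outputs: per-lesion CSV, delineation summary,
    histogram CSVs, equivalence table, full JSON report and a text summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gtv_metrics"] = out / "gtv_metrics.csv"
    report.gtv_table.to_csv(paths["gtv_metrics"], index=False)

    summary = _delineation_summary(report.gtv_table)
    paths["delineation_summary"] = out / "delineation_summary.csv"
    summary.to_csv(paths["delineation_summary"], index=False)

    for (region, cand), hist in report.histograms.items():
        p = out / f"histogram_{region}_{cand}.csv"
        pd.DataFrame(
            {
                "bin_center_pct": hist.bin_centers,
                "mean_fraction_pct": hist.mean_per_bin,
                "se_fraction_pct": hist.se_per_bin,
            }
        ).to_csv(p, index=False)
        paths[f"histogram_{region}_{cand}"] = p

    paths["equivalence"] = out / "equivalence.csv"
    report.equivalence_table().to_csv(paths["equivalence"], index=False)

    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(report.to_json_dict(), indent=2))

    lines = [
        f"petmrac study report (seed {report.seed}, config {report.config_hash})",
        "",
        "Whole-image / bone-region mean SUV differences to CTAC (%):",
    ]
    for (region, cand), v in sorted(report.region_mean_diff.items()):
        lines.append(f"  {region:5s} {cand:6s} {v:+.2f}%")
    lines.append("")
    lines.append("Equivalence (TOST, margin "
                 f"{report.equivalence[0].margin:.1f}%, alpha "
                 f"{report.equivalence[0].alpha_corrected:.4f}):"
                 if report.equivalence else "Equivalence: no tests run")
    for e in report.equivalence:
        verdict = "equivalent" if e.equivalent else "NOT equivalent"
        lines.append(
            f"  {e.label:24s} n={e.n:2d} mean={e.mean_diff:+6.2f}% "
            f"se={e.se_diff:5.2f}% p={e.p_value:.4f} -> {verdict}"
        )
    if report.warnings:
        lines += ["", "Warnings:"] + [f"  {w}" for w in report.warnings]
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
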