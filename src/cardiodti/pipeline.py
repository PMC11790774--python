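"""End-to-end orchestration: simulate → denoise → fit → angles → segment → cohort.

A single :class:`PipelineConfig` drives every stage.  All randomness derives
from the master seed (per-subject noise seeds are drawn deterministically
from it), so a given configuration reproduces its report byte for byte.
Every stage logs its quality-control counts — clamped eigenvalues, voxels
excluded by the radial-fiber guard, annulus violations — since silent voxel
loss is the classic failure mode of this kind of analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cardiodti import frame as frame_mod
from cardiodti import segments as seg_mod
from cardiodti.denoise import denoise_local_pca
from cardiodti.phantom import PhantomSpec, disease_spec, make_cohort
from cardiodti.stats import CohortModel, CohortResults
from cardiodti.tensor import DiffusionTensorModel

logger = logging.getLogger("cardiodti.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one cohort simulation + analysis run."""

    n_control: int = 3
    n_disease: int = 3
    snr: float = 50.0
    between_subject_sd: float = 0.05
    master_seed: int = 0
    denoise: bool = True
    denoise_window: int = 5
    n_transmural_bins: int = 10
    neutral_band_deg: float = 30.0
    roc_metrics: tuple = ("fa", "c_planar", "c_spherical")
    regressions: tuple = (("lv_mass_index", "c_planar"),)
    weighted_fit: bool = False
    save_maps: bool = False
    out_dir: str = "cardiodti_out"
    phantom_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "roc_metrics" in raw:
            raw["roc_metrics"] = tuple(raw["roc_metrics"])
        if "regressions" in raw:
            raw["regressions"] = tuple(tuple(p) for p in raw["regressions"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["roc_metrics"] = list(self.roc_metrics)
        d["regressions"] = [list(p) for p in self.regressions]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def control_spec(self) -> PhantomSpec:
        return PhantomSpec(snr=self.snr, **self.phantom_overrides)

    def disease_spec(self) -> PhantomSpec:
        return disease_spec(self.control_spec())


def process_subject(dataset, config: PipelineConfig, tibial_length: float) -> dict:
    """Run denoise → fit → angles → segmentation for one subject.

    Returns a flat metric dictionary (global means, ROI means for the ROC
    metrics and |E2A|, helicity slopes, mass) plus QC counts.
    """
    dwi = dataset.dwi
    if config.denoise:
        dwi = denoise_local_pca(dwi, window=config.denoise_window, mask=dataset.mask)

    fit = DiffusionTensorModel(dwi, dataset.gtab, dataset.mask).fit(weighted=config.weighted_fit)
    eigs = fit.eigensystem
    maps = fit.maps

    depth, depth_valid, wall_table = frame_mod.depth_from_mask(dataset.mask, dataset.affine)
    fr = frame_mod.local_frame(dataset.mask, dataset.affine)
    ha, n_ha_excl = frame_mod.helix_angle(eigs.e1, fr)
    e2a, n_e2a_excl = frame_mod.sheetlet_angle(eigs.e1, eigs.e2, fr)

    wall_mm = float(
        np.average(wall_table["wall_thickness_mm"], weights=wall_table["n_voxels"])
    )
    ha_ring = np.where(depth_valid, ha, np.nan)
    profile = frame_mod.transmural_profile(
        ha_ring, depth, wall_mm, n_bins=config.n_transmural_bins
    )
    fractions = frame_mod.ha_proportions(ha_ring, neutral_band=config.neutral_band_deg)

    spec = dataset.spec
    model = seg_mod.aha17(dataset.mask, dataset.affine, spec.rv_insertion_azimuth)
    metric_maps = dict(maps.as_dict())
    metric_maps["abs_e2a"] = e2a
    metric_maps["ha"] = ha
    summary = seg_mod.segment_summary(metric_maps, model)
    mass_mg, mass_index = seg_mod.lv_mass(dataset.mask, [spec.voxel_size] * 3, tibial_length)

    row: dict = {}
    glob = summary[summary.region == "global"].set_index("metric")["mean"]
    for metric in ("md", "fa", "c_linear", "c_planar", "c_spherical", "abs_e2a"):
        row[metric] = float(glob[metric])
    for roi in seg_mod.ROI_SEGMENTS:
        roi_means = summary[summary.region == roi].set_index("metric")["mean"]
        for metric in ("fa", "c_planar", "c_spherical", "abs_e2a"):
            row[f"{metric}_{roi}"] = float(roi_means[metric])
    row.update(
        {
            "neutral_ha_fraction": fractions["neutral"],
            "helicity_slope_mm": profile.slope_mm,
            "helicity_slope_pct": profile.slope_pct,
            "wall_thickness_mm": wall_mm,
            "lv_mass_mg": mass_mg,
            "lv_mass_index": mass_index,
            "qc_clamped_eigenvalues": eigs.n_clamped,
            "qc_radial_guard_excluded": n_ha_excl,
            "qc_e2a_excluded": n_e2a_excl,
        }
    )
    logger.info(
        "subject QC: clamped=%d radial-guard=%d e2a-excluded=%d",
        eigs.n_clamped,
        n_ha_excl,
        n_e2a_excl,
    )
    return row, summary, profile, fit


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig):
    """Execute the full cohort pipeline and write the artifact tree.

    Returns ``(CohortResults, metrics DataFrame, manifest DataFrame)``.
    Output files: per-subject metric tables, the cohort report JSON, the
    manifest CSV, and a SHA-256 hash manifest of everything written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    try:
        datasets, manifest = make_cohort(
            config.control_spec(),
            config.disease_spec(),
            config.n_control,
            config.n_disease,
            between_subject_sd=config.between_subject_sd,
            seed=config.master_seed,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc

    rows = []
    for ds, (_, mrow) in zip(datasets, manifest.iterrows()):
        sid = mrow["subject_id"]
        try:
            row, summary, profile, fit = process_subject(ds, config, mrow["tibial_length_mm"])
        except Exception as exc:  # noqa: BLE001
            _write_hashes(out, written)
            raise StageError("subject:" + sid, str(exc)) from exc
        row["subject_id"] = sid
        rows.append(row)
        if config.save_maps:
            from cardiodti.io import save_volume

            sub_dir = out / sid
            sub_dir.mkdir(exist_ok=True)
            for name, vol in fit.maps.as_dict().items():
                p = sub_dir / f"{name}.nii"
                save_volume(np.nan_to_num(vol), ds.affine, p)
                written.append(p)
            p = sub_dir / "segments.csv"
            summary.to_csv(p, index=False)
            written.append(p)
            p = sub_dir / "transmural_profile.csv"
            profile.to_frame().to_csv(p, index=False)
            written.append(p)

    metrics = pd.DataFrame(rows)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    written.append(metrics_path)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    written.append(manifest_path)

    try:
        merged = manifest.merge(metrics, on="subject_id")
        qc_cols = [c for c in merged.columns if c.startswith("qc_")]
        model = CohortModel(merged.drop(columns=["subject_id"] + qc_cols))
        results = model.fit(
            roc_metrics=config.roc_metrics, regressions=config.regressions
        )
    except Exception as exc:  # noqa: BLE001
        _write_hashes(out, written)
        raise StageError("cohort", str(exc)) from exc

    report_path = out / "report.json"
    results.to_json(report_path)
    written.append(report_path)
    _write_hashes(out, written)
    return results, metrics, manifest


def _write_hashes(out: Path, written: list[Path]) -> None:
    hashes = {str(p.relative_to(out)): _sha256(p) for p in written if p.exists()}
    with open(out / "hashes.json", "w") as fh:
        json.dump(hashes, fh, indent=2, sort_keys=True)
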