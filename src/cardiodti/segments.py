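"""AHA 17-segment model of the left ventricle, ROI grouping and LV mass.

The long axis is split into basal/mid/apical thirds by the extent of the
slices that still enclose a cavity; slices below the endocardial apex form
the apical cap (segment 17).  Basal and mid rings are divided into six 60°
azimuthal sectors and the apical ring into four 90° sectors, all referenced
to the anterior right-ventricular insertion azimuth.  Segments advance with
increasing counterclockwise azimuth starting at that reference.

Region-of-interest groups follow the standard reporting convention:
anterior {1, 7, 13}, septal {2, 3, 8, 9, 14}, inferior {4, 10, 15},
lateral {5, 6, 11, 12, 16}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

ROI_SEGMENTS = {
    "anterior": frozenset({1, 7, 13}),
    "septal": frozenset({2, 3, 8, 9, 14}),
    "inferior": frozenset({4, 10, 15}),
    "lateral": frozenset({5, 6, 11, 12, 16}),
}

MYOCARDIAL_DENSITY_MG_PER_MM3 = 1.05  # 1.05 g/cm³


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentModel:
    """Per-voxel AHA label volume (1–17, 0 outside the myocardium)."""

    labels: np.ndarray
    roi_map: dict[str, frozenset]
    apex_excluded: bool = True  # segment 17 excluded from transmural metrics

    def segment_mask(self, segment: int) -> np.ndarray:
        return self.labels == segment

    def roi_mask(self, roi: str) -> np.ndarray:
        return np.isin(self.labels, list(self.roi_map[roi]))


def aha17(
    mask: np.ndarray,
    affine: np.ndarray,
    rv_insertion_azimuth: float,
    long_axis: np.ndarray | None = None,
) -> SegmentModel:
    """Partition a myocardial mask into the 17 AHA segments.

    ``rv_insertion_azimuth`` (degrees, world frame, counterclockwise from +x)
    anchors the sector boundaries; it must be supplied explicitly — there is
    no defensible default on real data, and the phantom knows its own.
    """
    if rv_insertion_azimuth is None:
        raise SegmentationError("rv_insertion_azimuth is required")
    mask = np.asarray(mask, dtype=bool)
    slices_with_mask = np.flatnonzero(mask.any(axis=(0, 1)))
    if len(slices_with_mask) < 3:
        raise SegmentationError("mask must span at least 3 slices along the long axis")
    if long_axis is None:
        long_axis = affine[:3, 2] / np.linalg.norm(affine[:3, 2])
    if long_axis[2] < 0:
        raise SegmentationError("long axis must point apex -> base (+z slice order)")

    # ring slices = slices whose myocardium encloses a cavity; the rest of the
    # masked extent (below the endocardial apex) is the apical cap
    has_cavity = np.zeros(mask.shape[2], dtype=bool)
    for sl in slices_with_mask:
        filled = ndimage.binary_fill_holes(mask[:, :, sl])
        has_cavity[sl] = bool((filled & ~mask[:, :, sl]).any())
    ring_slices = np.flatnonzero(has_cavity)
    if len(ring_slices) < 3:
        raise SegmentationError("need >= 3 cavity-bearing slices for basal/mid/apical thirds")

    lo, hi = ring_slices.min(), ring_slices.max()
    # equal thirds of the cavity-bearing extent; base is the high-z end
    edges = np.linspace(lo, hi + 1, 4)
    labels = np.zeros(mask.shape, dtype=np.int16)
    sx, sy = np.linalg.norm(affine[:3, 0]), np.linalg.norm(affine[:3, 1])

    for sl in slices_with_mask:
        sl_mask = mask[:, :, sl]
        ii, jj = np.nonzero(sl_mask)
        if not has_cavity[sl]:
            labels[ii, jj, sl] = 17
            continue
        filled = ndimage.binary_fill_holes(sl_mask)
        ci, cj = np.nonzero(filled)
        cx, cy = ci.mean(), cj.mean()
        wx = (ii - cx) * sx
        wy = (jj - cy) * sy
        az = (np.degrees(np.arctan2(wy, wx)) - rv_insertion_azimuth) % 360.0
        if sl >= edges[2]:  # basal third
            seg = 1 + np.floor(az / 60.0).astype(int)
        elif sl >= edges[1]:  # mid third
            seg = 7 + np.floor(az / 60.0).astype(int)
        else:  # apical third
            seg = 13 + np.floor(az / 90.0).astype(int)
        labels[ii, jj, sl] = seg

    return SegmentModel(labels=labels, roi_map=dict(ROI_SEGMENTS))


def lv_mass(mask: np.ndarray, voxel_size, tibial_length: float):
    """LV mass (mg) and tibial-length-normalized mass index (mg/mm).

    Mass is myocardial volume × density 1.05 g/cm³ (= 1.05 mg/mm³).
    """
    if tibial_length <= 0:
        raise ValueError("tibial_length must be positive")
    mask = np.asarray(mask, dtype=bool)
    voxel_volume = float(np.prod(np.asarray(voxel_size, dtype=float)))
    n = int(mask.sum())
    if n == 0:
        import warnings

        warnings.warn("empty myocardial mask: LV mass is 0", stacklevel=2)
    mass_mg = n * voxel_volume * MYOCARDIAL_DENSITY_MG_PER_MM3
    return mass_mg, mass_mg / tibial_length


def segment_summary(
    maps: dict[str, np.ndarray],
    model: SegmentModel,
    transmural_metrics: tuple = (),
) -> pd.DataFrame:
    """Mean of each metric per segment, per ROI and globally.

    Metrics named in ``transmural_metrics`` exclude the apical cap (segment
    17) from their ROI and global summaries, mirroring the convention for
    transmural-profile-based quantities.  Empty segments yield missing
    values, never zeros.
    """
    rows = []
    labels = model.labels
    for metric, vol in maps.items():
        exclude_apex = metric in transmural_metrics or model.apex_excluded
        max_seg = 16 if exclude_apex else 17
        for seg in range(1, 18):
            sel = (labels == seg) & np.isfinite(vol)
            rows.append(
                {
                    "metric": metric,
                    "region": f"segment_{seg}",
                    "mean": float(vol[sel].mean()) if sel.any() else np.nan,
                    "n_voxels": int(sel.sum()),
                }
            )
        for roi, segs in model.roi_map.items():
            sel = np.isin(labels, [s for s in segs if s <= max_seg]) & np.isfinite(vol)
            rows.append(
                {
                    "metric": metric,
                    "region": roi,
                    "mean": float(vol[sel].mean()) if sel.any() else np.nan,
                    "n_voxels": int(sel.sum()),
                }
            )
        sel = (labels >= 1) & (labels <= max_seg) & np.isfinite(vol)
        rows.append(
            {
                "metric": metric,
                "region": "global",
                "mean": float(vol[sel].mean()) if sel.any() else np.nan,
                "n_voxels": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def percentage_difference(summary_disease: pd.DataFrame, summary_control: pd.DataFrame) -> pd.DataFrame:
    """Per-region percentage difference of group means,
    100 × (mean_disease − mean_control) / mean_control."""
    merged = summary_disease.merge(
        summary_control, on=["metric", "region"], suffixes=("_disease", "_control")
    )
    merged["pct_difference"] = (
        100.0
        * (merged["mean_disease"] - merged["mean_control"])
        / merged["mean_control"]
    )
    return merged[["metric", "region", "mean_disease", "mean_control", "pct_difference"]]
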