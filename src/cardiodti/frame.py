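"""Local wall coordinate system, transmural depth, helix and sheetlet angles.

The left ventricle is treated as a roughly axisymmetric shell around a long
axis pointing from apex to base.  Each myocardial voxel carries an orthonormal
triad: circumferential ``c_hat``, longitudinal ``l_hat`` (apex→base) and
radial ``r_hat`` (endo→epi).  The helix angle (HA) is the elevation of the
primary diffusion eigenvector within the wall tangent plane relative to the
circumferential direction; the absolute sheetlet angle (|E2A|) is the
elevation of the secondary eigenvector out of the in-wall cross-fiber
direction.  Transmural depth is 0 at the endocardium and 1 at the epicardium.

Sign convention: positive HA means the fiber tilts toward the base while
advancing counterclockwise as viewed from the base (right-handed endocardial
helix positive), the conventional endo-positive/epi-negative display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask

RADIAL_GUARD = 0.95  # |e1·r̂| above this → projection unstable, voxel excluded


class ProfileError(ValueError):
    """Too few populated depth bins to form a transmural profile."""


@dataclass
class CardiacFrameField:
    """Per-voxel wall coordinate triad plus transmural geometry.

    ``c_hat``, ``l_hat``, ``r_hat`` have shape ``(*vol, 3)``; ``valid`` marks
    voxels where the triad is defined (mask voxels off the long axis).
    """

    c_hat: np.ndarray
    l_hat: np.ndarray
    r_hat: np.ndarray
    depth: np.ndarray | None = None
    valid: np.ndarray | None = None
    wall_thickness: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class TransmuralProfile:
    """Binned transmural HA course and its fitted slopes (helicity)."""

    bin_centers: np.ndarray  # normalized depth
    bin_means: np.ndarray  # degrees
    bin_counts: np.ndarray
    slope_mm: float  # degrees per mm of wall
    slope_pct: float  # degrees per percent wall thickness
    wall_thickness_mm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.bin_centers,
                "mean_ha_deg": self.bin_means,
                "n_voxels": self.bin_counts,
            }
        )


# ---------------------------------------------------------------------------
# transmural depth


def _rasterize(poly_mm: np.ndarray, affine_2d: tuple, shape) -> np.ndarray:
    """Polygon in world mm -> boolean in-slice mask over voxel centers."""
    ox, oy, sx, sy = affine_2d
    ij = np.column_stack([(poly_mm[:, 0] - ox) / sx, (poly_mm[:, 1] - oy) / sy])
    return polygon2mask(shape, ij)


def transmural_depth(
    mask: np.ndarray,
    contours: dict[int, dict[str, np.ndarray]],
    affine: np.ndarray,
    n_sectors: int = 12,
):
    """Normalized transmural depth from traced endo/epi contours.

    Per slice the contours are rasterized; each in-annulus voxel gets
    ``d = dist_endo / (dist_endo + dist_epi)`` from Euclidean distance
    transforms (in mm) to the cavity and to the outside of the epicardium.
    Mask voxels outside the contour annulus are flagged and excluded.

    Returns ``(depth, valid, wall_table, n_excluded)`` where ``wall_table``
    lists per-slice, per-angular-sector wall thickness estimates
    ``dist_endo + dist_epi`` in mm.
    """
    mask = np.asarray(mask, dtype=bool)
    sx, sy = np.linalg.norm(affine[:3, 0]), np.linalg.norm(affine[:3, 1])
    ox, oy = affine[0, 3], affine[1, 3]
    depth = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    rows = []
    n_excluded = 0
    for sl in range(mask.shape[2]):
        sl_mask = mask[:, :, sl]
        if not sl_mask.any():
            continue
        if sl not in contours:
            n_excluded += int(sl_mask.sum())
            continue
        endo_poly = contours[sl]["endo"]
        epi_poly = contours[sl]["epi"]
        cavity = _rasterize(endo_poly, (ox, oy, sx, sy), sl_mask.shape)
        epi_region = _rasterize(epi_poly, (ox, oy, sx, sy), sl_mask.shape)
        annulus = epi_region & ~cavity
        outside = ~epi_region
        # distance (mm) to the nearest cavity / outside pixel; the surface
        # itself lies ~half a pixel closer than that pixel's center
        px = 0.5 * (sx + sy)
        d_endo = ndimage.distance_transform_edt(~cavity, sampling=(sx, sy)) - 0.5 * px
        d_epi = ndimage.distance_transform_edt(~outside, sampling=(sx, sy)) - 0.5 * px
        d_endo = np.clip(d_endo, 0.0, None)
        d_epi = np.clip(d_epi, 0.0, None)
        ok = sl_mask & annulus
        n_excluded += int((sl_mask & ~annulus).sum())
        total = d_endo + d_epi
        with np.errstate(invalid="ignore"):
            depth[:, :, sl][ok] = d_endo[ok] / total[ok]
        valid[:, :, sl] |= ok
        # sector-wise wall thickness around the cavity centroid
        ii, jj = np.nonzero(ok)
        if len(ii) == 0:
            continue
        ci, cj = np.nonzero(epi_region)
        cx, cy = ci.mean(), cj.mean()
        az = np.degrees(np.arctan2((jj - cy) * sy, (ii - cx) * sx)) % 360.0
        sector = np.floor(az / (360.0 / n_sectors)).astype(int)
        for s in range(n_sectors):
            sel = sector == s
            if sel.any():
                rows.append(
                    {
                        "slice": sl,
                        "sector": s,
                        "wall_thickness_mm": float(total[ii[sel], jj[sel]].mean()),
                        "n_voxels": int(sel.sum()),
                    }
                )
    wall_table = pd.DataFrame(rows)
    return depth, valid, wall_table, n_excluded


def depth_from_mask(mask: np.ndarray, affine: np.ndarray, n_sectors: int = 12):
    """Contour-free variant of :func:`transmural_depth` for mask-only input.

    Per slice, the cavity is recovered as the hole enclosed by the myocardium
    and the outside as the complement of the filled mask.  Slices without a
    cavity (the apical cap) yield no depth and are left invalid.
    """
    mask = np.asarray(mask, dtype=bool)
    sx, sy = np.linalg.norm(affine[:3, 0]), np.linalg.norm(affine[:3, 1])
    depth = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    rows = []
    for sl in range(mask.shape[2]):
        sl_mask = mask[:, :, sl]
        if not sl_mask.any():
            continue
        filled = ndimage.binary_fill_holes(sl_mask)
        cavity = filled & ~sl_mask
        if not cavity.any():
            continue
        outside = ~filled
        px = 0.5 * (sx + sy)
        d_endo = ndimage.distance_transform_edt(~cavity, sampling=(sx, sy)) - 0.5 * px
        d_epi = ndimage.distance_transform_edt(~outside, sampling=(sx, sy)) - 0.5 * px
        d_endo = np.clip(d_endo, 0.0, None)
        d_epi = np.clip(d_epi, 0.0, None)
        total = d_endo + d_epi
        depth[:, :, sl][sl_mask] = d_endo[sl_mask] / total[sl_mask]
        valid[:, :, sl] = sl_mask
        ii, jj = np.nonzero(sl_mask)
        ci, cj = np.nonzero(filled)
        cx, cy = ci.mean(), cj.mean()
        az = np.degrees(np.arctan2((jj - cy) * sy, (ii - cx) * sx)) % 360.0
        sector = np.floor(az / (360.0 / n_sectors)).astype(int)
        for s in range(n_sectors):
            sel = sector == s
            if sel.any():
                rows.append(
                    {
                        "slice": sl,
                        "sector": s,
                        "wall_thickness_mm": float(total[ii[sel], jj[sel]].mean()),
                        "n_voxels": int(sel.sum()),
                    }
                )
    return depth, valid, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# local frame


def mask_long_axis(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Long-axis unit vector (world frame) as the mask's principal axis."""
    idx = np.column_stack(np.nonzero(mask))
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    centered = world - world.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient apex -> base: positive z by convention when undetermined
    if axis[2] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def local_frame(mask: np.ndarray, affine: np.ndarray, long_axis: np.ndarray | None = None) -> CardiacFrameField:
    """Build the circumferential/longitudinal/radial triad per mask voxel.

    ``l_hat`` is the long-axis unit vector (slice-stack normal by default for
    axis-aligned acquisitions; pass the mask principal axis for oblique data).
    ``r_hat`` points from the per-slice mask centroid through the voxel,
    orthogonalized against ``l_hat``; ``c_hat = l_hat × r_hat`` closes a
    right-handed triad.  Voxels at a slice centroid (zero radial component)
    are excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    if long_axis is None:
        long_axis = affine[:3, 2] / np.linalg.norm(affine[:3, 2])
    l_vec = np.asarray(long_axis, dtype=float)
    l_vec = l_vec / np.linalg.norm(l_vec)

    shape = mask.shape
    c_hat = np.zeros(shape + (3,))
    l_hat = np.zeros(shape + (3,))
    r_hat = np.zeros(shape + (3,))
    valid = np.zeros(shape, dtype=bool)

    for sl in range(shape[2]):
        sl_mask = mask[:, :, sl]
        if not sl_mask.any():
            continue
        ii, jj = np.nonzero(sl_mask)
        idx = np.column_stack([ii, jj, np.full_like(ii, sl)])
        world = idx @ affine[:3, :3].T + affine[:3, 3]
        centroid = world.mean(axis=0)
        rad = world - centroid
        rad -= np.outer(rad @ l_vec, l_vec)  # Gram–Schmidt vs long axis
        norms = np.linalg.norm(rad, axis=1)
        ok = norms > 1e-9
        rad[ok] /= norms[ok, None]
        circ = np.cross(l_vec, rad)
        c_hat[ii[ok], jj[ok], sl] = circ[ok]
        r_hat[ii[ok], jj[ok], sl] = rad[ok]
        l_hat[ii[ok], jj[ok], sl] = l_vec
        valid[ii[ok], jj[ok], sl] = True

    return CardiacFrameField(c_hat=c_hat, l_hat=l_hat, r_hat=r_hat, valid=valid)


# ---------------------------------------------------------------------------
# angle maps


def helix_angle(e1: np.ndarray, frame: CardiacFrameField):
    """Helix-angle map in degrees, range (−90, 90].

    ``e1`` is projected onto the wall tangent plane span(ĉ, l̂); its sign is
    chosen so the circumferential component is non-negative (eigenvectors are
    axes, not arrows).  Voxels whose fiber is nearly radial
    (|e1·r̂| > 0.95) or whose tangent projection vanishes are excluded; the
    exclusion count is returned alongside the map.
    """
    dot_r = np.sum(e1 * frame.r_hat, axis=-1)
    p = e1 - dot_r[..., None] * frame.r_hat
    pc = np.sum(p * frame.c_hat, axis=-1)
    pl = np.sum(p * frame.l_hat, axis=-1)
    # antipodal symmetry: flip so the circumferential component is >= 0
    flip = pc < 0
    pc = np.where(flip, -pc, pc)
    pl = np.where(flip, -pl, pl)
    norm = np.hypot(pc, pl)
    base_valid = frame.valid if frame.valid is not None else np.ones(dot_r.shape, bool)
    guard = np.abs(dot_r) <= RADIAL_GUARD
    ok = base_valid & guard & (norm > 1e-12)
    n_excluded = int((base_valid & ~(guard & (norm > 1e-12))).sum())
    ha = np.full(dot_r.shape, np.nan)
    with np.errstate(invalid="ignore"):
        ha[ok] = np.degrees(np.arctan2(pl[ok], pc[ok]))
    # pc >= 0 confines arctan2 to [-90, 90]; fold -90 onto +90
    ha[ha <= -90.0] = 90.0
    return ha, n_excluded


def sheetlet_angle(e1: np.ndarray, e2: np.ndarray, frame: CardiacFrameField):
    """Absolute sheetlet-angle map |E2A| in degrees, range [0, 90].

    The in-wall cross-fiber direction is ``ŵ = normalize(r̂ × e1)``; the
    wall-normal direction within the cross-fiber plane is
    ``n̂ = normalize(e1 × ŵ)``.  |E2A| is the elevation of e2 out of ŵ:
    ``atan(|e2·n̂| / |e2·ŵ|)``.  The near-radial fiber guard matches
    :func:`helix_angle`.
    """
    dot_r = np.sum(e1 * frame.r_hat, axis=-1)
    w = np.cross(frame.r_hat, e1)
    w_norm = np.linalg.norm(w, axis=-1)
    base_valid = frame.valid if frame.valid is not None else np.ones(dot_r.shape, bool)
    ok = base_valid & (np.abs(dot_r) <= RADIAL_GUARD) & (w_norm > 1e-12)
    n_excluded = int((base_valid & ~ok).sum())
    w = np.where(ok[..., None], w / np.where(w_norm[..., None] > 0, w_norm[..., None], 1.0), 0.0)
    n = np.cross(e1, w)
    n_norm = np.linalg.norm(n, axis=-1)
    n = np.where(ok[..., None], n / np.where(n_norm[..., None] > 0, n_norm[..., None], 1.0), 0.0)
    comp_w = np.abs(np.sum(e2 * w, axis=-1))
    comp_n = np.abs(np.sum(e2 * n, axis=-1))
    e2a = np.full(dot_r.shape, np.nan)
    e2a[ok] = np.degrees(np.arctan2(comp_n[ok], comp_w[ok]))
    return e2a, n_excluded


# ---------------------------------------------------------------------------
# transmural profile / helicity


def transmural_profile(
    ha: np.ndarray,
    depth: np.ndarray,
    wall_thickness_mm: float,
    n_bins: int = 10,
) -> TransmuralProfile:
    """Bin HA by transmural depth and fit the helicity slopes.

    The mean HA in ``n_bins`` equal-width depth bins spanning [0, 1] is
    regressed (ordinary least squares on the bin means) against depth
    expressed in percent of wall thickness (``slope_pct``, °/% ) and in mm
    (``slope_mm``, °/mm).  At least three populated bins are required.
    """
    sel = np.isfinite(ha) & np.isfinite(depth)
    d = np.clip(depth[sel], 0.0, 1.0)
    h = ha[sel]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=h, minlength=n_bins)
    depth_sums = np.bincount(which, weights=d, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        depth_means = np.where(counts > 0, depth_sums / np.maximum(counts, 1), np.nan)
    populated = counts > 0
    if populated.sum() < 3:
        raise ProfileError(f"only {int(populated.sum())} populated depth bins (need >= 3)")
    # regress against the realized mean depth of each bin, not the nominal
    # center: edge bins are populated off-center and would flatten the slope
    x = depth_means[populated]
    y = means[populated]
    slope_unit = np.polyfit(x, y, 1)[0]  # degrees per unit depth
    return TransmuralProfile(
        bin_centers=centers,
        bin_means=means,
        bin_counts=counts,
        slope_mm=float(slope_unit / wall_thickness_mm),
        slope_pct=float(slope_unit / 100.0),
        wall_thickness_mm=float(wall_thickness_mm),
    )


def ha_proportions(ha: np.ndarray, neutral_band: float = 30.0) -> dict[str, float]:
    """Fractions of voxels in the negative / neutral / positive HA bands.

    Bands are (−90, −band), [−band, +band], (+band, 90]; the three fractions
    sum to one over the finite voxels of the map.
    """
    vals = ha[np.isfinite(ha)]
    if vals.size == 0:
        raise ValueError("empty HA map")
    n = float(vals.size)
    neutral = np.sum((vals >= -neutral_band) & (vals <= neutral_band)) / n
    negative = np.sum(vals < -neutral_band) / n
    positive = np.sum(vals > neutral_band) / n
    return {"negative": float(negative), "neutral": float(neutral), "positive": float(positive)}
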