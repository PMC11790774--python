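"""Synthetic ex-vivo left-ventricle phantom with fully known microstructure.

The phantom voxelizes a truncated, axisymmetric thick-walled half-ellipsoid
shell emulating a fixed mouse LV at 150 µm isotropic resolution.  Every mask
voxel carries an analytic transmural depth, a local wall frame, a fiber
direction following a linear transmural helix-angle ramp, a sheetlet
direction at a prescribed |E2A|, and the diffusion tensor assembled from a
prescribed eigenvalue triple.  Signals follow the Stejskal–Tanner decay
``S_k = S0 · exp(−b_k g_kᵀ D g_k)``; optional Rician noise models
magnitude-MRI reconstruction.

Every quantity the analysis pipeline later estimates is therefore available
as ground truth, which is what makes end-to-end validation possible in the
absence of deposited scan data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cardiodti.frame import CardiacFrameField
from cardiodti.io import DWIStack, GradientTable


class IdentifiabilityError(ValueError):
    """Gradient scheme cannot identify the six tensor components."""


class GeometryError(ValueError):
    """Shell too thin for transmural analysis at the requested resolution."""


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# gradient table


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere
    phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _repulsion_directions(n: int, n_iter: int = 400, step: float = 0.02) -> np.ndarray:
    """Deterministic electrostatic-repulsion layout on the half-sphere.

    Points interact with each other and with every antipode (directions are
    axes), starting from a Fibonacci hemisphere; fixed iteration count and
    step schedule make the result reproducible for a given ``n``.
    """
    p = _fibonacci_hemisphere(n)
    for it in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        anti = p[:, None, :] + p[None, :, :]
        d3 = (np.sum(diff * diff, axis=-1) + 1e-12) ** 1.5
        a3 = (np.sum(anti * anti, axis=-1) + 1e-12) ** 1.5
        np.fill_diagonal(d3, np.inf)
        force = np.sum(diff / d3[..., None], axis=1) + np.sum(anti / a3[..., None], axis=1)
        force -= np.sum(force * p, axis=1, keepdims=True) * p  # tangent projection
        p = p + step * (0.995**it) * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    p[p[:, 2] < 0] *= -1.0
    return p


def make_gradient_table(n_b0: int, n_dirs: int, b_max: float) -> GradientTable:
    """Acquisition scheme: ``n_b0`` unweighted references plus ``n_dirs``
    quasi-uniform unit directions at ``b_max`` (s/mm²).

    At least six directions are required for tensor identifiability; the
    resulting log-linear design matrix is verified to have full column
    rank 7.
    """
    if n_dirs < 6:
        raise IdentifiabilityError(f"need >= 6 diffusion directions, got {n_dirs}")
    if b_max <= 0:
        raise ParameterError("b_max must be positive")
    dirs = _repulsion_directions(n_dirs)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b_max))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    gtab = GradientTable(bvals=bvals, bvecs=bvecs)
    if np.linalg.matrix_rank(gtab.design_matrix()) < 7:
        raise IdentifiabilityError("degenerate direction scheme (design rank < 7)")
    return gtab


# ---------------------------------------------------------------------------
# phantom specification


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric, microstructural and acquisition parameters of one phantom.

    Defaults emulate a healthy fixed mouse LV: ~1 mm wall at the base,
    +60°→−60° transmural helix ramp, |E2A| of 30°, eigenvalues
    (0.95, 0.80, 0.70)×10⁻³ mm²/s (FA ≈ 0.15, c_spherical ≈ 0.86,
    c_planar ≈ 0.08), 150 µm isotropic voxels, 3 b=0 references and 12
    directions at b = 1123 s/mm².
    """

    endo_radius_base: float = 1.1  # mm
    epi_radius_base: float = 2.1  # mm
    lv_length: float = 4.2  # mm, base plane to epicardial apex
    voxel_size: float = 0.15  # mm isotropic
    ha_endo: float = 60.0  # degrees
    ha_epi: float = -60.0  # degrees
    e2a_true: float = 30.0  # degrees in [0, 90]
    eigenvalues_true: tuple = (0.95e-3, 0.80e-3, 0.70e-3)  # mm²/s, descending
    s0: float = 1000.0  # arbitrary signal units
    snr: float = math.inf  # b0 signal / Rician sigma
    tibial_length: float = 17.5  # mm
    rv_insertion_azimuth: float = 0.0  # degrees
    n_b0: int = 3
    n_dirs: int = 12
    b_max: float = 1123.0  # s/mm²
    seed: int = 0

    def __post_init__(self):
        l1, l2, l3 = self.eigenvalues_true
        if not (self.epi_radius_base > self.endo_radius_base > 0):
            raise ParameterError("require epi_radius_base > endo_radius_base > 0")
        if not (l1 >= l2 >= l3 > 0):
            raise ParameterError("eigenvalues must be descending and positive")
        if self.voxel_size <= 0:
            raise ParameterError("voxel_size must be positive")
        if not self.ha_endo > self.ha_epi:
            raise ParameterError("require ha_endo > ha_epi")
        if not 0 <= self.e2a_true <= 90:
            raise ParameterError("e2a_true must lie in [0, 90] degrees")
        if not (self.snr > 0):
            raise ParameterError("snr must be positive (or infinite)")

    @property
    def wall_thickness_base(self) -> float:
        return self.epi_radius_base - self.endo_radius_base


@dataclass
class PhantomDataset:
    """One synthetic acquisition together with its ground truth."""

    dwi: DWIStack
    gtab: GradientTable
    mask: np.ndarray
    depth_true: np.ndarray
    frame_true: CardiacFrameField
    tensor_true: np.ndarray  # (*vol, 3, 3)
    ha_true: np.ndarray
    e2a_true: np.ndarray
    dwi_clean: DWIStack = field(repr=False, default=None)
    spec: PhantomSpec = None

    @property
    def affine(self) -> np.ndarray:
        return self.dwi.affine


# ---------------------------------------------------------------------------
# phantom construction


def _shell_radii(spec: PhantomSpec, z: np.ndarray):
    """In-slice endo/epi radii of the shell at longitudinal position z<=0."""
    L = spec.lv_length
    c_endo = L - spec.wall_thickness_base  # endocardial apex depth
    with np.errstate(invalid="ignore"):
        r_epi = spec.epi_radius_base * np.sqrt(np.clip(1.0 - (z / L) ** 2, 0.0, None))
        r_endo = spec.endo_radius_base * np.sqrt(np.clip(1.0 - (z / c_endo) ** 2, 0.0, None))
    r_epi = np.where((z <= 0) & (z >= -L), r_epi, 0.0)
    r_endo = np.where((z <= 0) & (z >= -c_endo), r_endo, 0.0)
    return r_endo, r_epi


def shell_volume_mm3(spec: PhantomSpec) -> float:
    """Analytic myocardial volume of the shell (mm³).

    Volume of the epicardial half-ellipsoid minus the cavity half-ellipsoid:
    V = 2π a² c / 3 each, with (a, c) the radial and longitudinal semi-axes.
    """
    L = spec.lv_length
    c_endo = L - spec.wall_thickness_base
    v_epi = 2.0 * math.pi * spec.epi_radius_base**2 * L / 3.0
    v_endo = 2.0 * math.pi * spec.endo_radius_base**2 * c_endo / 3.0
    return v_epi - v_endo


def make_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Voxelize the shell and synthesize the diffusion-weighted signals.

    Per mask voxel: analytic in-slice transmural depth d ∈ [0,1]; local frame
    (ĉ, l̂, r̂); fiber direction e1 at helix angle
    ``HA(d) = ha_endo + d·(ha_epi − ha_endo)`` within the tangent plane;
    sheet direction e2 elevated by ``e2a_true`` out of the in-wall
    cross-fiber direction; tensor ``D = R diag(λ) Rᵀ`` with R = [e1 e2 e3].
    Noiseless signals follow the mono-exponential decay; Rician noise is
    added when ``spec.snr`` is finite (σ = s0/snr, seeded).
    """
    vox = spec.voxel_size
    L = spec.lv_length
    margin = 2  # voxels of padding on every side
    nx = int(math.ceil(2 * spec.epi_radius_base / vox)) + 2 * margin
    ny = nx
    nz = int(math.ceil(L / vox)) + 2 * margin

    affine = np.diag([vox, vox, vox, 1.0])
    affine[0, 3] = -(nx - 1) / 2.0 * vox
    affine[1, 3] = -(ny - 1) / 2.0 * vox
    # align voxel *faces* with the base plane z=0 (centers at ±vox/2), so the
    # truncation does not systematically overcount a half-slab at the base
    affine[2, 3] = -L - (margin - 0.5) * vox

    xs = affine[0, 3] + vox * np.arange(nx)
    ys = affine[1, 3] + vox * np.arange(ny)
    zs = affine[2, 3] + vox * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    rho = np.hypot(X, Y)

    r_endo, r_epi = _shell_radii(spec, Z)
    in_epi = (Z <= 0) & (Z >= -L) & (rho <= r_epi)
    in_cavity = (r_endo > 0) & (rho < r_endo)
    mask = in_epi & ~in_cavity

    # shell-thinness guard: the in-slice wall must span >= 2 voxels wherever a
    # cavity exists, otherwise transmural profiles are meaningless
    ring = mask.any(axis=(0, 1)) & (r_endo[0, 0, :] > 0)
    wall_width = (r_epi - r_endo)[0, 0, :]
    if np.any(wall_width[ring] < 2 * vox):
        raise GeometryError(
            f"shell thinner than 2 voxels (min {wall_width[ring].min():.3f} mm at {vox} mm)"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        depth = (rho - r_endo) / np.where(r_epi > r_endo, r_epi - r_endo, 1.0)
    depth = np.clip(depth, 0.0, 1.0)
    depth_true = np.where(mask, depth, np.nan)

    # local frame (axisymmetric: l̂ = ẑ, r̂ in-slice radial, ĉ = l̂ × r̂)
    phi = np.arctan2(Y, X)
    # on-axis apical voxels have undefined azimuth; pick φ=0 deterministically
    on_axis = rho < 1e-9
    phi = np.where(on_axis, 0.0, phi)
    cphi, sphi = np.cos(phi), np.sin(phi)
    zeros = np.zeros_like(cphi)
    r_hat = np.stack([cphi, sphi, zeros], axis=-1)
    c_hat = np.stack([-sphi, cphi, zeros], axis=-1)
    l_hat = np.zeros_like(r_hat)
    l_hat[..., 2] = 1.0
    frame_valid = mask & ~on_axis

    ha = spec.ha_endo + depth * (spec.ha_epi - spec.ha_endo)
    ha_true = np.where(mask, ha, np.nan)
    ha_r = np.radians(ha)
    e2a_r = math.radians(spec.e2a_true)

    e1 = np.cos(ha_r)[..., None] * c_hat + np.sin(ha_r)[..., None] * l_hat
    w_hat = np.cos(ha_r)[..., None] * l_hat - np.sin(ha_r)[..., None] * c_hat  # r̂ × e1
    e2 = math.cos(e2a_r) * w_hat + math.sin(e2a_r) * r_hat
    e3 = np.cross(e1, e2)

    l1, l2, l3 = spec.eigenvalues_true
    tensor = (
        l1 * e1[..., :, None] * e1[..., None, :]
        + l2 * e2[..., :, None] * e2[..., None, :]
        + l3 * e3[..., :, None] * e3[..., None, :]
    )
    tensor_true = np.where(mask[..., None, None], tensor, 0.0)

    gtab = make_gradient_table(spec.n_b0, spec.n_dirs, spec.b_max)
    # ADC along each gradient direction, then mono-exponential decay
    adc = np.einsum("...ij,ki,kj->...k", tensor_true, gtab.bvecs, gtab.bvecs)
    signals = spec.s0 * np.exp(-gtab.bvals * adc)
    signals = np.where(mask[..., None], signals, 0.0)

    clean = DWIStack(data=signals, affine=affine, b0_indices=gtab.b0_indices)
    if math.isinf(spec.snr):
        noisy = clean
    else:
        noisy = add_rician_noise(clean, spec.snr, s_ref=spec.s0, seed=spec.seed)

    e2a_map = np.where(mask, float(spec.e2a_true), np.nan)
    frame_true = CardiacFrameField(
        c_hat=c_hat * frame_valid[..., None],
        l_hat=l_hat * frame_valid[..., None],
        r_hat=r_hat * frame_valid[..., None],
        depth=depth_true,
        valid=frame_valid,
    )
    return PhantomDataset(
        dwi=noisy,
        gtab=gtab,
        mask=mask,
        depth_true=depth_true,
        frame_true=frame_true,
        tensor_true=tensor_true,
        ha_true=ha_true,
        e2a_true=e2a_map,
        dwi_clean=clean,
        spec=spec,
    )


def phantom_contours(spec: PhantomSpec, dataset: PhantomDataset, n_vertices: int = 90):
    """Analytic endo/epi contour polygons for every slice with a cavity."""
    affine = dataset.affine
    vox = spec.voxel_size
    out: dict[int, dict[str, np.ndarray]] = {}
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    for sl in range(dataset.mask.shape[2]):
        z = affine[2, 3] + vox * sl
        r_endo, r_epi = _shell_radii(spec, np.asarray(z))
        if r_endo <= 0 or r_epi <= r_endo:
            continue
        if not dataset.mask[:, :, sl].any():
            continue
        out[sl] = {
            "endo": np.column_stack([r_endo * np.cos(theta), r_endo * np.sin(theta)]),
            "epi": np.column_stack([r_epi * np.cos(theta), r_epi * np.sin(theta)]),
        }
    return out


# ---------------------------------------------------------------------------
# noise


def add_rician_noise(dwi: DWIStack, snr: float, s_ref: float, seed: int) -> DWIStack:
    """Rician (magnitude-MRI) noise: ``sqrt((S+n1)² + n2²)``, σ = s_ref/snr.

    The reference signal is conventionally the mean b=0 myocardial signal.
    Identical ``(dwi, snr, seed)`` produce bit-identical output.
    """
    if not snr > 0:
        raise ParameterError("snr must be positive")
    if math.isinf(snr):
        return DWIStack(data=dwi.data.copy(), affine=dwi.affine.copy(), b0_indices=dwi.b0_indices)
    sigma = s_ref / snr
    rng = np.random.default_rng(seed)
    n1 = rng.standard_normal(dwi.data.shape)
    n2 = rng.standard_normal(dwi.data.shape)
    noisy = np.hypot(dwi.data + sigma * n1, sigma * n2)
    return DWIStack(data=noisy, affine=dwi.affine.copy(), b0_indices=dwi.b0_indices)


# ---------------------------------------------------------------------------
# cohorts


def disease_spec(base: PhantomSpec) -> PhantomSpec:
    """Atrophic-remodeling preset: −25% wall thickness, −15% λ2, −25% λ3.

    Thinner wall plus reduced secondary/tertiary eigenvalues raise FA and
    tensor planarity and lower sphericity, the qualitative phenotype of
    anthracycline-induced cardiotoxicity.
    """
    l1, l2, l3 = base.eigenvalues_true
    wall = base.wall_thickness_base * 0.75
    return replace(
        base,
        endo_radius_base=base.epi_radius_base - wall,
        eigenvalues_true=(l1, l2 * 0.85, l3 * 0.75),
    )


def _jitter_spec(spec: PhantomSpec, sd: float, rng: np.random.Generator, seed: int, max_tries: int = 20) -> PhantomSpec:
    for _ in range(max_tries):
        wall = spec.wall_thickness_base * (1.0 + sd * rng.standard_normal())
        l1, l2, l3 = spec.eigenvalues_true
        l2_j = l2 * (1.0 + sd * rng.standard_normal())
        l3_j = l3 * (1.0 + sd * rng.standard_normal())
        ha_endo = spec.ha_endo + 3.0 * rng.standard_normal() * (sd > 0)
        ha_epi = spec.ha_epi + 3.0 * rng.standard_normal() * (sd > 0)
        tibial = spec.tibial_length + 0.25 * rng.standard_normal() * (sd > 0)
        if not (l1 >= l2_j >= l3_j > 0 and wall > 0 and ha_endo > ha_epi):
            continue
        try:
            return replace(
                spec,
                endo_radius_base=spec.epi_radius_base - wall,
                eigenvalues_true=(l1, l2_j, l3_j),
                ha_endo=ha_endo,
                ha_epi=ha_epi,
                tibial_length=tibial,
                seed=seed,
            )
        except ParameterError:
            continue
    raise ParameterError("could not draw a valid subject spec (jitter too large?)")


def make_cohort(
    spec_control: PhantomSpec,
    spec_disease: PhantomSpec,
    n_control: int,
    n_disease: int,
    between_subject_sd: float = 0.05,
    seed: int = 0,
):
    """Simulate a two-group cohort of phantoms with biological variability.

    Per-subject parameters (wall thickness, λ2, λ3, helix-ramp endpoints,
    tibial length) are drawn from Gaussian jitter around each group's spec;
    ``between_subject_sd`` is the fractional SD on magnitudes.  Returns the
    list of :class:`PhantomDataset` and a manifest DataFrame with subject id,
    group and tibial length.
    """
    if n_control < 2 or n_disease < 2:
        raise ParameterError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    datasets, rows = [], []
    idx = 0
    for group, base, n in (("control", spec_control, n_control), ("disease", spec_disease, n_disease)):
        for _ in range(n):
            subject_seed = int(rng.integers(0, 2**31 - 1))
            sub_spec = _jitter_spec(base, between_subject_sd, rng, subject_seed)
            ds = make_phantom(sub_spec)
            sid = f"{group}_{idx:02d}"
            datasets.append(ds)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "tibial_length_mm": sub_spec.tibial_length,
                }
            )
            idx += 1
    return datasets, pd.DataFrame(rows)


def write_phantom(dataset: PhantomDataset, out_dir) -> dict[str, str]:
    """Write one phantom to disk (NIfTI DWI + mask + truth maps, FSL bvals/bvecs)."""
    from pathlib import Path

    from cardiodti.io import save_dwi, save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": str(out / "dwi.nii"),
        "bvals": str(out / "bvals"),
        "bvecs": str(out / "bvecs"),
        "mask": str(out / "mask.nii"),
        "ha_true": str(out / "ha_true.nii"),
        "depth_true": str(out / "depth_true.nii"),
    }
    save_dwi(dataset.dwi, dataset.gtab, paths["dwi"], paths["bvals"], paths["bvecs"])
    save_volume(dataset.mask, dataset.affine, paths["mask"])
    save_volume(np.nan_to_num(dataset.ha_true), dataset.affine, paths["ha_true"])
    save_volume(np.nan_to_num(dataset.depth_true), dataset.affine, paths["depth_true"])
    return paths
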