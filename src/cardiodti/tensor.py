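"""Per-voxel diffusion tensor estimation and scalar/shape metrics.

The model is the mono-exponential Stejskal–Tanner decay
``S_k = S0 exp(−b_k g_kᵀ D g_k)`` with a symmetric 3×3 tensor D per voxel.
Estimation is log-linear ordinary least squares (optionally one reweighted
pass with weights equal to the squared predicted signals), the standard
estimator at ex-vivo SNR.

Scalar metrics follow the usual eigenvalue parameterizations: mean
diffusivity MD = (λ1+λ2+λ3)/3; fractional anisotropy

    FA = sqrt(1/2) · sqrt((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / sqrt(λ1²+λ2²+λ3²);

and the Westin shape decomposition normalized by the trace T = λ1+λ2+λ3:
c_linear = (λ1−λ2)/T, c_planar = 2(λ2−λ3)/T, c_spherical = 3λ3/T, which sum
to one and locate a tensor on the stick–disc–ball simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cardiodti.io import DWIStack, GradientTable


class IdentifiabilityError(ValueError):
    pass


TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor in compact 6-component form."""

    components: np.ndarray  # (*vol, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    ln_s0: np.ndarray
    residual_rms: np.ndarray
    mask: np.ndarray
    invalid: np.ndarray  # voxels flagged unusable (e.g. all-zero signal)

    def as_matrix(self) -> np.ndarray:
        """Expand to full (*vol, 3, 3) symmetric matrices."""
        c = self.components
        out = np.empty(c.shape[:-1] + (3, 3))
        out[..., 0, 0] = c[..., 0]
        out[..., 1, 1] = c[..., 1]
        out[..., 2, 2] = c[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
        return out

    @staticmethod
    def from_matrix(mat: np.ndarray, mask: np.ndarray) -> "TensorField":
        comps = np.stack(
            [
                mat[..., 0, 0],
                mat[..., 1, 1],
                mat[..., 2, 2],
                mat[..., 0, 1],
                mat[..., 0, 2],
                mat[..., 1, 2],
            ],
            axis=-1,
        )
        shape = mat.shape[:-2]
        return TensorField(
            components=comps,
            ln_s0=np.zeros(shape),
            residual_rms=np.zeros(shape),
            mask=np.asarray(mask, bool),
            invalid=np.zeros(shape, bool),
        )


@dataclass
class EigenSystem:
    """Sorted eigen-decomposition of a tensor field.

    ``evals`` are descending (λ1 ≥ λ2 ≥ λ3); ``evecs[..., :, i]`` is the unit
    eigenvector of λ_{i+1}.  Negative eigenvalues from noisy fits are clamped
    to a small positive floor (1e−7 × the voxel's MD, at least 1e−12) and the
    number of affected voxels is recorded.  Eigenvector signs are fixed so
    each vector's largest-magnitude component is positive; e3 is then
    replaced by e1 × e2 so the triad is right-handed.
    """

    evals: np.ndarray  # (*vol, 3) descending
    evecs: np.ndarray  # (*vol, 3, 3) columns
    mask: np.ndarray
    n_clamped: int = 0

    @property
    def e1(self) -> np.ndarray:
        return self.evecs[..., :, 0]

    @property
    def e2(self) -> np.ndarray:
        return self.evecs[..., :, 1]

    @property
    def e3(self) -> np.ndarray:
        return self.evecs[..., :, 2]


@dataclass
class ScalarMaps:
    """Voxelwise MD, FA and Westin shape components."""

    md: np.ndarray
    fa: np.ndarray
    c_linear: np.ndarray
    c_planar: np.ndarray
    c_spherical: np.ndarray
    mask: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "md": self.md,
            "fa": self.fa,
            "c_linear": self.c_linear,
            "c_planar": self.c_planar,
            "c_spherical": self.c_spherical,
        }


# ---------------------------------------------------------------------------
# fitting


def fit_tensor_loglinear(
    dwi: DWIStack,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    weighted: bool = False,
) -> TensorField:
    """Log-linear least-squares tensor fit per voxel.

    Solves ``ln S_k = ln S0 − b_k g_kᵀ D g_k`` by OLS; with ``weighted`` a
    single reweighted pass follows, using the squared predicted signals as
    weights (the standard WLS correction for log-transformed Rician-ish
    noise).  Zero or negative signals inside the mask are clamped to the
    smallest positive double before the log; all-zero voxels are flagged
    invalid and excluded from downstream maps.
    """
    if len(gtab) < 7 or len(gtab.b0_indices) < 1:
        raise IdentifiabilityError("need >= 7 measurements including >= 1 b0")
    design = gtab.design_matrix()
    if np.linalg.matrix_rank(design) < 7:
        raise IdentifiabilityError("rank-deficient design matrix")
    if dwi.n_volumes != len(gtab):
        raise IdentifiabilityError(
            f"{dwi.n_volumes} volumes vs {len(gtab)} gradient rows"
        )
    vol_shape = dwi.data.shape[:3]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    signals = dwi.data[mask]  # (N, K)
    invalid_flat = ~np.any(signals > 0, axis=1)
    tiny = np.finfo(float).tiny
    log_s = np.log(np.clip(signals, tiny, None))

    pinv = np.linalg.pinv(design)
    theta = log_s @ pinv.T  # (N, 7)

    if weighted:
        pred = np.exp(theta @ design.T)
        w = pred**2  # (N, K)
        # per-voxel weighted normal equations
        xtw = design.T[None, :, :] * w[:, None, :]  # (N, 7, K)
        lhs = xtw @ design  # (N, 7, 7)
        rhs = np.einsum("npk,nk->np", xtw, log_s)
        theta = np.linalg.solve(lhs, rhs[..., None])[..., 0]

    resid = log_s - theta @ design.T
    rms = np.sqrt(np.mean(resid**2, axis=1))

    comps = np.zeros(vol_shape + (6,))
    ln_s0 = np.zeros(vol_shape)
    residual = np.zeros(vol_shape)
    invalid = np.zeros(vol_shape, dtype=bool)
    comps[mask] = theta[:, 1:]
    ln_s0[mask] = theta[:, 0]
    residual[mask] = rms
    tmp = np.zeros(mask.sum(), dtype=bool)
    tmp[invalid_flat] = True
    invalid[mask] = tmp
    comps[invalid] = 0.0
    return TensorField(
        components=comps, ln_s0=ln_s0, residual_rms=residual, mask=mask, invalid=invalid
    )


def eigen_decompose(tensor: TensorField) -> EigenSystem:
    """Sorted, sign-deterministic eigen-decomposition of a tensor field."""
    mats = tensor.as_matrix()[tensor.mask]
    evals, evecs = np.linalg.eigh(mats)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]

    md = evals.mean(axis=1)
    floor = np.maximum(1e-7 * np.abs(md), 1e-12)
    neg = evals < 0
    n_clamped = int(np.any(neg, axis=1).sum())
    evals = np.where(neg, floor[:, None], evals)

    # deterministic orientation: largest-|component| positive for e1, e2
    for i in (0, 1):
        v = evecs[:, :, i]
        lead = np.take_along_axis(v, np.abs(v).argmax(axis=1)[:, None], axis=1)[:, 0]
        sign = np.where(lead < 0, -1.0, 1.0)
        evecs[:, :, i] = v * sign[:, None]
    evecs[:, :, 2] = np.cross(evecs[:, :, 0], evecs[:, :, 1])  # right-handed

    vol_shape = tensor.mask.shape
    out_vals = np.zeros(vol_shape + (3,))
    out_vecs = np.zeros(vol_shape + (3, 3))
    out_vals[tensor.mask] = evals
    out_vecs[tensor.mask] = evecs
    valid = tensor.mask & ~tensor.invalid
    return EigenSystem(evals=out_vals, evecs=out_vecs, mask=valid, n_clamped=n_clamped)


def scalar_maps(eigs: EigenSystem) -> ScalarMaps:
    """MD, FA, and trace-normalized Westin shape components per voxel."""
    l1 = eigs.evals[..., 0]
    l2 = eigs.evals[..., 1]
    l3 = eigs.evals[..., 2]
    trace = l1 + l2 + l3
    valid = eigs.mask & (trace > 0)

    md = np.where(valid, trace / 3.0, np.nan)
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(valid & (den > 0), np.sqrt(0.5 * num / np.where(den > 0, den, 1.0)), np.nan)
        t = np.where(trace > 0, trace, 1.0)
        cl = np.where(valid, (l1 - l2) / t, np.nan)
        cp = np.where(valid, 2.0 * (l2 - l3) / t, np.nan)
        cs = np.where(valid, 3.0 * l3 / t, np.nan)
    return ScalarMaps(md=md, fa=fa, c_linear=cl, c_planar=cp, c_spherical=cs, mask=valid)


# ---------------------------------------------------------------------------
# model / results objects


class DiffusionTensorModel:
    """Voxelwise diffusion tensor model bound to one acquisition.

    Parameters
    ----------
    dwi : DWIStack
    gtab : GradientTable
    mask : ndarray of bool, optional
        Myocardial mask; defaults to all voxels.

    ``fit()`` returns a :class:`TensorFitResults` carrying the tensor field
    and lazily computed eigen-system and scalar maps.
    """

    def __init__(self, dwi: DWIStack, gtab: GradientTable, mask: np.ndarray | None = None):
        self.dwi = dwi
        self.gtab = gtab
        self.mask = None if mask is None else np.asarray(mask, dtype=bool)

    def fit(self, weighted: bool = False) -> "TensorFitResults":
        tf = fit_tensor_loglinear(self.dwi, self.gtab, self.mask, weighted=weighted)
        return TensorFitResults(model=self, tensor=tf)


@dataclass
class TensorFitResults:
    """Results of a per-voxel tensor fit."""

    model: DiffusionTensorModel
    tensor: TensorField
    _eigs: EigenSystem | None = field(default=None, repr=False)
    _maps: ScalarMaps | None = field(default=None, repr=False)

    @property
    def eigensystem(self) -> EigenSystem:
        if self._eigs is None:
            self._eigs = eigen_decompose(self.tensor)
        return self._eigs

    @property
    def maps(self) -> ScalarMaps:
        if self._maps is None:
            self._maps = scalar_maps(self.eigensystem)
        return self._maps

    def summary(self) -> str:
        m = self.maps
        mask = m.mask
        lines = [
            "Diffusion tensor fit",
            f"  voxels fitted      : {int(self.tensor.mask.sum())}",
            f"  invalid voxels     : {int(self.tensor.invalid.sum())}",
            f"  clamped eigenvalues: {self.eigensystem.n_clamped}",
            f"  MD  (mm^2/s)       : {np.nanmean(m.md[mask]):.4e}",
            f"  FA                 : {np.nanmean(m.fa[mask]):.4f}",
            f"  c_linear           : {np.nanmean(m.c_linear[mask]):.4f}",
            f"  c_planar           : {np.nanmean(m.c_planar[mask]):.4f}",
            f"  c_spherical        : {np.nanmean(m.c_spherical[mask]):.4f}",
            f"  log-residual RMS   : {np.nanmean(self.tensor.residual_rms[mask]):.3e}",
        ]
        return "\n".join(lines)
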