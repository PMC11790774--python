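"""Local principal-component denoising of 4-D diffusion-weighted stacks.

Sliding-window Casorati matrices (window³ voxels × measurements) are
eigen-decomposed and components whose eigenvalues are consistent with pure
noise are suppressed.  With ``noise_sigma="auto"`` the cut is placed by the
Marchenko–Pastur bulk-edge criterion, estimating the noise variance from the
trailing eigenvalues themselves; with a known sigma the threshold is the MP
upper edge ``σ²(1+√(N/M))²``.  Overlapping window reconstructions are
averaged with inverse-retained-rank weights, which favors windows that
compressed well.

This is a stand-in of the same local-PCA family as the overcomplete variant
used in the original processing chain, chosen because its behavior is
objectively testable against phantom ground truth.
"""

from __future__ import annotations

import numpy as np

from cardiodti.io import DWIStack


class ParameterError(ValueError):
    pass


def _mp_retained_rank(eigs_desc: np.ndarray, m: int) -> int:
    """Number of signal components by the Marchenko–Pastur bulk criterion.

    ``eigs_desc``: eigenvalues of the N×N sample covariance (descending);
    ``m``: number of rows (window voxels) of the Casorati matrix.  For each
    candidate signal rank p the trailing N−p eigenvalues are tested against
    the MP bulk of width ``4 σ̂² sqrt((N−p)/m)`` around their mean; the
    smallest consistent p is returned.
    """
    n = len(eigs_desc)
    for p in range(n):
        tail = eigs_desc[p:]
        sigma2 = tail.mean()
        if sigma2 <= 0:
            return p
        spread = tail[0] - tail[-1]
        if spread <= 4.0 * sigma2 * np.sqrt((n - p) / m):
            return p
    return n


def denoise_local_pca(
    dwi: DWIStack,
    window: int = 5,
    noise_sigma: float | str = "auto",
    mask: np.ndarray | None = None,
) -> DWIStack:
    """Denoise a 4-D stack by sliding-window PCA shrinkage.

    Parameters
    ----------
    dwi : DWIStack
        Input stack, shape (x, y, z, n_volumes).
    window : int
        Odd window edge length; ``window**3`` must exceed the number of
        volumes (tall Casorati matrix) and fit inside the volume.
    noise_sigma : float or "auto"
        Known noise standard deviation, or "auto" for the Marchenko–Pastur
        estimate per window.
    mask : ndarray of bool, optional
        When given, windows that do not touch the mask are skipped and
        non-mask voxels pass through unchanged.

    Returns
    -------
    DWIStack with identical shape and affine.
    """
    data = dwi.data
    nx, ny, nz, ng = data.shape
    if window % 2 == 0:
        raise ParameterError("window must be odd")
    if window > min(nx, ny, nz):
        raise ParameterError("window larger than volume")
    m = window**3
    if m <= ng:
        raise ParameterError(
            f"window³={m} must exceed the number of volumes ({ng}) for a tall Casorati matrix"
        )

    from numpy.lib.stride_tricks import sliding_window_view

    # (X', Y', Z', G, w, w, w) view over all fully-interior window positions
    view = sliding_window_view(data, (window, window, window), axis=(0, 1, 2))
    pos_shape = view.shape[:3]
    n_pos = int(np.prod(pos_shape))

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        touches = sliding_window_view(mask, (window, window, window), axis=(0, 1, 2))
        keep = touches.any(axis=(-3, -2, -1)).ravel()
    else:
        keep = np.ones(n_pos, dtype=bool)
    positions = np.flatnonzero(keep)

    num = np.zeros_like(data)
    den = np.zeros(data.shape[:3])

    known_sigma = None if noise_sigma == "auto" else float(noise_sigma)
    chunk = 2048
    for start in range(0, len(positions), chunk):
        pos = positions[start : start + chunk]
        wx, wy, wz = np.unravel_index(pos, pos_shape)
        block = view[wx, wy, wz]  # (B, G, w, w, w)
        casorati = block.reshape(len(pos), ng, m).transpose(0, 2, 1)  # (B, m, G)
        cov = casorati.transpose(0, 2, 1) @ casorati / m
        eigval, eigvec = np.linalg.eigh(cov)  # ascending
        eigval = eigval[:, ::-1]
        eigvec = eigvec[:, :, ::-1]
        b = len(pos)
        keep_mask = np.zeros((b, ng), dtype=bool)
        ranks = np.empty(b, dtype=int)
        if known_sigma is None:
            for i in range(b):
                p = _mp_retained_rank(eigval[i], m)
                p = max(p, 1)  # always keep the mean/leading component
                keep_mask[i, :p] = True
                ranks[i] = p
        else:
            edge = known_sigma**2 * (1.0 + np.sqrt(ng / m)) ** 2
            keep_mask = eigval > edge
            keep_mask[:, 0] = True
            ranks = keep_mask.sum(axis=1)
        proj = eigvec * keep_mask[:, None, :]
        recon = casorati @ (proj @ eigvec.transpose(0, 2, 1))
        weights = 1.0 / (1.0 + ranks.astype(float))

        # scatter-add the reconstructed windows back
        px, py, pz = wx, wy, wz
        recon = recon.reshape(b, window, window, window, ng)
        for i in range(b):
            sx, sy, sz = px[i], py[i], pz[i]
            num[sx : sx + window, sy : sy + window, sz : sz + window] += weights[i] * recon[i]
            den[sx : sx + window, sy : sy + window, sz : sz + window] += weights[i]

    out = data.copy()
    covered = den > 0
    out[covered] = num[covered] / den[covered, None]
    if mask is not None:
        out[~mask] = data[~mask]
    return DWIStack(data=out, affine=dwi.affine.copy(), b0_indices=dwi.b0_indices)
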