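"""Diffusion tensor estimation and the two tensor metrics reported (MD, FA).

The estimator is weighted linear least squares on the log-signal with weights
equal to the squared predicted signal and one refinement pass — the standard
WLLS scheme, which tracks nonlinear least squares closely at the SNR of
ex-vivo preclinical data while staying fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dmri_data import DWIDataset, ParameterMap, average_b0

log = logging.getLogger(__name__)

_B0_TOL = 1e-9
#: below this mean diffusivity (μm²/ms) the tensor is treated as zero, FA := 0
MD_FLOOR = 1e-6


@dataclass
class TensorFit:
    """Per-voxel diffusion tensor with its eigensystem and diagnostics."""

    d_tensor: np.ndarray  # 3×3 symmetric, μm²/ms
    s0: float
    eigvals: np.ndarray  # sorted descending
    eigvecs: np.ndarray  # columns, orthonormal
    rss: float
    negative_eigvals: bool = False


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows ``[1, -b gx², -b gy², -b gz², -2b gxgy, -2b gxgz, -2b gygz]``.

    ``A @ (ln s0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` predicts the log-signal.
    """
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def tensor_from_vec(vec: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = vec
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def sorted_eigensystem(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues descending; eigenvector signs fixed deterministically.

    When the two leading eigenvalues are degenerate (λ1−λ2 < 1e-9) the leading
    axis is chosen as the candidate with the largest |z| component; every
    eigenvector's sign is fixed so its maximum-magnitude entry is positive.
    """
    w, v = np.linalg.eigh(d)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if w[0] - w[1] < 1e-9 and abs(v[2, 1]) > abs(v[2, 0]):
        w[[0, 1]] = w[[1, 0]]
        v[:, [0, 1]] = v[:, [1, 0]]
    for i in range(3):
        j = np.argmax(np.abs(v[:, i]))
        if v[j, i] < 0:
            v[:, i] = -v[:, i]
    return w, v


def fit_dti_signal(
    signal: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray, n_refine: int = 1
) -> TensorFit:
    """WLLS tensor fit of a single voxel's measurement vector."""
    signal = np.asarray(signal, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    if signal.size < 7 or np.unique(np.round(bvals, 9)).size < 2:
        raise ValueError(
            "insufficient shells: need >= 7 measurements over >= 2 distinct b-values"
        )
    if np.any(signal <= 0):
        raise ValueError("non-positive signal in voxel")
    A = design_matrix(bvals, bvecs)
    y = np.log(signal)
    w = signal  # sqrt-weights for pass 1: observed signal
    x = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)[0]
    for _ in range(n_refine):
        w = np.exp(A @ x)  # predicted signal
        x = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)[0]
    d = tensor_from_vec(x[1:])
    pred = np.exp(A @ x)
    rss = float(np.sum((pred - signal) ** 2))
    eigvals, eigvecs = sorted_eigensystem(d)
    return TensorFit(
        d_tensor=d,
        s0=float(np.exp(x[0])),
        eigvals=eigvals,
        eigvecs=eigvecs,
        rss=rss,
        negative_eigvals=bool(eigvals.min() < 0),
    )


def dti_metrics(fit: TensorFit) -> dict[str, float]:
    """MD = mean eigenvalue; FA per the standard closed form, clamped to [0, 1]."""
    lam = fit.eigvals
    md = float(lam.mean())
    if abs(md) < MD_FLOOR:
        return {"MD": md, "FA": 0.0}
    num = np.sum((lam - md) ** 2)
    den = np.sum(lam**2)
    fa = float(np.sqrt(1.5 * num / den)) if den > 0 else 0.0
    return {"MD": md, "FA": min(fa, 1.0)}


@dataclass
class TensorFitMap:
    """Voxel map of tensor fits over a fit mask."""

    d_tensor: np.ndarray  # (..., 3, 3)
    s0: np.ndarray
    eigvals: np.ndarray  # (..., 3)
    rss: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def metrics(self) -> dict[str, ParameterMap]:
        shape = self.mask.shape
        md = np.full(shape, np.nan)
        fa = np.full(shape, np.nan)
        for idx in np.argwhere(self.mask):
            t = tuple(idx)
            lam = self.eigvals[t]
            m = dti_metrics(
                TensorFit(self.d_tensor[t], self.s0[t], lam, np.eye(3), self.rss[t])
            )
            md[t], fa[t] = m["MD"], m["FA"]
        return {
            "MD": ParameterMap("MD", md, "um^2/ms", self.mask, self.affine),
            "FA": ParameterMap("FA", fa, "dimensionless", self.mask, self.affine),
        }


def fit_dti(
    dataset: DWIDataset, mask: np.ndarray | None = None, b_max: float = 1.0
) -> TensorFitMap:
    """Voxel-wise WLLS tensor fit on shells with b ≤ ``b_max`` (ms/μm²).

    Voxels with any non-positive signal are dropped from the fit mask and
    logged.  b=0 frames are averaged into one effective measurement first.
    """
    bvals, bvecs = dataset.measurement_table()
    keep = bvals <= b_max + 1e-9
    if np.unique(np.round(bvals[keep], 9)).size < 2 or keep.sum() < 7:
        raise ValueError(
            f"insufficient shells at or below b_max={b_max}: need >= 7 "
            "measurements over >= 2 distinct b-values"
        )
    raw = dataset.signal[..., keep]
    sig, b, g = average_b0(raw, bvals[keep], bvecs[keep])
    shape = dataset.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool).copy()

    d_t = np.zeros(shape + (3, 3))
    s0 = np.zeros(shape)
    eigvals = np.zeros(shape + (3,))
    rss = np.zeros(shape)
    n_dropped = 0
    for idx in np.argwhere(mask):
        t = tuple(idx)
        s = sig[t]
        if np.any(raw[t] <= 0):  # checked pre-averaging: any bad frame drops the voxel
            mask[t] = False
            n_dropped += 1
            continue
        fit = fit_dti_signal(s, b, g)
        d_t[t], s0[t], eigvals[t], rss[t] = fit.d_tensor, fit.s0, fit.eigvals, fit.rss
    if n_dropped:
        log.info("fit_dti: excluded %d voxels with non-positive signal", n_dropped)
    return TensorFitMap(
        d_tensor=d_t, s0=s0, eigvals=eigvals, rss=rss, mask=mask, affine=dataset.affine
    )
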