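"""Conventional kurtosis-tensor NLLS fitting and the six kurtosis metrics.

Signal model (MD²-normalized kurtosis convention)::

    ln S(b, n) = ln S0 − b·D_app(n) + (b²/6)·MD²·Ŵ(n)

with ``D_app(n) = nᵀDn`` and ``Ŵ(n) = Σ n_i n_j n_k n_l W_ijkl``, so that the
apparent kurtosis is ``K_app(n) = MD²·Ŵ(n)/D_app(n)²``.  The fit is performed
on the shells with b ≤ 4.5 ms/μm², initialized from a log-linear solution and
refined by Levenberg–Marquardt on the signal domain.

With the study's 12-direction scheme the 15-component kurtosis tensor is only
determined up to a 3-dimensional null space of the directional design.  The
linear initialization resolves that null space by minimizing the
rotation-invariant anisotropy seminorm of W (the component orthogonal to the
isotropic rank-4 tensor), and Levenberg–Marquardt steps lie in the row space
of the Jacobian, so the chosen representative is preserved exactly.  Isotropic
and Gaussian ground truths are therefore recovered exactly; generic W is
recovered up to the unidentifiable subspace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import factorial

import numpy as np
from scipy.optimize import least_squares

from .dmri_data import DWIDataset, ParameterMap, average_b0
from .dti import TensorFit, dti_metrics, sorted_eigensystem, tensor_from_vec

log = logging.getLogger(__name__)

#: default b-value ceiling for the kurtosis fit, ms/μm²
B_MAX_DKI = 4.5

#: the 15 sorted index combinations of a fully symmetric rank-4 tensor
W_COMBOS: tuple[tuple[int, int, int, int], ...] = tuple(
    combinations_with_replacement(range(3), 4)
)


def _multiplicity(combo: tuple[int, ...]) -> int:
    counts = [combo.count(a) for a in range(3)]
    return factorial(4) // (factorial(counts[0]) * factorial(counts[1]) * factorial(counts[2]))


W_MULT = np.array([_multiplicity(c) for c in W_COMBOS], dtype=float)

#: component vector of the isotropic rank-4 tensor sym(δ⊗δ)
_ISO4 = np.array(
    [
        1.0 if len(set(c)) == 1 else (1.0 / 3.0 if sorted(
            [c.count(a) for a in range(3) if c.count(a)]) == [2, 2] else 0.0)
        for c in W_COMBOS
    ]
)


def w_vec_to_tensor(w: np.ndarray) -> np.ndarray:
    """Expand the 15 unique components into the full symmetric (3,3,3,3) array."""
    t = np.zeros((3, 3, 3, 3))
    for val, combo in zip(w, W_COMBOS):
        seen = set()
        from itertools import permutations

        for p in permutations(combo):
            if p not in seen:
                t[p] = val
                seen.add(p)
    return t


def w_tensor_to_vec(t: np.ndarray) -> np.ndarray:
    return np.array([t[c] for c in W_COMBOS])


def w_row(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Design rows for the 15 components of ``(b²/6)·Ŵ(n)`` (unnormalized U)."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    mono = np.stack(
        [g[:, c[0]] * g[:, c[1]] * g[:, c[2]] * g[:, c[3]] for c in W_COMBOS], axis=1
    )
    return (b**2 / 6.0)[:, None] * mono * W_MULT[None, :]


def _d_row(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    mono = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    return -b[:, None] * mono


def dki_design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Full (n, 22) design: ``[1 | −b·D(n) rows | (b²/6)·U(n) rows]``.

    The U block carries the *unnormalized* kurtosis tensor ``U = MD²·W``,
    which keeps the log-model linear in all 22 parameters.
    """
    n = len(bvals)
    return np.hstack([np.ones((n, 1)), _d_row(bvals, bvecs), w_row(bvals, bvecs)])


@dataclass
class DKIFit:
    """Joint diffusion/kurtosis tensor fit of one voxel."""

    s0: float
    d_tensor: np.ndarray  # (3, 3), μm²/ms
    w_tensor: np.ndarray  # (3, 3, 3, 3), dimensionless (MD²-normalized)
    converged: bool
    rss: float

    @property
    def md(self) -> float:
        return float(np.trace(self.d_tensor) / 3.0)


@dataclass
class KurtosisMetrics:
    MK: float
    AK: float
    RK: float
    MKT: float
    W_L: float
    W_T: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("MK", "AK", "RK", "MKT", "W_L", "W_T")}


def dki_signal(
    s0: float,
    d_tensor: np.ndarray,
    w_tensor: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
) -> np.ndarray:
    """Forward DKI model evaluated on a measurement table."""
    md = np.trace(d_tensor) / 3.0
    dvec = np.array(
        [
            d_tensor[0, 0],
            d_tensor[1, 1],
            d_tensor[2, 2],
            d_tensor[0, 1],
            d_tensor[0, 2],
            d_tensor[1, 2],
        ]
    )
    uvec = md**2 * w_tensor_to_vec(w_tensor)
    x = np.concatenate([[np.log(s0)], dvec, uvec])
    A = dki_design_matrix(bvals, bvecs)
    return np.exp(A @ x)


def isotropic_mixture_cumulants(
    f: float, d1: float, d2: float
) -> tuple[float, float]:
    """(MD, K) of a two-site non-exchanging isotropic mixture.

    The cumulant expansion of ``f·e^{−bD₁} + (1−f)·e^{−bD₂}`` gives
    ``MD = E[D]`` and ``K = 3·Var(D)/E[D]²``.
    """
    mean = f * d1 + (1 - f) * d2
    var = f * d1**2 + (1 - f) * d2**2 - mean**2
    return float(mean), float(3 * var / mean**2)


def isotropic_dki_pair(md: float, k: float) -> tuple[np.ndarray, np.ndarray]:
    """(D, W) tensors of an isotropic medium with mean diffusivity ``md`` and kurtosis ``k``."""
    return md * np.eye(3), k * w_vec_to_tensor(_ISO4)


def _resolve_null_space(x: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Pick the null-space representative minimizing the W anisotropy seminorm.

    The seminorm is the rotation-invariant norm of the component of U
    orthogonal to the isotropic rank-4 tensor; null directions of the design
    leave the measured signal untouched, so this choice is a pure convention,
    exact for isotropic and Gaussian ground truths.
    """
    if null.size == 0:
        return x
    mhalf = np.sqrt(W_MULT)
    iso = mhalf * _ISO4
    iso = iso / np.linalg.norm(iso)

    def aniso(u):
        u = mhalf * u
        return u - iso * (iso @ u)

    PN = np.stack([aniso(null[7:, j]) for j in range(null.shape[1])], axis=1)
    z = np.linalg.lstsq(PN, -aniso(x[7:]), rcond=None)[0]
    return x + null @ z


def fit_dki_signal(
    signal: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    b_max: float = B_MAX_DKI,
    max_nfev: int = 200,
) -> DKIFit:
    """Fit one voxel: log-linear initialization, then LM refinement on the signal.

    The nonlinear refinement is restricted to the row space of the design so
    that an under-determined direction set cannot make the optimizer wander;
    the null-space component is then fixed by :func:`_resolve_null_space`.
    """
    signal = np.asarray(signal, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    keep = (bvals <= b_max + 1e-9) & (signal > 0)
    signal, bvals, bvecs = signal[keep], bvals[keep], bvecs[keep]
    signal, bvals, bvecs = average_b0(signal, bvals, bvecs)
    if signal.size < 22:
        raise ValueError(
            f"fewer than 22 usable measurements ({signal.size}) for the kurtosis fit"
        )
    A = dki_design_matrix(bvals, bvecs)
    u_svd, sv, vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-10))
    y_log = np.log(signal)
    x_p = vt[:rank].T @ (u_svd[:, :rank].T @ y_log / sv[:rank])  # min-norm LS
    row_basis = vt[:rank].T
    null = vt[rank:].T

    def resid(y):
        return np.exp(A @ (x_p + row_basis @ y)) - signal

    def jac(y):
        return np.exp(A @ (x_p + row_basis @ y))[:, None] * (A @ row_basis)

    res = least_squares(resid, np.zeros(rank), jac=jac, method="lm", max_nfev=max_nfev)
    converged = res.status > 0
    x = x_p + row_basis @ res.x if converged else x_p
    if not converged:
        log.info("fit_dki: LM did not converge; retaining log-linear estimate")
    x = _resolve_null_space(x, null)
    d = tensor_from_vec(x[1:7])
    md = np.trace(d) / 3.0
    u = x[7:]
    w = u / md**2 if md**2 > 1e-12 else np.zeros(15)
    rss = float(np.sum((np.exp(A @ x) - signal) ** 2))
    return DKIFit(
        s0=float(np.exp(x[0])),
        d_tensor=d,
        w_tensor=w_vec_to_tensor(w),
        converged=converged,
        rss=rss,
    )


def directional_kurtosis(fit: DKIFit, n: np.ndarray) -> float:
    """Apparent kurtosis along unit vector ``n``: ``K_app = MD²·Ŵ(n)/D_app(n)²``."""
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    d_app = float(n @ fit.d_tensor @ n)
    if d_app <= 0:
        warnings.warn("non-positive apparent diffusivity; K_app undefined", stacklevel=2)
        return float("nan")
    w_app = float(np.einsum("i,j,k,l,ijkl->", n, n, n, n, fit.w_tensor))
    return fit.md**2 * w_app / d_app**2


def sphere_quadrature(n_polar: int = 32, n_az: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre × uniform-azimuth product rule; weights sum to 1.

    Exact for spherical polynomials up to degree ``2·n_polar − 1`` in cosθ and
    ``n_az − 1`` in azimuth — far beyond the degree-4 integrands here; the
    kurtosis ratio K_app is smooth, so the residual quadrature error is
    negligible against fit noise.
    """
    t, wt = np.polynomial.legendre.leggauss(n_polar)
    phi = 2 * np.pi * np.arange(n_az) / n_az
    ct, ph = np.meshgrid(t, phi, indexing="ij")
    st = np.sqrt(1 - ct**2)
    pts = np.stack(
        [st * np.cos(ph), st * np.sin(ph), ct], axis=-1
    ).reshape(-1, 3)
    w = np.repeat(wt / 2.0, n_az) / n_az
    return pts, w


def _apparent(fit: DKIFit, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d_app = np.einsum("ni,ij,nj->n", pts, fit.d_tensor, pts)
    w_app = np.einsum("ni,nj,nk,nl,ijkl->n", pts, pts, pts, pts, fit.w_tensor)
    return d_app, w_app


def rotate_w(w: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Components of W in the frame whose axes are the columns of ``rot``."""
    return np.einsum("ia,jb,kc,ld,ijkl->abcd", rot, rot, rot, rot, w)


def kurtosis_metrics(
    fit: DKIFit, n_polar: int = 32, n_az: int = 64
) -> KurtosisMetrics:
    """The six reported kurtosis scalars.

    MK is the spherical mean of K_app by quadrature; AK is K_app along the
    principal diffusion axis; RK the azimuthal mean of K_app in the
    perpendicular plane; MKT, W_L and W_T are contractions of W in the
    eigenframe of D (surface mean, axial component, azimuthal radial mean).
    """
    md = fit.md
    pts, wq = sphere_quadrature(n_polar, n_az)
    d_app, w_app = _apparent(fit, pts)
    with np.errstate(divide="ignore", invalid="ignore"):
        k_app = md**2 * w_app / d_app**2
    mk = float(np.sum(wq * k_app))

    lam, vecs = sorted_eigensystem(fit.d_tensor)
    wp = rotate_w(fit.w_tensor, vecs)

    ak = md**2 * wp[0, 0, 0, 0] / lam[0] ** 2 if lam[0] > 0 else float("nan")

    phi = 2 * np.pi * np.arange(n_az) / n_az
    c, s = np.cos(phi), np.sin(phi)
    w_perp = (
        wp[1, 1, 1, 1] * c**4
        + wp[2, 2, 2, 2] * s**4
        + 6 * wp[1, 1, 2, 2] * c**2 * s**2
        + 4 * wp[1, 1, 1, 2] * c**3 * s
        + 4 * wp[1, 2, 2, 2] * c * s**3
    )
    d_perp = lam[1] * c**2 + lam[2] * s**2
    with np.errstate(divide="ignore", invalid="ignore"):
        rk = float(np.mean(md**2 * w_perp / d_perp**2))

    mkt = (
        wp[0, 0, 0, 0]
        + wp[1, 1, 1, 1]
        + wp[2, 2, 2, 2]
        + 2 * (wp[0, 0, 1, 1] + wp[0, 0, 2, 2] + wp[1, 1, 2, 2])
    ) / 5.0
    w_l = wp[0, 0, 0, 0]
    w_t = (3.0 / 8.0) * (wp[1, 1, 1, 1] + wp[2, 2, 2, 2] + 2 * wp[1, 1, 2, 2])
    return KurtosisMetrics(
        MK=mk, AK=float(ak), RK=rk, MKT=float(mkt), W_L=float(w_l), W_T=float(w_t)
    )


@dataclass
class DKIFitMap:
    """Voxel map of joint diffusion/kurtosis fits."""

    s0: np.ndarray
    d_tensor: np.ndarray  # (..., 3, 3)
    w_tensor: np.ndarray  # (..., 3, 3, 3, 3)
    converged: np.ndarray
    rss: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def voxel(self, idx: tuple[int, ...]) -> DKIFit:
        return DKIFit(
            s0=float(self.s0[idx]),
            d_tensor=self.d_tensor[idx],
            w_tensor=self.w_tensor[idx],
            converged=bool(self.converged[idx]),
            rss=float(self.rss[idx]),
        )

    def metrics(self) -> dict[str, ParameterMap]:
        """Six kurtosis maps plus MD/FA from the jointly fitted tensor."""
        shape = self.mask.shape
        names = ("MK", "AK", "RK", "MKT", "W_L", "W_T", "MD", "FA")
        out = {n: np.full(shape, np.nan) for n in names}
        for idx in np.argwhere(self.mask):
            t = tuple(idx)
            fit = self.voxel(t)
            km = kurtosis_metrics(fit)
            for n, v in km.as_dict().items():
                out[n][t] = v
            lam, vecs = sorted_eigensystem(fit.d_tensor)
            dm = dti_metrics(
                TensorFit(fit.d_tensor, fit.s0, lam, vecs, fit.rss)
            )
            out["MD"][t], out["FA"][t] = dm["MD"], dm["FA"]
        units = {"MD": "um^2/ms"}
        return {
            n: ParameterMap(n, out[n], units.get(n, "dimensionless"), self.mask, self.affine)
            for n in names
        }


def fit_dki(
    dataset: DWIDataset, mask: np.ndarray | None = None, b_max: float = B_MAX_DKI
) -> DKIFitMap:
    """Voxel-wise kurtosis fit on the b ≤ ``b_max`` subset of the protocol."""
    bvals, bvecs = dataset.measurement_table()
    nz = np.unique(np.round(bvals[(bvals > 1e-9) & (bvals <= b_max + 1e-9)], 9))
    if nz.size < 3:
        raise ValueError(
            f"kurtosis fit needs >= 3 distinct nonzero shells at b <= {b_max}"
        )
    if dataset.protocol.n_directions < 9:
        raise ValueError("kurtosis fit needs >= 9 gradient directions")
    shape = dataset.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool).copy()
    s0 = np.zeros(shape)
    d_t = np.zeros(shape + (3, 3))
    w_t = np.zeros(shape + (3, 3, 3, 3))
    conv = np.zeros(shape, dtype=bool)
    rss = np.zeros(shape)
    for idx in np.argwhere(mask):
        t = tuple(idx)
        try:
            fit = fit_dki_signal(dataset.signal[t], bvals, bvecs, b_max=b_max)
        except ValueError:
            mask[t] = False
            log.info("fit_dki: voxel %s excluded (too few usable measurements)", t)
            continue
        s0[t], d_t[t], w_t[t] = fit.s0, fit.d_tensor, fit.w_tensor
        conv[t], rss[t] = fit.converged, fit.rss
    return DKIFitMap(
        s0=s0, d_tensor=d_t, w_tensor=w_t, converged=conv, rss=rss, mask=mask,
        affine=dataset.affine,
    )
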