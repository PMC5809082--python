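"""Kurtosis tensor fitting and metric contractions against independent oracles."""

import numpy as np
import pytest

from conftest import random_rotation, random_spd
from cmscortex import dki
from cmscortex.dki import (
    DKIFit,
    directional_kurtosis,
    dki_signal,
    fit_dki,
    fit_dki_signal,
    isotropic_dki_pair,
    isotropic_mixture_cumulants,
    kurtosis_metrics,
    rotate_w,
    sphere_quadrature,
    w_tensor_to_vec,
    w_vec_to_tensor,
)
from cmscortex.dmri_data import DWIDataset


def random_w(rng, scale=0.3):
    return w_vec_to_tensor(rng.standard_normal(15) * scale)


def test_gaussian_truth_zeroes_all_metrics(meas, rng):
    bv, gv = meas
    for _ in range(5):
        d = random_spd(rng, scale=1.0, floor=0.2)
        sig = dki_signal(1.0, d, np.zeros((3, 3, 3, 3)), bv, gv)
        fit = fit_dki_signal(sig, bv, gv)
        np.testing.assert_allclose(fit.w_tensor, 0.0, atol=1e-8)
        m = kurtosis_metrics(fit)
        assert max(abs(v) for v in m.as_dict().values()) < 1e-6


def test_mixture_cumulants_closed_form():
    md, k = isotropic_mixture_cumulants(0.5, 0.5, 1.5)
    assert md == pytest.approx(1.0)
    assert k == pytest.approx(0.75)  # 3·Var(D)/mean(D)²


def test_mixture_cumulant_signal_recovers_075(meas):
    """The mixture's cumulant pair yields all four averages = 0.75 after fitting."""
    bv, gv = meas
    md, k = isotropic_mixture_cumulants(0.5, 0.5, 1.5)
    d, w = isotropic_dki_pair(md, k)
    fit = fit_dki_signal(dki_signal(1.0, d, w, bv, gv), bv, gv)
    m = kurtosis_metrics(fit)
    for name in ("MK", "AK", "RK", "MKT"):
        assert getattr(m, name) == pytest.approx(0.75, abs=1e-3)


def test_raw_biexponential_fit_is_biased_below_true_kurtosis(meas):
    """Fitting the truncated cumulant model to the raw bi-exponential signal
    over the full b ≤ 4.5 range underestimates the b→0 kurtosis (the
    mixture's 4th cumulant is negative), so fitted MK lands strictly between
    0 and 0.75."""
    bv, gv = meas
    raw = 0.5 * (np.exp(-0.5 * bv) + np.exp(-1.5 * bv))
    fit = fit_dki_signal(raw, bv, gv)
    mk = kurtosis_metrics(fit).MK
    assert 0.0 < mk < 0.75


def test_directional_kurtosis_cases(meas, rng):
    d_iso, w_iso = isotropic_dki_pair(1.0, 0.75)
    fit = DKIFit(1.0, d_iso, w_iso, True, 0.0)
    for _ in range(5):
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        assert directional_kurtosis(fit, n) == pytest.approx(0.75, abs=1e-12)
    gauss = DKIFit(1.0, d_iso, np.zeros((3, 3, 3, 3)), True, 0.0)
    assert directional_kurtosis(gauss, np.array([0, 0, 1.0])) == 0.0
    # single-component W: K_app(e1) = MD²·W1111/λ1²
    lam = np.array([1.2, 0.5, 0.3])
    w = np.zeros(15)
    w[0] = 0.6  # W_xxxx
    fit = DKIFit(1.0, np.diag(lam), w_vec_to_tensor(w), True, 0.0)
    md = lam.mean()
    assert directional_kurtosis(fit, np.array([1.0, 0, 0])) == pytest.approx(
        md**2 * 0.6 / lam[0] ** 2, rel=1e-12
    )


def test_directional_kurtosis_rejects_non_unit(meas):
    d, w = isotropic_dki_pair(1.0, 0.5)
    with pytest.raises(ValueError, match="unit"):
        directional_kurtosis(DKIFit(1.0, d, w, True, 0.0), np.array([1.0, 1.0, 0.0]))


def test_metric_contractions_match_quadrature_oracles(rng):
    """Closed-form MKT equals the dense-sphere surface average of Ŵ(n); W_T
    equals the numerical azimuthal average in the radial plane."""
    pts, wq = sphere_quadrature(50, 100)  # 5000-point rule, exact for degree 4
    phi = 2 * np.pi * np.arange(720) / 720
    for _ in range(30):
        d = random_spd(rng, scale=1.0, floor=0.2)
        w = random_w(rng)
        fit = DKIFit(1.0, d, w, True, 0.0)
        m = kurtosis_metrics(fit)
        w_app = np.einsum("ni,nj,nk,nl,ijkl->n", pts, pts, pts, pts, w)
        assert m.MKT == pytest.approx(float(np.sum(wq * w_app)), abs=1e-3)
        # azimuthal average in the eigenframe plane ⊥ e1
        from cmscortex.dti import sorted_eigensystem

        _, vecs = sorted_eigensystem(d)
        wp = rotate_w(w, vecs)
        n_perp = np.stack(
            [np.zeros_like(phi), np.cos(phi), np.sin(phi)], axis=1
        )
        w_perp = np.einsum("ni,nj,nk,nl,ijkl->n", n_perp, n_perp, n_perp, n_perp, wp)
        assert m.W_T == pytest.approx(float(w_perp.mean()), abs=1e-6)
        assert m.W_L == pytest.approx(wp[0, 0, 0, 0], abs=1e-12)


def test_tensor_metrics_rotation_invariant(rng):
    d = random_spd(rng, scale=1.0, floor=0.2)
    w = random_w(rng)
    m0 = kurtosis_metrics(DKIFit(1.0, d, w, True, 0.0))
    for _ in range(5):
        r = random_rotation(rng)
        m1 = kurtosis_metrics(DKIFit(1.0, r @ d @ r.T, rotate_w(w, r.T), True, 0.0))
        for name in ("MKT", "W_L", "W_T"):
            assert getattr(m1, name) == pytest.approx(getattr(m0, name), abs=1e-8)


def test_mk_equals_mkt_for_isotropic_d(rng):
    for _ in range(5):
        w = random_w(rng)
        m = kurtosis_metrics(DKIFit(1.0, 0.8 * np.eye(3), w, True, 0.0))
        assert m.MK == pytest.approx(m.MKT, abs=1e-10)


def test_fit_self_consistency_and_determinism(meas, rng):
    """Refitting the forward signal of a fitted voxel reproduces the fit; the
    fit itself is exactly reproducible."""
    bv, gv = meas
    d = random_spd(rng, scale=1.0, floor=0.25)
    w = random_w(rng, scale=0.25)
    sig = dki_signal(1.0, d, w, bv, gv)
    fit1 = fit_dki_signal(sig, bv, gv)
    fit1b = fit_dki_signal(sig, bv, gv)
    np.testing.assert_array_equal(fit1.w_tensor, fit1b.w_tensor)
    sig2 = dki_signal(fit1.s0, fit1.d_tensor, fit1.w_tensor, bv, gv)
    fit2 = fit_dki_signal(sig2, bv, gv)
    np.testing.assert_allclose(fit2.d_tensor, fit1.d_tensor, atol=1e-6)
    np.testing.assert_allclose(fit2.w_tensor, fit1.w_tensor, atol=1e-6)
    # D itself is fully identifiable from 12 directions
    np.testing.assert_allclose(fit1.d_tensor, d, atol=1e-8)


def test_w_vec_tensor_roundtrip_and_symmetry(rng):
    v = rng.standard_normal(15)
    t = w_vec_to_tensor(v)
    np.testing.assert_array_equal(w_tensor_to_vec(t), v)
    np.testing.assert_array_equal(t, np.transpose(t, (1, 0, 2, 3)))
    np.testing.assert_array_equal(t, np.transpose(t, (3, 2, 1, 0)))


def test_fit_dki_preconditions(protocol):
    ds = DWIDataset(
        signal=np.ones((1, 1, 1, protocol.n_measurements)), protocol=protocol
    )
    with pytest.raises(ValueError, match="shells"):
        fit_dki(ds, b_max=0.6)


def test_too_few_usable_measurements_rejected(meas):
    bv, gv = meas
    keep = np.zeros(len(bv), bool)
    keep[:20] = True
    with pytest.raises(ValueError, match="22"):
        fit_dki_signal(np.ones(20), bv[keep], gv[keep])
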