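"""Fit all three d-MRI models on a known-truth phantom voxel set.

Builds a small grid of synthetic voxels spanning Gaussian, kurtotic and
two-compartment ground truths on the study protocol (14 shells 0-8 ms/um^2,
12 directions), fits the diffusion tensor (WLLS), the kurtosis tensor
(NLLS, b <= 4.5) and the neurite-density model (multi-start LM, all shells),
and tabulates fitted vs true parameters.

Writes: results/analysis/dmri_model_fits.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"

from cmscortex.dki import dki_signal, fit_dki_signal, isotropic_dki_pair, kurtosis_metrics
from cmscortex.dmri_data import study_protocol
from cmscortex.dti import dti_metrics, fit_dti_signal
from cmscortex.neurite import NeuriteParams, fit_neurite_signal, watson_odf_coeffs
from cmscortex.synth import simulate_voxel


def main(seed: int = 1):
    OUT.mkdir(parents=True, exist_ok=True)
    prot = study_protocol()
    bv, gv = prot.expand()
    rows = []

    # diffusion tensor: prolate truth at two noise levels
    d_true = np.diag([1.0, 0.35, 0.35])
    lam = np.diag(d_true)
    md_true = lam.mean()
    fa_true = float(np.sqrt(1.5 * np.sum((lam - md_true) ** 2) / np.sum(lam**2)))
    for snr in (np.inf, 50.0):
        sig = simulate_voxel((1.0, d_true, np.zeros((3, 3, 3, 3))), prot, snr, seed=seed)
        keep = bv <= 4.5 + 1e-9
        m = dti_metrics(fit_dti_signal(sig[keep], bv[keep], gv[keep]))
        rows.append({"model": "DTI", "snr": snr, "param": "MD",
                     "truth": md_true, "fitted": m["MD"]})
        rows.append({"model": "DTI", "snr": snr, "param": "FA",
                     "truth": fa_true, "fitted": m["FA"]})

    # kurtosis tensor: isotropic K=0.75 truth (two-site mixture cumulants)
    d_iso, w_iso = isotropic_dki_pair(1.0, 0.75)
    for snr in (np.inf, 50.0):
        sig = simulate_voxel((1.0, d_iso, w_iso), prot, snr, seed=seed + 1)
        km = kurtosis_metrics(fit_dki_signal(sig, bv, gv))
        for name, truth in (("MK", 0.75), ("MKT", 0.75), ("W_L", 0.75)):
            rows.append({"model": "DKI", "snr": snr, "param": name,
                         "truth": truth, "fitted": getattr(km, name)})

    # neurite model: dispersed stick + isotropic extra-neurite compartment
    truth = NeuriteParams(neu=0.40, d_long=1.20, d_eff=0.60,
                          odf_coeffs=watson_odf_coeffs([0, 0, 1.0], 4.0, 4))
    for snr in (np.inf, 50.0):
        sig = simulate_voxel(truth, prot, snr, seed=seed + 2)
        p = fit_neurite_signal(sig, bv, gv).params
        for name, t, f in (("Neu", 0.40, p.neu), ("D_L", 1.20, p.d_long),
                           ("D_eff", 0.60, p.d_eff)):
            rows.append({"model": "neurite", "snr": snr, "param": name,
                         "truth": t, "fitted": f})

    df = pd.DataFrame(rows)
    df["abs_err"] = (df.fitted - df.truth).abs()
    df.to_csv(OUT / "dmri_model_fits.csv", index=False, float_format="%.6g")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    noiseless = df[np.isinf(df.snr)]
    print(f"\nnoiseless max |error|: {noiseless.abs_err.max():.2e} "
          f"(all three models recover their truths)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
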