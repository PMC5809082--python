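"""Seeded validation experiments: parameter recovery, calibration, power.

Each function runs a self-contained experiment on synthetic data with known
ground truth and returns summary numbers.  They back both the test suite and
the reproduction script, so the problem sizes here are the canonical ones:
100-point Latin hypercubes for noiseless recovery, 200 Rician replicates at
SNR 50, 2000 null simulations for test calibration, and 100 end-to-end cohort
runs for the planted-effect power experiment.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.stats import qmc

from .dmri_data import study_protocol
from .neurite import FitOptions, NeuriteParams, fit_neurite_signal, isotropic_odf_coeffs, watson_odf_coeffs
from .stats import CohortTable, lmm_group_test, posthoc_pairwise
from .synth import CohortEffectSpec, simulate_cohort_maps, simulate_voxel

log = logging.getLogger(__name__)


def _spherical_dir(u: float, v: float) -> np.ndarray:
    z = 2 * u - 1
    phi = 2 * np.pi * v
    s = np.sqrt(max(1 - z * z, 0.0))
    return np.array([s * np.cos(phi), s * np.sin(phi), z])


def neurite_noiseless_recovery(n_points: int = 100, seed: int = 0) -> dict:
    """Noiseless fit(forward(θ)) ≈ θ over a Latin hypercube of admissible truths.

    Truths are axially symmetric Watson ODFs with dispersion κ ∈ [2, 10] and
    random orientation; ν is kept inside [0.05, 0.95] where the two
    compartments are identifiable.  Returns the maximum relative error over
    (ν, D_L, D_eff) and the per-parameter maxima.
    """
    prot = study_protocol()
    bv, gv = prot.expand()
    sampler = qmc.LatinHypercube(d=6, seed=seed)
    u = sampler.random(n_points)
    lo = np.array([0.05, 0.5, 0.2, 2.0, 0.0, 0.0])
    hi = np.array([0.95, 2.0, 1.5, 10.0, 1.0, 1.0])
    pts = qmc.scale(u, lo, hi)
    errs = np.zeros((n_points, 3))
    for i, (neu, dl, de, kappa, du, dv) in enumerate(pts):
        odf = watson_odf_coeffs(_spherical_dir(du, dv), kappa, order=4)
        truth = NeuriteParams(neu=neu, d_long=dl, d_eff=de, odf_coeffs=odf)
        sig = simulate_voxel(truth, prot, np.inf)
        fit = fit_neurite_signal(sig, bv, gv).params
        errs[i] = [
            abs(fit.neu - neu) / neu,
            abs(fit.d_long - dl) / dl,
            abs(fit.d_eff - de) / de,
        ]
    return {
        "max_rel_err": float(errs.max()),
        "max_rel_err_neu": float(errs[:, 0].max()),
        "max_rel_err_d_long": float(errs[:, 1].max()),
        "max_rel_err_d_eff": float(errs[:, 2].max()),
        "n": n_points,
    }


def neurite_rician_recovery(
    n_replicates: int = 200,
    snr_b0: float = 50.0,
    seed: int = 0,
    truth: NeuriteParams | None = None,
) -> dict:
    """Monte-Carlo bias of the fit under Rician noise at the study SNR.

    Replicates one moderately dispersed voxel; reports the median fitted
    parameters against the planted truth.
    """
    prot = study_protocol()
    bv, gv = prot.expand()
    truth = truth or NeuriteParams(
        neu=0.40, d_long=1.20, d_eff=0.60, odf_coeffs=watson_odf_coeffs([0, 0, 1.0], 4.0, 4)
    )
    rng = np.random.default_rng(seed)
    fits = np.zeros((n_replicates, 3))
    for i in range(n_replicates):
        sig = simulate_voxel(truth, prot, snr_b0, seed=rng)
        p = fit_neurite_signal(sig, bv, gv).params
        fits[i] = [p.neu, p.d_long, p.d_eff]
    med = np.median(fits, axis=0)
    return {
        "median_neu": float(med[0]),
        "median_d_long": float(med[1]),
        "median_d_eff": float(med[2]),
        "truth_neu": truth.neu,
        "truth_d_long": truth.d_long,
        "truth_d_eff": truth.d_eff,
        "n": n_replicates,
    }


def _null_cohort(rng: np.random.Generator, n_animals: int = 8, n_reps: int = 4):
    rows = []
    for g in ("control", "anhedonic", "resilient"):
        for a in range(n_animals):
            animal = f"{g}_{a}"
            eff = rng.normal(0.0, 1.0)
            for r in range(n_reps):
                rows.append((animal, g, "AC", r, "m", eff + rng.normal(0.0, 1.0)))
    return CohortTable.from_records(rows)


def lmm_type1_error(n_sims: int = 2000, alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the group F-test under a balanced null.

    8 animals per group, 4 replicates, between- and within-animal SD 1; a
    calibrated test rejects at ≈ α.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        table = _null_cohort(rng)
        res = lmm_group_test(table, "m", "AC")
        rejections += res.p_value < alpha
    return {"type1_rate": rejections / n_sims, "n": n_sims}


def deff_contrast_power(
    n_runs: int = 100, seed_base: int = 1, alpha: float = 0.05
) -> dict:
    """End-to-end power of the planted auditory-cortex D_eff effect.

    Each run simulates the full cohort at the d-MRI level (per-animal volumes,
    Rician noise at SNR 50), fits the neurite model voxel-wise, aggregates
    slice-wise ROI means, and runs the mixed model with FDR post hocs.
    Reports how often both control-vs-stress contrasts come out FDR-significant
    and how often the stress groups' descriptive CIs are wider than control's.
    """
    from .stats import aggregate_roi

    opts = FitOptions(
        sh_order=0, start_neu=(0.3, 0.7), start_d_long=(0.8, 1.5), start_d_eff=(0.4, 0.9)
    )
    hits = 0
    wider = 0
    for r in range(n_runs):
        spec = CohortEffectSpec(seed=seed_base + r)
        datasets, meta, _ = simulate_cohort_maps(spec)
        maps_by_animal = {}
        mask = None
        for animal, (ds, roi_mask) in datasets.items():
            from .neurite import fit_neurite

            fit = fit_neurite(ds, options=opts)
            maps_by_animal[animal] = [fit.metrics()["D_eff"]]
            mask = roi_mask
        table = aggregate_roi(maps_by_animal, mask, meta)
        res = posthoc_pairwise(lmm_group_test(table, "D_eff", "AC"), alpha=alpha)
        sig = {
            c.contrast: (c.p_fdr is not None and c.p_fdr < alpha) for c in res.pairwise
        }
        if sig.get("anhedonic - control") and sig.get("resilient - control"):
            hits += 1
        gm = res.group_means
        width = {g: v["ci_high"] - v["ci_low"] for g, v in gm.items()}
        stress_mean = 0.5 * (width["anhedonic"] + width["resilient"])
        if stress_mean > width["control"]:
            wider += 1
    return {
        "pct_both_contrasts_significant": 100.0 * hits / n_runs,
        "pct_stress_ci_wider": 100.0 * wider / n_runs,
        "n": n_runs,
    }


def monotone_power_check(seed: int = 0, n_runs: int = 40, alpha: float = 0.05) -> dict:
    """Power at the study's group sizes vs a 3/3/3 miniature (table-level).

    Uses the planted AC D_eff effect at the cohort-table level (no fitting) so
    the comparison isolates the design-size effect on the mixed-model test.
    """
    from .synth import simulate_cohort_table

    def run(groups, seed):
        spec = CohortEffectSpec(groups=groups, seed=seed)
        table, _ = simulate_cohort_table(spec)
        res = lmm_group_test(table, "D_eff", "AC")
        return res.p_value < alpha

    full = sum(
        run({"control": 8, "anhedonic": 7, "resilient": 8}, seed + i) for i in range(n_runs)
    )
    mini = sum(
        run({"control": 3, "anhedonic": 3, "resilient": 3}, seed + i) for i in range(n_runs)
    )
    return {
        "power_full": full / n_runs,
        "power_mini": mini / n_runs,
        "n": n_runs,
    }
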