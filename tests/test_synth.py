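"""Generators: determinism, noise contract, exact truth bookkeeping."""

import numpy as np
import pytest

from cmscortex.dmri_data import DIRECTIONS_12, DiffusionProtocol
from cmscortex.neurite import NeuriteParams, isotropic_odf_coeffs, neurite_forward
from cmscortex.synth import (
    CohortEffectSpec,
    MicrographSpec,
    simulate_cohort_maps,
    simulate_cohort_table,
    simulate_voxel,
    synth_cortex_montage,
    synth_micrograph,
)


def test_noiseless_equals_forward(protocol):
    p = NeuriteParams(0.4, 1.2, 0.6, isotropic_odf_coeffs(0))
    sim = simulate_voxel(p, protocol, np.inf)
    np.testing.assert_array_equal(sim, neurite_forward(p, protocol))


def test_same_seed_identical_vectors(protocol):
    p = NeuriteParams(0.4, 1.2, 0.6, isotropic_odf_coeffs(0))
    a = simulate_voxel(p, protocol, 50.0, seed=42)
    b = simulate_voxel(p, protocol, 50.0, seed=42)
    np.testing.assert_array_equal(a, b)
    c = simulate_voxel(p, protocol, 50.0, seed=43)
    assert not np.array_equal(a, c)


def test_invalid_snr_rejected(protocol):
    p = NeuriteParams(0.4, 1.2, 0.6, isotropic_odf_coeffs(0))
    with pytest.raises(ValueError, match="snr"):
        simulate_voxel(p, protocol, 0.0)


def test_rician_noise_contract():
    """At SNR 50 the b=0 magnitude mean exceeds S0 by the Rician bias and the
    per-channel noise SD is S0/SNR within 3%."""
    prot = DiffusionProtocol(bvalues=[0.0], directions=DIRECTIONS_12)
    p = NeuriteParams(0.4, 1.2, 0.6, isotropic_odf_coeffs(0), s0=1.0)
    rng = np.random.default_rng(7)
    draws = np.concatenate(
        [simulate_voxel(p, prot, 50.0, seed=rng) for _ in range(20000)]
    )
    sigma = 1.0 / 50.0
    # magnitude SD ≈ per-channel sigma in the high-SNR regime
    assert abs(draws.std(ddof=1) - sigma) / sigma < 0.03
    # Rician bias: E|S + n| ≈ S0 + σ²/(2 S0)
    bias = draws.mean() - 1.0
    assert bias > 0
    assert bias == pytest.approx(sigma**2 / 2, rel=0.5)


def test_cohort_table_zero_variance_collapses_to_means():
    spec = CohortEffectSpec(seed=0)
    for cell in spec.effects.values():
        cell.between_sd = cell.within_sd = 0.0
    table, truth = simulate_cohort_table(spec)
    sub = table.df[(table.df.metric == "D_eff") & (table.df.roi == "AC")]
    for g, want in (("control", 0.60), ("anhedonic", 0.48), ("resilient", 0.48)):
        assert (sub[sub.group == g].value == want).all()


def test_cohort_table_deterministic():
    a, _ = simulate_cohort_table(CohortEffectSpec(seed=5))
    b, _ = simulate_cohort_table(CohortEffectSpec(seed=5))
    assert a.df.equals(b.df)


def test_cohort_spec_validation():
    with pytest.raises(ValueError, match="2 animals"):
        CohortEffectSpec(groups={"control": 1, "anhedonic": 4})
    with pytest.raises(ValueError, match="D_eff"):
        simulate_cohort_maps(CohortEffectSpec(), metric="FA")


def test_cohort_maps_structure_and_determinism():
    spec = CohortEffectSpec(seed=9)
    ds_a, meta_a, truth_a = simulate_cohort_maps(spec)
    ds_b, _, truth_b = simulate_cohort_maps(CohortEffectSpec(seed=9))
    assert len(ds_a) == 23  # 8 + 7 + 8 animals
    assert truth_a.equals(truth_b)
    a0 = next(iter(ds_a))
    np.testing.assert_array_equal(ds_a[a0][0].signal, ds_b[a0][0].signal)
    assert ds_a[a0][0].signal.shape == (4, 1, 3, 168)
    assert sorted(meta_a.group.unique()) == ["anhedonic", "control", "resilient"]


def test_micrograph_truth_matches_brute_force_pixel_count():
    micro, truth = synth_micrograph(MicrographSpec(seed=4))
    label = truth["label"]
    assert truth["process_fraction_pct"] == pytest.approx(
        100.0 * np.count_nonzero(label == 1) / label.size
    )
    assert truth["n_bodies"] == len(truth["bodies"])
    # somata and processes never touch (margin enforced by construction)
    from scipy.ndimage import binary_dilation

    grown = binary_dilation(label == 2, iterations=2)
    assert not (grown & (label == 1)).any()


def test_micrograph_deterministic():
    a, ta = synth_micrograph(MicrographSpec(seed=8))
    b, tb = synth_micrograph(MicrographSpec(seed=8))
    np.testing.assert_array_equal(a.pixels, b.pixels)
    assert ta["process_fraction_pct"] == tb["process_fraction_pct"]


def test_micrograph_blank_field():
    micro, truth = synth_micrograph(MicrographSpec(seed=1, axon_area_fraction=0.0))
    assert truth["process_fraction_pct"] == 0.0
    from cmscortex.histology import StainProfile, quantify_density

    res = quantify_density(micro, StainProfile())
    assert res.density_pct < 0.5


def test_micrograph_unreachable_fraction_rejected():
    with pytest.raises(ValueError):
        synth_micrograph(MicrographSpec(seed=0, size_px=48, axon_area_fraction=0.5,
                                        n_cell_bodies=4))


def test_montage_flat_band_measures_exactly():
    _, lines, truth = synth_cortex_montage({"MC": 1500.0}, um_per_px=5.0, undulation_frac=0.0)
    from cmscortex.histology import cortical_thickness

    out = cortical_thickness(lines, 5.0, warn_protocol=False)
    np.testing.assert_allclose(out.thickness_um, 1500.0, atol=1e-9)
    assert len(out) == 5


def test_montage_undulating_within_bound():
    _, lines, truth = synth_cortex_montage(
        {"MC": 1800.0, "SC": 1700.0}, um_per_px=5.0, seed=3, undulation_frac=0.05
    )
    from cmscortex.histology import cortical_thickness

    out = cortical_thickness(lines, 5.0, warn_protocol=False)
    for roi, want in truth.items():
        got = out[out.roi == roi].thickness_um
        assert (np.abs(got - want) / want < 0.05).all()


def test_montage_determinism_and_validation():
    _, a, _ = synth_cortex_montage({"MC": 1500.0}, seed=6, undulation_frac=0.05)
    _, b, _ = synth_cortex_montage({"MC": 1500.0}, seed=6, undulation_frac=0.05)
    assert a.equals(b)
    with pytest.raises(ValueError, match="positive"):
        synth_cortex_montage({"MC": -5.0})
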