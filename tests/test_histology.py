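"""Stain-density chain and cortical-thickness measurement."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk, line
from skimage.transform import downscale_local_mean

from cmscortex.histology import (
    CellBodyCriteria,
    Micrograph,
    StainProfile,
    batch_enhancement_settings,
    binarize_stain,
    cortical_thickness,
    density_percent,
    preprocess_micrograph,
    quantify_density,
    read_micrograph,
    remove_cell_bodies,
    write_micrograph,
)
from cmscortex.synth import MicrographSpec, synth_micrograph


def white_image(h=64, w=64):
    return Micrograph(np.ones((h, w, 3)), um_per_px=0.5)


def test_pure_white_maps_to_zero_stain():
    with pytest.warns(UserWarning, match="constant"):  # no stain → no range
        enhanced = preprocess_micrograph(white_image())
    assert enhanced.max() == 0.0


def test_dark_structures_land_in_top_decile():
    px = np.ones((64, 64, 3))
    px[10:20, 10:20] = 0.2  # dark square on white
    enhanced = preprocess_micrograph(Micrograph(px, um_per_px=0.5))
    assert enhanced[12, 12] > 0.9
    assert enhanced[40, 40] < 0.1


def test_constant_image_warns_and_skips_enhancement():
    px = np.full((32, 32, 3), 0.5)
    with pytest.warns(UserWarning, match="constant"):
        preprocess_micrograph(Micrograph(px, um_per_px=0.5))


def test_batch_settings_make_processing_identical():
    rng = np.random.default_rng(0)
    imgs = [
        Micrograph(np.clip(rng.uniform(0.6, 1.0, (48, 48, 3)), 0, 1), um_per_px=0.5)
        for _ in range(2)
    ]
    white_ref, stretch = batch_enhancement_settings(imgs)
    a = [preprocess_micrograph(i, white_ref=white_ref, stretch=stretch) for i in imgs]
    b = [preprocess_micrograph(i, white_ref=white_ref, stretch=stretch) for i in imgs]
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_binarize_threshold_is_fraction_of_range():
    img = np.zeros((10, 10))
    img[:, 5:] = 1.0  # exactly half above any mid threshold
    mask = binarize_stain(img, 0.30)
    assert mask.mean() == pytest.approx(0.5)
    # constructed 12%-above image
    img = np.zeros((10, 10))
    img.flat[:12] = 0.9
    assert binarize_stain(img, 0.30).mean() == pytest.approx(0.12)


def test_binarize_uniform_zero_empty_and_bounds():
    assert not binarize_stain(np.zeros((5, 5)), 0.3).any()
    img = np.linspace(0, 1, 25).reshape(5, 5)
    assert binarize_stain(img, 0.0).all()  # boundary: everything passes
    with pytest.raises(ValueError):
        binarize_stain(img, 1.0)
    with pytest.raises(ValueError):
        binarize_stain(img, -0.1)


def _disc_and_lines_mask():
    """One soma-sized disc plus three non-crossing 2-px polylines."""
    mask = np.zeros((128, 128), bool)
    rr, cc = disk((40, 40), 15)  # 15 px radius = 15 μm diameter at 0.5 μm/px
    mask[rr, cc] = True
    for y0, x0, y1, x1 in ((80, 5, 90, 120), (100, 5, 100, 120), (110, 5, 120, 120)):
        rr, cc = line(y0, x0, y1, x1)
        mask[rr, cc] = True
        mask[rr + 1, cc] = True  # 2 px wide
    return mask


def test_disc_removed_polylines_retained():
    mask = _disc_and_lines_mask()
    process, bodies = remove_cell_bodies(mask, CellBodyCriteria(), um_per_px=0.5)
    assert bodies.sum() > 0
    # the disc is gone from the process mask, the polylines survive intact
    assert not process[40, 40]
    assert process[100, 60]
    from skimage.measure import label

    assert label(bodies, connectivity=2).max() == 1


def test_thin_components_left_untouched():
    mask = np.zeros((64, 64), bool)
    rr, cc = line(5, 5, 60, 50)
    mask[rr, cc] = True
    mask[rr, cc - 1] = True
    process, bodies = remove_cell_bodies(mask, CellBodyCriteria(), um_per_px=0.5)
    assert not bodies.any()
    np.testing.assert_array_equal(process, mask)


def test_oversized_disc_not_a_body():
    mask = np.zeros((128, 128), bool)
    rr, cc = disk((64, 64), 40)  # 40 μm diameter at 0.5 μm/px > 25 μm bound
    mask[rr, cc] = True
    process, bodies = remove_cell_bodies(mask, CellBodyCriteria(), um_per_px=0.5)
    assert not bodies.any()
    np.testing.assert_array_equal(process, mask)


def test_density_arithmetic():
    mask = np.zeros((100, 100), bool)
    mask.flat[:500] = True
    res = density_percent(mask)
    assert res.density_pct == pytest.approx(5.0)
    assert density_percent(np.zeros((10, 10), bool)).density_pct == 0.0


def test_pixel_conservation_invariant():
    """process ∪ (body ∩ binary) = binary: no pixel class is created or lost."""
    mask = _disc_and_lines_mask()
    process, bodies = remove_cell_bodies(mask, CellBodyCriteria(), um_per_px=0.5)
    assert int(process.sum()) + int((bodies & mask).sum()) == int(mask.sum())
    assert not (process & bodies).any()


def test_full_chain_recovers_planted_fraction():
    spec = MicrographSpec(seed=17)
    micro, truth = synth_micrograph(spec)
    res = quantify_density(micro, StainProfile())
    assert abs(res.density_pct - truth["process_fraction_pct"]) < 1.5
    assert abs(res.body_components - truth["n_bodies"]) <= 1


def test_density_roughly_scale_invariant():
    # higher-resolution field so strokes stay resolved after ×2 downsampling
    micro, truth = synth_micrograph(
        MicrographSpec(seed=23, size_px=768, um_per_px=0.4, process_width_um=(1.6, 2.4))
    )
    res_full = quantify_density(micro, StainProfile())
    small = downscale_local_mean(micro.pixels, (2, 2, 1))
    micro_small = Micrograph(np.clip(small, 0, 1), um_per_px=micro.um_per_px * 2)
    res_small = quantify_density(micro_small, StainProfile())
    assert abs(res_full.density_pct - res_small.density_pct) < 1.0


@pytest.mark.parametrize("name", ["field.tif", "field.png"])
def test_micrograph_file_roundtrip(tmp_path, name):
    rng = np.random.default_rng(5)
    px = rng.uniform(0.2, 1.0, size=(32, 32, 3))
    img = Micrograph(px, um_per_px=0.5, stain="MAP2")
    write_micrograph(img, tmp_path / name)
    back = read_micrograph(tmp_path / name, um_per_px=0.5, stain="MAP2")
    assert back.pixels.shape == (32, 32, 3)
    assert back.stain == "MAP2"
    np.testing.assert_allclose(back.pixels, px, atol=1 / 255)


# ---------------------------------------------------------------------------
# cortical thickness


def test_axis_aligned_line():
    lines = pd.DataFrame({"roi": ["MC"], "x1": [0.0], "y1": [0.0], "x2": [0.0], "y2": [400.0]})
    out = cortical_thickness(lines, um_per_px=5.0, warn_protocol=False)
    assert out.thickness_um.iloc[0] == pytest.approx(2000.0)


def test_3_4_5_triangle():
    lines = pd.DataFrame({"roi": ["MC"], "x1": [0.0], "y1": [0.0], "x2": [300.0], "y2": [400.0]})
    out = cortical_thickness(lines, um_per_px=1.0, warn_protocol=False)
    assert out.thickness_um.iloc[0] == pytest.approx(500.0)


def test_zero_length_lines_skipped_with_warning():
    lines = pd.DataFrame(
        {"roi": ["MC", "MC"], "x1": [0.0, 1.0], "y1": [0.0, 1.0], "x2": [0.0, 4.0], "y2": [0.0, 5.0]}
    )
    with pytest.warns(UserWarning, match="zero-length"):
        out = cortical_thickness(lines, um_per_px=1.0, warn_protocol=False)
    assert len(out) == 1
    assert out.thickness_um.iloc[0] == pytest.approx(5.0)


def test_protocol_shortfall_warns_not_errors():
    lines = pd.DataFrame(
        {"image": ["m0"] * 2, "roi": ["MC"] * 2, "x1": [0.0, 1.0], "y1": [0.0] * 2,
         "x2": [0.0, 1.0], "y2": [10.0, 12.0]}
    )
    with pytest.warns(UserWarning, match="3 montages"):
        out = cortical_thickness(lines, um_per_px=1.0)
    assert len(out) == 2


def test_invalid_inputs():
    lines = pd.DataFrame({"roi": ["MC"], "x1": [0.0], "y1": [0.0], "x2": [1.0], "y2": [0.0]})
    with pytest.raises(ValueError):
        cortical_thickness(lines, um_per_px=0.0)
    with pytest.raises(ValueError, match="columns"):
        cortical_thickness(pd.DataFrame({"roi": ["MC"]}), um_per_px=1.0)
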