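"""DAB-stain quantification: axonal/dendritic density [%] and cortical thickness.

The density chain mirrors the standard automated workflow for
DAB-immunostained micrographs: luminosity scaling against the unstained
background, contrast enhancement, a 30 %-of-signal-range threshold, removal of
neuronal cell bodies by connected-component shape criteria (eccentricity and
equivalent diameter), and an area fraction over the full image.  NF-H
(axons) and MAP2 (dendrites) use the identical chain with per-stain
enhancement/criteria profiles that differ only in configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage import measure

log = logging.getLogger(__name__)


def read_micrograph(path, um_per_px: float, **metadata) -> "Micrograph":
    """Load a TIFF/PNG micrograph with its pixel calibration.

    TIFFs go through tifffile, everything else through Pillow; grayscale
    images are promoted to RGB.
    """
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        px = tifffile.imread(str(path))
    else:
        from PIL import Image

        px = np.asarray(Image.open(path).convert("RGB"))
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    return Micrograph(pixels=px, um_per_px=um_per_px, **metadata)


def write_micrograph(img: "Micrograph", path) -> None:
    """Write pixels as 8-bit TIFF (via tifffile) or PNG (via Pillow)."""
    from pathlib import Path

    path = Path(path)
    px = (np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), px)
    else:
        from PIL import Image

        Image.fromarray(px).save(path)


@dataclass
class Micrograph:
    """Calibrated RGB micrograph with cohort metadata."""

    pixels: np.ndarray  # (H, W, 3), float in [0, 1] or uint8
    um_per_px: float
    stain: str = "NF-H"  # NF-H (axonal) or MAP2 (dendritic)
    roi: str = ""
    animal_id: str = ""
    group: str = ""
    section_index: int = 0

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("pixels must be a non-empty (H, W, 3) RGB array")
        if px.dtype == np.uint8:
            px = px.astype(float) / 255.0
        self.pixels = np.clip(px.astype(float), 0.0, 1.0)


@dataclass
class CellBodyCriteria:
    """Shape gates for soma removal.

    Neuronal somata appear as nearly round blobs of 6–25 μm equivalent
    diameter; processes are thin and elongated.  The defaults are declared
    (the workflow exposes, not infers, them) and echoed in reports.
    """

    max_eccentricity: float = 0.85
    min_equiv_diameter_um: float = 6.0
    max_equiv_diameter_um: float = 25.0
    min_area_px: int = 20

    def __post_init__(self):
        if not (0.0 <= self.max_eccentricity <= 1.0):
            raise ValueError("eccentricity bound must lie in [0, 1]")
        if self.min_equiv_diameter_um > self.max_equiv_diameter_um:
            raise ValueError("diameter bounds out of order")


@dataclass
class DensityResult:
    density_pct: float
    foreground_px: int
    body_px: int
    total_px: int
    body_components: int


@dataclass
class StainProfile:
    """Per-stain processing settings (NF-H vs MAP2 differ only here)."""

    threshold_frac: float = 0.30
    channel_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    stretch_percentiles: tuple = (1.0, 99.0)
    criteria: CellBodyCriteria = None

    def __post_init__(self):
        if self.criteria is None:
            self.criteria = CellBodyCriteria()


def _luminance(pixels: np.ndarray, weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    return pixels @ (w / w.sum())


def preprocess_micrograph(
    img: Micrograph,
    profile: StainProfile | None = None,
    white_ref: float | None = None,
    stretch: tuple[float, float] | None = None,
) -> np.ndarray:
    """Enhanced stain-intensity image in [0, 1] (higher = more stain).

    Luminosity scaling divides the channels by the white reference — the 99th
    percentile luminance of the least-stained (brightest) pixel decile — then
    stain intensity is one minus the scaled luminance of the DAB-weighted
    channel combination, stretched between its 1st and 99th percentiles.
    Passing precomputed ``white_ref``/``stretch`` applies identical settings
    across a batch.
    """
    profile = profile or StainProfile()
    lum = _luminance(img.pixels, profile.channel_weights)
    if white_ref is None:
        decile = np.quantile(lum, 0.9)
        background = lum[lum >= decile]
        white_ref = float(np.percentile(background, 99.0))
    if white_ref <= 0:
        white_ref = 1.0
    stain = 1.0 - np.clip(lum / white_ref, 0.0, 1.0)
    if stretch is None:
        lo, hi = np.percentile(stain, profile.stretch_percentiles)
    else:
        lo, hi = stretch
    if hi - lo < 1e-9:
        warnings.warn("constant image: contrast enhancement skipped", stacklevel=2)
        return np.clip(stain, 0.0, 1.0)
    return np.clip((stain - lo) / (hi - lo), 0.0, 1.0)


def batch_enhancement_settings(
    imgs: list[Micrograph], profile: StainProfile | None = None
) -> tuple[float, tuple[float, float]]:
    """Global (white_ref, stretch) so every image in a batch is processed identically."""
    profile = profile or StainProfile()
    lums = np.concatenate([_luminance(i.pixels, profile.channel_weights).ravel() for i in imgs])
    decile = np.quantile(lums, 0.9)
    white_ref = float(np.percentile(lums[lums >= decile], 99.0))
    stains = 1.0 - np.clip(lums / white_ref, 0.0, 1.0)
    lo, hi = np.percentile(stains, profile.stretch_percentiles)
    return white_ref, (float(lo), float(hi))


def binarize_stain(enhanced: np.ndarray, threshold_frac: float = 0.30) -> np.ndarray:
    """Foreground where intensity ≥ ``threshold_frac`` of the image's range.

    The threshold is relative to the post-enhancement signal level:
    ``thr = min + frac·(max − min)`` per image.
    """
    if not (0.0 <= threshold_frac < 1.0):
        raise ValueError("threshold_frac must lie in [0, 1)")
    lo, hi = float(enhanced.min()), float(enhanced.max())
    if hi - lo < 1e-12:  # no signal range → nothing is stain
        return np.zeros_like(np.asarray(enhanced), dtype=bool)
    thr = lo + threshold_frac * (hi - lo)
    return enhanced >= thr


def remove_cell_bodies(
    binary: np.ndarray, criteria: CellBodyCriteria, um_per_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split a binary stain mask into process and cell-body masks.

    8-connected components are hole-filled (nuclear counterstain leaves holes
    inside somata) before shape measurement; components that are round enough
    (eccentricity ≤ bound) with an equivalent diameter inside the soma range
    are classified as bodies and subtracted.  Returns
    ``(process_mask, body_mask)``.
    """
    binary = np.asarray(binary, dtype=bool)
    body_mask = np.zeros_like(binary)
    if not binary.any():
        return binary.copy(), body_mask
    labels = measure.label(binary, connectivity=2)
    for region in measure.regionprops(labels):
        filled = binary_fill_holes(region.image)
        area = int(filled.sum())
        if area < criteria.min_area_px:
            continue
        equiv_um = 2.0 * np.sqrt(area / np.pi) * um_per_px
        if not (criteria.min_equiv_diameter_um <= equiv_um <= criteria.max_equiv_diameter_um):
            if equiv_um > criteria.max_equiv_diameter_um:
                log.debug(
                    "component of equivalent diameter %.1f μm exceeds the soma bound; kept",
                    equiv_um,
                )
            continue
        ecc = measure.regionprops(filled.astype(np.uint8))[0].eccentricity
        if ecc <= criteria.max_eccentricity:
            sl = region.slice
            body_mask[sl] |= filled
    process_mask = binary & ~body_mask
    return process_mask, body_mask


def density_percent(
    process_mask: np.ndarray,
    binary: np.ndarray | None = None,
    body_mask: np.ndarray | None = None,
) -> DensityResult:
    """Stain-positive area fraction: 100 × process pixels / total pixels."""
    process_mask = np.asarray(process_mask, dtype=bool)
    total = int(process_mask.size)
    fg = int(binary.sum()) if binary is not None else int(process_mask.sum())
    body_px = 0
    n_bodies = 0
    if body_mask is not None:
        body_mask = np.asarray(body_mask, dtype=bool)
        body_px = int(body_mask.sum())
        n_bodies = int(measure.label(body_mask, connectivity=2).max())
    return DensityResult(
        density_pct=100.0 * process_mask.sum() / total,
        foreground_px=fg,
        body_px=body_px,
        total_px=total,
        body_components=n_bodies,
    )


def quantify_density(
    img: Micrograph,
    profile: StainProfile | None = None,
    white_ref: float | None = None,
    stretch: tuple[float, float] | None = None,
) -> DensityResult:
    """Full chain: enhance → threshold → remove somata → area fraction."""
    profile = profile or StainProfile()
    enhanced = preprocess_micrograph(img, profile, white_ref=white_ref, stretch=stretch)
    binary = binarize_stain(enhanced, profile.threshold_frac)
    process, bodies = remove_cell_bodies(binary, profile.criteria, img.um_per_px)
    return density_percent(process, binary=binary, body_mask=bodies)


def cortical_thickness(
    lines: pd.DataFrame, um_per_px: float, warn_protocol: bool = True
) -> pd.DataFrame:
    """Thickness per annotation line: Euclidean endpoint distance × calibration.

    ``lines`` needs columns ``roi, x1, y1, x2, y2`` (an ``image`` column, if
    present, identifies the montage).  Zero-length lines are skipped with a
    warning; fewer than 3 montages × 5 lines per ROI triggers a protocol
    warning, not an error.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    required = {"roi", "x1", "y1", "x2", "y2"}
    if not required.issubset(lines.columns):
        raise ValueError(f"line table needs columns {sorted(required)}")
    if len(lines) == 0:
        raise ValueError("no annotation lines")
    lines = lines.copy()
    d_px = np.hypot(lines.x2 - lines.x1, lines.y2 - lines.y1)
    zero = d_px < 1e-12
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} zero-length lines", stacklevel=2)
        lines = lines[~zero]
        d_px = d_px[~zero]
    lines["thickness_um"] = d_px * um_per_px
    if warn_protocol:
        montage_col = "image" if "image" in lines.columns else None
        for roi, sub in lines.groupby("roi"):
            n_montages = sub[montage_col].nunique() if montage_col else 1
            per = sub.groupby(montage_col).size() if montage_col else pd.Series([len(sub)])
            if n_montages < 3 or (per < 5).any():
                warnings.warn(
                    f"ROI {roi}: protocol is >= 3 montages with 5 lines each "
                    f"(got {n_montages} montages)",
                    stacklevel=2,
                )
    keep = ["roi", "thickness_um"] + (["image"] if "image" in lines.columns else [])
    return lines[keep].reset_index(drop=True)
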