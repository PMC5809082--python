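"""Synthetic-data generators with known ground truth for every pipeline input.

Every generator is a pure function of its spec and seed.  The cohort
templates encode the study's qualitative effect structure — lower
extracellular diffusivity in auditory cortex of both stress groups, higher FA
and axonal density and lower cortical thickness in motor cortex, and inflated
variance in the stress groups — with configurable magnitudes, since the
effect sizes themselves are free parameters of the emulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk
from skimage.morphology import dilation, footprint_rectangle

from .dmri_data import DiffusionProtocol, DWIDataset, ROIMask, study_protocol
from .dki import dki_signal
from .histology import Micrograph
from .neurite import NeuriteParams, isotropic_odf_coeffs, neurite_forward

log = logging.getLogger(__name__)

#: group sizes after the study's exclusions (two damaged anhedonic brains,
#: one failed control perfusion)
DEFAULT_GROUPS = {"control": 8, "anhedonic": 7, "resilient": 8}
ROIS = ("MC", "SC", "AC", "VC")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# single-voxel d-MRI simulation


def simulate_voxel(
    truth,
    protocol: DiffusionProtocol,
    snr_b0: float = np.inf,
    seed=0,
) -> np.ndarray:
    """Noisy magnitude signal of one voxel.

    ``truth`` is either a :class:`NeuriteParams` or a ``(s0, D, W)`` tuple for
    the kurtosis forward model.  Finite ``snr_b0`` adds Rician noise: the
    magnitude of the signal plus a complex Gaussian with per-channel standard
    deviation ``s0 / snr_b0``.
    """
    if not np.isinf(snr_b0) and snr_b0 <= 0:
        raise ValueError("snr_b0 must be positive (or infinite for noiseless)")
    bvals, bvecs = protocol.expand()
    if isinstance(truth, NeuriteParams):
        clean = neurite_forward(truth, bvals=bvals, bvecs=bvecs)
        s0 = truth.s0
    else:
        s0, d_tensor, w_tensor = truth
        clean = dki_signal(s0, d_tensor, w_tensor, bvals, bvecs)
    if np.isinf(snr_b0):
        return clean
    rng = _rng(seed)
    sigma = s0 / snr_b0
    noise = rng.normal(0.0, sigma, size=(2,) + clean.shape)
    return np.hypot(clean + noise[0], noise[1])


# ---------------------------------------------------------------------------
# cohort generator


@dataclass
class EffectCell:
    """Per (metric, roi) effect description."""

    means: dict[str, float]
    between_sd: float
    within_sd: float
    inflation: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "anhedonic": 1.5, "resilient": 1.5}
    )


@dataclass
class CohortEffectSpec:
    """Hierarchical-effect specification for the synthetic cohort."""

    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    rois: tuple = ROIS
    effects: dict = field(default_factory=lambda: default_effect_template())
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("need >= 2 animals per group")
        for (metric, roi), cell in self.effects.items():
            if cell.between_sd < 0 or cell.within_sd < 0:
                raise ValueError(f"negative SD for {(metric, roi)}")


def default_effect_template() -> dict:
    """Effect magnitudes for the qualitative finding structure.

    Directions follow the reported pattern (stress effects on AC D_eff, MC
    FA/axonal density/thickness); the magnitudes are plausible ex-vivo values
    chosen once for the emulation, with stress-group variance inflated 1.5×.
    """
    t: dict = {}

    def cell(metric, roi, ctrl, anh, res, b_sd, w_sd):
        t[(metric, roi)] = EffectCell(
            means={"control": ctrl, "anhedonic": anh, "resilient": res},
            between_sd=b_sd,
            within_sd=w_sd,
        )

    for roi in ROIS:
        # neurite model parameters
        cell("D_eff", roi, 0.60, *((0.48, 0.48) if roi == "AC" else (0.57, 0.57)), 0.03, 0.03)
        cell("Neu", roi, 0.40, 0.43, 0.43, 0.03, 0.03)
        cell("D_L", roi, 1.20, 1.20, 1.20, 0.08, 0.08)
        # tensor metrics
        cell("FA", roi, 0.20, *((0.22, 0.26) if roi == "MC" else (0.20, 0.20)), 0.02, 0.02)
        cell("MD", roi, 0.55, *((0.52, 0.53) if roi == "AC" else (0.55, 0.55)), 0.03, 0.03)
        # histology
        cell("axonal_density_pct", roi, 8.0, *((8.5, 10.0) if roi == "MC" else (8.0, 8.0)), 1.0, 1.0)
        cell("dendritic_density_pct", roi, 12.0, 12.0, 12.0, 1.5, 1.5)
        cell("cortical_thickness_um", roi,
             *((1800.0, 1660.0, 1650.0) if roi == "MC" else (1650.0, 1640.0, 1640.0)),
             60.0, 60.0)
    return t


def _animal_ids(groups: dict[str, int]) -> list[tuple[str, str]]:
    return [(f"{g[:3]}{i + 1:02d}", g) for g in groups for i in range(groups[g])]


def simulate_cohort_table(spec: CohortEffectSpec):
    """Draw the hierarchical cohort directly at the metric level.

    Returns ``(CohortTable, truth)`` where truth lists the per-animal latent
    means in the same tidy schema (replicate = -1 marks the latent row).
    """
    from .stats import CohortTable

    rng = _rng(spec.seed)
    records, truth_rows = [], []
    animals = _animal_ids(spec.groups)
    for (metric, roi), cell in spec.effects.items():
        for animal, group in animals:
            infl = cell.inflation.get(group, 1.0)
            latent = cell.means[group] + rng.normal(0.0, cell.between_sd * infl)
            truth_rows.append((animal, group, roi, -1, metric, latent))
            for rep in range(spec.n_replicates):
                records.append(
                    (animal, group, roi, rep, metric,
                     latent + rng.normal(0.0, cell.within_sd * infl))
                )
    return CohortTable.from_records(records), pd.DataFrame(
        truth_rows, columns=["animal_id", "group", "roi", "replicate", "metric", "value"]
    )


def simulate_cohort_maps(
    spec: CohortEffectSpec,
    metric: str = "D_eff",
    roi: str = "AC",
    protocol: DiffusionProtocol | None = None,
    n_voxels_per_slice: int = 4,
    snr_b0: float = 50.0,
    base_neu: float = 0.40,
    base_d_long: float = 1.20,
):
    """Simulate per-animal d-MRI volumes so the full fitting chain can run.

    Each animal gets a miniature volume — ``n_replicates`` slices of
    ``n_voxels_per_slice`` voxels, all labelled with the target ROI — whose
    size is chosen so the per-slice mean's fitting noise stays subdominant to
    the planted within-animal variability (a real ROI cross-section averages
    far more voxels, making fit noise negligible there); the planted
    variance structure, not Monte-Carlo fit error, must drive the group
    statistics.  Signals come from the two-compartment forward model with
    the animal/slice-level effect draws planted on the chosen metric
    (currently the extracellular diffusivity).
    Returns ``(datasets, meta, truth)``.
    """
    if metric != "D_eff":
        raise ValueError("map-mode simulation plants effects on D_eff")
    protocol = protocol or study_protocol()
    cell = spec.effects[(metric, roi)]
    rng = _rng(spec.seed)
    datasets: dict[str, tuple[DWIDataset, ROIMask]] = {}
    meta_rows, truth_rows = [], []
    odf = isotropic_odf_coeffs(0)
    n_slices = spec.n_replicates
    for animal, group in _animal_ids(spec.groups):
        infl = cell.inflation.get(group, 1.0)
        latent = cell.means[group] + rng.normal(0.0, cell.between_sd * infl)
        signal = np.zeros((n_voxels_per_slice, 1, n_slices, protocol.n_measurements))
        for k in range(n_slices):
            slice_val = np.clip(
                latent + rng.normal(0.0, cell.within_sd * infl), 0.05, 2.9
            )
            truth_rows.append((animal, group, roi, k, metric, float(slice_val)))
            params = NeuriteParams(
                neu=base_neu, d_long=base_d_long, d_eff=float(slice_val), odf_coeffs=odf
            )
            for v in range(n_voxels_per_slice):
                signal[v, 0, k] = simulate_voxel(params, protocol, snr_b0, seed=rng)
        ds = DWIDataset(signal=signal, protocol=protocol)
        mask = ROIMask(
            labels=np.ones(signal.shape[:3], dtype=np.int16),
            label_names={1: roi},
            slice_range=(0, n_slices),
            axis=2,
        )
        datasets[animal] = (ds, mask)
        meta_rows.append({"animal_id": animal, "group": group})
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        truth_rows, columns=["animal_id", "group", "roi", "replicate", "metric", "value"]
    )
    return datasets, meta, truth


# ---------------------------------------------------------------------------
# micrograph generator


@dataclass
class MicrographSpec:
    """Planted-truth stained-field description.

    The rendered field is a white background with dark quasi-circular somata
    and thin curvilinear processes; processes are kept clear of somata (with a
    margin) so the planted inventory stays exact under connected-component
    analysis.
    """

    size_px: int = 512
    um_per_px: float = 0.5
    axon_area_fraction: float = 0.08
    dendrite_area_fraction: float = 0.10
    n_cell_bodies: int = 10
    body_diameter_um: tuple = (12.0, 18.0)
    process_width_um: tuple = (0.6, 1.2)
    background_noise_sd: float = 0.01
    stain: str = "NF-H"
    seed: int = 0

    def __post_init__(self):
        for frac in (self.axon_area_fraction, self.dendrite_area_fraction):
            if not (0.0 <= frac <= 0.5):
                raise ValueError("area fractions must lie in [0, 0.5]")

    @property
    def process_fraction(self) -> float:
        return self.axon_area_fraction if self.stain == "NF-H" else self.dendrite_area_fraction


def synth_micrograph(spec: MicrographSpec):
    """Render a micrograph with exact truth bookkeeping.

    Returns ``(Micrograph, truth)``; truth holds the exact rendered pixel
    fraction of the process class, the soma inventory, and the label image
    (0 background, 1 process, 2 body).
    """
    rng = _rng(spec.seed)
    H = W = spec.size_px
    label = np.zeros((H, W), dtype=np.uint8)

    # somata first; processes must keep their distance
    bodies = []
    attempts = 0
    while len(bodies) < spec.n_cell_bodies:
        attempts += 1
        if attempts > 1000 * max(spec.n_cell_bodies, 1):
            raise ValueError("cannot place the requested somata in this field size")
        d_um = rng.uniform(*spec.body_diameter_um)
        r_px = d_um / 2.0 / spec.um_per_px
        cy, cx = rng.uniform(r_px + 2, H - r_px - 2), rng.uniform(r_px + 2, W - r_px - 2)
        if any((cy - by) ** 2 + (cx - bx) ** 2 < (r_px + br + 4) ** 2 for by, bx, br, _ in bodies):
            continue
        bodies.append((cy, cx, r_px, d_um))
    for cy, cx, r_px, _ in bodies:
        rr, cc = disk((cy, cx), r_px, shape=label.shape)
        label[rr, cc] = 2

    margin_px = int(np.ceil(max(spec.process_width_um) / spec.um_per_px)) + 3
    forbidden = dilation(
        label == 2, footprint_rectangle((2 * margin_px + 1, 2 * margin_px + 1))
    )

    target_px = int(round(spec.process_fraction * H * W))
    free_px = int((~forbidden).sum())
    if target_px > 0.9 * free_px:
        raise ValueError("requested process fraction unreachable in this field")
    stroke_cap = 100000
    strokes = 0
    while int((label == 1).sum()) < target_px and strokes < stroke_cap:
        strokes += 1
        w_um = rng.uniform(*spec.process_width_um)
        r = max(1, int(round(w_um / 2.0 / spec.um_per_px)))
        y, x = rng.uniform(0, H), rng.uniform(0, W)
        heading = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.integers(250, 500))
        for _ in range(n_steps):
            # long, gently curving strokes: thin and elongated is the
            # morphological signature that separates processes from somata
            heading += rng.normal(0.0, 0.05)
            y += np.sin(heading)
            x += np.cos(heading)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < H and 0 <= ix < W) or forbidden[iy, ix]:
                continue
            rr, cc = disk((iy, ix), r + 0.5, shape=label.shape)
            keep = label[rr, cc] == 0
            label[rr[keep], cc[keep]] = 1
            if int((label == 1).sum()) >= target_px:
                break
    if int((label == 1).sum()) < target_px * 0.98:
        raise ValueError("requested process fraction unreachable (stroke cap hit)")

    img = np.ones((H, W, 3))
    img[label == 1] = (0.38, 0.26, 0.18)
    img[label == 2] = (0.30, 0.20, 0.14)
    img += rng.normal(0.0, spec.background_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    micro = Micrograph(
        pixels=img, um_per_px=spec.um_per_px, stain=spec.stain
    )
    truth = {
        "process_fraction_pct": 100.0 * (label == 1).sum() / label.size,
        "body_fraction_pct": 100.0 * (label == 2).sum() / label.size,
        "n_bodies": len(bodies),
        "bodies": pd.DataFrame(bodies, columns=["cy", "cx", "r_px", "diameter_um"]),
        "label": label,
    }
    return micro, truth


# ---------------------------------------------------------------------------
# cortical-thickness montage generator


def synth_cortex_montage(
    thickness_um: dict[str, float] | float,
    um_per_px: float = 5.0,
    seed: int = 0,
    undulation_frac: float = 0.0,
    n_lines: int = 5,
    strip_width_px: int = 240,
):
    """Banded cortex montage with perpendicular measurement lines per ROI.

    The pial boundary undulates sinusoidally with amplitude
    ``undulation_frac × thickness``; the white-matter boundary is the normal
    offset of the pial curve, and each annotation line runs along the local
    pial normal, so flat bands measure the planted thickness exactly.
    Returns ``(image, lines, truth)`` with lines as a tidy DataFrame
    (``image, roi, x1, y1, x2, y2``, float pixel coordinates).
    """
    if isinstance(thickness_um, (int, float)):
        thickness_um = {"MC": float(thickness_um)}
    if any(t <= 0 for t in thickness_um.values()):
        raise ValueError("thickness must be positive")
    rng = _rng(seed)
    rois = list(thickness_um)
    t_px = {r: thickness_um[r] / um_per_px for r in rois}
    amp = {r: undulation_frac * t_px[r] for r in rois}
    height = int(np.ceil(max(t_px[r] + 2 * amp[r] for r in rois))) + 60
    width = strip_width_px * len(rois)
    image = np.ones((height, width))

    rows = []
    for s, roi in enumerate(rois):
        x0 = s * strip_width_px
        lam = 0.8 * strip_width_px
        phase = rng.uniform(0, 2 * np.pi)
        y_top = 20.0 + amp[roi]

        def pial(x):
            return y_top + amp[roi] * np.sin(2 * np.pi * (x - x0) / lam + phase)

        def slope(x):
            return amp[roi] * (2 * np.pi / lam) * np.cos(2 * np.pi * (x - x0) / lam + phase)

        xs = np.arange(x0, x0 + strip_width_px)
        top = pial(xs)
        for xi, yt in zip(xs, top):
            lo = int(np.clip(np.round(yt), 0, height - 1))
            hi = int(np.clip(np.round(yt + t_px[roi]), 0, height - 1))
            image[lo:hi, xi] = 0.35
        margin = 0.1 * strip_width_px
        line_x = np.linspace(x0 + margin, x0 + strip_width_px - margin, n_lines)
        for lx in line_x:
            m = slope(lx)
            norm = np.hypot(m, 1.0)
            nx, ny = -m / norm, 1.0 / norm  # unit normal, pointing into the band
            rows.append(
                {
                    "image": "montage_0",
                    "roi": roi,
                    "x1": float(lx),
                    "y1": float(pial(lx)),
                    "x2": float(lx + t_px[roi] * nx),
                    "y2": float(pial(lx) + t_px[roi] * ny),
                }
            )
    lines = pd.DataFrame(rows)
    return image, lines, dict(thickness_um)
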