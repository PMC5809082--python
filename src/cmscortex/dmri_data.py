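"""Data model and I/O for diffusion MRI datasets, protocols, masks and parameter maps.

The canonical internal b-value unit is ms/μm² (ex-vivo preclinical convention);
s/mm² tables are detected and converted on read.  Volumes and masks travel as
NIfTI-1, b-tables as FSL ``.bval``/``.bvec`` pairs or a single TSV with columns
``b, gx, gy, gz``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

#: Electrostatic-repulsion 12-direction scheme (unit vectors, no antipodal
#: pairs, minimum pairwise angle 38.1°).  Frozen so that protocol expansion is
#: bit-reproducible across runs.
DIRECTIONS_12 = np.array(
    [
        [-0.475559249378399, 0.879141958340564, 0.030867740697580],
        [-0.444398395820257, -0.887003987783367, 0.125435208170540],
        [-0.991519515011978, 0.027136291340630, 0.127093166782046],
        [0.808308987181913, -0.452602376891284, 0.376547035140778],
        [0.773730869703341, 0.497873646336949, 0.391742738989841],
        [0.006114805236183, 0.881397524648329, 0.472335699159742],
        [-0.722931381471562, -0.419043747026107, 0.549338289000448],
        [0.105898448563508, -0.793352103618489, 0.599481407781726],
        [-0.653339729665003, 0.423991332207470, 0.627198969908430],
        [0.555710698068163, -0.039980963255405, 0.830413838173332],
        [0.021480303013795, 0.389029775753286, 0.920974717437880],
        [-0.188772215895977, -0.262535161879284, 0.946277094345383],
    ]
)

#: The study's 14 shell b-values in ms/μm².
STUDY_BVALUES = np.array(
    [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0]
)

_B0_TOL = 1e-9
_SHELL_TOL = 1e-6

#: Metric names the pipeline knows how to interpret.
KNOWN_METRICS = {
    "Neu": "dimensionless",
    "D_L": "um^2/ms",
    "D_eff": "um^2/ms",
    "MD": "um^2/ms",
    "FA": "dimensionless",
    "MK": "dimensionless",
    "AK": "dimensionless",
    "RK": "dimensionless",
    "MKT": "dimensionless",
    "W_L": "dimensionless",
    "W_T": "dimensionless",
}


@dataclass(frozen=True)
class DiffusionProtocol:
    """Multi-shell acquisition table: one fixed direction set, shared by all shells.

    Parameters
    ----------
    bvalues:
        Shell b-values in ms/μm², strictly increasing, first entry 0.
    directions:
        ``(n_dir, 3)`` unit gradient directions.
    delta_big, delta_small:
        Diffusion time Δ and gradient duration δ in ms (metadata; the signal
        models here are pulse-sequence agnostic).
    """

    bvalues: np.ndarray
    directions: np.ndarray
    delta_big: float | None = None
    delta_small: float | None = None
    te_ms: float | None = None
    tr_ms: float | None = None

    def __post_init__(self):
        b = np.asarray(self.bvalues, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if b.ndim != 1 or b.size == 0:
            raise ValueError("bvalues must be a non-empty 1-D sequence")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if abs(b[0]) > _B0_TOL:
            raise ValueError("protocol must contain a b=0 shell")
        if np.any(np.diff(b) <= 0):
            raise ValueError("shell b-values must be strictly increasing")
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        norms = np.linalg.norm(g, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors (within 1e-6)")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", g)

    @property
    def n_shells(self) -> int:
        return len(self.bvalues)

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    @property
    def n_measurements(self) -> int:
        return self.n_shells * self.n_directions

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-measurement ``(bvals, bvecs)`` in shell-major order.

        Every shell (including b=0) is paired with every direction, so a
        14-shell × 12-direction protocol expands to 168 measurements.  The
        ordering is deterministic: shells ascending, directions in stored
        order.
        """
        bvals = np.repeat(self.bvalues, self.n_directions)
        bvecs = np.tile(self.directions, (self.n_shells, 1))
        return bvals, bvecs

    def subset(self, b_max: float) -> "DiffusionProtocol":
        """Protocol restricted to shells with b ≤ ``b_max``."""
        keep = self.bvalues <= b_max + _SHELL_TOL
        return replace(self, bvalues=self.bvalues[keep])

    @classmethod
    def from_measurements(
        cls, bvals: np.ndarray, bvecs: np.ndarray, **timing
    ) -> "DiffusionProtocol":
        """Reconstruct shell/direction structure from a flat measurement table.

        b-values with ``max(b) >= 100`` are interpreted as s/mm² and divided
        by 1000; otherwise they are taken as ms/μm² verbatim.
        """
        bvals = np.asarray(bvals, dtype=float).ravel()
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size) and bvecs.shape[0] == 3:
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"b-table shape mismatch: {bvals.size} b-values vs "
                f"{bvecs.shape} direction table"
            )
        if bvals.max() >= 100.0:  # s/mm² dialect
            bvals = bvals / 1000.0
        shells = _cluster_shells(bvals)
        nz = bvals > _B0_TOL
        dirs = bvecs[nz]
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero gradient vector on a diffusion-weighted frame")
        dirs = dirs / norms[:, None]
        directions = _unique_rows(dirs, tol=1e-6)
        return cls(bvalues=shells, directions=directions, **timing)


def _cluster_shells(bvals: np.ndarray) -> np.ndarray:
    """Unique shell values after merging near-duplicates."""
    shells: list[float] = []
    for b in np.sort(bvals):
        if not shells or b - shells[-1] > _SHELL_TOL:
            shells.append(float(b))
    if abs(shells[0]) > _B0_TOL:
        raise ValueError("b-table contains no b=0 measurement")
    return np.array(shells)


def _unique_rows(x: np.ndarray, tol: float) -> np.ndarray:
    out: list[np.ndarray] = []
    for row in x:
        if not any(np.linalg.norm(row - r) < tol for r in out):
            out.append(row)
    return np.array(out)


def study_protocol(n_directions: int = 12) -> DiffusionProtocol:
    """The study's ex-vivo protocol: 14 shells 0–8 ms/μm², 12 directions, Δ/δ=15/5 ms."""
    return DiffusionProtocol(
        bvalues=STUDY_BVALUES.copy(),
        directions=DIRECTIONS_12[:n_directions].copy(),
        delta_big=15.0,
        delta_small=5.0,
        te_ms=26.0,
        tr_ms=6500.0,
    )


@dataclass
class DWIDataset:
    """A 4-D diffusion-weighted volume with its acquisition protocol."""

    signal: np.ndarray
    protocol: DiffusionProtocol
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.full(3, 0.25))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, measurement)")
        n_frames = self.signal.shape[-1]
        n_expected = self.protocol.n_measurements
        if n_frames != n_expected:
            raise ValueError(
                f"measurement-count mismatch: image has {n_frames} frames but "
                f"the protocol expands to {n_expected} measurements"
            )
        bad = ~np.isfinite(self.signal)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"non-finite signal at voxel/frame index {idx}")
        if (self.signal < 0).any():
            idx = tuple(int(i) for i in np.argwhere(self.signal < 0)[0])
            raise ValueError(f"negative signal at voxel/frame index {idx}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def measurement_table(self) -> tuple[np.ndarray, np.ndarray]:
        return self.protocol.expand()


def average_b0(
    signal: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse all b=0 frames into one averaged measurement (leading position).

    Averaging the non-diffusion-weighted frames before fitting reduces their
    noise without affecting any model, and makes the result independent of
    frame order.
    """
    signal = np.asarray(signal, dtype=float)
    is_b0 = np.asarray(bvals) <= _B0_TOL
    if not is_b0.any():
        return signal, np.asarray(bvals, dtype=float), np.asarray(bvecs, dtype=float)
    s0 = signal[..., is_b0].mean(axis=-1, keepdims=True)
    out_sig = np.concatenate([s0, signal[..., ~is_b0]], axis=-1)
    out_b = np.concatenate([[0.0], np.asarray(bvals)[~is_b0]])
    out_g = np.concatenate([np.zeros((1, 3)), np.asarray(bvecs)[~is_b0]], axis=0)
    return out_sig, out_b, out_g


@dataclass
class ROIMask:
    """Integer label volume with named cortical ROIs and a slice window.

    ``slice_range`` is a half-open ``[lo, hi)`` window of indices on ``axis``
    emulating the anatomical (Bregma −3.10 to −4.10 mm) section selection;
    label 0 is background.
    """

    labels: np.ndarray
    label_names: dict[int, str]
    slice_range: tuple[int, int] | None = None
    axis: int = 2

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("ROI labels must be an integer array")
        if 0 in self.label_names:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.labels).tolist())
        missing = [n for lab, n in self.label_names.items() if lab not in present]
        if missing:
            raise ValueError(f"named labels absent from the array: {missing}")
        if self.slice_range is None:
            self.slice_range = (0, self.labels.shape[self.axis])

    def roi_voxels(self, name: str) -> np.ndarray:
        """Boolean mask of the named ROI restricted to the slice window."""
        lab = {v: k for k, v in self.label_names.items()}[name]
        m = self.labels == lab
        lo, hi = self.slice_range
        window = np.zeros(self.labels.shape[self.axis], dtype=bool)
        window[lo:hi] = True
        shape = [1, 1, 1]
        shape[self.axis] = -1
        return m & window.reshape(shape)


@dataclass
class ParameterMap:
    """A named voxel-wise metric with its validity mask.

    Values are NaN outside the mask and finite inside; diffusivities are in
    μm²/ms, everything else dimensionless.
    """

    name: str
    values: np.ndarray
    units: str
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        inside = self.values[self.mask]
        if inside.size and not np.isfinite(inside).all():
            raise ValueError(f"non-finite values inside mask of map '{self.name}'")
        self.values = np.where(self.mask, self.values, np.nan)
        if self.name == "FA" and inside.size:
            if inside.min() < -1e-9 or inside.max() > 1 + 1e-9:
                raise ValueError("FA values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# I/O


def read_dwi(image_path: str | Path, btable_path: str | Path) -> DWIDataset:
    """Load a 4-D NIfTI and its b-table into a :class:`DWIDataset`.

    ``btable_path`` may point at an FSL ``.bval`` file (the matching ``.bvec``
    is looked up next to it), or at a TSV with columns ``b, gx, gy, gz``.
    A JSON sidecar next to the image (same stem, ``.json``) supplies Δ/δ/TE/TR
    when present.
    """
    image_path = Path(image_path)
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got {data.ndim}-D")
    bvals, bvecs = _read_btable(Path(btable_path))
    if data.shape[-1] != bvals.size:
        raise ValueError(
            f"measurement-count mismatch: image has {data.shape[-1]} frames "
            f"but the b-table has {bvals.size} rows"
        )
    timing = _read_sidecar(image_path)
    protocol = DiffusionProtocol.from_measurements(bvals, bvecs, **timing)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIDataset(
        signal=data, protocol=protocol, voxel_size_mm=voxel_size, affine=img.affine
    )


def _read_btable(path: Path) -> tuple[np.ndarray, np.ndarray]:
    if path.suffix == ".bval":
        bvals = np.loadtxt(path).ravel()
        bvec_path = path.with_suffix(".bvec")
        if not bvec_path.exists():
            raise FileNotFoundError(f"no .bvec next to {path}")
        bvecs = np.loadtxt(bvec_path)
        return bvals, bvecs
    # single-table dialect
    table = np.genfromtxt(path, names=True, delimiter=None)
    required = ("b", "gx", "gy", "gz")
    if table.dtype.names is None or any(c not in table.dtype.names for c in required):
        raise ValueError(f"b-table {path} must have columns {required}")
    bvals = np.atleast_1d(table["b"]).astype(float)
    bvecs = np.stack(
        [np.atleast_1d(table[c]).astype(float) for c in ("gx", "gy", "gz")], axis=1
    )
    return bvals, bvecs


def _read_sidecar(image_path: Path) -> dict:
    stem = image_path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
    sidecar = image_path.parent / f"{stem}.json"
    if not sidecar.exists():
        return {}
    meta = json.loads(sidecar.read_text())
    keys = {"delta_big", "delta_small", "te_ms", "tr_ms"}
    return {k: meta[k] for k in keys if k in meta}


def write_dwi(dataset: DWIDataset, image_path: str | Path, btable_path: str | Path):
    """Write a dataset as NIfTI + TSV b-table (+ JSON timing sidecar)."""
    image_path = Path(image_path)
    img = nib.Nifti1Image(dataset.signal.astype(np.float64), dataset.affine)
    img.header.set_zooms(tuple(dataset.voxel_size_mm) + (1.0,))
    nib.save(img, str(image_path))
    bvals, bvecs = dataset.protocol.expand()
    with open(btable_path, "w") as fh:
        fh.write("b\tgx\tgy\tgz\n")
        for b, g in zip(bvals, bvecs):
            fh.write(f"{b:.17g}\t{g[0]:.17g}\t{g[1]:.17g}\t{g[2]:.17g}\n")
    timing = {
        k: getattr(dataset.protocol, k)
        for k in ("delta_big", "delta_small", "te_ms", "tr_ms")
        if getattr(dataset.protocol, k) is not None
    }
    if timing:
        stem = image_path.name
        for suf in (".nii.gz", ".nii"):
            if stem.endswith(suf):
                stem = stem[: -len(suf)]
        (image_path.parent / f"{stem}.json").write_text(json.dumps(timing))


def write_map(pmap: ParameterMap, path: str | Path):
    """Write a :class:`ParameterMap` as NIfTI; units go into the header description."""
    if pmap.name not in KNOWN_METRICS:
        warnings.warn(
            f"metric '{pmap.name}' is not in the supported list; writing anyway",
            stacklevel=2,
        )
    img = nib.Nifti1Image(pmap.values.astype(np.float64), pmap.affine)
    img.header["descrip"] = f"{pmap.name} [{pmap.units}]".encode()[:79]
    nib.save(img, str(path))


def read_map(path: str | Path) -> ParameterMap:
    """Read a map written by :func:`write_map` (mask = finite voxels)."""
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj).astype(float)
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode()
    if "[" in descrip and descrip.endswith("]"):
        name, units = descrip[:-1].split(" [", 1)
    else:
        name, units = descrip or "unknown", ""
    return ParameterMap(
        name=name,
        values=values,
        units=units,
        mask=np.isfinite(values),
        affine=img.affine,
    )
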