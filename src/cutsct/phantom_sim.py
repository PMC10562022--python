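"""Seeded pelvic phantom generator and CBCT-style degradation model.

The phantom is an ellipse-composite axial cross-section: a fat body
ellipse with per-slice jitter, an inner muscle compartment, a bladder, two
femoral heads and a posterior sacrum arc (trabecular bone with a cortical
rim), an optional handful of high-density fiducial seeds inside a central
prostate ellipse, and a treatment couch slab separated from the body by an
air gap. Every voxel's HU equals its tissue label's table entry, so the
label map is exact ground truth for masking and evaluation.

The degradation emulates the characteristic CBCT failure modes
phenomenologically: a multiplicative low-order polynomial shading/cupping
field, scatter modeled as leakage of a Gaussian-blurred copy of the image,
additive Gaussian noise, and a global HU offset — applied in that order,
then clipped to the HU range. Zero parameters give the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from cutsct.volume_io import CTVolume, HU_MIN, HU_MAX, clip_hu

TISSUE_HU = {
    "air": -1000.0,
    "fat": -100.0,
    "muscle": 40.0,
    "bladder": 0.0,
    "trabecular_bone": 200.0,
    "cortical_bone": 700.0,
    "fiducial": 3000.0,
    "couch": 150.0,
}

LABELS = {name: i for i, name in enumerate(TISSUE_HU)}  # air = 0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU content of one synthetic pelvis."""

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 8.0)
    body_axes_frac: tuple[float, float] = (0.40, 0.30)   # of grid size, (x, y)
    slice_jitter_frac: float = 0.03
    n_fiducials_range: tuple[int, int] = (0, 3)
    fiducial_radius_vox: tuple[int, int] = (1, 3)
    couch_gap_vox: int = 2
    couch_thickness_vox: int = 3

    def validate(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("phantom grid must be at least 8 voxels per axis")
        ax, ay = self.body_axes_frac
        if not (0 < ax < 0.5 and 0 < ay < 0.5):
            raise ValueError("body axes must fit inside the grid")
        if self.couch_gap_vox < 2:
            raise ValueError("couch must be separated from the body by >= 2 voxels")


@dataclass(frozen=True)
class DegradeParams:
    """CBCT degradation strengths; all-zero parameters give the identity."""

    shading_amplitude: float = 0.08
    scatter_fraction: float = 0.15
    scatter_blur_vox: float = 3.0
    noise_sd_hu: float = 25.0
    hu_offset: float = 40.0
    streaks: bool = False
    seed: int = 0

    def validate(self) -> None:
        for v in (self.shading_amplitude, self.scatter_fraction,
                  self.scatter_blur_vox, self.noise_sd_hu, self.hu_offset):
            if not np.isfinite(v):
                raise ValueError("degradation parameters must be finite")

    @classmethod
    def identity(cls) -> "DegradeParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, False, 0)


def _ellipse(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
             ax: float, ay: float) -> np.ndarray:
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0) -> tuple[CTVolume, np.ndarray]:
    """Generate one phantom: (HU volume, integer label map), deterministic given seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.shape
    labels = np.zeros(spec.shape, dtype=np.uint8)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    cx, cy = nx / 2.0, ny * 0.45
    ax0 = spec.body_axes_frac[0] * nx
    ay0 = spec.body_axes_frac[1] * ny
    jit = spec.slice_jitter_frac

    fid_lo, fid_hi = spec.n_fiducials_range
    n_fid = int(rng.integers(fid_lo, fid_hi + 1))
    prost_ax, prost_ay = 0.22 * ax0, 0.22 * ay0
    prost_cy = cy + 0.25 * ay0
    fid_specs = []
    for _ in range(n_fid):
        fx = cx + rng.uniform(-0.5, 0.5) * prost_ax
        fy = prost_cy + rng.uniform(-0.5, 0.5) * prost_ay
        fz = int(rng.integers(nz // 4, 3 * nz // 4))
        fr = int(rng.integers(spec.fiducial_radius_vox[0], spec.fiducial_radius_vox[1] + 1))
        fid_specs.append((fx, fy, fz, fr))

    for z in range(nz):
        axz = ax0 * (1.0 + rng.uniform(-jit, jit))
        ayz = ay0 * (1.0 + rng.uniform(-jit, jit))
        body = _ellipse(xx, yy, cx, cy, axz, ayz)
        sl = np.zeros((nx, ny), dtype=np.uint8)
        sl[body] = LABELS["fat"]
        muscle = _ellipse(xx, yy, cx, cy, 0.82 * axz, 0.82 * ayz)
        sl[muscle] = LABELS["muscle"]
        # bladder: anterior midline ellipse
        bladder = _ellipse(xx, yy, cx, cy - 0.35 * ayz, 0.30 * axz, 0.25 * ayz)
        sl[bladder & muscle] = LABELS["bladder"]
        # femoral heads: lateral circles, cortical rim around trabecular core
        for side in (-1.0, 1.0):
            fcx, fcy = cx + side * 0.62 * axz, cy + 0.10 * ayz
            r = 0.16 * min(axz, ayz)
            outer = _ellipse(xx, yy, fcx, fcy, r, r)
            inner = _ellipse(xx, yy, fcx, fcy, 0.65 * r, 0.65 * r)
            sl[outer & body] = LABELS["cortical_bone"]
            sl[inner & body] = LABELS["trabecular_bone"]
        # sacrum arc: posterior annulus sector
        rr = np.sqrt(((xx - cx) / (0.55 * axz)) ** 2 + ((yy - cy - 0.45 * ayz) / (0.35 * ayz)) ** 2)
        arc = (rr <= 1.0) & (rr >= 0.55) & (yy > cy + 0.3 * ayz)
        sl[arc & body] = LABELS["cortical_bone"]
        arc_in = (rr < 0.85) & (rr >= 0.65) & (yy > cy + 0.35 * ayz)
        sl[arc_in & body] = LABELS["trabecular_bone"]
        for fx, fy, fz, fr in fid_specs:
            if abs(z - fz) <= max(0, fr - 1):
                seed_mask = _ellipse(xx, yy, fx, fy, fr, fr)
                sl[seed_mask & muscle] = LABELS["fiducial"]
        labels[:, :, z] = sl

    # couch: full-width slab below (posterior to) the body, detached by an air gap
    body_any = labels > 0
    max_y = int(np.max(np.nonzero(body_any.any(axis=(0, 2)))[0]))
    couch_y0 = max_y + 1 + spec.couch_gap_vox
    couch_y1 = min(ny, couch_y0 + spec.couch_thickness_vox)
    if couch_y1 <= couch_y0:
        raise ValueError("couch geometry exceeds the grid")
    labels[nx // 8: nx - nx // 8, couch_y0:couch_y1, :] = LABELS["couch"]

    hu_table = np.array([TISSUE_HU[name] for name in TISSUE_HU], dtype=np.float32)
    vol = CTVolume(hu_table[labels], spec.spacing_mm)
    return vol, labels


def degrade_to_cbct(vol: CTVolume, params: DegradeParams = DegradeParams()) -> CTVolume:
    """Apply shading, scatter leakage, noise, and HU offset (in that order), then clip."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    v = vol.voxels.astype(np.float64)
    nx, ny, nz = v.shape

    if params.shading_amplitude != 0.0:
        # low-order radial polynomial: cupping (center depressed, edge raised)
        x = (np.arange(nx) - nx / 2) / (nx / 2)
        y = (np.arange(ny) - ny / 2) / (ny / 2)
        r2 = x[:, None] ** 2 + y[None, :] ** 2
        fieldxy = 1.0 + params.shading_amplitude * (r2 - 0.5)
        v = (v - HU_MIN) * fieldxy[:, :, None] + HU_MIN

    if params.scatter_fraction != 0.0 and params.scatter_blur_vox > 0:
        blur = ndimage.gaussian_filter(
            v, sigma=(params.scatter_blur_vox, params.scatter_blur_vox, 0.0))
        v = (1.0 - params.scatter_fraction) * v + params.scatter_fraction * blur

    if params.streaks:
        phase = rng.uniform(0, 2 * np.pi)
        ang = np.arctan2(*np.meshgrid((np.arange(ny) - ny / 2), (np.arange(nx) - nx / 2)))
        v = v + 15.0 * np.sin(8.0 * ang + phase)[:, :, None]

    if params.noise_sd_hu != 0.0:
        v = v + rng.normal(0.0, params.noise_sd_hu, size=v.shape)

    if params.hu_offset != 0.0:
        v = v + params.hu_offset

    changed = (params.shading_amplitude, params.scatter_fraction,
               params.noise_sd_hu, params.hu_offset) != (0.0, 0.0, 0.0, 0.0) or params.streaks
    if changed:
        v = np.clip(v, HU_MIN, HU_MAX)
    return vol.like(v)


@dataclass
class PatientRecord:
    patient_id: str
    role: str                       # "train" or "eval"
    geometry_seed: int
    clean: CTVolume                 # FBCT-like ground truth for this patient
    cbct: CTVolume                  # degraded volume (unpaired geometry when role=train)
    cbct_geometry_seed: int
    labels: np.ndarray
    eval_cbct: CTVolume | None = None  # aligned degraded copy of `clean` (eval pairs)


@dataclass
class UnpairedDataset:
    patients: list[PatientRecord]
    manifest: dict


def make_unpaired_dataset(
    n_patients: int,
    spec: PhantomSpec = PhantomSpec(),
    degrade: DegradeParams = DegradeParams(),
    seed: int = 0,
    eval_fraction: float = 0.25,
) -> UnpairedDataset:
    """Build an unpaired training cohort plus voxel-aligned evaluation pairs.

    For every patient a clean (FBCT-domain) phantom is generated; the
    CBCT-domain training sample is an *independently generated* phantom
    (different geometry seed) passed through the degradation, so the two
    training streams are truly unpaired. A degraded copy of each patient's
    own clean phantom is retained separately — those aligned pairs are for
    evaluation only and never enter training.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    n_eval = max(1, int(round(eval_fraction * n_patients)))
    patients: list[PatientRecord] = []
    entries = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        g_clean = int(rng.integers(2**31))
        g_cbct = int(rng.integers(2**31))
        d_seed = int(rng.integers(2**31))
        e_seed = int(rng.integers(2**31))
        role = "eval" if i >= n_patients - n_eval else "train"
        clean, labels = make_phantom(spec, g_clean)
        other, _ = make_phantom(spec, g_cbct)
        dp = DegradeParams(**{**asdict(degrade), "seed": d_seed})
        cbct = degrade_to_cbct(other, dp)
        ep = DegradeParams(**{**asdict(degrade), "seed": e_seed})
        eval_cbct = degrade_to_cbct(clean, ep)
        patients.append(PatientRecord(pid, role, g_clean, clean, cbct, g_cbct,
                                      labels, eval_cbct))
        entries.append({"patient_id": pid, "role": role,
                        "geometry_seed": g_clean, "cbct_geometry_seed": g_cbct,
                        "degrade_seed": d_seed, "eval_degrade_seed": e_seed})
    manifest = {"seed": seed, "n_patients": n_patients,
                "spec": asdict(spec), "degrade": asdict(degrade),
                "patients": entries}
    return UnpairedDataset(patients, manifest)


def write_dataset(ds: UnpairedDataset, out_dir: str | Path) -> Path:
    """Write all volumes as NIfTI plus the JSON manifest; returns the manifest path."""
    from cutsct.volume_io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in ds.patients:
        base = out / rec.patient_id
        base.mkdir(exist_ok=True)
        write_volume(rec.clean, base / "clean.nii.gz")
        write_volume(rec.cbct, base / "cbct.nii.gz")
        write_volume(rec.eval_cbct, base / "eval_cbct.nii.gz")
        lab = CTVolume(rec.labels.astype(np.float32), rec.clean.spacing_mm)
        write_volume(lab, base / "labels.nii.gz")
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(ds.manifest, indent=2))
    return mpath
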