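"""Synthetic torso phantoms for PET/MR attenuation-correction experiments.

A phantom is a co-registered truth bundle on a pseudo-3D stack of transaxial
slices: a tissue-label volume, a CT volume in Hounsfield units, an in-phase
Dixon-like MR volume in arbitrary units (bone and air both dark, corrupted by
a smooth multiplicative bias field plus additive noise), and an FDG-like
activity volume (soft-tissue background, cold lungs, hot lesions).

Anatomy is deliberately minimal: an elliptical body with a subcutaneous fat
rim, two lateral arm ellipses (targets for truncation), two elliptical lungs,
a spine disk with marrow, a few rib disks, and a liver-like soft-tissue
region.  Four clinically motivated corruptions are provided: lateral MR
truncation, a metal-implant susceptibility void, removal of one lung, and a
small soft-tissue lung nodule.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io

TISSUES = ("air", "lung", "fat", "soft", "bone", "marrow", "lesion", "implant")
LABELS = {name: i for i, name in enumerate(TISSUES)}


@dataclass
class TissueProps:
    """Mean/SD of CT (HU) and MR (a.u.) intensity plus mean activity for one class."""

    ct_hu_mean: float
    ct_hu_sd: float
    mr_mean: float
    mr_sd: float
    activity_mean: float


def default_tissue_table() -> dict:
    # In-phase Dixon contrast: fat bright, soft mid, lung/bone/air dark.
    # Lung HU denser than the vendor's -770 HU assumption on purpose: real lung
    # density is patient specific, which is what makes a fixed lung coefficient
    # a source of bias.
    return {
        "air": TissueProps(-1000.0, 0.0, 0.02, 0.01, 0.0),
        "lung": TissueProps(-700.0, 25.0, 0.15, 0.02, 0.3),
        "fat": TissueProps(-100.0, 15.0, 0.90, 0.03, 0.7),
        "soft": TissueProps(40.0, 15.0, 0.60, 0.03, 1.0),
        "bone": TissueProps(700.0, 50.0, 0.08, 0.02, 0.8),
        "marrow": TissueProps(250.0, 30.0, 0.75, 0.03, 0.8),
        "lesion": TissueProps(40.0, 15.0, 0.60, 0.03, 4.0),
        "implant": TissueProps(3000.0, 0.0, 0.02, 0.01, 1.0),
    }


@dataclass
class PhantomConfig:
    """Geometry, tissue contrast and noise model of the synthetic torso.

    All lengths are millimetres.  ``grid_shape`` is ``(n_slices, ny, nx)``;
    slices share the in-plane anatomy and differ only in noise, so 3D
    structures (nodules) are well defined while every algorithm can run
    slice-wise.
    """

    grid_shape: tuple = (8, 128, 128)
    voxel_spacing: tuple = (2.0, 2.0, 2.0)  # (sz, sy, sx) mm
    body_axes: tuple = (88.0, 66.0)  # (x, y) semi-axes
    arm_axes: tuple = (13.0, 19.0)
    arm_gap: float = 4.0
    lung_axes: tuple = (26.0, 40.0)
    lung_centers: tuple = ((40.0, -14.0), (-40.0, -14.0))  # (x, y): right, left
    spine_radius: float = 13.0
    spine_center: tuple = (0.0, 46.0)
    marrow_fraction: float = 0.5
    rib_spec: dict = field(
        default_factory=lambda: {
            "n_ribs": 4,
            "radius": 5.0,
            "ring_fraction": 0.86,
            "angles_deg": (30.0, 150.0, 210.0, 330.0),
        }
    )
    fat_ring_fraction: float = 0.93
    liver_axes: tuple = (24.0, 16.0)
    liver_center: tuple = (-38.0, 18.0)
    tissue_table: dict = field(default_factory=default_tissue_table)
    mr_bias_field_amplitude: float = 0.20
    jitter_fraction: float = 0.06
    noise_seed: int = 0

    def validate(self):
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        tt = self.tissue_table
        if tt["air"].ct_hu_mean > -950:
            raise ValueError("air CT mean must be <= -950 HU")
        if not (-900 <= tt["lung"].ct_hu_mean <= -500):
            raise ValueError("lung CT mean must lie in [-900, -500] HU")
        if tt["bone"].ct_hu_mean <= 160:
            raise ValueError("bone CT mean must exceed 160 HU")
        soft_mr = tt["soft"].mr_mean
        if tt["bone"].mr_mean >= soft_mr or tt["air"].mr_mean >= soft_mr:
            raise ValueError("in-phase MR requires bone and air darker than soft tissue")
        for name, props in tt.items():
            if props.activity_mean < 0:
                raise ValueError(f"negative activity for class {name!r}")
        return self

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d["tissue_table"] = {k: dataclasses.asdict(v) for k, v in self.tissue_table.items()}
        io.write_yaml(path, d)

    @classmethod
    def from_yaml(cls, path):
        d = io.read_yaml(path)
        d["tissue_table"] = {k: TissueProps(**v) for k, v in d["tissue_table"].items()}
        for key in ("grid_shape", "voxel_spacing", "body_axes", "arm_axes", "lung_axes",
                    "spine_center", "liver_axes", "liver_center"):
            if key in d:
                d[key] = tuple(d[key])
        if "lung_centers" in d:
            d["lung_centers"] = tuple(tuple(c) for c in d["lung_centers"])
        if "rib_spec" in d and "angles_deg" in d["rib_spec"]:
            d["rib_spec"]["angles_deg"] = tuple(d["rib_spec"]["angles_deg"])
        return cls(**d)


def desk_config(n_slices: int = 1, slice_thickness: float = 2.0, **overrides) -> PhantomConfig:
    """A 64x64 single- or few-slice preset sized for laptop-scale experiments."""
    cfg = PhantomConfig(
        grid_shape=(n_slices, 64, 64),
        voxel_spacing=(slice_thickness, 3.5, 3.5),
        body_axes=(76.0, 58.0),
        arm_axes=(11.0, 16.0),
        arm_gap=4.0,
        lung_axes=(22.0, 34.0),
        lung_centers=((34.0, -12.0), (-34.0, -12.0)),
        spine_radius=11.0,
        spine_center=(0.0, 40.0),
        rib_spec={"n_ribs": 4, "radius": 4.5, "ring_fraction": 0.86,
                  "angles_deg": (30.0, 150.0, 210.0, 330.0)},
        liver_axes=(20.0, 13.0),
        liver_center=(-32.0, 15.0),
    )
    return dataclasses.replace(cfg, **overrides)


@dataclass
class TorsoPhantom:
    """Co-registered truth bundle: labels, CT (HU), MR (a.u.), activity, organ masks."""

    labels: np.ndarray
    ct_hu: np.ndarray
    mr: np.ndarray
    activity: np.ndarray
    organs: dict
    spacing: tuple
    config: PhantomConfig
    seed: int
    outliers_applied: list = field(default_factory=list)

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels != LABELS["air"]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def copy(self) -> "TorsoPhantom":
        return TorsoPhantom(
            labels=self.labels.copy(),
            ct_hu=self.ct_hu.copy(),
            mr=self.mr.copy(),
            activity=self.activity.copy(),
            organs={k: v.copy() for k, v in self.organs.items()},
            spacing=self.spacing,
            config=self.config,
            seed=self.seed,
            outliers_applied=copy.deepcopy(self.outliers_applied),
        )

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        io.write_volume(directory / "labels.nii.gz", self.labels, self.spacing, np.uint8)
        io.write_volume(directory / "ct_hu.nii.gz", self.ct_hu, self.spacing, np.float32)
        io.write_volume(directory / "mr.nii.gz", self.mr, self.spacing, np.float32)
        io.write_volume(directory / "activity.nii.gz", self.activity, self.spacing, np.float32)
        for name, mask in self.organs.items():
            io.write_volume(directory / f"organ_{name}.nii.gz", mask, self.spacing, np.uint8)
        io.write_yaml(directory / "meta.yaml",
                      {"seed": self.seed, "outliers_applied": self.outliers_applied})
        self.config.to_yaml(directory / "config.yaml")


def _grids_mm(config):
    _, ny, nx = config.grid_shape
    sz, sy, sx = config.voxel_spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    return np.meshgrid(y, x, indexing="ij")  # (Y, X) each (ny, nx)


def _ellipse(Y, X, center, axes):
    cx, cy = center
    ax, ay = axes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig, subject_seed: int) -> TorsoPhantom:
    """Generate a deterministic phantom; ``subject_seed`` jitters the anatomy.

    Raises ``ValueError`` when the configured body plus arms do not fit in the
    grid's transaxial field of view.
    """
    config.validate()
    nz, ny, nx = config.grid_shape
    sz, sy, sx = config.voxel_spacing
    rng = np.random.default_rng([int(config.noise_seed), int(subject_seed)])

    j = config.jitter_fraction
    jit = lambda: 1.0 + rng.uniform(-j, j)
    body_ax = (config.body_axes[0] * jit(), config.body_axes[1] * jit())
    arm_ax = (config.arm_axes[0] * jit(), config.arm_axes[1] * jit())
    lung_ax = (config.lung_axes[0] * jit(), config.lung_axes[1] * jit())
    lung_centers = [
        (cx0 + rng.uniform(-3, 3) * j / 0.06 if j > 0 else cx0, cy0)
        for cx0, cy0 in config.lung_centers
    ]

    arm_cx = body_ax[0] + config.arm_gap + arm_ax[0]
    half_fov_x = nx * sx / 2.0
    half_fov_y = ny * sy / 2.0
    if arm_cx + arm_ax[0] >= half_fov_x or body_ax[1] >= half_fov_y:
        raise ValueError(
            "grid too small: body plus arms extend to "
            f"{arm_cx + arm_ax[0]:.1f} mm but half-FOV is {half_fov_x:.1f} mm"
        )

    Y, X = _grids_mm(config)
    body = _ellipse(Y, X, (0.0, 0.0), body_ax)
    arm_r = _ellipse(Y, X, (arm_cx, 0.0), arm_ax)
    arm_l = _ellipse(Y, X, (-arm_cx, 0.0), arm_ax)
    fat_inner = _ellipse(Y, X, (0.0, 0.0),
                         (body_ax[0] * config.fat_ring_fraction,
                          body_ax[1] * config.fat_ring_fraction))
    lung_r = _ellipse(Y, X, lung_centers[0], lung_ax)
    lung_l = _ellipse(Y, X, lung_centers[1], lung_ax)
    spine = _ellipse(Y, X, config.spine_center, (config.spine_radius,) * 2)
    marrow = _ellipse(Y, X, config.spine_center,
                      (config.spine_radius * config.marrow_fraction,) * 2)
    rs = config.rib_spec
    ribs = np.zeros_like(body)
    for ang in rs["angles_deg"][: rs["n_ribs"]]:
        t = np.deg2rad(ang)
        c = (rs["ring_fraction"] * body_ax[0] * np.cos(t),
             rs["ring_fraction"] * body_ax[1] * np.sin(t))
        ribs |= _ellipse(Y, X, c, (rs["radius"],) * 2)
    ribs &= body
    liver = _ellipse(Y, X, config.liver_center, config.liver_axes) & body

    plane = np.full((ny, nx), LABELS["air"], dtype=np.uint8)
    plane[body | arm_r | arm_l] = LABELS["soft"]
    plane[body & ~fat_inner] = LABELS["fat"]
    plane[lung_r & fat_inner] = LABELS["lung"]
    plane[lung_l & fat_inner] = LABELS["lung"]
    plane[spine] = LABELS["bone"]
    plane[marrow] = LABELS["marrow"]
    plane[ribs & ~spine] = LABELS["bone"]

    labels = np.repeat(plane[None], nz, axis=0)

    tt = config.tissue_table
    lut = lambda attr: np.array([getattr(tt[name], attr) for name in TISSUES])
    ct_mean = lut("ct_hu_mean")[labels]
    ct_sd = lut("ct_hu_sd")[labels]
    mr_mean = lut("mr_mean")[labels]
    mr_sd = lut("mr_sd")[labels]
    activity = lut("activity_mean")[labels].astype(np.float32)
    activity[labels == LABELS["air"]] = 0.0

    ct_hu = (ct_mean + rng.standard_normal(labels.shape) * ct_sd).astype(np.float32)

    # Smooth multiplicative bias field: exponentiated random second-order
    # polynomial, scaled so max |field - 1| ~= the configured amplitude.
    amp = config.mr_bias_field_amplitude
    u = X / max(half_fov_x, 1e-9)
    v = Y / max(half_fov_y, 1e-9)
    coeffs = rng.standard_normal(5)
    g = (coeffs[0] * u + coeffs[1] * v + coeffs[2] * u * v
         + coeffs[3] * u ** 2 + coeffs[4] * v ** 2)
    g -= g.mean()
    peak = np.abs(g).max()
    if amp > 0 and peak > 0:
        g *= np.log1p(amp) / peak
    else:
        g = np.zeros_like(g)
    bias = np.exp(g)[None]

    mr = (mr_mean * bias + rng.standard_normal(labels.shape) * mr_sd).astype(np.float32)

    lung_r3 = np.repeat((lung_r & fat_inner & (plane == LABELS["lung"]))[None], nz, 0)
    lung_l3 = np.repeat((lung_l & fat_inner & (plane == LABELS["lung"]))[None], nz, 0)
    organs = {
        "right_lung": lung_r3,
        "left_lung": lung_l3,
        "spine": np.repeat(spine[None], nz, 0),
        "ribs": np.repeat((ribs & ~spine)[None], nz, 0),
        "liver_like": np.repeat((liver & (plane == LABELS["soft"]))[None], nz, 0),
    }
    return TorsoPhantom(
        labels=labels, ct_hu=ct_hu, mr=mr, activity=activity, organs=organs,
        spacing=config.voxel_spacing, config=config, seed=int(subject_seed),
    )


# ---------------------------------------------------------------------------
# outlier corruptions
# ---------------------------------------------------------------------------

def _air_mr_level(phantom):
    return phantom.config.tissue_table["air"].mr_mean


def inject_truncation(phantom: TorsoPhantom, lateral_fraction: float) -> TorsoPhantom:
    """Blank the MR signal outside a laterally reduced field of view.

    CT, activity and labels are untouched: truncation is an MR acquisition
    artifact, the truth anatomy is still there.
    """
    if not (0 <= lateral_fraction < 0.5):
        raise ValueError("lateral_fraction must lie in [0, 0.5)")
    out = phantom.copy()
    if lateral_fraction == 0:
        return out
    nx = out.mr.shape[-1]
    cut = int(round(lateral_fraction * nx))
    outside = np.zeros(out.mr.shape, dtype=bool)
    if cut > 0:
        outside[..., :cut] = True
        outside[..., nx - cut:] = True
    out.mr[outside] = _air_mr_level(phantom)
    affected = outside & phantom.body_mask
    out.organs["truncation_affected"] = affected
    out.outliers_applied.append(
        {"type": "truncation", "lateral_fraction": float(lateral_fraction),
         "n_affected_voxels": int(affected.sum())}
    )
    return out


def inject_metal(phantom: TorsoPhantom, center, void_radius: float,
                 implant_radius: float, implant_hu: float = 3000.0) -> TorsoPhantom:
    """Add a metal implant: MR susceptibility void plus high-HU implant disk.

    ``center`` is a physical in-plane point ``(x, y)`` in mm; the void and the
    implant run through the whole slice stack (a prosthesis stem).  Activity
    is unchanged.
    """
    if implant_radius >= void_radius:
        raise ValueError("implant_radius must be smaller than void_radius")
    cx, cy = float(center[0]), float(center[1])
    Y, X = _grids_mm(phantom.config)
    iy = int(np.abs(Y[:, 0] - cy).argmin())
    ix = int(np.abs(X[0] - cx).argmin())
    if not phantom.body_mask[phantom.labels.shape[0] // 2, iy, ix]:
        raise ValueError("implant center must lie inside the body")
    out = phantom.copy()
    void2d = (X - cx) ** 2 + (Y - cy) ** 2 <= void_radius ** 2
    impl2d = (X - cx) ** 2 + (Y - cy) ** 2 <= implant_radius ** 2
    void = np.repeat(void2d[None], out.mr.shape[0], 0)
    impl = np.repeat(impl2d[None], out.mr.shape[0], 0)
    out.mr[void] = _air_mr_level(phantom)
    out.ct_hu[impl] = implant_hu
    out.labels[impl] = LABELS["implant"]
    affected = void & phantom.body_mask
    out.organs["metal_affected"] = affected
    out.outliers_applied.append(
        {"type": "metal", "center": (cx, cy), "void_radius": float(void_radius),
         "implant_radius": float(implant_radius), "implant_hu": float(implant_hu),
         "n_affected_voxels": int(affected.sum())}
    )
    return out


def remove_lung(phantom: TorsoPhantom, side: str) -> TorsoPhantom:
    """Replace one lung by soft tissue (post-pneumonectomy anatomy)."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    key = f"{side}_lung"
    mask = phantom.organs[key]
    out = phantom.copy()
    soft = phantom.config.tissue_table["soft"]
    rng = np.random.default_rng([int(phantom.seed), 1001 if side == "left" else 1002])
    n = int(mask.sum())
    out.labels[mask] = LABELS["soft"]
    out.ct_hu[mask] = soft.ct_hu_mean + rng.standard_normal(n) * soft.ct_hu_sd
    out.mr[mask] = soft.mr_mean + rng.standard_normal(n) * soft.mr_sd
    out.activity[mask] = soft.activity_mean
    del out.organs[key]
    out.organs[f"removed_{side}_lung"] = mask.copy()
    out.outliers_applied.append(
        {"type": "single_lung", "side": side, "n_affected_voxels": n}
    )
    return out


def add_lung_nodule(phantom: TorsoPhantom, center, radius: float,
                    uptake_ratio: float = 4.0) -> TorsoPhantom:
    """Insert a spherical soft-tissue nodule entirely inside a lung.

    ``center`` is ``(x, y, z)`` in mm (z measured from the stack centre).
    Activity inside the nodule is ``uptake_ratio`` times the soft-tissue mean.
    """
    cx, cy, cz = (float(c) for c in center)
    nz, ny, nx = phantom.labels.shape
    sz, sy, sx = phantom.spacing
    z = (np.arange(nz) - (nz - 1) / 2.0) * sz
    Y, X = _grids_mm(phantom.config)
    d2 = ((X[None] - cx) ** 2 + (Y[None] - cy) ** 2
          + ((z - cz) ** 2)[:, None, None])
    sphere = d2 <= radius ** 2
    if not sphere.any():
        raise ValueError("nodule sphere does not intersect the grid")
    lungs = np.zeros_like(sphere)
    for key in ("right_lung", "left_lung"):
        if key in phantom.organs:
            lungs |= phantom.organs[key]
    if not np.all(lungs[sphere]):
        raise ValueError("nodule sphere must lie entirely inside a lung")
    out = phantom.copy()
    soft = phantom.config.tissue_table["soft"]
    lesion = phantom.config.tissue_table["lesion"]
    rng = np.random.default_rng([int(phantom.seed), 2001])
    n = int(sphere.sum())
    out.labels[sphere] = LABELS["lesion"]
    out.ct_hu[sphere] = soft.ct_hu_mean + rng.standard_normal(n) * soft.ct_hu_sd
    out.mr[sphere] = lesion.mr_mean + rng.standard_normal(n) * lesion.mr_sd
    out.activity[sphere] = uptake_ratio * soft.activity_mean
    k = 1 + sum(1 for name in out.organs if name.startswith("lesion_"))
    out.organs[f"lesion_{k}"] = sphere
    out.outliers_applied.append(
        {"type": "nodule", "center": (cx, cy, cz), "radius": float(radius),
         "uptake_ratio": float(uptake_ratio), "n_affected_voxels": n,
         "volume_ml": n * phantom.voxel_volume_ml}
    )
    return out


def simulate_session_misalignment(phantom: TorsoPhantom, magnitude_mm: float,
                                  seed: int):
    """Resample the MR through a smooth random in-plane deformation.

    Emulates the inter-session MR-to-CT misalignment that registration must
    recover.  Returns ``(mr_moved, truth_field)`` where the truth field is the
    applied pull-back displacement (mm, on the fixed grid).
    """
    from .preprocess import DeformationField, resample

    rng = np.random.default_rng([int(seed), 7])
    nz, ny, nx = phantom.mr.shape
    from scipy.ndimage import gaussian_filter

    disp2d = rng.standard_normal((2, ny, nx))
    disp2d = np.stack([gaussian_filter(d, sigma=max(ny, nx) / 8.0) for d in disp2d])
    mag = np.sqrt((disp2d ** 2).sum(axis=0)).max()
    if mag > 0:
        disp2d *= magnitude_mm / mag
    disp = np.zeros(phantom.mr.shape + (3,), dtype=np.float64)
    disp[..., 1] = disp2d[0][None]  # y displacement, mm
    disp[..., 2] = disp2d[1][None]  # x displacement, mm
    fld = DeformationField(displacement=disp, spacing=phantom.spacing,
                           stages=["synthetic"])
    mr_moved = resample(phantom.mr, fld, interpolation="linear",
                        fill=_air_mr_level(phantom))
    return mr_moved, fld
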