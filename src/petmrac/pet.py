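"""Desk-scale 2D PET physics.

Hounsfield units are converted to 511 keV linear attenuation coefficients
with the standard bilinear model anchored at air (-1000 HU -> 0 cm^-1), water
(0 HU -> 0.096 cm^-1) and cortical bone (1000 HU -> 0.172 cm^-1).  Activity
slices are forward projected with a parallel-beam rotation projector (176
angles over 180 degrees), attenuated along each line of response, optionally
Poisson sampled, and reconstructed with ordered-subset expectation
maximization using a candidate attenuation map in the system model — so that
mu-map errors translate into reconstructed-uptake bias through the same
mechanism as on a scanner.  Defaults: 4 iterations, 8 angle-interleaved
subsets, 5e5 counts per slice.

SUV here is a phantom surrogate: no injected dose or body weight exists, so
all reconstruction arms of a subject are scaled by one common factor chosen
to give the reference (CT-based) arm a body mean of 1.0.  Relative bias is
invariant to this common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import rotate as _nd_rotate

MU_WATER = 0.096  # cm^-1 at 511 keV
MU_BONE_1000HU = 0.172
BONE_SLOPE = (MU_BONE_1000HU - MU_WATER) / 1000.0  # per HU above water


@dataclass
class AttenuationMap:
    """Voxel grid of linear attenuation coefficients (cm^-1) with provenance."""

    mu: np.ndarray
    spacing: tuple
    source: str  # reference_ct | seg | atlas | dl

    def __post_init__(self):
        self.mu = np.asarray(self.mu, np.float32)
        if (self.mu < -1e-6).any():
            raise ValueError("attenuation coefficients must be non-negative")
        self.mu = np.maximum(self.mu, 0.0)


def hu_to_mu(ct_hu: np.ndarray, spacing=(1.0, 1.0, 1.0),
             source: str = "reference_ct") -> AttenuationMap:
    """Bilinear HU -> mu conversion, clamped at zero."""
    hu = np.asarray(ct_hu, np.float64)
    mu = np.where(hu <= 0.0, MU_WATER * (hu + 1000.0) / 1000.0,
                  MU_WATER + BONE_SLOPE * hu)
    return AttenuationMap(mu=np.maximum(mu, 0.0), spacing=tuple(spacing),
                          source=source)


@dataclass
class ProjectionGeometry:
    """Parallel-beam geometry: 180-degree coverage, bins at voxel pitch."""

    n_angles: int
    n_bins: int
    bin_spacing: float  # mm
    angles_deg: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.angles_deg is None:
            self.angles_deg = np.arange(self.n_angles) * 180.0 / self.n_angles


def make_geometry(image_shape, spacing, n_angles: int = 176) -> ProjectionGeometry:
    """Geometry whose radial extent covers the (padded) image diagonal."""
    h, w = image_shape[-2:]
    sy, sx = spacing[-2], spacing[-1]
    if not np.isclose(sy, sx):
        raise ValueError("the rotation projector requires isotropic in-plane voxels")
    n_bins = int(np.ceil(max(h, w) * np.sqrt(2.0))) | 1  # odd: center bin on axis
    return ProjectionGeometry(n_angles=n_angles, n_bins=n_bins, bin_spacing=float(sx))


@dataclass
class Sinogram:
    counts: np.ndarray  # (n_angles, n_bins) or (nz, n_angles, n_bins)
    geometry: ProjectionGeometry
    noise: str = "noiseless"  # or "poisson(seed)"

    def __post_init__(self):
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("sinogram counts must be non-negative")

    def save(self, path):
        from . import io
        np.savez(path, counts=self.counts)
        io.write_yaml(str(path) + ".yaml", {
            "n_angles": self.geometry.n_angles, "n_bins": self.geometry.n_bins,
            "bin_spacing_mm": self.geometry.bin_spacing, "noise": self.noise})


def _pad_to(img2d, n_bins):
    h, w = img2d.shape
    py, px = n_bins - h, n_bins - w
    return np.pad(img2d.astype(np.float64),
                  ((py // 2, py - py // 2), (px // 2, px - px // 2)))


def _crop_from(img2d, shape):
    h, w = shape
    n = img2d.shape[0]
    py, px = n - h, n - w
    return img2d[py // 2:py // 2 + h, px // 2:px // 2 + w]


def _rotate(img, angle_deg):
    if angle_deg == 0.0:
        return img
    return _nd_rotate(img, angle_deg, reshape=False, order=1, prefilter=False)


def _project_2d(img2d, geom):
    """Line integrals (value x mm) for every angle; bins along the rotated x."""
    padded = _pad_to(img2d, geom.n_bins)
    out = np.empty((geom.n_angles, geom.n_bins))
    for i, ang in enumerate(geom.angles_deg):
        out[i] = _rotate(padded, ang).sum(axis=0)
    return out * geom.bin_spacing


def _backproject_2d(sino_rows, angle_indices, geom):
    """Adjoint smear of selected sinogram rows onto the padded grid."""
    n = geom.n_bins
    acc = np.zeros((n, n))
    for row, ai in zip(sino_rows, angle_indices):
        acc += _rotate(np.broadcast_to(row, (n, n)).copy(), -geom.angles_deg[ai])
    return acc


def _per_slice(vol):
    arr = np.asarray(vol)
    return arr[None] if arr.ndim == 2 else arr


def attenuation_factors(mu: AttenuationMap, geom: ProjectionGeometry) -> np.ndarray:
    """exp(-integral of mu) per line of response; in (0, 1]."""
    slices = _per_slice(mu.mu)
    out = np.stack([
        np.exp(-_project_2d(s, geom) / 10.0)  # mm -> cm
        for s in slices
    ])
    return out[0] if np.asarray(mu.mu).ndim == 2 else out


def forward_project(activity, mu_true: AttenuationMap, geom: ProjectionGeometry,
                    total_counts="noiseless", seed: int = 0) -> Sinogram:
    """Attenuated forward projection, optionally Poisson sampled per slice."""
    act = _per_slice(activity)
    af = _per_slice(attenuation_factors(mu_true, geom))
    ys = []
    rng = np.random.default_rng(seed)
    for s in range(act.shape[0]):
        y = af[s] * _project_2d(act[s], geom)
        if total_counts != "noiseless":
            tot = y.sum()
            if tot > 0:
                y = y * (float(total_counts) / tot)
            y = rng.poisson(y).astype(np.float64)
        ys.append(y)
    counts = np.stack(ys)
    if np.asarray(activity).ndim == 2:
        counts = counts[0]
    noise = "noiseless" if total_counts == "noiseless" else f"poisson(seed={seed})"
    return Sinogram(counts=counts, geometry=geom, noise=noise)


def osem_reconstruct(sino: Sinogram, mu_candidate: AttenuationMap,
                     iterations: int = 4, subsets: int = 8,
                     eps: float = 1e-12) -> np.ndarray:
    """OSEM with the candidate mu-map in the system model.

    Multiplicative EM update over angle-interleaved subsets; non-negativity is
    preserved at every update.  Returns the activity estimate on the original
    image grid.
    """
    geom = sino.geometry
    if geom.n_angles % subsets:
        raise ValueError("subset count must divide the number of angles")
    counts = _per_slice(sino.counts)
    mus = _per_slice(mu_candidate.mu)
    if mus.shape[0] != counts.shape[0]:
        raise ValueError("mu map and sinogram must have matching slice counts")
    subset_idx = [np.arange(s, geom.n_angles, subsets) for s in range(subsets)]
    n = geom.n_bins
    yy, xx = np.ogrid[:n, :n]
    c = (n - 1) / 2.0
    fov = (yy - c) ** 2 + (xx - c) ** 2 <= c ** 2

    recons = []
    for z in range(counts.shape[0]):
        af = np.exp(-_project_2d(mus[z], geom) / 10.0)
        y = counts[z]
        x = fov.astype(np.float64)
        sens = [
            _backproject_2d(af[idx], idx, geom) for idx in subset_idx
        ]
        for _ in range(iterations):
            for s, idx in enumerate(subset_idx):
                proj = np.empty((len(idx), n))
                for j, ai in enumerate(idx):
                    proj[j] = _rotate(x, geom.angles_deg[ai]).sum(axis=0)
                proj *= geom.bin_spacing
                fwd = af[idx] * proj
                ratio = np.where(fwd > eps, y[idx] / np.maximum(fwd, eps), 0.0)
                back = _backproject_2d(af[idx] * ratio, idx, geom)
                x = x * back / np.maximum(sens[s], eps)
                x[~fov] = 0.0
        recons.append(_crop_from(x, mus[z].shape))
    out = np.stack(recons)
    return out[0] if np.asarray(sino.counts).ndim == 2 else out


def to_suv(recon: np.ndarray, body: np.ndarray, scale: float = None):
    """Scale a reconstruction to the surrogate SUV convention.

    With ``scale=None`` the factor is derived from this reconstruction's body
    mean (use for the reference arm, whose body mean becomes exactly 1.0);
    pass the returned factor to the other arms of the same subject.
    Returns ``(suv_volume, scale)``.
    """
    body = np.asarray(body, bool)
    if not body.any():
        raise ValueError("empty body mask")
    if scale is None:
        m = float(np.asarray(recon)[body].mean())
        if m <= 0:
            raise ValueError("non-positive body mean; cannot normalize")
        scale = 1.0 / m
    return np.asarray(recon) * scale, scale


def suv_normalize(recons: dict, body: np.ndarray,
                  reference: str = "reference_ct") -> dict:
    """Apply the reference-derived common SUV scale to every arm."""
    _, scale = to_suv(recons[reference], body)
    return {k: to_suv(v, body, scale)[0] for k, v in recons.items()}
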