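"""Voxel-wise weighted multi-atlas synthetic CT.

Each atlas MR-CT pair is deformed onto the target MR (affine + B-spline,
mutual information; the transform estimated on the MR pair is shared with the
CT).  A target bone map is obtained by voxel-wise voting over the aligned
atlas bone masks; per-atlas weight volumes then combine a signed-distance
discrepancy kernel (bone morphology agreement) and a phase-congruency
discrepancy kernel (local structural agreement), and the continuous sCT is the
weight-normalized convex combination of the aligned atlas CTs.

The Gaussian product weight

    w_i(v) = exp(-dd_i(v)^2 / 2 sigma_d^2) * exp(-dp_i(v)^2 / 2 sigma_p^2)

with ``dd`` the signed-distance difference (mm) and ``dp`` the mean absolute
phase-congruency difference over a small patch, is this package's normative
fusion rule; ``sigma_d`` = 5 mm, ``sigma_p`` = 0.2, patch radius 2 voxels by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.fft import fft2, ifft2, ifftshift
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import io
from .preprocess import coverage_mask, register, resample

log = logging.getLogger(__name__)

BONE_HU_THRESHOLD = 160.0  # shared with the evaluation tissue masks


@dataclass
class AtlasEntry:
    """One target-aligned atlas member plus its derived features."""

    mr: np.ndarray
    ct_hu: np.ndarray
    bone_mask: np.ndarray
    signed_distance: np.ndarray
    pcm: np.ndarray
    valid_mask: np.ndarray
    subject_id: str = ""


@dataclass
class AtlasDataset:
    entries: list
    spacing: tuple
    excluded_target: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def signed_distance(mask: np.ndarray, spacing=(1.0, 1.0)) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask boundary.

    Negative inside, positive outside, exactly zero on boundary voxels (mask
    voxels with a face-adjacent outside neighbour).  For slice stacks the
    distance is computed in-plane per slice, matching the stack's
    slice-independent anatomy.
    """
    mask = np.asarray(mask, bool)
    if mask.ndim == 3:
        sy, sx = spacing[-2], spacing[-1]
        return np.stack([signed_distance(s, (sy, sx)) for s in mask])
    if not mask.any():
        raise ValueError("signed distance undefined for an empty mask")
    if mask.all():
        raise ValueError("signed distance undefined for an all-true mask")
    interior = ndimage.binary_erosion(mask)
    boundary = mask & ~interior
    d = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    return np.where(mask, -d, d)


def phase_congruency(img: np.ndarray, nscale: int = 4, norient: int = 6,
                     min_wavelength: float = 3.0, mult: float = 2.1,
                     sigma_onf: float = 0.55, k: float = 2.0,
                     cut_off: float = 0.5, sharpness: float = 10.0,
                     eps: float = 1e-4) -> np.ndarray:
    """Phase congruency map in [0, 1] from a log-Gabor filter bank.

    Contrast invariant up to the numerical noise floor: the Rayleigh-based
    noise threshold is estimated from the smallest-scale filter responses, so
    an affine intensity rescaling of the input cancels out.
    """
    img = np.asarray(img, np.float64)
    if img.ndim == 3:
        return np.stack([
            phase_congruency(s, nscale, norient, min_wavelength, mult,
                             sigma_onf, k, cut_off, sharpness, eps)
            for s in img
        ])
    rows, cols = img.shape
    IM = fft2(img)

    y = (np.arange(rows) - rows // 2) / rows
    x = (np.arange(cols) - cols // 2) / cols
    Y, X = np.meshgrid(y, x, indexing="ij")
    radius = ifftshift(np.sqrt(X ** 2 + Y ** 2))
    radius[0, 0] = 1.0
    theta = ifftshift(np.arctan2(-Y, X))
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)

    log_gabors = []
    for s in range(nscale):
        fo = 1.0 / (min_wavelength * mult ** s)
        lg = np.exp(-(np.log(radius / fo)) ** 2 / (2 * np.log(sigma_onf) ** 2))
        lg *= lowpass
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    total_energy = np.zeros((rows, cols))
    total_an = np.zeros((rows, cols))
    for o in range(norient):
        angl = o * np.pi / norient
        ds = np.sin(theta) * np.cos(angl) - np.cos(theta) * np.sin(angl)
        dc = np.cos(theta) * np.cos(angl) + np.sin(theta) * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        sigma_theta = np.pi / norient / 1.2
        spread = np.exp(-dtheta ** 2 / (2 * sigma_theta ** 2))

        sumE = np.zeros((rows, cols))
        sumO = np.zeros((rows, cols))
        sumAn = np.zeros((rows, cols))
        maxAn = np.zeros((rows, cols))
        tau = 0.0
        for s in range(nscale):
            eo = ifft2(IM * log_gabors[s] * spread)
            e, od = np.real(eo), np.imag(eo)
            an = np.abs(eo)
            sumE += e
            sumO += od
            sumAn += an
            maxAn = np.maximum(maxAn, an)
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4))
        x_energy = np.sqrt(sumE ** 2 + sumO ** 2) + eps
        mean_e, mean_o = sumE / x_energy, sumO / x_energy
        energy = np.zeros((rows, cols))
        for s in range(nscale):
            eo = ifft2(IM * log_gabors[s] * spread)
            e, od = np.real(eo), np.imag(eo)
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        # expected noise energy from the Rayleigh-distributed amplitudes
        total_tau = tau * (1 - (1 / mult) ** nscale) / (1 - 1 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        T = noise_mean + k * noise_sigma
        energy = np.maximum(energy - T, 0.0)
        width = (sumAn / (maxAn + eps) - 1.0) / max(nscale - 1, 1)
        weight = 1.0 / (1.0 + np.exp(sharpness * (cut_off - width)))
        total_energy += weight * energy
        total_an += sumAn
    return np.clip(total_energy / (total_an + eps), 0.0, 1.0)


# ---------------------------------------------------------------------------
# atlas mapping and fusion
# ---------------------------------------------------------------------------

def _entry_from_aligned(mr, ct, valid, spacing, bone_hu, subject_id=""):
    bone = (ct > bone_hu) & valid
    if bone.any() and not bone.all():
        sd = signed_distance(bone, spacing[-2:])
    else:
        # no bone coverage: park the signed distance far away so the bone
        # morphology kernel gives this atlas negligible weight near bone
        diag = float(np.sqrt(sum((n * s) ** 2
                                 for n, s in zip(mr.shape[-2:], spacing[-2:]))))
        sd = np.full(mr.shape, diag, dtype=np.float64)
    return AtlasEntry(mr=mr, ct_hu=ct, bone_mask=bone, signed_distance=sd,
                      pcm=phase_congruency(mr), valid_mask=valid,
                      subject_id=subject_id)


def map_atlases_to_target(atlas_mrs, atlas_cts, target_mr,
                          spacing=(1.0, 1.0, 1.0), bone_hu: float = BONE_HU_THRESHOLD,
                          subject_ids=None, registration: str = "two_stage",
                          excluded_target: str = "") -> AtlasDataset:
    """Deform every atlas MR-CT pair onto the target MR grid.

    Registration is estimated on the mid-slice MR pair in 2D and the recovered
    in-plane field is applied to every slice (the phantom stacks share their
    in-plane anatomy across slices); the same transform maps MR and CT.
    """
    entries = []
    nz = target_mr.shape[0]
    mid = nz // 2
    tgt2d = target_mr[mid:mid + 1]
    for i, (amr, act) in enumerate(zip(atlas_mrs, atlas_cts)):
        sid = subject_ids[i] if subject_ids else f"atlas_{i}"
        mov2d = amr[mid:mid + 1]
        aff = register(mov2d, tgt2d, spacing, stage="affine")
        if registration == "two_stage":
            warped = resample(mov2d, aff, interpolation="linear")
            bsp = register(warped, tgt2d, spacing, stage="bspline")
            fld2d = aff.compose(bsp)
        else:
            fld2d = aff
        disp = np.repeat(fld2d.displacement, nz, axis=0)
        fld = type(fld2d)(displacement=disp, spacing=spacing,
                          stages=fld2d.stages)
        mr_w = resample(amr, fld, interpolation="linear", fill=0.0)
        ct_w = resample(act, fld, interpolation="linear", fill=-1000.0)
        valid = coverage_mask(fld, amr.shape)
        entries.append(_entry_from_aligned(mr_w, ct_w, valid, spacing, bone_hu,
                                           subject_id=sid))
    return AtlasDataset(entries=entries, spacing=tuple(spacing),
                        excluded_target=excluded_target)


def vote_bone_map(dataset: AtlasDataset, threshold: float = 0.5) -> np.ndarray:
    """Voxel-wise majority bone map over the aligned atlas bone masks."""
    if len(dataset) < 2:
        raise ValueError("bone voting requires at least two atlas entries")
    votes = np.stack([e.bone_mask for e in dataset.entries]).astype(np.float64)
    valid = np.stack([e.valid_mask for e in dataset.entries]).astype(np.float64)
    n_valid = valid.sum(axis=0)
    frac = np.divide(votes.sum(axis=0), n_valid, out=np.zeros_like(n_valid),
                     where=n_valid > 0)
    return frac >= threshold


def atlas_weights(target_sd, target_pcm, dataset: AtlasDataset,
                  sigma_d: float = 5.0, sigma_p: float = 0.2,
                  patch_radius: int = 2) -> np.ndarray:
    """Per-atlas weight volumes, normalized to sum to one at every voxel.

    ``target_sd`` may be None when the voted bone map is empty; the signed
    distance kernel is then skipped and weights derive from phase congruency
    alone (logged).
    """
    size = 2 * patch_radius + 1
    raws = []
    for e in dataset.entries:
        if target_sd is not None:
            dd = e.signed_distance - target_sd
            wd = np.exp(-dd ** 2 / (2 * sigma_d ** 2))
        else:
            wd = np.ones_like(e.pcm)
        dp = np.abs(e.pcm - target_pcm)
        if dp.ndim == 3:
            dp = ndimage.uniform_filter(dp, size=(1, size, size))
        else:
            dp = ndimage.uniform_filter(dp, size=size)
        wp = np.exp(-dp ** 2 / (2 * sigma_p ** 2))
        raws.append(wd * wp * e.valid_mask)
    if target_sd is None:
        log.warning("empty voted bone map: atlas weights use phase congruency only")
    w = np.stack(raws)
    tot = w.sum(axis=0)
    under = tot < 1e-12
    if under.any():
        log.info("uniform-weight fallback at %d voxels", int(under.sum()))
        valid = np.stack([e.valid_mask for e in dataset.entries]).astype(np.float64)
        n_valid = valid.sum(axis=0)
        fallback = np.divide(valid, n_valid, out=np.full_like(valid, 1.0 / len(w)),
                             where=n_valid > 0)
        w = np.where(under, fallback, w)
        tot = w.sum(axis=0)
    return w / tot


def fuse_sct(dataset: AtlasDataset, weights=None) -> np.ndarray:
    """Weighted voxel-wise fusion of the aligned atlas CTs (convex combination)."""
    cts = np.stack([e.ct_hu for e in dataset.entries])
    if weights is None or len(dataset) == 1:
        weights = np.full((len(dataset),) + cts.shape[1:], 1.0 / len(dataset))
    return (weights * cts).sum(axis=0).astype(np.float32)


class AtlasSCT(BaseEstimator):
    """Multi-atlas sCT estimator: fit stores the atlas library, predict fuses."""

    def __init__(self, sigma_d: float = 5.0, sigma_p: float = 0.2,
                 patch_radius: int = 2, vote_threshold: float = 0.5,
                 bone_hu: float = BONE_HU_THRESHOLD,
                 registration: str = "two_stage"):
        self.sigma_d = sigma_d
        self.sigma_p = sigma_p
        self.patch_radius = patch_radius
        self.vote_threshold = vote_threshold
        self.bone_hu = bone_hu
        self.registration = registration

    def fit(self, atlas_mrs, atlas_cts, spacing=(1.0, 1.0, 1.0),
            subject_ids=None):
        if len(atlas_mrs) != len(atlas_cts) or len(atlas_mrs) == 0:
            raise ValueError("need equal, non-zero numbers of atlas MRs and CTs")
        self.atlas_mrs_ = [np.asarray(a) for a in atlas_mrs]
        self.atlas_cts_ = [np.asarray(a) for a in atlas_cts]
        self.spacing_ = tuple(spacing)
        self.subject_ids_ = subject_ids or [f"atlas_{i}"
                                            for i in range(len(atlas_mrs))]
        return self

    def predict(self, target_mr, exclude_subject: str = "") -> np.ndarray:
        """Fuse a synthetic CT (HU) for the target MR volume."""
        keep = [i for i, s in enumerate(self.subject_ids_) if s != exclude_subject]
        ds = map_atlases_to_target(
            [self.atlas_mrs_[i] for i in keep],
            [self.atlas_cts_[i] for i in keep],
            target_mr, spacing=self.spacing_, bone_hu=self.bone_hu,
            subject_ids=[self.subject_ids_[i] for i in keep],
            registration=self.registration, excluded_target=exclude_subject)
        if len(ds) == 1:
            return fuse_sct(ds)
        bone = vote_bone_map(ds, self.vote_threshold)
        target_sd = signed_distance(bone, self.spacing_[-2:]) if bone.any() else None
        target_pcm = phase_congruency(target_mr)
        w = atlas_weights(target_sd, target_pcm, ds, self.sigma_d,
                          self.sigma_p, self.patch_radius)
        return fuse_sct(ds, w)


# ---------------------------------------------------------------------------
# on-disk atlas library
# ---------------------------------------------------------------------------

def save_atlas_library(directory, atlas_mrs, atlas_cts, spacing, subject_ids=None,
                       excluded=()):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subject_ids = subject_ids or [f"atlas_{i}" for i in range(len(atlas_mrs))]
    pairs = []
    for sid, mr, ct in zip(subject_ids, atlas_mrs, atlas_cts):
        io.write_volume(directory / f"{sid}_mr.nii.gz", mr, spacing, np.float32)
        io.write_volume(directory / f"{sid}_ct.nii.gz", ct, spacing, np.float32)
        pairs.append({"id": sid, "mr": f"{sid}_mr.nii.gz", "ct": f"{sid}_ct.nii.gz"})
    io.write_yaml(directory / "manifest.yaml",
                  {"pairs": pairs, "loocv_excluded": list(excluded)})


def load_atlas_library(directory):
    directory = Path(directory)
    manifest = io.read_yaml(directory / "manifest.yaml")
    mrs, cts, ids = [], [], []
    spacing = None
    for pair in manifest["pairs"]:
        if pair["id"] in manifest.get("loocv_excluded", []):
            continue
        mr, spacing = io.read_volume(directory / pair["mr"])
        ct, _ = io.read_volume(directory / pair["ct"])
        mrs.append(mr)
        cts.append(ct)
        ids.append(pair["id"])
    return mrs, cts, ids, spacing
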