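"""Three-class segmentation-based attenuation map.

Vendor-style bulk tissue classification: a body contour is delineated on the
normalized MR image, lungs are segmented as large low-intensity regions inside
the body, and fixed values are assigned per class — soft tissue 0 HU
(0.096 cm^-1), background air -1000 HU (0 cm^-1), lung -770 HU (0.022 cm^-1).
No bone class exists by construction; the resulting bone underestimation is a
documented property of this approach, not a defect of the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

CLASS_VALUES_HU = {"background_air": -1000.0, "lung": -770.0, "soft_tissue": 0.0}
CLASS_VALUES_MU = {"background_air": 0.0, "lung": 0.022, "soft_tissue": 0.096}
CLASS_CODES = {"background_air": 0, "lung": 1, "soft_tissue": 2}


@dataclass
class ThreeClassMap:
    """Exhaustive, mutually exclusive background/lung/soft classification."""

    classes: np.ndarray  # uint8 per CLASS_CODES
    provenance: dict = field(default_factory=dict)

    def mask(self, name: str) -> np.ndarray:
        return self.classes == CLASS_CODES[name]


def delineate_body(mr_norm: np.ndarray, closing_radius: int = 2) -> np.ndarray:
    """Body contour: Otsu threshold, morphological closing, hole filling,
    largest connected component."""
    mr_norm = np.asarray(mr_norm)
    if np.ptp(mr_norm) == 0:
        raise ValueError("cannot delineate a body on a constant image")
    thr = threshold_otsu(mr_norm)
    fg = mr_norm > thr
    if not fg.any():
        raise ValueError("empty body mask after thresholding")
    struct = _plane_ball(closing_radius, mr_norm.ndim)
    fg = ndimage.binary_closing(fg, structure=struct)
    # fill holes slice-wise so dark interior organs (lungs, bone) are inside
    fg = np.stack([ndimage.binary_fill_holes(s) for s in fg]) if fg.ndim == 3 \
        else ndimage.binary_fill_holes(fg)
    lab, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("empty body mask after morphology")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def segment_lungs(mr_norm: np.ndarray, body: np.ndarray,
                  spacing=(1.0, 1.0, 1.0), min_volume_ml: float = 50.0,
                  reference_stack_cm: float = 4.0,
                  hole_area_cm2: float = 4.0) -> np.ndarray:
    """Lungs: large low-intensity components interior to the body.

    The size prior (``min_volume_ml``, expressed for a ``reference_stack_cm``
    thick stack and scaled to the actual stack extent) excludes bone and small
    signal voids; interior holes up to ``hole_area_cm2`` per slice are filled,
    so sub-centimetre structures such as vessels or small nodules are absorbed
    into the lung — the behaviour of bulk classification at coarse scale.
    """
    body = np.asarray(body, bool)
    mr_norm = np.asarray(mr_norm)
    inside = mr_norm[body]
    if inside.size == 0:
        raise ValueError("empty body mask")
    # lungs are far darker than the soft/fat bulk: threshold at half the
    # median body intensity (contrast-invariant after unit-range scaling)
    thr = 0.5 * float(np.median(inside))
    interior = ndimage.binary_erosion(body, structure=_plane_ball(1, body.ndim))
    cand = (mr_norm < thr) & interior

    sz, sy, sx = spacing
    voxel_ml = sz * sy * sx / 1000.0
    stack_cm = mr_norm.shape[0] * sz / 10.0 if mr_norm.ndim == 3 else sz / 10.0
    thr_ml = min_volume_ml * min(1.0, stack_cm / reference_stack_cm)

    lab, n = ndimage.label(cand)
    lungs = np.zeros_like(body)
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() * voxel_ml < thr_ml:
            continue
        # positional prior: component centred well inside the body
        com = ndimage.center_of_mass(comp)
        idx = tuple(int(round(c)) for c in com)
        if not interior[idx]:
            continue
        lungs |= comp
    if lungs.any():
        max_hole_vox = int(round(hole_area_cm2 * 100.0 / (sy * sx)))
        filled = []
        for s in (lungs if lungs.ndim == 3 else lungs[None]):
            holes = ndimage.binary_fill_holes(s) & ~s
            hl, hn = ndimage.label(holes)
            keep = s.copy()
            for h in range(1, hn + 1):
                hole = hl == h
                if hole.sum() <= max_hole_vox:
                    keep |= hole
            filled.append(keep)
        lungs = np.stack(filled) if lungs.ndim == 3 else filled[0]
    return lungs & body


def build_seg_sct(mr_norm: np.ndarray, spacing=(1.0, 1.0, 1.0),
                  min_volume_ml: float = 50.0, closing_radius: int = 2):
    """Run the full three-class pipeline.

    Returns ``(ThreeClassMap, sct_hu, mu_map)`` where the attenuation map is
    a :class:`petmrac.pet.AttenuationMap` tagged ``'seg'``.
    """
    from .pet import AttenuationMap

    try:
        body = delineate_body(mr_norm, closing_radius=closing_radius)
        lungs = segment_lungs(mr_norm, body, spacing=spacing,
                              min_volume_ml=min_volume_ml)
    except ValueError:
        # no detectable body (e.g. an all-air field of view): everything is
        # background air
        body = np.zeros(np.shape(mr_norm), bool)
        lungs = np.zeros(np.shape(mr_norm), bool)
    classes = np.zeros(mr_norm.shape, dtype=np.uint8)
    classes[body] = CLASS_CODES["soft_tissue"]
    classes[lungs] = CLASS_CODES["lung"]

    sz, sy, sx = spacing
    voxel_ml = sz * sy * sx / 1000.0
    lung_ml = float(lungs.sum() * voxel_ml)
    body_ml = float(body.sum() * voxel_ml)
    n_lung_components = int(ndimage.label(lungs)[1])
    warnings = []
    if body_ml > 0 and lung_ml / body_ml > 0.40:
        warnings.append("lung volume exceeds 40% of body volume; "
                        "possible signal-void mis-segmentation")
    if n_lung_components != 2:
        warnings.append(f"{n_lung_components} lung component(s) found; "
                        "atypical anatomy or signal-void mis-segmentation")
    prov = {
        "thresholds": "otsu(body) / otsu(image)",
        "closing_radius_vox": closing_radius,
        "min_volume_ml": min_volume_ml,
        "lung_volume_ml": lung_ml,
        "n_lung_components": n_lung_components,
        "warnings": warnings,
    }
    tcm = ThreeClassMap(classes=classes, provenance=prov)

    sct_hu = np.zeros(mr_norm.shape, dtype=np.float32)
    mu = np.zeros(mr_norm.shape, dtype=np.float32)
    for name, code in CLASS_CODES.items():
        sct_hu[classes == code] = CLASS_VALUES_HU[name]
        mu[classes == code] = CLASS_VALUES_MU[name]
    return tcm, sct_hu, AttenuationMap(mu=mu, spacing=spacing, source="seg")


class SegmentationSCT(BaseEstimator):
    """Estimator facade over the three-class pipeline (stateless: fit is a no-op)."""

    def __init__(self, min_volume_ml: float = 50.0, closing_radius: int = 2):
        self.min_volume_ml = min_volume_ml
        self.closing_radius = closing_radius

    def fit(self, X=None, y=None):
        self.fitted_ = True
        return self

    def predict(self, mr_norm, spacing=(1.0, 1.0, 1.0)):
        """Return the synthetic CT (HU) for a normalized MR volume."""
        _, sct_hu, _ = build_seg_sct(mr_norm, spacing=spacing,
                                     min_volume_ml=self.min_volume_ml,
                                     closing_radius=self.closing_radius)
        return sct_hu

    def predict_full(self, mr_norm, spacing=(1.0, 1.0, 1.0)):
        return build_seg_sct(mr_norm, spacing=spacing,
                             min_volume_ml=self.min_volume_ml,
                             closing_radius=self.closing_radius)


def _plane_ball(radius: int, ndim: int) -> np.ndarray:
    """In-plane disk structuring element (no coupling across slices)."""
    r = int(radius)
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    disk = (x ** 2 + y ** 2) <= r ** 2
    return disk[None] if ndim == 3 else disk
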