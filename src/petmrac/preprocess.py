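"""MR conditioning and registration: N4 bias correction, histogram matching,
unit-range normalization, and affine + B-spline registration driven by Mattes
mutual information.

Deformations are represented as pull-back displacement fields on the fixed
grid: ``output(v) = moving(v + d(v))`` with ``d`` in millimetres, component
order ``(z, y, x)`` matching the array axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates
from skimage.exposure import match_histograms as _sk_match_histograms

log = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Raised when moving and fixed grids do not overlap physically."""


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) on the fixed grid, pull-back convention."""

    displacement: np.ndarray  # shape grid + (3,), components (z, y, x)
    spacing: tuple
    stages: list = field(default_factory=list)
    metric_trace: list = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field must be finite everywhere")

    @classmethod
    def identity(cls, shape, spacing) -> "DeformationField":
        return cls(displacement=np.zeros(tuple(shape) + (3,)), spacing=tuple(spacing),
                   stages=["identity"])

    def magnitude_mm(self) -> np.ndarray:
        return np.sqrt((self.displacement ** 2).sum(axis=-1))

    def compose(self, inner: "DeformationField") -> "DeformationField":
        """Field equivalent to applying ``self`` first, then ``inner``.

        Pull-back composition: resampling through the composed field equals
        resampling through ``inner`` an image already resampled through
        ``self``  (d(v) = d_inner(v) + d_self(v + d_inner(v))).
        """
        grid = self.displacement.shape[:-1]
        sz, sy, sx = self.spacing
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in grid], indexing="ij"))
        inner_vox = np.moveaxis(inner.displacement, -1, 0) / np.array(
            [sz, sy, sx]).reshape(3, 1, 1, 1)
        coords = idx + inner_vox
        outer_at = np.stack([
            map_coordinates(self.displacement[..., c], coords, order=1, mode="nearest")
            for c in range(3)
        ], axis=-1)
        return DeformationField(
            displacement=inner.displacement + outer_at,
            spacing=self.spacing,
            stages=list(self.stages) + list(inner.stages),
        )

    def save(self, path):
        from . import io
        io.write_volume(path, np.moveaxis(self.displacement, -1, 0), self.spacing,
                        np.float32)

    @classmethod
    def load(cls, path, stages=None):
        from . import io
        arr, spacing = io.read_volume(path)
        return cls(displacement=np.moveaxis(arr, 0, -1), spacing=spacing,
                   stages=stages or ["loaded"])


def resample(img: np.ndarray, fld: DeformationField, interpolation: str = "linear",
             fill: float = 0.0) -> np.ndarray:
    """Resample ``img`` through ``fld`` (nearest for labels, linear otherwise)."""
    order = {"linear": 1, "nearest": 0}[interpolation]
    grid = img.shape
    sz, sy, sx = fld.spacing
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in grid], indexing="ij"))
    disp_vox = np.moveaxis(fld.displacement, -1, 0) / np.array(
        [sz, sy, sx]).reshape(3, 1, 1, 1)
    coords = idx + disp_vox
    out = map_coordinates(img.astype(np.float64), coords, order=order,
                          mode="constant", cval=fill)
    return out.astype(img.dtype if np.issubdtype(img.dtype, np.floating) else np.float64)


def coverage_mask(fld: DeformationField, shape) -> np.ndarray:
    """Boolean mask of voxels whose pulled-back position stays inside the grid."""
    sz, sy, sx = fld.spacing
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"))
    disp_vox = np.moveaxis(fld.displacement, -1, 0) / np.array(
        [sz, sy, sx]).reshape(3, 1, 1, 1)
    coords = idx + disp_vox
    ok = np.ones(shape, dtype=bool)
    for ax, n in enumerate(shape):
        ok &= (coords[ax] >= -0.5) & (coords[ax] <= n - 0.5)
    return ok


# ---------------------------------------------------------------------------
# intensity conditioning
# ---------------------------------------------------------------------------

def correct_bias_field(mr: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0),
                       shrink: int = 2, fitting_levels: int = 2,
                       iterations: int = 20) -> np.ndarray:
    """N4 bias-field correction of an MR volume within a body mask.

    The low-frequency multiplicative component is estimated on a shrunk copy
    and removed at full resolution; the mean intensity inside the mask is
    preserved so downstream normalization is unaffected.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to correct")
    arr = np.asarray(mr, np.float32)
    squeeze = arr.shape[0] == 1
    a = arr[0] if squeeze else arr
    m = mask[0] if squeeze else mask
    sp = tuple(float(s) for s in (spacing[::-1][:2] if squeeze else spacing[::-1]))

    img = sitk.GetImageFromArray(a)
    img.SetSpacing(sp)
    mimg = sitk.GetImageFromArray(m.astype(np.uint8))
    mimg.SetSpacing(sp)
    shrink_f = [min(shrink, max(1, s // 8)) for s in img.GetSize()]
    small = sitk.Shrink(img, shrink_f)
    msmall = sitk.Shrink(mimg, shrink_f)
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([iterations] * fitting_levels)
    n4.Execute(small, msmall)
    log_bias = sitk.GetArrayFromImage(n4.GetLogBiasFieldAsImage(img))
    corrected = a / np.exp(log_bias).astype(np.float32)
    # preserve the in-mask mean
    scale = float(a[m].mean()) / max(float(corrected[m].mean()), 1e-12)
    corrected = corrected * scale
    out = corrected[None] if squeeze else corrected
    return out.astype(np.float32)


def match_histogram(mr: np.ndarray, reference_mr: np.ndarray) -> np.ndarray:
    """Map the intensity distribution of ``mr`` onto that of the reference."""
    mr = np.asarray(mr, np.float32)
    ref = np.asarray(reference_mr, np.float32)
    if np.ptp(mr) == 0:
        # degenerate histogram: a constant image maps to the reference median
        return np.full_like(mr, float(np.median(ref)))
    if np.ptp(ref) == 0:
        return np.full_like(mr, float(ref.flat[0]))
    return _sk_match_histograms(mr, ref).astype(np.float32)


def normalize_unit_range(img: np.ndarray, clip_percentiles=(0.0, 99.5)) -> np.ndarray:
    """Linearly map intensities to [0, 1] with percentile clipping.

    Zero-range images map to all zeros by convention.
    """
    img = np.asarray(img, np.float32)
    lo, hi = np.percentile(img, clip_percentiles)
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _to_sitk(arr, spacing, origin):
    squeeze = arr.shape[0] == 1
    a = np.asarray(arr, np.float32)
    sz, sy, sx = (float(s) for s in spacing)
    if squeeze:
        img = sitk.GetImageFromArray(a[0])
        img.SetSpacing((sx, sy))
        img.SetOrigin(tuple(float(o) for o in origin[:2]))
    else:
        img = sitk.GetImageFromArray(a)
        img.SetSpacing((sx, sy, sz))
        img.SetOrigin(tuple(float(o) for o in origin))
    return img, squeeze


def _check_overlap(moving, fixed, spacing, moving_origin, fixed_origin):
    # physical extents along (x, y, z) = reversed array axes
    sp = np.array(spacing, float)[::-1]  # (sx, sy, sz)
    m_shape = np.array(moving.shape, float)[::-1]
    f_shape = np.array(fixed.shape, float)[::-1]
    m_lo = np.array(moving_origin, float)
    f_lo = np.array(fixed_origin, float)
    m_hi = m_lo + m_shape * sp
    f_hi = f_lo + f_shape * sp
    if np.any(m_hi <= f_lo) or np.any(f_hi <= m_lo):
        raise GeometryError("moving and fixed physical extents do not overlap")


def _field_from_transform(transform, fixed_img, squeeze, spacing, metric_trace,
                          stages):
    flt = sitk.TransformToDisplacementFieldFilter()
    flt.SetReferenceImage(fixed_img)
    disp_img = flt.Execute(transform)
    disp = sitk.GetArrayFromImage(disp_img)  # (..., (x, y[, z])) mm
    if squeeze:
        full = np.zeros((1,) + disp.shape[:-1] + (3,))
        full[0, ..., 2] = disp[..., 0]
        full[0, ..., 1] = disp[..., 1]
    else:
        full = disp[..., ::-1]  # (x,y,z) -> (z,y,x)
    return DeformationField(displacement=np.ascontiguousarray(full),
                            spacing=tuple(spacing), stages=stages,
                            metric_trace=metric_trace)


def register(moving: np.ndarray, fixed: np.ndarray, spacing=(1.0, 1.0, 1.0),
             stage: str = "affine", metric: str = "mutual_information",
             moving_origin=(0.0, 0.0, 0.0), fixed_origin=(0.0, 0.0, 0.0),
             grid_spacing_mm: float = 32.0, sampling: float = 0.5,
             seed: int = 12345, n_retries: int = 1) -> DeformationField:
    """Register ``moving`` onto ``fixed``; returns the recovered field.

    ``stage`` is ``'affine'`` or ``'bspline'``.  The Mattes mutual-information
    metric trace is recorded on the returned field; when a B-spline stage ends
    no better than it started, the registration is retried once with a
    perturbed control-point spacing.
    """
    if metric != "mutual_information":
        raise ValueError("only the mutual-information metric is supported")
    if stage not in ("affine", "bspline"):
        raise ValueError("stage must be 'affine' or 'bspline'")
    _check_overlap(moving, fixed, spacing, moving_origin, fixed_origin)

    mov_img, squeeze = _to_sitk(moving, spacing, moving_origin)
    fix_img, _ = _to_sitk(fixed, spacing, fixed_origin)
    dim = fix_img.GetDimension()

    def _run(grid_mm):
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(sampling, seed)
        reg.SetInterpolator(sitk.sitkLinear)
        if stage == "affine":
            tx = sitk.CenteredTransformInitializer(
                fix_img, mov_img, sitk.AffineTransform(dim),
                sitk.CenteredTransformInitializerFilter.GEOMETRY)
            reg.SetInitialTransform(tx, inPlace=False)
            reg.SetOptimizerAsRegularStepGradientDescent(
                learningRate=1.0, minStep=1e-4, numberOfIterations=200,
                relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
            reg.SetOptimizerScalesFromPhysicalShift()
            reg.SetShrinkFactorsPerLevel([4, 2, 1])
            reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
        else:
            phys = [sz * n for sz, n in zip(fix_img.GetSpacing(), fix_img.GetSize())]
            mesh = [max(2, int(round(p / grid_mm))) for p in phys]
            tx = sitk.BSplineTransformInitializer(fix_img, mesh)
            reg.SetInitialTransform(tx, inPlace=False)
            reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                                     numberOfIterations=100)
            reg.SetShrinkFactorsPerLevel([2, 1])
            reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
        trace = []
        reg.AddCommand(sitk.sitkIterationEvent,
                       lambda: trace.append(float(reg.GetMetricValue())))
        out_tx = reg.Execute(fix_img, mov_img)
        return out_tx, trace

    try:
        out_tx, trace = _run(grid_spacing_mm)
    except RuntimeError as exc:
        # degenerate content (e.g. a slice dominated by signal voids) can make
        # the sampled metric unevaluable; fall back to the identity field
        log.warning("%s registration failed (%s); returning identity field",
                    stage, exc)
        return DeformationField.identity(np.shape(moving), tuple(spacing))
    if stage == "bspline" and n_retries > 0 and trace and min(trace) >= trace[0]:
        log.warning("bspline registration did not improve the metric "
                    "(%g -> %g); retrying with perturbed control-point spacing",
                    trace[0], trace[-1])
        try:
            tx2, trace2 = _run(grid_spacing_mm * 0.75)
            if trace2 and trace2[-1] < trace[-1]:
                out_tx, trace = tx2, trace2
        except RuntimeError as exc:
            log.warning("bspline retry failed (%s); keeping first result", exc)
    if trace:
        log.info("%s registration metric: %g -> %g (%d evaluations)",
                 stage, trace[0], trace[-1], len(trace))
    return _field_from_transform(out_tx, fix_img, squeeze, spacing, trace,
                                 [stage])


def register_two_stage(moving, fixed, spacing=(1.0, 1.0, 1.0), **kw):
    """Affine followed by B-spline; returns the composed field."""
    aff = register(moving, fixed, spacing, stage="affine", **kw)
    warped = resample(moving, aff, interpolation="linear")
    bsp = register(warped, fixed, spacing, stage="bspline", **kw)
    out = aff.compose(bsp)
    out.metric_trace = list(aff.metric_trace) + list(bsp.metric_trace)
    return out
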