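"""NIfTI and YAML input/output helpers.

Array convention throughout the package: volumes are numpy arrays indexed
``(z, y, x)`` with voxel spacing given as ``(sz, sy, sx)`` in millimetres.
On disk the standard NIfTI-1 ``(x, y, z)`` layout is used, with the affine
carrying the spacing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


def write_volume(path, arr, spacing, dtype=None):
    """Write a ``(z, y, x)`` array as a NIfTI-1 file with the given spacing."""
    arr = np.asarray(arr)
    if dtype is not None:
        arr = arr.astype(dtype)
    sz, sy, sx = (float(s) for s in spacing)
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(arr.T), affine)
    img.header.set_zooms((sx, sy, sz) + (1.0,) * (arr.ndim - 3))
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI file, returning ``(array_zyx, spacing_zyx)``."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).T
    sx, sy, sz = (float(z) for z in img.header.get_zooms()[:3])
    return np.ascontiguousarray(arr), (sz, sy, sx)


def write_yaml(path, obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(_plain(obj), sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
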