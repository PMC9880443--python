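"""NIfTI and tabular I/O for grids, masks and displacement fields.

Volumes are stored as NIfTI-1 with the on-disk axis order (x, y, z) expected
by most viewers; in memory the package uses (z, y, x).  Displacement fields
are 4-D volumes whose last axis holds the (x, y, z) components in mm.
Masks round-trip bit-exactly (uint8); doses and fields are stored as
float64.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import DisplacementField, DoseGrid, GridSpec, StructureMask

__all__ = ["read_grid", "write_grid", "require_same_grid", "write_json", "read_json"]


def _affine(spec: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spec.spacing[::-1]
    aff[:3, 3] = spec.origin[::-1]
    return aff


def _spec_from(img) -> GridSpec:
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in (2, 1, 0))
    origin = tuple(float(aff[i, 3]) for i in (2, 1, 0))
    shape = tuple(int(s) for s in img.shape[:3][::-1])
    return GridSpec(shape, spacing, origin)


def write_grid(path, obj) -> None:
    """Write a DoseGrid, StructureMask or DisplacementField as NIfTI."""
    if isinstance(obj, StructureMask):
        data = obj.values.astype(np.uint8).transpose(2, 1, 0)
    elif isinstance(obj, DisplacementField):
        # (z,y,x,3 zyx-components) -> (x,y,z,3 xyz-components)
        data = obj.values[..., ::-1].transpose(2, 1, 0, 3).astype(np.float64)
    elif isinstance(obj, DoseGrid):
        data = obj.values.astype(np.float64).transpose(2, 1, 0)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    nib.save(nib.Nifti1Image(data, _affine(obj.grid)), str(path))


def read_grid(path, kind: str | None = None):
    """Read a NIfTI volume as DoseGrid, StructureMask or DisplacementField.

    ``kind`` (dose / mask / field) overrides the inference from
    dimensionality (4-D → field) and dtype (integer → mask).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spec = _spec_from(img)
    data = np.asarray(img.dataobj)
    if kind is None:
        if data.ndim == 4:
            kind = "field"
        elif np.issubdtype(data.dtype, np.integer):
            kind = "mask"
        else:
            kind = "dose"
    if kind == "field":
        if data.ndim != 4 or data.shape[3] != 3:
            raise ValueError(f"malformed field volume {path}: shape {data.shape}")
        vals = data.transpose(2, 1, 0, 3)[..., ::-1].astype(float)
        return DisplacementField(spec, vals)
    if data.ndim != 3:
        raise ValueError(f"malformed volume {path}: shape {data.shape}")
    if kind == "mask":
        return StructureMask(spec, data.transpose(2, 1, 0).astype(bool))
    if kind == "dose":
        return DoseGrid(spec, data.transpose(2, 1, 0).astype(float))
    raise ValueError(f"unknown kind {kind!r}")


def require_same_grid(a, b, name_a: str, name_b: str) -> None:
    """Raise a descriptive error when two volumes disagree on geometry."""
    if a.grid != b.grid:
        raise ValueError(
            f"grid mismatch between {name_a} ({a.grid.shape} @ {a.grid.spacing} mm) "
            f"and {name_b} ({b.grid.shape} @ {b.grid.spacing} mm)"
        )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
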