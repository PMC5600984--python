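"""NIfTI volume container and intensity utilities.

A :class:`Volume` is the carrier used by every pipeline stage: a 3-D scalar
array plus voxel spacing (mm) and a voxel-to-world affine.  The ``role``
string records what the scalars mean (raw intensity, tissue probability,
Laplace potential, width in mm, integer label, or binary mask) and is used to
enforce role-specific invariants at construction time.

All physical distances in the package are computed in world millimetres
through the affine, so anisotropic acquisitions (e.g. 0.8594 x 0.8594 x 0.9 mm)
are honoured without resampling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import DegenerateRangeError, DimensionalityError, DomainError, GeometryError

VALID_ROLES = ("intensity", "probability", "potential", "width", "label", "mask")


@dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing (mm) and world affine.

    Parameters
    ----------
    data
        3-D array; dtype is preserved as given.
    spacing
        Voxel edge lengths in mm along each axis, all strictly positive.
    affine
        4x4 voxel-index to world-mm map.  Defaults to ``diag(spacing)``.
    role
        One of ``intensity``, ``probability``, ``potential``, ``width``,
        ``label``, ``mask``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    role: str = "intensity"
    _extras: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionalityError(
                f"volume data must be 3-D with non-empty axes, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be a 4x4 matrix")
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown volume role {self.role!r}")
        self._check_role_invariants()

    def _check_role_invariants(self):
        if self.role == "probability":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("probability-role volume has values outside [0, 1]")
        elif self.role == "width":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and finite.min() < 0:
                raise ValueError("width-role volume has negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray, role: str | None = None) -> "Volume":
        """New Volume sharing this one's geometry."""
        return Volume(data, self.spacing, self.affine.copy(), role or self.role)

    def world(self, index) -> np.ndarray:
        """World-mm coordinates of a voxel index triple."""
        idx = np.asarray(index, dtype=float)
        return (self.affine @ np.append(idx, 1.0))[:3]


def read_volume(path, role: str = "intensity") -> Volume:
    """Read a NIfTI-1 volume (optionally .gz).

    Spacing is taken from the header zooms; the data array is returned in the
    header's native axis order with no resampling.
    """
    if not os.path.exists(str(path)):
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path} is {data.ndim}-D, expected a 3-D volume")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise GeometryError(f"{path} has non-positive voxel spacing {zooms}")
    return Volume(data, zooms, np.asarray(img.affine), role)


def write_volume(v: Volume, path) -> str:
    """Write a Volume as NIfTI-1; returns the path written.

    Integer-role volumes round-trip bit-exactly; float data is stored as
    float32 unless already wider-than-float64 (never the case here).
    """
    path = str(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    data = v.data
    if v.role in ("label", "mask") and data.dtype.kind in "ui":
        out = data.astype(np.uint8) if data.max(initial=0) < 256 else data
    elif data.dtype.kind in "ui":
        out = data
    else:
        out = data.astype(np.float32)
    img = nib.Nifti1Image(out, v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, path)
    return path


def rescale_intensity(v: Volume, lo: float = 0.0, hi: float = 255.0) -> Volume:
    """Affine-linear rescale so min -> lo and max -> hi.

    The working normalization of the pipeline (intensities in [0, 255]).
    Monotone, idempotent once applied; raises on constant images.
    """
    if v.role != "intensity":
        raise ValueError("rescale_intensity expects an intensity-role volume")
    if hi <= lo:
        raise DomainError(f"require hi > lo, got lo={lo}, hi={hi}")
    data = np.asarray(v.data, dtype=float)
    dmin, dmax = float(np.nanmin(data)), float(np.nanmax(data))
    if dmax == dmin:
        raise DegenerateRangeError("cannot rescale a constant image")
    scaled = lo + (data - dmin) * ((hi - lo) / (dmax - dmin))
    return v.like(scaled)
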