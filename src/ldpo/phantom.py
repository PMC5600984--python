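"""Synthetic brain-like phantoms with known boundary geometry.

Phantoms emulate the three features the pipeline consumes: three Gaussian
intensity classes ordered CSF < GM < WM as on T1, a partial-volume intensity
ramp of controllable physical width at the GM/WM interface, and an optional
"lesion" where the ramp is locally thickened by a multiplier -- the minimal
model of a broadened, blurred gray/white junction.  Anisotropic spacing is
supported throughout.

Two geometries are provided: a planar slab (GM half-space, ramp band, WM
half-space, optionally a CSF layer below the GM so all three classes are
present) and a spherical shell (WM core, transition shell, GM mantle, CSF
exterior).  Every bundle carries ground-truth labels, the generating width
at each band voxel, and the lesion mask, so each pipeline stage can be
tested against construction.

What these phantoms do not emulate: cortical folding, bias fields, Rician
noise, and anatomy-dependent intensity variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .exceptions import DomainError, GeometryError
from .labeling import LABEL_BG, LABEL_CSF, LABEL_GM, LABEL_GWB, LABEL_WM
from .volume import Volume, write_volume


@dataclass
class LesionSpec:
    """A region where the boundary band is locally thickened."""

    center: tuple[int, int, int]  # voxel index triple
    radius_mm: float = 8.0
    thickness_multiplier: float = 2.0

    def __post_init__(self):
        if self.thickness_multiplier <= 1:
            raise DomainError("lesion thickness_multiplier must be > 1")


@dataclass
class PhantomSpec:
    """Generating parameters of a phantom volume."""

    shape: tuple[int, int, int] = (40, 40, 40)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry: str = "slab"  # "slab" | "spherical_shell"
    gwb_thickness_mm: float = 3.0
    tissue_means: tuple[float, float, float] = (50.0, 110.0, 170.0)  # CSF, GM, WM
    tissue_sds: tuple[float, float, float] = (10.0, 10.0, 10.0)
    lesion: LesionSpec | None = None
    seed: int = 0
    slab_axis: int = 2
    csf_margin_mm: float = 0.0  # slab only: CSF layer thickness below the GM
    shell_radii_mm: tuple[float, float, float] = (8.0, 10.0, 16.0)  # WM core, shell out, GM out
    profile: str = "linear"  # "linear" | "smoothstep"

    def __post_init__(self):
        if self.gwb_thickness_mm <= 0:
            raise DomainError("gwb_thickness_mm must be > 0")
        m = self.tissue_means
        if not (m[0] < m[1] < m[2]):
            raise DomainError("tissue means must be strictly increasing (CSF < GM < WM)")
        if self.profile not in ("linear", "smoothstep"):
            raise DomainError(f"unknown profile {self.profile!r}")

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        if d.get("lesion"):
            d["lesion"] = LesionSpec(**{**d["lesion"],
                                        "center": tuple(d["lesion"]["center"])})
        for key in ("shape", "spacing", "tissue_means", "tissue_sds", "shell_radii_mm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomBundle:
    """A phantom image with its ground truth.

    ``pv_gm`` / ``pv_wm`` are the generating partial-volume fractions (the
    proportion of each tissue in the voxel): 1 on the pure plateau, a linear
    exchange across the ramp, 0 in CSF.  They are exact probability images
    in the partial-volume reading of tissue probability, so the labeling and
    width stages can be exercised with perfectly known inputs.
    """

    image: Volume
    truth_labels: Volume
    truth_width: Volume
    lesion_mask: Volume
    pv_gm: Volume = None
    pv_wm: Volume = None
    spec: PhantomSpec = field(repr=False, default=None)


def _ramp(t: np.ndarray, profile: str) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    if profile == "smoothstep":
        return t * t * (3.0 - 2.0 * t)
    return t


def _apply_noise(clean: np.ndarray, sd_map: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(int(seed))
    return clean + rng.standard_normal(clean.shape) * sd_map


def make_slab_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Planar GM | ramp | WM phantom, optional CSF layer and lesion.

    The ramp band starts at a half-voxel offset so a band of integer width w
    (in voxels) contains exactly w voxels with strictly intermediate
    intensities.  A lesion thickens the band by its multiplier inside an
    in-plane circular footprint, keeping the GM-side edge fixed (so a
    multiplier-2 lesion over a 3-voxel band yields a 6-voxel ramp).
    """
    axis = spec.slab_axis
    nz = spec.shape[axis]
    dz = spec.spacing[axis]
    mu_csf, mu_gm, mu_wm = spec.tissue_means
    sd_csf, sd_gm, sd_wm = spec.tissue_sds
    w = spec.gwb_thickness_mm
    w_vox = w / dz
    csf_vox = int(round(spec.csf_margin_mm / dz))
    if w_vox + csf_vox + 2 > nz:
        raise GeometryError("band plus CSF margin thicker than the volume")

    z0 = csf_vox + int((nz - csf_vox - int(round(w_vox))) // 2)
    b_lo = (z0 - 0.5) * dz  # GM-side band edge, fixed also inside the lesion

    idx = np.indices(spec.shape).astype(float)
    z_mm = idx[axis] * dz

    w_loc = np.full(spec.shape, float(w))
    lesion_fp = np.zeros(spec.shape, dtype=bool)
    if spec.lesion is not None:
        plane_axes = [a for a in range(3) if a != axis]
        c = spec.lesion.center
        d2 = np.zeros(spec.shape)
        for a in plane_axes:
            d2 += ((idx[a] - c[a]) * spec.spacing[a]) ** 2
        lesion_fp = d2 <= spec.lesion.radius_mm ** 2
        w_loc[lesion_fp] = w * spec.lesion.thickness_multiplier

    t = (z_mm - b_lo) / w_loc
    band = (t > 0) & (t < 1)
    above = t >= 1
    csf = (idx[axis] < csf_vox) if csf_vox else np.zeros(spec.shape, bool)

    r = _ramp(t, spec.profile)
    clean = mu_gm + r * (mu_wm - mu_gm)
    clean[csf] = mu_csf

    sd_map = sd_gm + _ramp(t, "linear") * (sd_wm - sd_gm)
    sd_map[csf] = sd_csf

    labels = np.full(spec.shape, LABEL_GM, dtype=np.uint8)
    labels[above] = LABEL_WM
    labels[band] = LABEL_GWB
    labels[csf] = LABEL_CSF

    truth_width = np.zeros(spec.shape, dtype=np.float32)
    truth_width[band] = w_loc[band]
    lesion_mask = (lesion_fp & band).astype(np.uint8)

    pv_wm = _ramp(t, "linear")
    pv_gm = 1.0 - pv_wm
    pv_wm[csf] = 0.0
    pv_gm[csf] = 0.0

    image = _apply_noise(clean, sd_map, spec.seed)
    aff = np.diag((*spec.spacing, 1.0))
    mk = lambda arr, role: Volume(arr, spec.spacing, aff.copy(), role)
    return PhantomBundle(mk(image, "intensity"), mk(labels, "label"),
                         mk(truth_width, "width"), mk(lesion_mask, "mask"),
                         mk(pv_gm, "probability"), mk(pv_wm, "probability"), spec)


def make_shell_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Concentric WM core / transition shell / GM mantle / CSF exterior."""
    r_core, r_shell, r_gm = spec.shell_radii_mm
    if not (0 < r_core < r_shell < r_gm):
        raise DomainError("shell radii must satisfy 0 < core < shell < gm")
    if abs((r_shell - r_core) - spec.gwb_thickness_mm) > 1e-9:
        raise DomainError("shell_radii_mm must be consistent with gwb_thickness_mm")
    half_extent = min(n * s for n, s in zip(spec.shape, spec.spacing)) / 2.0
    if r_gm > half_extent:
        raise GeometryError("shell radii do not fit inside the volume")
    mu_csf, mu_gm, mu_wm = spec.tissue_means
    sd_csf, sd_gm, sd_wm = spec.tissue_sds
    center = [(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing)]
    idx = np.indices(spec.shape).astype(float)
    r = np.sqrt(sum(((idx[a] * spec.spacing[a]) - center[a]) ** 2 for a in range(3)))

    w_loc = np.full(spec.shape, float(spec.gwb_thickness_mm))
    lesion_fp = np.zeros(spec.shape, dtype=bool)
    if spec.lesion is not None:
        c = spec.lesion.center
        d2 = sum(((idx[a] - c[a]) * spec.spacing[a]) ** 2 for a in range(3))
        lesion_fp = d2 <= spec.lesion.radius_mm ** 2
        w_loc[lesion_fp] = spec.gwb_thickness_mm * spec.lesion.thickness_multiplier

    r_mid = (r_core + r_shell) / 2.0
    b_lo = r_mid - w_loc / 2.0  # WM side
    t = (r - b_lo) / w_loc  # 0 at WM edge, 1 at GM edge
    band = (t > 0) & (t < 1)
    wm = t <= 0
    gm = (t >= 1) & (r < r_gm)
    csf = r >= r_gm

    ramp = _ramp(t, spec.profile)
    clean = mu_wm + ramp * (mu_gm - mu_wm)
    clean[csf] = mu_csf
    sd_map = sd_wm + _ramp(t, "linear") * (sd_gm - sd_wm)
    sd_map[csf] = sd_csf

    labels = np.full(spec.shape, LABEL_BG, dtype=np.uint8)
    labels[wm] = LABEL_WM
    labels[gm] = LABEL_GM
    labels[band] = LABEL_GWB
    labels[csf] = LABEL_CSF

    truth_width = np.zeros(spec.shape, dtype=np.float32)
    truth_width[band] = w_loc[band]
    lesion_mask = (lesion_fp & band).astype(np.uint8)

    pv_gm = _ramp(t, "linear")  # t runs WM -> GM for the shell
    pv_wm = 1.0 - pv_gm
    pv_gm[csf] = 0.0
    pv_wm[csf] = 0.0

    image = _apply_noise(clean, sd_map, spec.seed)
    aff = np.diag((*spec.spacing, 1.0))
    mk = lambda arr, role: Volume(arr, spec.spacing, aff.copy(), role)
    return PhantomBundle(mk(image, "intensity"), mk(labels, "label"),
                         mk(truth_width, "width"), mk(lesion_mask, "mask"),
                         mk(pv_gm, "probability"), mk(pv_wm, "probability"), spec)


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    if spec.geometry == "slab":
        return make_slab_phantom(spec)
    if spec.geometry == "spherical_shell":
        return make_shell_phantom(spec)
    raise DomainError(f"unknown phantom geometry {spec.geometry!r}")


def write_bundle(bundle: PhantomBundle, out_dir) -> dict[str, str]:
    """Write image + truth volumes and the generating spec to a directory."""
    import os

    os.makedirs(str(out_dir), exist_ok=True)
    paths = {}
    for name, vol in (("image", bundle.image), ("truth_labels", bundle.truth_labels),
                      ("truth_width", bundle.truth_width), ("lesion_mask", bundle.lesion_mask),
                      ("pv_gm", bundle.pv_gm), ("pv_wm", bundle.pv_wm)):
        paths[name] = write_volume(vol, os.path.join(str(out_dir), f"{name}.nii.gz"))
    if bundle.spec is not None:
        spec_path = os.path.join(str(out_dir), "spec.yaml")
        with open(spec_path, "w") as fh:
            fh.write(bundle.spec.to_yaml())
        paths["spec"] = spec_path
    return paths
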