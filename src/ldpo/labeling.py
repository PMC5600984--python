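"""Working label volume: GM / WM / GWB / background from probability images.

A voxel is gray/white boundary (GWB) when neither the GM nor the WM
posterior dominates: both probabilities lie strictly inside (0, T_prob).
The probability threshold T_prob defaults to 0.9.  Rule precedence is GM,
then WM, then GWB: certainty about a pure tissue wins over junction
membership.  CSF probability does not participate; voxels failing all three
clauses are background.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError, GeometryError
from .volume import Volume

LABEL_BG = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
LABEL_GWB = 4

LABEL_NAMES = {
    LABEL_BG: "background",
    LABEL_CSF: "csf",
    LABEL_GM: "gm",
    LABEL_WM: "wm",
    LABEL_GWB: "gwb",
}


def label_regions(p_gm: Volume, p_wm: Volume, t_prob: float = 0.9) -> Volume:
    """Label voxels GM / WM / GWB / background from the two posteriors.

    Parameters
    ----------
    p_gm, p_wm
        Probability-role volumes of identical geometry.
    t_prob
        Threshold in (0, 1]; a posterior at or above it claims the voxel.

    Returns
    -------
    Volume
        label-role uint8 volume with codes 0=background, 2=GM, 3=WM, 4=GWB.
    """
    if p_gm.shape != p_wm.shape:
        raise GeometryError(f"shape mismatch: {p_gm.shape} vs {p_wm.shape}")
    if not np.allclose(p_gm.spacing, p_wm.spacing):
        raise GeometryError("spacing mismatch between probability images")
    if not (0 < t_prob <= 1):
        raise DomainError(f"t_prob must lie in (0, 1], got {t_prob}")
    g = np.asarray(p_gm.data, dtype=float)
    w = np.asarray(p_wm.data, dtype=float)
    out = np.zeros(g.shape, dtype=np.uint8)
    gwb = (g > 0) & (g < t_prob) & (w > 0) & (w < t_prob)
    out[gwb] = LABEL_GWB
    out[w >= t_prob] = LABEL_WM
    out[g >= t_prob] = LABEL_GM  # GM precedence over WM over GWB
    return Volume(out, p_gm.spacing, p_gm.affine.copy(), "label")


def count_labels(labels: Volume) -> dict[str, int]:
    """Voxel count per label name; counts sum to the total voxel count."""
    data = np.asarray(labels.data)
    values, counts = np.unique(data, return_counts=True)
    return {
        LABEL_NAMES.get(int(v), str(int(v))): int(c) for v, c in zip(values, counts)
    }
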