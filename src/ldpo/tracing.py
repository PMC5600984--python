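"""Greedy potential-field tracing and the GWB width map.

For every GWB voxel the potential field is descended to its nearest GM voxel
(always stepping to the neighbour with the smallest potential) and ascended
to its nearest WM voxel (largest potential).  The discrete maximum principle
of the converged Laplace field guarantees that a strictly monotone neighbour
exists for every interior voxel connected to both boundaries, so the greedy
walk terminates at the boundary labels.

The search neighbourhood is the full 26-connected 3x3x3 window by default
(6-connected available).  Neighbour ties are broken by the smallest step
length first (face before edge before corner), then lexicographically by
offset: on an exactly planar field the walk then advances along the slab
normal instead of drifting diagonally, which keeps measured slab widths at
their geometric value.  A visited set guards against revisits (defensive;
strict monotone stepping cannot cycle).

Widths are Euclidean distances in world millimetres through the affine.
``endpoint`` mode reports the GM-endpoint-to-WM-endpoint distance (the mean
of the defining pair of distances, which share their endpoints);
``halfpath-mean`` averages the two origin-to-endpoint half distances and is
provided because it can produce sub-voxel widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, DomainError, EmptyRegionError, GeometryError
from .labeling import LABEL_GM, LABEL_GWB, LABEL_WM
from .laplace import PotentialField
from .volume import Volume

STATUS_OK = "ok"
STATUS_GM_UNREACHABLE = "gm_unreachable"
STATUS_WM_UNREACHABLE = "wm_unreachable"
STATUS_CYCLE = "cycle_detected"

# status-map integer codes (0 = not a GWB voxel)
STATUS_CODES = {STATUS_OK: 1, STATUS_GM_UNREACHABLE: 2, STATUS_WM_UNREACHABLE: 3,
                STATUS_CYCLE: 4}


def _neighborhood(connectivity: int) -> tuple[tuple[int, int, int], ...]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                offs.append((dx, dy, dz))
    # smallest step first, then lexicographic: deterministic, axis-aligned ties win
    offs.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o))
    return tuple(offs)


OFFSETS_26 = _neighborhood(26)
OFFSETS_6 = _neighborhood(6)


@dataclass
class PathResult:
    """Trace result for one GWB voxel."""

    origin: tuple[int, int, int]
    gm_endpoint: tuple[int, int, int] | None = None
    wm_endpoint: tuple[int, int, int] | None = None
    path: list = field(default_factory=list)  # ordered GM -> origin -> WM
    status: str = STATUS_OK
    width_mm: float | None = None


@dataclass
class RegionStats:
    mean: float
    std: float
    max: float
    min: float
    mode: float
    n_voxels: int


@dataclass
class WidthMap:
    """Width volume (mm), per-voxel trace status and summary statistics."""

    width: Volume  # width-role, 0 outside successfully traced GWB voxels
    status_map: Volume  # label-role codes, see STATUS_CODES
    stats: RegionStats | None


def _trace(psi: np.ndarray, lab: np.ndarray, origin, minimize: bool, target: int,
           offsets, max_steps: int):
    """Greedy monotone walk; returns (endpoint|None, path, status)."""
    shape = lab.shape
    cur = tuple(int(c) for c in origin)
    visited = {cur}
    path = [cur]
    for _ in range(max_steps):
        best = None
        best_v = None
        for off in offsets:
            n0, n1, n2 = cur[0] + off[0], cur[1] + off[1], cur[2] + off[2]
            if not (0 <= n0 < shape[0] and 0 <= n1 < shape[1] and 0 <= n2 < shape[2]):
                continue
            l = lab[n0, n1, n2]
            if l != LABEL_GM and l != LABEL_WM and l != LABEL_GWB:
                continue
            v = psi[n0, n1, n2]
            if not np.isfinite(v):
                continue
            if best_v is None or (v < best_v if minimize else v > best_v):
                best_v = v
                best = (n0, n1, n2)
        cur_v = psi[cur]
        if best is None or (best_v >= cur_v if minimize else best_v <= cur_v):
            # no strictly improving neighbour: a plateau or an interior extremum
            return None, path, (STATUS_GM_UNREACHABLE if minimize else STATUS_WM_UNREACHABLE)
        if best in visited:  # defensive; strict monotonicity forbids this
            return None, path, STATUS_CYCLE
        visited.add(best)
        path.append(best)
        cur = best
        if lab[cur] == target:
            return cur, path, STATUS_OK
    return None, path, (STATUS_GM_UNREACHABLE if minimize else STATUS_WM_UNREACHABLE)


def _check_origin(labels: Volume, origin):
    if labels.data[tuple(int(c) for c in origin)] != LABEL_GWB:
        raise ContractError(f"trace origin {tuple(origin)} is not a GWB voxel")


def trace_to_gm(fieldstate: PotentialField, labels: Volume, origin,
                neighborhood: int = 26, max_steps: int | None = None) -> PathResult:
    """Descend the potential from ``origin`` until a GM-labelled voxel."""
    _check_origin(labels, origin)
    offsets = OFFSETS_6 if neighborhood == 6 else OFFSETS_26
    steps = max_steps or sum(labels.shape)
    end, path, status = _trace(np.asarray(fieldstate.psi.data), np.asarray(labels.data),
                               origin, True, LABEL_GM, offsets, steps)
    return PathResult(tuple(int(c) for c in origin), gm_endpoint=end, path=path,
                      status=status)


def trace_to_wm(fieldstate: PotentialField, labels: Volume, origin,
                neighborhood: int = 26, max_steps: int | None = None) -> PathResult:
    """Ascend the potential from ``origin`` until a WM-labelled voxel."""
    _check_origin(labels, origin)
    offsets = OFFSETS_6 if neighborhood == 6 else OFFSETS_26
    steps = max_steps or sum(labels.shape)
    end, path, status = _trace(np.asarray(fieldstate.psi.data), np.asarray(labels.data),
                               origin, False, LABEL_WM, offsets, steps)
    return PathResult(tuple(int(c) for c in origin), wm_endpoint=end, path=path,
                      status=status)


def width_at(origin, gm_endpoint, wm_endpoint, spacing=None, mode: str = "endpoint",
             affine: np.ndarray | None = None) -> float:
    """GWB width (mm) from a traced endpoint pair.

    ``endpoint`` (default): world distance between the GM and WM endpoints.
    ``halfpath-mean``: mean of the two origin-to-endpoint distances; can be
    sub-voxel when the origin sits between the endpoints.
    """
    if affine is None:
        if spacing is None:
            raise DomainError("width_at needs spacing or an affine")
        affine = np.diag((*[float(s) for s in spacing], 1.0))
    w = lambda idx: (affine @ np.append(np.asarray(idx, dtype=float), 1.0))[:3]
    g, m, o = w(gm_endpoint), w(wm_endpoint), w(origin)
    if np.allclose(g, m):
        raise GeometryError("coincident GM and WM endpoints")
    if mode == "endpoint":
        return float(np.linalg.norm(g - m))
    if mode == "halfpath-mean":
        return float((np.linalg.norm(o - g) + np.linalg.norm(o - m)) / 2.0)
    raise DomainError(f"unknown width mode {mode!r}")


def compute_width_map(fieldstate: PotentialField, labels: Volume,
                      neighborhood: int = 26, mode: str = "endpoint",
                      max_steps: int | None = None) -> WidthMap:
    """Trace every GWB voxel and assemble the width map.

    Per-voxel trace failures are recorded in the status map, never raised.
    Width is 0 for non-GWB voxels and for voxels whose trace did not reach
    both boundaries.
    """
    lab = np.asarray(labels.data)
    psi = np.asarray(fieldstate.psi.data, dtype=float)
    offsets = OFFSETS_6 if neighborhood == 6 else OFFSETS_26
    steps = max_steps or sum(labels.shape)
    width = np.zeros(lab.shape, dtype=np.float32)
    status = np.zeros(lab.shape, dtype=np.uint8)
    affine = labels.affine
    for origin in map(tuple, np.argwhere(lab == LABEL_GWB)):
        gm_end, _, st_g = _trace(psi, lab, origin, True, LABEL_GM, offsets, steps)
        if st_g != STATUS_OK:
            status[origin] = STATUS_CODES[st_g]
            continue
        wm_end, _, st_w = _trace(psi, lab, origin, False, LABEL_WM, offsets, steps)
        if st_w != STATUS_OK:
            status[origin] = STATUS_CODES[st_w]
            continue
        width[origin] = width_at(origin, gm_end, wm_end, mode=mode, affine=affine)
        status[origin] = STATUS_CODES[STATUS_OK]
    wvol = Volume(width, labels.spacing, labels.affine.copy(), "width")
    svol = Volume(status, labels.spacing, labels.affine.copy(), "label")
    stats = None
    if (width > 0).any():
        stats = region_stats(WidthMap(wvol, svol, None),
                             Volume(np.ones(lab.shape, dtype=np.uint8),
                                    labels.spacing, labels.affine.copy(), "mask"))
    return WidthMap(wvol, svol, stats)


def region_stats(width_map: WidthMap, region: Volume) -> RegionStats:
    """Summary statistics over strictly positive widths inside ``region``.

    The mode is computed on widths rounded to 0.01 mm; ties go to the
    smallest value.
    """
    w = np.asarray(width_map.width.data, dtype=float)
    r = np.asarray(region.data, dtype=bool)
    if w.shape != r.shape:
        raise GeometryError("region shape does not match the width map")
    vals = w[r & (w > 0)]
    if vals.size == 0:
        raise EmptyRegionError("region contains no positive widths")
    rounded = np.round(vals, 2)
    uniq, counts = np.unique(rounded, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # first max -> smallest value on ties
    return RegionStats(mean=float(vals.mean()), std=float(vals.std()),
                       max=float(vals.max()), min=float(vals.min()),
                       mode=mode, n_voxels=int(vals.size))
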