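"""Hidden-Markov-random-field + EM tissue segmentation.

Segments a skull-stripped T1 volume into CSF / GM / WM.  The model couples a
per-voxel Gaussian intensity likelihood G(y; mu_l, sigma_l) with a Potts-type
spatial prior over 6-connected voxel pairs whose clique potential is
0.5 * (1 - I[labels equal]), scaled by a weight ``beta``.  MAP labels are
estimated by iterated conditional modes (ICM) in raster order; the Gaussian
parameters are re-estimated each EM round as posterior-weighted moments.

Posterior tissue probabilities are normalized per voxel over the three
labels, so p_csf + p_gm + p_wm = 1 inside the brain mask and all three are
zero outside it.  The T1 intensity ordering mu_CSF < mu_GM < mu_WM is
enforced after every M-step by sorting the components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.cluster import KMeans

from .exceptions import (
    ContractError,
    DegenerateClassError,
    DegenerateModelError,
    DomainError,
    InitializationError,
)
from .volume import Volume

# internal class indices, ordered by T1 intensity
CSF, GM, WM = 0, 1, 2
_CLASS_NAMES = ("csf", "gm", "wm")

_FACE_OFFSETS = np.array(
    [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)], dtype=np.int64
)


@dataclass
class TissueModel:
    """Per-class Gaussian parameters plus the MRF pairwise weight."""

    mu: np.ndarray  # (3,) means, ascending
    sigma: np.ndarray  # (3,) standard deviations, > 0
    beta: float = 1.0
    labels: tuple[str, ...] = _CLASS_NAMES
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise DegenerateModelError(f"all sigma must be > 0, got {self.sigma}")
        if self.beta < 0:
            raise DomainError("beta must be >= 0")
        if not np.all(np.diff(self.mu) > 0):
            raise DomainError(f"means must be strictly increasing (CSF<GM<WM), got {self.mu}")


@dataclass
class SegmentationResult:
    """Labels, per-tissue posterior images and the fitted model."""

    labels: Volume  # label-role, codes 0=outside mask, 1=CSF, 2=GM, 3=WM
    p_csf: Volume
    p_gm: Volume
    p_wm: Volume
    model: TissueModel
    em_iterations: int
    converged: bool


def initialize_model(y: Volume, mask: Volume, k: int = 3, seed: int = 0,
                     beta: float = 1.0) -> TissueModel:
    """K-means initialization of the Gaussian components.

    Components are sorted by ascending mean and assigned CSF/GM/WM in that
    order.  Deterministic given ``seed``.
    """
    vals = np.asarray(y.data, dtype=float)[np.asarray(mask.data, dtype=bool)]
    if vals.size < k * 10:
        raise InitializationError(
            f"mask selects {vals.size} voxels; need at least {k * 10} for k={k}"
        )
    if np.unique(vals).size < k:
        raise InitializationError("fewer distinct intensities than components")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit(vals.reshape(-1, 1))
    mu = km.cluster_centers_.ravel()
    order = np.argsort(mu)
    sigma = np.empty(k)
    for rank, comp in enumerate(order):
        member = vals[km.labels_ == comp]
        sigma[rank] = max(member.std(), 1e-6)
    return TissueModel(mu=mu[order], sigma=sigma, beta=float(beta))


def clique_potential(label_a: int, label_b: int, beta: float = 1.0) -> float:
    """Pairwise Potts penalty: 0 for equal labels, 0.5*beta otherwise."""
    for lab in (label_a, label_b):
        if lab not in (CSF, GM, WM):
            raise DomainError(f"label {lab!r} not in {{CSF, GM, WM}}")
    return 0.0 if label_a == label_b else 0.5 * float(beta)


def local_prior(labels: np.ndarray, voxel, candidate: int, beta: float = 1.0,
                mask: np.ndarray | None = None) -> float:
    """Normalized Gibbs prior of ``candidate`` at ``voxel``.

    exp(-sum of clique potentials against the 6 face neighbours), normalized
    so the three candidate priors sum to 1.  Neighbours outside the volume or
    outside ``mask`` contribute nothing; with no valid neighbour the prior is
    uniform 1/3.
    """
    labels = np.asarray(labels)
    voxel = tuple(int(c) for c in voxel)
    if candidate not in (CSF, GM, WM):
        raise DomainError(f"candidate label {candidate!r} not in {{CSF, GM, WM}}")
    for c, n in zip(voxel, labels.shape):
        if c < 0 or c >= n:
            raise IndexError(f"voxel {voxel} outside volume of shape {labels.shape}")
    energies = np.zeros(3)
    for off in _FACE_OFFSETS:
        nb = tuple(voxel[d] + int(off[d]) for d in range(3))
        if any(c < 0 or c >= n for c, n in zip(nb, labels.shape)):
            continue
        if mask is not None and not mask[nb]:
            continue
        nb_label = int(labels[nb])
        for cand in (CSF, GM, WM):
            energies[cand] += clique_potential(cand, nb_label, beta)
    w = np.exp(-energies)
    return float(w[candidate] / w.sum())


@njit(cache=True)
def _icm_sweep(y, labels, mask, mu, sigma, beta):  # pragma: no cover - jitted
    """One raster-order ICM sweep, in place. Returns number of changed voxels."""
    nx, ny, nz = y.shape
    nl = mu.shape[0]
    changed = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                best_l = -1
                best_e = 1e300
                for l in range(nl):
                    d = (y[i, j, k] - mu[l]) / sigma[l]
                    e = 0.5 * d * d + np.log(sigma[l])
                    u = 0.0
                    if i > 0 and mask[i - 1, j, k] and labels[i - 1, j, k] != l:
                        u += 0.5
                    if i < nx - 1 and mask[i + 1, j, k] and labels[i + 1, j, k] != l:
                        u += 0.5
                    if j > 0 and mask[i, j - 1, k] and labels[i, j - 1, k] != l:
                        u += 0.5
                    if j < ny - 1 and mask[i, j + 1, k] and labels[i, j + 1, k] != l:
                        u += 0.5
                    if k > 0 and mask[i, j, k - 1] and labels[i, j, k - 1] != l:
                        u += 0.5
                    if k < nz - 1 and mask[i, j, k + 1] and labels[i, j, k + 1] != l:
                        u += 0.5
                    e += beta * u
                    if e < best_e:  # strict: ties keep the lowest label index
                        best_e = e
                        best_l = l
                if labels[i, j, k] != best_l:
                    changed += 1
                    labels[i, j, k] = best_l
    return changed


def icm_update(y: Volume, labels: np.ndarray, model: TissueModel, mask: Volume) -> np.ndarray:
    """One ICM sweep in fixed raster order; returns a new label array.

    Every in-mask voxel takes the label minimizing the local conditional
    energy -log G(y; theta_l) + beta * sum of clique potentials; ties go to
    the lowest label index.
    """
    if np.any(model.sigma <= 0):
        raise DegenerateModelError("sigma must be positive for ICM")
    out = np.ascontiguousarray(np.asarray(labels, dtype=np.int8)).copy()
    _icm_sweep(
        np.ascontiguousarray(y.data, dtype=np.float64),
        out,
        np.ascontiguousarray(mask.data, dtype=np.bool_),
        model.mu,
        model.sigma,
        float(model.beta),
    )
    return out


def _neighbor_disagreement(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """U[l, v] = 0.5 * number of valid 6-neighbours of v whose label != l."""
    n_valid = np.zeros(labels.shape)
    same = np.zeros((3,) + labels.shape)
    for axis in range(3):
        for shift in (-1, 1):
            lab_s = _shift(labels, axis, shift, fill=-1)
            msk_s = _shift(mask, axis, shift, fill=False)
            n_valid += msk_s
            for l in range(3):
                same[l] += msk_s & (lab_s == l)
    return 0.5 * (n_valid[None] - same)


def _shift(a: np.ndarray, axis: int, shift: int, fill):
    out = np.full_like(a, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift > 0:
        src[axis] = slice(None, -shift)
        dst[axis] = slice(shift, None)
    else:
        src[axis] = slice(-shift, None)
        dst[axis] = slice(None, shift)
    out[tuple(dst)] = a[tuple(src)]
    return out


def posterior_probabilities(y: np.ndarray, labels: np.ndarray, model: TissueModel,
                            mask: np.ndarray) -> np.ndarray:
    """Per-voxel tissue posteriors, shape (3, *volume), normalized over labels.

    p_l(v) is proportional to G(y(v); theta_l) * exp(-beta * U_l(v)) where
    U_l counts label disagreements with the current 6-neighbour labels.
    Zero outside the mask.
    """
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    u = model.beta * _neighbor_disagreement(labels, mask)
    logp = np.empty((3,) + y.shape)
    for l in range(3):
        logp[l] = (
            -0.5 * ((y - model.mu[l]) / model.sigma[l]) ** 2
            - np.log(model.sigma[l])
            - u[l]
        )
    logp -= logp.max(axis=0, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=0, keepdims=True)
    p[:, ~mask] = 0.0
    return p


def mrf_energy(y: Volume, labels: np.ndarray, model: TissueModel, mask: Volume) -> float:
    """Total negative log-posterior energy (up to constants) of a labelling."""
    ydat = np.asarray(y.data, dtype=float)
    m = np.asarray(mask.data, dtype=bool)
    lab = np.asarray(labels)
    mu = model.mu[lab.clip(0)]
    sg = model.sigma[lab.clip(0)]
    like = 0.5 * ((ydat - mu) / sg) ** 2 + np.log(sg)
    total = float(like[m].sum())
    pair = 0.0
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        va, vb = tuple(a), tuple(b)
        both = m[va] & m[vb]
        pair += 0.5 * np.count_nonzero(both & (lab[va] != lab[vb]))
    return total + model.beta * pair


def em_fit(y: Volume, mask: Volume, beta: float = 1.0, max_em_iter: int = 30,
           max_icm_iter: int = 10, tol: float = 1e-4, seed: int = 0,
           init_model: TissueModel | None = None) -> SegmentationResult:
    """Fit the HMRF-EM model and emit posterior probability images.

    Alternates ICM label estimation (raster sweeps until no voxel changes or
    ``max_icm_iter``) with posterior-weighted M-step updates of (mu, sigma).
    Stops when the largest absolute change over all (mu_l, sigma_l) drops
    below ``tol`` or after ``max_em_iter`` rounds.  Deterministic given
    ``seed``.
    """
    mdat = np.asarray(mask.data, dtype=bool)
    if not mdat.any():
        raise ContractError("empty brain mask")
    if tol <= 0:
        raise ContractError("tol must be > 0")
    ydat = np.asarray(y.data, dtype=float)
    model = init_model or initialize_model(y, mask, seed=seed, beta=beta)
    model = TissueModel(model.mu.copy(), model.sigma.copy(), beta=float(beta))

    # initial labels: maximum-likelihood classification
    d2 = np.stack([((ydat - model.mu[l]) / model.sigma[l]) ** 2 / 2 + np.log(model.sigma[l])
                   for l in range(3)])
    labels = np.where(mdat, d2.argmin(axis=0), -1).astype(np.int8)

    converged = False
    it = 0
    for it in range(1, max_em_iter + 1):
        for _ in range(max_icm_iter):
            changed = _icm_sweep(
                np.ascontiguousarray(ydat), labels, np.ascontiguousarray(mdat),
                model.mu, model.sigma, float(model.beta))
            if changed == 0:
                break
        post = posterior_probabilities(ydat, labels, model, mdat)
        w = post[:, mdat]  # (3, n)
        mass = w.sum(axis=1)
        for l in range(3):
            if mass[l] <= 1e-12:
                raise DegenerateClassError(
                    f"class {_CLASS_NAMES[l]!r} lost all posterior mass")
        vals = ydat[mdat]
        new_mu = (w * vals).sum(axis=1) / mass
        new_sigma = np.sqrt((w * (vals - new_mu[:, None]) ** 2).sum(axis=1) / mass)
        new_sigma = np.maximum(new_sigma, 1e-6)
        order = np.argsort(new_mu)
        if not np.array_equal(order, [0, 1, 2]):
            # re-impose the T1 ordering and remap the labels accordingly
            remap = np.empty(3, dtype=np.int8)
            remap[order] = np.arange(3, dtype=np.int8)
            inmask = labels >= 0
            labels[inmask] = remap[labels[inmask]]
            new_mu, new_sigma = new_mu[order], new_sigma[order]
        delta = max(np.abs(new_mu - model.mu).max(), np.abs(new_sigma - model.sigma).max())
        model.mu, model.sigma = new_mu, new_sigma
        model.history.append((new_mu.copy(), new_sigma.copy()))
        if delta < tol:
            converged = True
            break

    post = posterior_probabilities(ydat, labels, model, mdat)
    # emitted labels agree with the arg-max posterior at every in-mask voxel
    final = np.where(mdat, post.argmax(axis=0).astype(np.int8) + 1, 0).astype(np.uint8)
    mk = lambda arr, role: Volume(arr, y.spacing, y.affine.copy(), role)
    return SegmentationResult(
        labels=mk(final, "label"),
        p_csf=mk(post[CSF], "probability"),
        p_gm=mk(post[GM], "probability"),
        p_wm=mk(post[WM], "probability"),
        model=model,
        em_iterations=it,
        converged=converged,
    )
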