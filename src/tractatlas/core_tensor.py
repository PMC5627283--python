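"""Diffusion-tensor data model: eigendecomposition, scalar maps, averaging,
and log-linear tensor fitting from diffusion-weighted signals.

Tensor volumes hold the full symmetric 3x3 tensor per voxel in memory; on
disk the 6 unique components are stored in lower-triangular order
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) as a 4-D NIfTI-1 image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

#: On-disk component order (lower-triangular, row-major).
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")
_LOWER_IDX = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ScalarVolume:
    """A 3-D scalar map on a voxel grid with a voxel-to-world affine."""

    values: np.ndarray          # (X, Y, Z)
    affine: np.ndarray          # (4, 4) voxel -> mm
    mask: np.ndarray = None     # (X, Y, Z) bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("ScalarVolume expects a 3-D array")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")

    @property
    def shape(self):
        return self.values.shape

    def same_grid(self, other) -> bool:
        return (self.shape == tuple(other.shape)
                and np.allclose(self.affine, other.affine, atol=1e-6))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float64), self.affine)

    def save(self, path):
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, mask=None) -> "ScalarVolume":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, mask)


@dataclass
class TensorVolume:
    """Per-voxel symmetric 3x3 diffusion tensors (mm^2/s) on a grid."""

    tensors: np.ndarray         # (X, Y, Z, 3, 3)
    affine: np.ndarray          # (4, 4)
    mask: np.ndarray = None     # (X, Y, Z) bool

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have shape (X, Y, Z, 3, 3)")
        if self.mask is None:
            self.mask = np.ones(self.tensors.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.tensors.shape[:3]:
            raise ValueError("mask shape does not match tensor grid")

    @property
    def shape(self):
        return self.tensors.shape[:3]

    def same_grid(self, other) -> bool:
        return (self.shape == tuple(other.shape)
                and np.allclose(self.affine, other.affine, atol=1e-6))

    def symmetrized(self) -> "TensorVolume":
        sym = 0.5 * (self.tensors + np.swapaxes(self.tensors, -1, -2))
        return TensorVolume(sym, self.affine, self.mask.copy())

    # -- 6-component packing (lower-triangular order) -----------------------

    def to_components(self) -> np.ndarray:
        """Pack to (X, Y, Z, 6) in the documented component order."""
        out = np.empty(self.shape + (6,), dtype=float)
        for c, (i, j) in enumerate(_LOWER_IDX):
            out[..., c] = self.tensors[..., i, j]
        return out

    @classmethod
    def from_components(cls, comps, affine, mask=None) -> "TensorVolume":
        comps = np.asarray(comps, dtype=float)
        if comps.ndim != 4 or comps.shape[-1] != 6:
            raise ValueError("expected a (X, Y, Z, 6) component array")
        t = np.empty(comps.shape[:3] + (3, 3), dtype=float)
        for c, (i, j) in enumerate(_LOWER_IDX):
            t[..., i, j] = comps[..., c]
            t[..., j, i] = comps[..., c]
        return cls(t, affine, mask)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.to_components(), self.affine)

    def save(self, path):
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, mask=None) -> "TensorVolume":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        return cls.from_components(np.asarray(img.dataobj, dtype=float),
                                   img.affine, mask)


@dataclass
class EigenSystem:
    """Sorted eigenvalue/eigenvector fields of a tensor volume.

    ``lambdas[..., j]`` is the j-th eigenvalue (descending) and
    ``vectors[..., j, :]`` the matching unit eigenvector, sign-canonicalized
    so its first nonzero component is positive.
    """

    lambdas: np.ndarray      # (..., 3) descending
    vectors: np.ndarray      # (..., 3, 3); vectors[..., j, :] = eps_j
    mask: np.ndarray = None

    @property
    def principal(self) -> np.ndarray:
        return self.vectors[..., 0, :]

    def reconstruct(self) -> np.ndarray:
        """Rebuild the tensors as sum_j lambda_j eps_j eps_j^T."""
        return np.einsum("...j,...jk,...jl->...kl",
                         self.lambdas, self.vectors, self.vectors)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _canonicalize_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its first nonzero component is positive."""
    v = vectors.copy()
    flat = v.reshape(-1, 3)
    # index of first component with magnitude above tolerance
    big = np.abs(flat) > 1e-12
    first = np.argmax(big, axis=-1)
    lead = flat[np.arange(flat.shape[0]), first]
    flat[lead < 0] *= -1.0
    return flat.reshape(v.shape)


def eigendecompose(t: TensorVolume) -> EigenSystem:
    """Per-voxel eigendecomposition, eigenvalues sorted descending.

    Voxels with non-finite tensor entries are excluded from the output mask
    (a warning is logged) and decomposed from a zeroed tensor.
    """
    tens = 0.5 * (t.tensors + np.swapaxes(t.tensors, -1, -2))
    finite = np.isfinite(tens).all(axis=(-1, -2))
    n_bad = int((~finite & t.mask).sum())
    if n_bad:
        log.warning("eigendecompose: %d in-mask voxels with non-finite "
                    "tensors masked out", n_bad)
    work = np.where(finite[..., None, None], tens, 0.0)
    lam, vec = np.linalg.eigh(work)         # ascending; vec columns
    lam = lam[..., ::-1]
    vec = vec[..., ::-1]
    vectors = np.swapaxes(vec, -1, -2)      # rows = eigenvectors
    vectors = _canonicalize_signs(vectors)
    return EigenSystem(lam, vectors, t.mask & finite)


def fractional_anisotropy(es) -> np.ndarray:
    """FA from an EigenSystem or an (..., 3) eigenvalue array.

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2)
                   / sqrt(l1^2 + l2^2 + l3^2), clipped to [0, 1].
    All-zero voxels get FA = 0. Negative eigenvalues (noisy fits) are
    clamped to 0 with the clamp count logged.
    """
    lam = es.lambdas if isinstance(es, EigenSystem) else np.asarray(es, float)
    n_neg = int((lam < 0).sum())
    if n_neg:
        log.info("fractional_anisotropy: clamped %d negative eigenvalues",
                 n_neg)
    lam = np.clip(lam, 0.0, None)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num) / np.sqrt(den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_volume(t: TensorVolume) -> ScalarVolume:
    """FA map of a tensor volume; all-zero voxels are masked out."""
    es = eigendecompose(t)
    fa = fractional_anisotropy(es)
    nonzero = (np.abs(es.lambdas) > 0).any(axis=-1)
    return ScalarVolume(fa, t.affine, es.mask & nonzero)


def tensor_log(tensors: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Matrix logarithm of symmetric tensors; eigenvalues floored at
    ``floor`` so non-PD voxels stay finite."""
    lam, vec = np.linalg.eigh(0.5 * (tensors + np.swapaxes(tensors, -1, -2)))
    lam = np.clip(lam, floor, None)
    return np.einsum("...ij,...j,...kj->...ik", vec, np.log(lam), vec)


def tensor_exp(logs: np.ndarray) -> np.ndarray:
    lam, vec = np.linalg.eigh(0.5 * (logs + np.swapaxes(logs, -1, -2)))
    return np.einsum("...ij,...j,...kj->...ik", vec, np.exp(lam), vec)


def mean_tensor_volume(ts, mode: str = "euclidean") -> TensorVolume:
    """Voxel-wise mean of tensor volumes (euclidean or log_euclidean).

    The output mask is the intersection of the input masks.
    """
    ts = list(ts)
    if not ts:
        raise ValueError("mean_tensor_volume needs at least one volume")
    ref = ts[0]
    for t in ts[1:]:
        if not ref.same_grid(t):
            raise ValueError("tensor volumes must share shape and affine")
    mask = np.logical_and.reduce([t.mask for t in ts])
    if mode == "euclidean":
        mean = np.mean([t.tensors for t in ts], axis=0)
    elif mode == "log_euclidean":
        mean = tensor_exp(np.mean([tensor_log(t.tensors) for t in ts], axis=0))
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    return TensorVolume(mean, ref.affine.copy(), mask)


# ---------------------------------------------------------------------------
# tensor fitting from diffusion-weighted signals
# ---------------------------------------------------------------------------

def _design_matrix(bvals, bvecs) -> np.ndarray:
    """Rows [1, -b gx^2, -2b gx gy, -b gy^2, -2b gx gz, -2b gy gz, -b gz^2]
    matching [ln S0, Dxx, Dxy, Dyy, Dxz, Dyz, Dzz]."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -2 * b * gx * gy, -b * gy * gy,
        -2 * b * gx * gz, -2 * b * gy * gz, -b * gz * gz,
    ])


def fit_tensors(dwis, bvals, bvecs, signal_floor: float = 1e-12) -> TensorVolume:
    """Log-linear least-squares tensor fit, exact on noise-free signals.

    Parameters
    ----------
    dwis : list of ScalarVolume
        One volume per gradient table entry (b=0 entries included).
    bvals, bvecs : arrays (s/mm^2, unit vectors)
    """
    dwis = list(dwis)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if len(dwis) != len(bvals) or len(bvals) != len(bvecs):
        raise ValueError("dwis, bvals and bvecs must have matching lengths")
    if not (bvals == 0).any():
        raise ValueError("need at least one b=0 volume")
    X = _design_matrix(bvals, bvecs)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        n_dirs = len({tuple(np.round(v, 6)) for b, v in zip(bvals, bvecs)
                      if b > 0})
        raise ValueError(
            f"rank-deficient gradient design (rank {rank} < 7): "
            f"{n_dirs} unique diffusion directions; at least 6 non-collinear "
            "directions plus a b=0 volume are required")
    ref = dwis[0]
    signals = np.stack([d.values for d in dwis], axis=-1)
    n_clamped = int((signals <= 0).sum())
    if n_clamped:
        log.warning("fit_tensors: clamped %d nonpositive signal samples to "
                    "%g", n_clamped, signal_floor)
    signals = np.clip(signals, signal_floor, None)
    y = np.log(signals).reshape(-1, len(dwis)).T      # (nmeas, nvox)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)      # (7, nvox)
    comps = coef[1:].T.reshape(ref.shape + (6,))
    mask = np.logical_and.reduce([d.mask for d in dwis])
    return TensorVolume.from_components(comps, ref.affine.copy(), mask)
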