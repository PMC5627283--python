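"""Feature images driving registration: FA, hFA (largest eigenvalue of the
spatial Hessian of the FA map), and a T1-like structural channel."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._grid import voxel_sizes
from .core_tensor import ScalarVolume, fa_volume

FEATURE_KINDS = ("FA", "hFA", "T1")

#: default hFA smoothing scale (mm); Hessians of raw FA are noise-dominated
DEFAULT_HFA_SIGMA_MM = 2.0


@dataclass
class FeatureImage:
    kind: str
    image: ScalarVolume
    smoothing_sigma: float = None       # mm, hFA only

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; "
                             f"expected one of {FEATURE_KINDS}")
        if self.kind == "FA":
            vals = self.image.values[self.image.mask]
            if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
                raise ValueError("FA feature values must lie in [0, 1]")
        if not np.isfinite(self.image.values[self.image.mask]).all():
            raise ValueError("feature image contains non-finite values")


def _hessian(values: np.ndarray, spacings) -> np.ndarray:
    """Per-voxel 3x3 Hessian by central second differences in world (mm)
    units, with reflective boundary padding. Returns (X, Y, Z, 3, 3)."""
    padded = np.pad(values, 1, mode="reflect")
    core = (slice(1, -1),) * 3
    H = np.empty(values.shape + (3, 3), dtype=float)
    for i in range(3):
        hi = spacings[i]
        up, dn = [slice(1, -1)] * 3, [slice(1, -1)] * 3
        up[i], dn[i] = slice(2, None), slice(None, -2)
        H[..., i, i] = (padded[tuple(up)] - 2 * values
                        + padded[tuple(dn)]) / hi ** 2
    # mixed terms from first central differences of first differences
    grads = np.gradient(values, *spacings, edge_order=1)
    for i in range(3):
        for j in range(i + 1, 3):
            gij = np.gradient(grads[i], spacings[j], axis=j, edge_order=1)
            H[..., i, j] = gij
            H[..., j, i] = gij
    return H


def compute_hfa(fa: ScalarVolume, sigma: float = DEFAULT_HFA_SIGMA_MM
                ) -> ScalarVolume:
    """Largest eigenvalue of the Hessian of the (Gaussian-smoothed) FA map.

    ``sigma`` is in mm and converted per axis to voxels through the affine,
    so anisotropic voxel sizes are honored; derivatives are taken in world
    units, making the result resolution-independent.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    spacings = voxel_sizes(fa.affine)
    fov = np.asarray(fa.shape) * spacings
    if sigma > 0.5 * fov.min():
        raise ValueError(f"sigma {sigma} mm exceeds half the smallest "
                         f"field-of-view extent ({0.5 * fov.min():.1f} mm)")
    values = fa.values
    if sigma > 0:
        values = ndimage.gaussian_filter(values, sigma=sigma / spacings,
                                         mode="reflect")
    H = _hessian(values, spacings)
    lam_max = np.linalg.eigvalsh(H)[..., -1]
    return ScalarVolume(lam_max, fa.affine.copy(), fa.mask.copy())


def make_feature(subject, kind: str, sigma: float = DEFAULT_HFA_SIGMA_MM
                 ) -> FeatureImage:
    """Build the requested feature image from a subject record.

    The record must expose ``tensor`` (TensorVolume, for FA/hFA) or
    ``structural`` (ScalarVolume, for T1); attribute or mapping access both
    work.
    """
    def get(name):
        if isinstance(subject, dict):
            val = subject.get(name)
        else:
            val = getattr(subject, name, None)
        if val is None:
            raise ValueError(f"subject record is missing the {name!r} "
                             f"channel required for feature kind {kind!r}")
        return val

    if kind == "FA":
        return FeatureImage("FA", fa_volume(get("tensor")))
    if kind == "hFA":
        fa = fa_volume(get("tensor"))
        return FeatureImage("hFA", compute_hfa(fa, sigma),
                            smoothing_sigma=sigma)
    if kind == "T1":
        return FeatureImage("T1", get("structural"))
    raise ValueError(f"unknown feature kind {kind!r}; "
                     f"expected one of {FEATURE_KINDS}")
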