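"""Synthetic ground truth: a tensor phantom with curved anisotropic bundles
in an isotropic background, a co-registered T1-like structural channel with
homogeneous white matter, per-subject anatomical variability via smooth
invertible sinusoidal warps, an optional DWI simulator with Rician noise,
and a two-group design with a localized FA effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._grid import grid_world_coords
from .core_tensor import (ScalarVolume, TensorVolume,
                          fractional_anisotropy)
from .deformation import (GRADIENT_BOUND, SinusoidSpec, random_sinusoid_spec,
                          warp_tensor_volume)
from .registration import DeformationField
from .similarity import RoiAtlas

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    name: str
    control_points: np.ndarray          # (n, 3) mm centerline control polygon
    radius: float                       # mm tube radius
    eigenvalues: tuple = (1.7e-3, 0.35e-3, 0.25e-3)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)


@dataclass
class PhantomSpec:
    shape: tuple = (48, 48, 48)
    voxel_size: float = 2.0             # mm, isotropic
    bundles: list = None
    # distinct background eigenvalues (FA ~ 0.07) keep eigenvector frames
    # stable under interpolation; degenerate spectra make OVL ill-posed
    background_eigenvalues: tuple = (0.75e-3, 0.70e-3, 0.65e-3)
    wm_intensity: float = 0.8           # structural channel, homogeneous WM
    gm_intensity: float = 0.35
    brain_margin: float = 4.0           # mm shaved off the ellipsoid "brain"
    taper: float = 3.0                  # mm cosine taper outside each tube
    seed: int = 0

    def __post_init__(self):
        if self.bundles is None:
            self.bundles = default_bundles(self.shape, self.voxel_size)
        fa_bg = fractional_anisotropy(
            np.asarray(self.background_eigenvalues))
        if fa_bg > 0.1:
            raise ValueError(f"background FA {fa_bg:.3f} exceeds 0.1")
        for b in self.bundles:
            if fractional_anisotropy(np.asarray(b.eigenvalues)) < 0.4:
                raise ValueError(f"bundle {b.name} FA below 0.4")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


def default_bundles(shape, voxel_size) -> list:
    """Three desk-scale bundles: a straight pyramidal-tract-like column, a
    callosal-like arc, and an S-shaped cingulum-like curve, spaced so their
    taper zones do not abut (abutting tapers create orientation seams)."""
    ext = np.asarray(shape) * voxel_size        # mm extents
    cx = ext[0] / 2

    z = np.linspace(0.25, 0.75, 25) * ext[2]
    straight = np.stack([np.full_like(z, 0.25 * ext[0]),
                         np.full_like(z, 0.75 * ext[1]), z], axis=1)

    theta = np.linspace(np.pi * 0.15, np.pi * 0.85, 40)
    r = 0.27 * ext[0]
    arc = np.stack([cx + r * np.cos(theta),
                    np.full_like(theta, 0.25 * ext[1]),
                    0.31 * ext[2] + 0.8 * r * np.sin(theta)], axis=1)

    ty = np.linspace(0.2, 0.8, 40) * ext[1]
    sx = 0.68 * ext[0] + 0.08 * ext[0] * np.sin(
        2 * np.pi * (ty / ext[1] - 0.2) / 0.6)
    scurve = np.stack([sx, ty, np.full_like(ty, 0.72 * ext[2])], axis=1)

    return [
        BundleSpec("cst_like", straight, radius=6.0),
        BundleSpec("cc_like", arc, radius=6.0),
        BundleSpec("cg_like", scurve, radius=5.0),
    ]


@dataclass
class CohortSpec:
    n_per_group: int = 10
    amplitude_range: tuple = (0.5, 2.0)
    frequency_range: tuple = (0.004, 0.015)
    effect_bundle: str = "cc_like"
    effect_interval: tuple = (0.4, 0.6)     # arc-fraction interval
    effect_delta: float = 0.0               # FA reduction in group B
    noise: str = "none"                     # none | tensor_jitter
    noise_sigma: float = 0.0                # tensor_jitter scale (mm^2/s)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.effect_interval
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("effect interval must be within [0, 1]")


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _densify(control_points: np.ndarray, n: int = 400) -> np.ndarray:
    """Upsample a control polygon to a dense polyline (linear)."""
    seg = np.linalg.norm(np.diff(control_points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0, s[-1], n)
    return np.stack([np.interp(t, s, control_points[:, c])
                     for c in range(3)], axis=1)


def _tube_geometry(spec: PhantomSpec):
    """Rasterize bundle tubes with a taper margin.

    Returns (labels, arc_fraction, tangents, dist): labels is -1 outside any
    tube-plus-taper reach, else the index of the nearest-centerline bundle
    (overlaps resolved by centerline distance, fraction logged); dist is the
    distance to the owning bundle's centerline.
    """
    W = grid_world_coords(spec.shape, spec.affine).reshape(-1, 3)
    n_vox = len(W)
    best_dist = np.full(n_vox, np.inf)
    labels = np.full(n_vox, -1, dtype=int)
    arcfrac = np.zeros(n_vox)
    tangents = np.zeros((n_vox, 3))
    n_overlap = 0
    for bi, b in enumerate(spec.bundles):
        line = _densify(b.control_points)
        seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        frac = s / s[-1]
        tang = np.gradient(line, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        # chunked nearest-centerline-point search (squared-distance GEMM)
        dmin = np.empty(n_vox)
        amin = np.empty(n_vox, dtype=int)
        l2 = (line ** 2).sum(axis=1)
        for lo in range(0, n_vox, 20000):
            hi = lo + 20000
            chunk = W[lo:hi]
            d2 = ((chunk ** 2).sum(axis=1)[:, None] + l2[None]
                  - 2.0 * chunk @ line.T)
            am = d2.argmin(axis=1)
            amin[lo:hi] = am
            dmin[lo:hi] = np.sqrt(np.maximum(
                d2[np.arange(len(chunk)), am], 0.0))
        inside = dmin <= b.radius + spec.taper
        n_overlap += int(((dmin <= b.radius) & (labels >= 0)).sum())
        take = inside & (dmin < best_dist)
        best_dist[take] = dmin[take]
        labels[take] = bi
        arcfrac[take] = frac[amin[take]]
        tangents[take] = tang[amin[take]]
    if n_overlap:
        log.info("phantom: %.2f%% of tube voxels lie in bundle overlaps "
                 "(dominant bundle kept)", 100 * n_overlap / n_vox)
    sh = spec.shape
    return (labels.reshape(sh), arcfrac.reshape(sh),
            tangents.reshape(sh + (3,)), best_dist.reshape(sh))


def _aniso_tensor(eigenvalues, tangent: np.ndarray) -> np.ndarray:
    """Tensor field with principal eigenvector along the tangent and the
    remaining eigenvalues in the orthogonal complement."""
    l1, l2, l3 = eigenvalues
    t = tangent / (np.linalg.norm(tangent, axis=-1, keepdims=True) + 1e-300)
    helper = np.where(np.abs(t[..., :1]) < 0.9,
                      np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    u = np.cross(t, helper)
    u /= np.linalg.norm(u, axis=-1, keepdims=True) + 1e-300
    v = np.cross(t, u)
    return (l1 * t[..., :, None] * t[..., None, :]
            + l2 * u[..., :, None] * u[..., None, :]
            + l3 * v[..., :, None] * v[..., None, :])


@dataclass
class Phantom:
    tensor: TensorVolume
    structural: ScalarVolume
    atlas: RoiAtlas
    labels: np.ndarray              # bundle index per voxel, -1 background
    arc_fraction: np.ndarray
    spec: PhantomSpec


def build_phantom(spec: PhantomSpec = None) -> Phantom:
    """Rasterize the phantom: anisotropic tensors tangent to each bundle's
    centerline inside its tube, isotropic brain background, a homogeneous-WM
    structural channel, and an ROI atlas (per-bundle masks plus waypoint and
    endpoint slabs)."""
    spec = spec or PhantomSpec()
    sh, aff = spec.shape, spec.affine
    W = grid_world_coords(sh, aff)
    ext = np.asarray(sh) * spec.voxel_size
    center = ext / 2
    semi = center - spec.brain_margin
    brain = (((W - center) / semi) ** 2).sum(axis=-1) <= 1.0

    reach_labels, arcfrac, tangents, dist = _tube_geometry(spec)
    reach_labels = np.where(brain, reach_labels, -1)

    tensors = np.zeros(sh + (3, 3))
    lbg = np.asarray(spec.background_eigenvalues)
    tensors[brain] = np.diag(lbg)
    labels = np.full(sh, -1, dtype=int)
    structural = np.zeros(sh)
    structural[brain] = spec.gm_intensity
    for bi, b in enumerate(spec.bundles):
        m = reach_labels == bi
        # cosine taper of the anisotropy weight from the tube surface out
        w = np.clip((b.radius + spec.taper - dist[m]) / max(spec.taper, 1e-9),
                    0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * np.minimum(w, 1.0))
        w = np.where(dist[m] <= b.radius, 1.0, w)
        aniso = _aniso_tensor(b.eigenvalues, tangents[m])
        tensors[m] = (w[:, None, None] * aniso
                      + (1 - w)[:, None, None] * np.diag(lbg))
        core = m & (dist <= b.radius)
        labels[core] = bi
        structural[m] = (w * spec.wm_intensity
                         + (1 - w) * structural[m])

    masks = {}
    for bi, b in enumerate(spec.bundles):
        m = labels == bi
        masks[b.name] = m
        masks[f"{b.name}_waypoint"] = m & (np.abs(arcfrac - 0.5) < 0.08)
        masks[f"{b.name}_start"] = m & (arcfrac < 0.15)
        masks[f"{b.name}_end"] = m & (arcfrac > 0.85)
    atlas = RoiAtlas(masks, affine=aff)

    tvol = TensorVolume(tensors, aff, mask=brain)
    svol = ScalarVolume(structural, aff, mask=brain)
    return Phantom(tvol, svol, atlas, labels, arcfrac, spec)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _isotropize_blend_for_delta(eigenvalues, delta: float) -> float:
    """Blend factor t such that D' = (1-t) D + t (tr D / 3) I has FA lower
    than FA(D) by ``delta``."""
    lam = np.asarray(eigenvalues, dtype=float)
    fa0 = fractional_anisotropy(lam)
    target = max(fa0 - delta, 0.0)
    iso = lam.mean()

    def fa_of(t):
        return fractional_anisotropy((1 - t) * lam + t * iso) - target

    if target <= 0:
        return 1.0
    return float(brentq(fa_of, 0.0, 1.0, xtol=1e-12))


@dataclass
class SubjectRecord:
    subject: str
    group: str
    tensor: TensorVolume            # native space
    structural: ScalarVolume
    true_warp: DeformationField     # native -> phantom space (pull-back on
                                    # the native grid)
    warp_spec: SinusoidSpec = None


def make_cohort(phantom: Phantom, spec: CohortSpec):
    """Generate per-subject records: the phantom warped by a random smooth
    sinusoidal field per subject (stored as the true warp), with group-B
    subjects' bundle FA reduced by ``effect_delta`` on the configured arc
    interval *before* warping, plus optional tensor jitter.

    Returns ``(records, manifest)``.
    """
    rng = np.random.default_rng(spec.seed)
    names = [b.name for b in phantom.spec.bundles]
    if spec.effect_delta > 0 and spec.effect_bundle not in names:
        raise ValueError(f"unknown effect bundle {spec.effect_bundle!r}")

    # group-B source volume with the FA effect injected in anatomical space
    gt = phantom.tensor
    if spec.effect_delta > 0:
        bi = names.index(spec.effect_bundle)
        lo, hi = spec.effect_interval
        sel = ((phantom.labels == bi)
               & (phantom.arc_fraction >= lo) & (phantom.arc_fraction <= hi))
        bspec = phantom.spec.bundles[bi]
        t = _isotropize_blend_for_delta(bspec.eigenvalues, spec.effect_delta)
        tensors_b = gt.tensors.copy()
        tr = np.trace(tensors_b[sel], axis1=-2, axis2=-1) / 3.0
        tensors_b[sel] = ((1 - t) * tensors_b[sel]
                          + t * tr[:, None, None] * np.eye(3))
        gt_b = TensorVolume(tensors_b, gt.affine.copy(), gt.mask.copy())
    else:
        gt_b = gt

    records, rows = [], []
    for g, src in (("A", gt), ("B", gt_b)):
        for i in range(spec.n_per_group):
            attempts = 0
            while True:
                attempts += 1
                wspec = random_sinusoid_spec(rng, spec.amplitude_range,
                                             spec.frequency_range)
                if wspec.max_gradient() < GRADIENT_BOUND:
                    break
            warp = wspec.render(gt.shape, gt.affine,
                                source_space="phantom",
                                target_space=f"native_{g}{i}")
            tensor = warp_tensor_volume(src, warp)
            structural = _warp_scalar(phantom.structural, warp)
            if spec.noise == "tensor_jitter" and spec.noise_sigma > 0:
                jit = rng.normal(0.0, spec.noise_sigma,
                                 size=tensor.tensors.shape)
                jit = 0.5 * (jit + np.swapaxes(jit, -1, -2))
                tensor = TensorVolume(tensor.tensors + jit,
                                      tensor.affine, tensor.mask)
            elif spec.noise not in ("none", "tensor_jitter"):
                raise ValueError(f"unknown noise model {spec.noise!r}")
            sid = f"{g}{i:02d}"
            records.append(SubjectRecord(sid, g, tensor, structural, warp,
                                         wspec))
            rows.append({"subject": sid, "group": g,
                         "warp_amplitude_mm":
                             float(np.linalg.norm(wspec.amplitude)),
                         "warp_max_gradient": wspec.max_gradient(),
                         "resample_attempts": attempts})
    return records, pd.DataFrame(rows)


def _warp_scalar(vol: ScalarVolume, d: DeformationField) -> ScalarVolume:
    from .registration import apply_transform
    return apply_transform(vol, d, out_shape=d.shape, out_affine=d.affine)


# ---------------------------------------------------------------------------
# DWI simulation
# ---------------------------------------------------------------------------

def fibonacci_directions(n: int = 30) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (hemisphere-folded)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    g = np.stack([np.sin(phi) * np.cos(theta),
                  np.sin(phi) * np.sin(theta),
                  np.cos(phi)], axis=1)
    g[g[:, 2] < 0] *= -1
    return g


def default_gradient_table(n_dirs: int = 30, b: float = 1000.0,
                           n_b0: int = 5):
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_dirs)])
    return bvals, bvecs


def simulate_dwis(t: TensorVolume, bvals, bvecs, snr: float = None,
                  s0: float = 1.0, seed: int = 0):
    """S = S0 exp(-b g^T D g) per gradient entry, with optional Rician noise
    at the given SNR on S0. Non-PSD voxels get their negative eigenvalues
    clipped for the signal model (count logged); noise-free path is exact.
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive (or None for noise-free)")
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    lam = np.linalg.eigvalsh(t.tensors)
    n_npsd = int((lam[..., 0] < 0).sum())
    D = t.tensors
    if n_npsd:
        log.warning("simulate_dwis: clipping negative eigenvalues in %d "
                    "voxels for the signal model", n_npsd)
        lamc, vec = np.linalg.eigh(t.tensors)
        D = np.einsum("...ij,...j,...kj->...ik", vec,
                      np.clip(lamc, 0.0, None), vec)
    rng = np.random.default_rng(seed)
    out = []
    for b, g in zip(bvals, bvecs):
        adc = np.einsum("i,...ij,j->...", g, D, g)
        sig = s0 * np.exp(-b * adc)
        if snr is not None:
            sigma = s0 / snr
            re = sig + rng.normal(0.0, sigma, size=sig.shape)
            im = rng.normal(0.0, sigma, size=sig.shape)
            sig = np.sqrt(re ** 2 + im ** 2)
        out.append(ScalarVolume(sig, t.affine.copy(), t.mask.copy()))
    return out
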