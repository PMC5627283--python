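"""Ground-truth sinusoidal deformation families and tensor-volume warping
with reorientation.

A sinusoidal field displaces every point along a fixed unit direction by a
sum of per-axis sine waves:

    d(x) = direction * sum_j amplitude_j * sin(2*pi*frequency_j*x_j + phase_j)

so the Jacobian perturbation norm is bounded by
sum_j 2*pi*amplitude_j*frequency_j, which is kept < 1 to guarantee
invertibility. "Inverse" family members are exact negations: this makes the
per-voxel vector sum over the family exactly zero; negation equals the true
inverse only to first order, so the composition residual is computed and
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._grid import grid_world_coords, sample_vector_at_world, voxel_sizes
from .core_tensor import TensorVolume, tensor_exp, tensor_log
from .registration import DeformationField

log = logging.getLogger(__name__)

#: safety margin on the invertibility bound max|grad d| < 1
GRADIENT_BOUND = 0.5


@dataclass
class SinusoidSpec:
    amplitude: np.ndarray       # (3,) mm per axis
    frequency: np.ndarray       # (3,) cycles/mm per axis
    phase: np.ndarray           # (3,) radians per axis
    direction: np.ndarray       # unit 3-vector

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if nrm == 0:
            raise ValueError("direction must be nonzero")
        self.direction = self.direction / nrm
        if self.max_gradient() >= GRADIENT_BOUND:
            raise ValueError(
                f"amplitude/frequency product too large: max |grad d| bound "
                f"{self.max_gradient():.3f} >= {GRADIENT_BOUND} "
                "(field would not be safely invertible)")

    def max_gradient(self) -> float:
        return float(2 * np.pi * (self.amplitude * self.frequency).sum())

    def render(self, shape, affine, **field_kw) -> DeformationField:
        W = grid_world_coords(shape, affine)
        waves = (self.amplitude
                 * np.sin(2 * np.pi * self.frequency * W + self.phase))
        mag = waves.sum(axis=-1)
        disp = mag[..., None] * self.direction
        return DeformationField(disp, np.asarray(affine, float), **field_kw)


def random_sinusoid_spec(rng: np.random.Generator,
                         amplitude_range=(0.5, 2.0),
                         frequency_range=(0.004, 0.02)) -> SinusoidSpec:
    """Draw a spec and rescale amplitudes if the invertibility bound would
    be violated."""
    amp = rng.uniform(*amplitude_range, size=3)
    freq = rng.uniform(*frequency_range, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    bound = 2 * np.pi * (amp * freq).sum()
    if bound >= GRADIENT_BOUND:
        amp *= 0.9 * GRADIENT_BOUND / bound
    return SinusoidSpec(amp, freq, phase, direction)


def inversion_residual(d: DeformationField, dinv: DeformationField) -> float:
    """Max norm (voxels) of x + dinv(x) + d(x + dinv(x)) - x on the mask."""
    W = grid_world_coords(d.shape, d.affine)
    pts = W + dinv.displacement
    d_at = sample_vector_at_world(d.displacement, d.affine, pts, order=1)
    res = np.linalg.norm((dinv.displacement + d_at)[d.mask], axis=-1).max()
    return float(res / voxel_sizes(d.affine).min())


def generate_sinusoid_family(n_pairs: int, shape, affine, seed: int,
                             amplitude_range=(0.5, 2.0),
                             frequency_range=(0.004, 0.02)):
    """Generate 2*n_pairs dense sinusoidal fields: n_pairs seeded random
    specs rendered on the grid, each immediately followed by its exact
    negation. The interleaved pairing makes the per-voxel vector sum over
    the family exactly zero (bitwise) under sequential summation.

    Returns ``(fields, manifest)``: the field list
    ``[f1, -f1, f2, -f2, ...]`` and a DataFrame with the spec parameters and
    the true-inverse composition residual per pair (voxels).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    specs = [random_sinusoid_spec(rng, amplitude_range, frequency_range)
             for _ in range(n_pairs)]
    originals = [s.render(shape, affine) for s in specs]
    negations = [DeformationField(-f.displacement, f.affine.copy(),
                                  source_space=f.target_space,
                                  target_space=f.source_space)
                 for f in originals]
    rows = []
    for k, (s, f, g) in enumerate(zip(specs, originals, negations)):
        rows.append({
            "pair": k,
            "amplitude_mm": float(np.linalg.norm(s.amplitude)),
            "max_gradient": s.max_gradient(),
            "direction_x": s.direction[0],
            "direction_y": s.direction[1],
            "direction_z": s.direction[2],
            "negation_residual_vox": inversion_residual(f, g),
        })
    manifest = pd.DataFrame(rows)
    log.info("sinusoid family: max negation-vs-inverse residual %.4g voxels",
             manifest["negation_residual_vox"].max())
    fields = [f for pair in zip(originals, negations) for f in pair]
    return fields, manifest


# ---------------------------------------------------------------------------
# tensor warping with reorientation
# ---------------------------------------------------------------------------

def _rotation_finite_strain(F: np.ndarray) -> np.ndarray:
    """Rotation from the polar decomposition F = R U, batched via SVD."""
    U, _, Vt = np.linalg.svd(F)
    R = U @ Vt
    # enforce det +1 (proper rotation)
    det = np.linalg.det(R)
    neg = det < 0
    if neg.any():
        U = U.copy()
        U[neg, :, -1] *= -1
        R = U @ Vt
    return R


def _rotation_ppd(F: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Preservation-of-principal-direction rotation mapping e1 to the
    normalized image of F e1 and e2 into the plane spanned accordingly."""
    n1 = np.einsum("...ij,...j->...i", F, e1)
    n1 /= np.linalg.norm(n1, axis=-1, keepdims=True) + 1e-300
    f2 = np.einsum("...ij,...j->...i", F, e2)
    f2 -= np.einsum("...i,...i->...", f2, n1)[..., None] * n1
    n2 = f2 / (np.linalg.norm(f2, axis=-1, keepdims=True) + 1e-300)
    n3 = np.cross(n1, n2)
    e3 = np.cross(e1, e2)
    # R = [n1 n2 n3] [e1 e2 e3]^T  (maps ej to nj)
    N = np.stack([n1, n2, n3], axis=-1)
    E = np.stack([e1, e2, e3], axis=-1)
    return N @ np.swapaxes(E, -1, -2)


def warp_tensor_volume(t: TensorVolume, d: DeformationField,
                       reorient: str = "finite_strain",
                       interp: str = "log") -> TensorVolume:
    """Pull a tensor volume back through a deformation field and reorient.

    Tensors are interpolated componentwise (trilinear) on the log-tensor
    representation by default (``interp='linear'`` for the literal linear
    domain) and rotated by the local rotation extracted from the field's
    Jacobian: ``finite_strain`` uses the polar-decomposition rotation of
    F = (I + grad d)^-1, ``ppd`` preserves the principal direction.
    Voxels pulled outside the source volume are masked out (fraction logged).
    """
    if reorient not in ("finite_strain", "ppd", "none"):
        raise ValueError(f"unknown reorientation mode {reorient!r}")
    if interp not in ("log", "linear"):
        raise ValueError(f"unknown interpolation domain {interp!r}")
    if (not d.displacement.any() and t.shape == d.shape
            and np.allclose(t.affine, d.affine)):
        # zero field on the same grid: exact identity
        return TensorVolume(t.tensors.copy(), d.affine.copy(),
                            t.mask & d.mask)
    W = grid_world_coords(d.shape, d.affine)
    pts = W + d.displacement

    from ._grid import world_to_voxel
    vox = world_to_voxel(pts, t.affine)
    inside = np.logical_and.reduce(
        [(vox[..., i] >= -0.5) & (vox[..., i] <= t.shape[i] - 0.5)
         for i in range(3)])
    frac_out = 1.0 - inside.mean()
    if frac_out > 0:
        log.info("warp_tensor_volume: %.2f%% of target voxels map outside "
                 "the source volume", 100 * frac_out)

    if interp == "log":
        rep = tensor_log(t.tensors)
    elif interp == "linear":
        rep = t.tensors
    else:
        raise ValueError(f"unknown interpolation domain {interp!r}")
    comps = rep.reshape(t.shape + (9,))
    sampled = sample_vector_at_world(comps, t.affine, pts, order=1)
    sampled = 0.5 * (sampled.reshape(d.shape + (3, 3))
                     + np.swapaxes(sampled.reshape(d.shape + (3, 3)), -1, -2))
    tensors = tensor_exp(sampled) if interp == "log" else sampled

    if reorient != "none":
        J = d.jacobian()
        F = np.linalg.inv(J)
        if reorient == "finite_strain":
            R = _rotation_finite_strain(F)
        else:
            lam, vec = np.linalg.eigh(tensors)
            e1 = vec[..., :, 2]
            e2 = vec[..., :, 1]
            R = _rotation_ppd(F, e1, e2)
        tensors = R @ tensors @ np.swapaxes(R, -1, -2)

    src_mask = sample_vector_at_world(
        t.mask.astype(float)[..., None], t.affine, pts, order=0)[..., 0] > 0.5
    return TensorVolume(tensors, d.affine.copy(), src_mask & inside & d.mask)


def simulate_dataset(gt: TensorVolume, fields,
                     reorient: str = "finite_strain"):
    """Warp the ground-truth volume once per field (with reorientation)."""
    return [warp_tensor_volume(gt, f, reorient=reorient) for f in fields]
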