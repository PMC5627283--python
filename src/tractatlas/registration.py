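"""Scalar-image registration and deformation-field algebra.

The nonlinear engine is a B-spline free-form deformation minimizing
sum-of-squared differences plus a bending-energy penalty, optimized by
L-BFGS-B on the control lattice over a multiresolution pyramid. All
deformation fields use the pull-back (backward) convention: a field on the
target grid stores, per voxel, the mm world-frame displacement to add to the
voxel's world coordinate to find the source-space sample point.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from ._grid import (grid_world_coords, sample_at_world, sample_vector_at_world,
                    voxel_sizes, world_to_voxel)
from .core_tensor import ScalarVolume

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transform types
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """World-to-world affine, mapping target (fixed) coordinates to source
    (moving) coordinates (pull-back convention)."""

    matrix: np.ndarray                      # (4, 4)
    source_space: str = None                # None acts as a wildcard tag
    target_space: str = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        det = np.linalg.det(self.matrix[:3, :3])
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise ValueError("affine transform is not invertible")
        if det <= 0:
            raise ValueError("affine transform has non-positive determinant")

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix),
                               self.target_space, self.source_space)

    def save(self, path):
        np.savetxt(str(path), self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path, **kw) -> "AffineTransform":
        return cls(np.loadtxt(str(path)), **kw)


@dataclass
class DeformationField:
    """Dense voxelwise displacement (mm, world frame) on a target grid."""

    displacement: np.ndarray                # (X, Y, Z, 3) mm
    affine: np.ndarray                      # target grid voxel -> mm
    source_space: str = None                # None acts as a wildcard tag
    target_space: str = None
    mask: np.ndarray = None

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must have shape (X, Y, Z, 3)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement contains non-finite values")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)

    @property
    def shape(self):
        return self.displacement.shape[:3]

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        disp = sample_vector_at_world(self.displacement, self.affine, pts,
                                      order=1)
        return pts + disp

    def jacobian(self) -> np.ndarray:
        """Voxelwise world-frame Jacobian of the point map x + d(x),
        shape (X, Y, Z, 3, 3)."""
        linv = np.linalg.inv(self.affine[:3, :3])
        grads = np.stack(
            [np.stack(np.gradient(self.displacement[..., m]), axis=-1)
             for m in range(3)], axis=-2)        # d d_m / d index_i
        jac = np.einsum("...mi,in->...mn", grads, linv)
        return jac + np.eye(3)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.displacement.astype(np.float64),
                               self.affine)

    def save(self, path):
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, **kw) -> "DeformationField":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, **kw)


@dataclass
class TransformChain:
    """Ordered transform stages, applied to an image first-to-last.

    Adjacent space tags must match: stage k+1 consumes the space stage k
    produced (``stages[k].target_space == stages[k+1].source_space``).
    """

    stages: list

    def __post_init__(self):
        if not self.stages:
            raise ValueError("empty transform chain")
        for k, (a, b) in enumerate(zip(self.stages, self.stages[1:])):
            if (a.target_space is not None and b.source_space is not None
                    and a.target_space != b.source_space):
                raise ValueError(
                    f"space-tag mismatch at junction {k}: stage {k} produces "
                    f"{a.target_space!r} but stage {k + 1} expects "
                    f"{b.source_space!r}")

    @property
    def source_space(self):
        return self.stages[0].source_space

    @property
    def target_space(self):
        return self.stages[-1].target_space

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        # pull-back: the last-applied stage is evaluated first
        for stage in reversed(self.stages):
            pts = stage.map_points(pts)
        return pts


def identity_field(shape, affine, **kw) -> DeformationField:
    return DeformationField(np.zeros(tuple(shape) + (3,)), affine, **kw)


def apply_transform(vol: ScalarVolume, transform, out_shape=None,
                    out_affine=None, order: int = 1) -> ScalarVolume:
    """Resample a scalar volume through a transform (pull-back).

    Masks are resampled nearest-neighbor. Defaults to the input grid.
    """
    if out_shape is None:
        out_shape = vol.shape
    if out_affine is None:
        out_affine = vol.affine
    pts = grid_world_coords(out_shape, out_affine)
    src = transform.map_points(pts)
    values = sample_at_world(vol.values, vol.affine, src, order=order)
    mask = sample_at_world(vol.mask.astype(float), vol.affine, src,
                           order=0) > 0.5
    # points falling outside the source volume are masked out
    vox = world_to_voxel(src, vol.affine)
    inside = np.logical_and.reduce(
        [(vox[..., i] >= -0.5) & (vox[..., i] <= vol.shape[i] - 0.5)
         for i in range(3)])
    return ScalarVolume(values, np.asarray(out_affine, float), mask & inside)


# ---------------------------------------------------------------------------
# image pyramid helpers
# ---------------------------------------------------------------------------

def _downsample(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    smoothed = ndimage.gaussian_filter(values, sigma=factor / 2.0,
                                       mode="nearest")
    return smoothed[::factor, ::factor, ::factor]


def _level_affine(affine: np.ndarray, factor: int) -> np.ndarray:
    out = affine.copy()
    out[:3, :3] *= factor
    return out


def _world_gradient(values: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Image gradient in world (mm) units, shape (X, Y, Z, 3)."""
    gvox = np.stack(np.gradient(values), axis=-1)
    linv = np.linalg.inv(affine[:3, :3])
    return gvox @ linv      # d f / d x_world = (d f / d idx) @ d idx / d x


def _check_not_constant(*vols):
    for v in vols:
        vals = v.values[v.mask] if v.mask.any() else v.values
        if vals.size == 0 or np.ptp(vals) < 1e-12:
            raise ValueError("degenerate (constant) image cannot drive "
                             "registration")


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------

def register_affine(moving: ScalarVolume, fixed: ScalarVolume,
                    levels: int = 3, maxiter: int = 200) -> AffineTransform:
    """12-parameter affine minimizing SSD over a multiresolution pyramid.

    Returns the pull-back map: fixed-space world coordinates to moving-space
    world coordinates.
    """
    from scipy.optimize import minimize

    _check_not_constant(moving, fixed)
    center = grid_world_coords(fixed.shape, fixed.affine).reshape(-1, 3).mean(0)
    # state carried across levels: matrix deviation from identity + shift
    A_dev = np.zeros((3, 3))
    b_cur = np.zeros(3)

    for lvl in range(levels - 1, -1, -1):
        f = 2 ** lvl
        if min(min(moving.shape), min(fixed.shape)) // f < 8:
            continue
        mov = _downsample(moving.values, f)
        fix = _downsample(fixed.values, f)
        fmask = _downsample(fixed.mask.astype(float), f) > 0.5
        mov_aff = _level_affine(moving.affine, f)
        fix_aff = _level_affine(fixed.affine, f)

        pts = grid_world_coords(fix.shape, fix_aff).reshape(-1, 3)
        w = fmask.reshape(-1).astype(float)
        n = max(w.sum(), 1.0)
        xc = pts - center
        grad = _world_gradient(mov, mov_aff)
        grad = np.stack([ndimage.spline_filter(grad[..., m], order=3,
                                               mode="nearest")
                         for m in range(3)], axis=-1)
        mov_pref = ndimage.spline_filter(mov, order=3, mode="nearest")
        fixv = fix.reshape(-1)

        # scale matrix parameters to mm-like units so L-BFGS-B sees a
        # well-conditioned problem (unscaled, dA has ~|xc| x the leverage)
        L = float(np.sqrt((xc ** 2).sum(axis=1).mean()))

        def cost_grad(p, xc=xc, fixv=fixv, w=w, n=n, mov=mov_pref,
                      mov_aff=mov_aff, grad=grad):
            A = np.eye(3) + p[:9].reshape(3, 3) / L
            b = p[9:]
            y = xc @ A.T + b + center
            sampled = sample_at_world(mov, mov_aff, y, order=3,
                                      prefilter=False)
            r = (sampled - fixv) * w
            c = float((r ** 2).sum() / n)
            vox = world_to_voxel(y, mov_aff)
            coords = np.moveaxis(vox, -1, 0)
            from scipy.ndimage import map_coordinates
            g = np.stack([map_coordinates(grad[..., m], coords, order=3,
                                          prefilter=False, mode="nearest")
                          for m in range(3)], axis=-1)
            rw = 2.0 * r / n
            gA = np.einsum("i,im,ik->mk", rw, g, xc) / L
            gb = rw @ g
            return c, np.concatenate([gA.ravel(), gb])

        p = np.concatenate([(A_dev * L).ravel(), b_cur])

        # translation-only stage first (matrix parameters have far more
        # leverage and pull the optimizer into rotation local minima)
        def cost_grad_t(b, p=p):
            full = p.copy()
            full[9:] = b
            c, g = cost_grad(full)
            return c, g[9:]

        opts = {"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-12}
        res_t = minimize(cost_grad_t, p[9:], jac=True, method="L-BFGS-B",
                         options=opts)
        p = np.concatenate([p[:9], res_t.x])
        res = minimize(cost_grad, p, jac=True, method="L-BFGS-B",
                       options=opts)
        if res.fun <= res_t.fun:
            p = res.x
        A_dev = p[:9].reshape(3, 3) / L
        b_cur = p[9:]

    A = np.eye(3) + A_dev
    mat = np.eye(4)
    mat[:3, :3] = A
    mat[:3, 3] = b_cur + center - A @ center
    return AffineTransform(mat)


# ---------------------------------------------------------------------------
# B-spline free-form deformation
# ---------------------------------------------------------------------------

@dataclass
class NonlinearConfig:
    """Settings for the B-spline FFD registration engine.

    The inner optimizer is L-BFGS-B on the control-point displacements;
    plain gradient descent proved too ill-conditioned for this cost.
    """

    control_point_spacing: int = 6      # voxels, at each pyramid level
    levels: int = 3
    iterations: int = 80                # L-BFGS-B iterations per level
    bending_weight: float = 5e-4
    min_level_size: int = 8             # skip levels coarser than this
    tol: float = 1e-9                   # L-BFGS-B ftol (relative)


def _bspline3(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    out[m1] = (4 - 6 * at[m1] ** 2 + 3 * at[m1] ** 3) / 6.0
    m2 = (at >= 1) & (at < 2)
    out[m2] = (2 - at[m2]) ** 3 / 6.0
    return out


def _basis_matrix(n: int, spacing: float) -> np.ndarray:
    """Cubic B-spline basis (n voxels x n_ctrl nodes), nodes at
    (a - 1) * spacing for a = 0..n_ctrl-1."""
    n_ctrl = int(np.floor((n - 1) / spacing)) + 4
    i = np.arange(n)[:, None]
    a = np.arange(n_ctrl)[None, :]
    return _bspline3(i / spacing - (a - 1))


def _bending_energy_grad(c: np.ndarray):
    """Sum of squared second differences of the control lattice, per axis,
    with its gradient."""
    total = 0.0
    grad = np.zeros_like(c)
    for ax in range(3):
        if c.shape[ax] < 3:
            continue
        sl = [slice(None)] * c.ndim
        sl0, sl1, sl2 = list(sl), list(sl), list(sl)
        sl0[ax] = slice(None, -2)
        sl1[ax] = slice(1, -1)
        sl2[ax] = slice(2, None)
        d2 = c[tuple(sl2)] - 2 * c[tuple(sl1)] + c[tuple(sl0)]
        total += float((d2 ** 2).sum())
        grad[tuple(sl2)] += 2 * d2
        grad[tuple(sl1)] += -4 * d2
        grad[tuple(sl0)] += 2 * d2
    return total, grad


def register_nonlinear(moving: ScalarVolume, fixed: ScalarVolume,
                       cfg: NonlinearConfig = None,
                       source_space: str = "moving",
                       target_space: str = "fixed") -> DeformationField:
    """B-spline FFD registration (SSD + bending energy, gradient descent with
    backtracking, multiresolution). Returns a dense pull-back displacement
    field on the fixed grid; guaranteed not to increase SSD vs identity.
    """
    cfg = cfg or NonlinearConfig()
    _check_not_constant(moving, fixed)
    if moving.shape != fixed.shape or not np.allclose(moving.affine,
                                                      fixed.affine):
        raise ValueError("register_nonlinear expects images pre-aligned on a "
                         "common grid (run register_affine + resample first)")

    d_prev = None           # dense mm field from the previous (coarser) level
    aff_prev = None
    warned = False

    factors = [2 ** lvl for lvl in range(cfg.levels - 1, -1, -1)]
    factors = [f for f in factors if min(fixed.shape) // f >= cfg.min_level_size]
    if not factors:
        factors = [1]

    for f in factors:
        mov = _downsample(moving.values, f)
        fix = _downsample(fixed.values, f)
        fmask = (_downsample(fixed.mask.astype(float), f) > 0.5).astype(float)
        aff = _level_affine(fixed.affine, f)
        shape = fix.shape
        W = grid_world_coords(shape, aff)
        n_eff = max(fmask.sum(), 1.0)

        if d_prev is None:
            d0 = np.zeros(shape + (3,))
        else:
            d0 = sample_vector_at_world(d_prev, aff_prev, W, order=1)

        s = float(cfg.control_point_spacing)
        Bx = _basis_matrix(shape[0], s)
        By = _basis_matrix(shape[1], s)
        Bz = _basis_matrix(shape[2], s)
        c = np.zeros((Bx.shape[1], By.shape[1], Bz.shape[1], 3))

        grad_mov = _world_gradient(mov, aff)
        mov_pref = ndimage.spline_filter(mov, order=3, mode="nearest")

        def dense(c):
            return np.einsum("ia,jb,kc,abcm->ijkm", Bx, By, Bz, c,
                             optimize=True)

        def cost_grad(c):
            d = d0 + dense(c)
            y = W + d
            warped = sample_at_world(mov_pref, aff, y, order=3,
                                     prefilter=False)
            r = (warped - fix) * fmask
            ssd = float((r ** 2).sum() / n_eff)
            be, be_grad = _bending_energy_grad(c)
            g = sample_vector_at_world(grad_mov, aff, y, order=1)
            g_dense = (2.0 / n_eff) * r[..., None] * g
            g_ctrl = np.einsum("ia,jb,kc,ijkm->abcm", Bx, By, Bz, g_dense,
                               optimize=True)
            w_be = cfg.bending_weight / c.size      # mean-scale the penalty
            return ssd + w_be * be, g_ctrl + w_be * be_grad

        from scipy.optimize import minimize

        cshape = c.shape
        level_start, _ = cost_grad(c)

        def fun(flat):
            cost, grad = cost_grad(flat.reshape(cshape))
            return cost, grad.ravel()

        res = minimize(fun, c.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": cfg.iterations,
                                "ftol": cfg.tol, "gtol": 0.0})
        cost_end, _ = cost_grad(res.x.reshape(cshape))
        if cost_end <= level_start + 1e-15:
            c = res.x.reshape(cshape)
        elif not warned:
            log.warning("register_nonlinear: cost increased at level %d; "
                        "keeping best-so-far field", f)
            warned = True

        d_prev = d0 + dense(c)
        aff_prev = aff

    # resample final field to the full-resolution fixed grid
    Wfull = grid_world_coords(fixed.shape, fixed.affine)
    d_full = sample_vector_at_world(d_prev, aff_prev, Wfull, order=1)

    # guarantee the post-condition SSD(warped) <= SSD(identity)
    fmask = fixed.mask.astype(float)
    n_eff = max(fmask.sum(), 1.0)

    def _ssd(d):
        warped = sample_at_world(moving.values, moving.affine, Wfull + d,
                                 order=1)
        return float((((warped - fixed.values) * fmask) ** 2).sum() / n_eff)

    if _ssd(d_full) > _ssd(np.zeros_like(d_full)):
        log.warning("register_nonlinear: final field worse than identity; "
                    "returning zero field")
        d_full = np.zeros_like(d_full)

    return DeformationField(d_full, fixed.affine.copy(),
                            source_space=source_space,
                            target_space=target_space, mask=fixed.mask.copy())


# ---------------------------------------------------------------------------
# groupwise normalization
# ---------------------------------------------------------------------------

def groupwise_mean_deformation(features, cfg: NonlinearConfig = None,
                               group_iters: int = 1):
    """Iterative pairwise strategy: align every subject to every other and
    return, per subject, the arithmetic-mean displacement field.

    ``features`` may be FeatureImage objects or ScalarVolumes, all of the
    same kind on a common grid. Failed pairs are excluded (logged); more
    than 50% failures is a hard error.
    """
    vols = [getattr(f, "image", f) for f in features]
    if len(vols) < 2:
        raise ValueError("groupwise registration needs at least 2 subjects")
    ref = vols[0]
    for v in vols[1:]:
        if not ref.same_grid(v):
            raise ValueError("all feature images must share a common grid")
    kinds = {getattr(f, "kind", None) for f in features}
    if len(kinds) > 1:
        raise ValueError(f"mixed feature kinds in groupwise input: {kinds}")

    n = len(vols)
    current = list(vols)
    totals = [np.zeros(ref.shape + (3,)) for _ in range(n)]

    for _ in range(max(1, group_iters)):
        n_fail = 0
        round_fields = []
        for i in range(n):
            fields_i = []
            for j in range(n):
                if i == j:
                    continue
                try:
                    fields_i.append(register_nonlinear(
                        current[i], current[j], cfg).displacement)
                except Exception as exc:       # registration failure
                    n_fail += 1
                    log.warning("groupwise pair (%d -> %d) failed: %s",
                                i, j, exc)
            if not fields_i:
                raise RuntimeError(f"all pairwise registrations failed for "
                                   f"subject {i}")
            round_fields.append(np.mean(fields_i, axis=0))
        if n_fail > 0.5 * n * (n - 1):
            raise RuntimeError(f"{n_fail} of {n * (n - 1)} pairwise "
                               "registrations failed")
        for i in range(n):
            totals[i] = totals[i] + round_fields[i]
        if group_iters > 1:
            current = [apply_transform(
                vols[i], DeformationField(totals[i], ref.affine))
                for i in range(n)]

    return [DeformationField(totals[i], ref.affine.copy(),
                             source_space=f"subject{i}",
                             target_space="population", mask=ref.mask.copy())
            for i in range(n)]


def mean_pairwise_ssd(vols) -> float:
    """Mean over unordered pairs of the masked mean squared difference."""
    vols = list(vols)
    vals = []
    for a, b in itertools.combinations(vols, 2):
        m = a.mask & b.mask
        vals.append(float(((a.values - b.values)[m] ** 2).mean()))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# composition and inversion
# ---------------------------------------------------------------------------

def compose(chain, out_shape=None, out_affine=None) -> DeformationField:
    """Collapse a TransformChain (or stage list) into one dense field such
    that applying it equals applying the stages in sequence."""
    if not isinstance(chain, TransformChain):
        chain = TransformChain(list(chain))
    if out_affine is None:
        for stage in reversed(chain.stages):
            if isinstance(stage, DeformationField):
                out_shape, out_affine = stage.shape, stage.affine
                break
        else:
            raise ValueError("output grid must be given for all-affine chains")
    pts = grid_world_coords(out_shape, out_affine)
    src = chain.map_points(pts)
    return DeformationField(src - pts, np.asarray(out_affine, float),
                            source_space=chain.source_space,
                            target_space=chain.target_space)


def invert_field(d: DeformationField, tol: float = 0.01, max_iter: int = 50
                 ) -> DeformationField:
    """Fixed-point inversion: find e with e(x) = -d(x + e(x)).

    ``tol`` is the maximum composition residual in voxels on the mask.
    Raises on non-convergence, reporting the residual attained.
    """
    jac_det = np.linalg.det(d.jacobian())
    if (jac_det[d.mask] <= 0).any():
        raise ValueError("field is not invertible: non-positive Jacobian "
                         "determinant inside the mask")
    vox_mm = float(voxel_sizes(d.affine).min())
    W = grid_world_coords(d.shape, d.affine)
    e = -d.displacement.copy()
    for _ in range(max_iter):
        d_at = sample_vector_at_world(d.displacement, d.affine, W + e,
                                      order=1)
        e_new = -d_at
        step = float(np.linalg.norm((e_new - e)[d.mask], axis=-1).max())
        e = e_new
        if step / vox_mm < 0.25 * tol:
            break
    # composition residual ||x + e(x) + d(x + e(x)) - x|| in voxels
    d_at = sample_vector_at_world(d.displacement, d.affine, W + e, order=1)
    residual = float(np.linalg.norm((e + d_at)[d.mask], axis=-1).max()) / vox_mm
    if residual > tol:
        raise RuntimeError(
            f"invert_field did not converge: residual {residual:.4g} voxels "
            f"after {max_iter} iterations (tol {tol})")
    return DeformationField(e, d.affine.copy(),
                            source_space=d.target_space,
                            target_space=d.source_space, mask=d.mask.copy())
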