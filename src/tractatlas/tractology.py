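"""Deterministic streamline tractography on a tensor template, ROI-logic
bundle selection, arc-length parameterization with cross-subject point
correspondence, and inverse mapping of parameterized points to native space.

Tracking is fixed-step Euler integration along the principal eigenvector of
the trilinearly interpolated tensor, bidirectional from each seed, with FA
and per-step turning-angle termination. Streamlines are stored in mm world
coordinates; TCK is the primary on-disk format (TRK readable) via
nibabel.streamlines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._grid import sample_vector_at_world, voxel_sizes, world_to_voxel
from .core_tensor import ScalarVolume, TensorVolume, fractional_anisotropy
from .registration import DeformationField

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Streamline:
    points: np.ndarray          # (n, 3) mm, world frame
    seed_index: int = -1

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("streamline points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least 2 points")

    def __len__(self):
        return len(self.points)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0),
                                    axis=1).sum())


@dataclass
class FiberBundle:
    streamlines: list
    space: str = "population"
    selection_log: list = field(default_factory=list)

    def __len__(self):
        return len(self.streamlines)

    @property
    def empty(self) -> bool:
        return len(self.streamlines) == 0


@dataclass
class ParameterizedTractSet:
    K: int
    representative: np.ndarray          # (K, 3) mm, population space
    arc_fractions: np.ndarray           # (K,) in [0, 1], strictly increasing
    streamline_points: np.ndarray       # (n_lines, K, 3) after matching
    samples: pd.DataFrame = None        # tidy: subject, point_index, value

    def __post_init__(self):
        fr = np.asarray(self.arc_fractions, float)
        if not (np.all(np.diff(fr) > 0) and fr[0] == 0.0 and fr[-1] == 1.0):
            raise ValueError("arc fractions must increase strictly from 0 "
                             "to 1")


# ---------------------------------------------------------------------------
# streamline I/O (TCK primary, TRK readable)
# ---------------------------------------------------------------------------

def save_bundle(bundle: FiberBundle, path, sidecar: bool = True):
    import nibabel.streamlines as nibs
    tg = nibs.Tractogram([s.points for s in bundle.streamlines],
                         affine_to_rasmm=np.eye(4))
    path = str(path)
    nibs.save(tg, path)
    if sidecar:
        meta = {"space": bundle.space, "selection_log": bundle.selection_log,
                "n_streamlines": len(bundle)}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def load_bundle(path) -> FiberBundle:
    import nibabel.streamlines as nibs
    tf = nibs.load(str(path))
    lines = [Streamline(np.asarray(p, float)) for p in tf.streamlines]
    meta = {}
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    return FiberBundle(lines, space=meta.get("space", "unknown"),
                       selection_log=meta.get("selection_log", []))


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _principal_dirs_and_fa(template: TensorVolume, pts: np.ndarray):
    """Interpolate tensors at world points; return (e1, fa, inside)."""
    comps = template.tensors.reshape(template.shape + (9,))
    sampled = sample_vector_at_world(comps, template.affine, pts, order=1)
    T = sampled.reshape(pts.shape[:-1] + (3, 3))
    T = 0.5 * (T + np.swapaxes(T, -1, -2))
    lam, vec = np.linalg.eigh(T)
    e1 = vec[..., :, 2]
    fa = fractional_anisotropy(lam[..., ::-1])
    vox = world_to_voxel(pts, template.affine)
    inside = np.logical_and.reduce(
        [(vox[..., i] >= 0) & (vox[..., i] <= template.shape[i] - 1)
         for i in range(3)])
    inmask = sample_vector_at_world(
        template.mask.astype(float)[..., None], template.affine, pts,
        order=0)[..., 0] > 0.5
    return e1, fa, inside & inmask


def _march(template, seeds_mm, dirs0, fa_thresh, cos_thresh, step_mm,
           max_steps):
    """Batched Euler marching; returns per-seed list of point arrays
    (excluding the seed point itself)."""
    n = len(seeds_mm)
    pos = seeds_mm.copy()
    direction = dirs0.copy()
    active = np.ones(n, dtype=bool)
    paths = [[] for _ in range(n)]
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.where(active)[0]
        new_pos = pos[idx] + step_mm * direction[idx]
        e1, fa, inside = _principal_dirs_and_fa(template, new_pos)
        # align eigenvector sign with the incoming direction
        dots = np.einsum("ij,ij->i", e1, direction[idx])
        e1 = np.where(dots[:, None] < 0, -e1, e1)
        dots = np.abs(dots)
        ok = inside & (fa >= fa_thresh) & (dots >= cos_thresh)
        for m, k in enumerate(idx):
            if ok[m]:
                paths[k].append(new_pos[m])
        pos[idx[ok]] = new_pos[ok]
        direction[idx[ok]] = e1[ok]
        active[idx[~ok]] = False
    return paths


def default_seeds(template: TensorVolume, fa_thresh: float) -> np.ndarray:
    """One seed at the center of every in-mask voxel with FA >= threshold."""
    from .core_tensor import fa_volume
    fa = fa_volume(template)
    sel = fa.mask & (fa.values >= fa_thresh)
    idx = np.argwhere(sel).astype(float)
    return idx @ template.affine[:3, :3].T + template.affine[:3, 3]


def track(template: TensorVolume, fa_thresh: float = 0.2,
          angle_thresh_deg: float = 30.0, step_mm: float = None,
          seeds: np.ndarray = None, min_length_mm: float = 10.0,
          max_steps: int = 2000):
    """Deterministic whole-volume streamline tracking.

    Euler integration along the interpolated principal eigenvector,
    bidirectional from each seed; termination on FA < ``fa_thresh``, per-step
    turning angle > ``angle_thresh_deg``, or leaving the volume/mask.
    Streamlines shorter than ``min_length_mm`` are discarded.
    """
    if not (0 < fa_thresh < 1):
        raise ValueError("fa_thresh must be in (0, 1)")
    if not (0 < angle_thresh_deg <= 90):
        raise ValueError("angle_thresh_deg must be in (0, 90]")
    if step_mm is None:
        step_mm = 0.5 * float(voxel_sizes(template.affine).min())
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    if seeds is None:
        seeds = default_seeds(template, fa_thresh)
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 3)
    if len(seeds) == 0:
        log.warning("track: no seeds above the FA threshold")
        return []

    e1, fa, inside = _principal_dirs_and_fa(template, seeds)
    valid = inside & (fa >= fa_thresh)
    if not valid.any():
        log.warning("track: no valid seeds above the FA threshold")
        return []
    seed_ids = np.where(valid)[0]
    seeds_v = seeds[valid]
    dirs_v = e1[valid]
    cos_thresh = float(np.cos(np.radians(angle_thresh_deg)))

    fwd = _march(template, seeds_v, dirs_v, fa_thresh, cos_thresh, step_mm,
                 max_steps)
    bwd = _march(template, seeds_v, -dirs_v, fa_thresh, cos_thresh, step_mm,
                 max_steps)
    out = []
    for k in range(len(seeds_v)):
        pts = list(reversed(bwd[k])) + [seeds_v[k]] + fwd[k]
        if len(pts) < 2:
            continue
        sl = Streamline(np.asarray(pts), seed_index=int(seed_ids[k]))
        if sl.length >= min_length_mm:
            out.append(sl)
    return out


# ---------------------------------------------------------------------------
# bundle selection
# ---------------------------------------------------------------------------

def _visits_mask(streamline: Streamline, mask: np.ndarray, affine) -> bool:
    vox = np.round(world_to_voxel(streamline.points, affine)).astype(int)
    ok = np.logical_and.reduce(
        [(vox[:, i] >= 0) & (vox[:, i] < mask.shape[i]) for i in range(3)])
    if not ok.any():
        return False
    v = vox[ok]
    return bool(mask[v[:, 0], v[:, 1], v[:, 2]].any())


def select_bundle(streamlines, rois, logic, affine) -> FiberBundle:
    """Filter streamlines by ROI logic.

    ``logic`` is a sequence of ``(op, roi_name)`` with op in
    {"AND", "OR", "NOT"}: keep lines passing through every AND mask, at
    least one OR mask (if any OR terms exist), and no NOT mask. The
    selection log records the surviving count after each term.
    """
    masks = rois.masks if isinstance(rois, RoiAtlasProxy) else rois
    lines = list(streamlines)
    sel_log = [{"term": "input", "count": len(lines)}]
    or_names = [name for op, name in logic if op == "OR"]
    for op, name in logic:
        if name not in masks:
            raise KeyError(f"unknown ROI name {name!r}")
        mask = masks[name]
        if op == "AND":
            lines = [s for s in lines if _visits_mask(s, mask, affine)]
        elif op == "NOT":
            lines = [s for s in lines if not _visits_mask(s, mask, affine)]
        elif op == "OR":
            continue            # handled jointly below
        else:
            raise ValueError(f"unknown logic op {op!r}")
        sel_log.append({"term": f"{op} {name}", "count": len(lines)})
    if or_names:
        lines = [s for s in lines
                 if any(_visits_mask(s, masks[n], affine) for n in or_names)]
        sel_log.append({"term": "OR " + "|".join(or_names),
                        "count": len(lines)})
    if not lines:
        log.warning("select_bundle: selection produced an empty bundle")
    return FiberBundle(lines, selection_log=sel_log)


class RoiAtlasProxy:          # tiny shim so select_bundle takes dict or atlas
    def __init__(self, masks):
        self.masks = masks


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

def resample_arclength(points: np.ndarray, K: int) -> np.ndarray:
    """Resample a polyline at K equal arc-length fractions (linear interp)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("zero-length streamline")
    targets = np.linspace(0.0, total, K)
    return np.stack([np.interp(targets, s, points[:, c]) for c in range(3)],
                    axis=1)


def _endpoint_dist(a: np.ndarray, b: np.ndarray):
    """Flip-aware endpoint distance: (distance, flipped?)."""
    straight = np.linalg.norm(a[0] - b[0]) + np.linalg.norm(a[-1] - b[-1])
    flipped = np.linalg.norm(a[0] - b[-1]) + np.linalg.norm(a[-1] - b[0])
    return (straight, False) if straight <= flipped else (flipped, True)


def parameterize(bundle: FiberBundle, K: int) -> ParameterizedTractSet:
    """Resample each streamline to K equal arc-length fractions, unify
    orientations against the bundle medoid (endpoint-matching flip), and
    take the pointwise mean as the representative curve.
    """
    if bundle.empty:
        raise ValueError("cannot parameterize an empty bundle")
    if K < 2:
        raise ValueError("K must be >= 2")
    resampled, dropped = [], 0
    for s in bundle.streamlines:
        try:
            resampled.append(resample_arclength(s.points, K))
        except ValueError:
            dropped += 1
    if dropped:
        log.warning("parameterize: dropped %d zero-length streamlines",
                    dropped)
    if not resampled:
        raise ValueError("no usable streamlines after dropping "
                         "zero-length entries")
    P = np.stack(resampled)                      # (n, K, 3)
    n = len(P)
    starts, ends = P[:, 0], P[:, -1]
    d_ss = np.linalg.norm(starts[:, None] - starts[None], axis=-1)
    d_ee = np.linalg.norm(ends[:, None] - ends[None], axis=-1)
    d_se = np.linalg.norm(starts[:, None] - ends[None], axis=-1)
    d_es = np.linalg.norm(ends[:, None] - starts[None], axis=-1)
    pair = np.minimum(d_ss + d_ee, d_se + d_es)
    medoid = int(pair.sum(axis=1).argmin())
    aligned = np.empty_like(P)
    for i in range(n):
        _, flip = _endpoint_dist(P[i], P[medoid])
        aligned[i] = P[i, ::-1] if flip else P[i]
    rep = aligned.mean(axis=0)
    return ParameterizedTractSet(
        K=K, representative=rep, arc_fractions=np.linspace(0.0, 1.0, K),
        streamline_points=aligned)


def representative_curve(pts: ParameterizedTractSet, mode: str = "mean"
                         ) -> np.ndarray:
    if mode == "mean":
        return pts.streamline_points.mean(axis=0)
    if mode == "median":
        return np.median(pts.streamline_points, axis=0)
    raise ValueError(f"unknown aggregation {mode!r}")


# ---------------------------------------------------------------------------
# native-space sampling
# ---------------------------------------------------------------------------

def map_to_native_and_sample(pts: ParameterizedTractSet, inverse_fields: dict,
                             native_measures: dict) -> pd.DataFrame:
    """Map the representative curve through each subject's inverse field and
    sample the subject's native measure at the mapped points (trilinear).

    Returns a tidy frame (subject, point_index, arc_fraction, value); points
    mapping outside the measure volume yield NaN with per-subject counts
    logged.
    """
    subjects = list(inverse_fields)
    missing = [s for s in subjects if s not in native_measures]
    missing += [s for s in native_measures if s not in inverse_fields]
    if missing:
        raise ValueError("missing field or measure for subject(s): "
                         f"{sorted(set(missing))}")
    rows = []
    for subj in subjects:
        fieldv = inverse_fields[subj]
        meas = native_measures[subj]
        native_pts = fieldv.map_points(pts.representative)
        vox = world_to_voxel(native_pts, meas.affine)
        inside = np.logical_and.reduce(
            [(vox[:, i] >= 0) & (vox[:, i] <= meas.shape[i] - 1)
             for i in range(3)])
        vals = sample_vector_at_world(meas.values[..., None], meas.affine,
                                      native_pts, order=1)[:, 0]
        vals = np.where(inside, vals, np.nan)
        n_out = int((~inside).sum())
        if n_out:
            log.info("map_to_native_and_sample: subject %s has %d of %d "
                     "points outside the volume", subj, n_out, pts.K)
        for k in range(pts.K):
            rows.append({"subject": subj, "point_index": k,
                         "arc_fraction": pts.arc_fractions[k],
                         "value": vals[k]})
    return pd.DataFrame(rows)
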