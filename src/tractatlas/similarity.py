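"""Similarity metrics between tensor volumes: FA accuracy/precision,
eigenvalue-eigenvector overlap (OVL) and its accuracy/precision, tensor
Euclidean distances (DTED/DVED), primary-eigenvector angle and coherence
(AI/COH), FA cross-correlation, and ROI/histogram summaries with group
tests.

Conventions (isolated here so alternates are one-line swaps): DTED/DVED are
Frobenius norms of the tensor difference and of the deviatoric-part
difference; COH = |eps1 . eps1*|; AI = arccos(COH), reported in degrees by
default. OVL pairs eigenvalues by descending sorted order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_tensor import (ScalarVolume, TensorVolume, eigendecompose,
                          mean_tensor_volume)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RoiAtlas:
    """Named boolean masks on the population grid."""

    masks: dict                         # name -> (X, Y, Z) bool
    affine: np.ndarray = None

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("ROI masks have inconsistent shapes")

    def __getitem__(self, name):
        return self.masks[name]

    @property
    def names(self):
        return list(self.masks)


@dataclass
class MetricReport:
    metric: str
    maps: dict = field(default_factory=dict)        # name -> ScalarVolume
    roi_table: pd.DataFrame = None
    histogram: pd.DataFrame = None                  # bin_left/bin_right/fraction
    tests: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FA accuracy / precision
# ---------------------------------------------------------------------------

def fa_accuracy_precision(normalized, gt: ScalarVolume):
    """Voxelwise accuracy |mean_i FA_i - FA_GT| and precision
    |mean_i (FA_i - FA_GT)^2| over N normalized FA maps."""
    normalized = list(normalized)
    if not normalized:
        raise ValueError("need at least one normalized image")
    for v in normalized:
        if not gt.same_grid(v):
            raise ValueError("normalized images must be on the ground-truth "
                             "grid")
    stackv = np.stack([v.values for v in normalized])
    mask = gt.mask & np.logical_and.reduce([v.mask for v in normalized])
    accuracy = np.abs(stackv.mean(axis=0) - gt.values)
    precision = np.abs(((stackv - gt.values) ** 2).mean(axis=0))
    return (ScalarVolume(accuracy, gt.affine.copy(), mask),
            ScalarVolume(precision, gt.affine.copy(), mask))


# ---------------------------------------------------------------------------
# eigen-based pairwise metrics
# ---------------------------------------------------------------------------

def ovl(a: TensorVolume, b: TensorVolume) -> ScalarVolume:
    """Overlap of eigenvalue-eigenvector pairs:

        OVL = sum_j lam_j lam*_j (eps_j . eps*_j)^2 / sum_j lam_j lam*_j

    with eigenvalues paired in descending order. Symmetric; in [0, 1] for
    nonnegative eigenvalues. Voxels with zero denominator are masked out.
    """
    if not a.same_grid(b):
        raise ValueError("tensor volumes must share a grid")
    ea, eb = eigendecompose(a), eigendecompose(b)
    dots = np.einsum("...ji,...ji->...j", ea.vectors, eb.vectors)
    lamprod = ea.lambdas * eb.lambdas
    num = (lamprod * dots ** 2).sum(axis=-1)
    den = lamprod.sum(axis=-1)
    mask = ea.mask & eb.mask & (np.abs(den) > 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(mask, num / np.where(den == 0, 1, den), 0.0)
    return ScalarVolume(vals, a.affine.copy(), mask)


def ovl_accuracy_precision(normalized, gt: TensorVolume,
                           mean_mode: str = "euclidean"):
    """OVL accuracy = OVL(mean of normalized volumes, gt);
    OVL precision = mean_i OVL(normalized_i, gt)."""
    normalized = list(normalized)
    if not normalized:
        raise ValueError("need at least one normalized volume")
    accuracy = ovl(mean_tensor_volume(normalized, mode=mean_mode), gt)
    per = [ovl(v, gt) for v in normalized]
    mask = np.logical_and.reduce([p.mask for p in per])
    precision = ScalarVolume(np.mean([p.values for p in per], axis=0),
                             gt.affine.copy(), mask)
    return accuracy, precision


def pairwise_tensor_metrics(a: TensorVolume, b: TensorVolume,
                            angle_units: str = "degrees",
                            iso_tol: float = 1e-9) -> dict:
    """DTED, DVED (Frobenius distances of tensors / deviatoric tensors),
    AI (primary-eigenvector angle) and COH (|eps1 . eps1*|).

    AI/COH are undefined where either tensor is isotropic to ``iso_tol``
    (lam1 ~ lam2); those voxels are excluded from the AI/COH masks but kept
    for DTED/DVED.
    """
    if not a.same_grid(b):
        raise ValueError("tensor volumes must share a grid")
    diff = a.tensors - b.tensors
    dted = np.linalg.norm(diff, axis=(-2, -1))
    tr = np.trace(diff, axis1=-2, axis2=-1)
    dev = diff - (tr[..., None, None] / 3.0) * np.eye(3)
    dved = np.linalg.norm(dev, axis=(-2, -1))
    mask = a.mask & b.mask

    ea, eb = eigendecompose(a), eigendecompose(b)
    coh = np.abs(np.einsum("...i,...i->...", ea.principal, eb.principal))
    coh = np.clip(coh, 0.0, 1.0)
    ai = np.arccos(coh)
    if angle_units == "degrees":
        ai = np.degrees(ai)
    elif angle_units != "radians":
        raise ValueError(f"unknown angle unit {angle_units!r}")
    aniso = ((ea.lambdas[..., 0] - ea.lambdas[..., 1] > iso_tol)
             & (eb.lambdas[..., 0] - eb.lambdas[..., 1] > iso_tol))
    dir_mask = mask & aniso
    return {
        "DTED": ScalarVolume(dted, a.affine.copy(), mask),
        "DVED": ScalarVolume(dved, a.affine.copy(), mask),
        "AI": ScalarVolume(np.where(dir_mask, ai, 0.0), a.affine.copy(),
                           dir_mask),
        "COH": ScalarVolume(np.where(dir_mask, coh, 0.0), a.affine.copy(),
                            dir_mask),
    }


def corr_fa(images, region: np.ndarray = None):
    """Pearson correlation of FA maps over region voxels, for every
    unordered image pair. Returns ``(matrix, mean)`` where the matrix has a
    unit diagonal and ``mean`` averages the defined off-diagonal entries.
    """
    images = list(images)
    if len(images) < 2:
        raise ValueError("corr_fa needs at least 2 images")
    ref = images[0]
    if region is None:
        region = np.logical_and.reduce([im.mask for im in images])
    if region.sum() < 3:
        raise ValueError("region must contain at least 3 voxels")
    data = np.stack([im.values[region] for im in images])
    n = len(images)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    n_undef = 0
    for i, j in itertools.combinations(range(n), 2):
        xi, xj = data[i], data[j]
        if xi.std() == 0 or xj.std() == 0:
            n_undef += 1
            continue
        r = float(np.corrcoef(xi, xj)[0, 1])
        mat[i, j] = mat[j, i] = r
    if n_undef:
        log.warning("corr_fa: %d pairs undefined (zero variance in region)",
                    n_undef)
    off = mat[np.triu_indices(n, k=1)]
    mean = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    return mat, mean


# ---------------------------------------------------------------------------
# summaries and group tests
# ---------------------------------------------------------------------------

#: natural value ranges used for default histogram binning
METRIC_RANGES = {"OVL": (0.0, 1.0), "COH": (0.0, 1.0), "AI": (0.0, 90.0),
                 "corrFA": (-1.0, 1.0)}


def roi_summary(vol: ScalarVolume, atlas: RoiAtlas) -> pd.DataFrame:
    """Per-ROI mean/SD of a map; empty ROIs get null rows with a warning."""
    rows = []
    for name in atlas.names:
        m = atlas[name] & vol.mask
        if not m.any():
            log.warning("roi_summary: ROI %s is empty on the map mask", name)
            rows.append({"roi": name, "mean": np.nan, "sd": np.nan,
                         "n_voxels": 0})
            continue
        vals = vol.values[m]
        rows.append({"roi": name, "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     "n_voxels": int(vals.size)})
    return pd.DataFrame(rows)


def relative_histogram(vol: ScalarVolume, bins=100, value_range=None
                       ) -> pd.DataFrame:
    """Relative-frequency histogram over the mask; fractions sum to 1."""
    vals = vol.values[vol.mask]
    if value_range is None:
        value_range = (float(vals.min()), float(vals.max()) or 1.0)
    counts, edges = np.histogram(vals, bins=bins, range=value_range)
    frac = counts / max(counts.sum(), 1)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "fraction": frac})


def anova_conditions(condition_values: dict) -> dict:
    """One-way ANOVA across metric distributions of different conditions,
    with Bonferroni-corrected pairwise Welch comparisons."""
    names = list(condition_values)
    groups = [np.asarray(condition_values[k], float) for k in names]
    if np.ptp(np.concatenate(groups)) < 1e-300:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
        if not (np.isfinite(f_stat) and np.isfinite(p)):
            # degenerate case (e.g. identical groups): no evidence of effect
            f_stat, p = 0.0, 1.0
    pairs = {}
    contrasts = list(itertools.combinations(range(len(names)), 2))
    for i, j in contrasts:
        _, pp = stats.ttest_ind(groups[i], groups[j], equal_var=False)
        if not np.isfinite(pp):
            pp = 1.0
        pairs[(names[i], names[j])] = min(1.0, float(pp) * len(contrasts))
    return {"F": float(f_stat), "p": float(p), "pairwise_bonferroni": pairs}


def wilcoxon_matched(a, b) -> dict:
    """Thin Wilcoxon matched-pairs signed-rank reporting utility."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.all(a == b):
        return {"statistic": 0.0, "p": 1.0}
    res = stats.wilcoxon(a, b)
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def summarize(metric: str, maps, atlas: RoiAtlas, bins: int = 100,
              condition_values: dict = None) -> MetricReport:
    """Assemble per-ROI tables, a whole-mask relative histogram, and (when
    per-condition samples are supplied) the ANOVA + Bonferroni tests.

    ``maps`` is a dict of named ScalarVolumes (e.g. one per image pair or
    condition); ROI rows are aggregated over all of them.
    """
    maps = dict(maps)
    tables = []
    for name, vol in maps.items():
        tab = roi_summary(vol, atlas)
        tab.insert(0, "map", name)
        tables.append(tab)
    roi_table = pd.concat(tables, ignore_index=True)
    pooled_vals = np.concatenate([v.values[v.mask] for v in maps.values()])
    pooled = ScalarVolume(pooled_vals.reshape(-1, 1, 1),
                          np.eye(4))
    hist = relative_histogram(pooled, bins=bins,
                              value_range=METRIC_RANGES.get(metric))
    tests = {}
    if condition_values:
        tests["anova"] = anova_conditions(condition_values)
    return MetricReport(metric=metric, maps=maps, roi_table=roi_table,
                        histogram=hist, tests=tests)
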