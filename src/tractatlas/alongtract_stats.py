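"""Group statistics along parameterized tracts: pointwise two-sample tests,
1-D threshold-free cluster enhancement (TFCE), permutation-based
family-wise-error control via the max-statistic distribution, tract-averaged
testing, and ROC/AUC classification.

TFCE defaults (E=0.5, H=2, dh=0.1) are the standard published values;
inference is two-tailed via the max of the two one-tailed TFCE maps.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class TractStatResult:
    t: np.ndarray                   # K pointwise statistics
    tfce: np.ndarray                # K enhanced values (two-tailed max)
    p_fwe: np.ndarray               # K corrected p-values
    significant: np.ndarray         # bool, p < alpha
    alpha: float
    n_perm: int
    seed: int
    exact: bool = False             # True if full enumeration substituted
    df: float = np.nan

    @property
    def significant_indices(self) -> np.ndarray:
        return np.where(self.significant)[0]


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    direction: int = 1              # +1: larger feature predicts class 1


# ---------------------------------------------------------------------------
# pointwise tests
# ---------------------------------------------------------------------------

def pointwise_ttest(group_a: np.ndarray, group_b: np.ndarray,
                    equal_var: bool = True):
    """Two-sample t per tract point (sign convention A - B).

    Inputs are (subjects x K) arrays; NaNs are handled pairwise-complete per
    point. Points with fewer than 2 complete values in either group, or with
    zero pooled variance, are returned as NaN (degenerate cases logged).
    Returns ``(t, df)`` arrays of length K.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    K = a.shape[1]
    t = np.full(K, np.nan)
    df = np.full(K, np.nan)
    na = (~np.isnan(a)).sum(axis=0).astype(float)
    nb = (~np.isnan(b)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        va = np.nanvar(a, axis=0, ddof=1)
        vb = np.nanvar(b, axis=0, ddof=1)
        valid = (na >= 2) & (nb >= 2)
        if equal_var:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1 / na + 1 / nb))
            dof = na + nb - 2
        else:
            se = np.sqrt(va / na + vb / nb)
            num = (va / na + vb / nb) ** 2
            den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            dof = np.where(den > 0, num / den, np.nan)
        # guard against float-noise "zero" variance (se ~ 1e-17 from
        # cancellation) which would produce absurd t values
        se_floor = 1e-10 * (np.abs(ma) + np.abs(mb) + 1e-30)
        ok = valid & (se > se_floor)
        t[ok] = ((ma - mb) / se)[ok]
        df[ok] = dof[ok]
    degen = valid & (se <= se_floor) & (ma != mb)
    if degen.any():
        log.warning("pointwise_ttest: %d points with zero pooled variance "
                    "and nonzero mean difference (t undefined)",
                    int(degen.sum()))
    return t, df


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def _run_lengths(above: np.ndarray) -> np.ndarray:
    """Length of the contiguous True run containing each point (0 where
    False)."""
    K = len(above)
    out = np.zeros(K)
    k = 0
    while k < K:
        if above[k]:
            j = k
            while j < K and above[j]:
                j += 1
            out[k:j] = j - k
            k = j
        else:
            k += 1
    return out


def tfce_1d(stats_map: np.ndarray, E: float = 0.5, H: float = 2.0,
            dh: float = 0.1) -> np.ndarray:
    """1-D threshold-free cluster enhancement, both tails.

    For each point k, TFCE(k) = sum over thresholds h = dh, 2dh, ...
    <= stat_k of extent(k, h)^E * h^H * dh, where extent is the length in
    points of the contiguous suprathreshold run containing k. Negative
    values are enhanced on the negated map and returned with negative sign.
    """
    s = np.asarray(stats_map, dtype=float)
    if s.ndim != 1:
        raise ValueError("tfce_1d expects a 1-D statistic map")
    if not np.isfinite(s).all():
        raise ValueError("non-finite statistics at indices "
                         f"{list(np.where(~np.isfinite(s))[0])}")
    if E <= 0 or H <= 0 or dh <= 0:
        raise ValueError("E, H and dh must all be positive")

    def one_tail(v):
        out = np.zeros_like(v)
        vmax = v.max(initial=0.0)
        h = dh
        while h <= vmax + 1e-12:
            above = v >= h
            if above.any():
                ext = _run_lengths(above)
                out += np.where(above, ext ** E * h ** H * dh, 0.0)
            h += dh
        return out

    return one_tail(np.maximum(s, 0.0)) - one_tail(np.maximum(-s, 0.0))


# ---------------------------------------------------------------------------
# permutation FWE
# ---------------------------------------------------------------------------

@dataclass
class TfceParams:
    E: float = 0.5
    H: float = 2.0
    dh: float = 0.1


def _label_permutations(n_a: int, n_b: int, n_perm: int, rng):
    """Yield boolean group-A membership vectors. Uses exact enumeration when
    there are no more than n_perm distinct label assignments."""
    n = n_a + n_b
    n_distinct = math.comb(n, n_a)
    if n_distinct <= n_perm:
        perms = []
        for comb in itertools.combinations(range(n), n_a):
            m = np.zeros(n, dtype=bool)
            m[list(comb)] = True
            perms.append(m)
        return perms, True
    perms = []
    for _ in range(n_perm):
        order = rng.permutation(n)
        m = np.zeros(n, dtype=bool)
        m[order[:n_a]] = True
        perms.append(m)
    return perms, False


def _tfce_stat(data, is_a, tfce_params, equal_var=True):
    t, _ = pointwise_ttest(data[is_a], data[~is_a], equal_var=equal_var)
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    return np.abs(tfce_1d(t, tfce_params.E, tfce_params.H, tfce_params.dh))


def permutation_fwe(group_a: np.ndarray, group_b: np.ndarray,
                    n_perm: int = 1000, seed: int = 0,
                    tfce_params: TfceParams = None, alpha: float = 0.05,
                    equal_var: bool = True,
                    max_missing_frac: float = 0.5) -> TractStatResult:
    """Permutation max-TFCE family-wise-error control along the tract.

    Corrected p_k = (1 + #{null max >= tfce_k}) / (n_perm + 1); the null
    distribution is the per-permutation maximum over points of the
    two-tailed TFCE map. Exact enumeration is substituted when the groups
    admit fewer distinct label assignments than ``n_perm``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    tfce_params = tfce_params or TfceParams()
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    # subjects missing too many points are excluded from this test
    def keep(x):
        frac = np.isnan(x).mean(axis=1)
        drop = frac > max_missing_frac
        if drop.any():
            log.warning("permutation_fwe: excluding %d subjects with > "
                        "%.0f%% missing points", int(drop.sum()),
                        100 * max_missing_frac)
        return x[~drop]
    a, b = keep(a), keep(b)

    data = np.vstack([a, b])
    n_a = len(a)
    rng = np.random.default_rng(seed)

    t_obs, df = pointwise_ttest(a, b, equal_var=equal_var)
    is_a_obs = np.zeros(len(data), dtype=bool)
    is_a_obs[:n_a] = True
    tfce_obs = _tfce_stat(data, is_a_obs, tfce_params, equal_var)

    perms, exact = _label_permutations(n_a, len(b), n_perm, rng)
    null_max = np.array([
        _tfce_stat(data, m, tfce_params, equal_var).max() for m in perms])
    n_eff = len(perms)
    p = (1.0 + (null_max[None, :] >= tfce_obs[:, None]).sum(axis=1)) \
        / (n_eff + 1.0)
    p = np.minimum(p, 1.0)
    sig = p < alpha
    return TractStatResult(t=t_obs, tfce=tfce_obs, p_fwe=p, significant=sig,
                           alpha=alpha, n_perm=n_eff, seed=seed, exact=exact,
                           df=float(np.nanmax(df)) if np.isfinite(df).any()
                           else np.nan)


# ---------------------------------------------------------------------------
# tract-averaged test
# ---------------------------------------------------------------------------

def tract_average_test(group_a: np.ndarray, group_b: np.ndarray,
                       equal_var: bool = True) -> dict:
    """Missing-aware per-subject mean over points, then one pooled
    two-sample t-test. Subjects with all-missing profiles are excluded."""
    def means(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        has_data = ~np.isnan(x).all(axis=1)
        n_drop = int((~has_data).sum())
        if n_drop:
            log.warning("tract_average_test: excluded %d all-missing "
                        "subjects", n_drop)
        return np.nanmean(x[has_data], axis=1)
    ma, mb = means(group_a), means(group_b)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("need at least 2 usable subjects per group")
    if np.ptp(np.concatenate([ma, mb])) == 0:
        return {"mean_a": ma, "mean_b": mb, "t": 0.0, "p": 1.0,
                "df": len(ma) + len(mb) - 2}
    res = stats.ttest_ind(ma, mb, equal_var=equal_var)
    return {"mean_a": ma, "mean_b": mb, "t": float(res.statistic),
            "p": float(res.pvalue), "df": float(res.df)}


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(feature, labels, significant_set=None) -> RocResult:
    """ROC curve and AUC via the rank (Mann-Whitney) formulation with tie
    correction.

    ``feature`` is per-subject scalar, or a (subjects x K) matrix reduced to
    a scalar by the mean over ``significant_set`` point indices. The curve
    orientation is chosen so the reported AUC >= 0.5; ``direction`` records
    the flip (-1 when larger feature values predict class 0).
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.ndim == 2:
        cols = (significant_set if significant_set is not None
                else slice(None))
        x = np.nanmean(x[:, cols], axis=1)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("roc_auc needs exactly two classes present")
    y = (y == classes.max()).astype(int)

    def auc_rank(xv):
        ranks = stats.rankdata(xv)          # midranks handle ties
        n1 = int(y.sum())
        n0 = len(y) - n1
        u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
        return u / (n0 * n1)

    auc = auc_rank(x)
    direction = 1
    if auc < 0.5:
        direction = -1
        x = -x
        auc = auc_rank(x)

    thresholds = np.concatenate([[np.inf], np.unique(x)[::-1]])
    tpr = np.array([(x[y == 1] >= th).mean() for th in thresholds])
    fpr = np.array([(x[y == 0] >= th).mean() for th in thresholds])
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr,
                     auc=float(auc), direction=direction)


# ---------------------------------------------------------------------------
# tidy-CSV plumbing
# ---------------------------------------------------------------------------

def profiles_from_tidy(samples: pd.DataFrame, labels: pd.DataFrame):
    """Split a tidy (subject, point_index, value) frame by a labels frame
    (subject, group) into two (subjects x K) matrices, returned with the
    subject orderings."""
    wide = samples.pivot(index="subject", columns="point_index",
                         values="value").sort_index(axis=1)
    lab = labels.set_index("subject")["group"]
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    a_ids = [s for s in wide.index if lab[s] == groups[0]]
    b_ids = [s for s in wide.index if lab[s] == groups[1]]
    return (wide.loc[a_ids].to_numpy(), wide.loc[b_ids].to_numpy(),
            a_ids, b_ids)
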