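"""Moderated-difference differential expression with permutation inference.

The statistic is the SAM-style relative difference

    d = (mean_a - mean_b) / (s + s0)

with ``s`` the pooled two-group standard error of the difference and
``s0`` a small "fudge" constant that damps the inflated d of
low-variance features.  p-values come from label permutations; the FDR
at a cut is the SAM-style median-over-permutations count ratio, without
pi0 correction.

Expression is expected on the log2 scale throughout this module.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

EXHAUSTIVE_LIMIT = 10_000


class DiffExprError(ValueError):
    pass


# ---------------------------------------------------------------------------
# The d statistic
# ---------------------------------------------------------------------------


def _pooled_s(ssa: np.ndarray, ssb: np.ndarray, na: int, nb: int) -> np.ndarray:
    """Pooled standard error of the two-group mean difference."""
    dof = na + nb - 2
    if dof <= 0:
        return np.zeros_like(np.asarray(ssa, dtype=float))
    return np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / dof)


def sam_statistic(
    group_a: Sequence[float], group_b: Sequence[float], s0: float
) -> Tuple[float, float, float]:
    """d, s and the mean difference for one feature.

    At ``s0 == 0`` and both group sizes >= 2 this is exactly the pooled
    two-sample t statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DiffExprError("empty group")
    if s0 < 0:
        raise DiffExprError("s0 must be >= 0")
    diff = a.mean() - b.mean()
    s = float(_pooled_s(((a - a.mean()) ** 2).sum(), ((b - b.mean()) ** 2).sum(), len(a), len(b)))
    denom = s + s0
    if denom == 0:
        d = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        d = diff / denom
    return float(d), s, float(diff)


def _group_stats(x: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    """Vectorized per-feature mean difference and pooled s for a
    features x samples matrix and two column index arrays."""
    na, nb = len(idx_a), len(idx_b)
    xa, xb = x[:, idx_a], x[:, idx_b]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    ssa = ((xa - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((xb - mb[:, None]) ** 2).sum(axis=1)
    return ma - mb, _pooled_s(ssa, ssb, na, nb)


# ---------------------------------------------------------------------------
# Fudge factor selection
# ---------------------------------------------------------------------------


def choose_s0(diffs: np.ndarray, s: np.ndarray, n_windows: int = 100) -> float:
    """Pick s0 among percentiles {0, 5, ..., 100} of s.

    The winner minimizes the coefficient of variation of the median
    absolute deviation of d computed within s-quantile windows — the
    value that makes the spread of d most uniform across the variance
    range.  Deterministic; ties break to the smallest candidate.
    """
    diffs = np.asarray(diffs, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(s) < 10:
        raise DiffExprError("need >= 10 features to choose s0")
    if np.all(s == 0):
        raise DiffExprError("all features have zero pooled SD")
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    n_windows = min(n_windows, max(2, len(s) // 5))
    windows = np.array_split(order, n_windows)
    best, best_cv = None, None
    for cand in candidates:
        d = diffs / (s + cand) if cand > 0 else np.where(s > 0, diffs / np.maximum(s, 1e-300), 0.0)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in windows])
        mean = mads.mean()
        cv = mads.std() / mean if mean > 0 else 0.0
        if best_cv is None or cv < best_cv - 1e-12 or (abs(cv - best_cv) <= 1e-12 and cand < best):
            best, best_cv = float(cand), cv
    return best


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


@dataclass
class SamTestResult:
    """Per-feature results plus the permutation machinery's byproducts."""

    table: pd.DataFrame  # feature_id, mean_change_pct, delta_log2, d, s, p, q_fdr, direction
    s0: float
    n_perm: int
    exhaustive: bool


def _permutation_indices(n: int, na: int, n_perm: int, rng: np.random.Generator):
    """All (or sampled) assignments of na out of n samples to group A."""
    total = math.comb(n, na)
    if total <= EXHAUSTIVE_LIMIT:
        combos = [np.array(c, dtype=int) for c in itertools.combinations(range(n), na)]
        return combos, True
    combos = [np.sort(rng.choice(n, size=na, replace=False)) for _ in range(n_perm)]
    return combos, False


def sam_test(
    expr: pd.DataFrame,
    labels: Sequence[str],
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    s0: Optional[float] = None,
) -> SamTestResult:
    """Two-group permutation differential expression on log2 expression.

    ``labels`` assigns each column of ``expr`` to a group; ``group_a``
    is reported relative to ``group_b`` (positive change = higher in A).
    When the number of distinct label assignments is at most
    ``EXHAUSTIVE_LIMIT`` all of them are enumerated and p is the exact
    count ratio (the identity assignment included, so p > 0); otherwise
    ``n_perm`` random assignments are drawn and p carries the +1
    correction.
    """
    labels = np.asarray(labels)
    if len(labels) != expr.shape[1]:
        raise DiffExprError("labels do not match expression columns")
    idx_a = np.flatnonzero(labels == group_a)
    idx_b = np.flatnonzero(labels == group_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise DiffExprError("each group needs >= 2 samples")
    cols = np.concatenate([idx_a, idx_b])
    x = expr.to_numpy(dtype=float)[:, cols]
    n, na = len(cols), len(idx_a)

    diffs, s = _group_stats(x, np.arange(na), np.arange(na, n))
    if s0 is None:
        s0 = choose_s0(diffs, s)
    d_obs = diffs / (s + s0)

    rng = np.random.default_rng(seed)
    combos, exhaustive = _permutation_indices(n, na, n_perm, rng)
    all_idx = np.arange(n)
    d_perm = np.empty((x.shape[0], len(combos)))
    for k, ia in enumerate(combos):
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        pd_diff, pd_s = _group_stats(x, ia, ib)
        d_perm[:, k] = pd_diff / (pd_s + s0)

    # p against the pooled permutation distribution of all features (the
    # classic SAM null), which makes p monotone in |d| across features
    abs_obs = np.abs(d_obs)
    pooled = np.sort(np.abs(d_perm).ravel())
    count = pooled.size - np.searchsorted(pooled, abs_obs, side="left")
    if exhaustive:
        p = count / pooled.size
    else:
        p = (1.0 + count) / (1.0 + pooled.size)

    # SAM-style FDR: median over permutations of the count of permuted |d|
    # above the cut, relative to the observed count above the cut.
    n_feat = x.shape[0]
    abs_perm_sorted = np.sort(np.abs(d_perm), axis=0)
    sorted_abs_obs = np.sort(abs_obs)
    n_called = n_feat - np.searchsorted(sorted_abs_obs, abs_obs, side="left")
    counts = np.empty((n_feat, len(combos)))
    for k in range(len(combos)):
        counts[:, k] = n_feat - np.searchsorted(abs_perm_sorted[:, k], abs_obs, side="left")
    q = np.median(counts, axis=1) / np.maximum(n_called, 1)
    q = np.minimum(q, 1.0)

    direction = np.where(diffs > 0, "up", np.where(diffs < 0, "down", "flat"))
    table = pd.DataFrame(
        {
            "feature_id": expr.index,
            "mean_change_pct": 100.0 * (np.exp2(diffs) - 1.0),
            "delta_log2": diffs,
            "d": d_obs,
            "s": s,
            "p": p,
            "q_fdr": q,
            "direction": direction,
        }
    )
    return SamTestResult(table=table, s0=float(s0), n_perm=len(combos), exhaustive=exhaustive)


def signed_significance(table: pd.DataFrame) -> pd.Series:
    """sign(change) * -log10(p) per feature; flat features score 0."""
    if (table["p"] <= 0).any():
        raise DiffExprError("p-values must be > 0")
    sign = np.sign(table["delta_log2"].to_numpy())
    score = sign * -np.log10(table["p"].to_numpy())
    return pd.Series(score, index=table["feature_id"].to_numpy(), name="signed_score")
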