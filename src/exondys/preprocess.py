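"""Array normalization and probe -> probeset -> gene summarization.

The summarization model is the multiplicative expression index
``PM[i, j] = theta[j] * phi[i] + eps`` (sample index ``j``, probe index
``i``), fitted by alternating least squares with a single outlier
re-fit pass.  The scale ambiguity is resolved by the constraint
``sum(phi**2) == n_probes``, which makes ``theta`` carry the intensity
scale: multiplying the input matrix by ``c`` multiplies ``theta`` by
``c`` and leaves ``phi`` unchanged.

Normalization is lowess against a per-probe median pseudo-array: for
each array the locally weighted regression of its log ratio to the
reference (as a function of reference log intensity) is removed, so a
constant or smoothly intensity-dependent bias disappears while the
reference itself is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .formats import IntensityTable


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Lowess normalization
# ---------------------------------------------------------------------------


def lowess_normalize(table: IntensityTable, span: float = 0.3) -> IntensityTable:
    """Remove each array's smooth log-scale bias against the reference
    pseudo-array (the per-probe median of log2 intensity across arrays)."""
    if table.values.shape[1] < 2:
        raise PreprocessError("lowess normalization needs at least 2 samples")
    log2 = np.log2(table.values.to_numpy(dtype=float))
    ref = np.median(log2, axis=1)
    out = np.empty_like(log2)
    for j in range(log2.shape[1]):
        diff = log2[:, j] - ref
        if np.allclose(diff, diff[0]):
            # constant offset: lowess of a constant is that constant
            out[:, j] = log2[:, j] - diff[0]
            continue
        fitted = _sm_lowess(diff, ref, frac=span, return_sorted=False, xvals=ref)
        out[:, j] = log2[:, j] - fitted
    values = pd.DataFrame(
        np.exp2(out), index=table.values.index, columns=table.values.columns
    )
    return IntensityTable(values, table.design.copy())


# ---------------------------------------------------------------------------
# Li-Wong model-based expression index
# ---------------------------------------------------------------------------


@dataclass
class LiWongFit:
    """Fitted multiplicative expression index for one probeset.

    theta : per-sample expression index (length n_samples, >= 0)
    phi : per-probe affinity, normalized to sum(phi**2) == n_probes
    cell_outliers : boolean probes x samples mask of excluded cells
    probe_outliers : boolean per-probe mask (probe excluded entirely)
    sse_path : sum of squared residuals after each ALS iteration (over
        unflagged cells); non-increasing by construction
    """

    theta: np.ndarray
    phi: np.ndarray
    cell_outliers: np.ndarray
    probe_outliers: np.ndarray
    converged: bool
    iterations: int
    sse_path: List[float] = field(default_factory=list)


def _als(y: np.ndarray, mask: np.ndarray, tol: float, max_iter: int):
    """Alternating least squares for y ~ outer(phi, theta) on cells where
    mask is True.  Returns (theta, phi, converged, iterations, sse_path)."""
    n_probes, n_samples = y.shape
    w = mask.astype(float)
    yw = y * w
    theta = yw.sum(axis=0) / np.maximum(w.sum(axis=0), 1.0)
    theta = np.maximum(theta, 1e-12)
    phi = np.ones(n_probes)
    sse_path: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom_phi = (w * theta[None, :] ** 2).sum(axis=1)
        phi_new = (yw * theta[None, :]).sum(axis=1) / np.maximum(denom_phi, 1e-300)
        denom_theta = (w * phi_new[:, None] ** 2).sum(axis=0)
        theta_new = (yw * phi_new[:, None]).sum(axis=0) / np.maximum(denom_theta, 1e-300)
        # identifiability: sum(phi^2) = n_probes
        scale = np.sqrt(np.maximum((phi_new**2).sum(), 1e-300) / n_probes)
        phi_new /= scale
        theta_new *= scale
        resid = y - np.outer(phi_new, theta_new)
        sse_path.append(float((w * resid**2).sum()))
        d_theta = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1e-12))
        d_phi = np.max(np.abs(phi_new - phi) / np.maximum(np.abs(phi), 1e-12))
        theta, phi = theta_new, phi_new
        if max(d_theta, d_phi) < tol:
            converged = True
            break
    return theta, phi, converged, it, sse_path


def liwong_summarize(
    probe_matrix: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 50,
    outlier_sd: float = 3.0,
) -> LiWongFit:
    """Fit the multiplicative model to one probeset's probes-by-samples
    matrix.

    After the first converged fit, cells whose absolute residual exceeds
    ``outlier_sd`` times the residual SD are flagged, probes with more
    than half their cells flagged are dropped entirely, and the model is
    re-fitted once on the remaining cells.  A single-probe probeset
    degenerates to theta = that probe's intensities, phi = (1,).
    """
    y = np.asarray(probe_matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 1 or y.shape[1] < 2:
        raise PreprocessError("need a probes x samples matrix with >= 2 samples")
    if not (y > 0).any():
        raise PreprocessError("all-zero probe matrix")
    n_probes, n_samples = y.shape
    if n_probes == 1:
        return LiWongFit(
            theta=y[0].copy(),
            phi=np.ones(1),
            cell_outliers=np.zeros_like(y, dtype=bool),
            probe_outliers=np.zeros(1, dtype=bool),
            converged=True,
            iterations=0,
            sse_path=[0.0],
        )
    # robust pre-screen on the log scale: the multiplicative model is
    # additive in log2, so a median polish localizes gross corruptions
    # that would otherwise hijack the least-squares fit
    ly = np.log2(np.maximum(y, 1e-12))
    lr = ly - np.median(ly, axis=1, keepdims=True)
    lr = lr - np.median(lr, axis=0, keepdims=True)
    lcentred = np.abs(lr - np.median(lr))
    lscale = 1.4826 * np.median(lcentred)
    if lscale <= 1e-8 * max(lcentred.max(), 1e-300):  # exact data apart from isolated corruptions
        lscale = lcentred.std()
    # residuals at floating-point noise level carry no outlier signal
    if lscale <= 1e-8 * max(np.abs(ly).max(), 1.0):
        pre_flags = np.zeros_like(y, dtype=bool)
    else:
        pre_flags = lcentred > outlier_sd * lscale
    if pre_flags.all(axis=0).any() or pre_flags.all(axis=1).any():
        pre_flags = np.zeros_like(y, dtype=bool)  # degenerate screen; ignore

    mask = ~pre_flags
    theta, phi, converged, it, sse_path = _als(y, mask, tol, max_iter)

    resid = y - np.outer(phi, theta)
    flat = resid[mask]
    # robust scale: a gross outlier would inflate the plain SD enough to
    # mask itself, so the cut uses the MAD-based estimate
    sd = 1.4826 * np.median(np.abs(flat - np.median(flat)))
    if sd == 0:
        sd = flat.std()
    cell_outliers = np.zeros_like(y, dtype=bool)
    probe_outliers = np.zeros(n_probes, dtype=bool)
    if sd > 1e-8 * np.abs(y).mean():  # ignore floating-point-level residuals
        cell_outliers = np.abs(resid) > outlier_sd * sd
    cell_outliers |= pre_flags
    probe_outliers = cell_outliers.mean(axis=1) > 0.5
    cell_outliers[probe_outliers, :] = True
    if cell_outliers.any() and not cell_outliers.all():
        mask = ~cell_outliers
        # keep every sample identified: a sample losing all probes keeps its
        # previous theta
        theta2, phi2, converged, it2, sse2 = _als(y, mask, tol, max_iter)
        dead = mask.sum(axis=0) == 0
        theta2[dead] = theta[dead]
        theta, phi = theta2, phi2
        it += it2
        sse_path = sse2  # objective trace of the final (re)fit
    theta = np.maximum(theta, 0.0)
    return LiWongFit(theta, phi, cell_outliers, probe_outliers, converged, it, sse_path)


def summarize_probesets(
    table: IntensityTable,
    probe_map: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 50,
    outlier_sd: float = 3.0,
) -> pd.DataFrame:
    """Li-Wong-summarize every probeset in the probe map.

    Returns a probesets x samples DataFrame of expression indexes
    (theta), raw intensity scale.
    """
    rows = {}
    values = table.values
    for probeset_id, grp in probe_map.groupby("probeset_id", sort=True):
        probe_ids = [p for p in grp["probe_id"] if p in values.index]
        if not probe_ids:
            continue
        fit = liwong_summarize(
            values.loc[probe_ids].to_numpy(), tol=tol, max_iter=max_iter,
            outlier_sd=outlier_sd,
        )
        rows[probeset_id] = fit.theta
    return pd.DataFrame(rows, index=table.samples).T


def summarize_gene_level(
    probeset_expr: pd.DataFrame,
    mapping: Mapping[str, str],
    tol: float = 1e-6,
    max_iter: int = 50,
    outlier_sd: float = 3.0,
) -> pd.DataFrame:
    """Summarize sense probeset expression indexes into gene-level indexes.

    ``mapping`` maps probeset_id -> gene_id and must contain only the
    probesets to use (antisense probesets are the caller's job to
    exclude).  Probesets play the probe role in a second Li-Wong fit.
    """
    per_gene: Dict[str, List[str]] = {}
    for ps, gene in mapping.items():
        if ps in probeset_expr.index:
            per_gene.setdefault(gene, []).append(ps)
    if not per_gene:
        raise PreprocessError("no probeset maps to any gene")
    rows = {}
    for gene in sorted(per_gene):
        ps_ids = sorted(per_gene[gene])
        sub = probeset_expr.loc[ps_ids].to_numpy()
        if sub.shape[0] == 0:
            raise PreprocessError(f"gene {gene} has zero sense probesets")
        fit = liwong_summarize(sub, tol=tol, max_iter=max_iter, outlier_sd=outlier_sd)
        rows[gene] = fit.theta
    return pd.DataFrame(rows, index=probeset_expr.columns).T


# ---------------------------------------------------------------------------
# Effective probesets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectiveFlag:
    probeset_id: str
    effective: bool
    background_z: float


def detect_effective_probesets(
    expr: pd.DataFrame,
    background_ids: Iterable[str],
    n_sd: float = 2.0,
    min_fraction: float = 0.5,
) -> List[EffectiveFlag]:
    """Flag probesets whose signal rises above array background.

    A probeset is effective iff its log2 expression exceeds the pooled
    background mean + ``n_sd`` background SDs in at least
    ``min_fraction`` of samples.  ``background_z`` is the probeset's
    mean log2 expression in background-SD units.
    """
    background_ids = [b for b in background_ids if b in expr.index]
    if not background_ids:
        raise PreprocessError("empty background probeset set")
    log2 = np.log2(np.maximum(expr.to_numpy(dtype=float), 1e-12))
    bg = np.log2(np.maximum(expr.loc[background_ids].to_numpy(dtype=float), 1e-12))
    bg_mean, bg_sd = float(bg.mean()), float(bg.std())
    if bg_sd == 0:
        bg_sd = 1e-12
    threshold = bg_mean + n_sd * bg_sd
    above = (log2 > threshold).mean(axis=1)
    zs = (log2.mean(axis=1) - bg_mean) / bg_sd
    return [
        EffectiveFlag(str(pid), bool(frac >= min_fraction), float(z))
        for pid, frac, z in zip(expr.index, above, zs)
    ]


# ---------------------------------------------------------------------------
# PCA embedding of samples
# ---------------------------------------------------------------------------


def pca_embed(gene_expr: pd.DataFrame, n_components: int = 2):
    """Project samples onto principal components of mean-centred log2
    expression.

    Returns ``(coords, explained)`` where coords is a samples x K frame
    and explained the fraction of variance per component (non-increasing,
    summing to <= 1).
    """
    if gene_expr.shape[1] < 3:
        raise PreprocessError("PCA needs at least 3 samples")
    x = np.log2(np.maximum(gene_expr.to_numpy(dtype=float), 1e-12))
    x = x - x.mean(axis=1, keepdims=True)
    if np.allclose(x, 0):
        raise PreprocessError("constant expression matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        (vt[:k].T * s[:k]),
        index=gene_expr.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    var = s**2
    explained = var[:k] / var.sum()
    return coords, explained
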