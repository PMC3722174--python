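"""Cross-tissue synthesis: inverse-dysregulation correlation, 8-subset
classification, DerSimonian-Laird meta-correlation, correlation screens.

The meta-analysis combines per-group Pearson correlations on the Fisher
z scale with sampling variance ``v_k = 1/(n_k - 3)`` and the
DerSimonian-Laird moment estimator of the between-group variance tau^2;
random-effects weights are ``1/(v_k + tau^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

_R_CLAMP = 0.999999


class CrossTissueError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Quadrant classification
# ---------------------------------------------------------------------------

SUBSETS = (
    "both_up_up", "both_up_down", "both_down_up", "both_down_down",
    "muscle_only_up", "muscle_only_down", "fcl_only_up", "fcl_only_down",
)


@dataclass(frozen=True)
class QuadrantAssignment:
    gene_id: str
    subset: Optional[str]  # one of SUBSETS or None (unclassified)


def quadrant_classify(
    muscle_results: pd.DataFrame,
    fcl_results: pd.DataFrame,
    p_cut: float = 0.05,
) -> Tuple[List[QuadrantAssignment], Dict[str, float]]:
    """Classify each shared gene into one of 8 subsets by which tissues it
    is significant in and the direction in each.

    Returns the assignments plus summary counts including
    ``inverse_fraction``: among genes significant in both tissues, the
    fraction changing in opposite directions.
    """
    m = muscle_results.set_index("feature_id")
    f = fcl_results.set_index("feature_id")
    shared = m.index.intersection(f.index)
    if len(shared) == 0:
        raise CrossTissueError("empty shared gene universe")
    assignments: List[QuadrantAssignment] = []
    counts = {s: 0 for s in SUBSETS}
    for gene in shared:
        pm, pf = float(m.loc[gene, "p"]), float(f.loc[gene, "p"])
        dm = "up" if m.loc[gene, "delta_log2"] > 0 else "down"
        df = "up" if f.loc[gene, "delta_log2"] > 0 else "down"
        sig_m, sig_f = pm < p_cut, pf < p_cut
        if sig_m and sig_f:
            subset = f"both_{dm}_{df}"
        elif sig_m:
            subset = f"muscle_only_{dm}"
        elif sig_f:
            subset = f"fcl_only_{df}"
        else:
            subset = None
        if subset:
            counts[subset] += 1
        assignments.append(QuadrantAssignment(str(gene), subset))
    n_both = sum(counts[s] for s in SUBSETS[:4])
    n_inverse = counts["both_up_down"] + counts["both_down_up"]
    summary: Dict[str, float] = dict(counts)
    summary["n_both_significant"] = n_both
    summary["n_inverse"] = n_inverse
    summary["inverse_fraction"] = n_inverse / n_both if n_both else float("nan")
    summary["n_classified"] = sum(counts.values())
    return assignments, summary


def crosstissue_correlation(
    signed_scores_muscle: pd.Series, signed_scores_fcl: pd.Series
) -> Tuple[float, float]:
    """Pearson correlation of signed significance scores over the shared
    gene universe."""
    shared = signed_scores_muscle.index.intersection(signed_scores_fcl.index)
    if len(shared) < 10:
        raise CrossTissueError("need >= 10 shared genes")
    a = signed_scores_muscle.loc[shared].to_numpy(dtype=float)
    b = signed_scores_fcl.loc[shared].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise CrossTissueError("constant score vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# DerSimonian-Laird meta-correlation
# ---------------------------------------------------------------------------


@dataclass
class MetaCorrelation:
    gene_a: str
    gene_b: str
    group_labels: Tuple[str, ...]
    r_per_group: np.ndarray
    n_per_group: np.ndarray
    z_per_group: np.ndarray
    v_per_group: np.ndarray
    Q: float
    tau2: float
    combined_z: float
    combined_r: float
    se: float
    p: float


def combine_correlations_dl(
    r_values: Sequence[float], n_values: Sequence[int], labels: Optional[Sequence[str]] = None,
    gene_a: str = "", gene_b: str = "",
) -> MetaCorrelation:
    """DerSimonian-Laird random-effects combination of correlations.

    Fisher z transform with v_k = 1/(n_k - 3); Q on fixed-effect
    weights; tau2 = max(0, (Q - (K-1)) / (sum(w) - sum(w^2)/sum(w)));
    the combined z is the 1/(v_k + tau2)-weighted mean, back-transformed
    with tanh; p from the normal approximation.
    """
    r = np.asarray(r_values, dtype=float)
    n = np.asarray(n_values, dtype=float)
    if len(r) < 1:
        raise CrossTissueError("need at least one group")
    if (n < 4).any():
        raise CrossTissueError("every group needs n >= 4")
    if (np.abs(r) >= 1).any():
        warnings.warn("|r| = 1 clamped for the Fisher transform")
        r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    v = 1.0 / (n - 3.0)
    w = 1.0 / v
    k = len(r)
    z_fixed = (w * z).sum() / w.sum()
    Q = float((w * (z - z_fixed) ** 2).sum())
    if k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_re = 1.0 / (v + tau2)
    combined_z = float((w_re * z).sum() / w_re.sum())
    se = float(np.sqrt(1.0 / w_re.sum()))
    p = float(2.0 * stats.norm.sf(abs(combined_z) / se))
    return MetaCorrelation(
        gene_a=gene_a,
        gene_b=gene_b,
        group_labels=tuple(labels) if labels is not None else tuple(str(i) for i in range(k)),
        r_per_group=r,
        n_per_group=n,
        z_per_group=z,
        v_per_group=v,
        Q=Q,
        tau2=tau2,
        combined_z=combined_z,
        combined_r=float(np.tanh(combined_z)),
        se=se,
        p=p,
    )


def meta_correlation(
    expr: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    design: pd.DataFrame,
) -> MetaCorrelation:
    """Combined correlation of two genes across tissue x disease groups.

    ``expr`` is genes x samples log2 expression; groups are the cells of
    the design's tissue x disease cross, each needing n >= 4.
    """
    for g in (gene_a, gene_b):
        if g not in expr.index:
            raise CrossTissueError(f"gene {g!r} absent from expression matrix")
    rs, ns, labels = [], [], []
    for (tissue, disease), grp in design.groupby(["tissue", "disease"], sort=True):
        samples = [s for s in grp.index if s in expr.columns]
        if len(samples) < 4:
            raise CrossTissueError(f"group {tissue}/{disease} has n < 4")
        a = expr.loc[gene_a, samples].to_numpy(dtype=float)
        b = expr.loc[gene_b, samples].to_numpy(dtype=float)
        rs.append(float(stats.pearsonr(a, b)[0]) if np.ptp(a) and np.ptp(b) else 0.0)
        ns.append(len(samples))
        labels.append(f"{tissue}/{disease}")
    return combine_correlations_dl(rs, ns, labels, gene_a=gene_a, gene_b=gene_b)


def geneset_meta_correlation_summary(
    focal_gene: str,
    gene_set: Iterable[str],
    expr: pd.DataFrame,
    design: pd.DataFrame,
) -> Tuple[pd.DataFrame, float, float]:
    """Meta-correlation of a focal gene against every member of a gene
    set, with a one-sample t-test of the combined r values against 0.

    The focal gene is excluded from the set (with a warning) if present.
    """
    members = sorted(set(gene_set) & set(expr.index))
    if focal_gene in members:
        warnings.warn(f"focal gene {focal_gene} removed from its own gene set")
        members.remove(focal_gene)
    if len(members) < 3:
        raise CrossTissueError("gene set needs >= 3 members")
    rows = []
    for gene in members:
        mc = meta_correlation(expr, focal_gene, gene, design)
        rows.append({"gene": gene, "combined_r": mc.combined_r, "tau2": mc.tau2, "p": mc.p})
    table = pd.DataFrame(rows)
    t = stats.ttest_1samp(table["combined_r"], 0.0)
    return table, float(table["combined_r"].mean()), float(t.pvalue)


# ---------------------------------------------------------------------------
# Correlation screen
# ---------------------------------------------------------------------------


def correlation_screen(
    focal_gene: str,
    expr_by_tissue: Mapping[str, pd.DataFrame],
    r_cut: float = 0.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Genes positively and significantly correlated with the focal gene
    in *every* tissue dataset.

    ``expr_by_tissue`` maps tissue -> genes x samples log2 expression
    (typically disease samples only).  The focal gene is excluded from
    its own output.
    """
    if not expr_by_tissue:
        raise CrossTissueError("no tissue datasets provided")
    per_tissue = []
    for tissue, expr in expr_by_tissue.items():
        if focal_gene not in expr.index:
            raise CrossTissueError(f"focal gene absent from tissue {tissue!r}")
        focal = expr.loc[focal_gene].to_numpy(dtype=float)
        rows = []
        for gene in expr.index:
            if gene == focal_gene:
                continue
            vals = expr.loc[gene].to_numpy(dtype=float)
            if np.ptp(vals) == 0 or np.ptp(focal) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(focal, vals)
            rows.append({"gene": gene, f"r_{tissue}": r, f"p_{tissue}": p})
        per_tissue.append(pd.DataFrame(rows).set_index("gene"))
    merged = pd.concat(per_tissue, axis=1, join="inner")
    keep = np.ones(len(merged), dtype=bool)
    for tissue in expr_by_tissue:
        keep &= (merged[f"r_{tissue}"] > r_cut).to_numpy()
        keep &= (merged[f"p_{tissue}"] < p_cut).to_numpy()
    return merged[keep].reset_index()
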