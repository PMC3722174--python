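"""UTR-centric analyses: AU-rich element classes, positional degradation
profiles, 5'-UTR baseline association and the terminal oligopyrimidine
motif.

AU-rich elements (AREs) destabilize mRNAs via ARE-binding proteins.
All AREs share the AUUUA core; more committed elements extend it with
A/U ("W") flanks, giving the ladder

    mer5   AUUUA
    mer7   W AUUUA W
    mer9   WW AUUUA WW
    mer11  WWW AUUUA WWW
    mer13  WWWW AUUUA WWWW

A 3'-UTR is assigned the *longest* motif it contains; the ladder is
monotone (a mer13 match implies matches of every shorter form).  Input
is DNA (U == T); N never matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

ARE_CLASSES = ("none", "mer5", "mer7", "mer9", "mer11", "mer13")
_CORE = "ATTTA"
_W = frozenset("AT")


class UtrError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ARE classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AreAnnotation:
    gene_id: str
    are_class: str
    match_positions: Tuple[int, ...]  # 0-based offsets of the AUUUA core


def classify_are(utr_sequence: str, gene_id: str = "") -> AreAnnotation:
    """Assign a 3'-UTR its most complex ARE class.

    Scans every overlapping AUUUA core and measures the run of W
    (A/U) characters immediately flanking it on both sides; the class
    level is the shorter of the two runs, capped at 4 extra W per side
    (the 13-mer).
    """
    seq = utr_sequence.upper().replace("U", "T")
    if len(seq) == 0:
        raise UtrError("empty sequence")
    best = -1
    positions: List[int] = []
    start = seq.find(_CORE)
    while start != -1:
        positions.append(start)
        left = 0
        i = start - 1
        while i >= 0 and seq[i] in _W and left < 4:
            left += 1
            i -= 1
        right = 0
        i = start + len(_CORE)
        while i < len(seq) and seq[i] in _W and right < 4:
            right += 1
            i += 1
        best = max(best, min(left, right))
        start = seq.find(_CORE, start + 1)
    are_class = "none" if best < 0 else ARE_CLASSES[best + 1]
    return AreAnnotation(gene_id, are_class, tuple(positions))


def are_group_change_test(
    annotations: Mapping[str, str],
    three_utr_changes: Mapping[str, float],
) -> pd.DataFrame:
    """Mean 3'-UTR percent change per ARE class, Welch-tested against the
    no-ARE class.

    ``annotations`` maps gene -> ARE class, ``three_utr_changes`` maps
    gene -> mean percent change of its 3'-UTR.  Classes with fewer than
    2 genes are skipped with a warning.
    """
    ann = pd.Series(dict(annotations))
    chg = pd.Series(dict(three_utr_changes))
    shared = ann.index.intersection(chg.index)
    ann, chg = ann.loc[shared], chg.loc[shared]
    none_vals = chg[ann == "none"].to_numpy()
    if len(none_vals) < 2:
        raise UtrError("fewer than 2 genes in the no-ARE comparison class")
    rows = []
    for cls in ARE_CLASSES:
        vals = chg[ann == cls].to_numpy()
        if len(vals) < 2:
            if len(vals):
                warnings.warn(f"ARE class {cls} has < 2 genes; skipped")
            continue
        if cls == "none":
            p = 1.0
        elif np.ptp(np.concatenate([vals, none_vals])) == 0:
            p = 1.0  # all changes identical: no evidence of a shift
        else:
            p = float(stats.ttest_ind(vals, none_vals, equal_var=False).pvalue)
        rows.append(
            {"are_class": cls, "n": len(vals), "mean_change_pct": float(vals.mean()), "p_vs_none": p}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Positional degradation profile
# ---------------------------------------------------------------------------


@dataclass
class PositionalProfile:
    region_kind: str
    bins: pd.DataFrame  # bin, position, control_mean, disease_mean, diff, diff_smooth
    gradient: float  # least-squares slope of the (disease - control) curve


def positional_profile(
    adjusted_log2: pd.DataFrame,
    relative_positions: Mapping[str, float],
    design: pd.DataFrame,
    region_kind: str = "three_utr",
    span: float = 0.3,
    n_bins: int = 100,
    disease_label: str = "RC",
    control_label: str = "control",
) -> PositionalProfile:
    """Bin exon-adjusted probe intensities into 1% position intervals.

    ``adjusted_log2`` holds probe log2 intensities already adjusted for
    the adjacent exon of the same gene (probes x samples);
    ``relative_positions`` maps probe -> relative position in [0, 1]
    with 0 at the transcript's 5' end (strand already accounted for).
    The gradient is the least-squares slope of the smoothed
    disease-minus-control difference over non-missing bins.
    """
    probes = [p for p in adjusted_log2.index if p in relative_positions]
    if not probes:
        raise UtrError(f"no probes with positions for region {region_kind}")
    x = adjusted_log2.loc[probes]
    pos = np.array([relative_positions[p] for p in probes])
    bin_idx = np.minimum((pos * n_bins).astype(int), n_bins - 1)
    ctrl_samples = design.index[design["disease"] == control_label]
    dis_samples = design.index[design["disease"] == disease_label]
    ctrl = x[ctrl_samples].mean(axis=1).to_numpy()
    dis = x[dis_samples].mean(axis=1).to_numpy()

    rows = []
    for b in range(n_bins):
        sel = bin_idx == b
        rows.append(
            {
                "bin": b,
                "position": (b + 0.5) / n_bins,
                "n_probes": int(sel.sum()),
                "control_mean": float(ctrl[sel].mean()) if sel.any() else np.nan,
                "disease_mean": float(dis[sel].mean()) if sel.any() else np.nan,
            }
        )
    bins = pd.DataFrame(rows)
    bins["diff"] = bins["disease_mean"] - bins["control_mean"]
    ok = bins["diff"].notna()
    if ok.sum() < 2:
        raise UtrError("fewer than 2 non-empty position bins")
    smooth = _sm_lowess(
        bins.loc[ok, "diff"].to_numpy(), bins.loc[ok, "position"].to_numpy(),
        frac=span, return_sorted=False,
    )
    bins["diff_smooth"] = np.nan
    bins.loc[ok, "diff_smooth"] = smooth
    slope = float(np.polyfit(bins.loc[ok, "position"], bins.loc[ok, "diff_smooth"], 1)[0])
    return PositionalProfile(region_kind=region_kind, bins=bins, gradient=slope)


# ---------------------------------------------------------------------------
# 5'-UTR baseline association
# ---------------------------------------------------------------------------


def baseline_abundance_association(
    five_utr_baseline: Mapping[str, float],
    five_utr_change: Mapping[str, float],
    span: float = 0.3,
) -> Tuple[float, float, pd.DataFrame]:
    """Spearman association between relative 5'-UTR baseline abundance and
    its percent change in disease, with a lowess trend for plotting.

    Baseline is mean control log2(5'-UTR index) minus mean control
    log2(gene index) — the 5'-UTR level relative to its own gene.
    """
    base = pd.Series(dict(five_utr_baseline))
    chg = pd.Series(dict(five_utr_change))
    shared = base.index.intersection(chg.index)
    if len(shared) < 10:
        raise UtrError("need >= 10 genes")
    base, chg = base.loc[shared].astype(float), chg.loc[shared].astype(float)
    if np.allclose(base, base.iloc[0]):
        raise UtrError("constant baseline vector")
    rho, p = stats.spearmanr(base, chg)
    order = np.argsort(base.to_numpy(), kind="stable")
    trend_fit = _sm_lowess(chg.to_numpy()[order], base.to_numpy()[order], frac=span)
    trend = pd.DataFrame({"baseline": trend_fit[:, 0], "trend": trend_fit[:, 1]})
    return float(rho), float(p), trend


# ---------------------------------------------------------------------------
# TOP motif
# ---------------------------------------------------------------------------


def detect_top_motif(five_utr_start_sequence: str, min_run: int = 5, max_window: int = 15) -> bool:
    """Detect a 5' terminal oligopyrimidine tract.

    True iff the sequence starts with C and the initial run of
    pyrimidines (C/T) reaches at least ``min_run`` bases within the
    first ``max_window`` bases.  The default run of 5 corresponds to a
    C start followed by >= 4 further pyrimidines.
    """
    seq = five_utr_start_sequence.upper().replace("U", "T")
    if len(seq) < 6:
        raise UtrError("sequence shorter than 6 bases")
    if seq[0] != "C":
        return False
    run = 0
    for ch in seq[:max_window]:
        if ch in "CT":
            run += 1
        else:
            break
    return run >= min_run
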