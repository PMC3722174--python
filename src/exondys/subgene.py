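"""Sub-gene (UTR / exon / antisense) alternative expression analysis.

A gene-region's representative is its smallest-p probeset, Bonferroni
corrected by the number of probesets in that gene-region.  A
representative indicates an alternative event when its adjusted p falls
below 0.05 and either (a) it moves in the opposite direction from the
gene-level change, or (b) its raw p is much smaller than the gene-level
p (``gene_p / p_raw >= ratio_k``; the ratio threshold is a configurable
concretization of "significantly smaller").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


class SubgeneError(ValueError):
    pass


@dataclass(frozen=True)
class AlternativeEvent:
    gene_id: str
    region_kind: str
    probeset_id: str
    p_raw: float
    p_adj: float
    gene_p: float
    same_direction: bool
    event: bool
    event_reason: Optional[str]  # "opposite_direction" | "stronger_than_gene" | None


def select_region_representative(probeset_results: pd.DataFrame) -> pd.Series:
    """Smallest-raw-p probeset of one gene-region, Bonferroni adjusted by
    the number of probesets in the region.  Ties break to the
    lexicographically smallest probeset_id."""
    if len(probeset_results) == 0:
        raise SubgeneError("no probeset results for region")
    df = probeset_results.sort_values(["p", "feature_id"], kind="stable")
    rep = df.iloc[0].copy()
    rep["p_adj"] = min(1.0, float(rep["p"]) * len(df))
    return rep


def detect_alternative_events(
    probeset_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    probeset_to_gene: Mapping[str, str],
    probeset_to_region: Mapping[str, str],
    ratio_k: float = 10.0,
    alpha: float = ALPHA,
) -> List[AlternativeEvent]:
    """Call alternative expression events per gene-region.

    ``probeset_results`` and ``gene_results`` are SAM tables (columns
    feature_id, p, delta_log2, ...).  Antisense probesets are treated
    as their own region of the gene.
    """
    gene_idx = gene_results.set_index("feature_id")
    events: List[AlternativeEvent] = []
    ps = probeset_results.copy()
    ps["gene_id"] = [probeset_to_gene.get(f) for f in ps["feature_id"]]
    ps["region_kind"] = [probeset_to_region.get(f) for f in ps["feature_id"]]
    ps = ps.dropna(subset=["gene_id", "region_kind"])
    for (gene_id, region), grp in ps.groupby(["gene_id", "region_kind"], sort=True):
        if gene_id not in gene_idx.index:
            raise SubgeneError(f"missing gene-level result for {gene_id}")
        rep = select_region_representative(grp)
        gene_row = gene_idx.loc[gene_id]
        gene_p = float(gene_row["p"])
        same_direction = np.sign(rep["delta_log2"]) == np.sign(gene_row["delta_log2"])
        reason = None
        if float(rep["p_adj"]) < alpha:
            if not same_direction and rep["delta_log2"] != 0:
                reason = "opposite_direction"
            elif float(rep["p"]) > 0 and gene_p / float(rep["p"]) >= ratio_k:
                reason = "stronger_than_gene"
        events.append(
            AlternativeEvent(
                gene_id=str(gene_id),
                region_kind=str(region),
                probeset_id=str(rep["feature_id"]),
                p_raw=float(rep["p"]),
                p_adj=float(rep["p_adj"]),
                gene_p=gene_p,
                same_direction=bool(same_direction),
                event=reason is not None,
                event_reason=reason,
            )
        )
    return events


def events_frame(events: Sequence[AlternativeEvent]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in events])


def summarize_region_changes(
    probeset_results: pd.DataFrame,
    probeset_to_gene: Mapping[str, str],
    probeset_to_region: Mapping[str, str],
    effective_ids: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-region counts of genes analyzed / up / down.

    A gene counts as up (down) in a region when its region
    representative has Bonferroni-adjusted p < alpha and positive
    (negative) change.  Antisense rows only count effective probesets;
    pass ``effective_ids`` to apply the filter.
    """
    ps = probeset_results.copy()
    ps["gene_id"] = [probeset_to_gene.get(f) for f in ps["feature_id"]]
    ps["region_kind"] = [probeset_to_region.get(f) for f in ps["feature_id"]]
    ps = ps.dropna(subset=["gene_id", "region_kind"])
    if effective_ids is not None:
        eff = set(effective_ids)
        keep = (ps["region_kind"] != "antisense") | ps["feature_id"].isin(eff)
        ps = ps[keep]
    rows = []
    for region in ("five_utr", "three_utr", "exon", "antisense"):
        sub = ps[ps["region_kind"] == region]
        n_genes = sub["gene_id"].nunique()
        up = down = 0
        for gene_id, grp in sub.groupby("gene_id", sort=True):
            rep = select_region_representative(grp)
            if float(rep["p_adj"]) < alpha:
                if rep["delta_log2"] > 0:
                    up += 1
                elif rep["delta_log2"] < 0:
                    down += 1
        rows.append({"region_kind": region, "n_genes": n_genes, "n_up": up, "n_down": down})
    return pd.DataFrame(rows)


def sense_antisense_concordance(
    sense_results: pd.DataFrame,
    antisense_results: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = ALPHA,
) -> Tuple[float, float, pd.DataFrame]:
    """Correlate baseline abundance and disease-control change between
    sense/antisense probeset pairs.

    ``pairs`` has columns ``sense_id`` and ``antisense_id``; both result
    frames need columns feature_id, baseline_log2, delta_log2, p_adj.
    Returns (baseline_r, delta_r, outliers) where outliers are pairs
    with significant changes of opposite sign.
    """
    if len(pairs) < 3:
        raise SubgeneError("need >= 3 sense/antisense pairs")
    s = sense_results.set_index("feature_id")
    a = antisense_results.set_index("feature_id")
    merged = pairs.copy()
    for col in ("baseline_log2", "delta_log2", "p_adj"):
        merged[f"sense_{col}"] = s.loc[merged["sense_id"], col].to_numpy()
        merged[f"antisense_{col}"] = a.loc[merged["antisense_id"], col].to_numpy()
    baseline_r = float(
        stats.pearsonr(merged["sense_baseline_log2"], merged["antisense_baseline_log2"])[0]
    )
    delta_r = float(stats.pearsonr(merged["sense_delta_log2"], merged["antisense_delta_log2"])[0])
    opposite = np.sign(merged["sense_delta_log2"]) * np.sign(merged["antisense_delta_log2"]) < 0
    significant = (merged["sense_p_adj"] < alpha) & (merged["antisense_p_adj"] < alpha)
    outliers = merged[opposite & significant].reset_index(drop=True)
    return baseline_r, delta_r, outliers
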