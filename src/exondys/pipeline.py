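"""End-to-end orchestration: normalize -> summarize -> differential
expression per tissue -> sub-gene events -> UTR statistics -> regulator
activity -> cross-tissue synthesis.

:func:`analyze` runs the whole chain in memory on an intensity table
plus its annotation; :func:`run_pipeline` wraps it with file input /
output and JSON sidecars.  A single global seed fans out to per-stage
seeds through a fixed :class:`numpy.random.SeedSequence` derivation, so
any stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import crosstissue as ct
from . import diffexpr, formats, preprocess, regulators, subgene, utr
from .formats import GeneModel, IntensityTable

log = logging.getLogger("exondys")

STAGES = ("preprocess", "diffexp", "subgene", "utr", "regulators", "crosstissue")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Every tunable of the pipeline, validated before any stage runs."""

    input_dir: str = "."
    output_dir: str = "run"
    seed: int = 0
    n_perm: int = 300
    lowess_span: float = 0.3
    liwong_tol: float = 1e-6
    liwong_max_iter: int = 50
    outlier_sd: float = 3.0
    effective_sd: float = 2.0
    effective_fraction: float = 0.5
    ratio_k: float = 10.0
    alpha: float = 0.05
    p_cut: float = 0.05
    pwm_similarity: float = 0.95
    s0: Optional[float] = None  # None = data-driven choice
    stages: Tuple[str, ...] = STAGES
    disease_label: str = "RC"
    control_label: str = "control"

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise PipelineError(f"unknown stage(s): {sorted(bad)}")
        return cfg

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))

    def as_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


# ---------------------------------------------------------------------------
# Annotation helpers
# ---------------------------------------------------------------------------


def probeset_maps(probe_map: pd.DataFrame) -> Tuple[Dict[str, str], Dict[str, str]]:
    """(probeset -> gene, probeset -> region_kind) from a probe map."""
    dedup = probe_map.drop_duplicates("probeset_id")
    return (
        dict(zip(dedup["probeset_id"], dedup["gene_id"])),
        dict(zip(dedup["probeset_id"], dedup["region_kind"])),
    )


def sense_mapping(probe_map: pd.DataFrame) -> Dict[str, str]:
    """probeset -> gene for sense probesets of real genes only."""
    dedup = probe_map.drop_duplicates("probeset_id")
    keep = (dedup["region_kind"] != "antisense") & (dedup["gene_id"] != "BACKGROUND")
    return dict(zip(dedup.loc[keep, "probeset_id"], dedup.loc[keep, "gene_id"]))


def transcript_last_exon_probeset(model: GeneModel) -> Optional[str]:
    """Probeset of the exon adjacent to the 3'-UTR (transcript order)."""
    exons = model.segments_of("exon")
    if not exons:
        return None
    last = max(exons, key=lambda s: s.start) if model.strand == "+" else min(
        exons, key=lambda s: s.start
    )
    for ps in model.probesets_of("exon"):
        if ps.probes and last.start <= ps.probes[0].start < last.end:
            return ps.probeset_id
    return None


def transcript_first_exon_probeset(model: GeneModel) -> Optional[str]:
    exons = model.segments_of("exon")
    if not exons:
        return None
    first = min(exons, key=lambda s: s.start) if model.strand == "+" else max(
        exons, key=lambda s: s.start
    )
    for ps in model.probesets_of("exon"):
        if ps.probes and first.start <= ps.probes[0].start < first.end:
            return ps.probeset_id
    return None


# ---------------------------------------------------------------------------
# In-memory analysis
# ---------------------------------------------------------------------------


def analyze(
    intensity: IntensityTable,
    probe_map: pd.DataFrame,
    config: Optional[RunConfig] = None,
    sequences: Optional[Mapping[str, str]] = None,
    pwm_library: Optional[Mapping[str, regulators.Pwm]] = None,
    models: Optional[Mapping[str, GeneModel]] = None,
    background_ids: Optional[Sequence[str]] = None,
) -> Dict:
    """Run the full analysis chain in memory; returns a results dict."""
    cfg = config or RunConfig()
    results: Dict = {"config": cfg.as_dict()}
    tissues = sorted(intensity.design["tissue"].unique())
    dis, ctl = cfg.disease_label, cfg.control_label

    # --- preprocess -------------------------------------------------------
    log.info("normalizing %d probes x %d samples", *intensity.values.shape)
    normalized = preprocess.lowess_normalize(intensity, span=cfg.lowess_span)
    probeset_expr = preprocess.summarize_probesets(
        normalized, probe_map, tol=cfg.liwong_tol, max_iter=cfg.liwong_max_iter,
        outlier_sd=cfg.outlier_sd,
    )
    gene_expr = preprocess.summarize_gene_level(
        probeset_expr, sense_mapping(probe_map), tol=cfg.liwong_tol,
        max_iter=cfg.liwong_max_iter, outlier_sd=cfg.outlier_sd,
    )
    ps_to_gene, ps_to_region = probeset_maps(probe_map)
    if background_ids is None:
        background_ids = [p for p, g in ps_to_gene.items() if g == "BACKGROUND"]
    if not background_ids:
        # fall back: lowest-decile antisense probesets stand in for background
        anti = [p for p, r in ps_to_region.items() if r == "antisense" and p in probeset_expr.index]
        means = probeset_expr.loc[anti].mean(axis=1)
        background_ids = list(means.sort_values().index[: max(1, len(anti) // 10)])
    effective = preprocess.detect_effective_probesets(
        probeset_expr, background_ids, n_sd=cfg.effective_sd,
        min_fraction=cfg.effective_fraction,
    )
    effective_ids = [f.probeset_id for f in effective if f.effective]
    pca_coords, pca_explained = preprocess.pca_embed(gene_expr)
    results.update(
        normalized=normalized, probeset_expr=probeset_expr, gene_expr=gene_expr,
        effective=effective, effective_ids=effective_ids,
        pca_coords=pca_coords, pca_explained=pca_explained,
    )

    # --- differential expression per tissue ------------------------------
    sam_gene: Dict[str, pd.DataFrame] = {}
    sam_probeset: Dict[str, pd.DataFrame] = {}
    signed: Dict[str, pd.Series] = {}
    seed_diff = cfg.stage_seed("diffexp")
    for tissue in tissues:
        samples = intensity.samples_where(tissue=tissue)
        labels = intensity.design.loc[samples, "disease"]
        glog2 = np.log2(np.maximum(gene_expr[samples], 1e-12))
        res = diffexpr.sam_test(glog2, labels, dis, ctl, n_perm=cfg.n_perm,
                                seed=seed_diff, s0=cfg.s0)
        sam_gene[tissue] = res.table
        signed[tissue] = diffexpr.signed_significance(res.table)
        plog2 = np.log2(np.maximum(probeset_expr[samples], 1e-12))
        res_ps = diffexpr.sam_test(plog2, labels, dis, ctl, n_perm=cfg.n_perm,
                                   seed=seed_diff + 1, s0=cfg.s0)
        sam_probeset[tissue] = res_ps.table
    results.update(sam_gene=sam_gene, sam_probeset=sam_probeset, signed_scores=signed)

    # --- sub-gene events --------------------------------------------------
    events: Dict[str, pd.DataFrame] = {}
    region_summary: Dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        ps_tab = sam_probeset[tissue]
        ps_tab = ps_tab[ps_tab["feature_id"].map(ps_to_gene).ne("BACKGROUND")]
        evs = subgene.detect_alternative_events(
            ps_tab, sam_gene[tissue], ps_to_gene, ps_to_region,
            ratio_k=cfg.ratio_k, alpha=cfg.alpha,
        )
        events[tissue] = subgene.events_frame(evs)
        region_summary[tissue] = subgene.summarize_region_changes(
            ps_tab, ps_to_gene, ps_to_region,
            effective_ids=effective_ids, alpha=cfg.alpha,
        )
    results.update(events=events, region_summary=region_summary)

    # --- UTR analyses -----------------------------------------------------
    if sequences is not None and models is not None:
        annotations = {
            g: utr.classify_are(sequences[f"{g}_three_utr"], g).are_class
            for g in models if f"{g}_three_utr" in sequences
        }
        results["are_annotations"] = annotations
        are_tables: Dict[str, pd.DataFrame] = {}
        for tissue in tissues:
            ps_tab = sam_probeset[tissue].set_index("feature_id")
            changes = {}
            for gene, model in models.items():
                utr3 = [p.probeset_id for p in model.probesets_of("three_utr")
                        if p.probeset_id in ps_tab.index and p.probeset_id in set(effective_ids)]
                if utr3:
                    changes[gene] = float(ps_tab.loc[utr3, "mean_change_pct"].mean())
            are_tables[tissue] = utr.are_group_change_test(annotations, changes)
        results["are_tables"] = are_tables
        results["top_motifs"] = {
            g: utr.detect_top_motif(sequences[f"{g}_five_utr"])
            for g in models
            if f"{g}_five_utr" in sequences and len(sequences[f"{g}_five_utr"]) >= 6
        }

        positional: Dict[str, utr.PositionalProfile] = {}
        baseline_assoc: Dict[str, Tuple[float, float, pd.DataFrame]] = {}
        norm_log2 = normalized.log2()
        for tissue in tissues:
            samples = intensity.samples_where(tissue=tissue)
            design_t = intensity.design.loc[samples]
            adjusted_rows, relpos = {}, {}
            for gene, model in models.items():
                exon_ps = transcript_last_exon_probeset(model)
                if exon_ps is None or exon_ps not in probeset_expr.index:
                    continue
                exon_log2 = np.log2(np.maximum(probeset_expr.loc[exon_ps, samples], 1e-12))
                for ps in model.probesets_of("three_utr"):
                    for probe in ps.probes:
                        if probe.probe_id in norm_log2.index:
                            adjusted_rows[probe.probe_id] = (
                                norm_log2.loc[probe.probe_id, samples] - exon_log2
                            )
                            relpos[probe.probe_id] = model.probe_relative_position(
                                "three_utr", probe
                            )
            if adjusted_rows:
                adjusted = pd.DataFrame(adjusted_rows).T
                positional[tissue] = utr.positional_profile(
                    adjusted, relpos, design_t, region_kind="three_utr",
                    span=cfg.lowess_span, disease_label=dis, control_label=ctl,
                )
            ctl_samples = intensity.samples_where(tissue=tissue, disease=ctl)
            baselines, changes5 = {}, {}
            ps_tab = sam_probeset[tissue].set_index("feature_id")
            for gene, model in models.items():
                utr5_ps = [p.probeset_id for p in model.probesets_of("five_utr")
                           if p.probeset_id in probeset_expr.index]
                if not utr5_ps or gene not in gene_expr.index:
                    continue
                b = (np.log2(np.maximum(probeset_expr.loc[utr5_ps[0], ctl_samples], 1e-12)).mean()
                     - np.log2(np.maximum(gene_expr.loc[gene, ctl_samples], 1e-12)).mean())
                baselines[gene] = float(b)
                if utr5_ps[0] in ps_tab.index:
                    changes5[gene] = float(ps_tab.loc[utr5_ps[0], "mean_change_pct"])
            try:
                baseline_assoc[tissue] = utr.baseline_abundance_association(baselines, changes5)
            except utr.UtrError:
                pass
        results["positional"] = positional
        results["baseline_assoc"] = baseline_assoc

    # --- regulators -------------------------------------------------------
    if sequences is not None and pwm_library is not None:
        promoters = {g[:-9]: s for g, s in sequences.items() if g.endswith("_promoter")}
        target_sets = regulators.build_target_sets(
            promoters, pwm_library, "promoter_1kb", min_similarity=cfg.pwm_similarity
        )
        results["target_sets"] = target_sets
        activity_rows = []
        for tissue in tissues:
            changes = dict(zip(sam_gene[tissue]["feature_id"], sam_gene[tissue]["mean_change_pct"]))
            for tf, ts in target_sets.items():
                try:
                    mt, mn, p = regulators.target_set_activity(changes, ts.gene_ids)
                except regulators.RegulatorError:
                    continue
                activity_rows.append(
                    {"tissue": tissue, "tf": tf, "scope": ts.region_scope,
                     "n_targets": len(ts.gene_ids), "mean_targets": mt,
                     "mean_nontargets": mn, "p": p}
                )
        results["tf_activity"] = pd.DataFrame(activity_rows)

    # --- cross-tissue synthesis -------------------------------------------
    if len(tissues) >= 2:
        t0, t1 = tissues[0], tissues[1]
        assignments, quad_summary = ct.quadrant_classify(
            sam_gene[t0], sam_gene[t1], p_cut=cfg.p_cut
        )
        r, p = ct.crosstissue_correlation(signed[t0], signed[t1])
        results.update(
            quadrants=assignments, quadrant_summary=quad_summary,
            crosstissue_r=r, crosstissue_p=p,
        )
    return results


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

INPUT_FILES = {
    "intensity": "intensity.tsv",
    "design": "design.tsv",
    "probe_map": "probe_map.tsv",
    "gff": "genes.gff3",
    "fasta": "sequences.fasta",
    "pwm": "pwms.txt",
}


def run_pipeline(config: RunConfig) -> Path:
    """Run the pipeline on a directory of input files; returns the run
    directory.  Missing optional inputs (FASTA, PWM library) skip the
    stages that need them."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in ("intensity", "design", "probe_map"):
        if not (in_dir / INPUT_FILES[key]).exists():
            raise PipelineError(f"missing input file: {INPUT_FILES[key]}")
    intensity = formats.read_intensity_table(
        in_dir / INPUT_FILES["intensity"], in_dir / INPUT_FILES["design"]
    )
    probe_map = formats.read_probe_map(in_dir / INPUT_FILES["probe_map"])
    models = sequences = pwm_library = None
    if (in_dir / INPUT_FILES["gff"]).exists():
        models = formats.read_gene_models(
            in_dir / INPUT_FILES["gff"], in_dir / INPUT_FILES["probe_map"]
        )
    if (in_dir / INPUT_FILES["fasta"]).exists():
        sequences = formats.read_fasta(in_dir / INPUT_FILES["fasta"])
    if (in_dir / INPUT_FILES["pwm"]).exists():
        raw = formats.read_pwm_library(in_dir / INPUT_FILES["pwm"])
        pwm_library = {tf: regulators.Pwm(tf, mat) for tf, mat in raw.items()}

    results = analyze(
        intensity, probe_map, config=config, sequences=sequences,
        pwm_library=pwm_library, models=models,
    )
    _write_outputs(results, out_dir, config)
    return out_dir


def _write_outputs(results: Dict, out_dir: Path, config: RunConfig) -> None:
    meta = {"config": config.as_dict(), "seed": config.seed}

    def table(df: pd.DataFrame, name: str):
        if df is not None and len(df):
            formats.write_result_table(df, out_dir / name, config=meta["config"],
                                       seed=config.seed)

    for tissue, df in results.get("sam_gene", {}).items():
        table(df, f"sam_gene_{tissue}.tsv")
    for tissue, df in results.get("sam_probeset", {}).items():
        table(df, f"sam_probeset_{tissue}.tsv")
    for tissue, df in results.get("events", {}).items():
        table(df, f"events_{tissue}.tsv")
    for tissue, df in results.get("region_summary", {}).items():
        table(df, f"region_summary_{tissue}.tsv")
    for tissue, df in results.get("are_tables", {}).items():
        table(df, f"are_groups_{tissue}.tsv")
    if "tf_activity" in results:
        table(results["tf_activity"], "tf_activity.tsv")
    for tissue, prof in results.get("positional", {}).items():
        table(prof.bins, f"positional_{tissue}.tsv")

    summary: Dict = {"seed": config.seed}
    if "crosstissue_r" in results:
        summary["crosstissue_r"] = results["crosstissue_r"]
        summary["crosstissue_p"] = results["crosstissue_p"]
        summary["quadrants"] = results["quadrant_summary"]
    for tissue, prof in results.get("positional", {}).items():
        summary[f"positional_gradient_{tissue}"] = prof.gradient
    for tissue, assoc in results.get("baseline_assoc", {}).items():
        summary[f"baseline_rho_{tissue}"] = assoc[0]
        summary[f"baseline_p_{tissue}"] = assoc[1]
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
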