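"""Synthetic exon-array datasets with planted, recoverable effects.

The generator emulates a two-tissue, two-condition exon-array study:
gene models with 5'-UTR / exon / intron / 3'-UTR structure, sense
probesets per segment, antisense probesets for a fraction of genes,
promoter and intron sequences with planted TF binding sites, 3'-UTR
sequences with planted AU-rich elements, and probe-level intensities
following the multiplicative model

    intensity[probe, sample] = theta[sample, probeset] * phi[probe] * exp(eps)

with log-normal probe affinities ``phi`` and log-scale Gaussian noise,
so the summarization stage's model assumptions hold by construction.
``theta`` carries the planted gene-level, region-level, ARE-dependent,
positional and tissue-sign-flipped effects, all of which are recorded
in ground-truth tables.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .formats import GeneModel, IntensityTable, Probe, Probeset, Segment
from .regulators import Pwm, scan_pwm
from .utr import ARE_CLASSES

_BASES = np.array(list("ACGT"))


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration and effect specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic experiment.

    Cohort sizes default to 12 disease vs 8 control samples per tissue.
    Fractions allocate genes to mutually exclusive planted-effect
    classes; whatever is left carries no effect.
    """

    n_genes: int = 120
    n_exons: int = 3
    probes_per_probeset: int = 4
    utr3_probes: int = 12  # probes across the 3'-UTR, for positional profiling
    n_disease: int = 12
    n_control: int = 8
    tissues: Tuple[str, str] = ("muscle", "fibroblast")
    # sequence geometry (bp)
    promoter_len: int = 1000
    utr5_len: int = 200
    exon_len: int = 300
    intron_len: int = 400
    utr3_len: int = 600
    # intensity model
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0
    affinity_sigma: float = 0.4  # natural-log SD of probe affinities
    noise_sigma: float = 0.1  # log2-scale SD of multiplicative noise
    background_log2: float = 4.0
    antisense_offset_log2: float = 3.0
    mirror_noise_log2: float = 0.15  # gene x sample jitter of mirrored antisense
    n_background_probesets: int = 40
    # planted effect classes (fractions of genes; must sum to <= 1)
    frac_gene_effect: float = 0.25
    frac_inverse: float = 0.6  # of gene-effect genes, sign-flipped in tissue 2
    gene_effect_log2fc: float = 1.0
    frac_utr_event: float = 0.10  # 3'-UTR-only override, no gene-level change
    utr_event_log2fc: float = 1.0
    frac_are: float = 0.25  # split evenly across mer5..mer13
    are_mer5_pct: float = 8.0
    are_extended_pct: float = 16.0
    frac_gradient: float = 0.10
    gradient_log2: float = 1.0  # disease-control log2 slope per unit 3'-UTR position
    # antisense structure (orthogonal to effect classes)
    frac_antisense: float = 0.4
    frac_antisense_opposite: float = 0.1  # of antisense genes
    frac_antisense_absent: float = 0.3  # antisense probesets left at background
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_genes, self.n_exons, self.probes_per_probeset,
                  self.utr3_probes, self.n_disease, self.n_control)
        if any(c < 1 for c in counts):
            raise SyntheticError("all counts must be >= 1")
        if self.noise_sigma < 0 or self.affinity_sigma < 0:
            raise SyntheticError("sigmas must be >= 0")
        total = self.frac_gene_effect + self.frac_utr_event + self.frac_are + self.frac_gradient
        if total > 1 + 1e-9:
            raise SyntheticError("effect-class fractions sum above 1")


@dataclass(frozen=True)
class EffectSpec:
    """Planted per-gene effect: what downstream stages should recover."""

    gene_id: str
    gene_log2fc: Mapping[str, float] = field(default_factory=dict)  # per tissue
    region_log2fc: Mapping[str, float] = field(default_factory=dict)  # region kind -> extra log2fc
    are_class: str = "none"
    are_shift_log2: float = 0.0  # extra 3'-UTR log2fc, multiplied by tissue sign
    positional_gradient: float = 0.0  # log2 per unit 3'-UTR position, x tissue sign
    antisense_mode: str = "mirror"  # mirror | independent | opposite
    antisense_probeset: bool = False  # the array interrogates this gene's antisense strand
    antisense_present: bool = False  # the antisense transcript rises above background
    tf_memberships: FrozenSet[Tuple[str, str]] = frozenset()  # (tf_id, scope)
    tissue_sign: Mapping[str, float] = field(default_factory=dict)  # default +1

    def sign(self, tissue: str) -> float:
        return float(self.tissue_sign.get(tissue, 1.0))


@dataclass(frozen=True)
class CorrelationModule:
    """Latent-factor co-expression: the focal gene loads 1.0 on a shared
    per-sample factor, members load ``loading`` (signed)."""

    focal_gene: str
    members: Mapping[str, float]  # gene -> loading
    factor_sd: float = 1.0


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    models: Dict[str, GeneModel]
    sequences: Dict[str, str]
    probe_map: pd.DataFrame
    pwm_library: Dict[str, Pwm]
    effects: List[EffectSpec]
    intensity: IntensityTable
    gene_truth: pd.DataFrame
    probeset_truth: pd.DataFrame

    @property
    def background_ids(self) -> List[str]:
        pt = self.probeset_truth
        return list(pt.loc[pt["is_background"], "probeset_id"])


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _scrub_are(seq: str) -> str:
    """Remove every AUUUA core so the planted class is the only one."""
    out = list(seq)
    i = "".join(out).find("ATTTA")
    while i != -1:
        out[i + 2] = "G"
        i = "".join(out).find("ATTTA", i + 1)
    return "".join(out)


_ARE_INSERT = {
    "mer5": "CATTTAC",
    "mer7": "CTATTTATC",
    "mer9": "CTTATTTATTC",
    "mer11": "CTTTATTTATTTC",
    "mer13": "TTTTATTTATTTT",
}


def _plant_are(seq: str, are_class: str, rng: np.random.Generator) -> str:
    seq = _scrub_are(seq)
    if are_class == "none":
        return seq
    insert = _ARE_INSERT[are_class]
    pos = int(rng.integers(1, max(2, len(seq) - len(insert) - 1)))
    return seq[:pos] + insert + seq[pos + len(insert):]


def make_pwm_library(
    tf_ids: Sequence[str], length: int = 12, rng: Optional[np.random.Generator] = None,
    consensus_weight: float = 0.85,
) -> Dict[str, Pwm]:
    """Random informative PWMs: each column puts ``consensus_weight`` on a
    random consensus base and spreads the rest evenly."""
    rng = rng or np.random.default_rng(0)
    library: Dict[str, Pwm] = {}
    for tf in tf_ids:
        consensus = rng.integers(0, 4, size=length)
        mat = np.full((4, length), (1 - consensus_weight) / 3)
        mat[consensus, np.arange(length)] = consensus_weight
        library[tf] = Pwm(tf, mat, pseudocount=0.0)
    return library


def _scrub_pwm_hits(
    seq: str, pwms: Sequence[Pwm], rng: np.random.Generator, min_similarity: float
) -> str:
    """Mutate accidental PWM matches away (so membership truth is exact)."""
    for pwm in pwms:
        if len(seq) < pwm.length:
            continue
        hits = scan_pwm(seq, pwm, min_similarity)
        guard = 0
        while hits and guard < 50:
            off = hits[0][0]
            mid = off + pwm.length // 2
            old = seq[mid]
            new = "ACGT"[int(rng.integers(0, 4))]
            while new == old:
                new = "ACGT"[int(rng.integers(0, 4))]
            seq = seq[:mid] + new + seq[mid + 1:]
            hits = scan_pwm(seq, pwm, min_similarity)
            guard += 1
    return seq


def _plant_pwm_site(
    seq: str, pwm: Pwm, rng: np.random.Generator, occupied: Optional[List[Tuple[int, int]]] = None
) -> str:
    """Insert the consensus at a random position that does not overlap any
    previously planted site (two overlapping plants would corrupt each
    other)."""
    occupied = occupied if occupied is not None else []
    for _ in range(100):
        pos = int(rng.integers(0, max(1, len(seq) - pwm.length)))
        if all(pos + pwm.length <= s or pos >= e for s, e in occupied):
            occupied.append((pos, pos + pwm.length))
            return seq[:pos] + pwm.consensus + seq[pos + pwm.length:]
    raise SyntheticError("could not place a PWM site without overlap")


# ---------------------------------------------------------------------------
# Effect drawing (the default planted scenario)
# ---------------------------------------------------------------------------


def gene_ids(config: GeneratorConfig) -> List[str]:
    return [f"G{i:04d}" for i in range(1, config.n_genes + 1)]


def draw_effects(
    config: GeneratorConfig,
    rng: np.random.Generator,
    pwm_library: Optional[Mapping[str, Pwm]] = None,
) -> List[EffectSpec]:
    """Allocate genes to the default planted-effect classes.

    Classes are mutually exclusive: gene-level fold change (a fraction
    sign-flipped in the second tissue), 3'-UTR-only override, ARE ladder
    shift (mirrored with opposite sign in the second tissue), positional
    gradient, or no effect.  Antisense structure and TF membership are
    drawn independently of the effect class.
    """
    config.validate()
    genes = gene_ids(config)
    order = rng.permutation(config.n_genes)
    t0, t1 = config.tissues
    n = config.n_genes
    n_fc = round(config.frac_gene_effect * n)
    n_utr = round(config.frac_utr_event * n)
    n_are = round(config.frac_are * n)
    n_grad = round(config.frac_gradient * n)

    are_ladder = [c for c in ARE_CLASSES if c != "none"]
    effects: List[EffectSpec] = []
    cursor = 0
    cls_of: Dict[int, Tuple[str, object]] = {}
    for idx in order[cursor:cursor + n_fc]:
        sign0 = 1.0 if rng.random() < 0.5 else -1.0
        inverse = rng.random() < config.frac_inverse
        cls_of[idx] = ("gene_fc", (sign0, inverse))
    cursor += n_fc
    for idx in order[cursor:cursor + n_utr]:
        cls_of[idx] = ("utr_event", 1.0 if rng.random() < 0.5 else -1.0)
    cursor += n_utr
    for j, idx in enumerate(order[cursor:cursor + n_are]):
        cls_of[idx] = ("are", are_ladder[j % len(are_ladder)])
    cursor += n_are
    for idx in order[cursor:cursor + n_grad]:
        cls_of[idx] = ("gradient", None)
    cursor += n_grad

    tf_ids = sorted(pwm_library) if pwm_library else []
    for i, gene in enumerate(genes):
        kind, detail = cls_of.get(i, ("none", None))
        gene_fc: Dict[str, float] = {}
        region_fc: Dict[str, float] = {}
        are_class, are_shift, gradient = "none", 0.0, 0.0
        tissue_sign = {t0: 1.0, t1: 1.0}
        if kind == "gene_fc":
            sign0, inverse = detail
            fc = sign0 * config.gene_effect_log2fc
            gene_fc = {t0: fc, t1: -fc if inverse else fc}
        elif kind == "utr_event":
            region_fc = {"three_utr": detail * config.utr_event_log2fc}
            tissue_sign = {t0: 1.0, t1: -1.0}
        elif kind == "are":
            are_class = detail
            pct = config.are_mer5_pct if detail == "mer5" else config.are_extended_pct
            are_shift = float(np.log2(1.0 + pct / 100.0))
            tissue_sign = {t0: 1.0, t1: -1.0}
        elif kind == "gradient":
            gradient = config.gradient_log2
            tissue_sign = {t0: 1.0, t1: -1.0}

        has_antisense = rng.random() < config.frac_antisense
        as_mode = "mirror"
        as_present = True
        if has_antisense:
            if rng.random() < config.frac_antisense_opposite:
                as_mode = "opposite"
            if rng.random() < config.frac_antisense_absent:
                as_present = False

        memberships: Set[Tuple[str, str]] = set()
        for k, tf in enumerate(tf_ids):
            scope = "intron" if k % 3 == 2 else "promoter"
            if rng.random() < 0.25:
                memberships.add((tf, scope))

        effects.append(
            EffectSpec(
                gene_id=gene,
                gene_log2fc=gene_fc,
                region_log2fc=region_fc,
                are_class=are_class,
                are_shift_log2=are_shift,
                positional_gradient=gradient,
                antisense_mode=as_mode,
                antisense_probeset=has_antisense,
                antisense_present=has_antisense and as_present,
                tf_memberships=frozenset(memberships),
                tissue_sign=tissue_sign,
            )
        )
    return effects


# ---------------------------------------------------------------------------
# Gene models, sequences, probe map
# ---------------------------------------------------------------------------


def generate_gene_models(
    config: GeneratorConfig,
    effects: Sequence[EffectSpec],
    rng: np.random.Generator,
    pwm_library: Optional[Mapping[str, Pwm]] = None,
    min_similarity: float = 0.95,
) -> Tuple[Dict[str, GeneModel], Dict[str, str], pd.DataFrame]:
    """Build gene models, their sequences and the probe map.

    Each gene has a 5'-UTR, ``n_exons`` exons separated by introns, and
    a 3'-UTR; one sense probeset per segment (the 3'-UTR probeset gets
    ``utr3_probes`` probes for positional analysis) and, where the
    effect spec says so, one antisense probeset over the 5'-UTR.
    Promoter/intron sequences carry planted PWM consensus sites exactly
    for member genes; 3'-UTR sequences carry exactly the planted ARE
    class.  Background-only probesets are appended to the probe map with
    gene_id "BACKGROUND".
    """
    config.validate()
    effects_by_gene = {e.gene_id: e for e in effects}
    unknown = set(effects_by_gene) - set(gene_ids(config))
    if unknown:
        raise SyntheticError(f"effect for unknown gene(s): {sorted(unknown)}")
    pwms = dict(pwm_library) if pwm_library else {}

    models: Dict[str, GeneModel] = {}
    sequences: Dict[str, str] = {}
    pm_rows: List[dict] = []
    cursor = 10_000
    gap = 5_000

    for gene in gene_ids(config):
        eff = effects_by_gene.get(gene, EffectSpec(gene_id=gene))
        strand = "+" if rng.random() < 0.5 else "-"
        # transcript segment order, 5' -> 3'
        t_order: List[Tuple[str, int]] = [("five_utr", config.utr5_len)]
        for e in range(config.n_exons):
            t_order.append(("exon", config.exon_len))
            if e < config.n_exons - 1:
                t_order.append(("intron", config.intron_len))
        t_order.append(("three_utr", config.utr3_len))
        genomic_order = t_order if strand == "+" else list(reversed(t_order))

        start = cursor
        segments: List[Segment] = []
        pos = start
        for kind, length in genomic_order:
            segments.append(Segment(kind, pos, pos + length))
            pos += length
        end = pos
        cursor = end + gap
        model = GeneModel(gene, "chrS", strand, start, end, segments)

        # sense probesets: one per non-intron segment
        ps_counter = 0
        for seg in segments:
            if seg.kind == "intron":
                continue
            ps_counter += 1
            n_probes = config.utr3_probes if seg.kind == "three_utr" else config.probes_per_probeset
            ps_id = f"{gene}_ps{ps_counter:02d}_{seg.kind}"
            ps = Probeset(ps_id, gene, seg.kind, strand)
            span = seg.end - seg.start
            for k in range(n_probes):
                p_start = seg.start + int((k + 0.25) * span / n_probes)
                p_end = min(seg.end, p_start + 25)
                probe = Probe(f"{ps_id}_p{k:02d}", p_start, p_end)
                ps.probes.append(probe)
                pm_rows.append(
                    {"probe_id": probe.probe_id, "probeset_id": ps_id, "gene_id": gene,
                     "region_kind": seg.kind if seg.kind != "exon" else "exon",
                     "start": probe.start, "end": probe.end, "strand": strand}
                )
            model.probesets[ps_id] = ps

        # antisense probeset over the 5'-UTR
        if eff.antisense_probeset:
            seg = model.segments_of("five_utr")[0]
            as_strand = "-" if strand == "+" else "+"
            ps_id = f"{gene}_as01"
            ps = Probeset(ps_id, gene, "antisense", as_strand)
            span = seg.end - seg.start
            for k in range(config.probes_per_probeset):
                p_start = seg.start + int((k + 0.5) * span / config.probes_per_probeset)
                p_end = min(seg.end, p_start + 25)
                probe = Probe(f"{ps_id}_p{k:02d}", p_start, p_end)
                ps.probes.append(probe)
                pm_rows.append(
                    {"probe_id": probe.probe_id, "probeset_id": ps_id, "gene_id": gene,
                     "region_kind": "antisense", "start": probe.start, "end": probe.end,
                     "strand": as_strand}
                )
            model.probesets[ps_id] = ps

        models[gene] = model

        # sequences
        promoter = _random_seq(rng, config.promoter_len)
        intron = _random_seq(rng, config.intron_len)
        if pwms:
            member_scopes = {tf: scope for tf, scope in eff.tf_memberships}
            promoter = _scrub_pwm_hits(
                promoter, [pwms[t] for t in sorted(pwms) if member_scopes.get(t) != "promoter"],
                rng, min_similarity,
            )
            intron = _scrub_pwm_hits(
                intron, [pwms[t] for t in sorted(pwms) if member_scopes.get(t) != "intron"],
                rng, min_similarity,
            )
            occ_promoter: List[Tuple[int, int]] = []
            occ_intron: List[Tuple[int, int]] = []
            for tf, scope in sorted(eff.tf_memberships):
                if scope == "promoter":
                    promoter = _plant_pwm_site(promoter, pwms[tf], rng, occ_promoter)
                else:
                    intron = _plant_pwm_site(intron, pwms[tf], rng, occ_intron)
        utr5 = _random_seq(rng, config.utr5_len)
        utr3 = _plant_are(_random_seq(rng, config.utr3_len), eff.are_class, rng)
        sequences[f"{gene}_promoter"] = promoter
        sequences[f"{gene}_intron"] = intron
        sequences[f"{gene}_five_utr"] = utr5
        sequences[f"{gene}_three_utr"] = utr3

    # background-only probesets
    for b in range(config.n_background_probesets):
        ps_id = f"BG{b:04d}"
        for k in range(config.probes_per_probeset):
            pm_rows.append(
                {"probe_id": f"{ps_id}_p{k:02d}", "probeset_id": ps_id,
                 "gene_id": "BACKGROUND", "region_kind": "antisense",
                 "start": k * 30, "end": k * 30 + 25, "strand": "+"}
            )

    probe_map = pd.DataFrame(pm_rows)
    return models, sequences, probe_map


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def make_design(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        for i in range(config.n_control):
            rows.append({"sample_id": f"{tissue[:3]}_ctl_{i:02d}", "tissue": tissue, "disease": "control"})
        for i in range(config.n_disease):
            rows.append({"sample_id": f"{tissue[:3]}_dis_{i:02d}", "tissue": tissue, "disease": "RC"})
    return pd.DataFrame(rows).set_index("sample_id")


def generate_expression(
    models: Mapping[str, GeneModel],
    effects: Sequence[EffectSpec],
    config: GeneratorConfig,
    rng: np.random.Generator,
    probe_map: Optional[pd.DataFrame] = None,
    modules: Sequence[CorrelationModule] = (),
) -> Tuple[IntensityTable, pd.DataFrame, pd.DataFrame]:
    """Simulate probe intensities and the ground-truth tables.

    Returns (intensity, gene_truth, probeset_truth).  Probe intensity is
    ``theta * phi * exp(eps)`` where theta carries every planted log2
    effect (gene-level, region override, ARE shift, positional gradient
    at probe level, antisense behaviour) and the per-sample latent
    factors of any correlation modules.
    """
    config.validate()
    effects_by_gene = {e.gene_id: e for e in effects}
    unknown = set(effects_by_gene) - set(models)
    if unknown:
        raise SyntheticError(f"effect for unknown gene(s): {sorted(unknown)}")
    design = make_design(config)
    samples = list(design.index)
    n_samples = len(samples)
    tissue_of = design["tissue"].to_numpy()
    diseased = (design["disease"] == "RC").to_numpy()

    region_offset = {"five_utr": -0.5, "three_utr": -0.5, "exon": 0.0}

    # latent factors for correlation modules: one per module per sample
    factor = {m.focal_gene: rng.normal(0.0, m.factor_sd, size=n_samples) for m in modules}
    loading: Dict[str, Dict[str, float]] = {}
    for m in modules:
        loading.setdefault(m.focal_gene, {})[m.focal_gene] = 1.0
        for gene, lo in m.members.items():
            loading.setdefault(m.focal_gene, {})[gene] = float(lo)

    baselines = {g: rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)
                 for g in sorted(models)}

    probe_rows: List[str] = []
    intensity_rows: List[np.ndarray] = []
    ps_truth_rows: List[dict] = []

    for gene in sorted(models):
        model = models[gene]
        eff = effects_by_gene.get(gene, EffectSpec(gene_id=gene))
        base = baselines[gene]
        # per-sample disease effect by tissue, gene level
        gene_term = np.zeros(n_samples)
        for t in config.tissues:
            sel = diseased & (tissue_of == t)
            gene_term[sel] = eff.gene_log2fc.get(t, 0.0)
        module_term = np.zeros(n_samples)
        for focal, loads in loading.items():
            if gene in loads:
                module_term = module_term + loads[gene] * factor[focal]
        sign = np.ones(n_samples)
        for t in config.tissues:
            sign[tissue_of == t] = eff.sign(t)
        mirror_jitter = rng.normal(0.0, config.mirror_noise_log2, size=n_samples)

        for ps_id in sorted(model.probesets):
            ps = model.probesets[ps_id]
            region = ps.region_kind
            if region == "antisense":
                if not eff.antisense_present:
                    theta_log2 = np.full(n_samples, config.background_log2)
                else:
                    theta_log2 = (base - config.antisense_offset_log2
                                  + module_term + mirror_jitter)
                    if eff.antisense_mode == "mirror":
                        theta_log2 = theta_log2 + gene_term
                    elif eff.antisense_mode == "opposite":
                        theta_log2 = theta_log2 - gene_term - np.where(
                            diseased, sign * eff.region_log2fc.get("five_utr", 0.0), 0.0
                        )
                    # "independent": no disease term at all
            else:
                theta_log2 = base + region_offset[region] + gene_term + module_term
                extra = eff.region_log2fc.get(region, 0.0)
                if region == "three_utr":
                    extra += eff.are_shift_log2
                if extra:
                    theta_log2 = theta_log2 + np.where(diseased, sign * extra, 0.0)

            phi = np.exp(rng.normal(0.0, config.affinity_sigma, size=len(ps.probes)))
            relpos = np.array(
                [model.probe_relative_position(region, p) for p in ps.probes]
            ) if region == "three_utr" else np.zeros(len(ps.probes))
            for k, probe in enumerate(ps.probes):
                log2_level = theta_log2 + np.log2(phi[k])
                if region == "three_utr" and eff.positional_gradient:
                    grad = eff.positional_gradient * (relpos[k] - 0.5)
                    log2_level = log2_level + np.where(diseased, sign * grad, 0.0)
                if config.noise_sigma > 0:
                    log2_level = log2_level + rng.normal(0.0, config.noise_sigma, size=n_samples)
                probe_rows.append(probe.probe_id)
                intensity_rows.append(np.exp2(log2_level))
            ps_truth_rows.append(
                {"probeset_id": ps_id, "gene_id": gene, "region_kind": region,
                 "is_background": False,
                 "effective_true": bool(region != "antisense" or eff.antisense_present)}
            )

    # background-only probesets
    for b in range(config.n_background_probesets):
        ps_id = f"BG{b:04d}"
        phi = np.exp(rng.normal(0.0, config.affinity_sigma, size=config.probes_per_probeset))
        for k in range(config.probes_per_probeset):
            log2_level = np.full(n_samples, config.background_log2) + np.log2(phi[k])
            if config.noise_sigma > 0:
                log2_level = log2_level + rng.normal(0.0, config.noise_sigma, size=n_samples)
            probe_rows.append(f"{ps_id}_p{k:02d}")
            intensity_rows.append(np.exp2(log2_level))
        ps_truth_rows.append(
            {"probeset_id": ps_id, "gene_id": "BACKGROUND", "region_kind": "antisense",
             "is_background": True, "effective_true": False}
        )

    values = pd.DataFrame(np.vstack(intensity_rows), index=probe_rows, columns=samples)
    intensity = IntensityTable(values, design)

    t0, t1 = config.tissues
    gene_truth = pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                f"log2fc_{t0}": e.gene_log2fc.get(t0, 0.0),
                f"log2fc_{t1}": e.gene_log2fc.get(t1, 0.0),
                "utr3_override_log2": e.region_log2fc.get("three_utr", 0.0),
                "are_class": e.are_class,
                "are_shift_log2": e.are_shift_log2,
                "positional_gradient": e.positional_gradient,
                "antisense_mode": e.antisense_mode,
                "antisense_probeset": e.antisense_probeset,
                "antisense_present": e.antisense_present,
                "tf_memberships": ";".join(f"{tf}:{sc}" for tf, sc in sorted(e.tf_memberships)),
                f"sign_{t0}": e.sign(t0),
                f"sign_{t1}": e.sign(t1),
            }
            for e in (effects_by_gene.get(g, EffectSpec(gene_id=g)) for g in sorted(models))
        ]
    )
    probeset_truth = pd.DataFrame(ps_truth_rows)
    return intensity, gene_truth, probeset_truth


# ---------------------------------------------------------------------------
# One-call simulation
# ---------------------------------------------------------------------------


def simulate(
    config: Optional[GeneratorConfig] = None,
    tf_ids: Sequence[str] = ("TF_A", "TF_B", "TF_C"),
    modules: Sequence[CorrelationModule] = (),
    effects: Optional[Sequence[EffectSpec]] = None,
) -> SyntheticDataset:
    """Generate a complete dataset under the default planted scenario.

    Separate RNG streams (spawned from the config seed) drive the
    effect draw, the gene models and the expression noise, so the same
    seed always yields byte-identical outputs.
    """
    config = config or GeneratorConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_eff, rng_models, rng_expr, rng_pwm = (np.random.default_rng(s) for s in ss.spawn(4))
    pwm_library = make_pwm_library(list(tf_ids), rng=rng_pwm)
    if effects is None:
        effects = draw_effects(config, rng_eff, pwm_library)
    models, sequences, probe_map = generate_gene_models(
        config, effects, rng_models, pwm_library
    )
    intensity, gene_truth, probeset_truth = generate_expression(
        models, effects, config, rng_expr, probe_map, modules=modules
    )
    return SyntheticDataset(
        config=config,
        models=models,
        sequences=sequences,
        probe_map=probe_map,
        pwm_library=pwm_library,
        effects=list(effects),
        intensity=intensity,
        gene_truth=gene_truth,
        probeset_truth=probeset_truth,
    )
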