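"""Readers and writers for the external formats the pipeline touches.

Coordinate convention
---------------------
Everything in memory is 0-based, half-open ``[start, end)``.  GFF3 is
1-based inclusive and is converted at the boundary, in both directions,
so a round trip through :func:`write_gff3` / :func:`read_gene_models`
reproduces the original coordinates exactly.

Antisense probesets are *declared* in the probe map (``region_kind ==
"antisense"``), never inferred from overlap: exon arrays carry a fixed
set of antisense probesets by design.
"""

from __future__ import annotations

import hashlib
import json
import os
import textwrap
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

REGION_KINDS = ("five_utr", "three_utr", "exon", "antisense")

#: reserved gene_id for background-only probesets (no genomic locus)
BACKGROUND_GENE = "BACKGROUND"

PROBE_MAP_COLUMNS = [
    "probe_id",
    "probeset_id",
    "gene_id",
    "region_kind",
    "start",
    "end",
    "strand",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented contract."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Probe:
    probe_id: str
    start: int  # genomic, 0-based half-open
    end: int

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Probeset:
    probeset_id: str
    gene_id: str
    region_kind: str
    strand: str
    probes: List[Probe] = field(default_factory=list)


@dataclass(frozen=True)
class Segment:
    kind: str  # five_utr | three_utr | exon | intron
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise FormatError(
                f"segment {self.kind} has start {self.start} >= end {self.end}"
            )


@dataclass
class GeneModel:
    """A gene's strand, segment structure and attached probesets."""

    gene_id: str
    seqid: str
    strand: str
    start: int
    end: int
    segments: List[Segment] = field(default_factory=list)
    probesets: Dict[str, Probeset] = field(default_factory=dict)

    def segments_of(self, kind: str) -> List[Segment]:
        return [s for s in self.segments if s.kind == kind]

    def probesets_of(self, region_kind: str) -> List[Probeset]:
        return [p for p in self.probesets.values() if p.region_kind == region_kind]

    def region_span(self, region_kind: str) -> Optional[Segment]:
        """Merged span of the gene's segments of ``region_kind`` (UTRs are
        contiguous in this model; exon regions are per-segment)."""
        segs = self.segments_of(region_kind)
        if not segs:
            return None
        return Segment(region_kind, min(s.start for s in segs), max(s.end for s in segs))

    def probe_relative_position(self, region_kind: str, probe: Probe) -> float:
        """Relative position of a probe within a region, 0 at the transcript's
        5' end of the region and 1 at its 3' end (minus-strand genes flipped)."""
        span = self.region_span(region_kind)
        if span is None:
            raise FormatError(f"gene {self.gene_id} has no {region_kind} region")
        rel = (probe.mid - span.start) / (span.end - span.start)
        rel = min(1.0, max(0.0, rel))
        return 1.0 - rel if self.strand == "-" else rel


@dataclass
class IntensityTable:
    """Probes-by-samples intensity matrix plus the sample design.

    ``values`` rows are probe_ids, columns are sample_ids in design order.
    ``design`` is indexed by sample_id with columns ``tissue`` and
    ``disease`` (``disease in {"RC", "control"}`` by convention but labels
    are free text).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"sample not in design: {missing}")
        self.values = self.values[list(self.design.index)]

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    def samples_where(self, tissue: Optional[str] = None, disease: Optional[str] = None) -> List[str]:
        mask = pd.Series(True, index=self.design.index)
        if tissue is not None:
            mask &= self.design["tissue"] == tissue
        if disease is not None:
            mask &= self.design["disease"] == disease
        return list(self.design.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityTable":
        return IntensityTable(self.values[list(sample_ids)], self.design.loc[list(sample_ids)])

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)


# ---------------------------------------------------------------------------
# Intensity tables and sample designs
# ---------------------------------------------------------------------------


def read_design(path: os.PathLike) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "tissue", "disease"):
        if col not in design.columns:
            raise FormatError(f"design file missing column {col!r}")
    if design["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in design")
    return design.set_index("sample_id")


def read_intensity_table(path: os.PathLike, design_path: os.PathLike) -> IntensityTable:
    """Read a probes-by-samples TSV and its sample design.

    The TSV has a header row of sample ids and a first column of probe ids.
    Values must be strictly positive (raw intensity scale).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe_id: {dups}")
    non_numeric = values.columns[[not np.issubdtype(dt, np.number) for dt in values.dtypes]]
    if len(non_numeric):
        raise FormatError(f"non-numeric cell(s) in columns {list(non_numeric)}")
    if not np.isfinite(values.to_numpy()).all() or (values.to_numpy() <= 0).any():
        raise FormatError("intensities must be strictly positive and finite")
    design = read_design(design_path)
    missing = [s for s in values.columns if s not in design.index]
    if missing:
        raise FormatError(f"sample not in design: {missing}")
    return IntensityTable(values, design.loc[list(values.columns)])


def write_intensity_table(table: IntensityTable, path: os.PathLike, design_path: os.PathLike) -> None:
    table.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.12g")
    table.design.to_csv(design_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Probe maps and gene models
# ---------------------------------------------------------------------------


def read_probe_map(path: os.PathLike) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype={"start": np.int64, "end": np.int64})
    for col in PROBE_MAP_COLUMNS:
        if col not in pm.columns:
            raise FormatError(f"probe map missing column {col!r}")
    if pm["probe_id"].duplicated().any():
        raise FormatError("probe mapped to more than one probeset")
    bad = pm.groupby("probeset_id")["region_kind"].nunique()
    if (bad > 1).any():
        raise FormatError(
            f"probeset with more than one region_kind: {list(bad.index[bad > 1])}"
        )
    unknown = set(pm["region_kind"]) - set(REGION_KINDS)
    if unknown:
        raise FormatError(f"unknown region_kind: {sorted(unknown)}")
    if (pm["start"] >= pm["end"]).any():
        raise FormatError("probe with start >= end")
    return pm[PROBE_MAP_COLUMNS]


def write_probe_map(pm: pd.DataFrame, path: os.PathLike) -> None:
    pm[PROBE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


_GFF_KIND = {
    "five_prime_UTR": "five_utr",
    "three_prime_UTR": "three_utr",
    "exon": "exon",
    "intron": "intron",
}
_KIND_GFF = {v: k for k, v in _GFF_KIND.items()}


def read_gene_models(gff_path: os.PathLike, probemap_path: os.PathLike) -> Dict[str, GeneModel]:
    """Build :class:`GeneModel` objects from a GFF3 file and a probe map TSV.

    Every probeset in the probe map must reference a gene present in the
    GFF3; antisense probesets are attached to the gene named in the map
    (they interrogate the opposite strand of that gene's locus).
    """
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: Dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        model = GeneModel(
            gene_id=gene.id,
            seqid=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
            end=gene.end,
        )
        for child in db.children(gene, order_by="start"):
            kind = _GFF_KIND.get(child.featuretype)
            if kind is None:
                continue
            seg = Segment(kind, child.start - 1, child.end)
            if seg.start < model.start or seg.end > model.end:
                raise FormatError(
                    f"segment {kind} [{seg.start},{seg.end}) outside gene span of {gene.id}"
                )
            model.segments.append(seg)
        models[gene.id] = model

    pm = read_probe_map(probemap_path)
    for (probeset_id, gene_id, region_kind, strand), grp in pm.groupby(
        ["probeset_id", "gene_id", "region_kind", "strand"], sort=True
    ):
        if gene_id == BACKGROUND_GENE:
            continue  # background probesets have no locus to attach to
        if gene_id not in models:
            raise FormatError(f"probe map references unknown gene {gene_id!r}")
        model = models[gene_id]
        ps = Probeset(probeset_id, gene_id, region_kind, strand)
        for row in grp.itertuples():
            ps.probes.append(Probe(row.probe_id, int(row.start), int(row.end)))
        ps.probes.sort(key=lambda p: p.start)
        model.probesets[probeset_id] = ps
    return models


def write_gff3(models: Mapping[str, GeneModel], path: os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(models):
            m = models[gene_id]
            fh.write(
                f"{m.seqid}\texondys\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={gene_id}\n"
            )
            for i, seg in enumerate(sorted(m.segments, key=lambda s: s.start)):
                fh.write(
                    f"{m.seqid}\texondys\t{_KIND_GFF[seg.kind]}\t{seg.start + 1}\t{seg.end}"
                    f"\t.\t{m.strand}\t.\tID={gene_id}.{seg.kind}.{i};Parent={gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: os.PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(sequences[name], 80))
            fh.write("\n")


# ---------------------------------------------------------------------------
# PWM libraries
# ---------------------------------------------------------------------------


def read_pwm_library(path: os.PathLike) -> Dict[str, np.ndarray]:
    """Parse a PWM library: ``>tf_id`` headers, then 4 tab-separated rows of
    base frequencies in A, C, G, T order."""
    library: Dict[str, np.ndarray] = {}
    name, rows = None, []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise FormatError(f"PWM {name!r} has {len(rows)} rows, expected 4")
        mat = np.array(rows, dtype=float)
        if mat.shape[1] < 4:
            raise FormatError(f"PWM {name!r} shorter than 4 columns")
        library[name] = mat

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], []
            else:
                rows.append([float(x) for x in line.split("\t")])
    flush()
    return library


def write_pwm_library(library: Mapping[str, np.ndarray], path: os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sorted(library):
            fh.write(f">{name}\n")
            for row in np.asarray(library[name], dtype=float):
                fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Result tables with JSON sidecars
# ---------------------------------------------------------------------------


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_result_table(
    records: pd.DataFrame,
    path: os.PathLike,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a result table as TSV (NaN serialized as "NA") plus a JSON
    sidecar carrying the run config and seed for reproducibility."""
    if len(records) == 0:
        raise FormatError("refusing to write an empty result table")
    records.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")
    sidecar = {
        "config": dict(config) if config is not None else {},
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "n_records": int(len(records)),
        "columns": list(records.columns),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True, default=str)


def read_result_table(path: os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
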