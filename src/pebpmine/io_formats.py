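"""Plain-text I/O for the toolkit: FASTA/FASTQ, GFF3 gene models, VCF + TSV
variant reports, barcode manifests, and run configuration.

All genomic coordinates in emitted files are 1-based inclusive (GFF3/VCF
convention).  Any internal half-open representation is never serialized.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


@dataclass
class SeqRecord:
    """A named sequence (DNA or protein); the body is stored uppercased."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record requires a non-empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, strict: bool = True) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, in file order.

    Duplicate ids are rejected; an empty file raises when ``strict``.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: malformed FASTA header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq), rec.description))
    if strict and not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq), rec.description))
    return records


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gene_models(models, path: str | Path) -> None:
    """Write GeneModels as GFF3 (gene/mRNA/exon/CDS rows, 1-based inclusive).

    Round-trips losslessly (ids, strand, exon intervals) through
    :func:`read_gene_models`.
    """
    lines = ["##gff-version 3"]
    for m in models:
        start = min(s for s, _ in m.exons)
        end = max(e for _, e in m.exons)
        src = "pebpmine"
        lines.append("\t".join([m.scaffold_id, src, "gene", str(start), str(end), ".", m.strand, ".", f"ID={m.locus_id}"]))
        mrna = f"{m.locus_id}.t1"
        lines.append("\t".join([m.scaffold_id, src, "mRNA", str(start), str(end), ".", m.strand, ".", f"ID={mrna};Parent={m.locus_id}"]))
        # phases follow transcription order; rows are emitted in ascending coordinates
        order = m.exons if m.strand == "+" else list(reversed(m.exons))
        phases = {}
        cum = 0
        for s, e in order:
            phases[(s, e)] = (3 - cum % 3) % 3
            cum += e - s + 1
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append("\t".join([m.scaffold_id, src, "exon", str(s), str(e), ".", m.strand, ".", f"ID={mrna}.exon{i};Parent={mrna}"]))
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append("\t".join([m.scaffold_id, src, "CDS", str(s), str(e), ".", m.strand, str(phases[(s, e)]), f"ID={mrna}.cds{i};Parent={mrna}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path: str | Path, scaffolds: Mapping[str, str] | None = None):
    """Read GFF3 written by :func:`write_gene_models` back into GeneModels.

    If ``scaffolds`` (id -> sequence) is given, CDS and protein are re-derived
    by splicing; otherwise those fields are left empty.
    """
    from .gene_models import GeneModel, splice, translate_cds

    genes: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}: bad GFF3 row: {line!r}")
        seqid, _, ftype, start, end, _, strand, _, attrs = cols
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
        if ftype == "gene":
            genes[attr["ID"]] = {"scaffold": seqid, "strand": strand, "exons": []}
        elif ftype == "exon":
            locus = attr["Parent"].rsplit(".t1", 1)[0]
            genes[locus]["exons"].append((int(start), int(end)))
    models = []
    for locus, info in genes.items():
        exons = sorted(info["exons"])
        cds = protein = ""
        if scaffolds is not None:
            cds = splice(scaffolds[info["scaffold"]], exons, info["strand"])
            if len(cds) % 3 == 0:
                protein = translate_cds(cds)
        models.append(GeneModel(locus, info["scaffold"], info["strand"], exons, cds, protein, set()))
    return models


# ---------------------------------------------------------------------------
# VCF 4.2 + TSV variant reports
# ---------------------------------------------------------------------------

VARIANT_TSV_COLUMNS = [
    "position", "cds_position", "kind", "ref", "alt",
    "region", "effect", "aa_change", "external_prediction",
]


def write_variants(variants, allele1: str, locus_id: str,
                   vcf_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write variants of one named allele pair as minimal VCF 4.2 plus a TSV.

    Deletions are reported left-anchored: POS is the base before the deleted
    run, REF carries anchor + deleted bases, ALT the anchor alone.  The TSV
    mirrors the printed allele-variation tables (nucleotide position, region,
    substitution, amino-acid change, protein position) and reserves a column
    for externally supplied tolerance predictions.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={locus_id},length={len(allele1)}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in variants:
        if v.position < 1 or v.position > len(allele1):
            raise FormatError(f"variant position {v.position} outside allele length {len(allele1)}")
        if v.kind == "substitution":
            pos, ref, alt = v.position, v.ref, v.alt
        elif v.kind == "deletion":
            if v.position > 1:
                anchor = allele1[v.position - 2]
                pos, ref, alt = v.position - 1, anchor + v.ref, anchor
            else:  # deletion at sequence start: right-anchored
                anchor = allele1[v.position - 1 + len(v.ref)]
                pos, ref, alt = v.position, v.ref + anchor, anchor
        else:  # insertion relative to allele1
            anchor = allele1[v.position - 1]
            pos, ref, alt = v.position, anchor, anchor + v.alt
        lines.append(f"{locus_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    Path(vcf_path).write_text("\n".join(lines) + "\n")

    if tsv_path is not None:
        rows = []
        for v in variants:
            region = f"{v.region[0]}{v.region[1]}" if v.region else ""
            aa = f"{v.aa_change[0]}{v.aa_change[1]}{v.aa_change[2]}" if v.aa_change else ""
            rows.append({
                "position": v.position,
                "cds_position": v.cds_position if v.cds_position is not None else "",
                "kind": v.kind, "ref": v.ref, "alt": v.alt,
                "region": region, "effect": v.effect, "aa_change": aa,
                "external_prediction": "",
            })
        pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Barcode manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a barcode manifest TSV (sample_id, fwd_barcode, rev_barcode)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fwd_barcode", "rev_barcode"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    manifest = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in manifest:
            raise FormatError(f"{path}: duplicate sample_id {sid!r}")
        manifest[sid] = (row["fwd_barcode"].upper(), row["rev_barcode"].upper())
    return manifest


def write_manifest(manifest: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    rows = [{"sample_id": s, "fwd_barcode": f, "rev_barcode": r} for s, (f, r) in manifest.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS: dict[str, float] = {
    "seed_k": 4,                  # protein k-mer seed length for homology search
    "min_identity": 40.0,         # % identity floor for homology hits
    "min_score": 60.0,            # substitution-matrix score floor for hits
    "max_gap": 2000,              # bp; same-strand hits closer than this merge into one locus
    "barcode_max_edits": 2,       # per-end edit allowance in demultiplexing
    "cluster_identity": 0.995,    # read-vs-consensus admission identity in phasing
    "min_allele_fraction": 0.2,   # clusters below this share of a locus are noise
    "min_reads": 10,              # minimum inserts to attempt phasing
    "bootstrap_replicates": 100,  # phylogeny bootstrap resamples
    "gamma_alpha": 1.0,           # gamma shape for rate-corrected distances
    "upstream_window": 8000,      # bp of promoter region scanned upstream of ATG
    "repeat_min_len": 200,        # bp floor for reported repeat hits
    "repeat_min_identity": 70.0,  # % identity floor for repeat hits
}

_THRESHOLD_RANGES: dict[str, tuple[float, float]] = {
    "seed_k": (3, 12),
    "min_identity": (0, 100),
    "min_score": (0, 1e6),
    "max_gap": (0, 1e7),
    "barcode_max_edits": (0, 8),
    "cluster_identity": (0.5, 1.0),
    "min_allele_fraction": (0.0, 0.5),
    "min_reads": (1, 1e6),
    "bootstrap_replicates": (0, 100000),
    "gamma_alpha": (1e-3, 1e9),
    "upstream_window": (1, 1e6),
    "repeat_min_len": (1, 1e6),
    "repeat_min_identity": (0, 100),
}

_KNOWN_PATHS = {
    "genome", "queries", "cds_dir", "proteins", "reads", "manifest",
    "repeat_library", "out_dir", "locus",
}


@dataclass
class RunConfig:
    """Flat key/value run configuration; unknown keys warn, missing keys take defaults."""

    seed: int = 1
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    paths: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a flat key-value document")
        cfg = cls()
        for key, value in raw.items():
            if key == "seed":
                cfg.seed = int(value)
            elif key in DEFAULT_THRESHOLDS:
                cfg.thresholds[key] = type(DEFAULT_THRESHOLDS[key])(value)
            elif key in _KNOWN_PATHS:
                cfg.paths[key] = str(value)
            else:
                warnings.warn(f"config key {key!r} is not recognised and was ignored")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, value in self.thresholds.items():
            lo, hi = _THRESHOLD_RANGES[name]
            if not (lo <= float(value) <= hi):
                raise FormatError(f"threshold {name}={value} outside [{lo}, {hi}]")

    def to_yaml(self, path: str | Path) -> None:
        doc = {"seed": self.seed, **self.thresholds, **self.paths}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
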