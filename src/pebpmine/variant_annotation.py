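"""Allele-pair variant calling and annotation.

Aligns two alleles of a gene globally, calls substitutions and deletions,
places each variant in an exon or intron of the gene model, classifies coding
effects (synonymous / non-synonymous / stop-gained) with amino-acid changes,
and scans promoter windows for repeat/transposon insertions.

Conventions
-----------
* Variant positions are 1-based on allele1 (gene coordinates); exonic
  variants additionally carry a 1-based CDS coordinate.
* A maximal gap run is a single deletion event; deletions are left-aligned so
  that calls are bit-comparable across runs.
* Protein position of a CDS position is ceil(cds_pos / 3).
* Upstream coordinates are ATG-relative and negative: -1 is the base
  immediately 5' of the A of ATG.  A repeat spanning -near..-far is reported
  with span |far| - |near| (difference convention, matching the printed
  promoter-transposon interval where 3763 - 1052 = 2711 exactly).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from .gene_models import GeneModel, revcomp


@dataclass
class VariantRecord:
    """One substitution/deletion between two alleles of a locus."""

    position: int                          # 1-based on allele1
    kind: str                              # substitution | deletion | insertion
    ref: str
    alt: str
    region: tuple[str, int] | None = None  # ("exon", i) or ("intron", i), 1-based
    cds_position: int | None = None
    effect: str = ""
    aa_change: tuple[str, int, str] | None = None  # (ref aa, protein pos, alt aa)


@dataclass
class RepeatHit:
    repeat_id: str
    near: int          # ATG-relative negative coordinate closest to the gene
    far: int           # ATG-relative negative coordinate furthest from the gene
    span: int          # |far| - |near|
    percent_identity: float


@dataclass
class UpstreamRegion:
    sequence: str      # 5'->3' on the coding strand; last base is at position -1
    truncated: bool

    def atg_relative(self, offset_from_end: int) -> int:
        """Position of the base ``offset_from_end`` from the 3' end (0 = -1)."""
        return -(offset_from_end + 1)


def _pair_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def align_alleles(allele1: str, allele2: str) -> tuple[str, str]:
    """Global alignment of an allele pair; returns the two gapped rows."""
    if not allele1 or not allele2:
        raise ValueError("alleles must be non-empty")
    aln = _pair_aligner().align(allele1, allele2)[0]
    row1, row2 = str(aln[0]), str(aln[1])
    assert row1.replace("-", "") == allele1 and row2.replace("-", "") == allele2
    return row1, row2


def left_normalize_deletion(seq: str, pos: int, length: int) -> int:
    """Shift a deletion of ``length`` bases starting at 1-based ``pos`` to its
    leftmost equivalent placement in ``seq``."""
    while pos > 1 and seq[pos - 2] == seq[pos + length - 2]:
        pos -= 1
    return pos


def map_cds_to_protein_position(nt_pos: int) -> int:
    """Protein position of a 1-based CDS position: ceil(nt_pos / 3)."""
    if nt_pos < 1:
        raise ValueError("CDS positions are 1-based")
    return math.ceil(nt_pos / 3)


def _gene_local_exons(model: GeneModel) -> list[tuple[int, int]]:
    """Exon intervals in gene-local coordinates (1..gene length), in
    transcription order, derived from the model's exon lengths."""
    start, end = model.gene_interval
    exons = sorted(model.exons)
    if model.strand == "+":
        return [(s - start + 1, e - start + 1) for s, e in exons]
    return [(end - e + 1, end - s + 1) for s, e in reversed(exons)]


def _locate(pos: int, exons: list[tuple[int, int]]) -> tuple[tuple[str, int], int | None]:
    """Region of a gene-local position plus its CDS coordinate when exonic."""
    cds_before = 0
    for i, (s, e) in enumerate(exons, 1):
        if pos < s:
            return ("intron", i - 1), None
        if pos <= e:
            return ("exon", i), cds_before + (pos - s + 1)
        cds_before += e - s + 1
    return ("intron", len(exons)), None  # past the last exon (flanking)


def annotate_effect(variant: VariantRecord, cds1: str, cds2: str) -> VariantRecord:
    """Classify an exonic substitution by comparing the codon in both alleles.

    ``cds2`` must be positionally comparable to ``cds1`` (same length); exonic
    indels are not classified here and receive a frameshift/indel placeholder.
    """
    if variant.kind != "substitution":
        variant.effect = "frameshift/indel"
        return variant
    if variant.cds_position is None:
        raise ValueError("annotate_effect requires an exonic variant with a CDS position")
    if len(cds1) != len(cds2):
        variant.effect = "indel-context"
        return variant
    codon_idx = map_cds_to_protein_position(variant.cds_position)
    c1 = cds1[3 * (codon_idx - 1) : 3 * codon_idx]
    c2 = cds2[3 * (codon_idx - 1) : 3 * codon_idx]
    aa1, aa2 = str(Seq(c1).translate()), str(Seq(c2).translate())
    if aa2 == "*":
        variant.effect = "stop-gained"
    elif aa1 == aa2:
        variant.effect = "synonymous"
    else:
        variant.effect = "non-synonymous"
    variant.aa_change = (aa1, codon_idx, aa2)
    return variant


def call_variants(alignment: tuple[str, str], model: GeneModel | None = None,
                  annotate: bool = True) -> list[VariantRecord]:
    """Call substitutions and deletions from a global allele alignment.

    Each mismatch column yields one substitution; each maximal gap run in
    allele2 yields one deletion (left-aligned on allele1).  With a gene model
    (in allele1 coordinates) every variant is assigned its exon/intron and,
    when exonic and length-preserving, its coding effect.
    """
    row1, row2 = alignment
    allele1 = row1.replace("-", "")
    if model is not None and len(allele1) != model.gene_interval[1] - model.gene_interval[0] + 1:
        raise ValueError("alignment inconsistent with gene model length")

    variants: list[VariantRecord] = []
    pos1 = 0  # 1-based position on allele1 of the current column
    i = 0
    n = len(row1)
    while i < n:
        a, b = row1[i], row2[i]
        if a != "-" and b != "-":
            pos1 += 1
            if a != b:
                variants.append(VariantRecord(pos1, "substitution", a, b))
            i += 1
        elif b == "-":  # deletion in allele2
            run = 0
            deleted = []
            while i < n and row2[i] == "-" and row1[i] != "-":
                run += 1
                deleted.append(row1[i])
                pos1 += 1
                i += 1
            start = pos1 - run + 1
            start = left_normalize_deletion(allele1, start, run)
            variants.append(VariantRecord(start, "deletion", allele1[start - 1 : start - 1 + run], ""))
        else:  # insertion in allele2 relative to allele1
            run = 0
            inserted = []
            while i < n and row1[i] == "-" and row2[i] != "-":
                run += 1
                inserted.append(row2[i])
                i += 1
            variants.append(VariantRecord(max(pos1, 1), "insertion", "", "".join(inserted)))
    variants.sort(key=lambda v: (v.position, v.kind))

    if model is not None:
        exons = _gene_local_exons(model)
        exonic_indel = False
        for v in variants:
            v.region, v.cds_position = _locate(v.position, exons)
            if v.kind != "substitution" and v.region[0] == "exon":
                exonic_indel = True
        if annotate:
            cds1 = model.cds
            cds2 = _apply_exonic_substitutions(cds1, variants) if not exonic_indel else cds1
            for v in variants:
                if v.region[0] != "exon":
                    v.effect = "non-coding"
                elif v.kind == "substitution" and not exonic_indel:
                    annotate_effect(v, cds1, cds2)
                else:
                    v.effect = "frameshift/indel"
    return variants


def _apply_exonic_substitutions(cds: str, variants: list[VariantRecord]) -> str:
    out = list(cds)
    for v in variants:
        if v.kind == "substitution" and v.region and v.region[0] == "exon":
            assert out[v.cds_position - 1] == v.ref
            out[v.cds_position - 1] = v.alt
    return "".join(out)


def call_cds_variants(cds1: str, cds2: str) -> list[VariantRecord]:
    """Diff two CDSs directly (positions are CDS coordinates, all exonic)."""
    row1, row2 = align_alleles(cds1, cds2)
    variants = call_variants((row1, row2), model=None)
    length_preserving = len(cds1) == len(cds2)
    for v in variants:
        v.cds_position = v.position
        v.region = ("exon", 0)
        if v.kind == "substitution" and length_preserving:
            c2 = list(cds1)
            c2[v.cds_position - 1] = v.alt
            annotate_effect(v, cds1, "".join(c2))
        else:
            v.effect = "frameshift/indel"
    return variants


# ---------------------------------------------------------------------------
# Promoter / upstream analysis
# ---------------------------------------------------------------------------

def extract_upstream(model: GeneModel, scaffold_seq: str, window: int = 8000) -> UpstreamRegion:
    """Extract the promoter window 5' of the start codon on the coding strand.

    Returns up to ``window`` bases ending at ATG-relative position -1;
    truncated (with a flag) at the scaffold edge.
    """
    start, end = model.gene_interval
    if model.strand == "+":
        lo = max(1, start - window)
        if start == 1:
            raise ValueError("gene at scaffold edge has zero upstream sequence")
        seq = scaffold_seq[lo - 1 : start - 1]
        truncated = lo > start - window
    else:
        hi = min(len(scaffold_seq), end + window)
        if end == len(scaffold_seq):
            raise ValueError("gene at scaffold edge has zero upstream sequence")
        seq = revcomp(scaffold_seq[end : hi])
        truncated = hi < end + window
    return UpstreamRegion(seq, truncated)


def scan_promoter_repeats(upstream: UpstreamRegion, repeat_library,
                          min_len: int = 200, min_identity: float = 70.0) -> list[RepeatHit]:
    """Locally align each repeat-library entry against the upstream window.

    Hits of at least ``min_len`` aligned bases and ``min_identity`` percent
    identity are reported with ATG-relative interval edges and the
    difference-convention span.
    """
    if not repeat_library:
        warnings.warn("empty repeat library: no promoter scan performed")
        return []
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    window = upstream.sequence
    L = len(window)
    hits: list[RepeatHit] = []
    for rep in repeat_library:
        if not rep.sequence:
            continue
        aln = aligner.align(window, rep.sequence)[0]
        tblocks, _ = aln.aligned
        if len(tblocks) == 0:
            continue
        t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])  # 0-based half-open on window
        row_w, row_r = str(aln[0]), str(aln[1])
        matches = sum(1 for a, b in zip(row_w, row_r) if a == b and a != "-")
        cols = sum(1 for a, b in zip(row_w, row_r) if a != "-" and b != "-")
        if cols == 0:
            continue
        identity = 100.0 * matches / cols
        aln_len = t1 - t0
        if aln_len >= min_len and identity >= min_identity:
            near = -(L - t1 + 1)          # window end base t1-1 -> ATG-relative
            far = -(L - t0)
            hits.append(RepeatHit(rep.id, near, far, abs(far) - abs(near), round(identity, 1)))
    hits.sort(key=lambda h: abs(h.near))
    return hits
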