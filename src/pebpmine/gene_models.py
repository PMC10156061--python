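"""Gene models: spliced CDS-to-genome placement, canonical-structure checks,
translation, premature-stop detection and protein-length deduction.

The PEBP (FT/TFL1/MFT) gene family has a strongly conserved architecture of
four exons and three introns.  Exons II and III are fixed at 62 bp and 41 bp
across the family, while exons I and IV vary within narrow ranges; introns
are variable in length but bounded by canonical GT..AG splice dinucleotides.
These facts drive both the structure validation checks and the synthetic
gene generator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: canonical-structure expectations (bp)
EXON2_LEN = 62
EXON3_LEN = 41
EXON1_RANGE = (192, 216)
EXON4_RANGE = (209, 233)

MIN_INTRON = 20
MIN_EXON = 8


class SplicedAlignmentError(ValueError):
    """The CDS could not be fully placed within the locus."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A located gene: scaffold, strand, exon intervals, CDS, protein, flags.

    ``exons`` are 1-based inclusive intervals in ascending scaffold
    coordinates; for minus-strand genes the CDS is the reverse complement of
    the concatenated exon sequences.
    """

    locus_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str
    protein: str
    flags: set[str] = field(default_factory=set)

    @property
    def exon_lengths(self) -> list[int]:
        order = self.exons if self.strand == "+" else list(reversed(self.exons))
        return [e - s + 1 for s, e in order]

    @property
    def gene_interval(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass
class StructureReport:
    exon_count: int
    exon_lengths: list[int]
    intron_boundaries: list[tuple[str, str]]
    checks: dict[str, str]

    @property
    def all_pass(self) -> bool:
        return all(v == "pass" for v in self.checks.values())


def splice(scaffold_seq: str, exons: list[tuple[int, int]], strand: str) -> str:
    """Concatenate exon sequences (ascending coordinates); reverse-complement
    the result for minus-strand genes."""
    joined = "".join(scaffold_seq[s - 1 : e] for s, e in sorted(exons))
    return revcomp(joined) if strand == "-" else joined


def translate_cds(cds: str) -> str:
    """Standard genetic code; terminal stop dropped, internal stops kept as '*'."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def deduce_protein_length(cds_length: int) -> int:
    """Protein length implied by a CDS length: cds/3 - 1 (terminal stop excluded)."""
    if cds_length % 3 != 0:
        raise ValueError(f"CDS length {cds_length} not divisible by 3")
    if cds_length < 6:
        raise ValueError("CDS must hold at least start + stop codons")
    return cds_length // 3 - 1


def check_cds_protein_consistency(cds_length: int, reported_aa: int) -> bool:
    """True iff a reported (CDS bp, protein aa) pair satisfies the cds/3 - 1 rule."""
    return deduce_protein_length(cds_length) == reported_aa


@dataclass
class PrematureStopReport:
    position: int | None            # 1-based codon index of the first internal stop
    stop_codon: str | None
    downstream_frame_intact: bool


def detect_premature_stop(cds: str) -> PrematureStopReport:
    """Report the first in-frame internal stop, if any.

    ``downstream_frame_intact`` is true iff translation beyond the premature
    stop runs to the terminal codon with no further internal stop — the
    signature of a point nonsense mutation in an otherwise intact frame (as
    with a TGG -> TGA change truncating an FT paralog).
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    first = None
    intact = True
    for i in range(n_codons - 1):  # exclude the terminal codon
        codon = cds[3 * i : 3 * i + 3]
        if codon in ("TAA", "TAG", "TGA"):
            if first is None:
                first = i + 1
            else:
                intact = False
    if first is None:
        return PrematureStopReport(None, None, True)
    return PrematureStopReport(first, cds[3 * (first - 1) : 3 * first], intact)


def validate_structure(model: GeneModel, scaffold_seq: str | None = None) -> StructureReport:
    """Evaluate the six canonical-structure checks of the PEBP family.

    Exon count, the fixed exon II/III lengths and GT-AG splice sites are hard
    checks (``fail`` on violation); the exon I/IV length ranges are soft
    (``warn``) because in-family variation is documented (one paralog carries
    an unusually short 110 bp exon IV caused by a premature stop).
    """
    lengths = model.exon_lengths
    checks: dict[str, str] = {}
    checks["exon_count=4"] = "pass" if len(lengths) == 4 else "fail"

    def _soft(name: str, idx: int, lo: int, hi: int) -> None:
        if idx >= len(lengths):
            checks[name] = "fail"
        else:
            checks[name] = "pass" if lo <= lengths[idx] <= hi else "warn"

    def _hard(name: str, idx: int, expected: int) -> None:
        if idx >= len(lengths):
            checks[name] = "fail"
        else:
            checks[name] = "pass" if lengths[idx] == expected else "fail"

    _soft("exonI_length", 0, *EXON1_RANGE)
    _hard("exonII_length=62", 1, EXON2_LEN)
    _hard("exonIII_length=41", 2, EXON3_LEN)
    _soft("exonIV_length", 3, *EXON4_RANGE)

    # splice dinucleotides: read them from the scaffold when available,
    # otherwise trust the flag set during spliced placement
    boundaries: list[tuple[str, str]] = []
    if scaffold_seq is not None:
        boundaries = intron_boundaries(scaffold_seq, model)
        gt_ag = all(d == "GT" and a == "AG" for d, a in boundaries)
        checks["GT-AG"] = "pass" if gt_ag else "fail"
    else:
        checks["GT-AG"] = "fail" if "noncanonical_splice" in model.flags else "pass"
    return StructureReport(len(lengths), lengths, boundaries, checks)


def intron_boundaries(scaffold_seq: str, model: GeneModel) -> list[tuple[str, str]]:
    """Donor/acceptor dinucleotides of each intron, in transcription order."""
    exons = sorted(model.exons)
    out = []
    introns = [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)]
    if model.strand == "-":
        introns = list(reversed(introns))
    for s, e in introns:
        seq = scaffold_seq[s - 1 : e]
        if model.strand == "-":
            seq = revcomp(seq)
        out.append((seq[:2], seq[-2:]))
    return out


# ---------------------------------------------------------------------------
# Spliced CDS-to-genome alignment
# ---------------------------------------------------------------------------

def _place_exons_exact(cds: str, region: str) -> list[tuple[int, int]] | None:
    """Greedy exact placement of maximal CDS blocks, backtracking over exon
    boundaries.  Prefers fewer/longer exons, then leftmost placements, and
    requires canonical GT..AG introns between consecutive exons.  Returns
    0-based half-open intervals in ``region`` coordinates or None.
    """

    n = len(cds)

    def rec(ci: int, prev_end: int | None) -> list[tuple[int, int]] | None:
        if ci == n:
            return []
        remaining = n - ci
        for L in range(remaining, MIN_EXON - 1, -1):
            if L < remaining and remaining - L < MIN_EXON:
                continue  # would leave an implausibly short trailing exon
            block = cds[ci : ci + L]
            search_from = 0 if prev_end is None else prev_end + MIN_INTRON
            p = region.find(block, search_from)
            while p != -1:
                ok = True
                if prev_end is not None:
                    intron = region[prev_end:p]
                    ok = len(intron) >= MIN_INTRON and intron.startswith("GT") and intron.endswith("AG")
                if ok:
                    rest = rec(ci + L, p + L)
                    if rest is not None:
                        return [(p, p + L)] + rest
                p = region.find(block, p + 1)
        return None

    return rec(0, None)


def _fallback_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -4
    # deletions (CDS paused, genomic bases skipped) = introns: cheap to extend;
    # free at the ends so locus flanks cost nothing
    aligner.open_internal_deletion_score = -8
    aligner.extend_internal_deletion_score = -0.05
    aligner.end_deletion_score = 0
    # insertions (CDS bases unplaced in the genome) are heavily discouraged
    aligner.open_insertion_score = -50
    aligner.extend_insertion_score = -10
    return aligner


def _shift_for_splice(region: str, cds: str, exons: list[tuple[int, int]],
                      cds_breaks: list[int]) -> tuple[list[tuple[int, int]], bool]:
    """Shift intron boundaries within a small window to satisfy GT..AG where a
    score-neutral equivalent placement exists."""
    exons = [list(x) for x in exons]
    all_ok = True
    for k in range(len(exons) - 1):
        a = exons[k][1]       # intron start (0-based)
        b = exons[k + 1][0]   # intron end (exclusive of next exon start)
        c = cds_breaks[k]     # cds index at the junction

        def canonical(ai: int, bi: int) -> bool:
            return region[ai : ai + 2] == "GT" and region[bi - 2 : bi] == "AG"

        if canonical(a, b):
            continue
        found = False
        for delta in range(1, 16):
            # shift junction right: left exon grows by delta
            if (a + delta <= len(region) and b + delta <= len(region)
                    and region[a : a + delta] == cds[c : c + delta]
                    and canonical(a + delta, b + delta)):
                exons[k][1] = a + delta
                exons[k + 1][0] = b + delta
                found = True
                break
            # shift junction left: left exon shrinks by delta
            if (a - delta >= exons[k][0] + 1 and b - delta >= 0
                    and region[b - delta : b] == cds[c - delta : c]
                    and canonical(a - delta, b - delta)):
                exons[k][1] = a - delta
                exons[k + 1][0] = b - delta
                found = True
                break
        if not found:
            all_ok = False
    return [tuple(x) for x in exons], all_ok


def _place_exons_fallback(cds: str, region: str) -> tuple[list[tuple[int, int]], set[str]]:
    """Splice-aware global alignment for CDS blocks containing mismatches."""
    aligner = _fallback_aligner()
    aln = aligner.align(region, cds)[0]  # target=region, query=cds
    region_blocks, cds_blocks = aln.aligned
    flags: set[str] = set()
    exons: list[tuple[int, int]] = []
    cds_breaks: list[int] = []
    prev_cend = None
    covered = 0
    for (cs, ce), (rs, re) in zip(cds_blocks, region_blocks):
        covered += ce - cs
        if prev_cend is not None and cs != prev_cend:
            raise SplicedAlignmentError("CDS not fully placeable within locus")
        if exons and rs == exons[-1][1]:
            exons[-1] = (exons[-1][0], re)
        else:
            if exons:
                cds_breaks.append(cs)
            exons.append((rs, re))
        prev_cend = ce
    if covered != len(cds) or not exons:
        raise SplicedAlignmentError("CDS not fully placeable within locus")
    mism = sum(
        1
        for (cs, ce), (rs, re) in zip(cds_blocks, region_blocks)
        for i in range(ce - cs)
        if cds[cs + i] != region[rs + i]
    )
    if mism:
        flags.add("mismatch")
    if mism > max(3, 0.05 * len(cds)):
        raise SplicedAlignmentError("CDS too divergent from locus")
    exons, splice_ok = _shift_for_splice(region, cds, exons, cds_breaks)
    if not splice_ok:
        flags.add("noncanonical_splice")
    return exons, flags


def spliced_align_cds(cds: str, scaffold, locus: tuple[int, int], strand: str,
                      locus_id: str = "locus") -> GeneModel:
    """Place a CDS onto a scaffold locus as a spliced gene model.

    Exons are found by exact-substring search of maximal CDS blocks (preferring
    the fewest, longest exons and the leftmost placement), falling back to a
    splice-aware global alignment when blocks contain mismatches.  Introns are
    checked for GT..AG; failure to place the full CDS is an error.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    scaffold_seq = scaffold if isinstance(scaffold, str) else scaffold.sequence
    scaffold_id = "scaffold" if isinstance(scaffold, str) else scaffold.id
    s, e = locus
    if s < 1 or e > len(scaffold_seq) or s > e:
        raise ValueError(f"locus {locus} outside scaffold of length {len(scaffold_seq)}")
    region = scaffold_seq[s - 1 : e]
    if strand == "-":
        region = revcomp(region)

    flags: set[str] = set()
    local = _place_exons_exact(cds, region)
    if local is None:
        local, flags = _place_exons_fallback(cds, region)

    # check splice dinucleotides for the exact path too
    for k in range(len(local) - 1):
        intron = region[local[k][1] : local[k + 1][0]]
        if not (intron.startswith("GT") and intron.endswith("AG")):
            flags.add("noncanonical_splice")

    exons: list[tuple[int, int]] = []
    for st0, en0 in local:
        if strand == "+":
            exons.append((s + st0, s + en0 - 1))
        else:
            exons.append((e - en0 + 1, e - st0))
    exons.sort()

    model_cds = splice(scaffold_seq, exons, strand)
    protein = translate_cds(model_cds) if len(model_cds) % 3 == 0 else ""
    if "*" in protein:
        flags.add("internal_stop")
    if not model_cds.startswith("ATG"):
        flags.add("no_start_codon")
    if model_cds[-3:] not in ("TAA", "TAG", "TGA"):
        flags.add("no_stop_codon")
    return GeneModel(locus_id, scaffold_id, strand, exons, model_cds, protein, flags)
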