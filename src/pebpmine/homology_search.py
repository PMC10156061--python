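"""Translated homology search: find PEBP-family candidate loci in genomic
scaffolds by seeding exact protein k-mers between six-frame translations and
query proteins, extending seeds by local alignment (BLOSUM62, affine gaps),
and merging exon-level hits into candidate gene loci.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .gene_models import revcomp
from .io_formats import SeqRecord

DEFAULT_K = 4
DEFAULT_MIN_SCORE = 60.0
DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MAX_GAP = 2000


@dataclass
class TranslatedFrame:
    scaffold_id: str
    frame: int                 # one of +1,+2,+3,-1,-2,-3
    protein: str               # '*' at stops, 'X' at N-containing codons
    scaffold_length: int

    def nucleotide_interval(self, p_start: int, p_end: int) -> tuple[int, int]:
        """1-based inclusive scaffold interval of protein positions
        [p_start, p_end) (0-based half-open on the frame translation)."""
        off = abs(self.frame) - 1
        if self.frame > 0:
            return off + 3 * p_start + 1, off + 3 * p_end
        L = self.scaffold_length
        return L - off - 3 * p_end + 1, L - off - 3 * p_start

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass
class HomologyHit:
    scaffold_id: str
    strand: str
    start: int                 # 1-based inclusive, forward scaffold coordinates
    end: int
    query_id: str
    frame: int
    score: float               # substitution-matrix units
    percent_identity: float
    frame_interval: tuple[int, int]   # 0-based half-open on the frame protein


@dataclass
class CandidateLocus:
    scaffold_id: str
    strand: str
    start: int
    end: int
    best_query: str
    total_score: float
    n_hits: int


def sixframe_translate(scaffold: SeqRecord) -> list[TranslatedFrame]:
    """Translate a scaffold in all six frames (standard code, trailing partial
    codon dropped, stops rendered '*')."""
    seq = scaffold.sequence
    if set(seq) - set("ACGTN"):
        raise ValueError("scaffold contains non-DNA characters")
    frames = []
    rc = revcomp(seq)
    for f in (1, 2, 3):
        for src, sign in ((seq, 1), (rc, -1)):
            sub = src[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            protein = str(Seq(sub).translate()) if sub else ""
            frames.append(TranslatedFrame(scaffold.id, sign * f, protein, len(seq)))
    frames.sort(key=lambda fr: (-fr.frame if fr.frame < 0 else fr.frame, fr.frame < 0))
    return frames


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search(frames: list[TranslatedFrame], queries: list[SeqRecord],
           k: int = DEFAULT_K, min_score: float = DEFAULT_MIN_SCORE,
           min_identity: float = DEFAULT_MIN_IDENTITY,
           max_hits_per_frame: int = 4) -> list[HomologyHit]:
    """Seeded local-alignment search of query proteins against translated frames.

    A frame/query pair is examined only when it shares an exact protein k-mer
    seed; repeated local alignment with masking recovers up to
    ``max_hits_per_frame`` non-overlapping hits (separate exons of one gene
    surface as separate hits, typically in different frames).
    """
    if not queries:
        raise ValueError("query set must be non-empty")
    aligner = _local_aligner()
    hits: list[HomologyHit] = []
    for frame in frames:
        if len(frame.protein) < k:
            continue
        frame_kmers = _kmers(frame.protein, k)
        for query in queries:
            if not (_kmers(query.sequence, k) & frame_kmers):
                continue
            masked = frame.protein
            for _ in range(max_hits_per_frame):
                aln = aligner.align(masked, query.sequence)[0]
                if aln.score < min_score:
                    break
                tblocks, qblocks = aln.aligned
                t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
                row_t, row_q = str(aln[0]), str(aln[1])
                matches = sum(1 for a, b in zip(row_t, row_q) if a == b and a != "-")
                cols = sum(1 for a, b in zip(row_t, row_q) if a != "-" and b != "-")
                identity = 100.0 * matches / cols if cols else 0.0
                if identity >= min_identity:
                    s, e = frame.nucleotide_interval(t0, t1)
                    hits.append(HomologyHit(frame.scaffold_id, frame.strand, s, e,
                                            query.id, frame.frame, float(aln.score),
                                            round(identity, 2), (t0, t1)))
                masked = masked[:t0] + "X" * (t1 - t0) + masked[t1:]
    hits.sort(key=lambda h: (h.scaffold_id, h.strand, h.start, -h.score))
    return hits


def merge_hits_to_loci(hits: list[HomologyHit], max_gap: int = DEFAULT_MAX_GAP
                       ) -> list[CandidateLocus]:
    """Merge same-scaffold, same-strand hits within ``max_gap`` bp into
    candidate loci; each locus carries its best-scoring query."""
    loci: list[CandidateLocus] = []
    current: list[HomologyHit] = []

    def _flush() -> None:
        if not current:
            return
        best = max(current, key=lambda h: h.score)
        loci.append(CandidateLocus(best.scaffold_id, best.strand,
                                   min(h.start for h in current),
                                   max(h.end for h in current),
                                   best.query_id,
                                   sum(h.score for h in current), len(current)))

    for hit in sorted(hits, key=lambda h: (h.scaffold_id, h.strand, h.start)):
        if current and (hit.scaffold_id != current[-1].scaffold_id
                        or hit.strand != current[-1].strand
                        or hit.start - max(h.end for h in current) > max_gap):
            _flush()
            current = []
        current.append(hit)
    _flush()
    return loci
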