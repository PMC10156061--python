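"""Demultiplexing and allele phasing of asymmetric dual-barcoded long
amplicon reads.

Each sequenced molecule is fwd_barcode + gene insert + revcomp(rev_barcode);
the (fwd, rev) combination uniquely identifies a sample.  Reads are assigned
by best two-end barcode match within an edit budget, trimmed, clustered
greedily by identity to a growing consensus, and each sample/locus is typed
homozygous or heterozygous from the retained clusters' coverage ratios.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from .gene_models import revcomp
from .io_formats import SeqRecord

DEFAULT_MAX_EDITS = 2
DEFAULT_IDENTITY = 0.995
DEFAULT_MIN_FRACTION = 0.2
DEFAULT_MIN_READS = 10


@dataclass
class BarcodeAssignment:
    read_id: str
    sample_id: str | None
    orientation: str | None      # forward | reverse
    edits_used: tuple[int, int] | None
    reason: str | None = None    # no-match | ambiguous for unassigned reads


@dataclass
class AlleleCluster:
    sample_id: str
    locus_id: str
    consensus: str
    subread_coverage: int
    amplicon_coverage: int
    coverage_ratio: float        # raw fraction of the locus total

    @property
    def ratio_rounded(self) -> float:
        """Coverage ratio rounded to 1 decimal (reporting convention)."""
        return round(self.coverage_ratio, 1)


@dataclass
class LocusGenotype:
    sample_id: str
    locus_id: str
    alleles: list[AlleleCluster]
    zygosity: str                # homozygous | heterozygous
    flags: set[str] = field(default_factory=set)


def _prefix_edits(pattern: str, text: str) -> tuple[int, int]:
    """Best edit distance of ``pattern`` against a prefix of ``text`` and the
    consumed prefix length."""
    res = edlib.align(pattern, text, mode="SHW", task="locations")
    end = res["locations"][0][1] + 1 if res["locations"] else len(pattern)
    return res["editDistance"], end


def demultiplex(reads: list[SeqRecord], manifest: dict[str, tuple[str, str]],
                max_edits: int = DEFAULT_MAX_EDITS
                ) -> tuple[list[BarcodeAssignment], dict[str, list[SeqRecord]]]:
    """Assign reads to samples by their dual-barcode combination.

    Both read orientations are searched; the sample whose barcode pair gives
    the lowest total edits wins if both per-end distances are within
    ``max_edits`` and the best total is unique.  Barcodes are trimmed from
    the returned inserts (oriented forward).
    """
    if not manifest:
        raise ValueError("barcode manifest is empty")
    if len(set(manifest.values())) != len(manifest):
        raise ValueError("barcode pairs must be unique")

    assignments: list[BarcodeAssignment] = []
    inserts: dict[str, list[SeqRecord]] = {s: [] for s in manifest}
    window = max(len(b) for pair in manifest.values() for b in pair) + max_edits + 2

    for read in reads:
        candidates = []   # (total, fwd_edits, rev_edits, sample, orientation, trimmed)
        for orientation in ("forward", "reverse"):
            seq = read.sequence if orientation == "forward" else revcomp(read.sequence)
            head = seq[:window]
            tail = seq[-window:]
            for sample, (fwd, rev) in manifest.items():
                d_f, f_end = _prefix_edits(fwd, head)
                d_r, r_end = _prefix_edits(revcomp(rev)[::-1], tail[::-1])
                if d_f <= max_edits and d_r <= max_edits:
                    trimmed = seq[f_end : len(seq) - r_end]
                    candidates.append((d_f + d_r, d_f, d_r, sample, orientation, trimmed))
        if not candidates:
            assignments.append(BarcodeAssignment(read.id, None, None, None, "no-match"))
            continue
        candidates.sort(key=lambda c: c[0])
        best = candidates[0]
        ties = [c for c in candidates if c[0] == best[0] and c[3] != best[3]]
        if ties:
            assignments.append(BarcodeAssignment(read.id, None, None, None, "ambiguous"))
            continue
        total, d_f, d_r, sample, orientation, trimmed = best
        assignments.append(BarcodeAssignment(read.id, sample, orientation, (d_f, d_r)))
        inserts[sample].append(SeqRecord(read.id, trimmed, read.description))
    return assignments, inserts


# ---------------------------------------------------------------------------
# Clustering / phasing
# ---------------------------------------------------------------------------

def _distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _identity(a: str, b: str) -> float:
    return 1.0 - _distance(a, b) / max(len(a), len(b))


def _majority_consensus(reads: list[str], backbone: str) -> str:
    """Majority-per-column consensus of reads aligned to a backbone,
    including majority insertions."""
    n = len(reads)
    if n == 1:
        return reads[0]
    sub_votes: list[Counter] = [Counter() for _ in range(len(backbone))]
    ins_votes: list[Counter] = [Counter() for _ in range(len(backbone) + 1)]
    for read in reads:
        res = edlib.align(read, backbone, task="path", mode="NW")
        nice = edlib.getNiceAlignment(res, read, backbone)
        q, t = nice["query_aligned"], nice["target_aligned"]
        pos = 0               # backbone position (0-based) of the next column
        pending = []
        for qc, tc in zip(q, t):
            if tc == "-":
                pending.append(qc)
                continue
            ins_votes[pos]["".join(pending)] += 1
            pending = []
            sub_votes[pos][qc] += 1
            pos += 1
        ins_votes[pos]["".join(pending)] += 1
    out = []
    for i in range(len(backbone)):
        ins, _ = ins_votes[i].most_common(1)[0]
        if ins and ins_votes[i][ins] > n / 2:
            out.append(ins)
        base, _ = sub_votes[i].most_common(1)[0]
        if base != "-":
            out.append(base)
    ins, _ = ins_votes[len(backbone)].most_common(1)[0]
    if ins and ins_votes[len(backbone)][ins] > n / 2:
        out.append(ins)
    return "".join(out)


def phase_alleles(inserts: list[SeqRecord], sample_id: str = "sample",
                  locus_id: str = "locus",
                  identity_threshold: float = DEFAULT_IDENTITY,
                  min_fraction: float = DEFAULT_MIN_FRACTION,
                  min_reads: int = DEFAULT_MIN_READS) -> list[AlleleCluster]:
    """Cluster one sample's inserts into phased allele consensuses.

    Greedy seeding (longest unclustered read first) admits reads at
    >= ``identity_threshold`` to the cluster consensus; consensuses are then
    recomputed by per-column majority, deduplicated, and every read is
    re-assigned to its nearest consensus.  Clusters holding less than
    ``min_fraction`` of the locus' reads are discarded as noise.
    """
    if len(inserts) < min_reads:
        raise ValueError(f"need at least {min_reads} reads to phase (got {len(inserts)})")
    seqs = [r.sequence for r in inserts]
    n = len(seqs)

    # pass 1: greedy rough partition.  A cluster is meant to hold reads within
    # identity t of its (denoised) consensus; two such reads are within
    # 2t - 1 of each other, so that triangle-inequality radius governs
    # admission against the raw seed read.
    pair_radius = max(0.0, 2 * identity_threshold - 1)
    order = sorted(range(n), key=lambda i: -len(seqs[i]))
    cluster_seed: list[str] = []
    members: list[list[int]] = []
    for i in order:
        placed = False
        for ci, seed in enumerate(cluster_seed):
            if _identity(seqs[i], seed) >= pair_radius:
                members[ci].append(i)
                placed = True
                break
        if not placed:
            cluster_seed.append(seqs[i])
            members.append([i])

    # pass 2: allele candidates = deduplicated majority consensuses of the
    # sizable rough clusters (per-column majority cancels independent read
    # errors, so same-allele clusters converge to identical consensuses)
    sizable = [ci for ci in range(len(members)) if len(members[ci]) >= 3]
    if not sizable:
        sizable = sorted(range(len(members)), key=lambda ci: -len(members[ci]))[:2]
    candidates: list[str] = []
    for ci in sorted(sizable, key=lambda ci: -len(members[ci])):
        cons = _majority_consensus([seqs[i] for i in members[ci]], cluster_seed[ci])
        if cons not in candidates:
            candidates.append(cons)

    # pass 3: nearest-candidate assignment, noise filtering, final consensus
    assigned: list[list[int]] = [[] for _ in candidates]
    for i, s in enumerate(seqs):
        dists = [_distance(s, c) for c in candidates]
        assigned[dists.index(min(dists))].append(i)
    merged: dict[str, list[int]] = {}
    for c, m in zip(candidates, assigned):
        if not m or len(m) / n < min_fraction:
            continue
        final = _majority_consensus([seqs[i] for i in m], c)
        merged.setdefault(final, []).extend(m)

    clusters = []
    for c, m in sorted(merged.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        clusters.append(AlleleCluster(sample_id, locus_id, c, len(m), len(m), 0.0))
    retained_total = sum(cl.amplicon_coverage for cl in clusters)
    if retained_total == 0:
        raise ValueError("all clusters fell below the noise fraction")
    for cl in clusters:
        cl.coverage_ratio = cl.amplicon_coverage / retained_total
    return clusters


def genotype_locus(clusters: list[AlleleCluster]) -> LocusGenotype:
    """Call zygosity from retained clusters: one cluster is homozygous, two
    are heterozygous; more than two flags possible contamination."""
    if not clusters:
        raise ValueError("no retained allele clusters")
    sample_id = clusters[0].sample_id
    locus_id = clusters[0].locus_id
    if len(clusters) == 1:
        return LocusGenotype(sample_id, locus_id, clusters, "homozygous")
    if len(clusters) == 2:
        flags = set()
        if not all(0.2 <= c.coverage_ratio <= 0.8 for c in clusters):
            flags.add("unbalanced_alleles")
        return LocusGenotype(sample_id, locus_id, clusters, "heterozygous", flags)
    return LocusGenotype(sample_id, locus_id, clusters, "heterozygous",
                         {"multi-allelic/contamination"})
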