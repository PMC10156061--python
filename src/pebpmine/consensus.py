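"""Cross-assembly consensus calling.

Gene CDSs mined independently from multiple genome assemblies are grouped by
locus; a consensus is accepted only where at least two assemblies provide the
identical sequence (100 % identity), and any remaining divergent assembly
sequence is recorded as a variant with its coding-effect annotation.  This
mirrors the confidence rule used when surveying a gene family across several
assemblies of unequal quality.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .variant_annotation import VariantRecord, call_cds_variants


@dataclass
class ConsensusRecord:
    locus_id: str
    per_assembly_cds: dict[str, str]
    consensus_cds: str | None
    agreement: int
    variants: list[tuple[str, list[VariantRecord]]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)


def derive_consensus(per_assembly_cds: dict[str, str], locus_id: str = "locus"
                     ) -> ConsensusRecord:
    """Call the consensus CDS shared verbatim by the largest subset (>= 2) of
    assemblies; divergent assemblies are diffed against it as variants.

    Order-invariant in the input map.  A tie between disjoint agreeing pairs
    is resolved toward the pair containing the lexicographically first
    assembly name and flagged ``ambiguous_consensus``.
    """
    present = {a: cds for a, cds in per_assembly_cds.items() if cds}
    if len(present) < 2:
        raise ValueError("consensus requires CDSs from at least two assemblies")

    groups: dict[str, list[str]] = defaultdict(list)
    for assembly in sorted(present):
        groups[present[assembly]].append(assembly)
    best_size = max(len(v) for v in groups.values())
    record = ConsensusRecord(locus_id, dict(per_assembly_cds), None, 0)
    if best_size < 2:
        record.flags.add("no_consensus")
        record.agreement = 1
        return record

    candidates = [seq for seq, members in groups.items() if len(members) == best_size]
    if len(candidates) > 1:
        record.flags.add("ambiguous_consensus")
        candidates.sort(key=lambda seq: min(groups[seq]))
    consensus = candidates[0]
    record.consensus_cds = consensus
    record.agreement = best_size
    for assembly in sorted(present):
        seq = present[assembly]
        if seq != consensus:
            record.variants.append((assembly, call_cds_variants(consensus, seq)))
    return record


def match_loci(per_assembly_sets: dict[str, dict[str, str]], min_identity: float = 0.95
               ) -> dict[str, dict[str, str]]:
    """Match loci across assemblies by reciprocal best identity.

    ``per_assembly_sets`` maps assembly -> {cds_id: sequence}.  CDSs are
    clustered greedily: each sequence joins the first cluster whose exemplar
    it matches at >= ``min_identity`` (edit-distance identity over the longer
    sequence) with the match reciprocal by construction.  Returns
    locus_id -> {assembly: cds}.
    """
    clusters: list[dict] = []   # {"exemplar": str, "members": {assembly: (cds_id, seq)}}
    for assembly in sorted(per_assembly_sets):
        for cds_id, seq in sorted(per_assembly_sets[assembly].items()):
            placed = False
            for cl in clusters:
                ex = cl["exemplar"]
                d = edlib.align(seq, ex, task="distance")["editDistance"]
                if 1 - d / max(len(seq), len(ex)) >= min_identity and assembly not in cl["members"]:
                    cl["members"][assembly] = (cds_id, seq)
                    placed = True
                    break
            if not placed:
                clusters.append({"exemplar": seq, "members": {assembly: (cds_id, seq)}})
    out: dict[str, dict[str, str]] = {}
    for cl in clusters:
        # name the locus after the most common member id
        ids = [cid for cid, _ in cl["members"].values()]
        locus_id = max(sorted(set(ids)), key=ids.count)
        out[locus_id] = {a: seq for a, (_, seq) in cl["members"].items()}
    return out


CLADES = ("FT-like", "TFL1-like", "MFT-like")


def summarize_family(records: list[ConsensusRecord], clade_calls: dict[str, str]
                     ) -> pd.DataFrame:
    """Per-assembly counts of FT-like / TFL1-like / MFT-like loci."""
    assemblies = sorted({a for r in records for a in r.per_assembly_cds})
    table = pd.DataFrame(0, index=assemblies, columns=list(CLADES))
    for record in records:
        clade = clade_calls.get(record.locus_id)
        if clade not in CLADES:
            raise ValueError(f"locus {record.locus_id} has no clade classification")
        for assembly, cds in record.per_assembly_cds.items():
            if cds:
                table.loc[assembly, clade] += 1
    return table
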