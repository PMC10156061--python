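"""Diagnostic-residue classification of PEBP candidate proteins.

Candidates are mapped by global alignment onto reference-numbered positions.
The clade call rests on the single most discriminating site — Tyr at FT
position 85 (FT-like), His at the homologous TFL1 position 88 (TFL1-like) or
Trp there (MFT-like) — with Gln140/Asp144 recorded as supporting evidence.
For FT-like proteins the inducer/repressor prediction follows the external
loop of exon IV: inducers carry Tyr134 AND Trp138; loss of either marks a
repressor-like paralog, while changes confined to Gly137 do not abolish
inducer activity and are only noted.  The segment-B motif (positions
128-141, LGRQTVYAPGWRQN) and the LYN triad are scanned for completeness.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .references import (FT_DIAGNOSTICS, SEGMENT_B_MOTIF, SEGMENT_B_RANGE,
                         TFL1_DIAGNOSTICS, TRIAD_POSITIONS, reference_proteins)


class NotPEBPCandidateError(ValueError):
    """Alignment identity to every reference fell below the floor."""


@dataclass
class ResidueMap:
    reference_id: str
    identity: float                                     # fraction of identical aligned columns
    mapping: dict[int, tuple[int | None, str | None]]   # ref pos -> (candidate pos | None, residue | None)
    diagnostic_positions: tuple[int, ...]

    def residue_at(self, ref_pos: int) -> str | None:
        return self.mapping.get(ref_pos, (None, None))[1]

    def candidate_position(self, ref_pos: int) -> int | None:
        return self.mapping.get(ref_pos, (None, None))[0]


@dataclass
class MotifReport:
    segment_b_observed: str
    segment_b_mismatches: int | None     # None when the window is unmappable
    triad_observed: str


@dataclass
class FunctionCall:
    clade: str                           # FT-like | TFL1-like | MFT-like | unclassified
    ft_function: str                     # inducer | repressor-like | indeterminate | n/a
    evidence: list[tuple[int, str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    motif_report: MotifReport | None = None
    residue_map: ResidueMap | None = None


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    # terminal overhangs are free: candidate/reference length differences are
    # not evidence against homology
    aligner.end_gap_score = 0
    return aligner


def map_to_reference(candidate: str, reference: str, reference_id: str = "FT",
                     min_identity: float = 0.25) -> ResidueMap:
    """Project reference-numbered positions onto a candidate protein.

    Global alignment (BLOSUM62, gap open 10 / extend 1, free end gaps);
    every reference position receives an entry, gapped positions map to
    (None, None).
    """
    if len(candidate) < 100 or len(reference) < 100:
        raise ValueError("both sequences must be at least 100 residues")
    aln = _global_aligner().align(reference, candidate)[0]
    row_ref, row_cand = str(aln[0]), str(aln[1])
    mapping: dict[int, tuple[int | None, str | None]] = {}
    r = c = 0
    matches = cols = 0
    for a, b in zip(row_ref, row_cand):
        if a != "-" and b != "-":
            r += 1
            c += 1
            mapping[r] = (c, b)
            cols += 1
            matches += a == b
        elif a != "-":
            r += 1
            mapping[r] = (None, None)
        else:
            c += 1
    identity = matches / cols if cols else 0.0
    if identity < min_identity:
        raise NotPEBPCandidateError(
            f"identity {identity:.2f} to {reference_id} reference below {min_identity}")
    diag = tuple(FT_DIAGNOSTICS) if reference_id == "FT" else tuple(TFL1_DIAGNOSTICS)
    return ResidueMap(reference_id, identity, mapping, diag)


_CLADE_POSITION = {"FT": 85, "TFL1": 88}
_SECONDARY = {"FT": (140, "Q"), "TFL1": (144, "D")}


def call_clade(residue_map: ResidueMap) -> FunctionCall:
    """Clade verdict from the primary diagnostic residue of a residue map."""
    pos = _CLADE_POSITION[residue_map.reference_id]
    observed = residue_map.residue_at(pos)
    call = FunctionCall("unclassified", "n/a")
    if observed is None:
        call.notes.append(f"gap at diagnostic position {pos}")
        call.evidence.append((pos, "Y/H/W", "-"))
        return call
    call.evidence.append((pos, "Y/H/W", observed))
    if observed == "Y":
        call.clade = "FT-like"
    elif observed == "H":
        call.clade = "TFL1-like"
    elif observed == "W":
        call.clade = "MFT-like"
    sec_pos, sec_exp = _SECONDARY[residue_map.reference_id]
    sec_obs = residue_map.residue_at(sec_pos)
    call.evidence.append((sec_pos, sec_exp, sec_obs or "-"))
    if call.clade != "unclassified" and sec_obs != sec_exp:
        call.notes.append(f"secondary residue {sec_exp}{sec_pos} not conserved (observed {sec_obs})")
    return call


def call_ft_function(residue_map: ResidueMap) -> FunctionCall:
    """Inducer/repressor prediction for an FT-like candidate.

    Inducer iff Tyr134 AND Trp138; otherwise repressor-like.  A change at
    Gly137 alone leaves the inducer verdict intact with a note.  E109, N152
    and Q140 states are recorded as annotations only.
    """
    if residue_map.reference_id != "FT":
        raise ValueError("FT function calls require an FT-numbered map")
    call = FunctionCall("FT-like", "indeterminate")
    r134, r138 = residue_map.residue_at(134), residue_map.residue_at(138)
    call.evidence.append((134, "Y", r134 or "-"))
    call.evidence.append((138, "W", r138 or "-"))
    if r134 is None or r138 is None:
        call.notes.append("gap at position 134 or 138")
        return call
    if r134 == "Y" and r138 == "W":
        call.ft_function = "inducer"
        r137 = residue_map.residue_at(137)
        if r137 != "G":
            call.notes.append(f"G137 variant (observed {r137 or '-'})")
    else:
        call.ft_function = "repressor-like"
    for pos, expected in ((109, "E"), (152, "N"), (140, "Q"), (137, "G")):
        call.evidence.append((pos, expected, residue_map.residue_at(pos) or "-"))
    return call


def scan_motifs(candidate: str, residue_map: ResidueMap) -> MotifReport:
    """Report the candidate's segment-B window and triad via the residue map."""
    lo, hi = SEGMENT_B_RANGE
    observed = []
    mapped = 0
    for pos in range(lo, hi + 1):
        res = residue_map.residue_at(pos)
        observed.append(res or "-")
        mapped += res is not None
    seg = "".join(observed)
    mismatches = (sum(1 for a, b in zip(seg, SEGMENT_B_MOTIF) if a != b)
                  if mapped else None)
    triad = "".join(residue_map.residue_at(p) or "-" for p in TRIAD_POSITIONS)
    return MotifReport(seg if mapped else "", mismatches, triad)


def classify_protein(candidate: str, references: dict[str, str] | None = None
                     ) -> FunctionCall:
    """Full classification of one candidate protein.

    The candidate is mapped to both the FT- and TFL1-numbered references; the
    higher-identity alignment provides the clade residue (flagged when the
    identities differ by < 2 %).  FT-like candidates additionally receive the
    inducer/repressor call and the motif scan.
    """
    refs = references or reference_proteins()
    maps: dict[str, ResidueMap] = {}
    for ref_id in ("FT", "TFL1"):
        try:
            maps[ref_id] = map_to_reference(candidate, refs[ref_id], ref_id)
        except NotPEBPCandidateError:
            continue
    if not maps:
        raise NotPEBPCandidateError("candidate aligns to no reference above the identity floor")
    best_id = max(maps, key=lambda k: maps[k].identity)
    best = maps[best_id]
    call = call_clade(best)
    if len(maps) == 2 and abs(maps["FT"].identity - maps["TFL1"].identity) < 0.02:
        alt = call_clade(maps["FT" if best_id == "TFL1" else "TFL1"])
        if alt.clade != call.clade:
            call.notes.append("reference choice ambiguous: FT/TFL1 identities within 2%")
    if call.clade == "FT-like" and "FT" in maps:
        fn = call_ft_function(maps["FT"])
        call.ft_function = fn.ft_function
        call.evidence.extend(fn.evidence)
        call.notes.extend(fn.notes)
    ft_map = maps.get("FT", best)
    call.motif_report = scan_motifs(candidate, ft_map)
    call.residue_map = best
    return call
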