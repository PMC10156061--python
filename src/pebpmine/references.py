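"""Synthetic PEBP-like reference proteins carrying the published diagnostic
residue states.

These are NOT natural sequences: they are deterministic, synthetic scaffolds
built so that every clade- and function-diagnostic state sits at its
literature-numbered position (FT numbering: Tyr85, Glu109, Tyr134, Gly137,
Trp138, Gln140, Asn152, the segment-B motif LGRQTVYAPGWRQN at 128-141 and an
LYN triad; TFL1 numbering: His88, Asp144; MFT: Trp at the position homologous
to FT 85).  They let the classifier, phylogeny and fixture machinery run with
no external download; users may substitute real reference proteins by file.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: conserved segment-B motif of inducer FT proteins (reference positions 128-141)
SEGMENT_B_MOTIF = "LGRQTVYAPGWRQN"
SEGMENT_B_RANGE = (128, 141)
#: reference positions of the conserved LYN triad (FHN in the repressor-like paralog)
TRIAD_POSITIONS = (120, 121, 122)

#: diagnostic residue expectations by reference numbering
FT_DIAGNOSTICS = {85: "Y", 109: "E", 134: "Y", 137: "G", 138: "W", 140: "Q", 152: "N"}
TFL1_DIAGNOSTICS = {88: "H", 144: "D"}

#: preferred codon per amino acid for deterministic reverse translation
PREFERRED_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_BASE_SEED = 20230503  # fixed so the bundled references are stable artifacts


def _set(seq: list[str], pos1: int, residue: str) -> None:
    seq[pos1 - 1] = residue


@lru_cache(maxsize=1)
def _base_scaffold() -> str:
    rng = np.random.default_rng(_BASE_SEED)
    seq = list(rng.choice(list(AMINO_ACIDS), size=175))
    seq[0] = "M"
    return "".join(seq)


def _mutate_positions(seq: list[str], rng, n: int, reserved: set[int]) -> None:
    """Apply n substitutions at seeded non-reserved 1-based positions."""
    candidates = [p for p in range(2, len(seq) + 1) if p not in reserved]
    for pos in rng.choice(candidates, size=n, replace=False):
        old = seq[pos - 1]
        choices = [a for a in AMINO_ACIDS if a != old]
        seq[pos - 1] = str(rng.choice(choices))


@lru_cache(maxsize=1)
def reference_proteins() -> dict[str, str]:
    """Return the three synthetic clade references: FT (175 aa), TFL1 (175 aa),
    MFT (170 aa).

    The TFL1 reference carries small N-terminal insertions relative to FT so
    that its His88/Asp144 align with FT's Tyr85/Gln140, mirroring the offset
    between the two published numbering schemes.  Clades differ by ~20
    additional background substitutions so that distances and bootstrap
    signal between subfamilies are unambiguous.
    """
    base = list(_base_scaffold())

    # ---- FT reference -----------------------------------------------------
    ft = list(base)
    for pos, aa in FT_DIAGNOSTICS.items():
        _set(ft, pos, aa)
    for off, aa in enumerate(SEGMENT_B_MOTIF):
        _set(ft, SEGMENT_B_RANGE[0] + off, aa)
    for pos, aa in zip(TRIAD_POSITIONS, "LYN"):
        _set(ft, pos, aa)
    _set(ft, 127, "R")   # background states used by the cross-assembly variant fixture
    _set(ft, 156, "S")

    # ---- TFL1 reference ---------------------------------------------------
    rng = np.random.default_rng(_BASE_SEED + 1)
    tfl1 = list(ft)
    ins1 = [str(rng.choice(list(AMINO_ACIDS))) for _ in range(3)]
    ins2 = [str(rng.choice(list(AMINO_ACIDS)))]
    tfl1 = tfl1[:60] + ins1 + tfl1[60:]          # positions >60 shift +3 (85 -> 88)
    tfl1 = tfl1[:103] + ins2 + tfl1[103:]        # positions >100 shift +4 (140 -> 144)
    _set(tfl1, 88, "H")
    _set(tfl1, 144, "D")
    reserved = {1, 88, 144}
    _mutate_positions(tfl1, rng, 20, reserved)
    tfl1 = tfl1[:175]

    # ---- MFT reference ----------------------------------------------------
    rng = np.random.default_rng(_BASE_SEED + 2)
    mft = list(ft)
    _set(mft, 85, "W")
    # fixed ancestral states at the positions later probed by the allele-pair
    # fixtures (own-numbering 21/93/117/123)
    _set(mft, 21, "V")
    _set(mft, 93, "I")
    _set(mft, 117, "I")
    _set(mft, 123, "A")
    reserved = {1, 21, 85, 93, 117, 123}
    reserved.update(TRIAD_POSITIONS)
    reserved.update(range(SEGMENT_B_RANGE[0], SEGMENT_B_RANGE[1] + 1))
    _mutate_positions(mft, rng, 20, reserved)
    mft = mft[:170]

    return {"FT": "".join(ft), "TFL1": "".join(tfl1), "MFT": "".join(mft)}


def reverse_translate(protein: str, codon_overrides: dict[int, str] | None = None,
                      stop: str = "TGA") -> str:
    """Deterministic reverse translation with a fixed preferred-codon table.

    ``codon_overrides`` maps 1-based protein positions to explicit codons
    (used to realize specific printed nucleotide substitutions).
    """
    codon_overrides = codon_overrides or {}
    codons = []
    for i, aa in enumerate(protein, 1):
        if i in codon_overrides:
            codon = codon_overrides[i]
            if str(Seq(codon).translate()) != aa:
                raise ValueError(f"override codon {codon} at {i} does not encode {aa}")
            codons.append(codon)
        else:
            codons.append(PREFERRED_CODON[aa])
    return "".join(codons) + stop
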