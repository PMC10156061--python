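"""Synthetic inputs for every pipeline stage: scaffolds with embedded 4-exon
PEBP genes, multi-assembly variant sets, allele pairs realizing the published
variant tables, and barcoded long-amplicon read pools.

All generators are pure functions of (inputs, seed).  The packaged fixture
bundle (:func:`paper_fixtures`) is deterministic and reproduces, at desk
scale, the study conditions: a 513 bp MFT-like CDS whose two alleles differ
by 2 intronic substitutions, 1 bp + 4 bp intronic deletions and four
non-synonymous exonic substitutions at CDS positions 61/277/350/367
(V21F, I93L, I117R, A123T); a TFL1-like locus whose alleles differ by two
intronic substitutions and a single 12 bp intronic deletion (1027 vs
1015 bp); and a 12-sample amplicon cohort with one ~1:1 heterozygote.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .gene_models import GeneModel, revcomp, splice, translate_cds
from .io_formats import SeqRecord
from .references import reference_proteins, reverse_translate
from .variant_annotation import left_normalize_deletion

_BASES = "ACGT"
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}

_FIXTURE_SEED = 773_201  # fixed: the bundle is a study condition, not a dial


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass
class GeneTemplate:
    """A 4-exon gene blueprint: exon sequences plus intron lengths."""

    name: str
    exon_seqs: list[str]
    intron_lengths: list[int]

    def __post_init__(self) -> None:
        if len(self.exon_seqs) != 4 or len(self.intron_lengths) != 3:
            raise ValueError("a gene template has exactly 4 exons and 3 introns")
        cds = self.cds
        if len(cds) % 3 != 0:
            raise ValueError("concatenated exons must form a CDS divisible by 3")
        if not cds.startswith("ATG"):
            raise ValueError("CDS must start with ATG")
        if cds[-3:] not in ("TAA", "TAG", "TGA"):
            raise ValueError("CDS must end with a stop codon")
        if any(n < 4 for n in self.intron_lengths):
            raise ValueError("introns must hold at least GT..AG")

    @property
    def cds(self) -> str:
        return "".join(self.exon_seqs)

    @property
    def protein(self) -> str:
        return translate_cds(self.cds)

    @property
    def gene_length(self) -> int:
        return len(self.cds) + sum(self.intron_lengths)


@dataclass
class Edit:
    position: int           # 1-based on the base sequence (gene or scaffold)
    kind: str               # substitution | deletion
    ref: str
    alt: str
    region_hint: str = ""   # exon | intron (informational)


@dataclass
class VariantSpec:
    edits: list[Edit]

    def __post_init__(self) -> None:
        prev_end = 0
        for e in self.edits:
            if e.kind == "substitution" and (len(e.ref) != 1 or len(e.alt) != 1):
                raise ValueError("substitutions are single-base")
            if e.kind == "deletion" and e.alt != "":
                raise ValueError("deletion alt must be empty")
            if e.position <= prev_end:
                raise ValueError("edit positions must be strictly increasing and non-overlapping")
            prev_end = e.position + (len(e.ref) - 1 if e.kind == "deletion" else 0)

    @property
    def deleted_bases(self) -> int:
        return sum(len(e.ref) for e in self.edits if e.kind == "deletion")


@dataclass
class SamplePlan:
    """One barcoded sample in an amplicon pool.

    ``allele_counts``, when given, allocates reads to alleles exactly (used by
    fixtures that realize a printed coverage table); otherwise each read draws
    its allele independently from ``allele_weights``.
    """

    sample_id: str
    barcode_pair: tuple[str, str]
    allele_weights: dict[str, float]
    n_reads: int
    error_rate: float = 0.005
    allele_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.allele_weights.values()) - 1.0) > 1e-9:
            raise ValueError("allele weights must sum to 1")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must lie in [0, 0.1)")
        if self.allele_counts is not None and sum(self.allele_counts.values()) != self.n_reads:
            raise ValueError("allele_counts must sum to n_reads")


# ---------------------------------------------------------------------------
# Sequence generators
# ---------------------------------------------------------------------------

def make_scaffold(length: int, gc: float = 0.42, seed: int = 0,
                  scaffold_id: str = "scaffold1") -> SeqRecord:
    """I.i.d. random DNA of the requested length and GC content."""
    if length <= 0:
        raise ValueError("scaffold length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list(_BASES), size=length, p=p))
    return SeqRecord(scaffold_id, seq)


def _random_intron(length: int, rng) -> str:
    body = "".join(rng.choice(list(_BASES), size=length - 4))
    return "GT" + body + "AG"


def realize_gene(template: GeneTemplate, seed: int = 0, locus_id: str | None = None
                 ) -> tuple[str, GeneModel]:
    """Materialize a template into a gene sequence (exons + seeded canonical
    GT..AG introns) plus a gene-local model (coordinates 1..gene length)."""
    rng = np.random.default_rng(seed)
    locus_id = locus_id or template.name
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for i, exon in enumerate(template.exon_seqs):
        exons.append((pos + 1, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
        if i < 3:
            intron = _random_intron(template.intron_lengths[i], rng)
            parts.append(intron)
            pos += len(intron)
    gene_seq = "".join(parts)
    cds = template.cds
    model = GeneModel(locus_id, locus_id, "+", exons, cds, translate_cds(cds))
    return gene_seq, model


def embed_gene(scaffold: SeqRecord, template: GeneTemplate, start: int, strand: str,
               seed: int = 0, existing: list[GeneModel] = (),
               locus_id: str | None = None) -> tuple[SeqRecord, GeneModel]:
    """Embed a gene in a scaffold (replacing the resident bases) and return
    the updated scaffold plus the model in forward-scaffold coordinates.

    Splicing the returned model's exons out of the returned scaffold
    reproduces the template CDS exactly; minus strand means the reverse
    complement is inserted, with coordinates kept on the forward strand.
    """
    gene_seq, local = realize_gene(template, seed=seed, locus_id=locus_id)
    end = start + len(gene_seq) - 1
    if start < 1 or end > len(scaffold.sequence):
        raise ValueError(f"gene [{start}, {end}] does not fit in scaffold of length {len(scaffold.sequence)}")
    for other in existing:
        os, oe = other.gene_interval
        if not (end < os or start > oe):
            raise ValueError(f"gene overlaps previously embedded locus {other.locus_id}")
    insert = gene_seq if strand == "+" else revcomp(gene_seq)
    seq = scaffold.sequence[: start - 1] + insert + scaffold.sequence[end:]
    if strand == "+":
        exons = [(start + s - 1, start + e - 1) for s, e in local.exons]
    else:
        exons = sorted((end - e + 1, end - s + 1) for s, e in local.exons)
    model = GeneModel(local.locus_id, scaffold.id, strand, exons, local.cds, local.protein)
    return SeqRecord(scaffold.id, seq, scaffold.description), model


def apply_spec(sequence: str, spec: VariantSpec) -> str:
    """Apply a variant spec (positions on the input sequence) right-to-left."""
    out = sequence
    for e in sorted(spec.edits, key=lambda x: -x.position):
        i = e.position - 1
        if out[i : i + len(e.ref)] != e.ref:
            raise ValueError(f"ref mismatch at position {e.position}: expected {e.ref!r}, found {out[i:i+len(e.ref)]!r}")
        if e.kind == "substitution":
            out = out[:i] + e.alt + out[i + 1 :]
        else:
            out = out[:i] + out[i + len(e.ref) :]
    return out


def make_assembly_set(base_scaffold: SeqRecord, plans: dict[str, VariantSpec]
                      ) -> dict[str, SeqRecord]:
    """Derive per-assembly scaffolds from a base by applying each assembly's
    variant spec; an empty spec yields an identical copy."""
    out = {}
    for name, spec in plans.items():
        out[name] = SeqRecord(base_scaffold.id, apply_spec(base_scaffold.sequence, spec),
                              f"assembly={name}")
    return out


def make_allele_pair(gene_seq: str | SeqRecord, spec: VariantSpec,
                     name: str = "locus") -> tuple[SeqRecord, SeqRecord]:
    """allele1 = input gene; allele2 = input with the spec's edits applied."""
    seq = gene_seq.sequence if isinstance(gene_seq, SeqRecord) else gene_seq
    allele2 = apply_spec(seq, spec)
    assert len(seq) - len(allele2) == spec.deleted_bases
    return (SeqRecord(f"{name}_allele1", seq), SeqRecord(f"{name}_allele2", allele2))


def random_variant_spec(gene_seq: str, rng, n_sub: int = 3, n_del: int = 2,
                        max_del: int = 12, min_separation: int = 8) -> VariantSpec:
    """Draw a random, left-normalized, well-separated variant spec.

    Deletions are normalized to their leftmost equivalent placement so that
    diffing the realized allele pair recovers the spec verbatim.
    """
    n = len(gene_seq)
    for _ in range(200):
        kinds = ["substitution"] * n_sub + ["deletion"] * n_del
        rng.shuffle(kinds)
        edits: list[Edit] = []
        cursor = 10
        ok = True
        for kind in kinds:
            limit = n - 20
            if cursor >= limit:
                ok = False
                break
            pos = int(rng.integers(cursor, limit))
            if kind == "substitution":
                ref = gene_seq[pos - 1]
                alt = str(rng.choice([b for b in _BASES if b != ref]))
                edits.append(Edit(pos, "substitution", ref, alt))
                cursor = pos + min_separation
            else:
                length = int(rng.integers(1, max_del + 1))
                if pos + length >= limit:
                    ok = False
                    break
                npos = left_normalize_deletion(gene_seq, pos, length)
                if edits and npos <= edits[-1].position + min_separation:
                    ok = False
                    break
                edits.append(Edit(npos, "deletion", gene_seq[npos - 1 : npos - 1 + length], ""))
                cursor = pos + length + min_separation
        if not ok:
            continue
        edits.sort(key=lambda e: e.position)
        try:
            return VariantSpec(edits)
        except ValueError:
            continue
    raise RuntimeError("could not draw a well-separated variant spec")


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

def _add_noise(seq: str, error_rate: float, rng) -> str:
    """Per-base substitution/insertion/deletion noise split 60/20/20 across
    the total rate (0.3/0.1/0.1 % at the 0.5 % default, mimicking
    circular-consensus-quality long reads)."""
    if error_rate == 0:
        return seq
    p_sub, p_ins, p_del = 0.6 * error_rate, 0.2 * error_rate, 0.2 * error_rate
    out = []
    for base in seq:
        r = rng.random()
        if r < p_sub:
            out.append(str(rng.choice([b for b in _BASES if b != base])))
        elif r < p_sub + p_ins:
            out.append(base)
            out.append(str(rng.choice(list(_BASES))))
        elif r < p_sub + p_ins + p_del:
            continue
        else:
            out.append(base)
    return "".join(out)


def simulate_amplicon_reads(alleles: dict[str, str | SeqRecord],
                            plans: list[SamplePlan], seed: int = 0
                            ) -> tuple[list[SeqRecord], list[dict]]:
    """Simulate a barcoded amplicon pool.

    Each read is fwd_barcode + allele + revcomp(rev_barcode) with per-base
    noise; roughly half the reads are emitted reverse-complemented.  Read
    descriptions encode the truth labels (sample, allele, orientation); a
    parallel truth table is returned for testing.
    """
    pairs = [p.barcode_pair for p in plans]
    if len(set(pairs)) != len(pairs):
        raise ValueError("barcode pairs must be unique across sample plans")
    allele_seqs = {k: (v.sequence if isinstance(v, SeqRecord) else v) for k, v in alleles.items()}
    rng = np.random.default_rng(seed)
    reads: list[SeqRecord] = []
    truth: list[dict] = []
    counter = 0
    for plan in plans:
        names = sorted(plan.allele_weights)
        if plan.allele_counts is not None:
            draw = [n for n in names for _ in range(plan.allele_counts.get(n, 0))]
        else:
            weights = [plan.allele_weights[n] for n in names]
            draw = list(rng.choice(names, size=plan.n_reads, p=weights))
        rng.shuffle(draw)
        fwd, rev = plan.barcode_pair
        for allele_name in draw:
            counter += 1
            insert = allele_seqs[allele_name]
            amplicon = fwd + insert + revcomp(rev)
            noisy = _add_noise(amplicon, plan.error_rate, rng)
            flip = bool(rng.random() < 0.5)
            seq = revcomp(noisy) if flip else noisy
            orient = "rev" if flip else "fwd"
            rid = f"read{counter:05d}"
            reads.append(SeqRecord(rid, seq, f"sample={plan.sample_id} allele={allele_name} orient={orient}"))
            truth.append({"read_id": rid, "sample_id": plan.sample_id,
                          "allele": allele_name, "orientation": orient})
    return reads, truth


def default_barcodes(n: int = 12, length: int = 16, min_distance: int = 6,
                     seed: int = 4157) -> list[str]:
    """Deterministic barcode set with pairwise edit distance >= min_distance."""
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    while len(accepted) < n:
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(edlib.align(cand, b, task="distance")["editDistance"] >= min_distance
               for b in accepted):
            accepted.append(cand)
    return accepted


def clade_taxa(n_per_clade: int = 3, n_mutations: int = 3, n_stem: int = 12,
               seed: int = 17) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Protein taxa for phylogeny fixtures: three diverged subfamilies.

    Each clade descends from its reference through ``n_stem`` seeded stem
    substitutions (so every subfamily carries its own derived states and its
    bipartition edge has real length), then ``n_mutations`` per within-clade
    variant.  Returns (taxa, clade -> member names).
    """
    from .references import AMINO_ACIDS, reference_proteins

    rng = np.random.default_rng(seed)

    def mutate(seq: list[str], n: int) -> list[str]:
        out = list(seq)
        positions = rng.choice(range(1, len(out)), size=n, replace=False)
        for p in positions:
            out[p] = str(rng.choice([a for a in AMINO_ACIDS if a != out[p]]))
        return out

    taxa: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for clade, ref in reference_proteins().items():
        stem = mutate(list(ref), n_stem)
        names = []
        for v in range(n_per_clade):
            seq = stem if v == 0 else mutate(stem, n_mutations)
            name = f"{clade}_t{v + 1}"
            taxa[name] = "".join(seq)
            names.append(name)
        groups[clade] = names
    return taxa, groups


# ---------------------------------------------------------------------------
# The packaged fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class LocusFixture:
    name: str
    template: GeneTemplate
    gene_seq: str
    model: GeneModel            # gene-local coordinates (1..gene length)
    spec: VariantSpec
    allele1: SeqRecord
    allele2: SeqRecord


@dataclass
class FixtureBundle:
    references: dict[str, str]
    mft2: LocusFixture
    cen1: LocusFixture
    ft1_template: GeneTemplate
    ft2_template: GeneTemplate
    variant1_cds_edits: list[tuple[int, str, str]]   # (CDS pos, ref, alt) for the cross-assembly variant
    ft4_cds: str
    ft4_cds_mutated: str
    cohort: list[SamplePlan]
    manifest: dict[str, tuple[str, str]]
    het_sample: str
    promoter_scaffold: SeqRecord
    promoter_model: GeneModel
    repeat_library: list[SeqRecord]


def _split_cds(cds: str, exon_lengths: tuple[int, int, int, int]) -> list[str]:
    assert sum(exon_lengths) == len(cds)
    out, pos = [], 0
    for L in exon_lengths:
        out.append(cds[pos : pos + L])
        pos += L
    return out


def _intron_ranges(exon_lengths, intron_lengths):
    ranges = []
    pos = 0
    for i in range(3):
        pos += exon_lengths[i]
        ranges.append((pos + 1, pos + intron_lengths[i]))
        pos += intron_lengths[i]
    return ranges


def _normalized_deletion(seq: str, pos: int, length: int) -> Edit:
    npos = left_normalize_deletion(seq, pos, length)
    return Edit(npos, "deletion", seq[npos - 1 : npos - 1 + length], "")


def _sub(seq: str, pos: int, alt: str | None = None, hint: str = "") -> Edit:
    ref = seq[pos - 1]
    return Edit(pos, "substitution", ref, alt or _NEXT_BASE[ref], hint)


def paper_fixtures() -> FixtureBundle:
    """Deterministic bundle realizing the study's printed worked examples."""
    refs = reference_proteins()

    # ---- MFT-2-like locus: 513 bp CDS, gene 981 bp, allele2 976 bp --------
    mft_protein = refs["MFT"]
    mft_cds = reverse_translate(mft_protein, codon_overrides={117: "ATA"})
    mft2_template = GeneTemplate("MFT-2", _split_cds(mft_cds, (198, 62, 41, 212)), [150, 200, 118])
    mft2_seq, mft2_model = realize_gene(mft2_template, seed=_FIXTURE_SEED, locus_id="MFT-2")
    assert len(mft2_seq) == 981
    edits = [
        _sub(mft2_seq, 61, "T", "exon"),       # CDS 61  G>T: V21F
        _sub(mft2_seq, 250, hint="intron"),
        _normalized_deletion(mft2_seq, 300, 1),
        _sub(mft2_seq, 500, hint="intron"),
        _normalized_deletion(mft2_seq, 550, 4),
        _sub(mft2_seq, 627, "C", "exon"),      # CDS 277 A>C: I93L
        _sub(mft2_seq, 818, "G", "exon"),      # CDS 350 T>G: I117R
        _sub(mft2_seq, 835, "A", "exon"),      # CDS 367 G>A: A123T
    ]
    edits.sort(key=lambda e: e.position)
    mft2_spec = VariantSpec(edits)
    a1, a2 = make_allele_pair(mft2_seq, mft2_spec, name="MFT-2")
    mft2 = LocusFixture("MFT-2", mft2_template, mft2_seq, mft2_model, mft2_spec, a1, a2)

    # ---- CEN-1-like locus: 528 bp CDS, gene 1027 bp, allele2 1015 bp ------
    cen_cds = reverse_translate(refs["TFL1"])
    cen1_template = GeneTemplate("CEN-1", _split_cds(cen_cds, (200, 62, 41, 225)), [150, 200, 149])
    cen1_seq, cen1_model = realize_gene(cen1_template, seed=_FIXTURE_SEED + 1, locus_id="CEN-1")
    assert len(cen1_seq) == 1027
    cedits = [
        _sub(cen1_seq, 260, hint="intron"),
        _sub(cen1_seq, 470, hint="intron"),
        _normalized_deletion(cen1_seq, 520, 12),
    ]
    cedits.sort(key=lambda e: e.position)
    cen1_spec = VariantSpec(cedits)
    c1, c2 = make_allele_pair(cen1_seq, cen1_spec, name="CEN-1")
    cen1 = LocusFixture("CEN-1", cen1_template, cen1_seq, cen1_model, cen1_spec, c1, c2)

    # ---- FT-like templates for mining / consensus / classification -------
    ft1_cds = reverse_translate(refs["FT"])
    ft1_template = GeneTemplate("FT-1", _split_cds(ft1_cds, (200, 62, 41, 225)), [150, 200, 250])
    ft2_protein = list(refs["FT"])
    for pos, aa in ((134, "N"), (138, "S"), (120, "F"), (121, "H")):
        ft2_protein[pos - 1] = aa            # repressor-like states; triad reads FHN
    ft2_cds = reverse_translate("".join(ft2_protein))
    ft2_template = GeneTemplate("FT-2", _split_cds(ft2_cds, (200, 62, 41, 225)), [150, 200, 250])
    # cross-assembly coding variant: R127C and S156P on the FT-2 consensus
    variant1_cds_edits = [(379, "C", "T"), (466, "T", "C")]
    for pos, ref, _ in variant1_cds_edits:
        assert ft2_cds[pos - 1] == ref

    # ---- premature-stop fixture: 534 bp CDS with Trp codon 136 ------------
    ft4_protein = list(refs["FT"] + "GS")     # 177 aa
    ft4_protein[135] = "W"                    # codon 136 = TGG
    ft4_cds = reverse_translate("".join(ft4_protein))
    assert ft4_cds[405:408] == "TGG"
    ft4_cds_mutated = ft4_cds[:407] + "A" + ft4_cds[408:]   # G>A at CDS 408 -> TGA

    # ---- amplicon cohort: 11 homozygous samples + one ~1:1 heterozygote ---
    barcodes = default_barcodes(7)
    fwd, rev = barcodes[:4], barcodes[4:7]
    hom_counts = [169, 140, 186, 139, 169, 91, 159, 98, 160, 134, 120]
    cohort: list[SamplePlan] = []
    manifest: dict[str, tuple[str, str]] = {}
    pair_iter = iter([(f, r) for f in fwd for r in rev])
    for i, count in enumerate(hom_counts[:7], 1):
        sid = f"S{i:02d}"
        pair = next(pair_iter)
        manifest[sid] = pair
        cohort.append(SamplePlan(sid, pair, {"MFT-2_allele1": 1.0}, count))
    het_sid = "S08"
    pair = next(pair_iter)
    manifest[het_sid] = pair
    cohort.append(SamplePlan(het_sid, pair,
                             {"MFT-2_allele1": 0.5, "MFT-2_allele2": 0.5},
                             58 + 61, allele_counts={"MFT-2_allele1": 58, "MFT-2_allele2": 61}))
    for i, count in enumerate(hom_counts[7:], 9):
        sid = f"S{i:02d}"
        pair = next(pair_iter)
        manifest[sid] = pair
        cohort.append(SamplePlan(sid, pair, {"MFT-2_allele1": 1.0}, count))

    # ---- promoter fixture: repeat planted at ATG-relative -1052..-3763 ----
    scaffold = make_scaffold(12000, 0.42, seed=_FIXTURE_SEED + 2, scaffold_id="pscaffold")
    scaffold, promoter_model = embed_gene(scaffold, ft1_template, 8001, "+",
                                          seed=_FIXTURE_SEED + 3, locus_id="FT-1")
    repeat = SeqRecord("RE1-like_retro", scaffold.sequence[4237:6949])   # 2712 bp window copy
    assert len(repeat.sequence) == 2712
    decoy = make_scaffold(800, 0.42, seed=_FIXTURE_SEED + 4, scaffold_id="decoy_repeat")

    return FixtureBundle(
        references=refs,
        mft2=mft2,
        cen1=cen1,
        ft1_template=ft1_template,
        ft2_template=ft2_template,
        variant1_cds_edits=variant1_cds_edits,
        ft4_cds=ft4_cds,
        ft4_cds_mutated=ft4_cds_mutated,
        cohort=cohort,
        manifest=manifest,
        het_sample=het_sid,
        promoter_scaffold=scaffold,
        promoter_model=promoter_model,
        repeat_library=[repeat, decoy],
    )
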