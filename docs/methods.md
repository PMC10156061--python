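# Methods

This note documents the models and procedures implemented in `pebpmine`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## The gene family and its structural model

Plant PEBP (phosphatidylethanolamine-binding protein) genes fall into three
clades — FT-like (floral inducers, with derived repressor paralogs),
TFL1-like (floral repressors) and MFT-like (seed dormancy/germination).
Across the family the gene architecture is conserved: **four exons, three
introns**, with exon II fixed at 62 bp and exon III at 41 bp, exon I varying
within roughly 192–216 bp and exon IV within 209–233 bp, and introns of
variable length bounded by canonical GT..AG dinucleotides. The structure
validator treats exon count, the two fixed exon lengths and GT..AG as hard
checks, and the exon I/IV ranges as warnings, because biologically genuine
paralogs violate the ranges (a premature stop can shorten exon IV to
~110 bp without invalidating the locus).

## Spliced CDS-to-genome placement

Exons are located by a greedy exact search for maximal CDS blocks inside the
candidate locus, backtracking over block boundaries under three constraints:
introns are at least 20 bp, begin GT and end AG. Among valid placements the
algorithm prefers the fewest/longest exons, then the leftmost placement, so
output is deterministic. When no exact placement exists (the CDS carries
mismatches relative to the genome), a splice-aware global alignment takes
over: matches +2, mismatches −4, intron-type gaps open −8 / extend −0.05
(cheap to extend, so introns of hundreds of bases are preferred over
mismatch runs), unplaced-CDS gaps effectively forbidden (−50/−10), locus
flanks free. Intron boundaries from the fallback are then shifted within a
±15 bp window to a score-neutral placement satisfying GT..AG where one
exists; otherwise the model is flagged `noncanonical_splice`.

## Consensus across assemblies

A locus consensus is the CDS shared **verbatim** by the largest subset (at
least two) of assemblies; majority-vote base-level consensus of non-identical
sequences is deliberately out of scope. Remaining assemblies are diffed
against the consensus and their substitutions annotated codon-wise. Loci are
matched across assemblies by greedy clustering at ≥ 95 % edit-distance
identity (the family's paralogs are far more divergent than its orthologs at
this scale, so reciprocal-best refinement is not needed). A tie between two
disjoint agreeing pairs resolves toward the pair containing the
lexicographically first assembly name and is flagged `ambiguous_consensus`.

## Diagnostic residues and function calls

Candidates are mapped onto reference numbering by global alignment (BLOSUM62,
gap open 10 / extend 1, free terminal gaps) against two bundled references —
one FT-numbered, one TFL1-numbered — and the higher-identity mapping wins
(flagged if the identities differ by under 2 %). The clade call reads the
single homologous position: Tyr85 (FT numbering) ⇒ FT-like, His88 (TFL1
numbering) ⇒ TFL1-like, Trp ⇒ MFT-like; Gln140/Asp144 are recorded as
supporting evidence only. For FT-like proteins the function call is
**inducer** iff Tyr134 AND Trp138 are present, **repressor-like** otherwise;
a substitution confined to Gly137 leaves the inducer call standing with a
"G137 variant" note, since changes at that position alone are known not to
confer repressive activity. E109, N152 and Q140 states are annotations.

The bundled references are **synthetic**: deterministic PEBP-like scaffolds
carrying the published diagnostic states at their literature-numbered
positions (including the segment-B motif `LGRQTVYAPGWRQN` at 128–141 and an
LYN triad placed at fixed reference positions 120–122). They exist so the
classifier runs with no external download; real reference proteins can be
substituted by file. Because the triad's exact coordinates are not fixed by
the literature the scan simply reports the candidate residues mapped at the
triad positions of the bundled reference.

## Phylogeny

Distances use pairwise gap deletion and one of `p`, Poisson
(`d = −ln(1−p)`) or gamma (`d = α((1−p)^{−1/α} − 1)`) corrections; the gamma
shape defaults to α = 1.0 and is a free parameter. Trees are built by
Saitou–Nei neighbour joining on the Q-criterion with deterministic
tie-breaks; negative branch estimates are clamped to zero and flagged. On an
additive matrix the output is the unique additive tree with exact branch
lengths (verified against random additive matrices and an independent NJ
implementation). Bootstrap support resamples alignment columns with
replacement; support for a bipartition is the fraction of replicate trees
containing it, deterministic given the seed. Multiple alignment for the
phylogeny path is a center-star progressive merge ("once a gap, always a
gap") over BLOSUM62 pairwise alignments — adequate for the closely related
within-family proteins compared here, and not intended as a general aligner.

## Amplicon demultiplexing and phasing

Reads are modelled as `fwd_barcode + insert + revcomp(rev_barcode)`.
Demultiplexing scores each manifest barcode pair against both read ends in
both orientations using edit distance (default budget 2 edits per end);
assignment requires a unique best total, ties are reported `ambiguous`, and
barcodes are trimmed from the returned insert.

Phasing is identity clustering with consensus refinement. The admission
identity `t` (default 0.995) defines the cluster radius around a denoised
consensus; during greedy formation, where only raw reads are available, two
same-cluster reads are admitted at the triangle-inequality pairwise radius
`2t − 1`. Rough clusters of at least three reads are collapsed to
per-column majority consensuses (independent read errors cancel, so
same-allele clusters converge to identical consensuses and are
deduplicated); every read is then re-assigned to its nearest consensus, and
clusters holding under `min_fraction` (default 0.2) of the locus' reads are
discarded as noise. Coverage ratios are reported both raw and rounded to one
decimal, matching the convention of published coverage tables. Genotypes:
one retained cluster ⇒ homozygous, two ⇒ heterozygous (both ratios must lie
in [0.2, 0.8]), more ⇒ flagged `multi-allelic/contamination`. In simulated
data amplicon coverage equals read count; the separate subread-coverage
field exists so importers of real instrument output can populate both.

## Variant calling and promoter scans

Allele pairs are aligned globally (match +2 / mismatch −3 / gap open −5 /
extend −2). Each mismatch column is one substitution; each maximal gap run
is one deletion event, left-aligned on allele1 so calls are bit-comparable.
Exonic substitutions are classified by translating the codon
(⌈CDS pos / 3⌉) in both alleles: synonymous, non-synonymous or stop-gained;
exonic indels receive a frameshift/indel placeholder and are not classified
further. Deleteriousness/tolerance prediction is not computed (it depends on
external protein databases); the report reserves a column for user-supplied
predictions.

Promoter scans extract up to 8 kb upstream of the ATG on the coding strand
(ATG-relative negative coordinates, −1 = the base 5′ of the A) and locally
align each repeat-library entry; hits of ≥ 200 aligned bases and ≥ 70 %
identity are reported. The hit **span is the coordinate difference**
`|far| − |near|`, not the inclusive base count: the published promoter
transposon interval satisfies 3763 − 1052 = 2711 exactly under this
convention, while an inclusive count would give 2712.

## The synthetic-data generator

All generators are pure functions of their inputs and a seed. The fixture
bundle realizes the study conditions at desk scale:

- an MFT-like locus with a 513 bp CDS (170 aa), exons 198/62/41/212 bp and
  introns 150/200/118 bp (intron lengths chosen so the gene totals the
  printed 981 bp; the generic template default is 150/200/250 bp), whose
  allele pair differs by 2 intronic substitutions, 1 bp + 4 bp intronic
  deletions and exonic substitutions at CDS 61/277/350/367. Codon contexts
  are fixed so the substitutions produce the printed amino-acid states
  (codon 21 GTT so G→T gives V→F; codon 93 ATT so A→C gives I→L; codon 117
  ATA so T→G gives I→R; codon 123 GCT so G→A gives A→T);
- a TFL1-like locus (528 bp CDS, gene 1027 bp) whose alleles differ by two
  intronic substitutions and one 12 bp intronic deletion (allele2 1015 bp);
- a 534 bp CDS with Trp codon 136 (TGG) and its G→A nonsense mutant
  (TGA), truncating the frame at 408 bp / 135 aa;
- a 12-sample amplicon cohort: 11 homozygous samples with amplicon counts
  between 91 and 186 and one heterozygous sample whose reads are allocated
  exactly 58/61 between the two alleles, realizing the published coverage
  table (a 1:1 heterozygote); other plans draw alleles randomly from their
  weights;
- barcodes: 16-mers with pairwise edit distance ≥ 6, combined
  asymmetrically (4 forward × 3 reverse) so 7 barcodes yield 12 unique
  pairs;
- read noise: substitutions/insertions/deletions at 60/20/20 % of the total
  error rate, default 0.5 % per base (0.3/0.1/0.1 %), mimicking
  circular-consensus-quality long reads;
- a promoter scaffold with a repeat planted at ATG-relative −1052..−3763.

What the generator does **not** emulate: instrument subread/ZMW structure
(no CCS step — amplicon and subread coverage coincide), chimeric reads,
coverage unevenness within a sample, repeat-induced mis-mapping, assembly
fragmentation, and real inter-species divergence patterns. Passing tests
therefore demonstrate the pipeline's correctness on cleanly specified
inputs, not robustness to every artifact of real sequencing data.

## Problem sizes

Tests and the pipeline run at desk scale by choice: scaffolds of 4–30 kb,
single-locus cohorts of ~1,600 reads, alignments of ~10 proteins, bootstrap
at 100 replicates (the method supports arbitrary replicate counts), and
50-tree batches for the additive-recovery property.

## Known limitations

- The exact-placement search assumes introns ≥ 20 bp and canonical splice
  sites; non-canonical splicing is flagged, not modelled.
- The center-star aligner and the k-mer guide distances are not suitable for
  deeply diverged sequences.
- Effect classification of substitutions downstream of an exonic indel in
  the same pair is not attempted (`indel-context`).
- The two-fragment / partial-CDS situation is reported as-is (excluded from
  consensus), never merged into a single model.
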