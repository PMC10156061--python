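# pebpmine

A toolkit for mining, structurally validating, classifying, phylogenetically
placing and allele-typing plant **PEBP-family gene homologs** — the
*FLOWERING LOCUS T* / *TERMINAL FLOWER 1* / *MOTHER OF FT AND TFL1*
(FT/TFL1/MFT) family that controls floral induction, seed dormancy and
germination in angiosperms.

It is aimed at crop genomicists who survey a gene family across several
genome assemblies of one species and then probe allelic variation in
cultivars with long-read amplicon sequencing. The package covers that whole
workflow at desk scale:

- **Homology mining** — six-frame translation of genomic scaffolds, protein
  k-mer seeded local alignment (BLOSUM62, affine gaps) against query
  proteins, and merging of exon-level hits into candidate loci.
- **Gene-model validation** — spliced CDS-to-genome placement with exact
  block search plus a splice-aware alignment fallback, and canonical PEBP
  structure checks: four exons, exon II = 62 bp, exon III = 41 bp,
  exon I ∈ [192, 216], exon IV ∈ [209, 233], GT..AG introns. Premature
  stops (e.g. a TGG→TGA nonsense change) are detected with a
  frame-intactness report, and protein length is deduced as
  `len(CDS)/3 − 1`.
- **Cross-assembly consensus** — a locus consensus is accepted only where at
  least two assemblies provide the identical CDS; divergent assemblies are
  recorded as variants with codon-level effect annotation.
- **Diagnostic-residue classification** — candidates are mapped by global
  alignment onto reference numbering; Tyr85 ⇒ FT-like, His88 ⇒ TFL1-like,
  Trp ⇒ MFT-like. FT-like proteins are called **inducer** iff they carry
  Tyr134 *and* Trp138 in the exon-IV external loop, otherwise
  **repressor-like** (a change confined to Gly137 keeps the inducer call,
  with a note). The segment-B motif `LGRQTVYAPGWRQN` (positions 128–141)
  and the LYN triad are scanned.
- **Phylogeny** — p-distance, Poisson (`d = −ln(1−p)`) and gamma
  (`d = α((1−p)^{−1/α} − 1)`) protein distances with pairwise gap deletion,
  Saitou–Nei neighbour joining (exact on additive matrices), and
  column-resampling bootstrap support with clade-monophyly checks.
- **Amplicon phasing** — demultiplexing of asymmetric dual-barcoded long
  reads (edit-distance matching at both ends, both orientations), greedy
  identity clustering with per-column majority consensus, coverage-ratio
  reporting and homozygous/heterozygous genotype calls.
- **Variant annotation** — global allele-pair alignment, left-aligned
  deletion calls, exon/intron placement, synonymous / non-synonymous /
  stop-gained classification with amino-acid changes
  (protein position = ⌈CDS position / 3⌉), and promoter scans of the ~8 kb
  upstream of the ATG for repeat/transposon insertions.
- **Synthetic data** — every input above can be generated deterministically:
  scaffolds with embedded 4-exon genes, three-assembly variant sets, allele
  pairs realizing published variant tables, and barcoded read pools with a
  configurable error model.

## Worked example

The packaged fixture bundle realizes a heterozygous MFT-like locus whose two
alleles (981 bp and 976 bp) differ by two intronic substitutions, 1 bp and
4 bp intronic deletions, and four exonic substitutions:

```python
from pebpmine import align_alleles, call_variants, paper_fixtures

bundle = paper_fixtures()
aln = align_alleles(bundle.mft2.allele1.sequence, bundle.mft2.allele2.sequence)
for v in call_variants(aln, bundle.mft2.model):
    print(v.position, v.kind, v.ref or "-", v.alt or "-",
          f"{v.region[0]}{v.region[1]}", v.effect,
          "".join(map(str, v.aa_change)) if v.aa_change else "")
```

prints

```
61 substitution G T exon1 non-synonymous V21F
250 substitution C G intron1 non-coding
300 deletion A - intron1 non-coding
500 substitution T A intron2 non-coding
549 deletion CTTG - intron2 non-coding
627 substitution A C exon3 non-synonymous I93L
818 substitution T G exon4 non-synonymous I117R
835 substitution G A exon4 non-synonymous A123T
```

i.e. the four coding changes at CDS positions 61/277/350/367 map to protein
positions 21/93/117/123 with changes V→F, I→L, I→R and A→T, and every other
variant falls in an intron.

The full desk-scale pipeline (simulate → mine → annotate → consensus →
classify → phylo → demux → phase → callvars → report) runs with:

```bash
pebpmine run --seed 1 --out-dir runs/demo
```

and reports, among other things, two distinct phased alleles across a
12-sample amplicon cohort with exactly one heterozygous sample at coverage
ratios 0.5/0.5.

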