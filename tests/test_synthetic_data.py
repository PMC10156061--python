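import numpy as np
import pytest
from scipy import stats

from pebpmine.gene_models import splice, translate_cds
from pebpmine.synthetic_data import (Edit, GeneTemplate, SamplePlan, VariantSpec,
                                     default_barcodes, embed_gene, make_allele_pair,
                                     make_assembly_set, make_scaffold,
                                     simulate_amplicon_reads)


class TestScaffold:
    def test_seeded_determinism(self):
        a = make_scaffold(1000, 0.5, 7)
        b = make_scaffold(1000, 0.5, 7)
        assert a.sequence == b.sequence

    def test_gc_one_yields_only_gc(self):
        s = make_scaffold(500, 1.0, 3)
        assert set(s.sequence) <= {"G", "C"}

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            make_scaffold(0, 0.5, 1)


class TestEmbedGene:
    def test_splice_recovers_template_cds(self, bundle):
        scaffold = make_scaffold(4000, 0.4, 2)
        scaffold, model = embed_gene(scaffold, bundle.mft2.template, 501, "+", seed=5)
        assert splice(scaffold.sequence, model.exons, "+") == bundle.mft2.template.cds

    def test_minus_strand_translates_to_template_protein(self, bundle):
        scaffold = make_scaffold(4000, 0.4, 2)
        scaffold, model = embed_gene(scaffold, bundle.mft2.template, 501, "-", seed=5)
        cds = splice(scaffold.sequence, model.exons, "-")
        assert translate_cds(cds) == bundle.mft2.template.protein

    def test_out_of_bounds_rejected(self, bundle):
        scaffold = make_scaffold(500, 0.4, 2)
        with pytest.raises(ValueError, match="fit"):
            embed_gene(scaffold, bundle.mft2.template, 400, "+")

    def test_overlap_rejected(self, bundle):
        scaffold = make_scaffold(5000, 0.4, 2)
        scaffold, model = embed_gene(scaffold, bundle.mft2.template, 501, "+")
        with pytest.raises(ValueError, match="overlap"):
            embed_gene(scaffold, bundle.mft2.template, 900, "+", existing=[model])


class TestAssemblySet:
    def test_one_variant_assembly(self, bundle):
        base = make_scaffold(2000, 0.4, 4)
        pos = 500
        ref = base.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        spec = VariantSpec([Edit(pos, "substitution", ref, alt, "exon")])
        out = make_assembly_set(base, {"a1": VariantSpec([]), "a2": VariantSpec([]), "a3": spec})
        assert out["a1"].sequence == base.sequence == out["a2"].sequence
        assert out["a3"].sequence != base.sequence
        assert out["a3"].sequence[pos - 1] == alt

    def test_all_empty_specs_identical(self):
        base = make_scaffold(300, 0.4, 4)
        out = make_assembly_set(base, {n: VariantSpec([]) for n in "abc"})
        assert all(rec.sequence == base.sequence for rec in out.values())

    def test_same_position_edits_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec([Edit(5, "substitution", "A", "C"),
                         Edit(5, "substitution", "A", "G")])


class TestAllelePair:
    def test_mft2_fixture_length_difference_is_5(self, bundle):
        a1, a2 = bundle.mft2.allele1, bundle.mft2.allele2
        assert len(a1) == 981 and len(a2) == 976
        assert len(a1) - len(a2) == bundle.mft2.spec.deleted_bases == 5

    def test_cen1_fixture_length_difference_is_12(self, bundle):
        a1, a2 = bundle.cen1.allele1, bundle.cen1.allele2
        assert len(a1) == 1027 and len(a2) == 1015

    def test_empty_spec_identical_alleles(self):
        gene = make_scaffold(400, 0.4, 9).sequence
        a1, a2 = make_allele_pair(gene, VariantSpec([]))
        assert a1.sequence == a2.sequence == gene

    def test_ref_mismatch_rejected(self):
        gene = "ATG" + "A" * 100
        with pytest.raises(ValueError, match="ref mismatch"):
            make_allele_pair(gene, VariantSpec([Edit(50, "substitution", "G", "C")]))


class TestReadSimulation:
    def test_error_free_insert_equals_allele(self, bundle):
        plan = SamplePlan("s", ("A" * 16, "C" * 16), {"a1": 1.0}, 5, error_rate=0.0)
        reads, truth = simulate_amplicon_reads({"a1": "ACGTACGTGG" * 30}, [plan], seed=3)
        from pebpmine.gene_models import revcomp
        for read, t in zip(reads, truth):
            seq = read.sequence if t["orientation"] == "fwd" else revcomp(read.sequence)
            assert seq == "A" * 16 + "ACGTACGTGG" * 30 + revcomp("C" * 16)

    def test_balanced_weights_within_binomial_bounds(self):
        plan = SamplePlan("s", ("A" * 16, "C" * 16), {"a1": 0.5, "a2": 0.5}, 120,
                          error_rate=0.0)
        reads, truth = simulate_amplicon_reads(
            {"a1": "A" * 300, "a2": "G" * 300}, [plan], seed=5)
        n1 = sum(t["allele"] == "a1" for t in truth)
        lo, hi = stats.binom.ppf([0.005, 0.995], 120, 0.5)
        assert lo <= n1 <= hi

    def test_same_seed_identical_pool(self, bundle):
        alleles = {"a1": bundle.mft2.allele1.sequence}
        plan = SamplePlan("s", ("A" * 16, "C" * 16), {"a1": 1.0}, 20)
        r1, _ = simulate_amplicon_reads(alleles, [plan], seed=11)
        r2, _ = simulate_amplicon_reads(alleles, [plan], seed=11)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]

    def test_duplicate_barcode_pair_rejected(self):
        pair = ("A" * 16, "C" * 16)
        plans = [SamplePlan("s1", pair, {"a": 1.0}, 5),
                 SamplePlan("s2", pair, {"a": 1.0}, 5)]
        with pytest.raises(ValueError, match="unique"):
            simulate_amplicon_reads({"a": "ACGT" * 50}, plans, seed=1)


class TestPaperFixtures:
    def test_codon_117_mutation_encodes_arginine(self, bundle):
        cds = bundle.mft2.template.cds
        codon = cds[348:351]
        assert codon == "ATA"
        mutated = codon[0] + "G" + codon[2]
        assert mutated == "AGA"
        assert translate_cds("ATG" + mutated + "TGA") == "MR"

    def test_exactly_one_heterozygous_plan(self, bundle):
        het = [p for p in bundle.cohort if len(p.allele_weights) == 2]
        assert len(het) == 1
        assert het[0].sample_id == bundle.het_sample
        assert set(het[0].allele_weights.values()) == {0.5}
        assert len(bundle.cohort) == 12

    def test_allele1_cds_has_no_internal_stop(self, bundle):
        assert "*" not in translate_cds(bundle.mft2.template.cds)
        assert "*" not in translate_cds(bundle.cen1.template.cds)

    def test_cohort_amplicon_counts_at_table_scale(self, bundle):
        counts = [p.n_reads for p in bundle.cohort]
        assert all(50 <= c <= 200 for c in counts)


class TestBarcodes:
    def test_pairwise_distance_floor(self):
        import edlib
        bcs = default_barcodes(8)
        assert len(set(bcs)) == 8
        for i in range(len(bcs)):
            for j in range(i + 1, len(bcs)):
                d = edlib.align(bcs[i], bcs[j], task="distance")["editDistance"]
                assert d >= 6


class TestGeneTemplateInvariants:
    def test_bad_cds_rejected(self):
        with pytest.raises(ValueError):
            GeneTemplate("bad", ["AAA", "CCC", "GGG", "TTT"], [50, 50, 50])

    def test_exon_ii_and_iii_default_lengths(self, bundle):
        for template in (bundle.mft2.template, bundle.cen1.template,
                         bundle.ft1_template, bundle.ft2_template):
            assert len(template.exon_seqs[1]) == 62
            assert len(template.exon_seqs[2]) == 41
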