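import numpy as np
import pytest

from pebpmine.io_formats import SeqRecord
from pebpmine.synthetic_data import (make_allele_pair, make_scaffold,
                                     random_variant_spec)
from pebpmine.variant_annotation import (VariantRecord, align_alleles,
                                         annotate_effect, call_variants,
                                         extract_upstream,
                                         map_cds_to_protein_position,
                                         scan_promoter_repeats)


class TestAlignAlleles:
    def test_identical_sequences(self):
        seq = "ACGT" * 50
        r1, r2 = align_alleles(seq, seq)
        assert r1 == r2 == seq

    def test_internal_deletion_single_gap_run(self, bundle):
        a1 = bundle.cen1.allele1.sequence
        a2 = bundle.cen1.allele2.sequence
        variants = call_variants(align_alleles(a1, a2))
        deletions = [v for v in variants if v.kind == "deletion"]
        assert len(deletions) == 1
        assert len(deletions[0].ref) == 12

    def test_terminal_mismatch_aligned_end_to_end(self):
        a = "ACGTACGTAC" * 10
        b = a[:-1] + ("T" if a[-1] != "T" else "G")
        r1, r2 = align_alleles(a, b)
        assert "-" not in r1 and "-" not in r2
        assert sum(x != y for x, y in zip(r1, r2)) == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_alleles("", "ACGT")


class TestCallVariants:
    def test_mft2_fixture_composition(self, bundle):
        """The MFT-2 allele pair yields 2 intronic substitutions, 1 bp and
        4 bp intronic deletions, and 4 non-synonymous exonic substitutions."""
        aln = align_alleles(bundle.mft2.allele1.sequence, bundle.mft2.allele2.sequence)
        variants = call_variants(aln, bundle.mft2.model)
        intronic_subs = [v for v in variants
                         if v.kind == "substitution" and v.region[0] == "intron"]
        deletions = sorted(len(v.ref) for v in variants if v.kind == "deletion")
        exonic_subs = [v for v in variants
                       if v.kind == "substitution" and v.region[0] == "exon"]
        assert len(intronic_subs) == 2
        assert deletions == [1, 4]
        assert len(exonic_subs) == 4
        assert all(v.effect == "non-synonymous" for v in exonic_subs)
        aa = ["".join([v.aa_change[0], str(v.aa_change[1]), v.aa_change[2]])
              for v in exonic_subs]
        assert aa == ["V21F", "I93L", "I117R", "A123T"]
        assert all(v.effect == "non-coding" for v in intronic_subs)

    def test_cen1_fixture_composition(self, bundle):
        aln = align_alleles(bundle.cen1.allele1.sequence, bundle.cen1.allele2.sequence)
        variants = call_variants(aln, bundle.cen1.model)
        subs = [v for v in variants if v.kind == "substitution"]
        dels = [v for v in variants if v.kind == "deletion"]
        assert len(subs) == 2 and len(dels) == 1
        assert len(dels[0].ref) == 12
        assert all(v.region[0] == "intron" for v in variants)

    def test_identical_alleles_empty(self):
        seq = "ACGT" * 100
        assert call_variants(align_alleles(seq, seq)) == []

    def test_deletion_lengths_sum_to_length_difference(self, bundle):
        for fixture in (bundle.mft2, bundle.cen1):
            a1, a2 = fixture.allele1.sequence, fixture.allele2.sequence
            variants = call_variants(align_alleles(a1, a2))
            total_del = sum(len(v.ref) for v in variants if v.kind == "deletion")
            assert total_del == len(a1) - len(a2)


class TestSpecRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_specs_recovered_exactly(self, seed, bundle):
        """Applying a random spec then diffing recovers it verbatim."""
        rng = np.random.default_rng(seed)
        gene = bundle.mft2.gene_seq
        for _ in range(4):
            spec = random_variant_spec(gene, rng)
            a1, a2 = make_allele_pair(gene, spec)
            variants = call_variants(align_alleles(a1.sequence, a2.sequence))
            called = [(v.position, v.kind, v.ref, v.alt) for v in variants]
            expected = [(e.position, e.kind, e.ref, e.alt) for e in spec.edits]
            assert called == expected


class TestPositionMapping:
    @pytest.mark.parametrize("nt,aa", [(61, 21), (277, 93), (350, 117), (367, 123), (3, 1), (1, 1)])
    def test_ceiling_rule(self, nt, aa):
        assert map_cds_to_protein_position(nt) == aa

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            map_cds_to_protein_position(0)


class TestAnnotateEffect:
    def test_stop_gained_from_tgg(self):
        cds1 = "ATG" + "TGG" + "AAA" + "TGA"
        cds2 = "ATG" + "TGA" + "AAA" + "TGA"
        v = VariantRecord(6, "substitution", "G", "A", ("exon", 1), cds_position=6)
        annotate_effect(v, cds1, cds2)
        assert v.effect == "stop-gained"

    def test_synonymous(self):
        cds1 = "ATG" + "CTT" + "TGA"     # Leu
        cds2 = "ATG" + "CTC" + "TGA"     # Leu
        v = VariantRecord(6, "substitution", "T", "C", ("exon", 1), cds_position=6)
        annotate_effect(v, cds1, cds2)
        assert v.effect == "synonymous"
        assert v.aa_change == ("L", 2, "L")

    def test_agrees_with_full_translation(self, bundle):
        """Codon-wise effects match brute-force translation of both CDSs."""
        from pebpmine.gene_models import translate_cds

        aln = align_alleles(bundle.mft2.allele1.sequence, bundle.mft2.allele2.sequence)
        variants = call_variants(aln, bundle.mft2.model)
        cds1 = bundle.mft2.model.cds
        cds2 = list(cds1)
        for v in variants:
            if v.kind == "substitution" and v.region[0] == "exon":
                cds2[v.cds_position - 1] = v.alt
        p1, p2 = translate_cds(cds1), translate_cds("".join(cds2))
        diffs = {i + 1: (a, b) for i, (a, b) in enumerate(zip(p1, p2)) if a != b}
        for v in variants:
            if v.aa_change:
                ref_aa, pos, alt_aa = v.aa_change
                assert diffs[pos] == (ref_aa, alt_aa)


class TestUpstream:
    def test_plus_strand_window_arithmetic(self):
        scaffold = make_scaffold(12000, 0.5, 1).sequence
        from pebpmine.gene_models import GeneModel
        model = GeneModel("g", "s", "+", [(10000, 10100), (10200, 10250),
                                          (10300, 10340), (10400, 10500)], "", "")
        up = extract_upstream(model, scaffold, window=8000)
        assert not up.truncated
        assert up.sequence == scaffold[1999:9999]   # bases 2000..9999

    def test_minus_strand_revcomp(self):
        from pebpmine.gene_models import GeneModel, revcomp
        scaffold = make_scaffold(5000, 0.5, 2).sequence
        model = GeneModel("g", "s", "-", [(1000, 1100), (1200, 1250),
                                          (1300, 1340), (1400, 1500)], "", "")
        up = extract_upstream(model, scaffold, window=1000)
        assert up.sequence == revcomp(scaffold[1500:2500])

    def test_truncation_flag(self):
        from pebpmine.gene_models import GeneModel
        scaffold = make_scaffold(1000, 0.5, 3).sequence
        model = GeneModel("g", "s", "+", [(100, 150), (200, 230), (300, 340),
                                          (400, 450)], "", "")
        up = extract_upstream(model, scaffold, window=8000)
        assert up.truncated
        assert len(up.sequence) == 99

    def test_zero_upstream_is_error(self):
        from pebpmine.gene_models import GeneModel
        scaffold = make_scaffold(1000, 0.5, 3).sequence
        model = GeneModel("g", "s", "+", [(1, 50), (100, 130), (200, 240),
                                          (300, 350)], "", "")
        with pytest.raises(ValueError):
            extract_upstream(model, scaffold)


class TestPromoterScan:
    def test_planted_repeat_span_2711(self, bundle):
        up = extract_upstream(bundle.promoter_model,
                              bundle.promoter_scaffold.sequence, window=8000)
        hits = scan_promoter_repeats(up, bundle.repeat_library)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.near, hit.far) == (-1052, -3763)
        assert hit.span == 2711

    def test_absent_repeat_empty(self, bundle):
        up = extract_upstream(bundle.promoter_model,
                              bundle.promoter_scaffold.sequence, window=8000)
        decoy = [SeqRecord("none", make_scaffold(2500, 0.42, 77).sequence)]
        assert scan_promoter_repeats(up, decoy) == []

    def test_low_identity_repeat_not_reported(self, bundle):
        # mutate every 3rd base: uniform ~66.7% identity with no lucky
        # high-identity stretch for the local aligner to rescue
        rep = list(bundle.repeat_library[0].sequence)
        for pos in range(0, len(rep), 3):
            rep[pos] = "ACGT"[(("ACGT".index(rep[pos])) + 1) % 4]
        up = extract_upstream(bundle.promoter_model,
                              bundle.promoter_scaffold.sequence, window=8000)
        hits = scan_promoter_repeats(up, [SeqRecord("degraded", "".join(rep))])
        assert hits == []

    def test_empty_library_warns(self, bundle):
        up = extract_upstream(bundle.promoter_model,
                              bundle.promoter_scaffold.sequence, window=8000)
        with pytest.warns(UserWarning):
            assert scan_promoter_repeats(up, []) == []
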