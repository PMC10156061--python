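"""End-to-end orchestration: simulate -> mine -> annotate -> consensus ->
classify -> phylo -> demux -> phase -> callvars -> report.

The pipeline runs on the packaged fixture bundle (default) or on user paths
supplied through the run configuration.  Every stage writes plain-text
outputs under one run directory; reruns with the same config and seed are
byte-identical for deterministic stages.
"""
from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import amplicon_phasing, consensus as consensus_mod, homology_search
from . import phylogeny, residue_classify, synthetic_data, variant_annotation
from .gene_models import spliced_align_cds
from .io_formats import RunConfig, SeqRecord, write_fasta, write_gene_models, write_manifest, write_variants

logger = logging.getLogger("pebpmine")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineReport:
    seed: int
    thresholds: dict
    stage_counts: dict = field(default_factory=dict)
    family_table: dict = field(default_factory=dict)
    genotypes: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    clades: dict = field(default_factory=dict)
    tree_path: str | None = None
    skipped: list = field(default_factory=list)
    promoter_hits: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _stage(report: PipelineReport, name: str):
    logger.info("stage %s starting", name)
    t0 = time.time()

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(name, str(exc)) from exc
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineReport:
    """Run the full desk-scale workflow on the packaged fixture bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report = PipelineReport(seed=config.seed, thresholds=dict(th))

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)
    logger.info("seed=%d", config.seed)

    try:
        with _stage(report, "simulate"):
            bundle = synthetic_data.paper_fixtures()
            assemblies, models_by_assembly, cds_sets = _build_assemblies(bundle)
            for name, scaffold in assemblies.items():
                write_fasta([scaffold], out / f"assembly_{name}.fasta")
            reads, truth = synthetic_data.simulate_amplicon_reads(
                {"MFT-2_allele1": bundle.mft2.allele1.sequence,
                 "MFT-2_allele2": bundle.mft2.allele2.sequence},
                bundle.cohort, seed=config.seed)
            write_fasta(reads, out / "amplicon_reads.fasta")
            write_manifest(bundle.manifest, out / "barcode_manifest.tsv")
            report.stage_counts["simulate"] = {
                "assemblies": len(assemblies), "reads": len(reads),
                "samples": len(bundle.cohort)}

        with _stage(report, "mine"):
            queries = [SeqRecord(f"{k}_ref", v) for k, v in bundle.references.items()]
            loci_by_assembly = {}
            for name, scaffold in assemblies.items():
                frames = homology_search.sixframe_translate(scaffold)
                hits = homology_search.search(
                    frames, queries, k=int(th["seed_k"]),
                    min_score=th["min_score"], min_identity=th["min_identity"])
                loci_by_assembly[name] = homology_search.merge_hits_to_loci(
                    hits, max_gap=int(th["max_gap"]))
            report.stage_counts["mine"] = {
                name: len(loci) for name, loci in loci_by_assembly.items()}

        with _stage(report, "annotate"):
            annotated = {}
            for name, loci in loci_by_assembly.items():
                scaffold = assemblies[name]
                models = []
                for locus in loci:
                    pad = 50
                    interval = (max(1, locus.start - pad),
                                min(len(scaffold.sequence), locus.end + pad))
                    placed = []
                    for cds_id, cds in sorted(cds_sets[name].items()):
                        try:
                            placed.append(spliced_align_cds(
                                cds, scaffold, interval, locus.strand, locus_id=cds_id))
                        except Exception:
                            continue
                    if placed:
                        # the locus' own CDS places without mismatches
                        placed.sort(key=lambda m: "mismatch" in m.flags)
                        models.append(placed[0])
                annotated[name] = models
                write_gene_models(models, out / f"models_{name}.gff3")
            report.stage_counts["annotate"] = {n: len(m) for n, m in annotated.items()}

        with _stage(report, "consensus"):
            per_assembly = {name: {m.locus_id: m.cds for m in models}
                            for name, models in annotated.items()}
            matched = consensus_mod.match_loci(per_assembly)
            records = [consensus_mod.derive_consensus(members, locus_id=locus)
                       for locus, members in sorted(matched.items())]
            report.stage_counts["consensus"] = {
                r.locus_id: r.agreement for r in records}

        with _stage(report, "classify"):
            from .gene_models import translate_cds
            clade_calls = {}
            proteins = {}
            for record in records:
                if record.consensus_cds is None:
                    continue
                protein = translate_cds(record.consensus_cds)
                proteins[record.locus_id] = protein
                call = residue_classify.classify_protein(protein, bundle.references)
                clade_calls[record.locus_id] = call.clade
                report.clades[record.locus_id] = {
                    "clade": call.clade, "ft_function": call.ft_function,
                    "triad": call.motif_report.triad_observed}
            family = consensus_mod.summarize_family(records, clade_calls)
            family.to_csv(out / "family_table.tsv", sep="\t")
            report.family_table = {a: family.loc[a].to_dict() for a in family.index}

        n_boot = int(th["bootstrap_replicates"])
        if n_boot < 1:
            report.skipped.append("phylo (bootstrap_replicates=0)")
        else:
            with _stage(report, "phylo"):
                taxa = dict(proteins)
                taxa.update({f"{k}_ref": v for k, v in bundle.references.items()})
                aln = phylogeny.progressive_align(taxa)
                tree = phylogeny.bootstrap_support(
                    aln, model="poisson", replicates=n_boot, seed=config.seed)
                tree_path = out / "tree.nwk"
                tree_path.write_text(tree.to_newick() + "\n")
                report.tree_path = str(tree_path)

        with _stage(report, "promoter"):
            upstream = variant_annotation.extract_upstream(
                bundle.promoter_model, bundle.promoter_scaffold.sequence,
                window=int(th["upstream_window"]))
            hits = variant_annotation.scan_promoter_repeats(
                upstream, bundle.repeat_library,
                min_len=int(th["repeat_min_len"]),
                min_identity=th["repeat_min_identity"])
            report.promoter_hits = [
                {"repeat": h.repeat_id, "near": h.near, "far": h.far,
                 "span": h.span, "identity": h.percent_identity}
                for h in hits]

        with _stage(report, "demux"):
            assignments, inserts = amplicon_phasing.demultiplex(
                reads, bundle.manifest, max_edits=int(th["barcode_max_edits"]))
            n_assigned = sum(1 for a in assignments if a.sample_id)
            report.stage_counts["demux"] = {
                "assigned": n_assigned, "unassigned": len(assignments) - n_assigned}

        with _stage(report, "phase"):
            genotypes = []
            allele_consensuses = {}
            for sample in sorted(inserts):
                if len(inserts[sample]) < int(th["min_reads"]):
                    continue
                clusters = amplicon_phasing.phase_alleles(
                    inserts[sample], sample_id=sample, locus_id="MFT-2",
                    identity_threshold=th["cluster_identity"],
                    min_fraction=th["min_allele_fraction"],
                    min_reads=int(th["min_reads"]))
                genotype = amplicon_phasing.genotype_locus(clusters)
                genotypes.append(genotype)
                for cluster in clusters:
                    allele_consensuses.setdefault(cluster.consensus, []).append(sample)
                report.genotypes.append({
                    "sample": sample, "zygosity": genotype.zygosity,
                    "ratios": [c.ratio_rounded for c in clusters],
                    "subread_coverage": [c.subread_coverage for c in clusters],
                    "amplicon_coverage": [c.amplicon_coverage for c in clusters]})
            report.stage_counts["phase"] = {
                "distinct_alleles": len(allele_consensuses),
                "heterozygous_samples": sum(
                    1 for g in genotypes if g.zygosity == "heterozygous")}

        with _stage(report, "callvars"):
            het = next((g for g in genotypes if g.zygosity == "heterozygous"), None)
            if het is None:
                report.skipped.append("callvars (no heterozygous locus)")
            else:
                alleles = sorted((c.consensus for c in het.alleles), key=len, reverse=True)
                aln = variant_annotation.align_alleles(alleles[0], alleles[1])
                variants = variant_annotation.call_variants(aln, bundle.mft2.model)
                write_variants(variants, alleles[0], "MFT-2",
                               out / "variants.vcf", out / "variants.tsv")
                report.variants = [
                    {"position": v.position, "kind": v.kind, "ref": v.ref,
                     "alt": v.alt, "region": f"{v.region[0]}{v.region[1]}",
                     "cds_position": v.cds_position, "effect": v.effect,
                     "aa_change": (f"{v.aa_change[0]}{v.aa_change[1]}{v.aa_change[2]}"
                                   if v.aa_change else None)}
                    for v in variants]
    finally:
        logger.removeHandler(handler)
        handler.close()

    report.to_json(out / "report.json")
    return report


def _build_assemblies(bundle):
    """Three synthetic assemblies carrying FT-1, FT-2 and MFT-2 loci; one
    assembly's FT-2 differs by two exonic substitutions (the cross-assembly
    coding-variant situation)."""
    base = synthetic_data.make_scaffold(30000, 0.42, seed=991, scaffold_id="chrF")
    base, ft1_model = synthetic_data.embed_gene(
        base, bundle.ft1_template, 8001, "+", seed=11, locus_id="FT-1")
    base, ft2_model = synthetic_data.embed_gene(
        base, bundle.ft2_template, 15001, "+", seed=12,
        existing=[ft1_model], locus_id="FT-2")
    base, mft2_model = synthetic_data.embed_gene(
        base, bundle.mft2.template, 25001, "+", seed=13,
        existing=[ft1_model, ft2_model], locus_id="MFT-2")

    # FT-2 exon IV genomic offsets of the two coding edits
    ft2_exons = sorted(ft2_model.exons)
    cds_to_gene = {}
    cds_pos = 0
    for s, e in ft2_exons:
        for g in range(s, e + 1):
            cds_pos += 1
            cds_to_gene[cds_pos] = g
    edits = [synthetic_data.Edit(cds_to_gene[pos], "substitution", ref, alt, "exon")
             for pos, ref, alt in bundle.variant1_cds_edits]
    plans = {
        "asmA": synthetic_data.VariantSpec([]),
        "asmB": synthetic_data.VariantSpec([]),
        "asmC": synthetic_data.VariantSpec(edits),
    }
    assemblies = synthetic_data.make_assembly_set(base, plans)
    for name, rec in assemblies.items():
        assemblies[name] = SeqRecord(f"chrF_{name}", rec.sequence, rec.description)

    models = {"FT-1": ft1_model, "FT-2": ft2_model, "MFT-2": mft2_model}
    variant_cds = synthetic_data.apply_spec(
        bundle.ft2_template.cds,
        synthetic_data.VariantSpec(
            [synthetic_data.Edit(pos, "substitution", ref, alt, "exon")
             for pos, ref, alt in bundle.variant1_cds_edits]))
    cds_sets = {
        "asmA": {"FT-1": bundle.ft1_template.cds, "FT-2": bundle.ft2_template.cds,
                 "MFT-2": bundle.mft2.template.cds},
        "asmB": {"FT-1": bundle.ft1_template.cds, "FT-2": bundle.ft2_template.cds,
                 "MFT-2": bundle.mft2.template.cds},
        "asmC": {"FT-1": bundle.ft1_template.cds, "FT-2": variant_cds,
                 "MFT-2": bundle.mft2.template.cds},
    }
    return assemblies, models, cds_sets
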