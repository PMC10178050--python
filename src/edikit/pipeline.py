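"""End-to-end orchestration over a study directory.

Glues the stages together in the order the method runs: call tables ->
candidate selection -> filtration -> A-to-I subset -> annotation ->
differential / treatment-specific classification -> recoding ->
expression correlation -> enrichment -> summaries.  The directory layout
is the one :func:`edikit.synthetic.simulate_study` emits:

    genome.fa  annotation.gtf  known_snps.vcf  metadata.tsv
    gene_counts.tsv  transcript_counts.tsv
    rna/<sample_id>.rna.tsv  dna/<individual_id>.dna.tsv
    variants/<individual_id>.vcf
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx

from . import annotation as ann_mod
from . import correlation as corr_mod
from . import differential as diff_mod
from . import enrichment as enr_mod
from . import recoding as rec_mod
from . import report as rep_mod
from .filtering import EditingMatrix, apply_filtration, select_candidates, subset_atoi
from .io_formats import GeneModel, read_call_table, read_expression, read_gene_models, read_metadata, read_variants


@dataclass
class PipelineResult:
    matrix_all: EditingMatrix  # all substitution types, post-filtration
    matrix: EditingMatrix  # A-to-I subset
    gene_models: GeneModel
    annotations: dict
    diff_results: list
    specific_results: list
    functional: diff_mod.FunctionalSites
    tissue_tests: list[dict]
    pca: diff_mod.PcaResult
    recoding_results: list
    recoding_summary: dict
    correlations: list
    correlation_summary: dict
    utr3_enrichment: list
    feature_enrichment: list
    distance_stats: dict = field(default_factory=dict)
    tissue_summary: pd.DataFrame | None = None


def run_pipeline(
    study_dir: str | Path,
    min_samples: int = 3,
    min_per_group: int = 3,
    alpha: float = 0.05,
    min_pairs: int = 5,
    autosomes: list[str] | None = None,
    diff_method: str = "auto",
) -> PipelineResult:
    d = Path(study_dir)
    metadata = read_metadata(d / "metadata.tsv")
    meta_by_sample = {m.sample_id: m for m in metadata}

    dna_calls = {
        m.individual_id: read_call_table(d / "dna" / f"{m.individual_id}.dna.tsv", kind="DNA")
        for m in metadata
        if (d / "dna" / f"{m.individual_id}.dna.tsv").exists()
    }
    candidates = {}
    for m in metadata:
        rna = read_call_table(d / "rna" / f"{m.sample_id}.rna.tsv", kind="RNA")
        candidates[m.sample_id] = select_candidates(rna, dna_calls[m.individual_id])

    known = read_variants(d / "known_snps.vcf")
    individual_variants = {
        ind: read_variants(d / "variants" / f"{ind}.vcf")
        for ind in sorted({m.individual_id for m in metadata})
        if (d / "variants" / f"{ind}.vcf").exists()
    }

    gene_models = read_gene_models(d / "annotation.gtf")
    if autosomes is None:
        autosomes = sorted({g.chrom for g in gene_models.genes.values()})

    matrix_all = apply_filtration(
        candidates, known, individual_variants, metadata, min_samples=min_samples, autosomes=autosomes
    )
    matrix = subset_atoi(matrix_all)

    genome = pyfaidx.Fasta(str(d / "genome.fa"))
    chrom_lengths = {name: len(rec) for name, rec in genome.items()}
    findex = ann_mod.FeatureIndex(gene_models)
    annotations = ann_mod.annotate_sites(matrix.sites, findex)

    tissues = list(dict.fromkeys(m.tissue for m in metadata))
    diff_results, specific_results, tissue_tests = [], [], []
    for tissue in tissues:
        diff_results.extend(
            diff_mod.per_site_test(matrix, tissue, min_per_group=min_per_group, alpha=alpha, method=diff_method)
        )
        specific_results.extend(diff_mod.classify_treatment_specific(matrix, tissue, min_samples=min_samples))
        tissue_tests.append(diff_mod.tissue_level_test(matrix, tissue))
    functional = diff_mod.assemble_functional_sites(diff_results, specific_results)
    pca = diff_mod.run_pca(matrix)

    recoding_results, recoding_summary = rec_mod.recode_all(matrix.sites, annotations, gene_models, genome)

    counts, lengths = read_expression(d / "gene_counts.tsv")
    expr = corr_mod.rpkm(counts, lengths)
    correlations = corr_mod.correlate_site_expression(matrix, expr, annotations, min_pairs=min_pairs, alpha=alpha)
    correlation_summary = corr_mod.summarize_correlations(correlations, n_sites_total=matrix.n_sites)

    all_keys = set(matrix.levels.index)
    correlated = {c.site_key for c in correlations if c.significant}
    utr3_enrichment = corr_mod.correlated_site_enrichment(correlated, all_keys, annotations, alpha=alpha)

    length_table = ann_mod.feature_length_table(findex, chrom_lengths)
    class_counts = {
        cls: sum(1 for a in annotations.values() if cls in a.classes)
        for cls in ("exon", "intron", "five_prime_utr", "CDS", "three_prime_utr")
    }
    feature_enrichment = enr_mod.length_background_enrichment(
        class_counts,
        {cls: length_table[cls] for cls in class_counts},
        total_sites=matrix.n_sites,
        total_length=length_table["genome"],
        test="chi2",
    )

    return PipelineResult(
        matrix_all=matrix_all,
        matrix=matrix,
        gene_models=gene_models,
        annotations=annotations,
        diff_results=diff_results,
        specific_results=specific_results,
        functional=functional,
        tissue_tests=tissue_tests,
        pca=pca,
        recoding_results=recoding_results,
        recoding_summary=recoding_summary,
        correlations=correlations,
        correlation_summary=correlation_summary,
        utr3_enrichment=utr3_enrichment,
        feature_enrichment=feature_enrichment,
        distance_stats=rep_mod.distance_distribution(matrix.sites),
        tissue_summary=rep_mod.tissue_summary(matrix),
    )
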