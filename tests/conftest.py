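import pytest

from edikit.io_formats import Gene, GeneModel, SampleMeta, Transcript
from edikit.pipeline import run_pipeline
from edikit.synthetic import SimulationConfig, simulate_study

STUDY_SEED = 777


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One default synthetic study shared by the whole session."""
    out = tmp_path_factory.mktemp("study")
    return simulate_study(SimulationConfig(seed=STUDY_SEED), out)


@pytest.fixture(scope="session")
def pipeline_result(study):
    return run_pipeline(study.out_dir)


def make_transcript(
    tx_id="T1",
    gene_id="G1",
    chrom="1",
    strand="+",
    exons=((1, 100),),
    cds=(),
    utr5=(),
    utr3=(),
):
    start = min(s for s, _ in exons)
    end = max(e for _, e in exons)
    tx = Transcript(tx_id, gene_id, chrom, strand, start, end)
    tx.exons = sorted(exons)
    tx.cds = sorted(cds)
    tx.five_prime_utr = sorted(utr5)
    tx.three_prime_utr = sorted(utr3)
    return tx


def make_gene_model(*transcripts, biotype="protein_coding"):
    model = GeneModel()
    for tx in transcripts:
        gene = model.genes.get(tx.gene_id)
        if gene is None:
            gene = Gene(tx.gene_id, tx.chrom, tx.strand, tx.start, tx.end, biotype)
            model.genes[tx.gene_id] = gene
        gene.start = min(gene.start, tx.start)
        gene.end = max(gene.end, tx.end)
        gene.transcripts[tx.transcript_id] = tx
    return model


def make_meta(n_individuals=4, tissues=("Du", "Li"), hed=("P1", "P2")):
    metas = []
    for i in range(n_individuals):
        ind = f"P{i + 1}"
        for t in tissues:
            metas.append(SampleMeta(f"{ind}_{t}", ind, t, "HED" if ind in hed else "ND"))
    return metas
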