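"""Codon mapping and amino-acid consequences of CDS editing sites.

For a site inside an annotated CDS, the spliced nucleotide offset from the
start codon is computed (introns removed; minus-strand transcripts counted
from the rightmost CDS base leftward on the antisense, complemented
sequence), the containing codon is extracted from the strand-corrected CDS
sequence, and the A -> G edit is applied at the site's position within the
codon.  Offsets and codon indices are 0-based internally.

A -> G editing can never create a stop codon: reverting the introduced G
back to A in either stop codon containing G (TAG, TGA) yields TAA, itself
a stop — so ``stop_gain`` is asserted unreachable here.  ``stop_loss`` is
reachable (TGA -> TGG) only when a stop codon is annotated inside the CDS,
which the Ensembl dialect does not do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .annotation import SiteAnnotation
from .io_formats import GeneModel, Transcript

log = logging.getLogger("edikit")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class NotInCDSError(ValueError):
    """Site does not fall inside the transcript's CDS."""


class StrandMismatchError(ValueError):
    """Site strand differs from the transcript strand."""


class DataInconsistencyError(ValueError):
    """Reference codon lacks an A at the edited position."""


@dataclass(frozen=True)
class RecodingResult:
    site_key: str
    transcript_id: str
    gene_id: str
    cds_offset: int  # 0-based spliced offset from the start codon
    codon_index: int
    pos_in_codon: int  # 0, 1 or 2
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    consequence: str  # synonymous | nonsynonymous | stop_gain | stop_loss


def classify_consequence(ref_aa: str, edited_aa: str) -> str:
    if ref_aa == edited_aa:
        return "synonymous"
    if ref_aa == "*":
        return "stop_loss"
    if edited_aa == "*":
        return "stop_gain"
    return "nonsynonymous"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def _fetch(genome, chrom: str, pos: int) -> str:
    """One plus-strand base, 1-based; accepts pyfaidx.Fasta or dict of str."""
    seq = genome[chrom]
    if hasattr(seq, "seq"):  # pyfaidx chromosome record sliced below
        return str(genome[chrom][pos - 1 : pos]).upper()
    return str(seq[pos - 1]).upper()


def cds_offset(site: tuple[str, int, str], transcript: Transcript) -> int:
    """Spliced 0-based offset of a genomic site from the start codon.

    Plus strand counts left to right from the CDS start; minus strand
    counts right to left from the rightmost CDS base.
    """
    chrom, pos, strand = site
    if strand != transcript.strand:
        raise StrandMismatchError(
            f"site strand {strand} != transcript {transcript.transcript_id} strand {transcript.strand}"
        )
    if chrom != transcript.chrom or not any(s <= pos <= e for s, e in transcript.cds):
        raise NotInCDSError(f"{chrom}:{pos} not in CDS of {transcript.transcript_id}")
    if transcript.strand == "+":
        offset = 0
        for s, e in sorted(transcript.cds):
            if pos > e:
                offset += e - s + 1
            else:
                return offset + pos - s
    offset = 0
    for s, e in sorted(transcript.cds, reverse=True):
        if pos < s:
            offset += e - s + 1
        else:
            return offset + e - pos
    raise NotInCDSError(f"{chrom}:{pos} not in CDS of {transcript.transcript_id}")


def recode(site: tuple[str, int, str], transcript: Transcript, genome) -> RecodingResult:
    """Apply the A -> G edit to the containing codon and classify it.

    ``genome`` is a pyfaidx.Fasta or a mapping chrom -> sequence string.
    """
    chrom, pos, strand = site
    offset = cds_offset(site, transcript)
    codon_index, pos_in_codon = divmod(offset, 3)
    positions = transcript.spliced_cds_positions()
    codon_pos = positions[3 * codon_index : 3 * codon_index + 3]
    bases = [_fetch(genome, chrom, p) for p in codon_pos]
    if strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
    ref_codon = "".join(bases)
    if ref_codon[pos_in_codon] != "A":
        raise DataInconsistencyError(
            f"{chrom}:{pos}:{strand} is not an A on the coding strand "
            f"(codon {ref_codon}, position {pos_in_codon})"
        )
    edited_codon = ref_codon[:pos_in_codon] + "G" + ref_codon[pos_in_codon + 1 :]
    ref_aa = translate_codon(ref_codon)
    edited_aa = translate_codon(edited_codon)
    consequence = classify_consequence(ref_aa, edited_aa)
    assert consequence != "stop_gain", "A-to-G recoding cannot create a stop codon"
    return RecodingResult(
        site_key=f"{chrom}:{pos}:{strand}",
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
        cds_offset=offset,
        codon_index=codon_index,
        pos_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        edited_codon=edited_codon,
        ref_aa=ref_aa,
        edited_aa=edited_aa,
        consequence=consequence,
    )


def recode_all(
    sites,
    annotations: dict[str, SiteAnnotation],
    gene_models: GeneModel,
    genome,
) -> tuple[list[RecodingResult], dict]:
    """Evaluate every (CDS site, transcript) pair and summarize.

    ``sites`` is a DataFrame with chrom/pos/strand indexed by site_key or an
    iterable of (site_key, chrom, pos, strand).  One result is produced per
    (site, transcript) pair; transcripts whose CDS length is not divisible
    by 3 are skipped with a warning counter.  In the summary, a protein
    (transcript) is isoform-divergent when the same site is synonymous in
    one of its gene's transcripts and nonsynonymous in another.
    """
    try:
        records = [(k, str(r["chrom"]), int(r["pos"]), str(r["strand"])) for k, r in sites.iterrows()]
    except AttributeError:
        records = [(k, str(c), int(p), str(s)) for k, c, p, s in sites]

    results: list[RecodingResult] = []
    n_skipped_frame = 0
    for site_key, chrom, pos, strand in records:
        ann = annotations.get(site_key)
        if ann is None or "CDS" not in ann.classes:
            continue
        for gene_id in ann.gene_ids:
            gene = gene_models.genes.get(gene_id)
            if gene is None:
                continue
            for tx in gene.transcripts.values():
                if not tx.cds or tx.strand != strand:
                    continue
                if not any(s <= pos <= e for s, e in tx.cds):
                    continue
                if tx.cds_length % 3 != 0:
                    n_skipped_frame += 1
                    continue
                results.append(recode((chrom, pos, strand), tx, genome))
    if n_skipped_frame:
        log.warning("recode_all: skipped %d (site, transcript) pairs with CDS length %% 3 != 0", n_skipped_frame)

    sites_in_cds = {r.site_key for r in results}
    proteins = {r.transcript_id for r in results}
    nonsyn_proteins = {r.transcript_id for r in results if r.consequence == "nonsynonymous"}
    syn_proteins = {r.transcript_id for r in results if r.consequence == "synonymous"}
    # isoform divergence: same site, same gene, discordant consequence across transcripts
    by_site_gene: dict[tuple[str, str], list[RecodingResult]] = {}
    for r in results:
        by_site_gene.setdefault((r.site_key, r.gene_id), []).append(r)
    divergent: set[str] = set()
    for group in by_site_gene.values():
        consequences = {r.consequence for r in group}
        if "synonymous" in consequences and "nonsynonymous" in consequences:
            divergent.update(r.transcript_id for r in group)
    summary = {
        "n_sites_in_cds": len(sites_in_cds),
        "n_proteins": len(proteins),
        "n_nonsynonymous": len(nonsyn_proteins),
        "n_synonymous": len(syn_proteins),
        "n_isoform_divergent": len(divergent),
        "n_pairs": len(results),
        "n_pairs_nonsynonymous": sum(r.consequence == "nonsynonymous" for r in results),
        "n_pairs_synonymous": sum(r.consequence == "synonymous" for r in results),
        "n_skipped_frame": n_skipped_frame,
    }
    return results, summary
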