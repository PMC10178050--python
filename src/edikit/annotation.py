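"""Intersection of editing sites with gene features, biotypes and exon
boundaries.

A site is assigned every feature class it overlaps in any transcript (the
union rule — no precedence hierarchy), so per-class counts are
non-exclusive.  With ``strand_aware=True`` (the default, appropriate for
strand-specific libraries) a site only matches features on its own strand;
a site overlapping no gene body is intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GeneModel

log = logging.getLogger("edikit")

FEATURE_CLASSES = (
    "exon",
    "intron",
    "five_prime_utr",
    "CDS",
    "three_prime_utr",
    "start_codon",
    "stop_codon",
)


@dataclass
class SiteAnnotation:
    site_key: str
    gene_ids: list[str] = field(default_factory=list)
    transcript_ids: list[str] = field(default_factory=list)
    biotypes: list[str] = field(default_factory=list)
    classes: set[str] = field(default_factory=set)
    splice_related: bool = False
    distance_to_exon_boundary: int | None = None  # signed; negative = left of boundary

    @property
    def intergenic(self) -> bool:
        return not self.gene_ids


class FeatureIndex:
    """Interval indexes over one :class:`GeneModel`.

    Trees are keyed by (feature class, chrom, strand); gene-body trees by
    (chrom, strand).  Merged per-class genomic footprints (strand-collapsed)
    back the length table.
    """

    def __init__(self, model: GeneModel):
        self.model = model
        self.trees: dict[tuple[str, str, str], IntervalTree] = {}
        self.gene_trees: dict[tuple[str, str], IntervalTree] = {}
        self._boundaries: dict[tuple[str, str], np.ndarray] = {}
        self._class_intervals: dict[str, list[tuple[str, int, int]]] = {c: [] for c in FEATURE_CLASSES}
        self._biotype_intervals: dict[str, list[tuple[str, int, int]]] = {}
        self._gene_intervals: list[tuple[str, int, int]] = []

        boundary_sets: dict[tuple[str, str], set[int]] = {}
        for gene in model.genes.values():
            key = (gene.chrom, gene.strand)
            self.gene_trees.setdefault(key, IntervalTree()).addi(gene.start, gene.end + 1, gene.gene_id)
            self._gene_intervals.append((gene.chrom, gene.start, gene.end))
            self._biotype_intervals.setdefault(gene.biotype, []).append((gene.chrom, gene.start, gene.end))
            for tx in gene.transcripts.values():
                features = {
                    "exon": tx.exons,
                    "intron": tx.introns,
                    "five_prime_utr": tx.five_prime_utr,
                    "CDS": tx.cds,
                    "three_prime_utr": tx.three_prime_utr,
                    "start_codon": tx.start_codon,
                    "stop_codon": tx.stop_codon,
                }
                for cls, intervals in features.items():
                    for s, e in intervals:
                        tkey = (cls, gene.chrom, gene.strand)
                        self.trees.setdefault(tkey, IntervalTree()).addi(
                            s, e + 1, (gene.gene_id, tx.transcript_id, gene.biotype)
                        )
                        self._class_intervals[cls].append((gene.chrom, s, e))
                for s, e in tx.exons:
                    boundary_sets.setdefault(key, set()).update((s, e))
        for key, bset in boundary_sets.items():
            self._boundaries[key] = np.array(sorted(bset))

    # -- queries -----------------------------------------------------------

    def classes_at(self, chrom: str, pos: int, strand: str, strand_aware: bool = True):
        """(classes, gene_ids, transcript_ids, biotypes) overlapping a position."""
        strands = (strand,) if strand_aware else ("+", "-")
        classes: set[str] = set()
        genes: list[str] = []
        txs: list[str] = []
        biotypes: list[str] = []
        for st in strands:
            for cls in FEATURE_CLASSES:
                for iv in self.trees.get((cls, chrom, st), IntervalTree()).at(pos):
                    classes.add(cls)
                    gid, txid, bt = iv.data
                    if gid not in genes:
                        genes.append(gid)
                    if txid not in txs:
                        txs.append(txid)
                    if bt not in biotypes:
                        biotypes.append(bt)
            for iv in self.gene_trees.get((chrom, st), IntervalTree()).at(pos):
                if iv.data not in genes:
                    genes.append(iv.data)
                    bt = self.model.genes[iv.data].biotype
                    if bt not in biotypes:
                        biotypes.append(bt)
        return classes, genes, txs, biotypes

    def nearest_exon_boundary(self, chrom: str, pos: int, strand: str, strand_aware: bool = True) -> int | None:
        """Signed distance ``pos - boundary`` to the closest exon start/end."""
        keys = [(chrom, strand)] if strand_aware else [(chrom, "+"), (chrom, "-")]
        best: int | None = None
        for key in keys:
            b = self._boundaries.get(key)
            if b is None or len(b) == 0:
                continue
            i = int(np.searchsorted(b, pos))
            for j in (i - 1, i):
                if 0 <= j < len(b):
                    d = pos - int(b[j])
                    if best is None or abs(d) < abs(best):
                        best = d
        return best

    # -- lengths -----------------------------------------------------------

    @staticmethod
    def _merged_length(intervals: list[tuple[str, int, int]]) -> int:
        total = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    total += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            total += cur_e - cur_s + 1
        return total

    def class_lengths(self) -> dict[str, int]:
        return {cls: self._merged_length(ivs) if ivs else 0 for cls, ivs in self._class_intervals.items()}

    def biotype_lengths(self) -> dict[str, int]:
        return {bt: self._merged_length(ivs) for bt, ivs in self._biotype_intervals.items()}

    def gene_body_length(self) -> int:
        return self._merged_length(self._gene_intervals) if self._gene_intervals else 0


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def annotate_sites(
    sites,
    gene_models: GeneModel | FeatureIndex,
    strand_aware: bool = True,
    splice_window: int = 10,
) -> dict[str, SiteAnnotation]:
    """Annotate each site with overlapping features and splice proximity.

    ``sites`` is any iterable of (site_key, chrom, pos, strand) or a
    DataFrame with chrom/pos/strand indexed by site_key (the ``sites`` table
    of an :class:`~edikit.filtering.EditingMatrix`).
    """
    index = gene_models if isinstance(gene_models, FeatureIndex) else FeatureIndex(gene_models)
    records = _site_records(sites)
    known_chroms = {g.chrom for g in index.model.genes.values()}
    n_unknown = 0
    out: dict[str, SiteAnnotation] = {}
    for site_key, chrom, pos, strand in records:
        ann = SiteAnnotation(site_key=site_key)
        if chrom not in known_chroms:
            n_unknown += 1
            out[site_key] = ann
            continue
        classes, genes, txs, biotypes = index.classes_at(chrom, pos, strand, strand_aware)
        ann.classes = classes
        ann.gene_ids = genes
        ann.transcript_ids = txs
        ann.biotypes = biotypes
        d = index.nearest_exon_boundary(chrom, pos, strand, strand_aware)
        ann.distance_to_exon_boundary = d
        ann.splice_related = d is not None and abs(d) <= splice_window
        out[site_key] = ann
    if n_unknown:
        log.warning("annotate_sites: %d sites on chromosomes absent from the annotation", n_unknown)
    return out


def _site_records(sites):
    try:  # DataFrame path
        return [
            (k, str(r["chrom"]), int(r["pos"]), str(r["strand"]))
            for k, r in sites.iterrows()
        ]
    except AttributeError:
        return [(k, str(c), int(p), str(s)) for k, c, p, s in sites]


def classify_splice_proximity(annotations: dict[str, SiteAnnotation], window: int = 10) -> dict[str, bool]:
    """splice_related <=> |distance to nearest exon boundary| <= window (inclusive)."""
    out = {}
    for k, ann in annotations.items():
        d = ann.distance_to_exon_boundary
        flag = d is not None and abs(d) <= window
        ann.splice_related = flag
        out[k] = flag
    return out


def feature_length_table(
    gene_models: GeneModel | FeatureIndex,
    genome_lengths: dict[str, int] | None = None,
) -> dict[str, int]:
    """Merged genomic footprint (bp) per feature class and biotype.

    When ``genome_lengths`` is given, also reports total genome length and
    the intergenic complement of the gene-body union.
    """
    index = gene_models if isinstance(gene_models, FeatureIndex) else FeatureIndex(gene_models)
    table = dict(index.class_lengths())
    for bt, length in sorted(index.biotype_lengths().items()):
        table[f"biotype:{bt}"] = length
    table["gene_body"] = index.gene_body_length()
    if genome_lengths is not None:
        total = sum(genome_lengths.values())
        table["genome"] = total
        table["intergenic"] = total - table["gene_body"]
    return table
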