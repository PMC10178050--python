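"""Synthetic A-to-I editing study generator with planted ground truth.

Emulates the study design the pipeline is built for: 8 individuals, 9
tissues (6 gut segments plus abdominal aorta, liver, testis), half the
animals on a high-energy diet (HED) and half on normal chow (ND).  The
generator emits every file the downstream pipeline consumes — genome FASTA,
Ensembl-dialect GTF, known-variant VCF, per-individual variant VCFs,
per-sample RNA and per-individual DNA call tables, expression count
matrices, sample metadata — together with a serializable ground truth so
recovery can be scored.

Planted site classes
--------------------
stable                  present in a random tissue subset, same level in
                        both diet arms
differential            level differs by ``delta`` between HED and ND in
                        every tissue
hed_specific /          detected in one diet arm only (absent from every
nd_specific             sample of the other arm)
recoding                sits on an A of a coding codon; the expected
                        reference/edited codon and amino acids are recorded
expression_correlated   3'-UTR site whose editing level tracks the host
                        gene's realized expression with target correlation
                        ``rho``
decoy_*                 bait for each filtration step: known-SNP overlap,
                        individual-variant overlap, detected in < 3 samples,
                        100 % edited everywhere, non-autosomal placement,
                        and non-AG substitutions (C-to-T) for the A-to-I
                        subset step

Editing levels are Beta-distributed with mean 0.3 and are floored at 0.18:
the candidate-selection threshold of >= 5 edited reads censors low-level
sites, and without the floor stochastic per-sample dropout of genuinely
stable sites would masquerade as treatment specificity, which is not a
condition this generator is meant to plant.  Observed edited-read counts
are Binomial(coverage, level); coverage is a shifted negative binomial.
All randomness flows from a single seed through one generator instance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .recoding import classify_consequence
from .io_formats import (
    BaseCall,
    GeneModel,
    Gene,
    SampleMeta,
    Transcript,
    TISSUES,
    write_call_table,
    write_expression,
    write_fasta,
    write_gtf,
    write_metadata,
    write_vcf,
)

import pandas as pd


class SimulationError(ValueError):
    """Base class for generator failures."""


class ConfigError(SimulationError):
    """Impossible or inconsistent configuration."""


class SizingError(SimulationError):
    """Genome too short for the requested genes or sites."""


class PlacementError(SimulationError):
    """No suitable position available for a planted site."""


SITE_CLASSES = (
    "stable",
    "differential",
    "hed_specific",
    "nd_specific",
    "recoding",
    "expression_correlated",
    "decoy_known_snp",
    "decoy_individual_variant",
    "decoy_low_sample",
    "decoy_full_edit",
    "decoy_non_autosomal",
    "decoy_non_ag",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_individuals: int = 8
    n_hed: int = 4
    tissues: tuple[str, ...] = TISSUES

    autosome_lengths: dict[str, int] = field(default_factory=lambda: {"1": 150_000, "2": 150_000})
    sex_chrom: tuple[str, int] = ("X", 30_000)
    unplaced_chrom: tuple[str, int] = ("scaffold_1", 20_000)
    n_genes: int = 30
    noncoding_fraction: float = 0.2  # miRNA/lincRNA single-exon genes

    # planted site-class counts (n_stable fills up to n_sites)
    n_sites: int = 500
    n_differential: int = 30
    n_hed_specific: int = 15
    n_nd_specific: int = 15
    n_recoding: int = 12
    n_correlated: int = 15
    recoding_minus_fraction: float = 0.5

    # decoys, on top of n_sites
    n_snp_decoys: int = 12
    n_variant_decoys: int = 12
    n_low_sample_decoys: int = 10
    n_full_edit_decoys: int = 8
    n_non_autosomal_decoys: int = 10
    n_non_ag: int = 25
    n_extra_known_snps: int = 40

    # editing-level model: Beta(a, b) has mean 0.3; floor keeps planted
    # sites clear of the >= 5-edited-reads detection boundary
    beta_a: float = 3.0
    beta_b: float = 7.0
    level_floor: float = 0.18
    level_ceiling: float = 0.95
    sample_level_sd: float = 0.02
    delta: float = 0.3
    rho: float = 0.9
    fraction_clustered: float = 0.5
    cluster_window: int = 20

    # coverage: floor + NegativeBinomial(mean over floor, dispersion size)
    rna_coverage_floor: int = 50
    rna_coverage_mean: float = 70.0
    rna_coverage_size: float = 8.0
    dna_coverage_floor: int = 10
    dna_coverage_mean: float = 40.0
    dna_coverage_size: float = 8.0

    # expression model
    expression_mean: float = 200.0
    expression_size: float = 10.0
    expression_log_sd: float = 0.8  # per-sample spread for correlated genes
    tissue_presence_prob: float = 0.75
    adar_coupling: float = 0.0  # >0 couples stable-site levels to ADAR expression

    def validate(self) -> None:
        counts = [
            self.n_sites, self.n_differential, self.n_hed_specific, self.n_nd_specific,
            self.n_recoding, self.n_correlated, self.n_snp_decoys, self.n_variant_decoys,
            self.n_low_sample_decoys, self.n_full_edit_decoys, self.n_non_autosomal_decoys,
            self.n_non_ag,
        ]
        if any(c < 0 for c in counts):
            raise ConfigError("site counts must be non-negative")
        if self.n_hed > self.n_individuals:
            raise ConfigError("n_hed cannot exceed n_individuals")
        if not (0.0 < self.delta < 1.0):
            raise ConfigError(f"delta must be in (0,1), got {self.delta}")
        if not (-1.0 <= self.rho <= 1.0):
            raise ConfigError(f"rho must be in [-1,1], got {self.rho}")
        if self.n_stable < 0:
            raise ConfigError("planted class counts exceed n_sites")

    @property
    def n_stable(self) -> int:
        return self.n_sites - (
            self.n_differential + self.n_hed_specific + self.n_nd_specific
            + self.n_recoding + self.n_correlated
        )

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(self.autosome_lengths)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.tissues = tuple(cfg.tissues)
        cfg.sex_chrom = tuple(cfg.sex_chrom)
        cfg.unplaced_chrom = tuple(cfg.unplaced_chrom)
        return cfg


@dataclass
class SiteTruth:
    site_key: str
    chrom: str
    pos: int
    strand: str
    substitution: str
    klass: str
    base_level: float | None = None
    direction: str | None = None  # differential: "higher"/"lower" in HED
    delta: float | None = None
    rho: float | None = None
    gene_id: str | None = None
    transcript_id: str | None = None
    ref_codon: str | None = None
    edited_codon: str | None = None
    ref_aa: str | None = None
    edited_aa: str | None = None
    consequence: str | None = None
    tissues: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    sites: list[SiteTruth]
    hed_individuals: list[str]
    nd_individuals: list[str]
    gene_expression_means: dict[str, float]
    adar_gene_ids: list[str]

    def by_class(self, klass: str) -> list[SiteTruth]:
        return [s for s in self.sites if s.klass == klass]

    def keys_of(self, *klasses: str) -> set[str]:
        return {s.site_key for s in self.sites if s.klass in klasses}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sites": [asdict(s) for s in self.sites],
            "hed_individuals": self.hed_individuals,
            "nd_individuals": self.nd_individuals,
            "gene_expression_means": self.gene_expression_means,
            "adar_gene_ids": self.adar_gene_ids,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            sites=[SiteTruth(**s) for s in payload["sites"]],
            hed_individuals=payload["hed_individuals"],
            nd_individuals=payload["nd_individuals"],
            gene_expression_means=payload["gene_expression_means"],
            adar_gene_ids=payload["adar_gene_ids"],
        )


@dataclass
class SimulatedStudy:
    out_dir: Path
    config: SimulationConfig
    truth: GroundTruth
    genome_fasta: Path
    gtf: Path
    known_snps_vcf: Path
    individual_vcfs: dict[str, Path]
    rna_tables: dict[str, Path]  # sample_id -> path
    dna_tables: dict[str, Path]  # individual_id -> path
    gene_counts: Path
    transcript_counts: Path
    metadata: Path
    truth_json: Path
    samples: list[SampleMeta]


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------

_GENE_SPAN = 1600
_NONCODING_SPAN = 400


def _coding_layout(s: int, strand: str) -> dict[str, list[tuple[int, int]]]:
    """Two-exon coding gene occupying [s, s+1599].

    Plus strand: exon1 [s..s+299] = 240 nt 5'-UTR + 60 nt CDS; 500 nt
    intron; exon2 [s+800..s+1599] = 441 nt CDS + stop codon + 3'-UTR.
    CDS totals 501 nt (167 codons).  Minus strand is the mirror image.
    """
    if strand == "+":
        return {
            "exons": [(s, s + 299), (s + 800, s + 1599)],
            "five_prime_utr": [(s, s + 239)],
            "start_codon": [(s + 240, s + 242)],
            "cds": [(s + 240, s + 299), (s + 800, s + 1240)],
            "stop_codon": [(s + 1241, s + 1243)],
            "three_prime_utr": [(s + 1244, s + 1599)],
        }
    e = s + _GENE_SPAN - 1

    def refl(a: int, b: int) -> tuple[int, int]:
        return (s + (e - b), s + (e - a))

    plus = _coding_layout(s, "+")
    return {k: sorted(refl(a - s + s, b - s + s) for a, b in v) for k, v in plus.items()}


@dataclass
class _GeneSpec:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    coding: bool


def _build_gene_models(cfg: SimulationConfig, rng: np.random.Generator) -> GeneModel:
    adar_ids = ["ADAR", "ADARB1", "ADARB2"]
    n_total = cfg.n_genes + len(adar_ids)
    autosomes = list(cfg.autosome_lengths.items())
    per_chrom = math.ceil(n_total / len(autosomes))
    for chrom, length in autosomes:
        needed = per_chrom * (_GENE_SPAN + 2000) + 2000
        if length < needed:
            raise SizingError(
                f"chromosome {chrom} ({length} bp) too short for {per_chrom} genes (~{needed} bp)"
            )
    n_noncoding = int(round(cfg.n_genes * cfg.noncoding_fraction))
    model = GeneModel()
    gi = 0
    for ci, (chrom, length) in enumerate(autosomes):
        n_here = min(per_chrom, n_total - ci * per_chrom)
        spacing = (length - 2000) // max(n_here, 1)
        for k in range(n_here):
            start = 1000 + k * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            if gi < len(adar_ids):
                gene_id, coding = adar_ids[gi], True
            else:
                gene_id = f"G{gi - len(adar_ids) + 1:04d}"
                coding = (gi - len(adar_ids)) >= n_noncoding
            if coding:
                layout = _coding_layout(start, strand)
                gene = Gene(gene_id, chrom, strand, start, start + _GENE_SPAN - 1, "protein_coding")
                tx = Transcript(f"{gene_id}.t1", gene_id, chrom, strand, gene.start, gene.end)
                tx.exons = layout["exons"]
                tx.cds = layout["cds"]
                tx.five_prime_utr = layout["five_prime_utr"]
                tx.three_prime_utr = layout["three_prime_utr"]
                tx.start_codon = layout["start_codon"]
                tx.stop_codon = layout["stop_codon"]
                gene.transcripts[tx.transcript_id] = tx
            else:
                biotype = "miRNA" if (gi % 2 == 0) else "lincRNA"
                gene = Gene(gene_id, chrom, strand, start, start + _NONCODING_SPAN - 1, biotype)
                tx = Transcript(f"{gene_id}.t1", gene_id, chrom, strand, gene.start, gene.end)
                tx.exons = [(gene.start, gene.end)]
                gene.transcripts[tx.transcript_id] = tx
            model.genes[gene_id] = gene
            gi += 1
    return model


def _cds_sense_sequence(tx: Transcript, genome: dict[str, np.ndarray]) -> str:
    chars = genome[tx.chrom]
    raw = "".join("".join(chars[s - 1 : e]) for s, e in sorted(tx.cds))
    return raw if tx.strand == "+" else revcomp(raw)


def plant_recoding_sites(
    gene_models: GeneModel,
    genome: dict[str, np.ndarray],
    n: int,
    minus_fraction: float,
    rng: np.random.Generator,
    used_positions: set[tuple[str, int]] | None = None,
) -> list[SiteTruth]:
    """Choose n CDS positions carrying an A on the coding strand.

    Truth records the reference/edited codon and amino acids for each
    planted site; ``minus_fraction`` of sites go to minus-strand genes.
    """
    used = used_positions if used_positions is not None else set()
    coding = [
        tx for g in gene_models.genes.values() for tx in g.transcripts.values()
        if tx.cds and tx.cds_length % 3 == 0 and not g.gene_id.startswith("ADAR")
    ]
    minus = [t for t in coding if t.strand == "-"]
    plus = [t for t in coding if t.strand == "+"]
    n_minus = int(round(n * minus_fraction))
    picks: list[Transcript] = []
    for pool, count in ((minus, n_minus), (plus, n - n_minus)):
        if count and not pool:
            raise PlacementError("no transcripts available on requested strand")
        idx = rng.permutation(len(pool))
        for j in range(count):
            picks.append(pool[idx[j % len(pool)]])
    out: list[SiteTruth] = []
    for tx in picks:
        seq = _cds_sense_sequence(tx, genome)
        positions = tx.spliced_cds_positions()
        n_codons = len(seq) // 3
        codon_order = rng.permutation(np.arange(2, n_codons - 2))
        placed = False
        for ci in codon_order:
            codon = seq[3 * ci : 3 * ci + 3]
            a_positions = [i for i, b in enumerate(codon) if b == "A"]
            if not a_positions:
                continue
            pic = int(a_positions[int(rng.integers(len(a_positions)))])
            gpos = positions[3 * ci + pic]
            if (tx.chrom, gpos) in used:
                continue
            used.add((tx.chrom, gpos))
            edited = codon[:pic] + "G" + codon[pic + 1 :]
            ref_aa = str(Seq(codon).translate())
            edited_aa = str(Seq(edited).translate())
            out.append(
                SiteTruth(
                    site_key=f"{tx.chrom}:{gpos}:{tx.strand}",
                    chrom=tx.chrom,
                    pos=gpos,
                    strand=tx.strand,
                    substitution="AG",
                    klass="recoding",
                    gene_id=tx.gene_id,
                    transcript_id=tx.transcript_id,
                    ref_codon=codon,
                    edited_codon=edited,
                    ref_aa=ref_aa,
                    edited_aa=edited_aa,
                    consequence=classify_consequence(ref_aa, edited_aa),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(f"no A available in CDS of {tx.transcript_id}")
    return out


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------


def _nb(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _coverage(rng: np.random.Generator, floor: int, mean: float, size_param: float, n: int) -> np.ndarray:
    return floor + _nb(rng, max(mean - floor, 1.0), size_param, n)


_BASES = np.array(list("ACGT"))
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _force_base(genome: dict[str, np.ndarray], chrom: str, pos: int, strand: str, base: str) -> None:
    """Set the genome so position carries ``base`` on ``strand``."""
    plus = base if strand == "+" else base.translate(_COMPLEMENT)
    genome[chrom][pos - 1] = plus


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> SimulatedStudy:
    """Generate the full synthetic study into ``out_dir``.

    Returns paths to every emitted file plus the :class:`GroundTruth`.
    Identical config (including seed) gives byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    (out / "rna").mkdir(parents=True, exist_ok=True)
    (out / "dna").mkdir(exist_ok=True)
    (out / "variants").mkdir(exist_ok=True)

    # -- cohort ------------------------------------------------------------
    individuals = [f"P{i + 1}" for i in range(config.n_individuals)]
    hed = sorted(rng.choice(individuals, size=config.n_hed, replace=False).tolist())
    nd = [i for i in individuals if i not in hed]
    treatment = {i: ("HED" if i in hed else "ND") for i in individuals}
    samples = [
        SampleMeta(f"{ind}_{tis}", ind, tis, treatment[ind])
        for ind in individuals
        for tis in config.tissues
    ]
    sample_ids = [s.sample_id for s in samples]

    # -- genome and annotation --------------------------------------------
    chrom_lengths = dict(config.autosome_lengths)
    chrom_lengths[config.sex_chrom[0]] = config.sex_chrom[1]
    chrom_lengths[config.unplaced_chrom[0]] = config.unplaced_chrom[1]
    genome = {
        chrom: _BASES[rng.integers(0, 4, size=length)].copy()
        for chrom, length in chrom_lengths.items()
    }
    model = _build_gene_models(config, rng)
    for gene in model.genes.values():
        for tx in gene.transcripts.values():
            if not tx.cds:
                continue
            sc = tx.start_codon[0]
            st = tx.stop_codon[0]
            if tx.strand == "+":
                genome[tx.chrom][sc[0] - 1 : sc[0] + 2] = list("ATG")
                genome[tx.chrom][st[0] - 1 : st[0] + 2] = list("TAA")
            else:
                genome[tx.chrom][sc[0] - 1 : sc[0] + 2] = list("CAT")
                genome[tx.chrom][st[0] - 1 : st[0] + 2] = list("TTA")
            # open reading frame: rewrite internal stop codons left by the
            # random sequence (real CDS have none)
            positions = tx.spliced_cds_positions()
            seq = _cds_sense_sequence(tx, genome)
            for ci in range(len(seq) // 3):
                if seq[3 * ci : 3 * ci + 3] in ("TAA", "TAG", "TGA"):
                    gpos = positions[3 * ci]
                    _force_base(genome, tx.chrom, gpos, tx.strand, "C")

    # -- position pools ----------------------------------------------------
    used: set[tuple[str, int]] = set()
    # keep later base-forcing out of start/stop codons
    for gene in model.genes.values():
        for tx in gene.transcripts.values():
            for s, e in tx.start_codon + tx.stop_codon:
                used.update((tx.chrom, p) for p in range(s, e + 1))
    coding_txs = [
        tx for g in model.genes.values() for tx in g.transcripts.values() if tx.cds
    ]
    pools: dict[str, list[tuple[str, int, str]]] = {"intron": [], "three_prime_utr": [], "five_prime_utr": []}
    for tx in coding_txs:
        for s, e in tx.introns:
            pools["intron"].extend((tx.chrom, p, tx.strand) for p in range(s, e + 1))
        for s, e in tx.three_prime_utr:
            pools["three_prime_utr"].extend((tx.chrom, p, tx.strand) for p in range(s, e + 1))
        for s, e in tx.five_prime_utr:
            pools["five_prime_utr"].extend((tx.chrom, p, tx.strand) for p in range(s, e + 1))
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in model.genes.values():
        gene_spans.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in gene_spans.values():
        spans.sort()

    def _intergenic_position() -> tuple[str, int, str]:
        for _ in range(10_000):
            chrom = config.autosomes[int(rng.integers(len(config.autosomes)))]
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            if any(s <= pos <= e for s, e in gene_spans.get(chrom, [])):
                continue
            return chrom, pos, "+"
        raise SizingError("could not find an intergenic position")

    def _draw_position(pool_weights: Sequence[tuple[str, float]]) -> tuple[str, int, str]:
        r = rng.random()
        acc = 0.0
        choice = pool_weights[-1][0]
        for name, w in pool_weights:
            acc += w
            if r < acc:
                choice = name
                break
        for _ in range(10_000):
            if choice == "intergenic":
                chrom, pos, strand = _intergenic_position()
            else:
                pool = pools[choice]
                chrom, pos, strand = pool[int(rng.integers(len(pool)))]
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos, strand
        raise SizingError(f"pool {choice} exhausted")

    weights = [("intron", 0.55), ("three_prime_utr", 0.15), ("five_prime_utr", 0.05), ("intergenic", 0.25)]
    cds_positions: set[tuple[str, int]] = {
        (tx.chrom, p) for tx in coding_txs for s, e in tx.cds for p in range(s, e + 1)
    }

    truth_sites: list[SiteTruth] = []

    def _beta_level(lo: float | None = None, hi: float | None = None) -> float:
        lo = config.level_floor if lo is None else lo
        hi = config.level_ceiling if hi is None else hi
        return float(np.clip(rng.beta(config.beta_a, config.beta_b), lo, hi))

    def _plant(klass: str, n: int, substitution: str = "AG", **extra) -> list[SiteTruth]:
        placed = []
        cluster_anchor: tuple[str, int, str] | None = None
        for _ in range(n):
            clustered = (
                klass == "stable"
                and cluster_anchor is not None
                and rng.random() < config.fraction_clustered
            )
            if clustered:
                chrom, apos, strand = cluster_anchor
                pos = None
                offsets = rng.permutation(np.arange(1, config.cluster_window + 1))
                for off in offsets:
                    cand = apos + int(off)
                    if (
                        1 <= cand <= chrom_lengths[chrom]
                        and (chrom, cand) not in used
                        and (chrom, cand) not in cds_positions
                    ):
                        pos = cand
                        break
                if pos is None:
                    chrom, pos, strand = _draw_position(weights)
                else:
                    used.add((chrom, pos))
            else:
                chrom, pos, strand = _draw_position(weights)
            ref = substitution[0]
            _force_base(genome, chrom, pos, strand, ref)
            st = SiteTruth(
                site_key=f"{chrom}:{pos}:{strand}",
                chrom=chrom,
                pos=pos,
                strand=strand,
                substitution=substitution,
                klass=klass,
                base_level=_beta_level(**extra.get("level_bounds", {})),
            )
            placed.append(st)
            if klass == "stable":
                cluster_anchor = (chrom, pos, strand)
        return placed

    # recoding sites use existing As inside CDS; all other classes force the
    # reference base at a non-CDS position so codons stay intact
    recoding_sites = plant_recoding_sites(
        model, genome, config.n_recoding, config.recoding_minus_fraction, rng, used
    )
    tx_by_id = model.transcripts
    for st in recoding_sites:
        st.base_level = _beta_level()
        # reserve the whole codon so later base-forcing cannot change it
        positions = tx_by_id[st.transcript_id].spliced_cds_positions()
        offset = positions.index(st.pos)
        ci = offset // 3
        used.update((st.chrom, p) for p in positions[3 * ci : 3 * ci + 3])
    truth_sites.extend(recoding_sites)

    # expression-correlated sites live in 3'-UTRs of distinct coding genes
    corr_genes: list[Transcript] = []
    candidates = [tx for tx in coding_txs if not tx.gene_id.startswith("ADAR")]
    order = rng.permutation(len(candidates))
    corr_sites: list[SiteTruth] = []
    for j in range(config.n_correlated):
        tx = candidates[order[j % len(candidates)]]
        s, e = tx.three_prime_utr[0]
        pos = None
        for _ in range(1000):
            cand = int(rng.integers(s, e + 1))
            if (tx.chrom, cand) not in used:
                pos = cand
                break
        if pos is None:
            raise PlacementError(f"3'-UTR of {tx.transcript_id} exhausted")
        used.add((tx.chrom, pos))
        _force_base(genome, tx.chrom, pos, tx.strand, "A")
        corr_sites.append(
            SiteTruth(
                site_key=f"{tx.chrom}:{pos}:{tx.strand}",
                chrom=tx.chrom,
                pos=pos,
                strand=tx.strand,
                substitution="AG",
                klass="expression_correlated",
                rho=config.rho,
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
            )
        )
        corr_genes.append(tx)
    truth_sites.extend(corr_sites)

    diff_sites = _plant("differential", config.n_differential, level_bounds={"lo": config.level_floor, "hi": 0.6})
    for st in diff_sites:
        st.delta = config.delta
        st.direction = "higher" if rng.random() < 0.5 else "lower"
    truth_sites.extend(diff_sites)
    truth_sites.extend(_plant("hed_specific", config.n_hed_specific))
    truth_sites.extend(_plant("nd_specific", config.n_nd_specific))
    truth_sites.extend(_plant("stable", config.n_stable))
    truth_sites.extend(_plant("decoy_known_snp", config.n_snp_decoys))
    truth_sites.extend(_plant("decoy_individual_variant", config.n_variant_decoys))
    truth_sites.extend(_plant("decoy_low_sample", config.n_low_sample_decoys))
    full_edit = _plant("decoy_full_edit", config.n_full_edit_decoys)
    for st in full_edit:
        st.base_level = 1.0
    truth_sites.extend(full_edit)
    truth_sites.extend(_plant("decoy_non_ag", config.n_non_ag, substitution="CT"))
    # non-autosomal decoys: half on the sex chromosome, half unplaced
    non_auto = []
    for j in range(config.n_non_autosomal_decoys):
        chrom = config.sex_chrom[0] if j % 2 == 0 else config.unplaced_chrom[0]
        for _ in range(1000):
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            if (chrom, pos) not in used:
                break
        used.add((chrom, pos))
        _force_base(genome, chrom, pos, "+", "A")
        non_auto.append(
            SiteTruth(
                site_key=f"{chrom}:{pos}:+",
                chrom=chrom,
                pos=pos,
                strand="+",
                substitution="AG",
                klass="decoy_non_autosomal",
                base_level=_beta_level(),
            )
        )
    truth_sites.extend(non_auto)

    # -- per-site tissue sets ----------------------------------------------
    all_tissue_classes = {
        "differential", "recoding", "expression_correlated", "hed_specific", "nd_specific",
        "decoy_known_snp", "decoy_individual_variant", "decoy_full_edit", "decoy_non_autosomal",
    }
    for st in truth_sites:
        if st.klass in all_tissue_classes:
            st.tissues = list(config.tissues)
        elif st.klass == "decoy_low_sample":
            st.tissues = [config.tissues[int(rng.integers(len(config.tissues)))]]
        else:  # stable, decoy_non_ag
            mask = rng.random(len(config.tissues)) < config.tissue_presence_prob
            if not mask.any():
                mask[int(rng.integers(len(config.tissues)))] = True
            st.tissues = [t for t, m in zip(config.tissues, mask) if m]

    # -- expression counts -------------------------------------------------
    gene_ids = list(model.genes)
    gene_means = {
        gid: float(rng.lognormal(math.log(config.expression_mean), 0.5)) for gid in gene_ids
    }
    corr_gene_ids = {tx.gene_id for tx in corr_genes}
    n_samp = len(samples)
    counts = {}
    sample_factor: dict[str, np.ndarray] = {}
    for gid in gene_ids:
        mu = gene_means[gid]
        if gid in corr_gene_ids or (config.adar_coupling > 0 and gid.startswith("ADAR")):
            z = rng.normal(size=n_samp)
            sample_factor[gid] = z
            per_sample_mu = mu * np.exp(config.expression_log_sd * z - config.expression_log_sd**2 / 2)
            row = np.array([_nb(rng, float(m), config.expression_size, 1)[0] for m in per_sample_mu])
        else:
            row = _nb(rng, mu, config.expression_size, n_samp)
        counts[gid] = row
    gene_counts = pd.DataFrame(counts, index=sample_ids).T
    gene_lengths = pd.Series({gid: model.genes[gid].end - model.genes[gid].start + 1 for gid in gene_ids})
    tx_rows = {}
    tx_lengths = {}
    for gid in gene_ids:
        for tx in model.genes[gid].transcripts.values():
            tx_rows[tx.transcript_id] = counts[gid]
            tx_lengths[tx.transcript_id] = sum(e - s + 1 for s, e in tx.exons)
    tx_counts = pd.DataFrame(tx_rows, index=sample_ids).T
    tx_lengths = pd.Series(tx_lengths)

    # -- per-site, per-sample true levels ----------------------------------
    # standardized realized counts drive the correlated sites, so the
    # planted correlation survives expression noise
    level_matrix = np.zeros((len(truth_sites), n_samp))
    adar_z = None
    if config.adar_coupling > 0:
        arr = gene_counts.loc["ADAR"].to_numpy(dtype=float)
        adar_z = (arr - arr.mean()) / arr.std()
    tissue_of = np.array([s.tissue for s in samples])
    treat_of = np.array([s.treatment for s in samples])
    for i, st in enumerate(truth_sites):
        detect = np.isin(tissue_of, st.tissues)
        if st.klass == "hed_specific":
            detect &= treat_of == "HED"
        elif st.klass == "nd_specific":
            detect &= treat_of == "ND"
        elif st.klass == "decoy_low_sample":
            inds = rng.choice(individuals, size=2, replace=False)
            keep = np.array([s.individual_id in inds for s in samples])
            detect &= keep
        if st.klass == "decoy_full_edit":
            level = np.full(n_samp, 1.0)
        elif st.klass == "expression_correlated":
            cnt = gene_counts.loc[st.gene_id].to_numpy(dtype=float)
            z = (cnt - cnt.mean()) / cnt.std()
            eps = rng.normal(size=n_samp)
            # the planted rho is a target for the OBSERVED editing level;
            # binomial read sampling adds noise of roughly
            # sqrt(p(1-p)/coverage), so the latent mixing coefficient is
            # inflated to compensate
            center, slope = 0.5, 0.18
            sd_binom = math.sqrt(center * (1 - center) / config.rna_coverage_mean)
            rho_latent = math.copysign(
                min(1.0, abs(st.rho) * math.sqrt(1 + (sd_binom / slope) ** 2)), st.rho
            )
            mix = rho_latent * z + math.sqrt(max(0.0, 1 - rho_latent**2)) * eps
            level = np.clip(center + slope * mix, 0.12, 0.95)
        else:
            base = np.full(n_samp, st.base_level)
            if st.klass == "differential":
                bump = config.delta if st.direction == "higher" else 0.0
                alt = config.delta if st.direction == "lower" else 0.0
                base = np.where(treat_of == "HED", st.base_level + bump, st.base_level + alt)
            level = base + rng.normal(0.0, config.sample_level_sd, size=n_samp)
            if config.adar_coupling > 0 and st.klass == "stable" and adar_z is not None:
                level = level + config.adar_coupling * 0.12 * adar_z
            level = np.clip(level, 0.15, 0.98)
        level_matrix[i] = np.where(detect, level, np.nan)

    # -- RNA call tables ----------------------------------------------------
    cov_matrix = _coverage(
        rng, config.rna_coverage_floor, config.rna_coverage_mean, config.rna_coverage_size,
        len(truth_sites) * n_samp,
    ).reshape(len(truth_sites), n_samp)
    detected = ~np.isnan(level_matrix)
    edited = np.zeros_like(cov_matrix)
    edited[detected] = rng.binomial(cov_matrix[detected], level_matrix[detected])
    for i, st in enumerate(truth_sites):
        if st.klass == "decoy_full_edit":
            edited[i, detected[i]] = cov_matrix[i, detected[i]]

    site_order = sorted(range(len(truth_sites)), key=lambda i: (truth_sites[i].chrom, truth_sites[i].pos))
    rna_tables: dict[str, Path] = {}
    for j, meta in enumerate(samples):
        calls = []
        for i in site_order:
            if not detected[i, j] or edited[i, j] == 0:
                continue
            st = truth_sites[i]
            cov = int(cov_matrix[i, j])
            var = int(edited[i, j])
            countv = [0, 0, 0, 0]
            countv[_BASE_INDEX[st.substitution[0]]] = cov - var
            countv[_BASE_INDEX[st.substitution[1]]] = var
            calls.append(
                BaseCall(
                    chrom=st.chrom,
                    pos=st.pos,
                    strand=st.strand,
                    ref_base=st.substitution[0],
                    counts=tuple(countv),
                    coverage=cov,
                    substitution=st.substitution,
                    frequency=var / cov,
                    mean_quality=35.0,
                )
            )
        path = out / "rna" / f"{meta.sample_id}.rna.tsv"
        write_call_table(calls, path)
        rna_tables[meta.sample_id] = path

    # -- DNA call tables (one per individual, homozygous reference) ---------
    dna_tables: dict[str, Path] = {}
    for ind in individuals:
        covs = _coverage(
            rng, config.dna_coverage_floor, config.dna_coverage_mean, config.dna_coverage_size,
            len(truth_sites),
        )
        calls = []
        for rank, i in enumerate(site_order):
            st = truth_sites[i]
            ref_plus = str(genome[st.chrom][st.pos - 1])
            cov = int(covs[rank])
            countv = [0, 0, 0, 0]
            countv[_BASE_INDEX[ref_plus]] = cov
            calls.append(
                BaseCall(
                    chrom=st.chrom,
                    pos=st.pos,
                    strand="unknown",
                    ref_base=ref_plus,
                    counts=tuple(countv),
                    coverage=cov,
                    substitution="-",
                    frequency=0.0,
                    mean_quality=35.0,
                )
            )
        path = out / "dna" / f"{ind}.dna.tsv"
        write_call_table(calls, path)
        dna_tables[ind] = path

    # -- variant files -------------------------------------------------------
    def _plus_ref(st: SiteTruth) -> str:
        return str(genome[st.chrom][st.pos - 1])

    known = []
    for st in truth_sites:
        if st.klass == "decoy_known_snp":
            ref = _plus_ref(st)
            alt = "G" if ref != "G" else "C"
            known.append((st.chrom, st.pos, ref, alt))
    for _ in range(config.n_extra_known_snps):
        chrom = config.autosomes[int(rng.integers(len(config.autosomes)))]
        for _ in range(1000):
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            if (chrom, pos) not in used:
                break
        used.add((chrom, pos))
        ref = str(genome[chrom][pos - 1])
        alt = "A" if ref != "A" else "T"
        known.append((chrom, pos, ref, alt))
    known_path = out / "known_snps.vcf"
    write_vcf(known, known_path, contigs=chrom_lengths)

    per_individual: dict[str, list[tuple[str, int, str, str]]] = {ind: [] for ind in individuals}
    variant_decoys = [st for st in truth_sites if st.klass == "decoy_individual_variant"]
    for k, st in enumerate(variant_decoys):
        carriers = rng.choice(individuals, size=int(rng.integers(1, 4)), replace=False)
        ref = _plus_ref(st)
        alt = ("G" if ref != "G" else "C") if k % 2 == 0 else ref + "T"  # SNP / INDEL mix
        for ind in sorted(carriers):
            per_individual[ind].append((st.chrom, st.pos, ref, alt))
    individual_vcfs = {}
    for ind in individuals:
        path = out / "variants" / f"{ind}.vcf"
        write_vcf(per_individual[ind], path, contigs=chrom_lengths)
        individual_vcfs[ind] = path

    # -- remaining outputs ---------------------------------------------------
    genome_path = out / "genome.fa"
    write_fasta({c: "".join(a) for c, a in genome.items()}, genome_path)
    gtf_path = out / "annotation.gtf"
    write_gtf(model, gtf_path)
    gene_counts_path = out / "gene_counts.tsv"
    write_expression(gene_counts, gene_lengths, gene_counts_path, id_name="gene_id")
    tx_counts_path = out / "transcript_counts.tsv"
    write_expression(tx_counts, tx_lengths, tx_counts_path, id_name="transcript_id")
    meta_path = out / "metadata.tsv"
    write_metadata(samples, meta_path)

    truth = GroundTruth(
        sites=[truth_sites[i] for i in site_order],
        hed_individuals=hed,
        nd_individuals=nd,
        gene_expression_means=gene_means,
        adar_gene_ids=["ADAR", "ADARB1", "ADARB2"],
    )
    truth_path = out / "truth.json"
    truth.to_json(truth_path)

    return SimulatedStudy(
        out_dir=out,
        config=config,
        truth=truth,
        genome_fasta=genome_path,
        gtf=gtf_path,
        known_snps_vcf=known_path,
        individual_vcfs=individual_vcfs,
        rna_tables=rna_tables,
        dna_tables=dna_tables,
        gene_counts=gene_counts_path,
        transcript_counts=tx_counts_path,
        metadata=meta_path,
        truth_json=truth_path,
        samples=samples,
    )
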