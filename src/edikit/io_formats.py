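"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based and inclusive after parsing, matching both the
Ensembl GTF convention and the REDItools-style call tables that are the
pipeline's main input.  Strand codes are normalized at parse time
(0 -> "-", 1 -> "+", 2 -> "unknown"); chromosome names are matched by exact
string equality throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

log = logging.getLogger("edikit")

STRAND_CODES = {"0": "-", "1": "+", "2": "unknown"}
STRAND_TO_CODE = {v: k for k, v in STRAND_CODES.items()}

CALL_TABLE_COLUMNS = [
    "Region",
    "Position",
    "Reference",
    "Strand",
    "Coverage-q25",
    "MeanQ",
    "BaseCount[A,C,G,T]",
    "AllSubs",
    "Frequency",
]


class FormatError(ValueError):
    """Input file is not in the expected format."""


class CallTableParseError(FormatError):
    """A row of a call table could not be parsed."""


class ValidationError(ValueError):
    """Parsed values violate a documented invariant."""


# ---------------------------------------------------------------------------
# Core record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseCall:
    """Per-base evidence at one genomic position in one sample.

    ``ref_base`` and ``counts`` are reported on the annotated strand, so an
    A-to-I site on the minus strand still reads as reference A with edited
    reads counted under G.
    """

    chrom: str
    pos: int
    strand: str  # "+", "-", "unknown"
    ref_base: str
    counts: tuple[int, int, int, int]  # A, C, G, T on the reported strand
    coverage: int
    substitution: str  # e.g. "AG", or "-" for an invariant site
    frequency: float
    mean_quality: float = 30.0

    _BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

    def count(self, base: str) -> int:
        return self.counts[self._BASE_INDEX[base]]

    @property
    def variant_reads(self) -> int:
        """Reads supporting the substitution's alternate base (0 if invariant)."""
        if self.substitution == "-" or len(self.substitution) != 2:
            return 0
        return self.count(self.substitution[1])

    @property
    def non_variation_frequency(self) -> float:
        """Fraction of reads matching the reference base."""
        if self.coverage == 0:
            return 1.0
        return self.count(self.ref_base) / self.coverage

    def validate(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if min(self.counts) < 0:
            raise ValidationError(f"negative base count at {self.chrom}:{self.pos}")
        if self.coverage != sum(self.counts):
            raise ValidationError(
                f"coverage {self.coverage} != sum of base counts "
                f"{sum(self.counts)} at {self.chrom}:{self.pos}"
            )
        if self.substitution != "-":
            if self.coverage == 0:
                raise ValidationError(f"substitution with zero coverage at {self.chrom}:{self.pos}")
            expected = self.count(self.substitution[1]) / self.coverage
            if abs(self.frequency - expected) > 1e-9:
                raise ValidationError(
                    f"frequency {self.frequency} != {expected} at {self.chrom}:{self.pos}"
                )


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced library: which animal, which tissue, which diet arm."""

    sample_id: str
    individual_id: str
    tissue: str
    treatment: str  # "HED" or "ND"


TISSUES = ("Du", "Je", "Il", "Ce", "Co", "Re", "AA", "Li", "Te")
TREATMENTS = ("HED", "ND")


# ---------------------------------------------------------------------------
# Call tables (REDItools-style TSV)
# ---------------------------------------------------------------------------


def _parse_base_counts(token: str, lineno: int) -> tuple[int, int, int, int]:
    token = token.strip()
    if not (token.startswith("[") and token.endswith("]")):
        raise CallTableParseError(f"line {lineno}: malformed base-count list {token!r}")
    parts = token[1:-1].split(",")
    if len(parts) != 4:
        raise CallTableParseError(f"line {lineno}: expected 4 base counts, got {token!r}")
    try:
        return tuple(int(p) for p in parts)  # type: ignore[return-value]
    except ValueError as exc:
        raise CallTableParseError(f"line {lineno}: non-integer base count in {token!r}") from exc


def read_call_table(path: str | Path, kind: str = "RNA") -> list[BaseCall]:
    """Read a REDItools-style tab-separated call table.

    Parameters
    ----------
    path:
        TSV with header columns Region, Position, Reference, Strand,
        Coverage-q25, MeanQ, BaseCount[A,C,G,T], AllSubs, Frequency.
    kind:
        "RNA" or "DNA"; recorded for the caller, parsing is identical.
    """
    if kind not in ("RNA", "DNA"):
        raise ValueError(f"kind must be RNA or DNA, got {kind!r}")
    calls: list[BaseCall] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["Region", "Position"]:
            raise FormatError(f"{path}: not a call table (header {header[:2]})")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(CALL_TABLE_COLUMNS):
                raise CallTableParseError(
                    f"line {lineno}: expected {len(CALL_TABLE_COLUMNS)} fields, got {len(fields)}"
                )
            try:
                pos = int(fields[1])
                strand = STRAND_CODES[fields[3]]
                coverage = int(fields[4])
                meanq = float(fields[5])
                counts = _parse_base_counts(fields[6], lineno)
                frequency = float(fields[8])
            except CallTableParseError:
                raise
            except (KeyError, ValueError) as exc:
                raise CallTableParseError(f"line {lineno}: {exc}") from exc
            call = BaseCall(
                chrom=fields[0],
                pos=pos,
                strand=strand,
                ref_base=fields[2],
                counts=counts,
                coverage=coverage,
                substitution=fields[7],
                frequency=frequency,
                mean_quality=meanq,
            )
            try:
                call.validate()
            except ValidationError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
            calls.append(call)
    return calls


def write_call_table(calls: Iterable[BaseCall], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.pos),
                        c.ref_base,
                        STRAND_TO_CODE[c.strand],
                        str(c.coverage),
                        f"{c.mean_quality:.2f}",
                        "[" + ",".join(str(x) for x in c.counts) + "]",
                        c.substitution,
                        repr(c.frequency),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models (Ensembl GTF)
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    five_prime_utr: list[tuple[int, int]] = field(default_factory=list)
    three_prime_utr: list[tuple[int, int]] = field(default_factory=list)
    start_codon: list[tuple[int, int]] = field(default_factory=list)
    stop_codon: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        exons = sorted(self.exons)
        out = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def spliced_cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in translation order (strand-aware)."""
        if self.strand == "+":
            return [p for s, e in sorted(self.cds) for p in range(s, e + 1)]
        return [p for s, e in sorted(self.cds, reverse=True) for p in range(e, s - 1, -1)]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)


@dataclass
class GeneModel:
    """Hierarchical gene -> transcript -> feature model from a GTF."""

    genes: dict[str, Gene] = field(default_factory=dict)

    @property
    def transcripts(self) -> dict[str, Transcript]:
        return {t.transcript_id: t for g in self.genes.values() for t in g.transcripts.values()}

    def biotypes(self) -> set[str]:
        return {g.biotype for g in self.genes.values()}


_TX_FEATURES = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_utr": "five_prime_utr",
    "three_prime_utr": "three_prime_utr",
    "start_codon": "start_codon",
    "stop_codon": "stop_codon",
}


def read_gene_models(path: str | Path) -> GeneModel:
    """Parse an Ensembl-dialect GTF into a :class:`GeneModel` via gffutils.

    Introns are not read from the file; they are derived as the gaps between
    consecutive exons of each transcript.  A gene without a ``gene_biotype``
    attribute gets biotype "unknown" with a warning.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # noqa: BLE001 - gffutils raises assorted types
        raise FormatError(f"{path}: not a parseable GTF: {exc}") from exc

    model = GeneModel()
    for g in db.features_of_type("gene"):
        biotype_vals = g.attributes.get("gene_biotype")
        if not biotype_vals:
            warnings.warn(f"gene {g.attributes['gene_id'][0]} lacks gene_biotype; using 'unknown'")
            biotype = "unknown"
        else:
            biotype = biotype_vals[0]
        gene = Gene(g.attributes["gene_id"][0], g.seqid, g.strand, g.start, g.end, biotype)
        model.genes[gene.gene_id] = gene
        for t in db.children(g, featuretype="transcript"):
            tx = Transcript(t.attributes["transcript_id"][0], gene.gene_id, t.seqid, t.strand, t.start, t.end)
            gene.transcripts[tx.transcript_id] = tx
            for feature, attr_name in _TX_FEATURES.items():
                for f in db.children(t, featuretype=feature):
                    if feature == "exon" and not (tx.start <= f.start <= f.end <= tx.end):
                        raise ValidationError(
                            f"exon [{f.start}..{f.end}] outside transcript "
                            f"{tx.transcript_id} bounds [{tx.start}..{tx.end}]"
                        )
                    getattr(tx, attr_name).append((f.start, f.end))
            for attr_name in _TX_FEATURES.values():
                getattr(tx, attr_name).sort()
    return model


def write_gtf(model: GeneModel, path: str | Path) -> None:
    """Write a GeneModel back out as Ensembl-dialect GTF (gene/transcript/features)."""

    def attr(gene: Gene, tx: Transcript | None = None) -> str:
        parts = [f'gene_id "{gene.gene_id}"']
        if tx is not None:
            parts.append(f'transcript_id "{tx.transcript_id}"')
        parts.append(f'gene_biotype "{gene.biotype}"')
        return "; ".join(parts) + ";"

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#!genome-build synthetic\n")
        for gene in model.genes.values():
            fh.write(
                "\t".join(
                    [gene.chrom, "edikit", "gene", str(gene.start), str(gene.end), ".", gene.strand, ".", attr(gene)]
                )
                + "\n"
            )
            for tx in gene.transcripts.values():
                fh.write(
                    "\t".join(
                        [gene.chrom, "edikit", "transcript", str(tx.start), str(tx.end), ".", gene.strand, ".", attr(gene, tx)]
                    )
                    + "\n"
                )
                for feature, name in _TX_FEATURES.items():
                    for s, e in getattr(tx, name):
                        fh.write(
                            "\t".join(
                                [gene.chrom, "edikit", feature, str(s), str(e), ".", gene.strand, ".", attr(gene, tx)]
                            )
                            + "\n"
                        )


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------


def read_variants(path: str | Path) -> set[tuple[str, int, str]]:
    """Read a VCF into a set of (chrom, pos, type) with type in {SNP, INDEL}.

    Multi-allelic records expand to one entry per ALT.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF: {exc}") from exc
    out: set[tuple[str, int, str]] = set()
    with vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                vtype = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "INDEL"
                out.add((rec.chrom, rec.pos, vtype))
    return out


def write_vcf(records: Sequence[tuple[str, int, str, str]], path: str | Path, contigs: dict[str, int] | None = None) -> None:
    """Write (chrom, pos, ref, alt) records as a minimal VCF v4.2 file."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(records):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Expression matrices and metadata
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a read-count TSV (features x samples) with a ``length`` column.

    Returns (counts, lengths); counts columns are the sample ids in file order.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    if "length" not in df.columns:
        raise FormatError(f"{path}: missing 'length' column")
    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate feature id {dup.iloc[0]!r}")
    df = df.set_index(id_col)
    lengths = df.pop("length").astype(int)
    if (lengths <= 0).any():
        raise ValidationError(f"{path}: non-positive feature length")
    counts = df.astype(int)
    if (counts.values < 0).any():
        raise ValidationError(f"{path}: negative read count")
    return counts, lengths


def write_expression(counts: pd.DataFrame, lengths: pd.Series, path: str | Path, id_name: str = "feature_id") -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.loc[out.index].astype(int))
    out.index.name = id_name
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    metas = [
        SampleMeta(r.sample_id, r.individual_id, r.tissue, r.treatment) for r in df.itertuples(index=False)
    ]
    pairs = [(m.individual_id, m.tissue) for m in metas]
    if len(set(pairs)) != len(pairs):
        raise ValidationError(f"{path}: duplicate (individual, tissue) pair")
    for m in metas:
        if m.treatment not in TREATMENTS:
            raise ValidationError(f"{path}: unknown treatment {m.treatment!r}")
    return metas


def write_metadata(metas: Sequence[SampleMeta], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tindividual_id\ttissue\ttreatment\n")
        for m in metas:
            fh.write(f"{m.sample_id}\t{m.individual_id}\t{m.tissue}\t{m.treatment}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
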