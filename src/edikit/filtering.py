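"""Candidate editing-site selection and the four-step filtration cascade.

Candidate selection reproduces the comparative RNA/DNA thresholds
(RNA and DNA coverage >= 5, >= 5 reads supporting the RNA variant, DNA
non-variation frequency >= 0.95, single substitution only, DNA support
required).  Filtration then removes, in fixed order: (1) sites at known
variant positions, (2) sites at positions where any analyzed individual
carries a SNP or INDEL, (3) sites not detected in at least ``min_samples``
samples of at least one tissue, and (4) sites whose editing level is 100 %
in every detected sample.  Sites on non-autosomal or unplaced sequences and
sites with unknown strand are dropped up front with counts logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BaseCall, SampleMeta

log = logging.getLogger("edikit")


@dataclass(frozen=True)
class CandidateSite:
    """One per-sample candidate editing site with its editing level."""

    chrom: str
    pos: int
    strand: str
    substitution: str
    level: float

    @property
    def site_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


@dataclass
class EditingMatrix:
    """Sites x samples editing levels; NaN marks 'not detected'.

    ``levels`` is indexed by site_key with one column per sample;
    ``sites`` carries chrom/pos/strand/substitution per site_key;
    ``meta`` is indexed by sample_id with individual_id/tissue/treatment.
    """

    levels: pd.DataFrame
    sites: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.levels.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if present.any() and ((vals[present] < 0) | (vals[present] > 1)).any():
            raise ValueError("editing levels must lie in [0, 1]")

    @property
    def detection(self) -> pd.DataFrame:
        return self.levels.notna()

    @property
    def n_sites(self) -> int:
        return len(self.levels)

    @property
    def n_samples(self) -> int:
        return self.levels.shape[1]

    def samples_where(self, tissue: str | None = None, treatment: str | None = None) -> list[str]:
        m = self.meta
        if tissue is not None:
            m = m[m["tissue"] == tissue]
        if treatment is not None:
            m = m[m["treatment"] == treatment]
        return list(m.index)

    def subset_sites(self, site_keys: Sequence[str]) -> "EditingMatrix":
        keys = [k for k in self.levels.index if k in set(site_keys)]
        return EditingMatrix(self.levels.loc[keys], self.sites.loc[keys], self.meta)

    def write(self, path: str | Path) -> None:
        out = self.sites.copy()
        out = out.join(self.levels)
        out.index.name = "site_key"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read(cls, path: str | Path, meta: pd.DataFrame | Sequence[SampleMeta]) -> "EditingMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site_key", na_values=["NA"])
        site_cols = ["chrom", "pos", "strand", "substitution"]
        sites = df[site_cols].copy()
        sites["chrom"] = sites["chrom"].astype(str)
        levels = df.drop(columns=site_cols).astype(float)
        return cls(levels, sites, metadata_frame(meta))


def metadata_frame(meta: pd.DataFrame | Sequence[SampleMeta]) -> pd.DataFrame:
    if isinstance(meta, pd.DataFrame):
        return meta
    df = pd.DataFrame(
        [(m.sample_id, m.individual_id, m.tissue, m.treatment) for m in meta],
        columns=["sample_id", "individual_id", "tissue", "treatment"],
    )
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------


def select_candidates(
    rna: Iterable[BaseCall],
    dna: Iterable[BaseCall],
    min_rna_coverage: int = 5,
    min_dna_coverage: int = 5,
    min_variant_reads: int = 5,
    min_rna_frequency: float = 0.0,
    min_dna_nonvariation: float = 0.95,
) -> list[CandidateSite]:
    """Pair RNA calls with matched DNA evidence and apply the call thresholds.

    A site is kept iff the RNA row carries a single substitution with enough
    coverage and supporting reads, a DNA record exists at the position, and
    the DNA record is effectively invariant (non-variation frequency >=
    ``min_dna_nonvariation``).  The editing level is variant reads divided
    by RNA coverage.  Sites lacking a DNA record are counted, not errors.
    """
    dna_by_pos: dict[tuple[str, int], BaseCall] = {(d.chrom, d.pos): d for d in dna}
    kept: list[CandidateSite] = []
    n_no_dna = 0
    for r in rna:
        if min(r.counts) < 0:
            raise ValueError(f"negative counts at {r.chrom}:{r.pos}")
        if r.substitution == "-":
            continue  # invariant (non-strict input)
        if " " in r.substitution or len(r.substitution) != 2:
            continue  # multiple substitutions excluded
        d = dna_by_pos.get((r.chrom, r.pos))
        if d is None:
            n_no_dna += 1
            continue
        if r.coverage < min_rna_coverage or d.coverage < min_dna_coverage:
            continue
        if r.variant_reads < min_variant_reads:
            continue
        if r.frequency < min_rna_frequency:
            continue
        if d.non_variation_frequency < min_dna_nonvariation:
            continue
        kept.append(
            CandidateSite(
                chrom=r.chrom,
                pos=r.pos,
                strand=r.strand,
                substitution=r.substitution,
                level=r.variant_reads / r.coverage,
            )
        )
    if n_no_dna:
        log.info("select_candidates: %d RNA sites had no DNA record", n_no_dna)
    return kept


# ---------------------------------------------------------------------------
# Four-step filtration
# ---------------------------------------------------------------------------


def apply_filtration(
    candidates: Mapping[str, Sequence[CandidateSite]],
    known_variants: set[tuple[str, int, str]],
    individual_variants: Mapping[str, set[tuple[str, int, str]]],
    metadata: Sequence[SampleMeta] | pd.DataFrame,
    min_samples: int = 3,
    autosomes: Sequence[str] | None = None,
    per_individual: bool = False,
) -> EditingMatrix:
    """Run the filtration cascade and assemble the editing-level matrix.

    Parameters
    ----------
    candidates:
        sample_id -> per-sample candidate list from :func:`select_candidates`.
    known_variants, individual_variants:
        outputs of :func:`edikit.io_formats.read_variants`; individual
        variants are keyed by individual_id.
    min_samples:
        detection threshold of step 3, within at least one tissue.
    autosomes:
        chromosome whitelist; sites elsewhere are dropped before step 1.
        ``None`` keeps every chromosome.
    per_individual:
        if True, step 2 masks detections sample-wise for carrier individuals
        instead of removing the site globally.
    """
    meta = metadata_frame(metadata)
    for sample_id in candidates:
        if sample_id not in meta.index:
            raise ValueError(f"sample {sample_id!r} missing from metadata")

    # collect per-site detections: site_key -> {sample_id: level}
    detections: dict[str, dict[str, float]] = {}
    site_info: dict[str, CandidateSite] = {}
    n_unknown_strand = 0
    for sample_id, sites in candidates.items():
        for c in sites:
            if c.strand == "unknown":
                n_unknown_strand += 1
                continue
            detections.setdefault(c.site_key, {})[sample_id] = c.level
            site_info.setdefault(c.site_key, c)
    if n_unknown_strand:
        log.info("filter.unknown_strand.removed=%d", n_unknown_strand)

    def _drop(keys: set[str], label: str) -> None:
        for k in keys:
            detections.pop(k, None)
        log.info("filter.%s.removed=%d", label, len(keys))

    if autosomes is not None:
        allowed = set(autosomes)
        _drop({k for k, c in ((k, site_info[k]) for k in detections) if c.chrom not in allowed}, "non_autosomal")

    # step 1: known variant positions
    known_pos = {(chrom, pos) for chrom, pos, _t in known_variants}
    _drop({k for k in detections if (site_info[k].chrom, site_info[k].pos) in known_pos}, "step1")

    # step 2: individual genome variations (SNPs and INDELs)
    if per_individual:
        carrier_pos: dict[tuple[str, int], set[str]] = {}
        for ind, variants in individual_variants.items():
            for chrom, pos, _t in variants:
                carrier_pos.setdefault((chrom, pos), set()).add(ind)
        ind_of = meta["individual_id"].to_dict()
        n_masked = 0
        emptied = set()
        for k in list(detections):
            c = site_info[k]
            carriers = carrier_pos.get((c.chrom, c.pos))
            if not carriers:
                continue
            for sample_id in list(detections[k]):
                if ind_of[sample_id] in carriers:
                    del detections[k][sample_id]
                    n_masked += 1
            if not detections[k]:
                emptied.add(k)
        _drop(emptied, "step2")
        log.info("filter.step2.masked=%d", n_masked)
    else:
        variant_pos = {
            (chrom, pos) for variants in individual_variants.values() for chrom, pos, _t in variants
        }
        _drop({k for k in detections if (site_info[k].chrom, site_info[k].pos) in variant_pos}, "step2")

    # step 3: detected in >= min_samples samples within at least one tissue
    tissue_of = meta["tissue"].to_dict()
    failing = set()
    for k, det in detections.items():
        per_tissue: dict[str, int] = {}
        for sample_id in det:
            t = tissue_of[sample_id]
            per_tissue[t] = per_tissue.get(t, 0) + 1
        if not per_tissue or max(per_tissue.values()) < min_samples:
            failing.add(k)
    _drop(failing, "step3")

    # step 4: editing level exactly 1.0 in every detected sample
    _drop({k for k, det in detections.items() if det and all(v == 1.0 for v in det.values())}, "step4")

    # assemble matrix over surviving non-redundant sites
    keys = sorted(detections, key=lambda k: (site_info[k].chrom, site_info[k].pos, site_info[k].strand))
    sample_ids = list(meta.index)
    data = np.full((len(keys), len(sample_ids)), np.nan)
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, k in enumerate(keys):
        for sample_id, level in detections[k].items():
            data[i, col[sample_id]] = level
    levels = pd.DataFrame(data, index=pd.Index(keys, name="site_key"), columns=sample_ids)
    sites = pd.DataFrame(
        {
            "chrom": [site_info[k].chrom for k in keys],
            "pos": [site_info[k].pos for k in keys],
            "strand": [site_info[k].strand for k in keys],
            "substitution": [site_info[k].substitution for k in keys],
        },
        index=levels.index,
    )
    return EditingMatrix(levels, sites, meta)


def subset_atoi(matrix: EditingMatrix) -> EditingMatrix:
    """Retain sites whose substitution is AG on the annotated strand."""
    keys = matrix.sites.index[matrix.sites["substitution"] == "AG"]
    return EditingMatrix(matrix.levels.loc[keys], matrix.sites.loc[keys], matrix.meta)
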