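"""Editing-level / gene-expression correlation.

Expression is RPKM-normalized (reads per kilobase of feature per million
library reads; transcripts use total exon length).  Each site is paired
with the expression of every gene whose body contains it, and Pearson's r
is computed over the samples where the site is detected and expression is
available; missing editing values are excluded pairwise, never imputed.
|r| >= 0.5 counts as a strong correlation (inclusive).  The ADAR-family
genes (ADAR, ADARB1, ADARB2) — the enzymes that catalyze A-to-I editing —
can be paired against every site regardless of location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SiteAnnotation
from .enrichment import EnrichmentResult, set_background_enrichment
from .filtering import EditingMatrix

log = logging.getLogger("edikit")

STRONG_R = 0.5


@dataclass(frozen=True)
class CorrelationResult:
    site_key: str
    feature_id: str
    n_pairs: int
    r: float
    p_value: float
    significant: bool
    strong: bool  # |r| >= 0.5, inclusive
    positive: bool


def rpkm(
    counts: pd.DataFrame,
    feature_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """count / (length in kb) / (library size in millions).

    ``library_sizes`` defaults to the per-sample column sums of ``counts``.
    """
    lengths = feature_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


def _pearson(x: np.ndarray, y: np.ndarray, alpha: float) -> tuple[float, float] | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _correlate_pairs(
    matrix: EditingMatrix,
    expression: pd.DataFrame,
    pairs,  # iterable of (site_key, feature_id)
    min_pairs: int,
    alpha: float,
) -> list[CorrelationResult]:
    out: list[CorrelationResult] = []
    n_skipped = 0
    sample_cols = [c for c in matrix.levels.columns if c in expression.columns]
    expr = expression[sample_cols]
    levels = matrix.levels[sample_cols]
    for site_key, feature_id in pairs:
        if feature_id not in expr.index:
            continue
        lv = levels.loc[site_key].to_numpy(dtype=float)
        ev = expr.loc[feature_id].to_numpy(dtype=float)
        mask = ~np.isnan(lv) & ~np.isnan(ev)
        if mask.sum() < min_pairs:
            n_skipped += 1
            continue
        res = _pearson(lv[mask], ev[mask], alpha)
        if res is None:
            n_skipped += 1
            continue
        r, p = res
        out.append(
            CorrelationResult(
                site_key=site_key,
                feature_id=feature_id,
                n_pairs=int(mask.sum()),
                r=r,
                p_value=p,
                significant=p < alpha,
                strong=abs(r) >= STRONG_R,
                positive=r > 0,
            )
        )
    if n_skipped:
        log.info("correlation: skipped %d pairs (too few samples or zero variance)", n_skipped)
    return out


def correlate_site_expression(
    matrix: EditingMatrix,
    expression: pd.DataFrame,
    annotations: dict[str, SiteAnnotation],
    min_pairs: int = 5,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Pearson correlation of each site with its host genes' expression.

    Host genes are the genes whose body contains the site (from the
    annotation); ``expression`` is an RPKM matrix (features x samples).
    """
    pairs = []
    for site_key in matrix.levels.index:
        ann = annotations.get(site_key)
        if ann is None:
            continue
        for gid in ann.gene_ids:
            pairs.append((site_key, gid))
    return _correlate_pairs(matrix, expression, pairs, min_pairs, alpha)


def correlate_adar(
    matrix: EditingMatrix,
    expression: pd.DataFrame,
    adar_gene_ids: Sequence[str],
    min_pairs: int = 5,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate every site against each ADAR-family gene's expression."""
    pairs = []
    for gid in adar_gene_ids:
        if gid not in expression.index:
            log.warning("correlate_adar: %s missing from the expression matrix", gid)
            continue
        pairs.extend((site_key, gid) for site_key in matrix.levels.index)
    return _correlate_pairs(matrix, expression, pairs, min_pairs, alpha)


def summarize_correlations(results: Sequence[CorrelationResult], n_sites_total: int | None = None) -> dict:
    """Counts of significant / positive / strong correlations at site level."""
    sig_sites = {r.site_key for r in results if r.significant}
    pos_sites = {r.site_key for r in results if r.significant and r.positive}
    strong_sites = {r.site_key for r in results if r.significant and r.strong}
    out = {
        "n_pairs_tested": len(results),
        "n_sites_significant": len(sig_sites),
        "n_sites_positive": len(pos_sites),
        "n_sites_strong": len(strong_sites),
        "n_genes_significant": len({r.feature_id for r in results if r.significant}),
    }
    if n_sites_total:
        out["pct_sites_significant"] = 100.0 * len(sig_sites) / n_sites_total
    if sig_sites:
        out["pct_significant_positive"] = 100.0 * len(pos_sites) / len(sig_sites)
        out["pct_significant_strong"] = 100.0 * len(strong_sites) / len(sig_sites)
    return out


def correlated_site_enrichment(
    correlated_sites: set[str],
    all_sites: set[str],
    annotations: dict[str, SiteAnnotation],
    categories: Sequence[str] = ("exon", "intron", "five_prime_utr", "CDS", "three_prime_utr"),
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Feature-class enrichment of correlated sites over all A-to-I sites.

    Delegates to the nested-background set enrichment; an empty correlated
    set returns an empty result with a warning.
    """
    if not correlated_sites:
        log.warning("correlated_site_enrichment: empty correlated set")
        return []
    membership = {
        cat: {k for k in all_sites if annotations.get(k) and cat in annotations[k].classes}
        for cat in categories
    }
    return set_background_enrichment(correlated_sites, all_sites, membership, alpha=alpha)
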