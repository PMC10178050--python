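"""Fold-enrichment statistics for site sets.

Two backgrounds are supported: the merged length of each feature class
(are sites over-represented relative to the genomic footprint?) and a
site-set background (is a focal subset, e.g. expression-correlated sites,
differently distributed than all A-to-I sites?).  Length backgrounds use
the Chi-squared test by default (base pairs are pseudo-counts, which the
Fisher model takes too literally); set backgrounds use Fisher's exact
test.  The background of the set design is nested — it includes the
foreground — so the reported fold is a plain ratio of proportions.
P-values are two-sided and adjusted by Benjamini-Hochberg across the
category family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    category: str
    observed: int
    expected: float | None
    background_observed: int | None
    fold: float | None
    odds_ratio: float
    log2_odds_ratio: float
    p_value: float
    fdr: float | None = None
    test_used: str = "fisher"
    significant: bool = False
    corrected: bool = False  # Haldane-Anscombe +0.5 applied to a zero cell


def _odds_ratio(a: float, b: float, c: float, d: float) -> tuple[float, float, bool]:
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    odds = (a * d) / (b * c)
    return odds, math.log2(odds) if odds > 0 else float("-inf"), corrected


def _two_by_two_p(a: int, b: int, c: int, d: int, test: str) -> float:
    if test == "fisher":
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if test == "chi2":
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return 1.0
        return float(stats.chi2_contingency([[a, b], [c, d]], correction=True)[1])
    raise ValueError(f"unknown test {test!r}")


def adjust_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    ps = list(p_values)
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if not ps:
        return []
    return list(multipletests(ps, method="fdr_bh")[1])


def _finalize(results: list[EnrichmentResult], alpha: float) -> list[EnrichmentResult]:
    fdrs = adjust_fdr([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = q
        r.significant = q < alpha
    return results


def length_background_enrichment(
    site_counts: Mapping[str, int],
    lengths: Mapping[str, int],
    total_sites: int,
    total_length: int,
    test: str = "chi2",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-category 2x2 of [sites in/out] vs [bp in/out of the category].

    Expected count is ``total_sites * length_in / total_length``; the odds
    ratio is (sites_in * length_out) / (sites_out * length_in).
    """
    if total_length <= 0:
        raise ValueError("total length must be positive")
    results = []
    for cat in site_counts:
        a = int(site_counts[cat])
        b = total_sites - a
        c = int(lengths[cat])
        d = total_length - c
        if a < 0 or b < 0 or c < 0 or d < 0:
            raise ValueError(f"negative cell for category {cat!r}")
        odds, log2_odds, corrected = _odds_ratio(a, b, c, d)
        results.append(
            EnrichmentResult(
                category=cat,
                observed=a,
                expected=total_sites * c / total_length,
                background_observed=None,
                fold=(a / total_sites) / (c / total_length) if total_sites and c else None,
                odds_ratio=odds,
                log2_odds_ratio=log2_odds,
                p_value=_two_by_two_p(a, b, c, d, test),
                test_used=test,
                corrected=corrected,
            )
        )
    return _finalize(results, alpha)


def set_background_enrichment(
    foreground: set[str],
    background: set[str],
    category_membership: Mapping[str, set[str]] | Callable[[str], set[str]],
    test: str = "fisher",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-category 2x2 of foreground vs full (nested) background sites.

    ``category_membership`` maps category -> set of member site keys (or is
    a callable giving the categories of one site).  fold is the ratio of
    foreground to background proportions.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    if callable(category_membership):
        members: dict[str, set[str]] = {}
        for k in background:
            for cat in category_membership(k):
                members.setdefault(cat, set()).add(k)
    else:
        members = {c: set(m) for c, m in category_membership.items()}
    n_fg, n_bg = len(foreground), len(background)
    results = []
    for cat in sorted(members):
        fg_in = len(foreground & members[cat])
        bg_in = len(background & members[cat])
        a, b = fg_in, n_fg - fg_in
        c, d = bg_in, n_bg - bg_in
        odds, log2_odds, corrected = _odds_ratio(a, b, c, d)
        fold = (fg_in / n_fg) / (bg_in / n_bg) if n_fg and n_bg and bg_in else None
        results.append(
            EnrichmentResult(
                category=cat,
                observed=fg_in,
                expected=n_fg * bg_in / n_bg if n_bg else None,
                background_observed=bg_in,
                fold=fold,
                odds_ratio=odds,
                log2_odds_ratio=log2_odds,
                p_value=_two_by_two_p(a, b, c, d, test),
                test_used=test,
                corrected=corrected,
            )
        )
    return _finalize(results, alpha)
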