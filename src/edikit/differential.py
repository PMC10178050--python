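"""Diet-arm comparisons on the editing matrix.

Covers PCA of per-sample editing profiles (explained fraction reported as
the SD ratio: standard deviation of a component over the summed standard
deviations of all components), per-tissue pooled editing-level tests,
per-site two-sample Wilcoxon rank-sum tests, treatment-specific site
classification, and assembly of the "functional" site set (differential or
treatment-specific in at least one tissue).

"Wilcoxon" here is always the two-sample rank-sum (Mann-Whitney) test:
groups are different animals, and group sizes differ after detection
filtering, so a paired test is not applicable.  The exact null
distribution is used for tie-free data with both groups of size <= 10;
otherwise the normal approximation with tie correction and continuity
correction is used.  Note that with 3 vs 3 detected samples the smallest
attainable exact two-sided p is 0.1, so no 3v3 site can pass alpha = 0.05
on the exact path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_fdr
from .filtering import EditingMatrix


@dataclass
class DiffResult:
    site_key: str
    tissue: str
    n_hed: int
    n_nd: int
    p_value: float | None
    direction: str | None  # "higher"/"lower" in HED
    klass: str  # differential | HED-specific | ND-specific | not-significant | not-testable
    mean_hed: float | None = None
    mean_nd: float | None = None


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    sdev: np.ndarray
    explained_sd_ratio: np.ndarray  # sd_i / sum(sd)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        var = self.sdev**2
        return var / var.sum()


def wilcoxon_rank_sum(x, y, method: str = "auto") -> float:
    """Two-sided two-sample Wilcoxon rank-sum p-value.

    method "auto" takes the exact path for tie-free groups of size <= 10,
    else the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (tie_free and max(len(x), len(y)) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def run_pca(matrix: EditingMatrix, missing_fill: float = 0.0) -> PcaResult:
    """Centered (unscaled) PCA of samples over site editing levels.

    Missing levels are replaced by ``missing_fill`` before decomposition.
    Explained fractions use the SD-ratio convention, not the variance ratio.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.levels.T.fillna(missing_fill).to_numpy(dtype=float)  # samples x sites
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    sdev = S / np.sqrt(n - 1)
    scores = pd.DataFrame(
        U * S,
        index=matrix.levels.columns,
        columns=[f"PC{i + 1}" for i in range(len(S))],
    )
    total_sd = sdev.sum()
    explained = sdev / total_sd if total_sd > 0 else np.zeros_like(sdev)
    return PcaResult(scores=scores, sdev=sdev, explained_sd_ratio=explained)


def tissue_level_test(matrix: EditingMatrix, tissue: str, mode: str = "pooled") -> dict:
    """HED vs ND editing levels within one tissue.

    mode "pooled" compares all detected per-site levels of HED samples with
    those of ND samples; mode "sample_mean" compares per-sample means.
    """
    hed_cols = matrix.samples_where(tissue=tissue, treatment="HED")
    nd_cols = matrix.samples_where(tissue=tissue, treatment="ND")
    if not hed_cols or not nd_cols:
        raise ValueError(f"tissue {tissue!r} lacks one of the treatments")
    if mode == "pooled":
        hed_vals = matrix.levels[hed_cols].to_numpy().ravel()
        nd_vals = matrix.levels[nd_cols].to_numpy().ravel()
        hed_vals = hed_vals[~np.isnan(hed_vals)]
        nd_vals = nd_vals[~np.isnan(nd_vals)]
    elif mode == "sample_mean":
        hed_vals = matrix.levels[hed_cols].mean(axis=0, skipna=True).to_numpy()
        nd_vals = matrix.levels[nd_cols].mean(axis=0, skipna=True).to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(hed_vals) == 0 or len(nd_vals) == 0:
        return {"tissue": tissue, "p_value": None, "mean_hed": None, "mean_nd": None,
                "relative_change": None, "testable": False}
    p = wilcoxon_rank_sum(hed_vals, nd_vals, method="asymptotic")
    mean_hed = float(hed_vals.mean())
    mean_nd = float(nd_vals.mean())
    return {
        "tissue": tissue,
        "p_value": p,
        "mean_hed": mean_hed,
        "mean_nd": mean_nd,
        "relative_change": (mean_hed - mean_nd) / mean_nd if mean_nd else None,
        "testable": True,
    }


def per_site_test(
    matrix: EditingMatrix,
    tissue: str,
    min_per_group: int = 3,
    alpha: float = 0.05,
    method: str = "auto",
    fdr: bool = False,
) -> list[DiffResult]:
    """Per-site HED vs ND rank-sum tests within one tissue.

    Only sites detected in at least ``min_per_group`` samples of each
    treatment are tested; sites detected in the tissue but below the group
    minima are returned as not-testable.  Significance uses raw p-values by
    default; ``fdr=True`` adds a Benjamini-Hochberg adjustment.
    """
    hed_cols = matrix.samples_where(tissue=tissue, treatment="HED")
    nd_cols = matrix.samples_where(tissue=tissue, treatment="ND")
    results: list[DiffResult] = []
    tested_idx: list[int] = []
    hed_levels = matrix.levels[hed_cols]
    nd_levels = matrix.levels[nd_cols]
    for site_key, hrow, nrow in zip(matrix.levels.index, hed_levels.to_numpy(), nd_levels.to_numpy()):
        h = hrow[~np.isnan(hrow)]
        n = nrow[~np.isnan(nrow)]
        if len(h) == 0 and len(n) == 0:
            continue  # not detected in this tissue at all
        if len(h) < min_per_group or len(n) < min_per_group:
            results.append(DiffResult(site_key, tissue, len(h), len(n), None, None, "not-testable"))
            continue
        p = wilcoxon_rank_sum(h, n, method=method)
        mean_h, mean_n = float(h.mean()), float(n.mean())
        direction = "higher" if mean_h > mean_n else "lower"
        results.append(
            DiffResult(site_key, tissue, len(h), len(n), p, direction, "pending", mean_h, mean_n)
        )
        tested_idx.append(len(results) - 1)
    pvals = [results[i].p_value for i in tested_idx]
    adjusted = adjust_fdr(pvals) if fdr else pvals
    for i, q in zip(tested_idx, adjusted):
        results[i].klass = "differential" if q <= alpha and q is not None else "not-significant"
    return results


def classify_treatment_specific(
    matrix: EditingMatrix, tissue: str, min_samples: int = 3
) -> list[DiffResult]:
    """Sites detected in >= min_samples samples of one diet arm and zero of
    the other, within one tissue."""
    hed_cols = matrix.samples_where(tissue=tissue, treatment="HED")
    nd_cols = matrix.samples_where(tissue=tissue, treatment="ND")
    det = matrix.detection
    n_hed = det[hed_cols].sum(axis=1)
    n_nd = det[nd_cols].sum(axis=1)
    out = []
    for site_key in matrix.levels.index:
        h, n = int(n_hed[site_key]), int(n_nd[site_key])
        if h >= min_samples and n == 0:
            out.append(DiffResult(site_key, tissue, h, n, None, None, "HED-specific"))
        elif n >= min_samples and h == 0:
            out.append(DiffResult(site_key, tissue, h, n, None, None, "ND-specific"))
    return out


@dataclass
class FunctionalSites:
    """Per-tissue class counts plus the pooled non-redundant site set."""

    per_tissue: pd.DataFrame  # index tissue; columns Spe/Dif, HED, Higher, Lower, ND
    pooled: set[str]
    by_class: dict[str, set[str]]  # class -> pooled site keys


def assemble_functional_sites(
    diff_results: list[DiffResult], specific_results: list[DiffResult]
) -> FunctionalSites:
    """Combine differential and treatment-specific calls across tissues.

    The per-tissue table mirrors the class breakdown (HED-specific,
    higher/lower differential, ND-specific); the pooled set is the
    non-redundant union over tissues keyed by site.
    """
    rows: dict[str, dict[str, int]] = {}
    by_class: dict[str, set[str]] = {
        "HED-specific": set(), "ND-specific": set(), "higher": set(), "lower": set()
    }
    pooled: set[str] = set()

    def _row(tissue: str) -> dict[str, int]:
        return rows.setdefault(tissue, {"HED": 0, "Higher": 0, "Lower": 0, "ND": 0})

    for r in specific_results:
        if r.klass == "HED-specific":
            _row(r.tissue)["HED"] += 1
            by_class["HED-specific"].add(r.site_key)
            pooled.add(r.site_key)
        elif r.klass == "ND-specific":
            _row(r.tissue)["ND"] += 1
            by_class["ND-specific"].add(r.site_key)
            pooled.add(r.site_key)
    for r in diff_results:
        if r.klass != "differential":
            continue
        col = "Higher" if r.direction == "higher" else "Lower"
        _row(r.tissue)[col] += 1
        by_class[r.direction].add(r.site_key)
        pooled.add(r.site_key)

    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if table.empty:
        table = pd.DataFrame(columns=["Spe/Dif", "HED", "Higher", "Lower", "ND"]).astype(int)
    else:
        table.insert(0, "Spe/Dif", table[["HED", "Higher", "Lower", "ND"]].sum(axis=1))
    table.index.name = "tissue"
    return FunctionalSites(per_tissue=table, pooled=pooled, by_class=by_class)
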