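"""Study-level summaries: per-tissue counts and mean levels, tissue
overlap (UpSet-style) sets, inter-site distance distribution, and the
proportion arithmetic behind printed percentages.

Percentages and averages are rendered half-up to one decimal, keeping the
numerator and denominator alongside the rendered string.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
import pandas as pd

from .filtering import EditingMatrix


@dataclass(frozen=True)
class Proportion:
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return 100.0 * self.numerator / self.denominator

    def __str__(self) -> str:
        return f"{_half_up(self.value)}%"


def _half_up(x: float, places: int = 1) -> str:
    q = Decimal(1).scaleb(-places)
    return str(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion(numerator: int, denominator: int) -> Proportion:
    """Percentage as float plus a one-decimal half-up string rendering."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return Proportion(numerator, denominator)


def tissue_summary(matrix: EditingMatrix) -> pd.DataFrame:
    """Per-tissue detection counts and mean levels, split by treatment.

    Columns: mean detected sites per sample, mean editing level over all
    detected values, the same two per treatment, and non-redundant site
    counts per tissue and per (treatment, tissue) cell.
    """
    rows = {}
    det = matrix.detection
    for tissue in dict.fromkeys(matrix.meta["tissue"]):
        cols = matrix.samples_where(tissue=tissue)
        sub = matrix.levels[cols]
        row = {
            "mean_sites_per_sample": float(det[cols].sum(axis=0).mean()) if cols else 0.0,
            "mean_level": float(np.nanmean(sub.to_numpy())) if det[cols].to_numpy().any() else 0.0,
            "nonredundant_sites": int(det[cols].any(axis=1).sum()),
        }
        for treat in ("HED", "ND"):
            tcols = matrix.samples_where(tissue=tissue, treatment=treat)
            tsub = matrix.levels[tcols]
            any_det = det[tcols].to_numpy().any() if tcols else False
            row[f"mean_sites_per_sample_{treat}"] = (
                float(det[tcols].sum(axis=0).mean()) if tcols else 0.0
            )
            row[f"mean_level_{treat}"] = float(np.nanmean(tsub.to_numpy())) if any_det else 0.0
            row[f"nonredundant_sites_{treat}"] = int(det[tcols].any(axis=1).sum()) if tcols else 0
        rows[tissue] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tissue"
    return out


def treatment_tissue_table(matrix: EditingMatrix) -> pd.DataFrame:
    """Non-redundant site counts, treatments x tissues (Table-1 layout)."""
    summary = tissue_summary(matrix)
    return pd.DataFrame(
        {
            tissue: {
                "HED": summary.loc[tissue, "nonredundant_sites_HED"],
                "ND": summary.loc[tissue, "nonredundant_sites_ND"],
            }
            for tissue in summary.index
        }
    ).astype(int)


def overlap_sets(matrix: EditingMatrix, grouping: str = "tissue") -> dict:
    """UpSet-style membership cells over sample groups.

    A site belongs to a group if detected in >= 1 sample of the group.
    Returns per-group exclusive counts, the full-intersection count, and
    every non-empty exact-membership cell (2^k - 1 cells, k <= 10).
    """
    groups = list(dict.fromkeys(matrix.meta[grouping]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if len(groups) > 10:
        raise ValueError(f"{len(groups)} groups exceed the combinatorial guard (10)")
    det = matrix.detection
    membership: dict[str, frozenset[str]] = {}
    for site_key in matrix.levels.index:
        member = frozenset(
            g for g in groups if det.loc[site_key, matrix.samples_where(**{grouping: g})].any()
        )
        if member:
            membership[site_key] = member
    cells: dict[frozenset[str], int] = {}
    for member in membership.values():
        cells[member] = cells.get(member, 0) + 1
    exclusive = {g: cells.get(frozenset([g]), 0) for g in groups}
    full = cells.get(frozenset(groups), 0)
    per_group_total = {
        g: sum(n for m, n in cells.items() if g in m) for g in groups
    }
    return {
        "groups": groups,
        "cells": cells,
        "exclusive": exclusive,
        "full_intersection": full,
        "per_group_total": per_group_total,
        "union_size": len(membership),
    }


def distance_distribution(
    sites: pd.DataFrame, window: int = 20, bins=None
) -> dict:
    """Nearest-neighbour distances between sites, per chromosome.

    ``sites`` needs chrom and pos columns.  Chromosomes with a single site
    contribute nothing.  Returns the distances, a histogram, and the
    fraction of sites with a neighbour within ``window`` bp.
    """
    distances: list[int] = []
    for _chrom, grp in sites.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        pos = np.unique(pos)
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        nn = np.minimum(np.r_[gaps, np.inf], np.r_[np.inf, gaps])
        distances.extend(int(d) for d in nn if np.isfinite(d))
    arr = np.array(distances, dtype=float)
    if bins is None:
        bins = [0, 5, 10, 20, 50, 100, 1000, 10_000, np.inf]
    hist, edges = np.histogram(arr, bins=bins) if len(arr) else (np.zeros(len(bins) - 1, int), np.array(bins))
    return {
        "distances": arr,
        "histogram": hist,
        "bin_edges": edges,
        "fraction_within": float((arr <= window).mean()) if len(arr) else float("nan"),
        "window": window,
    }


def site_sample_frequency(matrix: EditingMatrix) -> pd.Series:
    """Count of samples detecting each site (circus-plot 'frequency')."""
    return matrix.detection.sum(axis=1)


class SummaryTable:
    """Named scalar statistics with one-decimal half-up renderings."""

    def __init__(self) -> None:
        self._entries: dict[str, dict] = {}

    def add_proportion(self, name: str, numerator: int, denominator: int) -> Proportion:
        p = proportion(numerator, denominator)
        self._entries[name] = {
            "value": p.value,
            "rendered": str(p),
            "numerator": numerator,
            "denominator": denominator,
        }
        return p

    def add_scalar(self, name: str, value: float, decimals: int = 1) -> None:
        self._entries[name] = {"value": float(value), "rendered": _half_up(float(value), decimals)}

    def __getitem__(self, name: str) -> dict:
        return self._entries[name]

    def to_dict(self) -> dict:
        return dict(self._entries)
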