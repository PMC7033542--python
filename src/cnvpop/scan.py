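"""Multi-allelic Fst selection scan on CNV segment genotypes.

For one segment, each individual carries a categorical copy-number class
(allele) in {A0, A1, A2, A3, A4, >A4}.  With class frequencies x_i, y_i in
groups X, Y of sizes N_x, N_y, the differentiation statistic is the
heterozygosity-based (Nei-style) Fst on size-weighted frequencies:

    t_i = (x_i * N_x + y_i * N_y) / (N_x + N_y)
    Ht  = 1 - sum_i t_i^2
    Hs  = [(1 - sum_i x_i^2) * N_x + (1 - sum_i y_i^2) * N_y] / (N_x + N_y)
    Fst = (Ht - Hs) / Ht

Ht >= Hs always (convexity of the square), so Fst lies in [0, 1] wherever
it is defined; a segment monomorphic across both groups has Ht = 0 and its
Fst is undefined.  The scan ranks segments by Fst, keeps the top quantile
(default 0.5%, ties at the threshold included), joins selected segments
that overlap or abut, and annotates genes overlapping the joined intervals
by >= 1 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CnvCall, GeneModel, chrom_sort_key
from .segmentation import (CN_CLASSES, GenotypeMatrix, build_genotype_matrix,
                           partition_all)

__all__ = [
    "AlleleFrequencies",
    "FstResult",
    "ScanConfig",
    "allele_frequencies",
    "fst_segment",
    "fst_scan",
    "select_top_quantile",
    "join_connected",
    "annotate_genes",
    "run_selection_scan",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class AlleleFrequencies:
    """Copy-number-class frequencies in one group at one segment.

    Classes absent from the group are omitted from ``freqs``; they
    contribute nothing to any sum.  ``n`` is the number of individuals.
    """

    freqs: Mapping[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        total = 0.0
        for cls, f in self.freqs.items():
            if cls not in CN_CLASSES:
                raise ValueError(f"unknown copy-number class {cls!r}")
            if not (-_FREQ_TOL <= f <= 1 + _FREQ_TOL):
                raise ValueError(f"frequency of {cls} out of [0,1]: {f}")
            total += f
        if abs(total - 1.0) > _FREQ_TOL:
            raise ValueError(f"frequencies sum to {total}, not 1")
        object.__setattr__(self, "freqs", dict(self.freqs))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "AlleleFrequencies":
        n = sum(counts.values())
        if n < 1:
            raise ValueError("empty count vector")
        return cls({c: k / n for c, k in counts.items() if k > 0}, n)

    def sum_sq(self) -> float:
        return sum(f * f for f in self.freqs.values())


@dataclass(frozen=True)
class FstResult:
    """Per-segment frequencies, weighted averages, Ht, Hs and Fst."""

    segment_id: Optional[str]
    x: AlleleFrequencies
    y: AlleleFrequencies
    t: dict[str, float]
    ht: float
    hs: float
    fst: float          # NaN when undefined
    defined: bool

    def __post_init__(self) -> None:
        if self.defined:
            if not (0 <= self.hs <= self.ht + 1e-12):
                raise ValueError("requires 0 <= Hs <= Ht when Ht > 0")
            if not (-1e-12 <= self.fst <= 1 + 1e-12):
                raise ValueError("Fst out of [0,1]")


def allele_frequencies(
    matrix: GenotypeMatrix, segment_id: str, group_ids: Sequence[str]
) -> AlleleFrequencies:
    """Class frequencies over one group's cells at one segment."""
    if not group_ids:
        raise ValueError("empty group")
    col = matrix.segment_column(segment_id)
    codes = matrix.rows_for(group_ids)[:, col]
    counts = np.bincount(codes, minlength=len(CN_CLASSES))
    return AlleleFrequencies.from_counts(
        {CN_CLASSES[i]: int(k) for i, k in enumerate(counts) if k > 0}
    )


def fst_segment(
    x: AlleleFrequencies, y: AlleleFrequencies, segment_id: Optional[str] = None
) -> FstResult:
    """Weighted multi-allelic Fst between two groups at one segment."""
    nx, ny = x.n, y.n
    wx, wy = nx / (nx + ny), ny / (nx + ny)
    classes = sorted(set(x.freqs) | set(y.freqs), key=CN_CLASSES.index)
    t = {c: wx * x.freqs.get(c, 0.0) + wy * y.freqs.get(c, 0.0) for c in classes}
    ht = 1.0 - sum(v * v for v in t.values())
    hs = wx * (1.0 - x.sum_sq()) + wy * (1.0 - y.sum_sq())
    defined = ht > 1e-12
    fst = (ht - hs) / ht if defined else math.nan
    return FstResult(segment_id, x, y, t, ht, hs, fst, defined)


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: top quantile and handling of monomorphic segments.

    ``monomorphic="exclude"`` drops Ht=0 segments from the ranked list
    (they cannot be differentiated); ``"zero"`` keeps them with Fst treated
    as 0, enlarging the denominator of the top-quantile rule.
    """

    q: float = 0.005
    monomorphic: str = "exclude"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("quantile q must be in (0, 1)")
        if self.monomorphic not in {"exclude", "zero"}:
            raise ValueError(f"unknown monomorphic policy {self.monomorphic!r}")


def fst_scan(
    matrix: GenotypeMatrix,
    group_x: Sequence[str],
    group_y: Sequence[str],
    config: Optional[ScanConfig] = None,
) -> pd.DataFrame:
    """Per-segment Fst between two disjoint groups, ordered by position.

    Returns one row per segment with columns segment_id, chrom, start, end,
    n_x, n_y, ht, hs, fst (NaN where undefined) and defined.  Samples in
    neither group are ignored.  The arithmetic is vectorised but follows
    the same equations as :func:`fst_segment`, which tests hold it to.
    """
    if not group_x or not group_y:
        raise ValueError("both groups must be non-empty")
    overlap = set(group_x) & set(group_y)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")

    cx = matrix.rows_for(group_x)
    cy = matrix.rows_for(group_y)
    nx, ny = len(group_x), len(group_y)
    n_classes = len(CN_CLASSES)
    # per-class counts: classes x segments
    kx = np.stack([(cx == c).sum(axis=0) for c in range(n_classes)])
    ky = np.stack([(cy == c).sum(axis=0) for c in range(n_classes)])
    fx, fy = kx / nx, ky / ny
    t = (fx * nx + fy * ny) / (nx + ny)
    ht = 1.0 - (t**2).sum(axis=0)
    hs = ((1.0 - (fx**2).sum(axis=0)) * nx + (1.0 - (fy**2).sum(axis=0)) * ny) / (nx + ny)
    defined = ht > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(defined, (ht - hs) / np.where(defined, ht, 1.0), np.nan)

    df = pd.DataFrame(
        {
            "segment_id": matrix.segment_ids,
            "chrom": [s.chrom for s in matrix.segments],
            "start": [s.start for s in matrix.segments],
            "end": [s.end for s in matrix.segments],
            "n_x": nx,
            "n_y": ny,
            "ht": ht,
            "hs": hs,
            "fst": fst,
            "defined": defined,
        }
    )
    order = sorted(range(len(df)), key=lambda i: (chrom_sort_key(df["chrom"][i]),
                                                  df["start"][i]))
    return df.iloc[order].reset_index(drop=True)


def select_top_quantile(
    table: pd.DataFrame, config: Optional[ScanConfig] = None
) -> tuple[float, pd.DataFrame]:
    """Select the top-q segments by Fst, ties at the threshold included.

    The ranked list holds the defined-Fst rows (plus, under the "zero"
    policy, monomorphic rows at Fst 0).  With N ranked rows, m = ceil(q*N)
    and the threshold is the m-th largest Fst; every row with Fst >= that
    threshold is selected, so ties can push the selection past m.
    """
    config = config or ScanConfig()
    if not table["defined"].any():
        raise ValueError("no segment has a defined Fst")
    if config.monomorphic == "exclude":
        ranked = table[table["defined"]].copy()
    else:
        ranked = table.copy()
        ranked["fst"] = ranked["fst"].fillna(0.0)
    m = math.ceil(config.q * len(ranked))
    threshold = float(np.sort(ranked["fst"].to_numpy())[::-1][m - 1])
    selected = ranked[ranked["fst"] >= threshold].copy()
    return threshold, selected


Interval = tuple[str, int, int]


def join_connected(intervals: Iterable[Union[Interval, Sequence]]) -> list[Interval]:
    """Union intervals on one chromosome that overlap or abut (end+1 = start).

    This is the adjacency-joining step applied to the selected segments;
    intervals separated by >= 1 uncovered bp stay separate.  Idempotent and
    order-invariant; returns (chrom, start, end) sorted by position.
    """
    items = sorted(
        ((c, int(s), int(e)) for c, s, e in intervals),
        key=lambda iv: (chrom_sort_key(iv[0]), iv[1], iv[2]),
    )
    joined: list[Interval] = []
    for chrom, start, end in items:
        if joined and joined[-1][0] == chrom and start <= joined[-1][2] + 1:
            prev = joined[-1]
            joined[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            joined.append((chrom, start, end))
    return joined


def annotate_genes(
    intervals: Sequence[Interval], genes: Sequence[GeneModel]
) -> dict[Interval, list[str]]:
    """Attach gene symbols overlapping each interval by >= 1 bp.

    Symbols are deduplicated and ordered by gene start (then symbol).
    Every input interval appears in the result, possibly with an empty list.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # 1-based inclusive -> half-open for the tree
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    out: dict[Interval, list[str]] = {}
    for chrom, start, end in intervals:
        hits = trees[chrom].overlap(start, end + 1) if chrom in trees else ()
        seen: dict[str, tuple[int, str]] = {}
        for hit in hits:
            g = hit.data
            key = (g.start, g.symbol)
            if g.symbol not in seen or key < seen[g.symbol]:
                seen[g.symbol] = key
        out[(chrom, start, end)] = [
            sym for sym, _ in sorted(seen.items(), key=lambda kv: kv[1])
        ]
    return out


@dataclass(frozen=True)
class ScanResults:
    """Everything one two-group comparison produces."""

    matrix: GenotypeMatrix
    table: pd.DataFrame
    threshold: float
    selected: pd.DataFrame
    joined: list[Interval]
    genes: Optional[dict[Interval, list[str]]]


def run_selection_scan(
    calls: Sequence[CnvCall],
    group_x: Sequence[str],
    group_y: Sequence[str],
    config: Optional[ScanConfig] = None,
    genes: Optional[Sequence[GeneModel]] = None,
) -> ScanResults:
    """Full comparison: joint re-segmentation of the two groups' calls,
    genotyping, per-segment Fst, top-quantile selection, adjacency joining
    and (optionally) gene annotation.

    Segmentation is re-run on the union of the two groups' calls so the
    segment boundaries reflect exactly the individuals being compared.
    """
    from .cnvr import merge_calls_to_cnvrs

    config = config or ScanConfig()
    members = set(group_x) | set(group_y)
    group_calls = [c for c in calls if c.sample_id in members]
    cnvrs = merge_calls_to_cnvrs(group_calls)
    segments = partition_all(cnvrs)
    matrix = build_genotype_matrix(list(group_x) + list(group_y), segments, group_calls)
    table = fst_scan(matrix, group_x, group_y, config)
    threshold, selected = select_top_quantile(table, config)
    joined = join_connected(selected[["chrom", "start", "end"]].itertuples(index=False))
    annotated = annotate_genes(joined, genes) if genes is not None else None
    return ScanResults(matrix, table, threshold, selected, joined, annotated)
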