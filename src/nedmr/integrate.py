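"""Integration of tumor-derived DMRs with cell-line ATAC peaks.

DMRs of varying width are standardized to fixed 500 bp consensus windows
centered on the DMR midpoint, overlap fractions between DMR windows and
ATAC peaks are computed in both directions, and module-level correlation
profiles summarize, per gene module, how peak-expression correlations
(cell lines) and DMR-expression correlations (tumors) distribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .modules import ModuleAssignment

__all__ = [
    "OverlapSummary",
    "consensus_windows",
    "overlap_fraction",
    "module_profile",
]


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_a_overlapped: int
    n_b_overlapped: int

    @property
    def frac_a(self) -> float:
        return np.nan if self.n_a == 0 else self.n_a_overlapped / self.n_a

    @property
    def frac_b(self) -> float:
        return np.nan if self.n_b == 0 else self.n_b_overlapped / self.n_b

    @property
    def pct_a(self) -> float:
        """Fraction of A overlapped, as a percent rounded to 1 d.p."""
        return np.nan if self.n_a == 0 else round(100.0 * self.frac_a, 1)

    @property
    def pct_b(self) -> float:
        return np.nan if self.n_b == 0 else round(100.0 * self.frac_b, 1)


def consensus_windows(
    intervals: pd.DataFrame, size: int = 500, chrom_sizes: dict | None = None
) -> pd.DataFrame:
    """Replace each interval by a fixed-size window on its midpoint.

    Window = [mid - size/2, mid + size/2) with mid = floor((start+end)/2),
    clamped to chromosome bounds (clamping may shorten, never re-center).
    Preserves all non-coordinate columns and the interval count.
    """
    if size <= 0 or size % 2:
        raise ValueError("size must be positive and even")
    half = size // 2
    out = intervals.copy()
    mid = (out["start"].astype(int) + out["end"].astype(int)) // 2
    start = mid - half
    end = mid + half
    start = start.clip(lower=0)
    if chrom_sizes is not None:
        limit = out["chrom"].map(chrom_sizes)
        end = np.minimum(end, limit)
    out["start"] = start
    out["end"] = end
    return out


def _trees(df: pd.DataFrame) -> dict:
    trees: dict[str, IntervalTree] = {}
    if df.empty:
        return trees
    for c, sub in df.groupby("chrom"):
        trees[c] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]) if e > s
        )
    return trees


def _count_overlapped(a: pd.DataFrame, b_trees: dict) -> int:
    n = 0
    for _, row in a.iterrows():
        t = b_trees.get(row["chrom"])
        if t is not None and t.overlaps(int(row["start"]), int(row["end"])):
            n += 1
    return n


def overlap_fraction(a: pd.DataFrame, b: pd.DataFrame) -> OverlapSummary:
    """Bidirectional >= 1 bp overlap counts between two interval sets.

    Intervals are half-open; sharing a single base counts, book-ended
    intervals do not.  Fractions are NaN when a side is empty.
    """
    bt = _trees(b)
    at = _trees(a)
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_a_overlapped=_count_overlapped(a, bt),
        n_b_overlapped=_count_overlapped(b, at),
    )


def module_profile(
    assignment: ModuleAssignment,
    peak_links: pd.DataFrame,
    dmr_links: pd.DataFrame,
    bins: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-module fraction of genes in each correlation bin, per data layer.

    Each gene is represented by its maximal-|r| link within a layer
    ("atac" from ``peak_links``; "methylation" from ``dmr_links``; both
    need gene_id and r columns).  ``bins`` must partition [-1, 1]; bin
    intervals are half-open [lo, hi) except the last, which includes 1.
    Genes of a module with no link in a layer are tallied as "unlinked".
    Bin fractions plus the unlinked fraction sum to 1 per module and layer.
    """
    if bins is None:
        bins = [(-1.0, -0.5), (-0.5, 0.0), (0.0, 0.5), (0.5, 1.0)]
    bins = sorted(bins)
    if bins[0][0] != -1.0 or bins[-1][1] != 1.0:
        raise ValueError("bins must span [-1, 1]")
    for (lo1, hi1), (lo2, hi2) in zip(bins, bins[1:]):
        if hi1 != lo2:
            raise ValueError("bins must partition [-1, 1] without gaps or overlap")

    def best_r(links: pd.DataFrame) -> pd.Series:
        sub = links.dropna(subset=["r"])
        if sub.empty:
            return pd.Series(dtype=float)
        idx = sub.groupby("gene_id")["r"].apply(lambda s: s.iloc[np.argmax(np.abs(s.to_numpy()))])
        return idx

    layers = {"atac": best_r(peak_links), "methylation": best_r(dmr_links)}
    rows = []
    for m in sorted(assignment.labels.unique()):
        genes = assignment.genes_in(m)
        n = len(genes)
        for layer, r_of in layers.items():
            hit = r_of.reindex(genes).dropna()
            row = {"module": m, "layer": layer, "n_genes": n,
                   "unlinked": (n - len(hit)) / n if n else np.nan}
            for lo, hi in bins:
                last = hi == 1.0
                inbin = ((hit >= lo) & ((hit < hi) | (last & (hit <= hi)))).sum()
                row[f"[{lo},{hi}{']' if last else ')'}"] = inbin / n if n else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
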