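"""Peak classification and peak-to-gene expression linking.

Differential ATAC peaks are classified as TSS-proximal (overlapping any
TSS +/- 1000 bp window), distal (midpoint more than 10 kb from every TSS),
or intermediate (excluded from both analyses).  Peaks are then linked to
candidate genes and the Pearson correlation between per-line accessibility
(replicates averaged on the normalized log2(x+1) scale) and per-line
expression decides the link: |r| > 0.7 for TSS links, r > 0.7 (positive
only) for distal links.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .linking import _pearson

__all__ = [
    "classify_peaks",
    "average_replicates",
    "link_and_correlate",
    "tss_gene_signature",
    "PeakGeneLinker",
]

TSS_FLANK = 1000
DISTAL_MIN = 10_000


def peak_midpoint(start: int, end: int) -> int:
    return (int(start) + int(end)) // 2


def classify_peaks(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Class per peak: "tss", "distal" or "intermediate".

    TSS iff the peak interval overlaps any [TSS-1000, TSS+1001) window
    (inclusive +/-1000 bp bound realized half-open).  Distal iff the peak
    midpoint is more than 10,000 bp from the nearest TSS.
    """
    out = pd.Series("intermediate", index=peaks.index, name="peak_class", dtype=object)
    by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")}
    for i, pk in peaks.iterrows():
        tss = by_chrom.get(pk["chrom"])
        if tss is None or tss.size == 0:
            out.at[i] = "distal"  # no TSS on the chromosome: infinitely distal
            continue
        s, e = int(pk["start"]), int(pk["end"])
        # overlap test vs [t-1000, t+1001)
        j = np.searchsorted(tss, s - TSS_FLANK)
        hit = False
        while j < tss.size and tss[j] - TSS_FLANK < e:
            if s < tss[j] + TSS_FLANK + 1:
                hit = True
                break
            j += 1
        if hit:
            out.at[i] = "tss"
            continue
        mid = peak_midpoint(s, e)
        k = np.searchsorted(tss, mid)
        d = min(
            abs(mid - tss[k - 1]) if k > 0 else np.inf,
            abs(tss[k] - mid) if k < tss.size else np.inf,
        )
        if d > DISTAL_MIN:
            out.at[i] = "distal"
    return out


def average_replicates(norm_counts: pd.DataFrame, line_of: pd.Series) -> pd.DataFrame:
    """Per-line mean of log2(normalized count + 1) over replicates."""
    logc = np.log2(norm_counts + 1.0)
    lines = line_of.reindex(norm_counts.columns)
    return logc.T.groupby(lines).mean().T


def link_and_correlate(
    peaks: pd.DataFrame,
    peak_classes: pd.Series,
    norm_counts: pd.DataFrame,
    line_of: pd.Series,
    expression: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 1_000_000,
    r_cutoff: float = 0.7,
    distal_absolute: bool = False,
) -> pd.DataFrame:
    """Peak-gene links with per-class correlation rules.

    TSS peaks link to genes whose TSS +/- 1000 bp window overlaps the peak;
    distal peaks link to genes with |TSS - peak midpoint| <= window.
    ``expression`` is genes x cell lines.  Returns a table with peak_id,
    gene_id, r, window class and pass flag.
    """
    per_line = average_replicates(norm_counts, line_of)
    shared = per_line.columns.intersection(expression.columns)
    if len(shared) < 4:
        raise ValueError("need >= 4 cell lines with both ATAC and expression data")
    A = per_line[shared]
    E = expression[shared]

    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    recs = []
    for i, pk in peaks.iterrows():
        cls = peak_classes.loc[i]
        if cls == "intermediate":
            continue
        g = by_chrom.get(pk["chrom"])
        if g is None:
            continue
        s, e = int(pk["start"]), int(pk["end"])
        if cls == "tss":
            tss = g["tss"].to_numpy()
            cand = g.loc[(tss - TSS_FLANK < e) & (s < tss + TSS_FLANK + 1), "gene_id"]
            wclass = "tss"
        else:
            mid = peak_midpoint(s, e)
            cand = g.loc[np.abs(g["tss"].to_numpy() - mid) <= window, "gene_id"]
            wclass = f"distal-{window}"
        sig = A.loc[pk["peak_id"]].to_numpy(dtype=float)
        for gid in cand:
            if gid not in E.index:
                continue
            r = _pearson(sig, E.loc[gid].to_numpy(dtype=float))
            if cls == "tss" or distal_absolute:
                ok = np.isfinite(r) and abs(r) > r_cutoff
            else:
                ok = np.isfinite(r) and r > r_cutoff
            recs.append(
                {
                    "peak_id": pk["peak_id"],
                    "gene_id": gid,
                    "r": r,
                    "window_class": wclass,
                    "pass": bool(ok),
                }
            )
    return pd.DataFrame(recs, columns=["peak_id", "gene_id", "r", "window_class", "pass"])


def tss_gene_signature(links: pd.DataFrame) -> list:
    """Unique genes of passing TSS links, for downstream clustering/scoring."""
    if links.empty:
        return []
    sub = links[(links["window_class"] == "tss") & links["pass"]]
    return sorted(sub["gene_id"].unique())


class PeakGeneLinker(BaseEstimator):
    """Classify differential peaks and link them to genes by correlation.

    Parameters
    ----------
    window : int
        Distal candidate window (|TSS - midpoint| bound) in bp.
    r_cutoff : float
        Correlation cutoff (0.7).
    distal_absolute : bool
        Apply |r| rather than positive-only r to distal links.

    Attributes (after ``fit``)
    --------------------------
    classes_ : per-peak class
    links_ : link table
    tss_genes_ : unique genes with passing TSS links
    """

    def __init__(self, window: int = 1_000_000, r_cutoff: float = 0.7,
                 distal_absolute: bool = False):
        self.window = window
        self.r_cutoff = r_cutoff
        self.distal_absolute = distal_absolute

    def fit(
        self,
        peaks: pd.DataFrame,
        norm_counts: pd.DataFrame,
        line_of: pd.Series,
        expression: pd.DataFrame,
        genes: pd.DataFrame,
    ):
        peaks = peaks.reset_index(drop=True)
        self.classes_ = classify_peaks(peaks, genes)
        self.links_ = link_and_correlate(
            peaks,
            self.classes_,
            norm_counts,
            line_of,
            expression,
            genes,
            window=self.window,
            r_cutoff=self.r_cutoff,
            distal_absolute=self.distal_absolute,
        )
        self.tss_genes_ = tss_gene_signature(self.links_)
        return self
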