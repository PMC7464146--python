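"""Linking DMRs to gene expression (eQTM-style).

Each DMR is paired with every gene whose TSS lies within a window (default
+/-500 kb) of the DMR midpoint; the Pearson correlation between DMR summary
methylation and gene expression is computed over pairwise-complete samples;
and links are called significant against an empirical 98th-percentile |r|
cutoff.  A Bonferroni-equivalent r threshold is reported for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .dmr import dmr_midpoint

__all__ = [
    "CutoffResult",
    "LinkCounts",
    "link_dmr_genes",
    "correlate_links",
    "empirical_cutoff",
    "bonferroni_r_threshold",
    "classify_links",
    "DMRGeneLinker",
]


@dataclass
class CutoffResult:
    percentile: float
    threshold: float          # empirical |r| cutoff
    bonferroni_r: float | None = None  # analytic reference threshold


@dataclass
class LinkCounts:
    positive: int
    negative: int
    unique_dmrs: int
    unique_genes: int

    @property
    def total(self) -> int:
        return self.positive + self.negative


def link_dmr_genes(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 500_000,
) -> tuple[pd.DataFrame, list]:
    """All (DMR, gene) pairs with |TSS - DMR midpoint| <= window (inclusive).

    Returns the candidate-pair table (dmr_id, gene_id, distance) and the
    list of DMR ids with no candidate gene.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pairs = []
    unlinked = []
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for _, d in dmrs.iterrows():
        mid = dmr_midpoint(d["start"], d["end"])
        g = by_chrom.get(d["chrom"])
        if g is None:
            unlinked.append(d["dmr_id"])
            continue
        dist = np.abs(g["tss"].to_numpy() - mid)
        hit = dist <= window
        if not hit.any():
            unlinked.append(d["dmr_id"])
            continue
        for gid, dd in zip(g.loc[hit, "gene_id"], dist[hit]):
            pairs.append({"dmr_id": d["dmr_id"], "gene_id": gid, "distance": int(dd)})
    return pd.DataFrame(pairs, columns=["dmr_id", "gene_id", "distance"]), unlinked


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def correlate_links(
    pairs: pd.DataFrame,
    dmr_beta: pd.DataFrame,
    expression: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson r for every candidate pair over pairwise-complete samples.

    Pairs with fewer than ``min_n`` complete samples or a zero-variance
    vector are flagged (``r`` NaN, ``dropped`` True) and excluded from the
    cutoff computation downstream.
    """
    shared = dmr_beta.columns.intersection(expression.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between methylation and expression")
    B = dmr_beta[shared]
    E = expression[shared]
    recs = []
    for _, p in pairs.iterrows():
        x = B.loc[p["dmr_id"]].to_numpy(dtype=float)
        y = E.loc[p["gene_id"]].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        r = _pearson(x[ok], y[ok]) if n >= min_n else np.nan
        recs.append(
            {
                "dmr_id": p["dmr_id"],
                "gene_id": p["gene_id"],
                "r": r,
                "n": n,
                "dropped": not np.isfinite(r),
            }
        )
    return pd.DataFrame(recs)


def empirical_cutoff(links: pd.DataFrame, percentile: float = 98.0) -> CutoffResult:
    """|r| threshold at the given percentile (type-7 / linear quantile).

    A link is significant iff |r| strictly exceeds the threshold.
    """
    r = links.loc[~links["dropped"].astype(bool), "r"].to_numpy(dtype=float)
    if r.size < 50:
        raise ValueError("need >= 50 correlation records for an empirical cutoff")
    thr = float(np.quantile(np.abs(r), percentile / 100.0))  # linear = type 7
    return CutoffResult(percentile=percentile, threshold=thr)


def bonferroni_r_threshold(n_samples: int, n_tests: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant after Bonferroni correction.

    Uses the t-transform of the Pearson test, t = r*sqrt(n-2)/sqrt(1-r^2)
    with df = n-2, and solves two-sided p = alpha/n_tests by root-finding
    to |dr| < 1e-6.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if n_samples < 4 or n_tests < 1:
        raise ValueError("need n_samples >= 4 and n_tests >= 1")
    target = alpha / n_tests
    if target >= 1.0:
        return 0.0
    df = n_samples - 2

    def f(r):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        return 2.0 * stats.t.sf(t, df) - target

    return float(optimize.brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-7))


def classify_links(links: pd.DataFrame, threshold: float) -> LinkCounts:
    """Counts of significant positive/negative links and unique DMRs/genes."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    r = links["r"].to_numpy(dtype=float)
    sig = np.isfinite(r) & (np.abs(r) > threshold)
    sub = links.loc[sig]
    return LinkCounts(
        positive=int((sub["r"] > 0).sum()),
        negative=int((sub["r"] < 0).sum()),
        unique_dmrs=int(sub["dmr_id"].nunique()),
        unique_genes=int(sub["gene_id"].nunique()),
    )


class DMRGeneLinker(BaseEstimator):
    """DMR-to-gene correlation linker.

    Parameters
    ----------
    window : int
        TSS-to-midpoint distance bound in bp (inclusive).
    percentile : float
        Percentile of the |r| distribution used as significance cutoff.
    min_n : int
        Minimum pairwise-complete sample count for a correlation.
    alpha : float
        Level for the Bonferroni-equivalent reference threshold.

    Attributes (after ``fit``)
    --------------------------
    candidates_ : candidate (DMR, gene) pair table
    unlinked_dmrs_ : DMR ids with no candidate gene
    links_ : LinkRecord table with r, n, significant flag and sign
    cutoff_ : CutoffResult
    counts_ : LinkCounts over significant links
    """

    def __init__(self, window: int = 500_000, percentile: float = 98.0,
                 min_n: int = 3, alpha: float = 0.05):
        self.window = window
        self.percentile = percentile
        self.min_n = min_n
        self.alpha = alpha

    def fit(self, dmrs: pd.DataFrame, genes: pd.DataFrame,
            dmr_beta: pd.DataFrame, expression: pd.DataFrame):
        self.candidates_, self.unlinked_dmrs_ = link_dmr_genes(
            dmrs, genes, window=self.window
        )
        # only candidates whose gene has expression data
        cand = self.candidates_[
            self.candidates_["gene_id"].isin(expression.index)
        ].reset_index(drop=True)
        links = correlate_links(cand, dmr_beta, expression, min_n=self.min_n)
        self.cutoff_ = empirical_cutoff(links, percentile=self.percentile)
        n_shared = len(dmr_beta.columns.intersection(expression.columns))
        self.cutoff_.bonferroni_r = bonferroni_r_threshold(
            n_shared, max(1, len(links)), alpha=self.alpha
        )
        r = links["r"].to_numpy(dtype=float)
        links["significant"] = np.isfinite(r) & (np.abs(r) > self.cutoff_.threshold)
        links["sign"] = np.where(r > 0, "+", "-")
        self.links_ = links
        self.counts_ = classify_links(links, self.cutoff_.threshold)
        return self
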