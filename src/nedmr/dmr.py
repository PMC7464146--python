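"""Differentially methylated region (DMR) discovery.

Workflow: filter probes (missingness and zero within-group variance), test
each probe for NE vs normal-lung and NE vs non-NE with a Mann-Whitney U
test, select probes passing Bonferroni-adjusted p < alpha and an absolute
median-methylation difference > delta in BOTH comparisons, assign each
selected probe a 101 bp window and merge overlapping windows into DMRs, and
annotate DMRs against gene models and CpG islands.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .simulate import GenomeAnnotation

__all__ = [
    "FilterReport",
    "MergeReport",
    "filter_probes",
    "mann_whitney",
    "probe_tests",
    "select_significant_probes",
    "build_dmrs",
    "annotate_dmrs",
    "DMRCaller",
]

EXACT_MAX_N = 12  # pooled size at or below which the exact null is enumerated


# ---------------------------------------------------------------------------
# reports


@dataclass
class FilterReport:
    """Accounting of probe removal; ``n_remaining`` is the count identity."""

    n_input: int
    n_removed_missing: int
    n_removed_zero_sd: int

    @property
    def n_removed(self) -> int:
        return self.n_removed_missing + self.n_removed_zero_sd

    @property
    def n_remaining(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class MergeReport:
    """Accounting of window merging.

    ``n_dmrs`` follows the identity: probes not in any multi-probe region
    each form their own DMR, plus one DMR per multi-probe region.
    """

    n_probes: int
    n_probes_in_multi: int
    n_multi_regions: int

    @property
    def n_singletons(self) -> int:
        return self.n_probes - self.n_probes_in_multi

    @property
    def n_dmrs(self) -> int:
        return self.n_singletons + self.n_multi_regions


# ---------------------------------------------------------------------------
# probe filtering


def filter_probes(
    beta: pd.DataFrame,
    groups: pd.Series,
    max_missing: float = 0.05,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove probes with excess missingness or zero within-group variance.

    A probe is removed if its fraction of missing values exceeds
    ``max_missing`` within ANY of the three groups, or (of the survivors)
    if its standard deviation within any group is zero.
    """
    if beta.empty:
        raise ValueError("empty beta matrix")
    present = set(groups.unique())
    missing_groups = {"NE", "nonNE", "normal"} - present
    if missing_groups:
        raise ValueError(f"missing sample groups: {sorted(missing_groups)}")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per group")

    bad_missing = np.zeros(len(beta), dtype=bool)
    for g in ("NE", "nonNE", "normal"):
        sub = beta.loc[:, (groups == g).to_numpy()]
        frac = sub.isna().mean(axis=1).to_numpy()
        bad_missing |= frac > max_missing

    survivors = beta.loc[~bad_missing]
    bad_sd = np.zeros(len(survivors), dtype=bool)
    for g in ("NE", "nonNE", "normal"):
        sub = survivors.loc[:, (groups == g).to_numpy()]
        sd = sub.std(axis=1, ddof=0).to_numpy()  # NaN-aware pandas std
        bad_sd |= ~(sd > 0)

    out = survivors.loc[~bad_sd]
    report = FilterReport(
        n_input=len(beta),
        n_removed_missing=int(bad_missing.sum()),
        n_removed_zero_sd=int(bad_sd.sum()),
    )
    return out, report


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_mw_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all labelings of the pooled values.

    Tie-aware: U is computed from midranks of the pooled sample, so the
    enumeration is the exact permutation null of the observed values.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    n = len(pooled)
    mu = nx * (n - nx) / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    offset = nx * (nx + 1) / 2.0
    for idx in itertools.combinations(range(n), nx):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (statistic of the first sample) and two-sided p.

    Missing values are dropped per group.  When the pooled non-missing size
    is at most 12 the exact, tie-aware permutation null is enumerated;
    otherwise the tie-corrected normal approximation (with continuity
    correction) is used.  p is capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a group has no non-missing values")
    u = float(stats.rankdata(np.concatenate([x, y]))[: len(x)].sum() - len(x) * (len(x) + 1) / 2)
    if len(x) + len(y) <= EXACT_MAX_N:
        p = _exact_mw_p(x, y, u)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u, min(p, 1.0)


def _mw_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected asymptotic MW over probes (rows), NaN-free."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=1)
    return np.asarray(res.statistic, dtype=float), np.minimum(np.asarray(res.pvalue), 1.0)


def probe_tests(
    beta: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-probe tests for both comparisons (NE vs normal, NE vs nonNE).

    Returns a DataFrame indexed by probe id with columns
    ``u_normal, p_normal, dmed_normal, u_nonne, p_nonne, dmed_nonne``.
    Median differences are NE median minus the other group's median over
    each group's non-missing values.  Probes with missing values (or pooled
    n <= 12) take the scalar path; complete rows are vectorized.
    """
    ne = beta.loc[:, (groups == "NE").to_numpy()].to_numpy()
    nn = beta.loc[:, (groups == "nonNE").to_numpy()].to_numpy()
    nm = beta.loc[:, (groups == "normal").to_numpy()].to_numpy()

    out = pd.DataFrame(index=beta.index, dtype=float)
    for tag, other in (("normal", nm), ("nonne", nn)):
        n_tot = ne.shape[1] + other.shape[1]
        complete = ~np.isnan(ne).any(axis=1) & ~np.isnan(other).any(axis=1)
        u = np.full(len(beta), np.nan)
        p = np.full(len(beta), np.nan)
        if n_tot > EXACT_MAX_N and complete.any():
            u[complete], p[complete] = _mw_matrix(ne[complete], other[complete])
            rest = np.where(~complete)[0]
        else:
            rest = np.arange(len(beta))
        for i in rest:
            u[i], p[i] = mann_whitney(ne[i], other[i])
        dmed = np.nanmedian(ne, axis=1) - np.nanmedian(other, axis=1)
        out[f"u_{tag}"] = u
        out[f"p_{tag}"] = p
        out[f"dmed_{tag}"] = dmed
    return out


def select_significant_probes(
    tests: pd.DataFrame,
    m: int,
    alpha: float = 0.01,
    delta: float = 0.1,
) -> pd.DataFrame:
    """Bonferroni-and-effect-size probe selection.

    A probe passes iff min(1, p*m) < ``alpha`` AND |median difference| >
    ``delta`` in BOTH comparisons.  ``m`` is the number of probes tested
    after filtering; the same correction applies to both comparisons.
    Returns the tests table with adjusted-p and ``pass`` columns added.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    res = tests.copy()
    ok = np.ones(len(res), dtype=bool)
    for tag in ("normal", "nonne"):
        adj = np.minimum(1.0, res[f"p_{tag}"].to_numpy() * m)
        res[f"padj_{tag}"] = adj
        ok &= (adj < alpha) & (np.abs(res[f"dmed_{tag}"].to_numpy()) > delta)
    res["pass"] = ok
    return res


# ---------------------------------------------------------------------------
# DMR construction


def probe_window(pos: int, width: int = 101) -> tuple[int, int]:
    """Half-open window of ``width`` bp centered on a probe position."""
    half = width // 2
    return pos - half, pos - half + width


def build_dmrs(
    probes: pd.DataFrame,
    beta: pd.DataFrame | None = None,
    window: int = 101,
) -> tuple[pd.DataFrame, pd.DataFrame | None, MergeReport]:
    """Merge per-probe windows into DMRs and summarize member betas.

    ``probes`` needs columns probe_id/chrom/pos (selected probes only).
    Windows sharing at least one base on the same chromosome are merged
    transitively; merely book-ended windows are not merged.  The DMR
    interval is the union of member windows.  The per-sample summary is
    the median over member-probe betas, ignoring missing values.
    """
    if probes.empty:
        return (
            pd.DataFrame(columns=["dmr_id", "chrom", "start", "end", "n_members", "members"]),
            None if beta is None else pd.DataFrame(columns=beta.columns),
            MergeReport(0, 0, 0),
        )
    df = probes.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    half = window // 2
    starts = df["pos"].to_numpy() - half
    ends = starts + window

    rows = []
    members: list[list[str]] = []
    cur = None
    for i in range(len(df)):
        c, s, e, pid = df["chrom"].iloc[i], int(starts[i]), int(ends[i]), df["probe_id"].iloc[i]
        if cur is not None and c == cur[0] and s < cur[2]:  # strict overlap
            cur[2] = max(cur[2], e)
            members[-1].append(pid)
        else:
            cur = [c, s, e]
            rows.append(cur)
            members.append([pid])
    dmrs = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    dmrs["n_members"] = [len(m) for m in members]
    dmrs["members"] = [";".join(m) for m in members]
    dmrs.insert(0, "dmr_id", [f"dmr_{i:05d}" for i in range(len(dmrs))])

    n_multi = int((dmrs["n_members"] > 1).sum())
    report = MergeReport(
        n_probes=len(df),
        n_probes_in_multi=int(dmrs.loc[dmrs["n_members"] > 1, "n_members"].sum()),
        n_multi_regions=n_multi,
    )

    summary = None
    if beta is not None:
        vals = np.empty((len(dmrs), beta.shape[1]))
        for i, mem in enumerate(members):
            vals[i] = np.nanmedian(beta.loc[mem].to_numpy(), axis=0)
        summary = pd.DataFrame(vals, index=dmrs["dmr_id"].to_numpy(), columns=beta.columns)
    return dmrs, summary, report


def dmr_midpoint(start: int, end: int) -> int:
    return (int(start) + int(end)) // 2


def annotate_dmrs(
    dmrs: pd.DataFrame,
    annotation: GenomeAnnotation,
    tss_window: int = 500_000,
    promoter_up: int = 2000,
    promoter_down: int = 500,
    shore_flank: int = 2000,
) -> pd.DataFrame:
    """Annotate DMRs with overlap classes and TSS links within +/-tss_window.

    Promoters are strand-aware: ``promoter_up`` bp upstream through
    ``promoter_down`` bp downstream of the TSS.  CpG class is "island" on
    island overlap, "shore" within the 2 kb flank, else "open_sea".  TSS
    links use the DMR midpoint and an inclusive distance bound.
    Unknown chromosomes are skipped with a warning-level log entry.
    """
    import logging

    log = logging.getLogger(__name__)
    genes = annotation.genes
    islands = annotation.cpg_islands
    known = set(annotation.chromosomes)

    recs = []
    for _, d in dmrs.iterrows():
        if d["chrom"] not in known:
            log.warning("skipping DMR %s on unknown chromosome %s", d["dmr_id"], d["chrom"])
            continue
        mid = dmr_midpoint(d["start"], d["end"])
        g = genes[genes["chrom"] == d["chrom"]]
        tss = g["tss"].to_numpy()
        linked = g.loc[np.abs(tss - mid) <= tss_window, "gene_id"].tolist()

        # transcript / exon-span overlap (gene body) and promoter overlap
        body = g[(g["start"] < d["end"]) & (g["end"] > d["start"])]["gene_id"].tolist()
        plus = g["strand"].to_numpy() == "+"
        pstart = np.where(plus, g["tss"].to_numpy() - promoter_up,
                          g["tss"].to_numpy() - promoter_down + 1)
        pend = np.where(plus, g["tss"].to_numpy() + promoter_down,
                        g["tss"].to_numpy() + promoter_up + 1)
        prom = g.loc[(pstart < d["end"]) & (pend > d["start"]), "gene_id"].tolist()

        isl = islands[islands["chrom"] == d["chrom"]]
        on_island = ((isl["start"] < d["end"]) & (isl["end"] > d["start"])).any()
        on_shore = (
            (isl["start"] - shore_flank < d["end"]) & (isl["end"] + shore_flank > d["start"])
        ).any()
        cls = "island" if on_island else ("shore" if on_shore else "open_sea")

        recs.append(
            {
                "dmr_id": d["dmr_id"],
                "midpoint": mid,
                "cpg_class": cls,
                "transcripts": ";".join(body),
                "promoters": ";".join(prom),
                "linked_genes": ";".join(linked),
                "n_linked": len(linked),
            }
        )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# estimator


class DMRCaller(BaseEstimator):
    """End-to-end NE-DMR caller.

    Parameters
    ----------
    alpha : float
        Bonferroni-adjusted significance level per comparison.
    delta : float
        Minimum absolute median-beta difference per comparison.
    window : int
        Probe window width in bp for merging (odd; default 101).
    max_missing : float
        Maximum within-group missing fraction tolerated by the filter.

    Attributes (after ``fit``)
    --------------------------
    filter_report_ : FilterReport
    tests_ : per-probe test table with adjusted p and pass flag
    selected_probes_ : DataFrame of passing probes with coordinates
    dmrs_ : DMR interval table
    summary_beta_ : DMR x sample median-beta matrix
    merge_report_ : MergeReport
    """

    def __init__(self, alpha: float = 0.01, delta: float = 0.1,
                 window: int = 101, max_missing: float = 0.05):
        self.alpha = alpha
        self.delta = delta
        self.window = window
        self.max_missing = max_missing

    def fit(self, beta: pd.DataFrame, groups: pd.Series, probes: pd.DataFrame):
        """Run filter -> test -> select -> merge on a beta matrix.

        ``probes`` must contain probe_id/chrom/pos for every row of ``beta``.
        """
        filtered, self.filter_report_ = filter_probes(beta, groups, self.max_missing)
        tests = probe_tests(filtered, groups)
        self.tests_ = select_significant_probes(
            tests, m=len(filtered), alpha=self.alpha, delta=self.delta
        )
        sel_ids = self.tests_.index[self.tests_["pass"].to_numpy()]
        coords = (
            probes.set_index("probe_id").loc[sel_ids]
            .rename_axis("probe_id").reset_index()
        )
        self.selected_probes_ = coords
        self.dmrs_, self.summary_beta_, self.merge_report_ = build_dmrs(
            coords, filtered.loc[sel_ids], window=self.window
        )
        return self
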