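"""Synthetic data generation with a planted ground-truth manifest.

Every downstream stage of the pipeline (DMR calling, methylation-expression
linking, tissue-module discovery, signature scoring, differential
accessibility, peak-gene linking, DMR/peak integration) can be exercised
against data produced here, with the truth recorded in a
:class:`TruthManifest` so recovery can be measured without external
downloads.

The generator emulates a three-group lung-tumor methylation study
(neuroendocrine [NE] tumors, non-NE tumors, normal lung) profiled on a
450K-like beta-value array, matched tumor expression, a multi-tissue
expression panel carrying six planted coexpression modules (one brain-high),
and an ATAC-seq cell-line experiment with negative-binomial peak counts and
planted NE-specific fold-changes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GenomeAnnotation",
    "TruthManifest",
    "generate_annotation",
    "simulate_methylation",
    "simulate_expression",
    "simulate_tissue_panel",
    "simulate_atac",
]

GROUPS = ("NE", "nonNE", "normal")


@dataclass
class SimulationConfig:
    """All generator knobs; defaults define the study conditions.

    Sizes are chosen so the full pipeline runs in seconds while keeping the
    statistical regimes (group sizes, effect magnitudes, dispersions) at the
    values the recovery analyses assume.
    """

    # genome
    chromosomes: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_genes: int = 300
    n_cpg_islands: int = 100
    # methylation
    n_background_probes: int = 4000
    n_planted_dmrs: int = 60
    probes_per_dmr: int = 3
    probe_spacing: int = 40  # < 101 so planted probes merge into one region
    delta_beta: float = 0.35
    frac_hypo: float = 0.5  # fraction of planted DMRs hypomethylated in NE
    n_ne: int = 30
    n_nonne: int = 30
    n_normal: int = 20
    missing_rate: float = 0.005
    beta_concentration: float = 60.0  # within-probe across-sample precision
    # expression
    link_slope: float = 4.0
    expr_noise_sd: float = 0.3
    ne_module_effect: float = 1.0  # NE upshift (in SD units) of brain-module genes
    # tissue panel
    n_modules: int = 6
    genes_per_module: int = 40
    tissues: tuple = (
        "brain", "lung", "liver", "kidney", "heart", "muscle", "skin",
        "colon", "stomach", "pancreas", "spleen", "thyroid", "adrenal",
        "ovary", "testis", "prostate", "breast", "blood",
    )
    module_effect: float = 1.0  # log10-scale elevation of a module's tissues
    tissue_noise_sd: float = 0.25
    # ATAC
    n_peaks: int = 2000
    n_diff_peaks: int = 100
    peak_log2fc: float = 4.0
    frac_peaks_in_dmr: float = 0.4
    n_ne_lines: int = 3
    n_nonne_lines: int = 5
    atac_reps: int = 2
    atac_dispersion: float = 0.05
    atac_base_mean: float = 200.0
    peak_width: int = 400
    atac_noise_sd: float = 0.2
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissues"] = list(self.tissues)
        return d


@dataclass
class GenomeAnnotation:
    """A small synthetic genome: chromosomes, gene models, probes, CpG islands.

    ``genes`` columns: gene_id, symbol, chrom, strand, tss, start, end.
    ``probes`` columns: probe_id, chrom, pos.  ``cpg_islands`` columns:
    chrom, start, end.  All coordinates 0-based, half-open.
    """

    chromosomes: dict
    genes: pd.DataFrame
    probes: pd.DataFrame
    cpg_islands: pd.DataFrame

    def validate(self) -> None:
        if self.probes["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids")
        for df, cols in ((self.genes, ["tss"]), (self.probes, ["pos"])):
            for _, row in df.iterrows():
                L = self.chromosomes[row["chrom"]]
                for c in cols:
                    if not (0 <= row[c] < L):
                        raise ValueError(f"position {row[c]} outside {row['chrom']}")


@dataclass
class TruthManifest:
    """Ground truth for every planted signal, sufficient for recovery tests."""

    planted_dmrs: pd.DataFrame  # dmr_id, chrom, start, end, delta_beta
    links: pd.DataFrame         # dmr_id, gene_id, sign, slope
    modules: pd.DataFrame       # gene_id, module (1..K)
    peaks: pd.DataFrame | None  # peak_id, log2fc, in_dmr_window (filled by simulate_atac)
    peak_gene_links: pd.DataFrame | None
    seed: int
    params: dict

    def probe_ids_in_dmrs(self, probes: pd.DataFrame) -> pd.Index:
        """Probe ids falling inside any planted DMR interval."""
        hits = []
        for _, d in self.planted_dmrs.iterrows():
            m = (
                (probes["chrom"] == d["chrom"])
                & (probes["pos"] >= d["start"])
                & (probes["pos"] < d["end"])
            )
            hits.append(probes.loc[m, "probe_id"])
        if not hits:
            return pd.Index([])
        return pd.Index(pd.concat(hits).unique())

    def to_json(self, path) -> None:
        obj = {
            "seed": self.seed,
            "params": self.params,
            "planted_dmrs": self.planted_dmrs.to_dict(orient="list"),
            "links": self.links.to_dict(orient="list"),
            "modules": self.modules.to_dict(orient="list"),
            "peaks": None if self.peaks is None else self.peaks.to_dict(orient="list"),
            "peak_gene_links": (
                None
                if self.peak_gene_links is None
                else self.peak_gene_links.to_dict(orient="list")
            ),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=str)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_annotation(config: SimulationConfig) -> tuple[GenomeAnnotation, TruthManifest]:
    """Build the synthetic genome and plant DMRs, links and modules.

    Deterministic given ``config.seed``.  Planted DMR intervals receive
    ``probes_per_dmr`` clustered probes spaced ``probe_spacing`` bp apart;
    background probes are scattered uniformly outside planted intervals.
    Each planted DMR is coupled to one gene whose TSS lies within +/-500 kb
    of the DMR midpoint, with a signed regression slope recorded in the
    manifest.
    """
    if config.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if config.n_planted_dmrs <= 0 or config.n_background_probes <= 0:
        raise ValueError("probe/DMR counts must be positive")
    if config.probes_per_dmr < 1:
        raise ValueError("probes_per_dmr must be >= 1")

    rng = _rng(config.seed)
    chroms = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in chroms])

    # planted DMR intervals, spread evenly across chromosomes with margin
    dmr_rows = []
    span = config.probe_spacing * (config.probes_per_dmr - 1) + 1
    margin = 600_000
    for i in range(config.n_planted_dmrs):
        ci = i % len(chroms)
        L = lengths[ci]
        start = int(rng.integers(margin, L - margin - span))
        hypo = rng.random() < config.frac_hypo
        delta = -config.delta_beta if hypo else config.delta_beta
        dmr_rows.append(
            {
                "dmr_id": f"planted_dmr_{i:04d}",
                "chrom": chroms[ci],
                "start": start,
                "end": start + span,
                "delta_beta": float(delta),
            }
        )
    planted = pd.DataFrame(dmr_rows)

    # probes: clustered inside planted intervals + uniform background outside
    probe_rows = []
    for _, d in planted.iterrows():
        for k in range(config.probes_per_dmr):
            probe_rows.append(
                {"chrom": d["chrom"], "pos": int(d["start"]) + k * config.probe_spacing}
            )
    planted_by_chrom = {c: planted[planted["chrom"] == c] for c in chroms}
    n_bg = 0
    while n_bg < config.n_background_probes:
        ci = int(rng.integers(0, len(chroms)))
        pos = int(rng.integers(0, lengths[ci]))
        sub = planted_by_chrom[chroms[ci]]
        # keep background clear of planted windows (incl. the 101 bp merge halo)
        if ((pos >= sub["start"] - 101) & (pos < sub["end"] + 101)).any():
            continue
        probe_rows.append({"chrom": chroms[ci], "pos": pos})
        n_bg += 1
    probes = pd.DataFrame(probe_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    probes.insert(0, "probe_id", [f"cg{i:07d}" for i in range(len(probes))])

    # genes: one partner per planted DMR within +/-500 kb, the rest uniform
    gene_rows = []
    link_rows = []
    sign_choices = rng.random(config.n_planted_dmrs) < 0.5
    for i, (_, d) in enumerate(planted.iterrows()):
        mid = (int(d["start"]) + int(d["end"])) // 2
        offset = int(rng.integers(-400_000, 400_000))
        tss = int(np.clip(mid + offset, 0, config.chromosomes[d["chrom"]] - 1))
        gid = f"gene_{i:04d}"
        gene_rows.append(
            {
                "gene_id": gid,
                "symbol": gid.upper(),
                "chrom": d["chrom"],
                "strand": "+" if rng.random() < 0.5 else "-",
                "tss": tss,
            }
        )
        sign = 1 if sign_choices[i] else -1
        link_rows.append(
            {
                "dmr_id": d["dmr_id"],
                "gene_id": gid,
                "sign": sign,
                "slope": sign * config.link_slope,
            }
        )
    for j in range(len(gene_rows), config.n_genes):
        ci = int(rng.integers(0, len(chroms)))
        tss = int(rng.integers(10_000, lengths[ci] - 10_000))
        gid = f"gene_{j:04d}"
        gene_rows.append(
            {
                "gene_id": gid,
                "symbol": gid.upper(),
                "chrom": chroms[ci],
                "strand": "+" if rng.random() < 0.5 else "-",
                "tss": tss,
            }
        )
    genes = pd.DataFrame(gene_rows)
    genes["start"] = np.where(genes["strand"] == "+", genes["tss"], genes["tss"] - 20_000)
    genes["start"] = genes["start"].clip(lower=0)
    genes["end"] = genes["start"] + 20_000

    # CpG islands: uniform 1 kb intervals
    isl_rows = []
    for i in range(config.n_cpg_islands):
        ci = int(rng.integers(0, len(chroms)))
        s = int(rng.integers(0, lengths[ci] - 1000))
        isl_rows.append({"chrom": chroms[ci], "start": s, "end": s + 1000})
    islands = pd.DataFrame(isl_rows)

    # module membership: drawn from genes that are NOT planted link partners,
    # so that non-brain modules are expression-null in the tumor groups
    n_mod_genes = config.n_modules * config.genes_per_module
    if config.n_planted_dmrs + n_mod_genes > config.n_genes:
        raise ValueError("n_genes too small for requested module membership")
    first = config.n_planted_dmrs
    modules = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].iloc[first:first + n_mod_genes].to_numpy(),
            "module": np.repeat(np.arange(1, config.n_modules + 1), config.genes_per_module),
        }
    )

    annotation = GenomeAnnotation(
        chromosomes=dict(config.chromosomes),
        genes=genes,
        probes=probes,
        cpg_islands=islands,
    )
    truth = TruthManifest(
        planted_dmrs=planted,
        links=pd.DataFrame(link_rows),
        modules=modules,
        peaks=None,
        peak_gene_links=None,
        seed=config.seed,
        params=config.to_dict(),
    )
    return annotation, truth


def _baseline_means(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal per-probe baseline: mixture of Beta(2,10) and Beta(10,2)."""
    low = rng.random(n) < 0.5
    out = np.where(low, rng.beta(2, 10, n), rng.beta(10, 2, n))
    return out


def simulate_methylation(
    annotation: GenomeAnnotation,
    truth: TruthManifest,
    n_ne: int | None = None,
    n_nonne: int | None = None,
    n_normal: int | None = None,
    missing_rate: float | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a probes x samples beta matrix plus group labels.

    Per-probe baseline methylation is bimodal (450K-like).  Sample-level
    values are Beta-distributed around the probe baseline with concentration
    ``beta_concentration``.  NE samples are shifted by the planted signed
    delta-beta at planted-DMR probes, clipped to [0,1].  Planted probes draw
    their baseline from the mixture mode compatible with the effect sign so
    clipping does not erase the planted effect.  Missing entries are MCAR.
    """
    p = truth.params
    n_ne = p["n_ne"] if n_ne is None else n_ne
    n_nonne = p["n_nonne"] if n_nonne is None else n_nonne
    n_normal = p["n_normal"] if n_normal is None else n_normal
    missing_rate = p["missing_rate"] if missing_rate is None else missing_rate
    seed = truth.seed + 1 if seed is None else seed
    if min(n_ne, n_nonne, n_normal) < 3:
        raise ValueError("need >= 3 samples per group")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")

    rng = _rng(seed)
    probes = annotation.probes
    n_probes = len(probes)
    n_samples = n_ne + n_nonne + n_normal
    labels = pd.Series(
        ["NE"] * n_ne + ["nonNE"] * n_nonne + ["normal"] * n_normal,
        index=[f"S{i:03d}" for i in range(n_samples)],
        name="group",
    )

    base = _baseline_means(rng, n_probes)

    # per-probe planted effect (0 for background probes)
    effect = np.zeros(n_probes)
    for _, d in truth.planted_dmrs.iterrows():
        m = (
            (probes["chrom"] == d["chrom"]).to_numpy()
            & (probes["pos"].to_numpy() >= d["start"])
            & (probes["pos"].to_numpy() < d["end"])
        )
        effect[m] = d["delta_beta"]
        # compatible baseline mode so the shifted value stays inside [0,1]
        idx = np.where(m)[0]
        if d["delta_beta"] > 0:
            base[idx] = rng.beta(2, 10, idx.size)
        else:
            base[idx] = rng.beta(10, 2, idx.size)

    conc = p["beta_concentration"]
    mu = np.repeat(base[:, None], n_samples, axis=1)
    a = np.clip(mu * conc, 1e-3, None)
    b = np.clip((1 - mu) * conc, 1e-3, None)
    beta = rng.beta(a, b)
    is_ne = (labels == "NE").to_numpy()
    beta[:, is_ne] = np.clip(beta[:, is_ne] + effect[:, None], 0.0, 1.0)

    if missing_rate > 0:
        mask = rng.random(beta.shape) < missing_rate
        beta[mask] = np.nan

    beta_df = pd.DataFrame(beta, index=probes["probe_id"].to_numpy(), columns=labels.index)
    return beta_df, labels


def dmr_summary_from_truth(
    truth: TruthManifest, annotation: GenomeAnnotation, beta: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample median beta over member probes of each planted DMR."""
    rows = {}
    for _, d in truth.planted_dmrs.iterrows():
        m = (
            (annotation.probes["chrom"] == d["chrom"])
            & (annotation.probes["pos"] >= d["start"])
            & (annotation.probes["pos"] < d["end"])
        )
        ids = annotation.probes.loc[m, "probe_id"]
        rows[d["dmr_id"]] = np.nanmedian(beta.loc[ids].to_numpy(), axis=0)
    return pd.DataFrame(rows, index=beta.columns).T


def simulate_expression(
    truth: TruthManifest,
    annotation: GenomeAnnotation,
    beta: pd.DataFrame,
    labels: pd.Series,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tumor expression (genes x tumor samples), coupled to planted DMRs.

    For each planted (DMR, gene) link the gene's expression is
    ``a + slope * median_beta(DMR) + N(0, noise_sd)`` across tumor samples
    (normal-lung samples are excluded, as expression was profiled in tumors).
    Genes of the brain-high module (the highest module number) are
    additionally shifted up by ``ne_module_effect`` standard deviations in
    NE tumors, planting the NE phenotype the module scores should detect.
    Other modules carry no tumor-group effect.  Unlinked genes are
    independent Gaussian noise around a baseline.
    """
    p = truth.params
    noise_sd = p["expr_noise_sd"] if noise_sd is None else noise_sd
    seed = truth.seed + 2 if seed is None else seed
    rng = _rng(seed)

    unknown = set(truth.links["gene_id"]) - set(annotation.genes["gene_id"])
    if unknown:
        raise ValueError(f"unknown gene ids in links: {sorted(unknown)[:3]}")
    unknown_d = set(truth.links["dmr_id"]) - set(truth.planted_dmrs["dmr_id"])
    if unknown_d:
        raise ValueError(f"unknown dmr ids in links: {sorted(unknown_d)[:3]}")

    tumor = labels.index[(labels != "normal").to_numpy()]
    summary = dmr_summary_from_truth(truth, annotation, beta[tumor])

    genes = annotation.genes["gene_id"].to_numpy()
    expr = rng.normal(5.0, 1.0, (len(genes), len(tumor)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for _, lk in truth.links.iterrows():
        sb = summary.loc[lk["dmr_id"]].to_numpy()
        vals = 5.0 + lk["slope"] * sb
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, vals.shape)
        expr[gene_pos[lk["gene_id"]]] = vals

    # planted NE phenotype: brain-high module genes elevated in NE tumors
    effect = p.get("ne_module_effect", 0.0)
    if effect:
        brain_module = int(truth.modules["module"].max())
        brain_genes = truth.modules.loc[
            truth.modules["module"] == brain_module, "gene_id"
        ]
        is_ne_tumor = (labels.loc[tumor] == "NE").to_numpy()
        for gid in brain_genes:
            expr[gene_pos[gid], is_ne_tumor] += effect  # baseline SD is 1
    return pd.DataFrame(expr, index=genes, columns=tumor)


def simulate_tissue_panel(
    truth: TruthManifest, seed: int | None = None
) -> pd.DataFrame:
    """RPKM-like tissue-panel matrix (genes x tissues) with planted modules.

    Each module has a distinct tissue-mean profile on the log10 scale; the
    last module's profile is highest in the designated "brain" tissue.
    Values are back-transformed to a non-negative RPKM-like scale.
    """
    p = truth.params
    seed = truth.seed + 3 if seed is None else seed
    rng = _rng(seed)
    tissues = list(p["tissues"])
    n_modules = p["n_modules"]
    brain = tissues.index("brain")

    # distinct elevated-tissue sets per module; module n_modules -> brain
    profiles = np.zeros((n_modules, len(tissues)))
    non_brain = [i for i in range(len(tissues)) if i != brain]
    rng.shuffle(non_brain)
    per = max(2, len(non_brain) // max(1, n_modules - 1))
    for m in range(n_modules - 1):
        chosen = non_brain[m * per:(m + 1) * per]
        profiles[m, chosen] = p["module_effect"]
    profiles[n_modules - 1, brain] = 2.0 * p["module_effect"]

    rows = []
    for _, r in truth.modules.iterrows():
        mu = 0.5 + profiles[int(r["module"]) - 1]
        logv = mu + rng.normal(0, p["tissue_noise_sd"], len(tissues))
        rows.append(np.clip(10 ** logv - 1, 0, None))
    panel = pd.DataFrame(rows, index=truth.modules["gene_id"].to_numpy(), columns=tissues)
    return panel


def simulate_atac(
    truth: TruthManifest,
    annotation: GenomeAnnotation,
    n_ne_lines: int | None = None,
    n_nonne_lines: int | None = None,
    reps: int | None = None,
    dispersion: float | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate ATAC peak counts, peak intervals, design, and line expression.

    Returns ``(peaks, counts, design, line_expression)`` where ``peaks`` has
    peak_id/chrom/start/end, ``counts`` is peaks x replicate-samples of
    NB-distributed integers, ``design`` maps each replicate sample to its
    cell line and NE/non-NE group, and ``line_expression`` is genes x lines.
    A configured fraction of planted differential peaks is placed inside
    planted-DMR 500 bp consensus windows; planted peak-gene couplings tie a
    line's expression to the log accessibility of its partner peak.
    Fills ``truth.peaks`` and ``truth.peak_gene_links``.
    """
    p = truth.params
    n_ne_lines = p["n_ne_lines"] if n_ne_lines is None else n_ne_lines
    n_nonne_lines = p["n_nonne_lines"] if n_nonne_lines is None else n_nonne_lines
    reps = p["atac_reps"] if reps is None else reps
    dispersion = p["atac_dispersion"] if dispersion is None else dispersion
    seed = truth.seed + 4 if seed is None else seed
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")

    rng = _rng(seed)
    chroms = list(annotation.chromosomes)
    lengths = np.array([annotation.chromosomes[c] for c in chroms])
    n_peaks = p["n_peaks"]
    n_diff = p["n_diff_peaks"]
    width = p["peak_width"]

    # place differential peaks: a fraction inside planted DMR consensus windows
    n_in_dmr = int(round(p["frac_peaks_in_dmr"] * n_diff))
    dmrs = truth.planted_dmrs
    peak_rows = []
    for i in range(n_diff):
        if i < n_in_dmr:
            d = dmrs.iloc[i % len(dmrs)]
            mid = (int(d["start"]) + int(d["end"])) // 2
            s = mid - width // 2  # peak centered on the DMR midpoint
            peak_rows.append({"chrom": d["chrom"], "start": s, "end": s + width,
                              "diff": True, "in_dmr_window": True})
        else:
            ci = int(rng.integers(0, len(chroms)))
            s = int(rng.integers(700_000, lengths[ci] - 700_000))
            peak_rows.append({"chrom": chroms[ci], "start": s, "end": s + width,
                              "diff": True, "in_dmr_window": False})
    for _ in range(n_peaks - n_diff):
        ci = int(rng.integers(0, len(chroms)))
        s = int(rng.integers(0, lengths[ci] - width))
        peak_rows.append({"chrom": chroms[ci], "start": s, "end": s + width,
                          "diff": False, "in_dmr_window": False})
    peaks = pd.DataFrame(peak_rows)
    peaks.insert(0, "peak_id", [f"peak_{i:05d}" for i in range(len(peaks))])

    lines = [f"NE{i}" for i in range(n_ne_lines)] + [
        f"nonNE{i}" for i in range(n_nonne_lines)
    ]
    groups = ["NE"] * n_ne_lines + ["nonNE"] * n_nonne_lines
    samples, line_of, group_of = [], [], []
    for ln, g in zip(lines, groups):
        for r in range(reps):
            samples.append(f"{ln}_rep{r + 1}")
            line_of.append(ln)
            group_of.append(g)
    design = pd.DataFrame({"sample": samples, "line": line_of, "group": group_of}).set_index(
        "sample"
    )

    base_mean = rng.lognormal(np.log(p["atac_base_mean"]), 0.5, n_peaks)
    log2fc = np.where(peaks["diff"].to_numpy(), p["peak_log2fc"], 0.0)
    lib = rng.uniform(0.7, 1.4, len(samples))
    is_ne_sample = np.array([g == "NE" for g in group_of])

    mean = base_mean[:, None] * lib[None, :]
    mean = mean * np.where(is_ne_sample[None, :], 2.0 ** log2fc[:, None], 1.0)
    # NB with mean m and dispersion a: size = 1/a, p = size/(size+m)
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mean))
    counts_df = pd.DataFrame(counts, index=peaks["peak_id"].to_numpy(), columns=samples)

    truth.peaks = pd.DataFrame(
        {
            "peak_id": peaks["peak_id"].to_numpy(),
            "log2fc": log2fc,
            "in_dmr_window": peaks["in_dmr_window"].to_numpy(),
        }
    )
    peaks = peaks.drop(columns=["diff", "in_dmr_window"])

    # line-level expression coupled to accessibility of partner peaks:
    # each planted differential peak in a DMR window couples to the gene its
    # parent DMR is linked to (if any), giving consistent distal couplings.
    per_line_log = np.zeros((n_peaks, len(lines)))
    for j, ln in enumerate(lines):
        cols = [s for s, l in zip(samples, line_of) if l == ln]
        per_line_log[:, j] = np.log2(counts_df[cols].mean(axis=1).to_numpy() + 1)

    genes = annotation.genes["gene_id"].to_numpy()
    expr = rng.normal(3.0, 1.0, (len(genes), len(lines)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    link_of_dmr = dict(zip(truth.links["dmr_id"], truth.links["gene_id"]))
    pg_rows = []
    for i in range(n_in_dmr):
        d = dmrs.iloc[i % len(dmrs)]
        gid = link_of_dmr.get(d["dmr_id"])
        if gid is None:
            continue
        sig = per_line_log[i]
        z = (sig - sig.mean()) / (sig.std() + 1e-12)
        expr[gene_pos[gid]] = 3.0 + z + rng.normal(0, p["atac_noise_sd"], len(lines))
        pg_rows.append({"peak_id": peaks["peak_id"].iloc[i], "gene_id": gid, "sign": 1})
    truth.peak_gene_links = pd.DataFrame(pg_rows)

    line_expr = pd.DataFrame(expr, index=genes, columns=lines)
    return peaks, counts_df, design, line_expr
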