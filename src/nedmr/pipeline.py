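"""Pipeline driver: simulate inputs, run every stage in dependency order,
and emit artifacts plus a provenance manifest.

Stages: simulate -> dmr -> link -> modules -> score -> atac-diff ->
peak-link -> integrate.  Each stage writes its outputs under the output
directory; the manifest records seeds, thresholds and record counts per
stage so reruns can be compared exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .atac import NBDifferentialTest
from .dmr import DMRCaller
from .integrate import consensus_windows, module_profile, overlap_fraction
from .linking import DMRGeneLinker
from .modules import TissueModuleClusterer
from .peaks import PeakGeneLinker
from .scoring import ModuleScorer
from .simulate import (
    SimulationConfig,
    generate_annotation,
    simulate_atac,
    simulate_expression,
    simulate_methylation,
    simulate_tissue_panel,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds, seeds and stage toggles for a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.01           # Bonferroni level per comparison
    delta: float = 0.1            # minimum |median beta difference|
    link_window: int = 500_000    # DMR-midpoint to TSS bound
    percentile: float = 98.0      # empirical |r| cutoff percentile
    fdr: float = 0.05             # BH level for differential peaks
    r_cutoff: float = 0.7         # peak-gene correlation cutoff
    peak_windows: tuple = (200_000, 500_000, 1_000_000)
    consensus_size: int = 500
    kmeans_restarts: int = 50
    seed: int = 0

    def __post_init__(self):
        checks = [
            (0 < self.alpha <= 1, "alpha"),
            (0 <= self.delta < 1, "delta"),
            (self.link_window > 0, "link_window"),
            (0 < self.percentile < 100, "percentile"),
            (0 < self.fdr <= 1, "fdr"),
            (0 <= self.r_cutoff <= 1, "r_cutoff"),
            (self.consensus_size > 0 and self.consensus_size % 2 == 0, "consensus_size"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"config value out of domain: {name}")
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["peak_windows"] = list(self.peak_windows)
        return d


@dataclass
class PipelineResult:
    """In-memory handles to every stage's outputs plus the manifest."""

    annotation: object
    truth: object
    dmr_caller: DMRCaller
    linker: DMRGeneLinker
    clusterer: TissueModuleClusterer
    scorer: ModuleScorer
    rocs: dict
    atac_test: NBDifferentialTest
    peak_linkers: dict
    overlaps: dict
    profile: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute every stage on freshly simulated data.

    When ``outdir`` is given, artifacts (BED/TSV/JSON) and the provenance
    manifest are written there; the manifest's per-stage record counts
    equal the on-disk row counts.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # --- simulate -----------------------------------------------------------
    log.info("[simulate] generating annotation and planted truth")
    annotation, truth = generate_annotation(config.simulation)
    beta, groups = simulate_methylation(annotation, truth)
    expression = simulate_expression(truth, annotation, beta, groups)
    panel = simulate_tissue_panel(truth)
    peaks, counts, design, line_expr = simulate_atac(truth, annotation)
    manifest["stages"]["simulate"] = {
        "n_probes": len(beta),
        "n_samples": int(beta.shape[1]),
        "n_genes": len(annotation.genes),
        "n_peaks": len(peaks),
        "seed": config.seed,
    }

    # --- dmr ----------------------------------------------------------------
    log.info("[dmr] probe filtering, testing and merging")
    caller = DMRCaller(alpha=config.alpha, delta=config.delta).fit(
        beta, groups, annotation.probes
    )
    manifest["stages"]["dmr"] = {
        "n_filtered_out": caller.filter_report_.n_removed,
        "n_tested": caller.filter_report_.n_remaining,
        "n_selected_probes": len(caller.selected_probes_),
        "n_dmrs": len(caller.dmrs_),
    }

    # --- link ---------------------------------------------------------------
    log.info("[link] DMR-gene correlation linking")
    linker = DMRGeneLinker(
        window=config.link_window, percentile=config.percentile
    ).fit(caller.dmrs_, annotation.genes, caller.summary_beta_, expression)
    manifest["stages"]["link"] = {
        "n_candidates": len(linker.candidates_),
        "n_unlinked_dmrs": len(linker.unlinked_dmrs_),
        "n_links": len(linker.links_),
        "n_significant": int(linker.links_["significant"].sum()),
        "r_threshold": linker.cutoff_.threshold,
        "bonferroni_r": linker.cutoff_.bonferroni_r,
    }

    # --- modules ------------------------------------------------------------
    log.info("[modules] tissue-panel MDS + k-means")
    clusterer = TissueModuleClusterer(
        n_restarts=config.kmeans_restarts, random_state=config.seed
    ).fit(panel)
    manifest["stages"]["modules"] = {
        "n_genes": clusterer.assignment_.total_genes,
        "sizes": clusterer.module_sizes_.to_dict(),
        "hclust_ari": clusterer.hclust_ari_,
    }

    # --- score --------------------------------------------------------------
    log.info("[score] module scores and ROC")
    scorer = ModuleScorer().fit(expression, clusterer.assignment_)
    tumor_labels = (groups.loc[scorer.scores_.index] == "NE").astype(int)
    rocs = scorer.evaluate(tumor_labels)
    manifest["stages"]["score"] = {
        "auc": {str(m): r.auc for m, r in rocs.items()},
    }

    # --- atac-diff ----------------------------------------------------------
    log.info("[atac-diff] NB Wald differential accessibility")
    atac_test = NBDifferentialTest(fdr=config.fdr).fit(counts, design["group"])
    n_sig = int(atac_test.significant_.sum())
    manifest["stages"]["atac_diff"] = {
        "n_peaks": len(counts),
        "n_significant": n_sig,
    }

    # --- peak-link ----------------------------------------------------------
    log.info("[peak-link] peak classification and gene linking")
    sig_peaks = peaks[atac_test.significant_.reindex(peaks["peak_id"]).to_numpy()]
    norm = atac_test.normalized_counts(counts)
    peak_linkers = {}
    for w in config.peak_windows:
        peak_linkers[w] = PeakGeneLinker(window=w, r_cutoff=config.r_cutoff).fit(
            sig_peaks, norm, design["line"], line_expr, annotation.genes
        )
    widest = peak_linkers[max(config.peak_windows)]
    manifest["stages"]["peak_link"] = {
        "n_differential_peaks": len(sig_peaks),
        "n_tss_peaks": int((widest.classes_ == "tss").sum()),
        "n_distal_peaks": int((widest.classes_ == "distal").sum()),
        "n_tss_genes": len(widest.tss_genes_),
        "links_per_window": {
            str(w): int(pl.links_["pass"].sum()) for w, pl in peak_linkers.items()
        },
    }

    # --- integrate ----------------------------------------------------------
    log.info("[integrate] DMR/peak overlap and module profiles")
    windows = consensus_windows(
        caller.dmrs_, size=config.consensus_size, chrom_sizes=annotation.chromosomes
    )
    overlaps = {"all_dmrs": overlap_fraction(windows, sig_peaks)}
    sig_dmr_ids = set(
        linker.links_.loc[linker.links_["significant"], "dmr_id"].unique()
    )
    overlaps["significant_dmrs"] = overlap_fraction(
        windows[windows["dmr_id"].isin(sig_dmr_ids)], sig_peaks
    )
    dmr_gene_links = linker.links_.rename(columns={})[["gene_id", "r"]].assign(
        dmr_id=linker.links_["dmr_id"]
    )
    profile = module_profile(
        clusterer.assignment_, widest.links_, linker.links_
    )
    manifest["stages"]["integrate"] = {
        "dmr_overlap_pct": overlaps["all_dmrs"].pct_a,
        "significant_dmr_overlap_pct": overlaps["significant_dmrs"].pct_a,
        "peak_overlap_pct": overlaps["all_dmrs"].pct_b,
        "n_profile_rows": len(profile),
    }
    _ = dmr_gene_links

    # --- artifacts ----------------------------------------------------------
    if out is not None:
        io.write_matrix(beta, out / "beta.tsv", index_label="probe_id")
        io.write_labels(groups, out / "labels.tsv")
        io.write_bed(
            annotation.probes.assign(
                start=annotation.probes["pos"], end=annotation.probes["pos"] + 1
            )[["chrom", "start", "end", "probe_id"]],
            out / "probes.bed",
        )
        io.write_matrix(expression, out / "expression.tsv", index_label="gene_id")
        io.write_matrix(panel, out / "tissue_panel.tsv", index_label="gene_id")
        io.write_bed(caller.dmrs_[["chrom", "start", "end", "dmr_id", "n_members"]],
                     out / "dmrs.bed")
        io.write_matrix(caller.summary_beta_, out / "dmr_beta.tsv", index_label="dmr_id")
        caller.tests_.to_csv(out / "probe_tests.tsv", sep="\t", index_label="probe_id")
        linker.links_.to_csv(out / "links.tsv", sep="\t", index=False)
        io.write_json(
            {
                "percentile": linker.cutoff_.percentile,
                "threshold": linker.cutoff_.threshold,
                "bonferroni_r": linker.cutoff_.bonferroni_r,
            },
            out / "cutoff.json",
        )
        clusterer.assignment_.labels.to_frame().to_csv(
            out / "modules.tsv", sep="\t", index_label="gene_id"
        )
        pd.DataFrame(
            clusterer.embedding_, index=clusterer.standardized_.index,
            columns=[f"mds{i + 1}" for i in range(clusterer.embedding_.shape[1])],
        ).to_csv(out / "mds.tsv", sep="\t", index_label="gene_id")
        scorer.scores_.to_csv(out / "module_scores.tsv", sep="\t", index_label="sample")
        atac_test.results_.to_csv(out / "atac_results.tsv", sep="\t", index_label="peak_id")
        io.write_bed(sig_peaks[["chrom", "start", "end", "peak_id"]],
                     out / "significant_peaks.bed")
        for w, pl in peak_linkers.items():
            pl.links_.to_csv(out / f"peak_links_{w}.tsv", sep="\t", index=False)
        io.write_bed(windows[["chrom", "start", "end", "dmr_id"]],
                     out / "dmr_consensus.bed")
        profile.to_csv(out / "module_profile.tsv", sep="\t", index=False)
        truth.to_json(out / "truth.json")
        io.write_json(manifest, out / "manifest.json")

    return PipelineResult(
        annotation=annotation,
        truth=truth,
        dmr_caller=caller,
        linker=linker,
        clusterer=clusterer,
        scorer=scorer,
        rocs=rocs,
        atac_test=atac_test,
        peak_linkers=peak_linkers,
        overlaps=overlaps,
        profile=profile,
        manifest=manifest,
    )
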