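"""Probe filtering, Mann-Whitney testing, probe selection and DMR merging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nedmr.dmr import (
    FilterReport,
    MergeReport,
    build_dmrs,
    filter_probes,
    mann_whitney,
    select_significant_probes,
    probe_tests,
    annotate_dmrs,
)
from nedmr.simulate import GenomeAnnotation, SimulationConfig, generate_annotation, simulate_methylation


def _labels(n_ne=4, n_nonne=4, n_normal=4):
    return pd.Series(
        ["NE"] * n_ne + ["nonNE"] * n_nonne + ["normal"] * n_normal,
        index=[f"s{i}" for i in range(n_ne + n_nonne + n_normal)],
    )


class TestFilterProbes:
    def test_toy_removal_by_hand(self, rng):
        """1 probe >5% NE-missing and 1 constant-in-NE probe -> 8 of 10 remain."""
        groups = _labels(10, 10, 10)
        vals = rng.uniform(0.1, 0.9, (10, 30))
        beta = pd.DataFrame(vals, index=[f"p{i}" for i in range(10)],
                            columns=groups.index)
        beta.iloc[0, 0] = np.nan  # 1/10 = 10% missing within NE
        beta.iloc[1, 0:10] = 0.5  # constant within NE
        out, report = filter_probes(beta, groups)
        assert len(out) == 8
        assert report.n_removed_missing == 1
        assert report.n_removed_zero_sd == 1
        assert report.n_remaining == 8
        assert "p0" not in out.index and "p1" not in out.index

    def test_constant_in_normal_only_removed(self, rng):
        groups = _labels(4, 4, 4)
        beta = pd.DataFrame(rng.uniform(size=(3, 12)),
                            index=list("abc"), columns=groups.index)
        beta.loc["b", (groups == "normal").to_numpy()] = 0.3
        out, _ = filter_probes(beta, groups)
        assert list(out.index) == ["a", "c"]

    def test_errors(self):
        groups = _labels(4, 4, 4)
        with pytest.raises(ValueError):
            filter_probes(pd.DataFrame(), groups)
        beta = pd.DataFrame(np.random.rand(2, 8),
                            columns=[f"s{i}" for i in range(8)])
        two_groups = pd.Series(["NE"] * 4 + ["nonNE"] * 4, index=beta.columns)
        with pytest.raises(ValueError):
            filter_probes(beta, two_groups)


class TestMannWhitney:
    def test_identical_sets_give_p_one(self):
        u, p = mann_whitney([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert p == 1.0

    def test_fully_separated_exact(self):
        """Enumerating all C(6,3)=20 labelings gives two-sided p = 2/20."""
        u, p = mann_whitney([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_exact_matches_scipy_on_tie_free_data(self, rng):
        """Our enumeration equals scipy's exact method when there are no ties."""
        for _ in range(20):
            nx, ny = rng.integers(3, 7, 2)
            if nx + ny > 12:
                continue
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            _, p = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_close_to_exact_n6v6(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p_exact = mann_whitney(x, y)  # pooled n = 12 -> exact path
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
            assert abs(res.pvalue - p_exact) < 0.02

    def test_missing_dropped_and_all_missing_errors(self):
        u, p = mann_whitney([0.1, np.nan, 0.3], [0.7, 0.8, np.nan])
        assert np.isfinite(p)
        with pytest.raises(ValueError):
            mann_whitney([np.nan], [0.1, 0.2])


class TestSelection:
    def _tests_frame(self, rows):
        return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))])

    def test_effect_size_required_in_both_comparisons(self):
        t = self._tests_frame([
            {"p_normal": 0.005 / 100, "dmed_normal": 0.2,
             "p_nonne": 0.005 / 100, "dmed_nonne": 0.05},
        ])
        res = select_significant_probes(t, m=100)
        assert not res["pass"].iloc[0]

    def test_significance_required_in_both_comparisons(self):
        t = self._tests_frame([
            {"p_normal": 0.005 / 100, "dmed_normal": 0.2,
             "p_nonne": 0.5, "dmed_nonne": 0.2},
        ])
        res = select_significant_probes(t, m=100)
        assert not res["pass"].iloc[0]
        assert res["padj_nonne"].iloc[0] == 1.0  # capped at 1

    def test_rejects_nonpositive_m(self):
        t = self._tests_frame([{"p_normal": 0.1, "dmed_normal": 0.0,
                                "p_nonne": 0.1, "dmed_nonne": 0.0}])
        with pytest.raises(ValueError):
            select_significant_probes(t, m=0)

    def test_null_simulation_selects_nothing(self):
        """With no planted effect, Bonferroni keeps false passes at zero."""
        total = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, delta_beta=0.0,
                                   n_planted_dmrs=5, n_background_probes=1985,
                                   n_genes=100, genes_per_module=5,
                                   missing_rate=0.0)
            ann, truth = generate_annotation(cfg)
            beta, groups = simulate_methylation(ann, truth)
            tests = probe_tests(beta, groups)
            res = select_significant_probes(tests, m=len(beta))
            total += int(res["pass"].sum())
        assert total == 0


class TestBuildDmrs:
    def _probes(self, positions, chrom="chr1"):
        return pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
        })

    def test_overlapping_windows_merge(self):
        dmrs, _, rep = build_dmrs(self._probes([100, 150]))
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["start"] == 50 and dmrs.iloc[0]["end"] == 201
        assert dmrs.iloc[0]["n_members"] == 2
        assert rep.n_dmrs == 1 and rep.n_probes_in_multi == 2

    def test_distant_windows_stay_separate(self):
        dmrs, _, _ = build_dmrs(self._probes([100, 300]))
        assert len(dmrs) == 2

    def test_book_ended_windows_not_merged(self):
        # windows [50,151) and [151,252): share no base
        dmrs, _, _ = build_dmrs(self._probes([100, 201]))
        assert len(dmrs) == 2

    def test_single_probe_window_and_identity_summary(self):
        beta = pd.DataFrame({"s1": [0.2], "s2": [0.8]}, index=["p0"])
        dmrs, summary, _ = build_dmrs(self._probes([500]), beta)
        assert dmrs.iloc[0]["start"] == 450 and dmrs.iloc[0]["end"] == 551
        assert summary.iloc[0].tolist() == [0.2, 0.8]

    def test_merge_idempotent(self, rng):
        pos = np.sort(rng.integers(0, 100_000, 200))
        dmrs1, _, _ = build_dmrs(self._probes(pos))
        # re-merging midpoints of the produced DMRs reproduces intervals only
        # if merging was maximal: no two output intervals overlap
        iv = dmrs1.sort_values("start")
        assert (iv["start"].to_numpy()[1:] >= iv["end"].to_numpy()[:-1]).all()

    def test_member_count_identity(self, rng):
        pos = np.sort(rng.integers(0, 50_000, 300))
        dmrs, _, rep = build_dmrs(self._probes(pos))
        assert dmrs["n_members"].sum() == 300
        assert rep.n_dmrs == len(dmrs)
        assert len(dmrs) <= 300

    def test_summary_median_matches_brute_force(self, rng):
        pos = np.sort(rng.integers(0, 5_000, 60))
        probes = self._probes(pos)
        beta = pd.DataFrame(rng.uniform(size=(60, 8)),
                            index=probes["probe_id"].to_numpy(),
                            columns=[f"s{i}" for i in range(8)])
        beta[beta < 0.05] = np.nan
        dmrs, summary, _ = build_dmrs(probes, beta)
        for _, d in dmrs.iterrows():
            mem = d["members"].split(";")
            expected = np.nanmedian(beta.loc[mem].to_numpy(), axis=0)
            got = summary.loc[d["dmr_id"]].to_numpy()
            np.testing.assert_allclose(got, expected, equal_nan=True)


class TestAnnotate:
    def _mini_annotation(self, tss_list):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(tss_list))],
            "symbol": [f"G{i}" for i in range(len(tss_list))],
            "chrom": "chr1",
            "strand": "+",
            "tss": tss_list,
        })
        genes["start"] = genes["tss"]
        genes["end"] = genes["tss"] + 1000
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [6000]})
        return GenomeAnnotation(chromosomes={"chr1": 10_000_000}, genes=genes,
                                probes=pd.DataFrame(columns=["probe_id", "chrom", "pos"]),
                                cpg_islands=islands)

    def test_tss_link_boundary_inclusive(self):
        mid = 1_000_000
        ann = self._mini_annotation([mid + 500_000, mid + 500_001])
        dmrs = pd.DataFrame([{"dmr_id": "d0", "chrom": "chr1",
                              "start": mid - 50, "end": mid + 51}])
        res = annotate_dmrs(dmrs, ann)
        assert res.iloc[0]["linked_genes"] == "g0"

    def test_three_gene_distance_scan(self):
        mid = 2_000_000
        ann = self._mini_annotation([mid + 100_000, mid - 499_000, mid + 600_000])
        dmrs = pd.DataFrame([{"dmr_id": "d0", "chrom": "chr1",
                              "start": mid - 50, "end": mid + 51}])
        res = annotate_dmrs(dmrs, ann)
        assert res.iloc[0]["n_linked"] == 2

    def test_cpg_island_and_shore_classes(self):
        ann = self._mini_annotation([100_000])
        inside = pd.DataFrame([{"dmr_id": "d0", "chrom": "chr1",
                                "start": 5400, "end": 5501}])
        shore = pd.DataFrame([{"dmr_id": "d1", "chrom": "chr1",
                               "start": 6500, "end": 6601}])
        sea = pd.DataFrame([{"dmr_id": "d2", "chrom": "chr1",
                             "start": 50_000, "end": 50_101}])
        assert annotate_dmrs(inside, ann).iloc[0]["cpg_class"] == "island"
        assert annotate_dmrs(shore, ann).iloc[0]["cpg_class"] == "shore"
        assert annotate_dmrs(sea, ann).iloc[0]["cpg_class"] == "open_sea"


def test_filter_report_accounting_matches_filter_output(methylation):
    beta, groups = methylation
    out, report = filter_probes(beta, groups)
    assert report.n_remaining == len(out)
    assert report.n_input == len(beta)
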