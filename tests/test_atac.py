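"""Size factors, NB GLM Wald tests, BH adjustment, calibration properties."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from nedmr.atac import (
    NBDifferentialTest,
    bh_adjust,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)
from nedmr.simulate import SimulationConfig, generate_annotation, simulate_atac


def _counts(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"pk{i}" for i in range(arr.shape[0])],
                        columns=samples)


def _design(n_ne, n_nonne):
    return pd.Series(["NE"] * n_ne + ["nonNE"] * n_nonne,
                     index=[f"s{i}" for i in range(n_ne + n_nonne)])


class TestSizeFactors:
    def test_identical_columns_give_ones(self):
        c = _counts([[10, 10], [20, 20], [5, 5]])
        np.testing.assert_allclose(size_factors(c).to_numpy(), [1.0, 1.0])

    def test_doubled_column_detected(self):
        c = _counts([[10, 20], [30, 60], [7, 14]])
        f = size_factors(c)
        # geometric mean of factors is 1, ratio is exactly 2
        assert f["s1"] / f["s0"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_three_by_three_by_hand(self):
        c = _counts([[2, 4, 8], [2, 4, 8], [2, 4, 8]])
        f = size_factors(c)
        # ratios to the per-peak geometric mean 4: (0.5, 1, 2) in each peak
        g = (0.5 * 1 * 2) ** (1 / 3)
        np.testing.assert_allclose(f.to_numpy(), np.array([0.5, 1, 2]) / g)

    def test_column_order_invariance(self, rng):
        c = _counts(rng.poisson(50, (40, 6)))
        f = size_factors(c)
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        f2 = size_factors(c[perm])
        np.testing.assert_allclose(f2.reindex(f.index).to_numpy(),
                                   f.to_numpy())

    def test_all_zero_rows_need_pseudo_reference(self):
        c = _counts([[0, 5], [3, 0]])
        with pytest.raises(ValueError):
            size_factors(c)
        f = size_factors(c, pseudo_reference=True)
        assert np.isfinite(f).all()


class TestBhAdjust:
    def test_textbook_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        from statsmodels.stats.multitest import multipletests

        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([np.nan])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0, allow_nan=False),
                    min_size=1, max_size=50))
    def test_invariants(self, p):
        q = bh_adjust(p)
        p = np.asarray(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        # ordering by p implies ordering by q
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestWaldTest:
    def test_identical_groups_give_null_results(self, rng):
        base = rng.poisson(100, (30, 1))
        c = _counts(np.repeat(base, 8, axis=1) + rng.poisson(5, (30, 8)))
        res = nb_wald_test(c, _design(4, 4))
        assert (res["p"] > 0.2).mean() > 0.9
        assert np.abs(res["log2fc"]).max() < 0.5

    def test_all_zero_peak_degenerate(self):
        arr = np.vstack([np.zeros(8), np.full(8, 50.0)])
        res = nb_wald_test(_counts(arr), _design(4, 4))
        assert res.iloc[0]["p"] == 1.0 and res.iloc[0]["log2fc"] == 0.0

    def test_requires_two_per_group(self):
        c = _counts(np.full((3, 3), 10))
        with pytest.raises(ValueError):
            nb_wald_test(c, pd.Series(["NE", "nonNE", "nonNE"],
                                      index=c.columns))

    def test_matches_statsmodels_glm(self, rng):
        """Coefficients and SEs agree with statsmodels NB GLM at fixed alpha."""
        n_peaks, design = 50, _design(4, 4)
        mu = rng.lognormal(4.5, 1.0, n_peaks)
        shape = 1 / 0.05
        lam = rng.gamma(shape, scale=mu[:, None] / shape, size=(n_peaks, 8))
        K = rng.poisson(lam)
        c = _counts(K)
        f = size_factors(c, pseudo_reference=True)
        res = nb_wald_test(c, design, factors=f)
        X = np.column_stack([np.ones(8), (design == "NE").to_numpy(float)])
        off = np.log(f.to_numpy())
        for i in range(n_peaks):
            a = res["dispersion"].iloc[i]
            fam = sm.families.NegativeBinomial(alpha=a)
            fit = sm.GLM(K[i], X, family=fam, offset=off).fit()
            assert res["log2fc"].iloc[i] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4)
            assert res["se"].iloc[i] == pytest.approx(
                fit.bse[1] / np.log(2), rel=1e-3)

    def test_rejection_set_agrees_with_lrt_on_strong_effects(self, rng):
        """For |log2FC| >= 2 truths, Wald and LRT calls agree >= 95%."""
        n_peaks, design = 60, _design(4, 4)
        mu = rng.lognormal(5, 0.5, n_peaks)
        lfc = np.where(rng.random(n_peaks) < 0.5, 2.0, 0.0) * rng.choice([-1, 1], n_peaks)
        shape = 1 / 0.05
        group = (design == "NE").to_numpy()
        m = mu[:, None] * np.where(group[None, :], 2.0 ** lfc[:, None], 1.0)
        K = rng.poisson(rng.gamma(shape, scale=m / shape))
        c = _counts(K)
        res = nb_wald_test(c, design, factors=pd.Series(1.0, index=c.columns))
        X = np.column_stack([np.ones(8), group.astype(float)])
        agree = 0
        for i in range(n_peaks):
            fam = sm.families.NegativeBinomial(alpha=res["dispersion"].iloc[i])
            full = sm.GLM(K[i], X, family=fam).fit()
            null = sm.GLM(K[i], X[:, :1], family=fam).fit()
            from scipy import stats as sps

            lrt_p = sps.chi2.sf(2 * (full.llf - null.llf), 1)
            agree += (res["p"].iloc[i] < 0.01) == (lrt_p < 0.01)
        assert agree / n_peaks >= 0.95


class TestCalibration:
    def test_null_type_one_error_near_nominal(self):
        """Raw p<0.05 rate over null peaks stays in a loose nominal band."""
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(5, 1, 400)
            shape = 1 / 0.05
            K = rng.poisson(rng.gamma(shape, scale=mu[:, None] / shape,
                                      size=(400, 8)))
            res = nb_wald_test(_counts(K), _design(4, 4),
                               factors=pd.Series(1.0, index=[f"s{i}" for i in range(8)]))
            rates.append((res["p"] < 0.05).mean())
        assert 0.02 <= np.mean(rates) <= 0.09

    def test_sensitivity_on_planted_peaks(self):
        """Planted |log2FC|=4 peaks are recovered at q<0.05 with rate >= 0.9."""
        sens = []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed)
            ann, truth = generate_annotation(cfg)
            peaks, counts, design, _ = simulate_atac(truth, ann)
            test = NBDifferentialTest().fit(counts, design["group"])
            planted = truth.peaks.loc[truth.peaks["log2fc"] != 0, "peak_id"]
            sens.append(test.significant_.loc[planted].mean())
        assert np.mean(sens) >= 0.9

    def test_q_at_least_p(self, pipeline_result):
        res = pipeline_result.atac_test.results_
        assert (res["q"] >= res["p"] - 1e-15).all()


def test_dispersion_estimator_recovers_truth(rng):
    """MoM dispersion on large groups is close to the generating alpha."""
    alpha_true = 0.1
    shape = 1 / alpha_true
    mu = 500.0
    K = rng.poisson(rng.gamma(shape, scale=mu / shape, size=(200, 400)))
    est = estimate_dispersion(K.astype(float), np.arange(400) < 200)
    assert np.median(est) == pytest.approx(alpha_true, rel=0.25)
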