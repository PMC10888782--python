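import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar

from pollenpipe.diffexp import (
    adjust_pvalues_holm,
    classify_degs,
    estimate_dispersion,
    estimate_size_factors,
    run_differential_expression,
    summarize_target_set,
    wald_test_nb,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: NB likelihood-ratio test at fixed dispersion


def _nb_loglik(y, mu, alpha):
    if alpha <= 0:
        return float(stats.poisson.logpmf(y, mu).sum())
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(stats.nbinom.logpmf(y, r, p).sum())


def _fit_mean_loglik(y, alpha):
    res = minimize_scalar(
        lambda m: -_nb_loglik(y, np.exp(m), alpha), bounds=(-10.0, 15.0), method="bounded"
    )
    return -res.fun


def lrt_oracle_p(y, is_group, alpha):
    y = np.asarray(y, float)
    ll_alt = _fit_mean_loglik(y[is_group], alpha) + _fit_mean_loglik(y[~is_group], alpha)
    ll_null = _fit_mean_loglik(y, alpha)
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    return float(stats.chi2.sf(stat, 1))


class TestSizeFactors:
    def test_identical_columns_give_ones(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3]})
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_hand_computed_two_sample(self):
        # column2 = 2 x column1: geometric mean row-wise = c*sqrt(2)
        # ratios: col1 -> 1/sqrt(2) (every gene), col2 -> sqrt(2)
        counts = pd.DataFrame({"a": [4, 10, 6], "b": [8, 20, 12]})
        sf = estimate_size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_single_sample_is_one(self):
        assert estimate_size_factors(pd.DataFrame({"a": [3, 1]})).tolist() == [1.0]

    def test_no_common_gene_errors(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(counts)


class TestDispersion:
    def test_poisson_gene_near_zero(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(200, 100)))
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf)
        assert disp.mean() < 0.01

    def test_constant_gene_zero(self):
        counts = pd.DataFrame(np.full((1, 10), 7))
        disp = estimate_dispersion(counts, pd.Series(1.0, index=counts.columns))
        assert disp.iloc[0] == 0.0

    def test_nb_recovery(self, rng):
        alpha = 0.2
        mu = 100.0
        lam = rng.gamma(1 / alpha, alpha * mu, size=(300, 200))
        counts = pd.DataFrame(rng.poisson(lam))
        disp = estimate_dispersion(counts, pd.Series(1.0, index=counts.columns))
        assert abs(disp.mean() - alpha) < 0.05


class TestWald:
    def test_identical_groups_null(self):
        counts = pd.DataFrame(np.full((3, 8), 50), columns=[f"s{i}" for i in range(8)])
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        res = wald_test_nb(counts, sf, disp, [True] * 4 + [False] * 4)
        assert (res["log2FoldChange"].abs() < 0.01).all()
        assert (res["pvalue"] > 0.9).all()

    def test_symmetry_under_label_swap(self, rng):
        counts = pd.DataFrame(rng.poisson(80, size=(20, 10)))
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        x = np.arange(10) < 4
        a = wald_test_nb(counts, sf, disp, x)
        b = wald_test_nb(counts, sf, disp, ~x)
        assert np.allclose(a["log2FoldChange"], -b["log2FoldChange"], atol=1e-6)
        assert np.allclose(a["pvalue"], b["pvalue"], atol=1e-8)

    def test_recovers_strong_fold_at_study_group_sizes(self, rng):
        # true fold 1/128 (log2FC = -7), 19 vs 7 samples, depth-matched
        n_rest, n_double = 19, 7
        mu_rest, alpha = 640.0, 0.05
        lam = np.concatenate(
            [
                rng.gamma(1 / alpha, alpha * mu_rest, size=(200, n_rest)),
                rng.gamma(1 / alpha, alpha * mu_rest / 128, size=(200, n_double)),
            ],
            axis=1,
        )
        counts = pd.DataFrame(rng.poisson(lam))
        is_double = np.arange(n_rest + n_double) >= n_rest
        # depth-matched: unit size factors (a global fold would otherwise be
        # absorbed by median-of-ratios normalization)
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf)
        res = wald_test_nb(counts, sf, disp, is_double)
        res["padj"] = adjust_pvalues_holm(res["pvalue"].to_numpy())
        assert abs(res["log2FoldChange"].median() + 7) < 1
        assert (res["padj"] <= 0.05).mean() > 0.95

    def test_null_type_one_error_calibrated(self, rng):
        alpha_true, mu, G, n = 0.2, 100.0, 1000, 50
        lam = rng.gamma(1 / alpha_true, alpha_true * mu, size=(G, n))
        counts = pd.DataFrame(rng.poisson(lam))
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, sf)
        res = wald_test_nb(counts, sf, disp, np.arange(n) < n // 2)
        frac = float((res["pvalue"].dropna() < 0.05).mean())
        assert abs(frac - 0.05) <= 0.02

    def test_agreement_with_lrt_oracle_tiny(self):
        # 2 genes x 4 samples: one moderate effect, one null (a moderate
        # effect keeps both tests out of the deep tail where Wald and LRT
        # legitimately diverge beyond an order of magnitude)
        counts = pd.DataFrame(
            {"s1": [60, 100], "s2": [66, 110], "s3": [20, 105], "s4": [24, 95]},
            index=["gsig", "gnull"],
        )
        sf = pd.Series(1.0, index=counts.columns)
        alpha = 0.05
        disp = pd.Series(alpha, index=counts.index)
        x = np.array([False, False, True, True])
        res = wald_test_nb(counts, sf, disp, x)
        for gene in counts.index:
            p_oracle = lrt_oracle_p(counts.loc[gene].to_numpy(), x, alpha)
            p_wald = res.loc[gene, "pvalue"]
            assert (p_wald <= 0.05) == (p_oracle <= 0.05)
            if min(p_wald, p_oracle) > 1e-300:
                assert abs(np.log10(p_wald) - np.log10(p_oracle)) < 1.0

    def test_group_validation(self, toy_counts):
        sf = pd.Series(1.0, index=toy_counts.columns)
        disp = pd.Series(0.1, index=toy_counts.index)
        with pytest.raises(ValueError, match="non-empty"):
            wald_test_nb(toy_counts, sf, disp, [True, True, True])


class TestHolm:
    def test_hand_computed_three(self):
        adj = adjust_pvalues_holm([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert adjust_pvalues_holm([0.2]).tolist() == [0.2]

    def test_all_ones(self):
        assert adjust_pvalues_holm([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_nan_passthrough(self):
        adj = adjust_pvalues_holm([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        # NaN not counted in m: m=2 here
        assert adj[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues_holm([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_properties(self, pvals):
        p = np.array(pvals)
        adj = adjust_pvalues_holm(p)
        assert (adj >= p - 1e-12).all()  # adjusted >= raw
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in raw order


class TestClassify:
    def _df(self, padj, lfc, bm):
        return pd.DataFrame({"padj": [padj], "log2FoldChange": [lfc], "baseMean": [bm]})

    @pytest.mark.parametrize(
        "padj,lfc,bm,expected",
        [
            (0.01, -7.0, 120.0, "strong_DEG"),
            (0.04, -1.5, 200.0, "weak_DEG"),
            (0.2, -8.0, 100.0, "ns"),
            (0.05, 3.0, 10.0, "strong_DEG"),  # all thresholds inclusive
            (0.01, -7.0, 9.0, "weak_DEG"),  # baseMean fails strong, passes weak
            (np.nan, -9.0, 100.0, "ns"),
        ],
    )
    def test_rules(self, padj, lfc, bm, expected):
        assert classify_degs(self._df(padj, lfc, bm)).iloc[0] == expected


class TestSummarizeTargetSet:
    def test_full_gene_set_fraction_one(self, toy_counts):
        groups = pd.Series({"s1": "WT", "s2": "double", "s3": "WT"})
        out = summarize_target_set(toy_counts, list(toy_counts.index), groups)
        assert np.allclose(out["per_sample_fraction"], 1.0)

    def test_toy_fraction(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["t", "o"])
        groups = pd.Series({"s1": "double"})
        out = summarize_target_set(counts, ["t"], groups)
        assert out["per_sample_fraction"]["s1"] == pytest.approx(0.10)

    def test_synthetic_recovery(self, small_sim):
        _, counts, truth = small_sim
        kept = [g for g, c in truth.depth_class.items() if c == "high"]
        groups = pd.Series({g: truth.genotypes[g] for g in kept})
        out = summarize_target_set(counts[kept], truth.target_genes, groups)
        wt_frac = out["per_group_fraction"]["WT"]["mean_fraction"]
        assert abs(wt_frac - 0.111) < 0.02
        assert abs(out["median_fold"] - 124.1) / 124.1 < 0.25

    def test_empty_set_rejected(self, toy_counts):
        groups = pd.Series({"s1": "double", "s2": "WT", "s3": "WT"})
        with pytest.raises(ValueError):
            summarize_target_set(toy_counts, ["nope"], groups)


class TestEndToEndRecovery:
    def test_strong_deg_recovery_on_synthetic(self, small_sim):
        _, counts, truth = small_sim
        kept = [g for g, c in truth.depth_class.items() if c == "high"]
        sub = counts[kept]
        is_double = np.array([truth.genotypes[g] == "double" for g in kept])
        res = run_differential_expression(sub, is_double)
        strong = set(res.index[res["class"] == "strong_DEG"])
        targets = set(truth.target_genes)
        assert len(strong & targets) >= 55
        assert len(strong - targets) == 0
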