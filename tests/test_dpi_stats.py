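"""DPI score and statistical machinery: interval-significance rule, bootstrap
enrichment, KS, Yates chi-square and Spearman correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dpiscope.dpi_stats import (
    bootstrap_enrichment,
    bootstrap_sample_size,
    chi2_above_below,
    dpi,
    dpi_column,
    interval_significance,
    ks_feature_test,
    set_dpi_ppi_correlation,
    spearman_corr,
    yates_chi2,
)


def _fv(DOM=0, CC10=0, IDR10=0, TMH=0, Ph=0, Ub=0, ELM=0):
    return dict(DOM=DOM, CC10=CC10, IDR10=IDR10, TMH=TMH, Ph=Ph, Ub=Ub, ELM=ELM)


class TestDPI:
    def test_featureless_protein_scores_zero(self):
        assert dpi(_fv()) == 0.0

    def test_hand_evaluated_example(self):
        # ln3 + ln2 + ln4 + ln1 + ln11 + ln5 under the ln(1+x) convention
        val = dpi(_fv(DOM=2, CC10=1, IDR10=3, TMH=0, Ph=6, Ub=4, ELM=4))
        want = math.log(3) + math.log(2) + math.log(4) + math.log(11) + math.log(5)
        assert val == pytest.approx(want)
        assert val == pytest.approx(7.185, abs=5e-4)

    def test_monotone_in_every_argument(self):
        base = _fv(DOM=2, CC10=1, IDR10=3, Ph=5, Ub=2, ELM=4)
        v0 = dpi(base)
        for key in base:
            bumped = dict(base)
            bumped[key] = base[key] * 2 + 1
            assert dpi(bumped) > v0 - 1e-12
        doubled = {k: 2 * v for k, v in base.items()}
        assert dpi(doubled) >= v0

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            dpi(_fv(DOM=-1))

    def test_drop_convention_sums_positive_terms(self):
        val = dpi(_fv(DOM=2, ELM=4), zero_convention="drop")
        assert val == pytest.approx(math.log(2) + math.log(4))
        assert dpi(_fv(), zero_convention="drop") == 0.0

    def test_column_matches_scalar(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {k: rng.integers(0, 6, 30) for k in ("DOM", "CC10", "IDR10", "TMH", "Ph", "Ub", "ELM")}
        )
        col = dpi_column(tab)
        for i in range(len(tab)):
            assert col.iloc[i] == pytest.approx(dpi(tab.iloc[i].to_dict()))

    def test_zero_iff_all_terms_zero(self):
        assert dpi(_fv(TMH=1)) > 0


class TestSpearman:
    def test_monotone_vectors(self):
        assert spearman_corr([1, 2, 3], [10, 20, 30]).statistic == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3], [30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_zero_rank_variance_raises(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])

    def test_exact_permutation_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=7)
        y = 0.8 * x + rng.normal(size=7)
        res = spearman_corr(x, y)
        rho_obs = stats.spearmanr(x, y).statistic
        assert res.statistic == pytest.approx(rho_obs)
        hits = 0
        for perm in itertools.permutations(range(7)):
            r = stats.spearmanr(x, y[list(perm)]).statistic
            hits += abs(r) >= abs(rho_obs) - 1e-12
        assert res.p_value == pytest.approx(hits / math.factorial(7))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = spearman_corr(x, y)
        ref = stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestIntervalSignificance:
    def test_three_sigma_separation(self):
        assert interval_significance(0, 1, 10, 1) == "0.01"

    def test_overlap_at_one_sigma_is_ns(self):
        assert interval_significance(0, 1, 1.5, 1) == "ns"

    def test_two_sigma_separation(self):
        # [−1,1] vs [2.3,2.7] disjoint; [−2,2] vs [2.1,2.9] disjoint;
        # [−3,3] vs [1.9,3.1] overlap -> p < 0.05
        assert interval_significance(0, 1, 2.5, 0.2) == "0.05"

    def test_symmetry(self):
        assert interval_significance(2.5, 0.2, 0, 1) == "0.05"

    def test_negative_sd_raises(self):
        with pytest.raises(ValueError):
            interval_significance(0, -1, 1, 1)


class TestBootstrapEnrichment:
    def test_sample_size_rule_rounds_half_up(self):
        assert bootstrap_sample_size(51) == 41
        assert bootstrap_sample_size(51, rule="floor") == 40

    def test_constant_double_gives_exact_log2_sd_zero(self):
        sub = pd.DataFrame({"f": np.full(30, 4.0)})
        ref = pd.DataFrame({"f": np.full(50, 2.0)})
        (res,) = bootstrap_enrichment(sub, ref, n_rep=100, sample_size=10, seed=0)
        assert res.log_ratio_mean == pytest.approx(math.log(2))
        assert res.log_ratio_sd == 0.0
        assert res.p_level == "0.01"

    def test_zero_reference_mean_flagged_not_dropped(self):
        sub = pd.DataFrame({"f": np.ones(20)})
        ref = pd.DataFrame({"f": np.zeros(20)})
        (res,) = bootstrap_enrichment(sub, ref, n_rep=50, sample_size=5, seed=0)
        assert res.undefined and res.undefined_replicates == 50

    def test_null_self_comparison_mostly_insignificant(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({f"f{i}": rng.poisson(3, 150) for i in range(8)})
        sig = tot = 0
        for seed in range(25):
            for r in bootstrap_enrichment(tab, tab, n_rep=300, sample_size=41, seed=seed):
                tot += 1
                sig += r.p_level in ("0.05", "0.01")
        assert sig / tot <= 0.10

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame({"f": rng.poisson(4, 60)})
        b = pd.DataFrame({"f": rng.poisson(2, 60)})
        r1 = bootstrap_enrichment(a, b, n_rep=200, sample_size=20, seed=9)
        r2 = bootstrap_enrichment(a, b, n_rep=200, sample_size=20, seed=9)
        assert r1[0].log_ratio_mean == r2[0].log_ratio_mean


class TestKS:
    def test_identical_samples(self):
        res = ks_feature_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert ks_feature_test([0, 0, 0, 0], [1, 1, 1, 1]).statistic == 1.0

    def test_matches_ecdf_sweep_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=10), rng.normal(size=10)
        grid = np.concatenate([a, b])
        d = max(
            abs((a <= t).mean() - (b <= t).mean()) for t in grid
        )
        assert ks_feature_test(a, b).statistic == pytest.approx(d, abs=1e-12)

    def test_invariant_under_common_monotone_transform(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=25), rng.normal(0.5, 1, size=25)
        d0 = ks_feature_test(a, b).statistic
        d1 = ks_feature_test(np.exp(a), np.exp(b)).statistic
        assert d0 == pytest.approx(d1)


def _yates_oracle(a, b, c, d):
    n = a + b + c + d
    num = n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


class TestChiSquare:
    def test_independence_table(self):
        res = yates_chi2([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        assert yates_chi2([[30, 10], [10, 30]]).statistic == pytest.approx(18.05)

    def test_row_swap_symmetry(self):
        s1 = yates_chi2([[30, 10], [5, 25]]).statistic
        s2 = yates_chi2([[5, 25], [30, 10]]).statistic
        assert s1 == pytest.approx(s2)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            yates_chi2([[0, 0], [5, 5]])

    def test_above_below_contingency_construction(self):
        sub = pd.DataFrame({"f": [5, 5, 1]})
        comp = pd.DataFrame({"f": [1, 1, 5]})
        res = chi2_above_below(sub, comp, "f", threshold=3.0)
        assert res.statistic == pytest.approx(_yates_oracle(2, 1, 1, 2))

    def test_small_margin_oracle_equivalence(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            got = yates_chi2([[a, b], [c, d]]).statistic
            assert got == pytest.approx(_yates_oracle(a, b, c, d), abs=1e-9)


class TestSetLevelCorrelation:
    def _tables(self, means):
        rng = np.random.default_rng(0)
        out = []
        for dm, pm in means:
            out.append(
                pd.DataFrame(
                    {"dpi": np.full(20, dm) + rng.normal(0, 1e-6, 20),
                     "ppi_degree": np.full(20, pm)}
                )
            )
        return out

    def test_needs_three_sets(self):
        with pytest.raises(ValueError):
            set_dpi_ppi_correlation(self._tables([(1, 1), (2, 2)]))

    def test_identical_means_undefined(self):
        with pytest.raises(ValueError):
            set_dpi_ppi_correlation(
                [pd.DataFrame({"dpi": [1.0] * 5, "ppi_degree": [2.0] * 5})] * 3
            )

    def test_concordant_means_give_rho_one(self):
        tabs = self._tables([(1, 10), (2, 20), (3, 30), (4, 40)])
        assert set_dpi_ppi_correlation(tabs).statistic == pytest.approx(1.0)
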