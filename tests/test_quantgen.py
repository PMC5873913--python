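import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dendrogwas import quantgen
from dendrogwas.quantgen import (
    RepeatabilityEstimate,
    anova_oneway,
    correlation_matrices,
    duncan_letters,
    reml_repeatability,
    repeatability_ratio,
    rm_anova,
    select_subset_qd,
    standardize_response,
    standardize_response_table,
)


class TestAnova:
    def test_hand_computed_table(self):
        # groups {1,2,3} and {2,3,4}: SSB = 1.5, SSW = 4, df = (1, 4)
        res = anova_oneway([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert res.f == pytest.approx(1.5)
        assert res.p == pytest.approx(stats.f.sf(1.5, 1, 4))
        assert res.group_means == {"a": 2.0, "b": 3.0}
        assert res.df_between == 1 and res.df_within == 4
        assert res.mse == pytest.approx(1.0)

    def test_equal_group_means_zero_f(self):
        res = anova_oneway([2.0, 3.0, 2.0, 3.0], ["a", "a", "b", "b"])
        assert res.f == 0.0

    def test_small_group_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            res = anova_oneway([1, 2, 3, 4, 9], ["a", "a", "b", "b", "c"])
        assert "c" not in res.group_means

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1, 2, 3], ["a", "a", "a"])

    def test_permutation_null_p_uniform(self, rng):
        # shuffled labels on null data: ANOVA p should be uniform
        y = rng.normal(size=24)
        labels = np.array(["a", "b", "c"] * 8)
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(labels)
            pvals.append(anova_oneway(y, perm).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestRmAnova:
    def test_type_one_error_rate(self, rng):
        hits = 0
        reps = 500
        for _ in range(reps):
            y = rng.normal(size=(24, 3))
            responses = pd.DataFrame(y, index=[f"i{j}" for j in range(24)])
            groups = pd.Series(["a", "b", "c"] * 8, index=responses.index)
            _, p = rm_anova(responses, groups)
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_large_effect_detected(self, rng):
        detected = 0
        reps = 200
        for _ in range(reps):
            shift = np.repeat([0.0, 2.0, 4.0], 8)  # 2 SD steps between groups
            y = rng.normal(size=(24, 3)) + shift[:, None]
            responses = pd.DataFrame(y, index=[f"i{j}" for j in range(24)])
            groups = pd.Series(np.repeat(["a", "b", "c"], 8), index=responses.index)
            _, p = rm_anova(responses, groups)
            detected += p < 1e-3
        assert detected / reps >= 0.99

    def test_perfect_repetition_equals_oneway_on_means(self, rng):
        base = rng.normal(size=18)
        responses = pd.DataFrame(
            {"e1": base, "e2": base, "e3": base}, index=[f"i{j}" for j in range(18)]
        )
        groups = pd.Series(["a", "b", "c"] * 6, index=responses.index)
        f_rm, _ = rm_anova(responses, groups)
        f_ow = anova_oneway(base, groups.to_numpy()).f
        assert f_rm == pytest.approx(f_ow)

    def test_single_event_rejected(self):
        responses = pd.DataFrame({"e1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="anova_oneway"):
            rm_anova(responses, pd.Series(["x", "y"], index=["a", "b"]))


def _duncan_oracle(means, mse, df, n, alpha=0.05):
    """Independent step-by-step textbook multiple-range procedure."""
    labels = sorted(means, key=lambda g: -means[g])
    m = len(labels)
    nonsig = []
    for span in range(m, 1, -1):
        q = stats.studentized_range.ppf((1 - alpha) ** (span - 1), span, df)
        for i in range(m - span + 1):
            j = i + span - 1
            if any(lo <= i and j <= hi for lo, hi in nonsig):
                continue
            if means[labels[i]] - means[labels[j]] <= q * math.sqrt(mse / n):
                nonsig.append((i, j))
    groups = [iv for iv in nonsig if not any(
        lo <= iv[0] and iv[1] <= hi and iv != (lo, hi) for lo, hi in nonsig
    )]
    for i in range(m):
        if not any(lo <= i <= hi for lo, hi in groups):
            groups.append((i, i))
    letters = {g: "" for g in labels}
    for idx, (lo, hi) in enumerate(sorted(groups)):
        for i in range(lo, hi + 1):
            letters[labels[i]] += chr(ord("a") + idx)
    return letters


class TestDuncan:
    def test_all_equal_means_share_letter(self):
        means = {g: 5.0 for g in "abcd"}
        letters = duncan_letters(means, 1.0, 20, {g: 6 for g in "abcd"})
        assert len(set(letters.values())) == 1

    def test_widely_separated_means_distinct(self):
        # 10 standard errors apart
        letters = duncan_letters({"a": 0.0, "b": 10.0}, 4.0, 10, {"a": 4, "b": 4})
        assert letters["a"] != letters["b"]

    def test_four_group_fixture_matches_stepwise_oracle(self):
        means = {"a": 9.8, "b": 15.4, "c": 17.6, "d": 21.6}
        mse, df, n = 8.06, 16, 5
        ours = duncan_letters(means, mse, df, {g: n for g in means})
        oracle = _duncan_oracle(means, mse, df, n)
        assert ours == oracle

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(6):
            k = int(rng.integers(3, 7))
            means = {f"g{i}": float(rng.normal(0, 2)) for i in range(k)}
            ours = duncan_letters(means, 1.3, 30, {g: 7 for g in means})
            oracle = _duncan_oracle(means, 1.3, 30, 7)
            assert ours == oracle

    def test_zero_mse_rejected(self):
        with pytest.raises(ValueError):
            duncan_letters({"a": 1.0, "b": 2.0}, 0.0, 10, {"a": 3, "b": 3})


class TestStandardize:
    def test_all_equal_values_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            standardize_response(pd.Series([1.0, 1.0, 1.0]), "Rt")

    def test_log_linearizes_exponentials(self):
        e = math.e
        out = standardize_response(pd.Series([e, e**2, e**3]), "Rt")
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_output_is_standardized(self, rng):
        out = standardize_response(pd.Series(rng.lognormal(0, 0.4, 40)), "Rs")
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_value_names_culprit(self):
        s = pd.Series([0.5, -0.1, 0.8], index=["t1", "t2", "t3"])
        with pytest.raises(ValueError, match="t2"):
            standardize_response(s, "Rt")

    def test_rrs_not_logged(self):
        out = standardize_response(pd.Series([-0.5, 0.0, 0.5]), "rRs")
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_table_helper_handles_all_kinds(self, rng):
        df = pd.DataFrame(
            {
                "Rt93": rng.lognormal(0, 0.3, 20),
                "rRs93": rng.normal(0, 0.3, 20),
            }
        )
        out = standardize_response_table(df)
        assert out.shape == df.shape


class TestReml:
    def test_published_component_ratio(self):
        # sigma_ind 0.304, sigma_res 0.575 -> r = 0.346 (reference Rt cell)
        assert repeatability_ratio(0.304, 0.575) == pytest.approx(0.346, abs=5e-4)

    def test_balanced_design_matches_closed_form(self, rng):
        n_ind, k = 10, 3
        a = rng.normal(0, 1.0, n_ind)
        y = (a[:, None] + rng.normal(0, 0.8, (n_ind, k))).ravel()
        ids = np.repeat(np.arange(n_ind), k)
        vc, _ = reml_repeatability(y, ids)
        Y = y.reshape(n_ind, k)
        msb = k * np.var(Y.mean(axis=1), ddof=1)
        msw = float(np.mean(np.var(Y, axis=1, ddof=1)))
        closed = max(0.0, (msb - msw) / k)
        assert vc.sigma2_ind == pytest.approx(closed, abs=1e-6)
        assert vc.sigma2_res == pytest.approx(msw, abs=1e-6)

    def test_identical_repeats_boundary(self, rng):
        y = np.repeat(rng.normal(0, 1, 8), 3)
        vc, est = reml_repeatability(y, np.repeat(np.arange(8), 3))
        assert est.r == 1.0
        assert vc.sigma2_res == 0.0

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            reml_repeatability([1.0, 2.0, 1.5, 2.5], ["a", "a", "b", "b"])

    def test_overall_model_denominator_includes_provenance(self, rng):
        prov = np.repeat(["p1", "p2", "p3"], 30)
        ind = np.repeat(np.arange(30), 3)
        prov_eff = {"p1": -1.0, "p2": 0.0, "p3": 1.0}
        a = rng.normal(0, 0.6, 30)
        y = np.array([prov_eff[p] for p in prov]) + a[ind] + rng.normal(0, 0.8, 90)
        vc, est = reml_repeatability(y, ind, prov)
        assert vc.sigma2_prov is not None and vc.sigma2_prov > 0
        expect = vc.sigma2_ind / (vc.sigma2_prov + vc.sigma2_ind + vc.sigma2_res)
        assert est.r == pytest.approx(expect)

    def test_parameter_recovery_within_one_se(self, rng):
        for true_r in (0.1, 0.3, 0.5):
            estimates, ses = [], []
            for _ in range(120):
                a = rng.normal(0, math.sqrt(true_r), 30)
                y = (a[:, None] + rng.normal(0, math.sqrt(1 - true_r), (30, 3))).ravel()
                vc, est = reml_repeatability(y, np.repeat(np.arange(30), 3))
                estimates.append(est.r)
                ses.append(est.se_r if est.se_r > 0 else np.nan)
            mean_se = np.nanmean(ses)
            assert abs(np.mean(estimates) - true_r) <= mean_se

    def test_r_close_to_mean_pairwise_correlation(self, rng):
        true_r = 0.4
        a = rng.normal(0, math.sqrt(true_r), 400)
        Y = a[:, None] + rng.normal(0, math.sqrt(1 - true_r), (400, 3))
        y = Y.ravel()
        _, est = reml_repeatability(y, np.repeat(np.arange(400), 3))
        cors = [np.corrcoef(Y[:, i], Y[:, j])[0, 1] for i in range(3) for j in range(i + 1, 3)]
        assert est.r == pytest.approx(np.mean(cors), abs=0.05)

    def test_lrt_size_under_null(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            y = rng.normal(size=60)
            _, est = reml_repeatability(y, np.repeat(np.arange(20), 3))
            hits += est.significant
        mc_se = math.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 2 * mc_se


class TestSubsetQD:
    @staticmethod
    def _est(sig):
        return RepeatabilityEstimate(r=0.2, se_r=0.1, significant=sig, scope="per-provenance")

    def test_published_significance_pattern(self):
        # reference significance pattern for Rt across the 11 provenances
        pattern = {
            "b03": False, "d04": False, "R06": True, "ST": False, "X05": False,
            "d14": True, "I19": True, "Q14": True, "R13": True, "S10": True,
            "Y18": False,
        }
        subset = select_subset_qd({k: self._est(v) for k, v in pattern.items()})
        assert subset == sorted(["R06", "d14", "I19", "Q14", "R13", "S10"])

    def test_empty_subset_warns(self, caplog):
        with caplog.at_level("WARNING"):
            subset = select_subset_qd({"a": self._est(False)})
        assert subset == []
        assert any("SubsetQD" in r.message for r in caplog.records)

    def test_all_significant_full_set(self):
        subset = select_subset_qd({k: self._est(True) for k in "abc"})
        assert subset == ["a", "b", "c"]


class TestCorrelationMatrices:
    def test_unit_diagonal(self, rng):
        traits = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        prov = pd.Series(["a", "b", "c"] * 10, index=traits.index)
        per_prov, overall, _ = correlation_matrices(traits, prov)
        np.testing.assert_allclose(np.diag(overall), 1.0)
        for m in per_prov.values():
            np.testing.assert_allclose(np.diag(m.dropna(how="all")), 1.0)

    def test_identical_provenances_zero_range(self, rng):
        block = rng.normal(size=(12, 3))
        traits = pd.DataFrame(np.vstack([block, block]), columns=list("xyz"))
        prov = pd.Series(["a"] * 12 + ["b"] * 12, index=traits.index)
        _, _, rng_matrix = correlation_matrices(traits, prov)
        np.testing.assert_allclose(rng_matrix.to_numpy(), 0.0, atol=1e-12)

    def test_range_is_difference_of_extremes(self, rng):
        def correlated(n, r, gen):
            x = gen.normal(size=n)
            z = gen.normal(size=n)
            z = z - z @ x / (x @ x) * x  # exact empirical orthogonality
            x = (x - x.mean()) / x.std()
            z = (z - z.mean()) / z.std()
            return x, r * x + math.sqrt(1 - r * r) * z

        gen = np.random.default_rng(3)
        x1, y1 = correlated(40, 0.62, gen)
        x2, y2 = correlated(40, -0.55, gen)
        traits = pd.DataFrame(
            {"t1": np.concatenate([x1, x2]), "t2": np.concatenate([y1, y2])}
        )
        prov = pd.Series(["a"] * 40 + ["b"] * 40, index=traits.index)
        _, _, rng_matrix = correlation_matrices(traits, prov)
        assert rng_matrix.loc["t1", "t2"] == pytest.approx(1.17, abs=0.02)

    def test_sparse_cells_degrade_to_missing(self, rng):
        traits = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "y"])
        traits.loc[traits.index[:8], "y"] = np.nan
        prov = pd.Series(["a"] * 10, index=traits.index)
        _, overall, _ = correlation_matrices(traits, prov, min_pairs=5)
        assert np.isnan(overall.loc["x", "y"])
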