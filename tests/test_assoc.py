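import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from dendrogwas import assoc
from dendrogwas.assoc import (
    MarkerFit,
    bonferroni_threshold,
    flag_single_individual,
    marker_r2,
    mlm_qk_scan,
    mlm_single,
    qq_data,
    stars_for,
)
from dendrogwas.io_core import GenotypeMatrix, KinshipMatrix, QMatrix


def reml_grid_oracle(y, x, K, Q=None, n_points=2001, refine=True):
    """Independent brute-force REML maximization by dense grid search over
    log delta in [-10, 10], optionally polished by scalar minimization."""
    n = len(y)
    W = np.ones((n, 1)) if Q is None else np.column_stack([np.ones(n), Q.q[:, :-1]])
    Z = np.column_stack([W, x])
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0, None)
    yt, Zt = U.T @ np.asarray(y, dtype=float), U.T @ Z
    p = Z.shape[1]
    df = n - p

    def negll(ld):
        d = math.exp(ld)
        w = 1 / (s + d)
        A = Zt.T @ (Zt * w[:, None])
        rhs = Zt.T @ (w * yt)
        beta = np.linalg.solve(A, rhs)
        rss = w @ (yt**2) - rhs @ beta
        return 0.5 * (
            df * (math.log(2 * math.pi * rss / df) + 1)
            + np.log(s + d).sum()
            + np.linalg.slogdet(A)[1]
        )

    grid = np.linspace(-10, 10, n_points)
    vals = np.array([negll(ld) for ld in grid])
    i = int(np.argmin(vals))
    ld = grid[i]
    if refine and 0 < i < n_points - 1:
        res = optimize.minimize_scalar(
            negll, bracket=(grid[i - 1], grid[i], grid[i + 1]), method="brent",
            options={"xtol": 1e-12},
        )
        ld = float(res.x)
    d = math.exp(ld)
    w = 1 / (s + d)
    A = Zt.T @ (Zt * w[:, None])
    rhs = Zt.T @ (w * yt)
    beta = np.linalg.solve(A, rhs)
    rss = w @ (yt**2) - rhs @ beta
    var_b = rss / df * np.linalg.inv(A)[-1, -1]
    f = beta[-1] ** 2 / var_b
    return float(stats.f.sf(f, 1, df))


def _instance(rng, n=20, beta=0.4, with_q=True):
    ids = [f"i{j}" for j in range(n)]
    A = rng.normal(size=(n, 2 * n))
    K = A @ A.T / (2 * n)
    x = rng.binomial(2, 0.4, n).astype(float)
    Q = None
    eta = 0.0
    if with_q:
        q1 = rng.uniform(0.2, 0.8, n)
        Q = QMatrix(ids, np.column_stack([q1, 1 - q1]))
        eta = 0.3 * q1
    u = np.linalg.cholesky(K + 1e-8 * np.eye(n)) @ rng.normal(size=n)
    y = pd.Series(0.5 + eta + beta * x + u + rng.normal(0, 1, n), index=ids)
    return ids, y, x, K, Q


class TestBonferroni:
    def test_published_thresholds_all_provenances(self):
        t05 = bonferroni_threshold(0.05, 1714)
        t001 = bonferroni_threshold(0.001, 1714)
        assert f"{t05:.2e}" == "2.92e-05"
        assert f"{t001:.2e}" == "5.83e-07"

    def test_published_threshold_subset(self):
        assert f"{bonferroni_threshold(0.05, 1707):.2e}" == "2.93e-05"

    def test_single_marker_is_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_star_labels(self):
        m = 1714
        assert stars_for(1e-8, m) == "***"
        assert stars_for(1e-6, m) == "**"
        assert stars_for(1e-5, m) == "*"
        assert stars_for(4e-5, m) == "+"
        assert stars_for(0.01, m) == ""


class TestMlm:
    def test_identity_kinship_equals_ols(self, rng):
        ids, y, x, _, _ = _instance(rng, n=25, with_q=False)
        K = KinshipMatrix(ids, np.eye(25))
        fit = mlm_single(y, x, K, None)
        # ordinary simple-regression F test
        X = np.column_stack([np.ones(25), x])
        beta, rss, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        df = 25 - 2
        cov = np.linalg.inv(X.T @ X) * rss[0] / df
        f = beta[1] ** 2 / cov[1, 1]
        p_ols = stats.f.sf(f, 1, df)
        assert abs(fit.p - p_ols) < 1e-8

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(8):
            ids, y, x, K, Q = _instance(rng)
            fit = mlm_single(y, x, KinshipMatrix(ids, K), Q)
            p_oracle = reml_grid_oracle(y.to_numpy(), x, K, Q)
            assert abs(fit.p - p_oracle) < 1e-6

    def test_p_f_distribution_relation(self, rng):
        ids, y, x, K, Q = _instance(rng)
        fit = mlm_single(y, x, KinshipMatrix(ids, K), Q)
        assert fit.p == pytest.approx(
            float(stats.f.sf(fit.f, 1, fit.n - fit.rank_fixed)), rel=1e-12
        )

    def test_causal_marker_ranked_first(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            n, m = 72, 40
            ids = [f"i{j}" for j in range(n)]
            X = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(np.int8)
            A = rng.normal(size=(n, n))
            K = A @ A.T / n
            x = X[:, 0].astype(float)
            # effect explaining ~30% of trait variance
            beta = math.sqrt(0.3 / 0.7 / max(x.var(), 0.1))
            u = np.linalg.cholesky(K + 1e-8 * np.eye(n)) @ rng.normal(0, 0.4, n)
            y = pd.Series(beta * x + u + rng.normal(0, math.sqrt(1 - 0.16), n), index=ids)
            G = GenotypeMatrix(ids, [f"m{j}" for j in range(m)], X)
            res = mlm_qk_scan(
                pd.DataFrame({"t": y}), G, None, KinshipMatrix(ids, K), flag_singles=False
            )
            hits += res.sort_values("p").iloc[0]["marker"] == "m0"
        assert hits / reps >= 0.95

    def test_scaling_convention_invariance(self, rng):
        ids, y, x, K, Q = _instance(rng, n=30)
        fit1 = mlm_single(y, x, KinshipMatrix(ids, K), Q)
        fit2 = mlm_single(y, x, KinshipMatrix(ids, 3.7 * K), Q)
        assert abs(fit1.p - fit2.p) < 1e-6

    def test_monomorphic_marker_untestable(self, rng):
        ids, y, _, K, Q = _instance(rng)
        fit = mlm_single(y, np.ones(len(ids)), KinshipMatrix(ids, K), Q)
        assert not fit.testable

    def test_non_psd_kinship_rejected(self, rng):
        ids, y, x, K, Q = _instance(rng)
        bad = K - 2 * np.eye(len(ids))
        with pytest.raises(ValueError, match="PSD"):
            mlm_single(y, x, KinshipMatrix(ids, bad), Q)


class TestTypeIError:
    def test_structure_correction_vs_naive_ols(self):
        rng = np.random.default_rng(99)
        n, m, n_traits = 120, 150, 12
        ids = [f"i{j}" for j in range(n)]
        cluster = np.repeat([0, 1], n // 2)
        p_anc = rng.uniform(0.1, 0.5, m)
        shift = rng.normal(0, 0.12, m)
        freqs = np.clip(np.vstack([p_anc - shift / 2, p_anc + shift / 2]), 0.02, 0.98)
        X = rng.binomial(2, freqs[cluster]).astype(np.int8)
        q1 = np.clip(cluster + rng.normal(0, 0.05, n), 0, 1)
        Q = QMatrix(ids, np.column_stack([q1, 1 - q1]))
        Xc = X - X.mean(axis=0)
        K = Xc @ Xc.T / np.sum(2 * X.mean(axis=0) / 2 * (1 - X.mean(axis=0) / 2))
        Km = KinshipMatrix(ids, K)
        # null traits driven only by structure + polygenic background
        traits = {}
        for t in range(n_traits):
            u = np.linalg.cholesky(K + 1e-6 * np.eye(n)) @ rng.normal(0, 0.7, n)
            traits[f"t{t}"] = 1.5 * cluster + u + rng.normal(0, 1, n)
        tdf = pd.DataFrame(traits, index=ids)
        G = GenotypeMatrix(ids, [f"m{j}" for j in range(m)], X)
        res = mlm_qk_scan(tdf, G, Q, Km, flag_singles=False)
        thr = bonferroni_threshold(0.05, m)
        mlm_hits = int((res["p"] < thr).sum())
        # naive per-marker OLS on the same grid
        ols_hits = 0
        for t in tdf.columns:
            y = tdf[t].to_numpy()
            for j in range(m):
                x = X[:, j].astype(float)
                Xd = np.column_stack([np.ones(n), x])
                beta, rss, *_ = np.linalg.lstsq(Xd, y, rcond=None)
                cov = np.linalg.inv(Xd.T @ Xd) * rss[0] / (n - 2)
                f = beta[1] ** 2 / cov[1, 1]
                ols_hits += stats.f.sf(f, 1, n - 2) < thr
        expected = 0.05 * n_traits  # expected false positives over all traits
        assert mlm_hits <= max(2, 2 * expected)
        assert ols_hits > 5 * max(1, mlm_hits)


class TestMarkerR2:
    def test_zero_effect_zero_r2(self):
        fit = MarkerFit(
            n=20, rank_fixed=2, beta=0.0, se=1.0, f=0.0, p=1.0, sigma2_g=1.0,
            sigma2_e=1.0, delta=1.0, rss_full=5.0, rss_reduced=5.0, tss=10.0,
        )
        assert marker_r2(fit) == 0.0

    def test_identity_kinship_matches_ols_partial_r2(self, rng):
        n = 30
        ids = [f"i{j}" for j in range(n)]
        x = rng.binomial(2, 0.4, n).astype(float)
        y = pd.Series(0.5 * x + rng.normal(0, 1, n), index=ids)
        fit = mlm_single(y, x, KinshipMatrix(ids, np.eye(n)), None)
        yv = y.to_numpy()
        X = np.column_stack([np.ones(n), x])
        rss1 = yv @ yv - yv @ X @ np.linalg.lstsq(X, yv, rcond=None)[0]
        tss = ((yv - yv.mean()) ** 2).sum()
        assert marker_r2(fit) == pytest.approx((tss - rss1) / tss, rel=1e-6)

    def test_monotone_in_f_for_fixed_df(self, rng):
        n, m = 40, 25
        ids = [f"i{j}" for j in range(n)]
        K = KinshipMatrix(ids, np.eye(n))
        y = pd.Series(rng.normal(size=n), index=ids)
        fits = [
            mlm_single(y, rng.binomial(2, 0.4, n).astype(float), K, None) for _ in range(m)
        ]
        fits = [f for f in fits if f.testable]
        order = np.argsort([f.f for f in fits])
        r2 = np.array([marker_r2(f) for f in fits])[order]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_zero_tss_rejected(self):
        fit = MarkerFit(
            n=20, rank_fixed=2, beta=0.0, se=1.0, f=0.0, p=1.0, sigma2_g=1.0,
            sigma2_e=1.0, delta=1.0, rss_full=0.0, rss_reduced=0.0, tss=0.0,
        )
        with pytest.raises(ValueError):
            marker_r2(fit)


class TestQQ:
    def test_exact_uniform_quantiles_on_identity(self):
        m = 100
        p = (np.arange(1, m + 1) - 0.5) / m
        df = qq_data(p)
        np.testing.assert_allclose(df["expected"], df["observed"], atol=1e-12)

    def test_single_value(self):
        df = qq_data([0.5])
        assert df.loc[0, "expected"] == pytest.approx(-math.log10(0.5))
        assert df.loc[0, "observed"] == pytest.approx(-math.log10(0.5))

    def test_uniform_simulation_close_to_identity(self, rng):
        p = rng.uniform(size=10_000)
        df = qq_data(p)
        body = df[df["expected"] < 3]
        assert (body["observed"] - body["expected"]).abs().max() < 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qq_data([])


class TestFlagSingle:
    def _setup(self, rng, outlier: bool):
        n = 40
        ids = [f"i{j}" for j in range(n)]
        x = np.zeros(n)
        if outlier:
            x[0] = 2.0  # single minor-genotype carrier ...
            y = rng.normal(0, 0.5, n)
            y[0] = 8.0  # ... with an extreme trait value
        else:
            x[:12] = 1.0  # effect spread over 12 carriers
            y = rng.normal(0, 0.5, n) + 2.5 * x
        K = KinshipMatrix(ids, np.eye(n))
        G = GenotypeMatrix(ids, ["mx"], x.astype(np.int8).reshape(-1, 1))
        return pd.Series(y, index=ids), G, K

    def test_outlier_driven_hit_flagged(self, rng):
        y, G, K = self._setup(rng, outlier=True)
        fit = mlm_single(y, G.column("mx").astype(float), K, None)
        assert fit.p < 1e-4
        assert flag_single_individual(y, G, None, K, "mx", threshold=1e-4)

    def test_spread_effect_not_flagged(self, rng):
        y, G, K = self._setup(rng, outlier=False)
        assert not flag_single_individual(y, G, None, K, "mx", threshold=1e-4)

    def test_non_significant_input_rejected(self, rng):
        n = 40
        ids = [f"i{j}" for j in range(n)]
        y = pd.Series(rng.normal(size=n), index=ids)
        x = rng.binomial(2, 0.4, n).astype(np.int8)
        G = GenotypeMatrix(ids, ["mx"], x.reshape(-1, 1))
        K = KinshipMatrix(ids, np.eye(n))
        with pytest.raises(ValueError, match="significant"):
            flag_single_individual(y, G, None, K, "mx", threshold=1e-12)


class TestScanFrame:
    def test_scan_row_contract(self, rng):
        n, m = 30, 10
        ids = [f"i{j}" for j in range(n)]
        X = rng.binomial(2, 0.4, (n, m)).astype(np.int8)
        X[0, 3] = -1  # one missing call
        G = GenotypeMatrix(ids, [f"m{j}" for j in range(m)], X)
        K = KinshipMatrix(ids, np.eye(n))
        y = pd.Series(rng.normal(size=n), index=ids)
        res = mlm_qk_scan(pd.DataFrame({"t": y}), G, None, K, flag_singles=False)
        assert len(res) == m
        assert res.loc[res["marker"] == "m3", "n"].item() == n - 1
        ok = res[res["testable"]]
        assert ((ok["p"] > 0) & (ok["p"] <= 1)).all()
        assert ((ok["rsq_marker"] >= 0) & (ok["rsq_marker"] <= 1)).all()
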