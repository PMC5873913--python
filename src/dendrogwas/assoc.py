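"""Exact per-marker mixed-linear-model association with Q and K (MLM+Q+K).

Model per marker: y = 1*mu + Q* v + x beta + u + e with u ~ N(0, sigma_g^2 K)
and e ~ N(0, sigma_e^2 I); Q* drops the last admixture column to stay
full-rank beside the intercept.  The variance ratio delta = sigma_e^2 /
sigma_g^2 is re-estimated for every marker by REML (no compression, no P3D):
a spectral decomposition of K — cached per missingness pattern — turns each
evaluation into weighted least squares, and delta is optimized on a coarse
log-grid, a fine local grid, and a final quadratic refinement.  beta is tested
with an F test at denominator df = n - rank(fixed effects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MISSING, GenotypeMatrix, KinshipMatrix, QMatrix, get_logger

log = get_logger("assoc")

LOG_DELTA_RANGE = (-10.0, 10.0)
STAR_LABELS = {0.001: "***", 0.01: "**", 0.05: "*", 0.1: "+"}
DEFAULT_ALPHA_LEVELS = (0.001, 0.01, 0.05, 0.1)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test p threshold alpha / m."""
    if m < 1:
        raise ValueError("number of markers must be >= 1")
    return alpha / m


def stars_for(p: float, m: int, alpha_levels=DEFAULT_ALPHA_LEVELS) -> str:
    """Star label for the most stringent Bonferroni level the p value passes."""
    for alpha in sorted(alpha_levels):
        if p < bonferroni_threshold(alpha, m):
            return STAR_LABELS.get(alpha, f"a{alpha}")
    return ""


def qq_data(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a Q-Q plot.

    Observed values are sorted descending in -log10 p; expected quantiles are
    -log10((i - 0.5) / m).
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p values")
    obs = np.sort(-np.log10(p))[::-1]
    m = len(obs)
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return pd.DataFrame({"expected": exp, "observed": obs})


@dataclass
class MarkerFit:
    """Internals of one per-marker mixed-model fit."""

    n: int
    rank_fixed: int
    beta: float
    se: float
    f: float
    p: float
    sigma2_g: float
    sigma2_e: float
    delta: float
    rss_full: float
    rss_reduced: float
    tss: float
    testable: bool = True
    reason: str = ""


def marker_r2(fit: MarkerFit) -> float:
    """Marker R^2 on the whitened scale at the marker's variance optimum:
    (RSS without marker - RSS with marker) / total corrected SS."""
    if not fit.testable:
        return float("nan")
    if fit.tss <= 0:
        raise ValueError("zero total corrected SS on the whitened scale")
    return max(0.0, (fit.rss_reduced - fit.rss_full) / fit.tss)


class _Pattern:
    """Spectral cache for one missingness pattern of one trait's individuals.

    All quantities that do not depend on the marker column — the rotated
    covariates, their pairwise cross-products, and the weight grid with its
    log-determinant term — are computed once, so a per-marker REML profile
    costs one small matrix product per delta grid.
    """

    def __init__(self, y, W, K, grid):
        n = len(y)
        s, U = np.linalg.eigh(K)
        if s[0] < -1e-8 * max(1.0, s[-1]):
            raise ValueError(f"kinship not PSD: min eigenvalue {s[0]:.3e}")
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.n = n
        self.y = U.T @ y
        self.W = U.T @ W
        self.one = U.T @ np.ones(n)
        self.grid = grid
        self.p0 = self.W.shape[1]
        self.iu0 = np.triu_indices(self.p0)
        # constant cross-products: W_a*W_b (upper triangle), W_a*y, y*y
        self.M_const = np.column_stack(
            [
                self.W[:, self.iu0[0]] * self.W[:, self.iu0[1]],
                self.W * self.y[:, None],
                self.y * self.y,
            ]
        )
        self.wgrid = self._weights(grid)
        self.logS = np.log(self.s[None, :] + np.exp(grid)[:, None]).sum(axis=1)
        self.C_const = self.wgrid @ self.M_const

    def _weights(self, grid):
        return 1.0 / (self.s[None, :] + np.exp(grid)[:, None])  # (d, n)

    def transform_marker(self, x):
        return self.U.T @ x

    def marker_products(self, x):
        """Marker-dependent cross-products: W*x, x*x, x*y."""
        return np.column_stack([self.W * x[:, None], x * x, x * self.y])


def _reml_profile(
    pat: _Pattern,
    C_const: np.ndarray,
    C_var: np.ndarray | None,
    logS: np.ndarray,
):
    """Restricted log-likelihood over a delta grid (batched over the grid).

    ``C_const``/``C_var`` are the weight-grid contractions of the constant and
    marker cross-product columns; ``C_var`` None means the no-marker design.
    """
    p0 = pat.p0
    t0 = len(pat.iu0[0])
    p = p0 + (1 if C_var is not None else 0)
    d = C_const.shape[0]
    A = np.empty((d, p, p))
    A[:, pat.iu0[0], pat.iu0[1]] = C_const[:, :t0]
    A[:, pat.iu0[1], pat.iu0[0]] = C_const[:, :t0]
    rhs = np.empty((d, p))
    rhs[:, :p0] = C_const[:, t0 : t0 + p0]
    yWy = C_const[:, -1]
    if C_var is not None:
        A[:, :p0, p - 1] = C_var[:, :p0]
        A[:, p - 1, :p0] = C_var[:, :p0]
        A[:, p - 1, p - 1] = C_var[:, p0]
        rhs[:, p - 1] = C_var[:, p0 + 1]
    try:
        beta = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        return np.full(d, -np.inf), None, None
    rss = yWy - np.einsum("dp,dp->d", rhs, beta)
    sign, logdetA = np.linalg.slogdet(A)
    df = pat.n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = -0.5 * (df * (np.log(2 * math.pi * rss / df) + 1) + logS + logdetA)
    ll[(sign <= 0) | ~(rss > 0)] = -np.inf
    return ll, rss, beta


def _wls(y, Z, w):
    """Weighted least squares: returns (rss, beta, A)."""
    ZW = Z * w[:, None]
    A = ZW.T @ Z
    rhs = ZW.T @ y
    beta = np.linalg.solve(A, rhs)
    rss = float(w @ (y * y) - rhs @ beta)
    return rss, beta, A


def _fit_marker(pat: _Pattern, x_t: np.ndarray) -> MarkerFit:
    """Optimize REML over delta and test the marker coefficient."""
    n = pat.n
    p = pat.p0 + 1
    M_var = pat.marker_products(x_t)
    ll, *_ = _reml_profile(pat, pat.C_const, pat.wgrid @ M_var, pat.logS)
    if not np.isfinite(ll).any():
        return MarkerFit(n, p, *[float("nan")] * 10, testable=False, reason="degenerate fit")
    best = int(np.argmax(ll))
    grid = pat.grid
    lo = grid[max(0, best - 1)]
    hi = grid[min(len(grid) - 1, best + 1)]
    fine = np.linspace(lo, hi, 41)
    wfine = pat._weights(fine)
    logSf = np.log(pat.s[None, :] + np.exp(fine)[:, None]).sum(axis=1)
    llf, *_ = _reml_profile(pat, wfine @ pat.M_const, wfine @ M_var, logSf)
    b = int(np.argmax(llf))
    # quadratic refinement on the best three fine points
    if 0 < b < len(fine) - 1 and np.isfinite(llf[b - 1 : b + 2]).all():
        x0, x1, x2 = fine[b - 1 : b + 2]
        y0, y1, y2 = llf[b - 1 : b + 2]
        denom = (y0 - 2 * y1 + y2)
        log_delta = x1 - 0.5 * (x2 - x0) * (y2 - y0) / (2 * denom) if denom < 0 else fine[b]
        log_delta = float(np.clip(log_delta, x0, x2))
    else:
        log_delta = float(fine[b])
    delta = math.exp(log_delta)
    w = 1.0 / (pat.s + delta)
    Z = np.column_stack([pat.W, x_t])
    try:
        rss_full, beta, A = _wls(pat.y, Z, w)
        cov_unscaled = np.linalg.inv(A)
        rss_reduced, _, _ = _wls(pat.y, pat.W, w)
    except np.linalg.LinAlgError:
        return MarkerFit(n, p, *[float("nan")] * 10, testable=False, reason="singular fixed effects")
    df = n - p
    sigma2_g = rss_full / df
    var_beta = sigma2_g * cov_unscaled[-1, -1]
    if var_beta <= 0 or not np.isfinite(var_beta):
        return MarkerFit(n, p, *[float("nan")] * 10, testable=False, reason="singular fixed effects")
    fstat = float(beta[-1] ** 2 / var_beta)
    pval = float(stats.f.sf(fstat, 1, df))
    # corrected total SS on the whitened scale (intercept-only weighted fit)
    one = pat.one
    tss = float(w @ (pat.y**2) - ((one * w) @ pat.y) ** 2 / ((one * w) @ one))
    return MarkerFit(
        n=n,
        rank_fixed=p,
        beta=float(beta[-1]),
        se=float(math.sqrt(var_beta)),
        f=fstat,
        p=pval,
        sigma2_g=float(sigma2_g),
        sigma2_e=float(delta * sigma2_g),
        delta=float(delta),
        rss_full=float(rss_full),
        rss_reduced=float(rss_reduced),
        tss=tss,
    )


def _q_star(Q: QMatrix | None, ids: list[str]) -> np.ndarray:
    if Q is None or Q.k <= 1:
        return np.empty((len(ids), 0))
    return Q.subset(ids).q[:, :-1]


def mlm_single(
    trait: pd.Series,
    x: np.ndarray,
    K: KinshipMatrix,
    Q: QMatrix | None = None,
    n_grid: int = 121,
) -> MarkerFit:
    """Fit the mixed model for a single marker (ids taken from ``K``)."""
    ids = [i for i in K.individuals if not pd.isna(trait.get(i))]
    idx = [K.individuals.index(i) for i in ids]
    x = np.asarray(x, dtype=float)[idx]
    keep = x != MISSING
    ids = [i for i, k in zip(ids, keep) if k]
    y = trait.reindex(ids).to_numpy(dtype=float)
    Ksub = K.subset(ids).values
    W = np.column_stack([np.ones(len(ids)), _q_star(Q, ids)])
    grid = np.linspace(*LOG_DELTA_RANGE, n_grid)
    pat = _Pattern(y, W, Ksub, grid)
    if np.var(x[keep]) == 0:
        fit = MarkerFit(len(ids), W.shape[1] + 1, *[float("nan")] * 10, testable=False, reason="monomorphic in sample")
        return fit
    return _fit_marker(pat, pat.transform_marker(x[keep]))


def mlm_qk_scan(
    traits: pd.DataFrame,
    G: GenotypeMatrix,
    Q: QMatrix | None,
    K: KinshipMatrix,
    alpha_levels=DEFAULT_ALPHA_LEVELS,
    flag_singles: bool = True,
    n_grid: int = 121,
) -> pd.DataFrame:
    """Scan every trait column against every marker with the exact MLM+Q+K.

    Individuals missing the trait or the marker call are dropped per test; the
    eigendecomposition of K is cached per trait and per marker-missingness
    pattern.  Returns one row per (trait, marker) with effect, F, p, marker
    R^2, variance components, Bonferroni stars (m = number of markers) and the
    single-extreme-individual flag for significant hits.
    """
    m = G.n_markers
    loosest = max(alpha_levels)
    rows = []
    for trait_name in traits.columns:
        trait = traits[trait_name]
        ids = [i for i in G.individuals if i in trait.index and not pd.isna(trait[i])]
        if len(ids) < 10 or trait.reindex(ids).nunique() < 2:
            log.warning("trait %s: unusable (constant or n < 10); skipped", trait_name)
            continue
        y = trait.reindex(ids).to_numpy(dtype=float)
        Ksub = K.subset(ids).values
        W = np.column_stack([np.ones(len(ids)), _q_star(Q, ids)])
        gpos = {ind: i for i, ind in enumerate(G.individuals)}
        codes = G.codes[[gpos[i] for i in ids], :].astype(float)
        grid = np.linspace(*LOG_DELTA_RANGE, n_grid)
        patterns: dict[bytes, _Pattern] = {}
        for j, mid in enumerate(G.markers):
            x = codes[:, j]
            present = x != MISSING
            key = present.tobytes()
            pat = patterns.get(key)
            if pat is None:
                sub = np.flatnonzero(present)
                pat = _Pattern(y[sub], W[sub], Ksub[np.ix_(sub, sub)], grid)
                pat._sub = sub  # type: ignore[attr-defined]
                patterns[key] = pat
            sub = pat._sub  # type: ignore[attr-defined]
            xs = x[sub]
            if np.var(xs) == 0:
                fit = MarkerFit(len(sub), W.shape[1] + 1, *[float("nan")] * 10, testable=False, reason="monomorphic in sample")
            else:
                fit = _fit_marker(pat, pat.transform_marker(xs))
            rows.append(_result_row(trait_name, mid, fit, m, alpha_levels))
        log.info("trait %s: scanned %d markers", trait_name, len(G.markers))
    out = pd.DataFrame(rows)
    if flag_singles and len(out):
        threshold = bonferroni_threshold(loosest, m)
        for i in out.index[(out["p"] < threshold) & out["testable"]]:
            try:
                out.loc[i, "flag_single"] = flag_single_individual(
                    traits[out.loc[i, "trait"]],
                    G,
                    Q,
                    K,
                    out.loc[i, "marker"],
                    threshold,
                )
            except ValueError:
                # the standalone refit can land marginally past the threshold
                out.loc[i, "flag_single"] = False
    return out


def _result_row(trait_name, marker_id, fit: MarkerFit, m, alpha_levels) -> dict:
    return {
        "trait": trait_name,
        "marker": marker_id,
        "n": fit.n,
        "beta": fit.beta,
        "se": fit.se,
        "F": fit.f,
        "p": fit.p,
        "neglog10p": -math.log10(fit.p) if fit.testable and fit.p > 0 else float("nan"),
        "rsq_marker": marker_r2(fit) if fit.testable else float("nan"),
        "sigma2_g": fit.sigma2_g,
        "sigma2_e": fit.sigma2_e,
        "stars": stars_for(fit.p, m, alpha_levels) if fit.testable else "",
        "flag_single": False,
        "testable": fit.testable,
        "reason": fit.reason,
    }


def flag_single_individual(
    trait: pd.Series,
    G: GenotypeMatrix,
    Q: QMatrix | None,
    K: KinshipMatrix,
    marker: str,
    threshold: float,
) -> bool:
    """Leave-one-out flag for significance driven by one extreme individual.

    Refits the marker with the most trait-extreme minor-genotype carrier
    removed; flags when the refit p no longer passes ``threshold`` (or when
    fewer than 10 individuals remain).
    """
    x_all = G.column(marker).astype(float)
    ids = [
        i
        for i, xv in zip(G.individuals, x_all)
        if xv != MISSING and i in trait.index and not pd.isna(trait[i]) and i in K.individuals
    ]
    fit0 = mlm_single(trait.reindex(ids), G.column(marker)[[G.individuals.index(i) for i in ids]], K.subset(ids), Q)
    if not fit0.testable or not fit0.p < threshold:
        raise ValueError("flag_single_individual requires a significant association")
    x = pd.Series(G.column(marker).astype(float), index=G.individuals).reindex(ids)
    p_alt = x.sum() / (2 * len(x))
    carriers = x.index[(x > 0) if p_alt <= 0.5 else (x < 2)]
    if len(carriers) == 0:
        return False
    y = trait.reindex(ids)
    extreme = (y.reindex(carriers) - y.mean()).abs().idxmax()
    kept = [i for i in ids if i != extreme]
    if len(kept) < 10:
        log.warning("marker %s: fewer than 10 individuals after removal; flagged", marker)
        return True
    xk = pd.Series(x, index=ids).reindex(kept).to_numpy()
    refit = mlm_single(trait.reindex(kept), xk, K.subset(kept), Q)
    return (not refit.testable) or not (refit.p < threshold)
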