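"""Among-provenance tests, REML variance components and repeatability.

Repeatability r = sigma_ind^2 / (sigma_ind^2 + sigma_res^2) is the fraction of
phenotypic variance in drought response attributable to differences between
individual trees across repeated drought events; for the overall (across
provenance) model the denominator also includes the provenance variance.
Variance components are estimated by REML with non-negativity constraints;
standard errors come from the inverse observed-information matrix and a delta
method; significance from a likelihood-ratio test of sigma_ind^2 = 0 against
the 50:50 chi2_0:chi2_1 mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .io_core import get_logger

log = get_logger("quantgen")


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    f: float
    p: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    mse: float  # within-group mean square
    df_between: int
    df_within: int


def anova_oneway(values, groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA of a trait over provenance labels.

    Groups with fewer than two non-missing observations are dropped with a
    warning; fewer than two usable groups is an error.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)}).dropna()
    usable = {}
    for g, grp in df.groupby("g"):
        if len(grp) < 2:
            log.warning("group %r has < 2 observations; dropped from ANOVA", g)
            continue
        usable[g] = grp["y"].to_numpy()
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable groups for ANOVA")
    all_y = np.concatenate(list(usable.values()))
    grand = all_y.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in usable.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in usable.values())
    df_b = len(usable) - 1
    df_w = len(all_y) - len(usable)
    msb = ss_between / df_b
    msw = ss_within / df_w
    f = msb / msw if msw > 0 else np.inf
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f=float(f),
        p=p,
        group_means={g: float(v.mean()) for g, v in usable.items()},
        group_sizes={g: len(v) for g, v in usable.items()},
        mse=float(msw),
        df_between=df_b,
        df_within=df_w,
    )


def rm_anova(responses: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Repeated-measures ANOVA F test for the provenance effect.

    ``responses`` is individuals x events (>= 2 events); ``groups`` maps each
    individual to its provenance.  Individuals with any missing event are
    excluded.  Provenance is tested against the among-individuals-within-
    provenance mean square (individual trees are the repeated random unit).
    """
    if responses.shape[1] < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 events; use anova_oneway")
    complete = responses.dropna()
    g = groups.reindex(complete.index)
    complete = complete[g.notna()]
    g = g.dropna()
    k = complete.shape[1]
    ind_means = complete.mean(axis=1)
    grand = complete.to_numpy().mean()
    a = g.nunique()
    n_ind = len(complete)
    if a < 2 or n_ind <= a:
        raise ValueError("not enough individuals/groups for repeated-measures ANOVA")
    ss_prov = 0.0
    ss_ind = 0.0
    for label, idx in g.groupby(g).groups.items():
        m = ind_means.loc[idx]
        ss_prov += k * len(m) * (m.mean() - grand) ** 2
        ss_ind += k * ((m - m.mean()) ** 2).sum()
    df_prov = a - 1
    df_ind = n_ind - a
    f = (ss_prov / df_prov) / (ss_ind / df_ind)
    return float(f), float(stats.f.sf(f, df_prov, df_ind))


def duncan_letters(
    group_means: dict[str, float],
    mse: float,
    df: int,
    group_sizes: dict[str, int],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Duncan multiple-range compact letter display.

    Means are ordered and ranges of p means tested against critical values
    from the studentized range distribution at protection level
    1 - (1 - alpha)^(p - 1); groups sharing a letter are not significantly
    different.  Unequal sizes use the pairwise harmonic mean.
    """
    if mse <= 0:
        raise ValueError("MSE must be positive for Duncan's test")
    labels = sorted(group_means, key=lambda g: -group_means[g])
    means = [group_means[g] for g in labels]
    m = len(labels)
    homogeneous: list[tuple[int, int]] = []

    def covered(i, j):
        return any(lo <= i and j <= hi for lo, hi in homogeneous)

    for span in range(m, 1, -1):
        alpha_p = 1 - (1 - alpha) ** (span - 1)
        q_crit = stats.studentized_range.ppf(1 - alpha_p, span, df)
        for i in range(m - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            n_h = 2.0 / (1.0 / group_sizes[labels[i]] + 1.0 / group_sizes[labels[j]])
            r_p = q_crit * math.sqrt(mse / n_h)
            if means[i] - means[j] <= r_p:
                homogeneous.append((i, j))
    # maximal homogeneous intervals plus singletons
    intervals = [iv for iv in homogeneous if not any(
        (lo <= iv[0] and iv[1] <= hi and iv != (lo, hi)) for lo, hi in homogeneous
    )]
    for i in range(m):
        if not any(lo <= i <= hi for lo, hi in intervals):
            intervals.append((i, i))
    intervals.sort()
    letters = {g: "" for g in labels}
    for letter_idx, (lo, hi) in enumerate(intervals):
        letter = chr(ord("a") + letter_idx)
        for i in range(lo, hi + 1):
            letters[labels[i]] += letter
    return letters


# ---------------------------------------------------------------------------
# Response standardization
# ---------------------------------------------------------------------------


def standardize_response(values: pd.Series, index_kind: str) -> pd.Series:
    """Standardize a drought index within one event.

    Rt/Rc/Rs: natural log then z-score (mean 0, sd 1 across trees); rRs:
    z-score only since it can be non-positive.  Missing propagates.
    """
    v = values.astype(float)
    if index_kind in ("Rt", "Rc", "Rs"):
        bad = v.index[(v <= 0) & v.notna()]
        if len(bad):
            raise ValueError(f"non-positive {index_kind} for trees {list(bad)}")
        v = np.log(v)
    elif index_kind != "rRs":
        raise ValueError(f"unknown index kind {index_kind!r}")
    sd = v.std(ddof=1)
    if not sd > 0:
        raise ValueError(f"zero standard deviation for {index_kind} within event")
    return (v - v.mean()) / sd


def standardize_response_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`standardize_response` to every RtYY/RcYY/RsYY/rRsYY column."""
    out = {}
    for col in responses.columns:
        kind = col[:-2] if not col.startswith("rRs") else "rRs"
        out[col] = standardize_response(responses[col], kind)
    return pd.DataFrame(out, index=responses.index)


# ---------------------------------------------------------------------------
# REML variance components and repeatability
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma2_ind: float
    sigma2_res: float
    sigma2_prov: float | None = None
    se_ind: float = float("nan")
    se_res: float = float("nan")
    se_prov: float = float("nan")
    loglik: float = float("nan")
    boundary: dict[str, bool] = field(default_factory=dict)


@dataclass
class RepeatabilityEstimate:
    r: float
    se_r: float
    significant: bool
    scope: str
    p_value: float = float("nan")
    estimable: bool = True


def repeatability_ratio(
    sigma2_ind: float, sigma2_res: float, sigma2_prov: float | None = None
) -> float:
    """r = sigma_ind^2 / (sigma_ind^2 + sigma_res^2 [+ sigma_prov^2])."""
    denom = sigma2_ind + sigma2_res + (sigma2_prov or 0.0)
    if denom <= 0:
        return float("nan")
    return sigma2_ind / denom


class _RemlModel:
    """REML for y = mu + (random groups) + e via the Woodbury identity.

    Random-effect design matrices enter as integer group codes; the covariance
    is V = sum_k sigma_k^2 Z_k Z_k' + sigma_e^2 I.  Restricted log-likelihood
    includes its constants so LRTs across nested models are exact.
    """

    def __init__(self, y: np.ndarray, group_codes: list[np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        self.n = len(self.y)
        self.X = np.ones((self.n, 1))
        self.Zs = []
        for codes in group_codes:
            codes = np.asarray(codes)
            _, inv = np.unique(codes, return_inverse=True)
            Z = np.zeros((self.n, inv.max() + 1))
            Z[np.arange(self.n), inv] = 1.0
            self.Zs.append(Z)

    def loglik(self, variances: np.ndarray) -> float:
        """Restricted log-likelihood; variances = (components..., residual)."""
        sig_e = max(variances[-1], 1e-12)
        comps = variances[:-1]
        active = [(s, Z) for s, Z in zip(comps, self.Zs) if s > 0]
        n, p = self.n, self.X.shape[1]
        if active:
            Z = np.hstack([Zk for _, Zk in active])
            g = np.concatenate([[s] * Zk.shape[1] for s, Zk in active])
            A = (Z.T @ Z) / sig_e + np.diag(1.0 / g)
            cA, low = linalg.cho_factor(A, lower=True)
            logdet_V = (
                n * math.log(sig_e)
                + 2 * np.log(np.diag(cA)).sum()
                + np.log(g).sum()
            )

            def vinv(B):
                return B / sig_e - Z @ linalg.cho_solve((cA, low), Z.T @ B) / sig_e**2

        else:
            logdet_V = n * math.log(sig_e)

            def vinv(B):
                return B / sig_e

        Vi_y = vinv(self.y)
        Vi_X = vinv(self.X)
        XtViX = self.X.T @ Vi_X
        XtViy = self.X.T @ Vi_y
        beta = np.linalg.solve(XtViX, XtViy)
        quad = float(self.y @ Vi_y - XtViy @ beta)
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0 or quad < 0:
            return -np.inf
        return -0.5 * ((n - p) * math.log(2 * math.pi) + logdet_V + logdet_XtViX + quad)

    def fit(self) -> tuple[np.ndarray, float]:
        """Maximize REML over non-negative components; returns (theta, loglik)."""
        vy = float(np.var(self.y, ddof=1))
        if vy <= 0:
            raise ValueError("total variance is zero")
        k = len(self.Zs)
        x0 = np.full(k + 1, vy / (k + 1))

        def nll(theta):
            ll = self.loglik(theta)
            return np.inf if not np.isfinite(ll) else -ll

        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 50 * vy)] * (k + 1),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(f"REML did not converge: {res.message}")
        best = res
        # near a boundary the surface can be flat: polish from alternative starts
        starts = (0.05, 0.8) if (not res.success or (res.x < 1e-6 * vy).any()) else ()
        for frac in starts:
            x_alt = np.full(k + 1, vy * (1 - frac) / max(k, 1))
            x_alt[-1] = vy * frac
            alt = optimize.minimize(
                nll, x_alt, method="L-BFGS-B",
                bounds=[(0.0, 50 * vy)] * (k + 1),
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
            if alt.fun < best.fun - 1e-10:
                best = alt
        theta = best.x.copy()
        theta[theta < 1e-10 * vy] = 0.0
        return theta, -best.fun

    def hessian_se(self, theta: np.ndarray) -> np.ndarray:
        """Delta-method SEs: sqrt(diag(inverse observed information)).

        Components at the zero boundary get SE 0 (matching the convention of
        reporting clamped components as 0.000 +/- 0.000).
        """
        free = np.flatnonzero(theta > 0)
        se = np.zeros(len(theta))
        if len(free) == 0:
            return se
        h = np.maximum(1e-4 * theta[free], 1e-7)

        def f(x):
            t = theta.copy()
            t[free] = x
            return self.loglik(t)

        x0 = theta[free]
        m = len(free)
        H = np.zeros((m, m))
        f0 = f(x0)
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m)
                ej = np.zeros(m)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
            d = np.diag(cov)
            se[free] = np.sqrt(np.where(d > 0, d, np.nan))
            self._cov_free = (free, cov)
        except np.linalg.LinAlgError:
            se[free] = np.nan
            self._cov_free = (free, None)
        return se


def reml_repeatability(
    y,
    individual_ids,
    provenance_ids=None,
    scope: str | None = None,
    alpha: float = 0.05,
) -> tuple[VarianceComponents, RepeatabilityEstimate]:
    """REML variance components and repeatability from repeated responses.

    ``y`` holds (transformed) responses over >= 2 events in long form with
    ``individual_ids`` per record; pass ``provenance_ids`` for the overall
    model, whose repeatability denominator additionally includes the
    provenance component.  Significance is a likelihood-ratio test of
    sigma_ind^2 = 0 against the 50:50 chi2_0:chi2_1 mixture.
    """
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    ind = np.asarray(individual_ids)[mask]
    counts = pd.Series(ind).value_counts()
    if (counts >= 2).sum() < 5:
        raise ValueError("need >= 2 records for >= 5 individuals")
    overall = provenance_ids is not None
    if scope is None:
        scope = "overall" if overall else "per-provenance"
    groups = [ind]
    if overall:
        groups = [np.asarray(provenance_ids)[mask], ind]
    model = _RemlModel(y, groups)
    theta, loglik = model.fit()
    se = model.hessian_se(theta)

    if overall:
        s_prov, s_ind, s_res = theta
        se_prov, se_ind, se_res = se
    else:
        s_ind, s_res = theta
        se_ind, se_res = se
        s_prov, se_prov = None, float("nan")
    vc = VarianceComponents(
        sigma2_ind=float(s_ind),
        sigma2_res=float(s_res),
        sigma2_prov=None if s_prov is None else float(s_prov),
        se_ind=float(se_ind),
        se_res=float(se_res),
        se_prov=float(se_prov),
        loglik=float(loglik),
        boundary={
            "ind": s_ind == 0,
            "res": s_res == 0,
            "prov": (s_prov == 0) if overall else False,
        },
    )

    denom = s_ind + s_res + (s_prov if overall else 0.0)
    estimable = denom > 0
    r = repeatability_ratio(s_ind, s_res, s_prov if overall else None) if estimable else float("nan")

    # delta-method SE for r = s_ind / denom
    se_r = 0.0
    cov_info = getattr(model, "_cov_free", None)
    if estimable and s_ind > 0 and cov_info and cov_info[1] is not None:
        free, cov = cov_info
        grad_full = np.zeros(len(theta))
        if overall:
            grad_full[0] = -s_ind / denom**2  # d r / d sigma_prov
            grad_full[1] = (denom - s_ind) / denom**2
            grad_full[2] = -s_ind / denom**2
        else:
            grad_full[0] = (denom - s_ind) / denom**2
            grad_full[1] = -s_ind / denom**2
        grad = grad_full[free]
        var_r = float(grad @ cov @ grad)
        se_r = math.sqrt(var_r) if var_r > 0 else float("nan")

    # LRT of sigma_ind^2 = 0 against the chi2_0:chi2_1 mixture
    if overall:
        ll0 = _RemlModel(y, [groups[0]]).fit()[1]
    else:
        ll0 = _null_loglik(y)
    lr = max(0.0, 2.0 * (loglik - ll0))
    p_value = 0.5 * float(stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
    est = RepeatabilityEstimate(
        r=float(r) if estimable else float("nan"),
        se_r=float(se_r),
        significant=bool(estimable and s_ind > 0 and p_value < alpha),
        scope=scope,
        p_value=p_value,
        estimable=bool(estimable),
    )
    return vc, est


def _null_loglik(y: np.ndarray) -> float:
    """REML log-likelihood of the intercept-only iid model (closed form in
    sigma^2 maximized numerically for symmetry with the full fit)."""
    model = _RemlModel(y, [])
    _, ll = model.fit()
    return ll


def select_subset_qd(estimates: dict[str, RepeatabilityEstimate]) -> list[str]:
    """Provenances with significant Rt repeatability (the SubsetQD rule)."""
    subset = [prov for prov, est in estimates.items() if est.significant]
    if not subset:
        log.warning("no provenance has significant Rt repeatability; SubsetQD empty")
    return sorted(subset)


# ---------------------------------------------------------------------------
# Trait correlation matrices
# ---------------------------------------------------------------------------


def correlation_matrices(
    traits: pd.DataFrame, provenances: pd.Series, min_pairs: int = 5
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Pearson trait-correlation matrices per provenance, overall, and the
    max - min range matrix across provenances (cells with fewer than
    ``min_pairs`` pairwise-complete observations are missing)."""
    prov = provenances.reindex(traits.index)
    per_prov = {}
    for label, idx in prov.groupby(prov).groups.items():
        per_prov[str(label)] = traits.loc[idx].corr(min_periods=min_pairs)
    overall = traits.corr(min_periods=min_pairs)
    stack = np.stack([m.to_numpy() for m in per_prov.values()])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        rng = np.nanmax(stack, axis=0) - np.nanmin(stack, axis=0)
    range_matrix = pd.DataFrame(rng, index=overall.index, columns=overall.columns)
    return per_prov, overall, range_matrix
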