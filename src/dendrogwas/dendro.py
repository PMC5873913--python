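"""Per-tree series, chronologies, drought response indicators and trait building.

The four drought response indicators follow the Lloret ratios computed from
raw, untransformed ring widths: resistance Rt = Dr / preDr, recovery
Rc = postDr / Dr, resilience Rs = postDr / preDr and relative resilience
rRs = (postDr - Dr) / preDr, where preDr/postDr are the mean ring widths of
the ``window`` years before/after the drought year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MEASUREMENTS, ClimateRecord, RingSeries, get_logger

log = get_logger("dendro")

MONTH_ABBR = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

#: Climate-growth variables used as association traits when selection is
#: pinned: correlations of ring width with monthly precipitation (P) and mean
#: temperature (T) of the current year.
DEFAULT_CLIMATE_VARIABLES = (
    "CorFebP", "CorMayP", "CorJunP",
    "CorJanT", "CorMarT", "CorMayT", "CorJunT", "CorAugT",
)

SCENARIO_IDS = ("Scen1", "Scen2", "Scen3", "Scen4")

ATANH_CLIP = 1.0 - 1e-12


@dataclass
class DroughtResponse:
    """Lloret indicators for one tree x drought event (NaN when undefined)."""

    tree_id: str
    event_year: int
    dr: float
    pre_dr: float
    post_dr: float
    rt: float
    rc: float
    rs: float
    rrs: float
    reason: str = ""  # non-empty when the response is undefined

    @property
    def defined(self) -> bool:
        return not self.reason


@dataclass
class MeanChronology:
    """Dimensionless ring-width index per year with sample depth."""

    index: pd.Series  # year -> index
    depth: pd.Series  # year -> number of trees contributing


def average_cores(a: RingSeries, b: RingSeries) -> RingSeries:
    """Average two cores of the same tree per year and measurement.

    Where one core misses a year (or a measurement), the other core's value
    is used.
    """
    if a.tree_id != b.tree_id:
        raise ValueError(f"cores from different trees: {a.tree_id!r} vs {b.tree_id!r}")
    years = np.union1d(a.years, b.years)
    data = {}
    for m in MEASUREMENTS:
        va = np.full(len(years), np.nan)
        vb = np.full(len(years), np.nan)
        if m in a.data:
            va[np.isin(years, a.years)] = a.data[m]
        if m in b.data:
            vb[np.isin(years, b.years)] = b.data[m]
        stacked = np.vstack([va, vb])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # both-missing years stay NaN
            data[m] = np.nanmean(stacked, axis=0)
    return RingSeries(
        tree_id=a.tree_id,
        core_id=f"{a.core_id}+{b.core_id}",
        provenance=a.provenance or b.provenance,
        years=years,
        data=data,
    )


def average_cores_by_tree(series: dict) -> dict[str, RingSeries]:
    """Collapse a (tree_id, core_id) keyed mapping to one series per tree."""
    by_tree: dict[str, list[RingSeries]] = {}
    for s in series.values():
        by_tree.setdefault(s.tree_id, []).append(s)
    out = {}
    for tree_id, cores in by_tree.items():
        merged = cores[0]
        for other in cores[1:]:
            merged = average_cores(merged, other)
        out[tree_id] = merged
    return out


def compute_drought_response(
    series: RingSeries, event_year: int, window: int = 2
) -> DroughtResponse:
    """Compute the four drought indicators for one tree and event.

    All ``window`` years before and after the event plus the event year must
    carry RW; otherwise the response is returned undefined with a reason (not
    raised), so missing rings degrade gracefully.
    """
    dr = series.value("RW", event_year)
    pre = np.array([series.value("RW", event_year - i) for i in range(1, window + 1)])
    post = np.array([series.value("RW", event_year + i) for i in range(1, window + 1)])
    nan = float("nan")
    if np.isnan(pre).any():
        reason = "insufficient pre-window"
    elif np.isnan(dr):
        reason = "missing drought-year ring"
    elif np.isnan(post).any():
        reason = "insufficient post-window"
    else:
        reason = ""
    if reason:
        return DroughtResponse(series.tree_id, event_year, nan, nan, nan, nan, nan, nan, nan, reason)
    pre_dr = float(pre.mean())
    post_dr = float(post.mean())
    return DroughtResponse(
        tree_id=series.tree_id,
        event_year=event_year,
        dr=float(dr),
        pre_dr=pre_dr,
        post_dr=post_dr,
        rt=dr / pre_dr,
        rc=post_dr / dr,
        rs=post_dr / pre_dr,
        rrs=(post_dr - dr) / pre_dr,
    )


def drought_response_table(
    trees: dict[str, RingSeries], event_years: list[int], window: int = 2
) -> pd.DataFrame:
    """Per-tree indicator columns (Rt93, Rc93, ... suffix = event year % 100)."""
    rows = {}
    for tree_id, s in trees.items():
        row = {}
        for year in event_years:
            resp = compute_drought_response(s, year, window=window)
            suffix = f"{year % 100:02d}"
            row[f"Rt{suffix}"] = resp.rt
            row[f"Rc{suffix}"] = resp.rc
            row[f"Rs{suffix}"] = resp.rs
            row[f"rRs{suffix}"] = resp.rrs
        rows[tree_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "individual_id"
    return df


def build_mean_chronology(trees: list[RingSeries] | dict) -> MeanChronology:
    """Average of per-tree RW indexed by each tree's own full-span mean.

    Trees whose RW is entirely missing are excluded with a warning.  Each
    tree's index has mean 1 over its span before cross-tree averaging.
    """
    if isinstance(trees, dict):
        trees = list(trees.values())
    if not trees:
        raise ValueError("no series supplied")
    per_tree = []
    for s in trees:
        rw = s.data.get("RW")
        if rw is None or np.all(np.isnan(rw)):
            log.warning("tree %s has no RW data; excluded from chronology", s.tree_id)
            continue
        mean = np.nanmean(rw)
        per_tree.append(pd.Series(rw / mean, index=s.years))
    if not per_tree:
        raise ValueError("all series have all-missing RW")
    frame = pd.DataFrame(per_tree).T.sort_index()
    return MeanChronology(index=frame.mean(axis=1), depth=frame.notna().sum(axis=1))


# ---------------------------------------------------------------------------
# Climate-growth correlation traits
# ---------------------------------------------------------------------------


def _variable_name(month: int, var: str, previous_year: bool) -> str:
    suffix = "P" if var == "prcp_mm" else "T"
    prev = "p" if previous_year else ""
    return f"Cor{prev}{MONTH_ABBR[month - 1]}{suffix}"


def _candidate_variables() -> list[tuple[str, int, bool]]:
    """(var, month, previous_year) from April of the previous year to September."""
    out = []
    for var in ("prcp_mm", "tmean_c"):
        for month in range(4, 13):
            out.append((var, month, True))
        for month in range(1, 10):
            out.append((var, month, False))
    return out


def _monthly_predictor(climate: ClimateRecord, var: str, month: int, previous_year: bool) -> pd.Series:
    s = climate.series(var)
    sel = s[s.index.get_level_values("month") == month]
    years = sel.index.get_level_values("year").to_numpy()
    if previous_year:
        years = years + 1  # value of the previous calendar year, aligned to ring year
    return pd.Series(sel.to_numpy(), index=years)


def _safe_pearson(x: np.ndarray, y: np.ndarray):
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_climate_variables(
    chronology: MeanChronology,
    climate: ClimateRecord,
    alpha_select: float = 0.05,
) -> list[str]:
    """Step 1: keep monthly variables significantly correlated (two-sided
    Pearson p < alpha) with the mean chronology, over April of the previous
    year .. September of the current year."""
    kept = []
    years = chronology.index.index.to_numpy()
    chron = chronology.index.to_numpy(dtype=float)
    for var, month, prev in _candidate_variables():
        pred = _monthly_predictor(climate, var, month, prev).reindex(years).to_numpy()
        r, p = _safe_pearson(chron, pred)
        if not np.isnan(r) and p < alpha_select:
            kept.append(_variable_name(month, var, prev))
    return kept


def _parse_variable_name(name: str) -> tuple[str, int, bool]:
    body = name[3:]
    prev = body.startswith("p") and body[1:4] in MONTH_ABBR
    if prev:
        body = body[1:]
    mon, suffix = body[:3], body[3:]
    var = "prcp_mm" if suffix == "P" else "tmean_c"
    return var, MONTH_ABBR.index(mon) + 1, prev


def climate_growth_traits(
    trees: dict[str, RingSeries],
    climate: ClimateRecord,
    alpha_select: float = 0.05,
    variables: list[str] | None = None,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Per-tree Fisher-z climate-growth correlation traits.

    Step 1 selects significant monthly variables against the mean chronology
    (skipped when ``variables`` pins the list); step 2 computes each tree's
    Pearson r with every kept variable and returns z = atanh(r) with |r|
    clipped to 1 - 1e-12.  Trees overlapping the climate record in fewer than
    ``min_overlap`` years get missing values.
    """
    chron = build_mean_chronology(trees)
    if variables is None:
        variables = select_climate_variables(chron, climate, alpha_select)
    rows = {}
    for tree_id, s in trees.items():
        rw = s.data["RW"]
        row = {}
        for name in variables:
            var, month, prev = _parse_variable_name(name)
            pred = _monthly_predictor(climate, var, month, prev).reindex(s.years).to_numpy()
            mask = ~(np.isnan(rw) | np.isnan(pred))
            if mask.sum() < min_overlap:
                row[name] = np.nan
                continue
            r, _ = _safe_pearson(rw, pred)
            row[name] = np.arctanh(np.clip(r, -ATANH_CLIP, ATANH_CLIP))
        rows[tree_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[list(variables)]
    df.index.name = "individual_id"
    return df


# ---------------------------------------------------------------------------
# Trait transforms and drought scenarios
# ---------------------------------------------------------------------------


class TransformError(ValueError):
    pass


def transform_trait(
    values: pd.Series, mode: str, cutpoints: list[float] | None = None
) -> pd.Series:
    """Discretize a trait: ``binomial`` (median split) or ``categorical``
    (tertiles).  Values exactly on a cutpoint go to the lower class; missing
    propagates.  Quantiles use linear interpolation between order statistics.
    """
    clean = values.dropna()
    if clean.nunique() < 2:
        raise TransformError("constant trait cannot be transformed")
    if mode == "binomial":
        cuts = cutpoints if cutpoints is not None else [float(clean.quantile(0.5))]
        if len(cuts) != 1:
            raise TransformError("binomial transform takes exactly one cutpoint")
    elif mode == "categorical":
        cuts = (
            cutpoints
            if cutpoints is not None
            else [float(clean.quantile(1 / 3)), float(clean.quantile(2 / 3))]
        )
        if len(cuts) != 2:
            raise TransformError("categorical transform takes exactly two cutpoints")
    else:
        raise TransformError(f"unknown transform mode {mode!r}")
    out = pd.Series(np.nan, index=values.index, dtype=float)
    notna = values.notna()
    classes = np.zeros(notna.sum())
    v = values[notna].to_numpy(dtype=float)
    for cut in cuts:
        classes += v > cut  # ties go to the lower class
    out[notna] = classes
    return out


def scenario_trait(
    rt_by_event: pd.DataFrame,
    scenario: str,
    cutoffs: tuple[float, float] | None = None,
) -> pd.Series:
    """Combine Rt of the first two drought events into a scenario trait.

    ``rt_by_event`` has two columns (first and second event Rt).  Defaults use
    per-event medians as cutoffs.  Registry:

    - ``Scen1`` (binomial): resistant (above cutoff) in both events.
    - ``Scen2`` (binomial): resistant in at least one event.
    - ``Scen3`` (categorical): number of events resistant (0, 1, 2).
    - ``Scen4`` (binomial): mean of the two Rt values above the cutoff mean.

    Trees missing either event's Rt get a missing scenario value.
    """
    if scenario not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario id {scenario!r}")
    if rt_by_event.shape[1] != 2:
        raise ValueError("scenario traits need exactly two event columns")
    a = rt_by_event.iloc[:, 0]
    b = rt_by_event.iloc[:, 1]
    if cutoffs is None:
        cutoffs = (float(a.median()), float(b.median()))
    ca, cb = cutoffs
    above_a = a > ca
    above_b = b > cb
    if scenario == "Scen1":
        vals = (above_a & above_b).astype(float)
    elif scenario == "Scen2":
        vals = (above_a | above_b).astype(float)
    elif scenario == "Scen3":
        vals = above_a.astype(float) + above_b.astype(float)
    else:  # Scen4
        vals = (((a + b) / 2.0) > ((ca + cb) / 2.0)).astype(float)
    vals[a.isna() | b.isna()] = np.nan
    vals.name = scenario
    return vals


# ---------------------------------------------------------------------------
# Full association trait table
# ---------------------------------------------------------------------------


def wood_trait_table(trees: dict[str, RingSeries]) -> pd.DataFrame:
    """Per-tree means of the nine wood measurements plus +b/+t transforms."""
    rows = {
        tid: {m: np.nanmean(s.data[m]) if m in s.data else np.nan for m in MEASUREMENTS}
        for tid, s in trees.items()
    }
    raw = pd.DataFrame.from_dict(rows, orient="index")
    out = {}
    for m in MEASUREMENTS:
        out[m] = raw[m]
        out[f"{m}b"] = transform_trait(raw[m], "binomial")
        out[f"{m}t"] = transform_trait(raw[m], "categorical")
    df = pd.DataFrame(out)
    df.index.name = "individual_id"
    return df


def assemble_trait_table(
    trees: dict[str, RingSeries],
    event_years: list[int],
    climate: ClimateRecord,
    window: int = 2,
    scenario_events: tuple[int, int] | None = None,
    climate_variables: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the full association trait table.

    Columns, in order: four scenario traits, the per-event drought indicators
    (4 per event), the climate-growth correlation traits, and the wood traits
    in raw/binomial/categorical form.  With three events and the default
    eight pinned climate variables this is 4 + 12 + 8 + 27 = 51 columns.
    """
    if climate_variables is None:
        climate_variables = list(DEFAULT_CLIMATE_VARIABLES)
    responses = drought_response_table(trees, event_years, window=window)
    if scenario_events is None:
        # first two events; the last is excluded for carry-over from the previous one
        scenario_events = (event_years[0], event_years[1])
    rt_cols = [f"Rt{y % 100:02d}" for y in scenario_events]
    scen = pd.DataFrame(
        {sid: scenario_trait(responses[rt_cols], sid) for sid in SCENARIO_IDS}
    )
    clim = climate_growth_traits(trees, climate, variables=climate_variables)
    wood = wood_trait_table(trees)
    table = pd.concat([scen, responses, clim, wood], axis=1)
    table.index.name = "individual_id"
    return table
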