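"""Site climate interpolation, standardized precipitation index, drought events.

The SPI maps k-month precipitation sums through a per-calendar-month mixed
distribution H(x) = q + (1 - q) * G(x), where q is the frequency of zero sums
over a reference period and G a gamma CDF fitted by maximum likelihood to the
nonzero sums; SPI = probit(H(x)), in standard-deviation units.  Values are
classified with McKee-style classes and years whose growing-season SPI minimum
falls at or below a threshold become drought events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_core import ClimateRecord, get_logger

log = get_logger("climate")

EARTH_RADIUS_KM = 6371.0088

#: Drought classes on the negative SPI axis (class applies to values <= upper
#: bound, ordered from weakest to strongest).
DROUGHT_CLASSES = (
    ("mild", 0.0),
    ("moderate", -1.0),
    ("severe", -1.5),
    ("extreme", -2.0),
)

DEFAULT_EVENT_THRESHOLD = -2.0
DEFAULT_GROWING_SEASON = (4, 5, 6, 7)


class SpiFitError(RuntimeError):
    """Gamma fit failed (e.g. too few nonzero reference values)."""


def classify_spi(value: float) -> str:
    """Drought class of an SPI value; non-negative values are ``none``.

    The classification partitions the real line: mild (0, -1), moderate
    [-1, -1.5), severe [-1.5, -2), extreme <= -2.
    """
    if np.isnan(value):
        return ""
    if value >= 0:
        return "none"
    label = "mild"
    for name, bound in DROUGHT_CLASSES:
        if value <= bound:
            label = name
    return label


@dataclass
class SPISeries:
    """SPI values on timescale ``k`` indexed by (year, month), with classes."""

    k: int
    values: pd.Series  # index (year, month), float

    def classes(self) -> pd.Series:
        return self.values.map(classify_spi)


@dataclass
class DroughtEvent:
    year: int
    month: int  # month of the SPI minimum
    spi: float
    klass: str
    in_growing_season: bool
    timescale: int


# ---------------------------------------------------------------------------
# Inverse distance weighting
# ---------------------------------------------------------------------------


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def idw_interpolate(
    stations: list[ClimateRecord],
    site_lat: float,
    site_lon: float,
    n_nearest: int = 4,
    power: float = 2.0,
) -> ClimateRecord:
    """Interpolate a site climate record by inverse-distance weighting.

    Uses the ``n_nearest`` stations with weights d^(-power) over great-circle
    distances.  A station within 1 m of the site returns its own series.  A
    (year, month) with no station data is missing in the output.
    """
    if not stations:
        raise ValueError("no stations supplied")
    dists = np.array(
        [great_circle_km(site_lat, site_lon, s.lat, s.lon) for s in stations]
    )
    order = np.argsort(dists)[:n_nearest]
    nearest = [stations[i] for i in order]
    d = dists[order]
    if d[0] < 1e-3:  # < 1 m: co-located station
        s = nearest[0]
        return ClimateRecord("site", site_lat, site_lon, s.elev, s.table.copy())
    w = d ** (-power)
    index = sorted(set().union(*(s.table.index for s in nearest)))
    out = {}
    for var in ("prcp_mm", "tmean_c"):
        vals = np.full((len(index), len(nearest)), np.nan)
        for j, s in enumerate(nearest):
            vals[:, j] = s.table[var].reindex(index).to_numpy()
        mask = ~np.isnan(vals)
        wsum = (mask * w).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[var] = np.where(
                wsum > 0, np.nansum(vals * w, axis=1) / wsum, np.nan
            )
    table = pd.DataFrame(out, index=pd.MultiIndex.from_tuples(index, names=["year", "month"]))
    elev = float(np.sum(w * [s.elev for s in nearest]) / w.sum())
    return ClimateRecord("site", site_lat, site_lon, elev, table)


# ---------------------------------------------------------------------------
# SPI
# ---------------------------------------------------------------------------


def _rolling_sums(precip: pd.Series, k: int) -> pd.Series:
    """Right-aligned k-month sums (months m-k+1..m); NaN where incomplete."""
    s = precip.sort_index()
    # reindex to a contiguous monthly calendar so windows line up
    years = s.index.get_level_values(0)
    full = pd.MultiIndex.from_product(
        [range(years.min(), years.max() + 1), range(1, 13)], names=["year", "month"]
    )
    s = s.reindex(full)
    return s.rolling(k, min_periods=k).sum()


def _fit_month(values: np.ndarray, month: int):
    """Fit the zero-inflated gamma H for one calendar month's k-sums.

    Returns (q, shape, scale).  MLE via numeric optimization initialized from
    Thom's approximation, which is stable on small monthly samples.
    """
    values = values[~np.isnan(values)]
    nonzero = values[values > 0]
    if len(nonzero) < 10:
        raise SpiFitError(
            f"month {month}: only {len(nonzero)} nonzero reference values (< 10)"
        )
    q = 1.0 - len(nonzero) / len(values)
    x = nonzero
    mean = x.mean()
    logs = np.log(x)
    A = math.log(mean) - logs.mean()
    # Thom's closed-form start for the shape
    shape0 = (1.0 + math.sqrt(1.0 + 4.0 * A / 3.0)) / (4.0 * A) if A > 0 else 10.0

    def nll(log_shape):
        if abs(log_shape) > 16:  # shape outside [1e-7, 9e6]: degenerate
            return np.inf
        a = math.exp(log_shape)
        scale = mean / a  # profile MLE of scale given shape
        return -np.sum(stats.gamma.logpdf(x, a, scale=scale))

    res = optimize.minimize_scalar(
        nll, bounds=(math.log(shape0) - 6, min(16.0, math.log(shape0) + 6)), method="bounded"
    )
    shape = math.exp(res.x)
    return q, shape, mean / shape


def compute_spi(
    precip: pd.Series,
    k: int = 1,
    reference_period: tuple[int, int] | None = None,
) -> SPISeries:
    """Compute the SPI on timescale ``k`` from a monthly precipitation series.

    ``precip`` is indexed by (year, month).  Distribution parameters are
    fitted per calendar month over ``reference_period`` (closed year range;
    defaults to the full span); SPI is returned for every complete k-month
    window in the input.
    """
    if k < 1:
        raise ValueError("timescale k must be >= 1")
    sums = _rolling_sums(precip, k)
    years = sums.index.get_level_values("year")
    if reference_period is None:
        reference_period = (int(years.min()), int(years.max()))
    y0, y1 = reference_period
    ref = sums[(years >= y0) & (years <= y1)]

    params = {}
    for month in range(1, 13):
        vals = ref[ref.index.get_level_values("month") == month].to_numpy(dtype=float)
        params[month] = _fit_month(vals, month)

    months = sums.index.get_level_values("month")
    out = np.full(len(sums), np.nan)
    x = sums.to_numpy(dtype=float)
    for month in range(1, 13):
        q, shape, scale = params[month]
        sel = (months == month) & ~np.isnan(x)
        h = np.where(
            x[sel] > 0,
            q + (1 - q) * stats.gamma.cdf(x[sel], shape, scale=scale),
            q / 2.0,  # plotting-position value for exact zeros
        )
        out[np.flatnonzero(sel)] = special.ndtri(np.clip(h, 1e-12, 1 - 1e-12))
    series = pd.Series(out, index=sums.index).dropna()
    return SPISeries(k=k, values=series)


def detect_drought_events(
    spi_series: list[SPISeries],
    threshold: float = DEFAULT_EVENT_THRESHOLD,
    growing_season: tuple[int, ...] = DEFAULT_GROWING_SEASON,
) -> list[DroughtEvent]:
    """Detect drought-event years from one or more SPI series.

    A year is an event when the minimum over growing-season months of any
    series is <= ``threshold``.  Years whose sub-threshold minima fall only
    outside the growing season are reported with ``in_growing_season=False``
    (and are excluded from downstream defaults).
    """
    if not growing_season:
        raise ValueError("growing-season month set is empty")
    events: dict[int, DroughtEvent] = {}
    for spi in spi_series:
        months = spi.values.index.get_level_values("month")
        for year in sorted(set(spi.values.index.get_level_values("year"))):
            ysel = spi.values[(spi.values.index.get_level_values("year") == year)]
            sub = ysel[ysel <= threshold]
            if sub.empty:
                continue
            in_season = sub[[m in growing_season for m in sub.index.get_level_values("month")]]
            pick = in_season if not in_season.empty else sub
            month = int(pick.idxmin()[1])
            value = float(pick.min())
            ev = DroughtEvent(
                year=int(year),
                month=month,
                spi=value,
                klass=classify_spi(value),
                in_growing_season=not in_season.empty,
                timescale=spi.k,
            )
            prev = events.get(ev.year)
            # prefer growing-season detections, then the deeper minimum
            if (
                prev is None
                or (ev.in_growing_season and not prev.in_growing_season)
                or (ev.in_growing_season == prev.in_growing_season and ev.spi < prev.spi)
            ):
                events[ev.year] = ev
    return [events[y] for y in sorted(events)]


def retained_event_years(events: list[DroughtEvent]) -> list[int]:
    """Years of events retained for analysis (growing season only)."""
    return [e.year for e in events if e.in_growing_season]
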