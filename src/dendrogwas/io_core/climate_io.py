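"""Monthly station climate records and their CSV schema.

Climate CSV: ``station_id,year,month,prcp_mm,tmean_c``; station CSV:
``station_id,lat,lon,elev``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ClimateFormatError(ValueError):
    pass


@dataclass
class ClimateRecord:
    """Monthly precipitation and mean temperature for one station (or a site).

    ``table`` is indexed by ``(year, month)`` with columns ``prcp_mm`` and
    ``tmean_c``; NaN = missing.
    """

    station_id: str
    lat: float
    lon: float
    elev: float
    table: pd.DataFrame

    def __post_init__(self) -> None:
        months = self.table.index.get_level_values("month")
        if len(months) and (months.min() < 1 or months.max() > 12):
            raise ClimateFormatError(f"{self.station_id}: month outside 1..12")
        if self.table.index.duplicated().any():
            raise ClimateFormatError(f"{self.station_id}: duplicate (year, month)")
        prcp = self.table["prcp_mm"]
        if (prcp.dropna() < 0).any():
            raise ClimateFormatError(f"{self.station_id}: negative precipitation")

    def series(self, var: str) -> pd.Series:
        """Monthly series of ``prcp_mm`` or ``tmean_c`` indexed by (year, month)."""
        return self.table[var]


def read_climate_csv(climate_path, stations_path) -> list[ClimateRecord]:
    clim = pd.read_csv(climate_path, dtype={"station_id": str})
    stations = pd.read_csv(stations_path, dtype={"station_id": str})
    for col in ("station_id", "year", "month", "prcp_mm", "tmean_c"):
        if col not in clim.columns:
            raise ClimateFormatError(f"{climate_path}: missing column {col!r}")
    for col in ("station_id", "lat", "lon", "elev"):
        if col not in stations.columns:
            raise ClimateFormatError(f"{stations_path}: missing column {col!r}")
    stations = stations.set_index("station_id")
    out = []
    for sid, grp in clim.groupby("station_id", sort=False):
        if sid not in stations.index:
            raise ClimateFormatError(f"station {sid!r} has climate rows but no metadata")
        meta = stations.loc[sid]
        table = grp.set_index(["year", "month"])[["prcp_mm", "tmean_c"]].sort_index()
        out.append(
            ClimateRecord(
                station_id=str(sid),
                lat=float(meta["lat"]),
                lon=float(meta["lon"]),
                elev=float(meta["elev"]),
                table=table,
            )
        )
    return out


def write_climate_csv(records: list[ClimateRecord], climate_path) -> None:
    frames = []
    for rec in records:
        df = rec.table.reset_index()
        df.insert(0, "station_id", rec.station_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(climate_path, index=False)


def write_stations_csv(records: list[ClimateRecord], stations_path) -> None:
    rows = [
        {"station_id": r.station_id, "lat": r.lat, "lon": r.lon, "elev": r.elev}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(stations_path, index=False)
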