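"""Reading per-animal length records and binning them into compositions.

Records are one row per measured krill (total length in mm, measured from
the anterior edge of the eye to the posterior end of the telson), with a
catch date and either an explicit management stratum or a lon/lat position
to be resolved against stratum polygons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .biology import ParameterError
from .lbspr import LengthComposition

__all__ = [
    "SchemaError",
    "LoadReport",
    "StratumMap",
    "DEFAULT_SCHEMA",
    "DEFAULT_LENGTH_WINDOW",
    "UNASSIGNED",
    "read_length_records",
    "assign_strata",
    "bin_composition",
]

#: column-name mapping: logical field -> CSV column
DEFAULT_SCHEMA: Mapping[str, str] = {
    "length": "length_mm",
    "date": "date",
    "stratum": "stratum",
    "lat": "lat",
    "lon": "lon",
    "vessel": "vessel",
    "nationality": "nationality",
}

#: plausibility window for krill total length, mm (inclusive)
DEFAULT_LENGTH_WINDOW = (10.0, 70.0)

#: recruit-length annotation (mm); reporting only, never a filter
RECRUIT_LENGTH_MM = 36.0

UNASSIGNED = "UNASSIGNED"


class SchemaError(ValueError):
    """A required column is missing from the input file."""


@dataclass
class LoadReport:
    """Kept/dropped bookkeeping for one records file."""

    n_read: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def __str__(self):
        drops = ", ".join(f"{k}={v}" for k, v in sorted(self.dropped.items())) or "none"
        return f"read={self.n_read} kept={self.n_kept} dropped: {drops}"


def read_length_records(
    path,
    schema: Optional[Mapping[str, str]] = None,
    length_window: tuple = DEFAULT_LENGTH_WINDOW,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a per-animal length records CSV.

    Returns a tidy frame with columns ``length_mm``, ``date``, ``year``,
    ``month`` plus whichever of ``stratum``/``lat``/``lon``/``vessel``/
    ``nationality`` the file provides, and a :class:`LoadReport` counting
    rows dropped per reason (unparseable date, missing or out-of-window
    length).
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path)
    report = LoadReport(n_read=len(df))
    for logical in ("length", "date"):
        if schema[logical] not in df.columns:
            raise SchemaError(f"required column missing: {schema[logical]!r}")
    out = pd.DataFrame(index=df.index)
    out["length_mm"] = pd.to_numeric(df[schema["length"]], errors="coerce")
    out["date"] = pd.to_datetime(df[schema["date"]], errors="coerce", format="mixed")
    for logical in ("stratum", "lat", "lon", "vessel", "nationality"):
        col = schema[logical]
        if col in df.columns:
            out[logical if logical != "stratum" else "stratum"] = df[col]
    bad_date = out["date"].isna()
    report.dropped["unparseable_date"] = int(bad_date.sum())
    out = out[~bad_date]
    bad_len = out["length_mm"].isna()
    report.dropped["missing_length"] = int(bad_len.sum())
    out = out[~bad_len]
    lo, hi = length_window
    outside = (out["length_mm"] < lo) | (out["length_mm"] > hi)
    report.dropped["out_of_window"] = int(outside.sum())
    out = out[~outside]
    out = out.copy()
    out["year"] = out["date"].dt.year
    out["month"] = out["date"].dt.month
    report.dropped = +report.dropped  # drop zero entries
    report.n_kept = len(out)
    return out.reset_index(drop=True), report


class StratumMap:
    """Named lon/lat polygons defining the management strata.

    Boundary points are assigned to the first matching polygon in declared
    order (documented tie-break), so the declaration order matters.
    """

    def __init__(self, names: Sequence[str], polygons: Sequence):
        if len(names) != len(polygons):
            raise ParameterError("names and polygons must have equal length")
        if len(set(names)) != len(names):
            raise ParameterError("stratum names must be unique")
        for name, poly in zip(names, polygons):
            if not poly.is_valid:
                raise ParameterError(f"polygon for stratum {name!r} is invalid")
        self.names = list(names)
        self.polygons = list(polygons)

    @classmethod
    def from_geojson(cls, path) -> "StratumMap":
        import json

        with open(path) as fh:
            gj = json.load(fh)
        names, polys = [], []
        for feat in gj["features"]:
            names.append(feat["properties"]["name"])
            polys.append(shapely_shape(feat["geometry"]))
        return cls(names, polys)

    def locate(self, lon: float, lat: float) -> str:
        """Stratum id for one point; ``UNASSIGNED`` when no polygon covers it."""
        pt = shapely.points(lon, lat)
        for name, poly in zip(self.names, self.polygons):
            if shapely.covers(poly, pt):
                return name
        return UNASSIGNED


def assign_strata(
    records: pd.DataFrame, smap: Optional[StratumMap] = None
) -> pd.DataFrame:
    """Resolve a stratum for every record.

    An explicit non-null ``stratum`` field always wins; otherwise the lon/lat
    position is tested against the polygons in declared order (boundary
    points go to the first match).  Records that resolve to nothing get
    ``UNASSIGNED`` and are excluded from compositions downstream.
    """
    out = records.copy()
    if "stratum" not in out.columns:
        out["stratum"] = pd.Series([None] * len(out), dtype=object)
    resolved = out["stratum"].astype(object).where(out["stratum"].notna(), None)
    need = np.array([s is None for s in resolved])
    if need.any():
        if smap is None or "lon" not in out.columns or "lat" not in out.columns:
            resolved[need] = UNASSIGNED
        else:
            lon = out.loc[need, "lon"].to_numpy(float)
            lat = out.loc[need, "lat"].to_numpy(float)
            pts = shapely.points(lon, lat)
            assigned = np.full(len(pts), UNASSIGNED, dtype=object)
            open_mask = np.ones(len(pts), dtype=bool)
            for name, poly in zip(smap.names, smap.polygons):
                if not open_mask.any():
                    break
                hit = shapely.covers(poly, pts[open_mask])
                idx = np.flatnonzero(open_mask)[hit]
                assigned[idx] = name
                open_mask[idx] = False
            resolved[need] = assigned
    out["stratum"] = resolved
    return out


def bin_composition(
    records: pd.DataFrame,
    bin_width: float = 2.0,
    by: Sequence[str] = ("year", "stratum"),
) -> list[LengthComposition]:
    """Bin records into half-open [edge, edge + width) compositions per cell.

    ``by`` is either ``("year", "stratum")`` or ``("year", "month",
    "stratum")``.  Records with stratum ``UNASSIGNED`` are excluded.  Binning
    is independent of row order and idempotent.
    """
    if records.empty:
        return []
    by = list(by)
    usable = records
    if "stratum" in usable.columns:
        usable = usable[usable["stratum"] != UNASSIGNED]
    comps = []
    for key, group in usable.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(by, key))
        comps.append(
            LengthComposition.from_lengths(
                group["length_mm"].to_numpy(float),
                bin_width=bin_width,
                stratum=meta.get("stratum"),
                year=int(meta["year"]) if "year" in meta else None,
                month=int(meta["month"]) if "month" in meta else None,
            )
        )
    return comps
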