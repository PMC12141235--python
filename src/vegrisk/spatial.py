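"""Risk-weighted spatial center of gravity and its year-over-year transfer.

For each year the centroid of risk is the weighted mean of provincial
capital coordinates with weights IR_i / Σ IR_i (whole-vegetable risk, or one
category's). Between consecutive years the centroid's displacement is
reported three ways:

* degree-space Euclidean distance √(ΔLong² + ΔLa²);
* great-circle (haversine) distance at a configurable mean Earth radius
  (default 6371.0 km);
* bearing from the four-quadrant arctangent of (ΔLong, ΔLa), 0° = due
  north, measured clockwise, plus a "<origin quadrant> to <destination
  quadrant>" transfer label (e.g. "Northeast to Southwest" for a centroid
  moving southwest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .ingest import GeoPoint

EARTH_RADIUS_KM = 6371.0

WHOLE_VEGETABLE = "WV"


@dataclass(frozen=True)
class Centroid:
    year: int
    longitude: float  # degrees E
    latitude: float  # degrees N
    scope: str = WHOLE_VEGETABLE  # whole-vegetable or one category


@dataclass(frozen=True)
class Transfer:
    from_year: int
    to_year: int
    scope: str
    d_degrees: float
    d_km: float
    bearing: Optional[float]  # degrees clockwise from due north; None if d = 0
    label: str


def haversine_km(
    lon1: float, lat1: float, lon2: float, lat2: float,
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Great-circle distance between two (lon, lat) points in km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(a)))


def centroid(
    risk_by_province: Mapping[str, float] | pd.Series,
    geo: Mapping[str, GeoPoint],
    year: int,
    scope: str = WHOLE_VEGETABLE,
) -> Centroid:
    """IR-weighted mean of provincial capital coordinates for one year.

    Provinces with zero IR contribute weight 0; an all-zero map leaves the
    centroid undefined and raises. Provinces missing from the geo table are
    an error naming the province. Negative weights are invalid.
    """
    items = list(risk_by_province.items())
    for prov, ir in items:
        if ir < 0:
            raise ValueError(f"negative risk index for {prov!r}")
        if prov not in geo:
            raise KeyError(f"no capital coordinates for province {prov!r}")
    total = sum(ir for _p, ir in items)
    if total <= 0:
        raise ValueError(f"centroid undefined for {scope} {year}: all risk indices are zero")
    lon = sum(geo[p].longitude * ir for p, ir in items) / total
    lat = sum(geo[p].latitude * ir for p, ir in items) / total
    return Centroid(year=year, longitude=lon, latitude=lat, scope=scope)


_QUADRANTS = {
    (1, 1): "Northeast",
    (1, -1): "Southeast",
    (-1, -1): "Southwest",
    (-1, 1): "Northwest",
    (0, 1): "North",
    (0, -1): "South",
    (1, 0): "East",
    (-1, 0): "West",
}

_OPPOSITE = {
    "Northeast": "Southwest",
    "Southwest": "Northeast",
    "Southeast": "Northwest",
    "Northwest": "Southeast",
    "North": "South",
    "South": "North",
    "East": "West",
    "West": "East",
}


def _direction(dlon: float, dlat: float) -> str:
    sgn = lambda v: (v > 0) - (v < 0)
    return _QUADRANTS[(sgn(dlon), sgn(dlat))]


def transfer(
    c_prev: Centroid,
    c_next: Centroid,
    radius_km: float = EARTH_RADIUS_KM,
) -> Transfer:
    """Displacement of the risk centroid between two years.

    The transfer label reads "<origin> to <destination>": the destination is
    the quadrant of motion (from the bearing), the origin its opposite — a
    centroid drifting southwest is labelled "Northeast to Southwest".
    """
    if c_prev.scope != c_next.scope:
        raise ValueError(f"scope mismatch: {c_prev.scope!r} vs {c_next.scope!r}")
    dlon = c_next.longitude - c_prev.longitude
    dlat = c_next.latitude - c_prev.latitude
    d_deg = math.hypot(dlon, dlat)
    if d_deg == 0.0:
        return Transfer(
            from_year=c_prev.year, to_year=c_next.year, scope=c_prev.scope,
            d_degrees=0.0, d_km=0.0, bearing=None, label="stationary",
        )
    d_km = haversine_km(c_prev.longitude, c_prev.latitude, c_next.longitude, c_next.latitude, radius_km)
    bearing = math.degrees(math.atan2(dlon, dlat)) % 360.0
    dest = _direction(dlon, dlat)
    return Transfer(
        from_year=c_prev.year, to_year=c_next.year, scope=c_prev.scope,
        d_degrees=d_deg, d_km=d_km, bearing=bearing,
        label=f"{_OPPOSITE[dest]} to {dest}",
    )


def centroid_track(
    yearly_risk: pd.DataFrame,
    geo: Mapping[str, GeoPoint],
    scope: str = WHOLE_VEGETABLE,
) -> tuple[list[Centroid], list[Transfer]]:
    """Centroids for every year plus transfers between consecutive years.

    ``yearly_risk`` carries columns year, province, ir (as produced by
    :func:`vegrisk.risk.provincial_yearly_risk`). Years whose provinces all
    have zero IR are skipped with their centroid undefined.
    """
    cents: list[Centroid] = []
    for year, sub in yearly_risk.groupby("year", sort=True):
        weights = dict(zip(sub["province"], sub["ir"]))
        if sum(weights.values()) <= 0:
            continue
        cents.append(centroid(weights, geo, int(year), scope))
    transfers = [transfer(a, b) for a, b in zip(cents, cents[1:])]
    return cents, transfers


def track_frame(cents: list[Centroid], transfers: list[Transfer]) -> pd.DataFrame:
    """Tabular view of a centroid track (one row per transfer)."""
    by_year = {c.year: c for c in cents}
    rows = []
    for t in transfers:
        a, b = by_year[t.from_year], by_year[t.to_year]
        rows.append(
            {
                "scope": t.scope,
                "from_year": t.from_year,
                "to_year": t.to_year,
                "from_longitude_e": a.longitude,
                "from_latitude_n": a.latitude,
                "to_longitude_e": b.longitude,
                "to_latitude_n": b.latitude,
                "label": t.label,
                "d_degrees": t.d_degrees,
                "d_km": t.d_km,
                "bearing_deg": t.bearing,
            }
        )
    return pd.DataFrame(rows)
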