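"""Reading, harmonizing and validating surveillance tables.

The pipeline starts from three delimiter-separated tables:

* **inspection records** — one row per (batch, pesticide) with columns
  ``province, vegetable, year, batch_id, pesticide, concentration, unit``;
  rows sharing a ``batch_id`` form one sampled batch. A row with BOTH the
  pesticide and concentration fields blank marks a batch sampled with no
  residue detected (it still counts toward the sampling denominator).
* **MRL table** — ``vegetable, pesticide, mrl_mg_per_kg, banned`` with the
  limit blank allowed for banned substances that have no tolerance.
* **geo table** — ``province, longitude_e, latitude_n``.

Cleaning is conservative and fully audited: every input row is either kept or
counted under an explicit drop reason in the :class:`CleaningReport`; nothing
is silently altered. Concentrations are normalized to mg/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from . import names as _names
from .names import UNMAPPED, canonicalize_name


class DataError(ValueError):
    """Raised for unreadable or structurally invalid input data."""


class ConfigError(ValueError):
    """Raised for invalid configuration (bad schema, bad policy values)."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class ResidueMeasurement:
    """A single pesticide detection in a sampled batch, in mg/kg."""

    pesticide: str
    concentration: float  # mg/kg, >= 0

    def __post_init__(self) -> None:
        if not self.pesticide:
            raise ValueError("pesticide name must be non-empty")
        if not (self.concentration >= 0):
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class InspectionRecord:
    """One sampled vegetable batch with its residue panel results."""

    batch_id: str
    province: str
    vegetable: str
    year: int
    measurements: tuple[ResidueMeasurement, ...] = ()


@dataclass(frozen=True)
class MRLEntry:
    """Permissible residue limit for a (vegetable, pesticide) pair.

    ``mrl`` is in mg/kg; banned substances may carry no limit at all, in
    which case any detection is a violation regardless of level.
    """

    vegetable: str
    pesticide: str
    mrl: Optional[float] = None
    banned: bool = False

    def __post_init__(self) -> None:
        if self.mrl is not None and not (self.mrl > 0):
            raise ValueError("mrl must be > 0 when present")
        if self.mrl is None and not self.banned:
            raise ValueError("non-banned entry must carry an mrl")


@dataclass(frozen=True)
class GeoPoint:
    province: str
    longitude: float  # degrees east
    latitude: float  # degrees north

    def __post_init__(self) -> None:
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError("longitude outside [-180, 180]")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError("latitude outside [-90, 90]")


@dataclass
class CleaningReport:
    """Row-level audit of the cleaning pass: every input row is accounted for."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_missing: int = 0
    n_dropped_unmapped_name: int = 0
    n_dropped_outlier: int = 0
    n_unit_converted: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (
            self.n_dropped_missing
            + self.n_dropped_unmapped_name
            + self.n_dropped_outlier
        )

    def check_conservation(self) -> None:
        if self.n_read != self.n_kept + self.n_dropped:
            raise AssertionError(
                f"cleaning report does not balance: read={self.n_read} "
                f"kept={self.n_kept} dropped={self.n_dropped}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_dropped"] = self.n_dropped
        return d


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SchemaConfig:
    """Column-name bindings for the inspection-record dialect."""

    province: str = "province"
    vegetable: str = "vegetable"
    year: str = "year"
    batch_id: str = "batch_id"
    pesticide: str = "pesticide"
    concentration: str = "concentration"
    unit: str = "unit"
    delimiter: str = ","

    def required(self) -> tuple[str, ...]:
        return (
            self.province,
            self.vegetable,
            self.year,
            self.batch_id,
            self.pesticide,
            self.concentration,
            self.unit,
        )


@dataclass(frozen=True)
class CleaningConfig:
    """Cleaning policy.

    ``outlier_cap`` is OFF by default: when set (and an MRL table is supplied
    to :func:`read_records`) measurements with concentration/MRL above the cap
    are dropped and counted — an auditable stand-in for an otherwise
    unspecified extreme-outlier rule, never a silent alteration.
    ``year_window`` bounds the study period; rows outside it are counted as
    invalid under ``n_dropped_missing``.
    """

    year_window: tuple[int, int] = (2021, 2023)
    outlier_cap: Optional[float] = None
    vegetable_dict: Mapping[str, str] = field(default_factory=lambda: _names.VEGETABLE_DICT)
    pesticide_dict: Mapping[str, str] = field(default_factory=lambda: _names.PESTICIDE_DICT)
    province_dict: Mapping[str, str] = field(default_factory=lambda: _names.PROVINCE_DICT)

    def __post_init__(self) -> None:
        if self.outlier_cap is not None and not (self.outlier_cap > 0):
            raise ConfigError("outlier_cap must be positive when set")
        if self.year_window[0] > self.year_window[1]:
            raise ConfigError("year_window must be (lo, hi) with lo <= hi")


# ---------------------------------------------------------------------------
# Unit normalization

# Supported unit dialects and their factor to mg/kg. ppm is a mass fraction
# synonym of mg/kg for these matrices; anything else is a counted drop.
_UNIT_FACTORS = {
    "mg/kg": 1.0,
    "mg kg-1": 1.0,
    "ppm": 1.0,
    "ug/kg": 1e-3,
    "µg/kg": 1e-3,
    "μg/kg": 1e-3,
    "ug kg-1": 1e-3,
    "ppb": 1e-3,
}


def normalize_concentration(value: float, unit: str) -> float:
    """Convert a concentration to mg/kg.

    Raises :class:`ValueError` for unsupported unit strings so the caller can
    drop (and count) the row instead of guessing.
    """
    key = str(unit).strip().lower()
    try:
        factor = _UNIT_FACTORS[key]
    except KeyError:
        raise ValueError(f"unsupported concentration unit: {unit!r}") from None
    return float(value) * factor


def unit_factor(unit: str) -> Optional[float]:
    return _UNIT_FACTORS.get(str(unit).strip().lower())


# ---------------------------------------------------------------------------
# Record reading


def _is_blank(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return str(v).strip() == ""


def read_records(
    path: Union[str, Path, pd.DataFrame],
    schema: SchemaConfig | None = None,
    cleaning: CleaningConfig | None = None,
    mrl_table: Optional["MRLTable"] = None,
) -> tuple[list[InspectionRecord], CleaningReport]:
    """Read, harmonize and validate an inspection-record table.

    Accepts a path to a delimited file or an already-loaded DataFrame.
    Returns the surviving records plus a :class:`CleaningReport` whose counts
    reconcile exactly with the number of input rows. Duplicate batch ids with
    conflicting (province, vegetable, year) keys are a fatal
    :class:`DataError` — the sampling protocol guarantees non-duplication.
    """
    schema = schema or SchemaConfig()
    cleaning = cleaning or CleaningConfig()

    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        p = Path(path)
        if not p.exists():
            raise DataError(f"records file not found: {p}")
        try:
            df = pd.read_csv(p, sep=schema.delimiter, dtype=str, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise DataError(f"unreadable records file {p}: {exc}") from exc

    missing_cols = [c for c in schema.required() if c not in df.columns]
    if missing_cols:
        raise ConfigError(
            f"records table lacks required columns {missing_cols}; "
            f"present: {list(df.columns)}"
        )

    report = CleaningReport(n_read=len(df))
    lo, hi = cleaning.year_window

    # batch_id -> (province, vegetable, year), measurements
    keys: dict[str, tuple[str, str, int]] = {}
    measurements: dict[str, list[ResidueMeasurement]] = {}
    order: list[str] = []

    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        prov_raw = rec[schema.province]
        veg_raw = rec[schema.vegetable]
        year_raw = rec[schema.year]
        bid = str(rec[schema.batch_id]).strip()
        pest_raw = rec[schema.pesticide]
        conc_raw = rec[schema.concentration]
        unit_raw = rec[schema.unit]

        if _is_blank(prov_raw) or _is_blank(veg_raw) or _is_blank(year_raw) or not bid:
            report.n_dropped_missing += 1
            continue

        # full dates reduce to the calendar year (annual centroid analysis)
        try:
            year = int(str(year_raw).strip()[:4])
        except ValueError:
            report.n_dropped_missing += 1
            continue
        if not (lo <= year <= hi):
            report.n_dropped_missing += 1
            report.warnings.append(f"batch {bid}: year {year} outside study window")
            continue

        province = canonicalize_name(prov_raw, cleaning.province_dict)
        vegetable = canonicalize_name(veg_raw, cleaning.vegetable_dict)
        if province is UNMAPPED or vegetable is UNMAPPED:
            report.n_dropped_unmapped_name += 1
            continue

        no_detection = _is_blank(pest_raw) and _is_blank(conc_raw)
        meas: Optional[ResidueMeasurement] = None
        if not no_detection:
            if _is_blank(pest_raw) or _is_blank(conc_raw):
                report.n_dropped_missing += 1
                continue
            pesticide = canonicalize_name(pest_raw, cleaning.pesticide_dict)
            if pesticide is UNMAPPED:
                report.n_dropped_unmapped_name += 1
                continue
            factor = unit_factor(unit_raw)
            if factor is None:
                report.n_dropped_missing += 1
                report.warnings.append(
                    f"batch {bid}: unsupported unit {unit_raw!r}, row dropped"
                )
                continue
            try:
                conc = float(str(conc_raw).strip())
            except ValueError:
                report.n_dropped_missing += 1
                continue
            if conc < 0:
                report.n_dropped_missing += 1
                continue
            if factor != 1.0:
                report.n_unit_converted += 1
            conc = conc * factor
            if (
                cleaning.outlier_cap is not None
                and mrl_table is not None
            ):
                entry = mrl_table.lookup(vegetable, pesticide)
                if entry is not None and entry.mrl:
                    if conc / entry.mrl > cleaning.outlier_cap:
                        report.n_dropped_outlier += 1
                        report.warnings.append(
                            f"batch {bid}: {pesticide} at {conc:g} mg/kg exceeds "
                            f"outlier cap ({cleaning.outlier_cap}x MRL), row dropped"
                        )
                        continue
            meas = ResidueMeasurement(pesticide, conc)

        key = (province, vegetable, year)
        if bid in keys:
            if keys[bid] != key:
                raise DataError(
                    f"duplicate batch_id {bid!r} with conflicting keys "
                    f"{keys[bid]} vs {key}"
                )
        else:
            keys[bid] = key
            measurements[bid] = []
            order.append(bid)
        if meas is not None:
            measurements[bid].append(meas)
        report.n_kept += 1

    report.check_conservation()
    records = [
        InspectionRecord(
            batch_id=bid,
            province=keys[bid][0],
            vegetable=keys[bid][1],
            year=keys[bid][2],
            measurements=tuple(measurements[bid]),
        )
        for bid in order
    ]
    return records, report


def records_to_frame(records: Iterable[InspectionRecord]) -> pd.DataFrame:
    """Serialize records back to the canonical table dialect (mg/kg)."""
    rows = []
    for r in records:
        if not r.measurements:
            rows.append((r.province, r.vegetable, r.year, r.batch_id, "", "", ""))
        for m in r.measurements:
            rows.append(
                (r.province, r.vegetable, r.year, r.batch_id, m.pesticide,
                 repr(m.concentration), "mg/kg")
            )
    return pd.DataFrame(
        rows,
        columns=["province", "vegetable", "year", "batch_id", "pesticide",
                 "concentration", "unit"],
    )


def write_records(records: Iterable[InspectionRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MRL table


class MRLTable:
    """MRL entries indexed by (vegetable, pesticide), case-insensitive."""

    def __init__(self, entries: Iterable[MRLEntry]):
        self._index: dict[tuple[str, str], MRLEntry] = {}
        for e in entries:
            key = (e.vegetable.lower(), e.pesticide.lower())
            if key in self._index:
                raise DataError(f"duplicate MRL entry for {key}")
            self._index[key] = e

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, vegetable: str, pesticide: str) -> Optional[MRLEntry]:
        return self._index.get((vegetable.lower(), pesticide.lower()))

    @property
    def entries(self) -> list[MRLEntry]:
        return list(self._index.values())


def read_mrl_table(path: Union[str, Path, pd.DataFrame]) -> MRLTable:
    """Load an MRL table (columns vegetable, pesticide, mrl_mg_per_kg, banned)."""
    if isinstance(path, pd.DataFrame):
        df = path
    else:
        p = Path(path)
        if not p.exists():
            raise DataError(f"MRL table not found: {p}")
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    required = {"vegetable", "pesticide", "mrl_mg_per_kg", "banned"}
    if not required.issubset(df.columns):
        raise ConfigError(f"MRL table needs columns {sorted(required)}")
    entries = []
    for row in df.itertuples(index=False):
        mrl = None if _is_blank(row.mrl_mg_per_kg) else float(row.mrl_mg_per_kg)
        banned = str(row.banned).strip().lower() in {"1", "true", "yes"}
        entries.append(MRLEntry(str(row.vegetable), str(row.pesticide), mrl, banned))
    return MRLTable(entries)


def read_geo_table(path: Union[str, Path, pd.DataFrame]) -> dict[str, GeoPoint]:
    """Load the province -> capital-coordinate table."""
    if isinstance(path, pd.DataFrame):
        df = path
    else:
        p = Path(path)
        if not p.exists():
            raise DataError(f"geo table not found: {p}")
        df = pd.read_csv(p)
    required = {"province", "longitude_e", "latitude_n"}
    if not required.issubset(df.columns):
        raise ConfigError(f"geo table needs columns {sorted(required)}")
    return {
        str(r.province): GeoPoint(str(r.province), float(r.longitude_e), float(r.latitude_n))
        for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# MRL matching


#: binding kinds
LIMIT, BANNED, NO_LIMIT = "limit", "banned", "no_limit"


@dataclass(frozen=True)
class LimitBinding:
    """A measurement tied to its applicable standard (or the lack of one)."""

    measurement: ResidueMeasurement
    kind: str  # limit | banned | no_limit
    entry: Optional[MRLEntry] = None


def match_mrl(record: InspectionRecord, mrl_table: MRLTable) -> list[LimitBinding]:
    """Bind every measurement of a batch to its MRL entry.

    Each measurement resolves to a limit entry, a banned entry (with or
    without a tolerance) or an explicit no-limit marker for substances absent
    from the standard; the compliance policy decides what a no-limit
    detection means.
    """
    bindings = []
    for m in record.measurements:
        entry = mrl_table.lookup(record.vegetable, m.pesticide)
        if entry is None:
            bindings.append(LimitBinding(m, NO_LIMIT, None))
        elif entry.banned:
            bindings.append(LimitBinding(m, BANNED, entry))
        else:
            bindings.append(LimitBinding(m, LIMIT, entry))
    return bindings
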