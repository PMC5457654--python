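"""Injury-registry schema, validation, variable encodings and CSV I/O.

One row of the registry is a single pedestrian transported by ambulance
after a traffic collision.  Beyond demographics and the binary severity
outcome (severe = admitted to hospital, incl. death in transit/at
hospital; minor = discharged home after evaluation), each record carries
planar residence and injury-site coordinates, road attributes at the
injury site and area-level attributes of the residence (aging rate and
proportion of low-income households, both in percent).

Only adults are admissible: cases aged 17 years and under are excluded
from the analysis, so ``age >= 18`` is a hard validation rule here.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "RegistryError",
    "SchemaError",
    "RecordValidationError",
    "InjuryRecord",
    "RecordSet",
    "GENDERS",
    "SEVERITIES",
    "AGE_GROUPS",
    "ROAD_WIDTH_LEVELS",
    "TIME_BINS",
    "SEASONS",
    "derive_age_group",
    "encode_road_width",
    "derive_season",
    "derive_time_bin",
    "read_registry",
    "read_registry_with_exclusions",
    "write_registry",
]


class RegistryError(ValueError):
    """Base class for registry schema/validation problems."""


class SchemaError(RegistryError):
    """The CSV header does not match the documented schema."""


class RecordValidationError(RegistryError):
    """A record violates a field invariant."""


GENDERS = ("male", "female")
SEVERITIES = ("minor", "severe")
AGE_GROUPS = ("working_age", "older")

#: Ordinal road-width classes, metres per lane, ascending.
ROAD_WIDTH_LEVELS = ("lt3", "w3to5_5", "w5_5to13", "gt13")
_ROAD_WIDTH_BOUNDS = (3.0, 5.5, 13.0)

#: Six 4-hour clock bins, in day order.
TIME_BINS = ("00-04", "04-08", "08-12", "12-16", "16-20", "20-24")

SEASONS = ("spring", "summer", "fall", "winter")
_SEASON_BY_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
}


def derive_age_group(age: int) -> str:
    """Map an adult age in years to ``working_age`` (18-64) or ``older`` (>=65)."""
    if age < 18:
        raise RecordValidationError(f"age {age} is below the adult inclusion threshold of 18")
    return "older" if age >= 65 else "working_age"


def encode_road_width(width_m: float) -> str:
    """Encode a measured road width per lane (metres) into its ordinal class.

    Classes are half-open intervals [0,3), [3,5.5), [5.5,13), [13,inf),
    so a boundary width falls in the upper class.
    """
    if not (width_m > 0) or not math.isfinite(width_m):
        raise RecordValidationError(f"road width must be a positive finite number, got {width_m}")
    for level, bound in zip(ROAD_WIDTH_LEVELS, _ROAD_WIDTH_BOUNDS):
        if width_m < bound:
            return level
    return ROAD_WIDTH_LEVELS[-1]


def derive_season(month: int) -> str:
    """Meteorological season for a calendar month (Mar-May spring, etc.)."""
    if month not in _SEASON_BY_MONTH:
        raise RecordValidationError(f"month must be in 1..12, got {month}")
    return _SEASON_BY_MONTH[month]


def derive_time_bin(hour: int) -> str:
    """4-hour clock bin ("00-04" .. "20-24") for an hour of day."""
    if not 0 <= hour <= 23:
        raise RecordValidationError(f"hour must be in 0..23, got {hour}")
    return TIME_BINS[hour // 4]


def _check_pct(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise RecordValidationError(f"{name} must lie in [0, 100], got {value}")


def _check_xy(name: str, xy: tuple) -> None:
    if len(xy) != 2 or not all(math.isfinite(v) for v in xy):
        raise RecordValidationError(f"{name} must be a pair of finite planar coordinates, got {xy!r}")


@dataclass
class InjuryRecord:
    """A single transported pedestrian injury case."""

    record_id: str
    age: int
    gender: str
    injury_datetime: datetime
    residence_xy: tuple[float, float]
    injury_xy: tuple[float, float]
    national_road: bool
    road_width_class: str
    did: bool
    aging_rate: float
    low_ses_prop: float
    severity: str
    network_distance_m: Optional[float] = None
    euclidean_distance_m: Optional[float] = None

    def __post_init__(self) -> None:
        self.age = int(self.age)
        if self.age < 18:
            raise RecordValidationError(
                f"record {self.record_id}: age {self.age} excluded (under 18)")
        if self.gender not in GENDERS:
            raise RecordValidationError(
                f"record {self.record_id}: gender must be one of {GENDERS}, got {self.gender!r}")
        if self.road_width_class not in ROAD_WIDTH_LEVELS:
            raise RecordValidationError(
                f"record {self.record_id}: road_width_class must be one of "
                f"{ROAD_WIDTH_LEVELS}, got {self.road_width_class!r}")
        if self.severity not in SEVERITIES:
            raise RecordValidationError(
                f"record {self.record_id}: severity must be one of {SEVERITIES}, "
                f"got {self.severity!r}")
        _check_pct(f"record {self.record_id}: aging_rate", self.aging_rate)
        _check_pct(f"record {self.record_id}: low_ses_prop", self.low_ses_prop)
        _check_xy(f"record {self.record_id}: residence_xy", self.residence_xy)
        _check_xy(f"record {self.record_id}: injury_xy", self.injury_xy)
        self.residence_xy = (float(self.residence_xy[0]), float(self.residence_xy[1]))
        self.injury_xy = (float(self.injury_xy[0]), float(self.injury_xy[1]))
        if self.network_distance_m is not None and self.network_distance_m < 0:
            raise RecordValidationError(
                f"record {self.record_id}: network_distance_m must be >= 0")

    # ---- derived attributes -------------------------------------------------

    @property
    def age_group(self) -> str:
        return derive_age_group(self.age)

    @property
    def time_bin(self) -> str:
        return derive_time_bin(self.injury_datetime.hour)

    @property
    def season(self) -> str:
        return derive_season(self.injury_datetime.month)

    @property
    def severe(self) -> bool:
        return self.severity == "severe"


@dataclass
class RecordSet:
    """An ordered collection of validated injury records with unique ids."""

    records: list[InjuryRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise RecordValidationError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InjuryRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> InjuryRecord:
        return self.records[i]

    def subset(self, predicate) -> "RecordSet":
        return RecordSet([r for r in self.records if predicate(r)], provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Analysis frame with one column per study variable plus the outcome.

        ``severe`` is boolean; categorical variables are plain strings so
        tests of independence and cut enumeration can treat them uniformly.
        """
        rows = []
        for r in self.records:
            rows.append({
                "record_id": r.record_id,
                "age": r.age,
                "gender": r.gender,
                "time_bin": r.time_bin,
                "season": r.season,
                "network_distance_m": r.network_distance_m,
                "euclidean_distance_m": r.euclidean_distance_m,
                "national_road": r.national_road,
                "road_width_class": r.road_width_class,
                "did": r.did,
                "aging_rate": r.aging_rate,
                "low_ses_prop": r.low_ses_prop,
                "age_group": r.age_group,
                "severity": r.severity,
                "severe": r.severe,
            })
        df = pd.DataFrame(rows)
        if len(df):
            df = df.set_index("record_id", drop=True)
        return df


# ---- CSV I/O ---------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "record_id", "age", "gender", "injury_datetime",
    "residence_x", "residence_y", "injury_x", "injury_y",
    "national_road", "did", "aging_rate", "low_ses_prop", "severity",
)
_BOOL_TRUE = {"1", "true", "yes"}
_BOOL_FALSE = {"0", "false", "no"}


def _parse_bool(raw: str, column: str, row_num: int) -> bool:
    token = raw.strip().lower()
    if token in _BOOL_TRUE:
        return True
    if token in _BOOL_FALSE:
        return False
    raise RecordValidationError(f"row {row_num}: cannot parse {column}={raw!r} as boolean")


def _parse_float(raw: str, column: str, row_num: int) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise RecordValidationError(f"row {row_num}: cannot parse {column}={raw!r} as number") from exc


def read_registry(path) -> RecordSet:
    """Read and validate a registry CSV; any invalid row raises.

    The header must contain the documented columns plus exactly one of
    ``road_width_m`` (measured metres, encoded on read) or
    ``road_width_class`` (one of the four ordinal tokens).
    """
    recs, _ = _read(path, exclude_underage=False)
    return RecordSet(recs, provenance=str(path))


def read_registry_with_exclusions(path) -> tuple[RecordSet, dict]:
    """Like :func:`read_registry` but silently drops under-18 rows.

    Returns the record set and a count dict ``{"read": ..,
    "excluded_underage": ..}`` for pipeline accounting.
    """
    recs, excluded = _read(path, exclude_underage=True)
    return RecordSet(recs, provenance=str(path)), {
        "read": len(recs) + excluded, "excluded_underage": excluded}


def _read(path, exclude_underage: bool) -> tuple[list[InjuryRecord], int]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        if "road_width_m" not in header and "road_width_class" not in header:
            raise SchemaError("missing required column 'road_width_m' or 'road_width_class'")

        records: list[InjuryRecord] = []
        excluded = 0
        for row_num, row in enumerate(reader, start=2):
            try:
                age = int(_parse_float(row["age"], "age", row_num))
            except RecordValidationError:
                raise
            if exclude_underage and age < 18:
                excluded += 1
                continue
            try:
                dt = datetime.fromisoformat(row["injury_datetime"].strip())
            except ValueError as exc:
                raise RecordValidationError(
                    f"row {row_num}: cannot parse injury_datetime="
                    f"{row['injury_datetime']!r} as ISO 8601") from exc
            if "road_width_class" in header and row.get("road_width_class", "").strip():
                width_class = row["road_width_class"].strip()
            else:
                width_class = encode_road_width(
                    _parse_float(row["road_width_m"], "road_width_m", row_num))
            nd = row.get("network_distance_m", "").strip() if "network_distance_m" in header else ""
            ed = row.get("euclidean_distance_m", "").strip() if "euclidean_distance_m" in header else ""
            try:
                rec = InjuryRecord(
                    record_id=row["record_id"].strip(),
                    age=age,
                    gender=row["gender"].strip(),
                    injury_datetime=dt,
                    residence_xy=(_parse_float(row["residence_x"], "residence_x", row_num),
                                  _parse_float(row["residence_y"], "residence_y", row_num)),
                    injury_xy=(_parse_float(row["injury_x"], "injury_x", row_num),
                               _parse_float(row["injury_y"], "injury_y", row_num)),
                    national_road=_parse_bool(row["national_road"], "national_road", row_num),
                    road_width_class=width_class,
                    did=_parse_bool(row["did"], "did", row_num),
                    aging_rate=_parse_float(row["aging_rate"], "aging_rate", row_num),
                    low_ses_prop=_parse_float(row["low_ses_prop"], "low_ses_prop", row_num),
                    severity=row["severity"].strip(),
                    network_distance_m=float(nd) if nd else None,
                    euclidean_distance_m=float(ed) if ed else None,
                )
            except RecordValidationError as exc:
                raise RecordValidationError(f"row {row_num}: {exc}") from exc
            records.append(rec)
    return records, excluded


_OUT_COLUMNS = _REQUIRED_COLUMNS[:8] + ("national_road", "road_width_class", "did",
                                        "aging_rate", "low_ses_prop", "severity",
                                        "age_group", "time_bin", "season",
                                        "euclidean_distance_m", "network_distance_m")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def write_registry(records: RecordSet | Iterable[InjuryRecord], path) -> None:
    """Write the validated/derived registry CSV (UTF-8, comma, '.' decimals).

    Floats are written in their shortest exact representation so a
    read-write-read cycle is the identity on every field.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_OUT_COLUMNS)
        for r in records:
            writer.writerow([
                r.record_id, r.age, r.gender, r.injury_datetime.isoformat(),
                _fmt(r.residence_xy[0]), _fmt(r.residence_xy[1]),
                _fmt(r.injury_xy[0]), _fmt(r.injury_xy[1]),
                _fmt(r.national_road), r.road_width_class, _fmt(r.did),
                _fmt(float(r.aging_rate)), _fmt(float(r.low_ses_prop)), r.severity,
                r.age_group, r.time_bin, r.season,
                _fmt(r.euclidean_distance_m), _fmt(r.network_distance_m),
            ])
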