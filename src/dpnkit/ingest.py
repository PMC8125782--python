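"""Reading, filtering and aggregating prescription records.

A record is one dispensed-drug event: patient identifier, sex, birth
year, dispensation date and a level-5 ATC code.  Ingest applies the
inclusion/exclusion filters (rows with missing mandatory fields or
unparseable ATC codes or dates are dropped as incomplete/ambiguous;
patients are restricted to a birth-year range) and aggregates the
surviving records into per-patient *sets* of distinct codes at each ATC
level.  Those sets are the basis of drug "popularity": Pi counts the
patients prescribed drug i at least once, never the number of
prescription events.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .atc import ATCCode, ATCError, parse_atc, project_to_level

__all__ = [
    "PrescriptionRecord",
    "FilterReport",
    "IncidenceMap",
    "DEFAULT_COLUMNS",
    "DEFAULT_AGE_BINS",
    "load_records",
    "filter_birth_year",
    "build_incidence",
    "demography_table",
]

#: Default column mapping from logical field -> header name in the file.
DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "sex": "sex",
    "birth_year": "birth_year",
    "date": "date",
    "atc5": "atc5",
}

#: Default age strata: 0-21, 22-64, >=65 years at the index date.
DEFAULT_AGE_BINS = ((0, 21), (22, 64), (65, None))


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensed-drug event."""

    patient_id: str
    sex: str  # "F" or "M"
    birth_year: int
    date: _dt.date
    atc5: ATCCode


@dataclass
class FilterReport:
    """Bookkeeping for one filtering stage."""

    records_in: int = 0
    records_out: int = 0
    patients_in: int = 0
    patients_out: int = 0
    dropped_by_rule: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "records_in": self.records_in,
            "records_out": self.records_out,
            "patients_in": self.patients_in,
            "patients_out": self.patients_out,
            "dropped_by_rule": dict(self.dropped_by_rule),
        }


@dataclass
class IncidenceMap:
    """Per-patient sets of distinct ATC codes at one hierarchy level."""

    level: int
    sets: dict[str, frozenset[ATCCode]]

    @property
    def n_patients(self) -> int:
        return len(self.sets)

    def popularity(self) -> Counter:
        """Pi for every code: number of patients whose set contains it."""
        counts: Counter = Counter()
        for codes in self.sets.values():
            counts.update(codes)
        return counts


class SchemaError(ValueError):
    """Input file lacks the mapped columns."""


def load_records(
    path,
    columns: dict[str, str] | None = None,
    delimiter: str = ",",
    allow_list: frozenset[str] | None = None,
) -> tuple[list[PrescriptionRecord], FilterReport]:
    """Read delimited prescription records, dropping incomplete/ambiguous rows.

    A row is incomplete or ambiguous when a mandatory field is missing,
    the ATC string does not parse, the date is not ISO-8601, the sex is
    not F/M, or the birth year is not an integer no later than the
    dispensation year.  Such rows are counted under
    ``dropped_by_rule["incomplete_or_ambiguous"]``.

    Parameters
    ----------
    columns
        Mapping logical field name -> header name; defaults to
        :data:`DEFAULT_COLUMNS`.
    allow_list
        Optional set of level-5 code strings enabling strict validation.
    """
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    try:
        df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read records file {path!r}: {exc}") from exc
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"input file lacks mapped columns: {missing}")

    records: list[PrescriptionRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        rec = _parse_row(row._asdict(), cols, allow_list)
        if rec is None:
            dropped += 1
        else:
            records.append(rec)

    report = FilterReport(
        records_in=len(df),
        records_out=len(records),
        patients_in=df[cols["patient_id"]].replace("", pd.NA).nunique(dropna=True),
        patients_out=len({r.patient_id for r in records}),
        dropped_by_rule={"incomplete_or_ambiguous": dropped} if dropped else {},
    )
    return records, report


def _parse_row(row: dict, cols: dict, allow_list) -> PrescriptionRecord | None:
    try:
        pid = str(row[cols["patient_id"]]).strip()
        sex = str(row[cols["sex"]]).strip().upper()
        if not pid or sex not in ("F", "M"):
            return None
        birth_year = int(str(row[cols["birth_year"]]).strip())
        date = _dt.date.fromisoformat(str(row[cols["date"]]).strip())
        atc = parse_atc(str(row[cols["atc5"]]))
        if atc.level != 5:
            return None
        if allow_list is not None and atc.text not in allow_list:
            return None
        if birth_year > date.year:
            return None
    except (ValueError, ATCError):
        return None
    return PrescriptionRecord(pid, sex, birth_year, date, atc)


def filter_birth_year(
    records: list[PrescriptionRecord],
    min_year: int = 1919,
    max_year: int = 2019,
) -> tuple[list[PrescriptionRecord], FilterReport]:
    """Keep records with ``min_year <= birth_year <= max_year`` (inclusive)."""
    if min_year > max_year:
        raise ValueError("min_year must not exceed max_year")
    kept = [r for r in records if min_year <= r.birth_year <= max_year]
    n_dropped = len(records) - len(kept)
    report = FilterReport(
        records_in=len(records),
        records_out=len(kept),
        patients_in=len({r.patient_id for r in records}),
        patients_out=len({r.patient_id for r in kept}),
        dropped_by_rule={"birth_year_out_of_range": n_dropped} if n_dropped else {},
    )
    return kept, report


def build_incidence(records: list[PrescriptionRecord], level: int) -> IncidenceMap:
    """Aggregate records to per-patient sets of distinct codes at ``level``.

    Each record's level-5 code is projected up the hierarchy; repeat
    prescriptions of the same (projected) code contribute a single set
    membership.
    """
    if level not in range(1, 6):
        raise ValueError(f"level must be 1-5, got {level!r}")
    sets: dict[str, set[ATCCode]] = {}
    for rec in records:
        sets.setdefault(rec.patient_id, set()).add(project_to_level(rec.atc5, level))
    return IncidenceMap(level=level, sets={p: frozenset(s) for p, s in sets.items()})


def _age_at(birth_year: int, index_date: _dt.date) -> int:
    # birth year only is recorded, so age is the calendar-year difference
    return index_date.year - birth_year


def _stratum_label(age: int, bins) -> str | None:
    for lo, hi in bins:
        if hi is None:
            if age >= lo:
                return f"{lo}+"
        elif lo <= age <= hi:
            return f"{lo}-{hi}"
    return None


def demography_table(
    records: list[PrescriptionRecord],
    index_date: _dt.date,
    age_bins=DEFAULT_AGE_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Patient and prescription counts by sex and age stratum.

    Returns two tables — patients and prescription events — each with
    counts and percentages of the respective total (percentages sum to
    100 within rounding), plus a report of records excluded for a
    negative age at the index date.
    """
    strata = [f"{lo}-{hi}" if hi is not None else f"{lo}+" for lo, hi in age_bins]
    pat_counts = {(s, st): set() for s in "FM" for st in strata}
    rx_counts = Counter()
    excluded = 0
    for rec in records:
        age = _age_at(rec.birth_year, index_date)
        label = _stratum_label(age, age_bins) if age >= 0 else None
        if label is None:
            excluded += 1
            continue
        pat_counts[(rec.sex, label)].add(rec.patient_id)
        rx_counts[(rec.sex, label)] += 1

    def _table(counts: dict) -> pd.DataFrame:
        rows = [
            {"sex": s, "age_stratum": st, "count": counts.get((s, st), 0)}
            for s in "FM"
            for st in strata
        ]
        df = pd.DataFrame(rows)
        total = df["count"].sum()
        df["percent"] = 100.0 * df["count"] / total if total else 0.0
        return df

    patients = _table({k: len(v) for k, v in pat_counts.items()})
    prescriptions = _table(rx_counts)
    report = FilterReport(
        records_in=len(records),
        records_out=len(records) - excluded,
        patients_in=len({r.patient_id for r in records}),
        patients_out=int(patients["count"].sum()),
        dropped_by_rule={"negative_or_unbinned_age": excluded} if excluded else {},
    )
    return patients, prescriptions, report
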