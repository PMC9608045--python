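"""Reading and writing spontaneous-reporting-system tables in the JADER layout.

The Japanese Adverse Drug Event Report database (JADER) distributes linked
tables sharing a case identification number: patient demographics (DEMO),
drug records (DRUG) and adverse events (REAC).  This module reads a
simplified CSV rendering of that layout into an in-memory
:class:`ReportDataset`, normalising drug names (whitespace trimming) and
parsing the partially-specified ``YYYYMMDD`` date strings the source uses.

Dates in JADER may be truncated to year or year-month precision.  All
downstream timing logic needs day resolution, so partial dates are mapped to
*missing* rather than imputed; see :func:`parse_partial_date`.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "DEMO_COLUMNS",
    "DRUG_COLUMNS",
    "REAC_COLUMNS",
    "SchemaError",
    "CaseDemographics",
    "DrugRecord",
    "EventRecord",
    "RejectedRow",
    "ReportDataset",
    "parse_partial_date",
    "read_report_tables",
    "dataset_from_frames",
    "write_report_tables",
    "write_rejects_log",
]

DEMO_COLUMNS = ("case_id", "sex", "age")
DRUG_COLUMNS = ("case_id", "drug_name", "route", "start_date", "end_date")
REAC_COLUMNS = ("case_id", "pt_code", "pt_name", "onset_date")


class SchemaError(ValueError):
    """An input table is missing a required column."""


def parse_partial_date(text: str) -> Optional[_dt.date]:
    """Parse a JADER-style ``YYYYMMDD`` date string.

    Returns a :class:`datetime.date` only for a full, valid eight-digit
    date.  Empty strings, year (``YYYY``) or year-month (``YYYYMM``)
    truncations and anything unparseable map to ``None``: timing rules need
    day resolution and any imputation convention would fabricate
    information.  The function is total — it never raises on string input.
    """
    if text is None:
        return None
    text = str(text).strip()
    if len(text) != 8 or not text.isdigit():
        return None
    try:
        return _dt.date(int(text[:4]), int(text[4:6]), int(text[6:8]))
    except ValueError:
        return None


def _format_date(d: Optional[_dt.date], raw: str) -> str:
    # raw strings are preserved verbatim so that write(read(f)) round-trips
    return raw


@dataclass(frozen=True)
class CaseDemographics:
    """One DEMO row: case identifier, sex and age band.

    JADER stores age as decade bands (e.g. ``"60s"``); the band string is
    kept verbatim and never converted to a numeric.
    """

    case_id: str
    sex: str
    age_band: str


@dataclass(frozen=True)
class DrugRecord:
    """One DRUG row.

    ``start_date``/``end_date`` hold the parsed calendar dates (``None``
    when missing or partial); the raw source strings are retained for
    lossless round-tripping.  Rows whose start date falls after their end
    date are kept but flagged (``date_order_violation``) and both parsed
    dates are treated as missing — real SRS data contains such rows and
    silently dropping them would bias counts.
    """

    case_id: str
    drug_name: str
    route: str
    start_date: Optional[_dt.date]
    end_date: Optional[_dt.date]
    record_order: int
    start_date_raw: str = ""
    end_date_raw: str = ""
    date_order_violation: bool = False


@dataclass(frozen=True)
class EventRecord:
    """One REAC row: a MedDRA preferred term with optional onset date."""

    case_id: str
    pt_code: str
    pt_name: str
    onset_date: Optional[_dt.date]
    record_order: int
    onset_date_raw: str = ""


@dataclass(frozen=True)
class RejectedRow:
    table: str
    row_index: int
    case_id: str
    reason: str


@dataclass
class ReportDataset:
    """The three linked SRS tables, keyed by case identifier.

    Source row order is preserved; ``demo_order`` maps a case id to its DEMO
    row index (registration order, used by duplicate-case resolution).
    Rows whose case id does not appear in DEMO are excluded at read time and
    recorded in ``rejects``.
    """

    demographics: list[CaseDemographics] = field(default_factory=list)
    drugs: list[DrugRecord] = field(default_factory=list)
    events: list[EventRecord] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._demo_order = {d.case_id: i for i, d in enumerate(self.demographics)}
        self._drugs_by_case: dict[str, list[DrugRecord]] = {}
        for r in self.drugs:
            self._drugs_by_case.setdefault(r.case_id, []).append(r)
        self._events_by_case: dict[str, list[EventRecord]] = {}
        for e in self.events:
            self._events_by_case.setdefault(e.case_id, []).append(e)

    @property
    def case_ids(self) -> list[str]:
        return [d.case_id for d in self.demographics]

    @property
    def demo_order(self) -> dict[str, int]:
        return self._demo_order

    def demographics_of(self, case_id: str) -> CaseDemographics:
        return self.demographics[self._demo_order[case_id]]

    def drugs_of(self, case_id: str) -> list[DrugRecord]:
        return self._drugs_by_case.get(case_id, [])

    def events_of(self, case_id: str) -> list[EventRecord]:
        return self._events_by_case.get(case_id, [])


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {', '.join(missing)}")


def dataset_from_frames(
    demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame
) -> ReportDataset:
    """Build a :class:`ReportDataset` from in-memory string DataFrames.

    Shared by :func:`read_report_tables` and the synthetic-data generator so
    every dataset passes through the same normalisation and validation.
    """
    _require_columns(demo, DEMO_COLUMNS, "DEMO")
    _require_columns(drug, DRUG_COLUMNS, "DRUG")
    _require_columns(reac, REAC_COLUMNS, "REAC")

    rejects: list[RejectedRow] = []
    demographics: list[CaseDemographics] = []
    seen: set[str] = set()
    for i, row in enumerate(demo.itertuples(index=False)):
        cid = str(row.case_id).strip()
        if not cid:
            rejects.append(RejectedRow("DEMO", i, cid, "empty case_id"))
            continue
        if cid in seen:
            rejects.append(RejectedRow("DEMO", i, cid, "duplicate case_id in DEMO"))
            continue
        seen.add(cid)
        demographics.append(CaseDemographics(cid, str(row.sex), str(row.age)))

    drugs: list[DrugRecord] = []
    for i, row in enumerate(drug.itertuples(index=False)):
        cid = str(row.case_id).strip()
        if cid not in seen:
            rejects.append(RejectedRow("DRUG", i, cid, "case_id absent from DEMO"))
            continue
        start_raw = "" if pd.isna(row.start_date) else str(row.start_date).strip()
        end_raw = "" if pd.isna(row.end_date) else str(row.end_date).strip()
        start = parse_partial_date(start_raw)
        end = parse_partial_date(end_raw)
        violation = start is not None and end is not None and start > end
        if violation:
            start = end = None
        drugs.append(
            DrugRecord(
                case_id=cid,
                drug_name=str(row.drug_name).strip(),
                route=str(row.route).strip(),
                start_date=start,
                end_date=end,
                record_order=i,
                start_date_raw=start_raw,
                end_date_raw=end_raw,
                date_order_violation=violation,
            )
        )

    events: list[EventRecord] = []
    for i, row in enumerate(reac.itertuples(index=False)):
        cid = str(row.case_id).strip()
        if cid not in seen:
            rejects.append(RejectedRow("REAC", i, cid, "case_id absent from DEMO"))
            continue
        pt_code = str(row.pt_code).strip()
        if not pt_code:
            rejects.append(RejectedRow("REAC", i, cid, "empty pt_code"))
            continue
        onset_raw = "" if pd.isna(row.onset_date) else str(row.onset_date).strip()
        events.append(
            EventRecord(
                case_id=cid,
                pt_code=pt_code,
                pt_name=str(row.pt_name),
                onset_date=parse_partial_date(onset_raw),
                record_order=i,
                onset_date_raw=onset_raw,
            )
        )

    return ReportDataset(demographics, drugs, events, rejects)


def _read_csv(path: str | Path, encoding: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding=encoding)


def read_report_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    encoding: str = "utf-8",
) -> ReportDataset:
    """Read the DEMO/DRUG/REAC CSV triple into a :class:`ReportDataset`.

    All fields are read as strings, dates parsed leniently and source row
    order preserved.  Drug or event rows whose case id is absent from DEMO
    are excluded and recorded in the dataset's rejects list (retrievable via
    :func:`write_rejects_log`).
    """
    demo = _read_csv(demo_path, encoding)
    drug = _read_csv(drug_path, encoding)
    reac = _read_csv(reac_path, encoding)
    return dataset_from_frames(demo, drug, reac)


def write_report_tables(
    dataset: ReportDataset,
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    encoding: str = "utf-8",
) -> None:
    """Write a dataset back to the three-CSV layout (lossless round-trip)."""
    demo = pd.DataFrame(
        [(d.case_id, d.sex, d.age_band) for d in dataset.demographics],
        columns=list(DEMO_COLUMNS),
    )
    drug = pd.DataFrame(
        [
            (r.case_id, r.drug_name, r.route, r.start_date_raw, r.end_date_raw)
            for r in sorted(dataset.drugs, key=lambda r: r.record_order)
        ],
        columns=list(DRUG_COLUMNS),
    )
    reac = pd.DataFrame(
        [
            (e.case_id, e.pt_code, e.pt_name, e.onset_date_raw)
            for e in sorted(dataset.events, key=lambda e: e.record_order)
        ],
        columns=list(REAC_COLUMNS),
    )
    demo.to_csv(demo_path, index=False, encoding=encoding)
    drug.to_csv(drug_path, index=False, encoding=encoding)
    reac.to_csv(reac_path, index=False, encoding=encoding)


def write_rejects_log(dataset: ReportDataset, path: str | Path) -> None:
    """Write the rows excluded at read time as a TSV with reasons."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["table", "row_index", "case_id", "reason"])
        for r in dataset.rejects:
            w.writerow([r.table, r.row_index, r.case_id, r.reason])
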