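"""Case-extraction cascade for index-drug analyses.

Reproduces the standard SRS data-cleaning sequence for a statin /
rhabdomyolysis analysis: select cases exposed to the index drug(s), drop
whole cases that received any injectable medication (injectables are
typically given to treat the adverse event in hospital, not before it),
collapse duplicate reports (same sex, age band and registered drug set,
keeping the first-registered case) and finally filter each case's drug list
by timing relative to the adverse-event onset:

* drugs started after onset are excluded;
* drugs discontinued before onset are kept only if stopped within
  ``discontinuation_window_days`` (default 7) of onset;
* drugs with a start but no end date are kept only if started within
  ``open_start_window_days`` (default 365) of onset;
* when the case has no usable onset date, every registered drug is kept.

Window boundaries are inclusive.  Every case- and drug-level exclusion is
logged with its stage and reason so the cascade is auditable: the number of
input cases always equals survivors plus the per-stage case exclusions.
"""

from __future__ import annotations

import csv
import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .srs_io import DrugRecord, EventRecord, ReportDataset

__all__ = [
    "STATIN_NAMES",
    "DEFAULT_INJECTABLE_TERMS",
    "ExtractionConfig",
    "AnalysisCase",
    "ExclusionRecord",
    "ExtractionResult",
    "ExtractionError",
    "select_cases_with_drug",
    "exclude_injectable_cases",
    "deduplicate_cases",
    "resolve_onset_date",
    "filter_concomitant_drugs",
    "build_analysis_cases",
]

#: The six statins marketed in Japan; removed from every case's concomitant
#: drug set so that tree splits describe non-statin co-medication only.
STATIN_NAMES = frozenset(
    {
        "atorvastatin",
        "simvastatin",
        "rosuvastatin",
        "fluvastatin",
        "pravastatin",
        "pitavastatin",
    }
)

DEFAULT_INJECTABLE_TERMS = frozenset(
    {"injection", "injectable", "intravenous", "drip", "infusion"}
)


class ExtractionError(RuntimeError):
    """Raised when the cleaning cascade leaves no analyzable case."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of the cleaning cascade.

    ``index_drug_names`` holds the target drug(s) — normally a single
    statin.  Route matching for the injectable exclusion is case-insensitive
    substring matching against ``injectable_route_terms``.  Drug-name
    matching is exact string matching after whitespace trimming; brand names
    and salt-form spellings must be supplied explicitly.
    """

    index_drug_names: frozenset[str]
    injectable_route_terms: frozenset[str] = DEFAULT_INJECTABLE_TERMS
    discontinuation_window_days: int = 7
    open_start_window_days: int = 365
    event_pt_code: str = "10039020"
    statin_names: frozenset[str] = STATIN_NAMES

    def __post_init__(self) -> None:
        if not self.index_drug_names:
            raise ValueError("index_drug_names must be non-empty")
        if self.discontinuation_window_days <= 0 or self.open_start_window_days <= 0:
            raise ValueError("timing windows must be positive")


@dataclass(frozen=True)
class AnalysisCase:
    """One cleaned case ready for feature building.

    ``concomitant_drugs`` excludes all statins; ``n_drugs`` counts distinct
    retained drug names *including* the index drug (the index drug is a used
    drug and belongs in the drug-count covariate).
    """

    case_id: str
    sex: str
    age_band: str
    index_drugs: frozenset[str]
    concomitant_drugs: frozenset[str]
    n_drugs: int
    event_flag: bool
    onset_date_used: Optional[_dt.date]


@dataclass(frozen=True)
class ExclusionRecord:
    case_id: str
    stage: str
    reason: str


@dataclass
class ExtractionResult:
    cases: list[AnalysisCase]
    exclusions: list[ExclusionRecord] = field(default_factory=list)
    n_selected: int = 0

    def exclusions_at(self, stage: str) -> list[ExclusionRecord]:
        return [e for e in self.exclusions if e.stage == stage]

    def write_audit_log(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["case_id", "stage", "reason"])
            for e in self.exclusions:
                w.writerow([e.case_id, e.stage, e.reason])


def select_cases_with_drug(
    dataset: ReportDataset, index_drug_names: Iterable[str]
) -> set[str]:
    """Case ids with at least one drug record naming an index drug."""
    names = set(index_drug_names)
    out = {r.case_id for r in dataset.drugs if r.drug_name in names}
    if not out:
        warnings.warn(
            f"no case uses any of the index drugs {sorted(names)}", stacklevel=2
        )
    return out


def exclude_injectable_cases(
    dataset: ReportDataset,
    case_ids: set[str],
    injectable_route_terms: Iterable[str],
) -> set[str]:
    """Drop every case with any injectable-route drug (whole-case rule)."""
    terms = [t.lower() for t in injectable_route_terms]
    if not terms:
        return set(case_ids)
    out = set()
    for cid in case_ids:
        routes = (r.route.lower() for r in dataset.drugs_of(cid))
        if not any(any(t in route for t in terms) for route in routes):
            out.add(cid)
    return out


def _dedup_groups(
    dataset: ReportDataset, case_ids: set[str]
) -> tuple[set[str], dict[str, str]]:
    groups: dict[tuple, list[str]] = {}
    for cid in case_ids:
        demo = dataset.demographics_of(cid)
        drug_names = frozenset(r.drug_name for r in dataset.drugs_of(cid))
        groups.setdefault((demo.sex, demo.age_band, drug_names), []).append(cid)
    kept: set[str] = set()
    dropped: dict[str, str] = {}
    order = dataset.demo_order
    for members in groups.values():
        members.sort(key=lambda c: order[c])
        kept.add(members[0])
        for dup in members[1:]:
            dropped[dup] = members[0]
    return kept, dropped


def deduplicate_cases(dataset: ReportDataset, case_ids: set[str]) -> set[str]:
    """Collapse duplicate reports.

    Cases matching on sex, age band and the full registered drug-name set
    are considered duplicates; only the first-registered case (DEMO row
    order) of each group is kept.  Missing sex or age groups with its own
    literal (empty) value.  Idempotent.
    """
    kept, _ = _dedup_groups(dataset, case_ids)
    return kept


def resolve_onset_date(events: Iterable[EventRecord]) -> Optional[_dt.date]:
    """Earliest non-missing onset date among a case's events, else None."""
    dates = [e.onset_date for e in events if e.onset_date is not None]
    return min(dates) if dates else None


def _classify_drug(
    record: DrugRecord, onset: Optional[_dt.date], config: ExtractionConfig
) -> tuple[bool, Optional[str]]:
    """Timing decision for one drug record; (keep, reason-if-dropped)."""
    if onset is None:
        return True, None
    start, end = record.start_date, record.end_date
    if start is not None and start > onset:
        return False, "started after onset"
    if end is not None and end < onset:
        if (onset - end).days <= config.discontinuation_window_days:
            return True, None
        return False, (
            f"discontinued more than {config.discontinuation_window_days} days before onset"
        )
    if start is not None and end is None:
        if (onset - start).days <= config.open_start_window_days:
            return True, None
        return False, (
            f"open-ended use started more than {config.open_start_window_days} days before onset"
        )
    # start <= onset <= end, or no usable dates: drug was plausibly in use
    return True, None


def filter_concomitant_drugs(
    drugs: Iterable[DrugRecord],
    onset: Optional[_dt.date],
    config: ExtractionConfig,
) -> list[DrugRecord]:
    """Drug records of one case retained by the onset-timing rules."""
    return [r for r in drugs if _classify_drug(r, onset, config)[0]]


def build_analysis_cases(
    dataset: ReportDataset, config: ExtractionConfig
) -> ExtractionResult:
    """Run the full cleaning cascade and assemble analysis cases.

    Stage order is fixed: index-drug selection, injectable exclusion,
    duplicate collapsing, then per-case drug timing filtering.  A case whose
    index drug is itself removed by the timing filter is dropped.  The event
    flag is true when the case reports the target preferred-term code.
    """
    exclusions: list[ExclusionRecord] = []

    selected = select_cases_with_drug(dataset, config.index_drug_names)
    n_selected = len(selected)

    after_inject = exclude_injectable_cases(
        dataset, selected, config.injectable_route_terms
    )
    for cid in sorted(selected - after_inject, key=dataset.demo_order.get):
        exclusions.append(
            ExclusionRecord(cid, "injectable", "case includes an injectable-route drug")
        )

    kept, dup_of = _dedup_groups(dataset, after_inject)
    for cid in sorted(dup_of, key=dataset.demo_order.get):
        exclusions.append(
            ExclusionRecord(cid, "duplicate", f"duplicate of first-registered case {dup_of[cid]}")
        )

    cases: list[AnalysisCase] = []
    for cid in sorted(kept, key=dataset.demo_order.get):
        events = dataset.events_of(cid)
        onset = resolve_onset_date(events)
        retained: list[DrugRecord] = []
        for record in dataset.drugs_of(cid):
            keep, reason = _classify_drug(record, onset, config)
            if keep:
                retained.append(record)
            else:
                exclusions.append(
                    ExclusionRecord(cid, "drug_timing", f"{record.drug_name}: {reason}")
                )
        names = {r.drug_name for r in retained}
        index_present = names & config.index_drug_names
        if not index_present:
            exclusions.append(
                ExclusionRecord(
                    cid, "index_timing", "index drug removed by timing filter"
                )
            )
            continue
        cases.append(
            AnalysisCase(
                case_id=cid,
                sex=dataset.demographics_of(cid).sex,
                age_band=dataset.demographics_of(cid).age_band,
                index_drugs=frozenset(index_present),
                concomitant_drugs=frozenset(names - config.statin_names),
                n_drugs=len(names),
                event_flag=any(e.pt_code == config.event_pt_code for e in events),
                onset_date_used=onset,
            )
        )

    if not cases:
        raise ExtractionError(
            "no case survived the extraction cascade; inputs are exhausted by the filters"
        )
    return ExtractionResult(cases=cases, exclusions=exclusions, n_selected=n_selected)
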