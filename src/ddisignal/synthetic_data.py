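"""Synthetic spontaneous-report generator with known ground truth.

Emits JADER-layout DEMO/DRUG/REAC tables for an index drug (a statin by
default) with polypharmacy structure, partially missing dates, duplicate
reports, injectable-route cases and — optionally — planted pairwise or
higher-order interaction effects, so the whole detection pipeline can be
exercised end-to-end with a known answer.

The risk model is multiplicative with a cap: a case's event probability is
``min(cap, baseline * prod(multipliers of planted drug sets fully contained
in the case's drug set))``.  A planted effect fires only when *all* of its
drugs are present — a pure interaction with no marginal main effect unless
one is separately planted — which isolates the multi-drug detection
property under test.  The multiplicative form keeps planted rate jumps in
the same reporting-rate units the analysis reports.

Every dataset is deterministic given its seed, and by construction the
default timing of drug start/end dates keeps all drugs inside the analysis
window; configured fractions of cases deliberately violate the filters
(late-started drugs, injectable routes, duplicate near-copies) and are
recorded in the ground truth.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .srs_io import ReportDataset, dataset_from_frames

__all__ = [
    "DEFAULT_VOCABULARY",
    "EVENT_PT",
    "OTHER_PT",
    "PlantedEffect",
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "make_worked_fixture",
    "WORKED_FIXTURE_EXPECTED",
]

EVENT_PT = ("10039020", "Rhabdomyolysis")
OTHER_PT = ("10019211", "Hepatic function abnormal")

#: Index drug first, then a vocabulary of commonly co-prescribed drugs.
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "pitavastatin",
    "allopurinol",
    "amlodipine",
    "aspirin",
    "benidipine",
    "benzbromarone",
    "bezafibrate",
    "candesartan",
    "carbocisteine",
    "clopidogrel",
    "doxazosin",
    "famotidine",
    "flunitrazepam",
    "furosemide",
    "glimepiride",
    "isosorbide mononitrate",
    "lansoprazole",
    "loxoprofen",
    "magnesium oxide",
    "mecobalamin",
    "metformin",
    "nifedipine",
    "pioglitazone",
    "rabeprazole",
    "rebamipide",
    "sitagliptin",
    "spironolactone",
    "telmisartan",
    "teneligliptin",
    "valsartan",
    "voglibose",
)

_SEXES = ("male", "female")
_AGE_BANDS = ("30s", "40s", "50s", "60s", "70s", "80s")


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth interaction: risk multiplier for carrying all drugs.

    ``carrier_frac``, when set, forces that fraction of cases to carry the
    whole drug set (drawn before the remaining concomitants), giving direct
    control over the carrier prevalence instead of relying on chance
    co-occurrence.
    """

    drugs: frozenset[str]
    multiplier: float
    carrier_frac: Optional[float] = None

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("risk multiplier must be >= 1")
        if self.carrier_frac is not None and not 0 <= self.carrier_frac <= 1:
            raise ValueError("carrier_frac must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults describe the emulated database.

    ``mean_concomitant_drugs`` parameterises a truncated-at-1 Poisson count
    of concomitant drugs per case (polypharmacy); ``drug_prevalence`` gives
    per-concomitant selection weights (uniform when omitted).  About 30% of
    onset and drug dates are missing, matching the deficiency level typical
    of spontaneous-report databases; small fractions of duplicate reports,
    injectable-route cases and post-onset drug starts exercise the cleaning
    cascade.
    """

    n_cases: int = 2000
    drug_vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    mean_concomitant_drugs: float = 4.0
    drug_prevalence: Optional[tuple[float, ...]] = None
    baseline_event_prob: float = 0.10
    planted_effects: tuple[PlantedEffect, ...] = ()
    max_event_prob: float = 0.95
    missing_onset_frac: float = 0.30
    missing_drug_date_frac: float = 0.30
    duplicate_frac: float = 0.05
    injectable_case_frac: float = 0.05
    late_start_drug_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if len(self.drug_vocabulary) < 2:
            raise ValueError("vocabulary needs the index drug plus concomitants")
        if self.mean_concomitant_drugs <= 0:
            raise ValueError("mean_concomitant_drugs must be positive")
        for p in (
            self.baseline_event_prob,
            self.max_event_prob,
            self.missing_onset_frac,
            self.missing_drug_date_frac,
            self.duplicate_frac,
            self.injectable_case_frac,
            self.late_start_drug_frac,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.drug_prevalence is not None and len(self.drug_prevalence) != len(
            self.drug_vocabulary
        ) - 1:
            raise ValueError(
                "drug_prevalence must give one weight per concomitant drug"
            )
        vocab = set(self.drug_vocabulary)
        for eff in self.planted_effects:
            missing = eff.drugs - vocab
            if missing:
                raise ValueError(
                    f"planted drugs not in vocabulary: {sorted(missing)}"
                )

    @property
    def index_drug(self) -> str:
        return self.drug_vocabulary[0]


@dataclass
class GroundTruth:
    """What the generator actually did, keyed by case id."""

    planted_effects: tuple[PlantedEffect, ...]
    event_prob: dict[str, float] = field(default_factory=dict)
    event: dict[str, bool] = field(default_factory=dict)
    drug_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    expected_filters: dict[str, list[str]] = field(default_factory=dict)


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson counts resampled until every draw is >= 1."""
    out = rng.poisson(mean, size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(mean, int(zero.sum()))


def _date_str(d: _dt.date) -> str:
    return d.strftime("%Y%m%d")


def simulate_dataset(config: SimulationConfig) -> tuple[ReportDataset, GroundTruth]:
    """Generate one dataset plus its ground truth, deterministic by seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    index_drug = config.index_drug
    concomitant_vocab = list(config.drug_vocabulary[1:])
    if config.drug_prevalence is None:
        weights = np.full(len(concomitant_vocab), 1.0 / len(concomitant_vocab))
    else:
        w = np.asarray(config.drug_prevalence, dtype=float)
        weights = w / w.sum()

    n = config.n_cases
    counts = _truncated_poisson(rng, config.mean_concomitant_drugs, n)
    forced_masks = [
        (
            eff,
            rng.random(n) < eff.carrier_frac
            if eff.carrier_frac is not None
            else np.zeros(n, dtype=bool),
        )
        for eff in config.planted_effects
    ]
    onset_base = _dt.date(2015, 1, 1)
    onset_offsets = rng.integers(0, 730, n)
    missing_onset = rng.random(n) < config.missing_onset_frac
    injectable = rng.random(n) < config.injectable_case_frac
    late_start = rng.random(n) < config.late_start_drug_frac
    duplicate = rng.random(n) < config.duplicate_frac

    demo_rows: list[tuple[str, str, str]] = []
    drug_rows: list[tuple[str, str, str, str, str]] = []
    reac_rows: list[tuple[str, str, str, str]] = []
    truth = GroundTruth(planted_effects=config.planted_effects)

    width = len(str(n))
    dup_queue: list[tuple[str, str, str, list, list]] = []

    for i in range(n):
        cid = f"C{i + 1:0{width}d}"
        sex = _SEXES[int(rng.integers(0, len(_SEXES)))]
        age = _AGE_BANDS[int(rng.integers(0, len(_AGE_BANDS)))]
        onset = onset_base + _dt.timedelta(days=int(onset_offsets[i]))

        forced: list[str] = []
        for eff, mask in forced_masks:
            if mask[i]:
                for d in sorted(eff.drugs):
                    if d != index_drug and d not in forced:
                        forced.append(d)
        m = max(int(counts[i]), len(forced))
        remaining_pool = [d for d in concomitant_vocab if d not in forced]
        need = m - len(forced)
        if need > 0:
            w = np.array([weights[concomitant_vocab.index(d)] for d in remaining_pool])
            picked = rng.choice(
                len(remaining_pool), size=min(need, len(remaining_pool)),
                replace=False, p=w / w.sum(),
            )
            chosen = forced + [remaining_pool[j] for j in sorted(picked)]
        else:
            chosen = list(forced)
        drug_set = frozenset([index_drug, *chosen])

        p_event = config.baseline_event_prob
        for eff in config.planted_effects:
            if eff.drugs <= drug_set:
                p_event *= eff.multiplier
        p_event = min(p_event, config.max_event_prob)
        event = bool(rng.random() < p_event)

        # drug timing: defaults keep every drug inside the analysis window
        case_drug_rows: list[tuple[str, str, str, str, str]] = []
        date_missing = rng.random(len(drug_set)) < config.missing_drug_date_frac
        inject_slot = int(rng.integers(0, len(drug_set))) if injectable[i] else -1
        for j, name in enumerate(sorted(drug_set)):
            route = "intravenous drip" if j == inject_slot else "oral"
            if date_missing[j]:
                start_s = end_s = ""
            else:
                start = onset - _dt.timedelta(days=int(rng.integers(10, 300)))
                u = rng.random()
                if u < 0.5:
                    end_s = ""  # still in use
                elif u < 0.9:
                    end_s = _date_str(onset + _dt.timedelta(days=int(rng.integers(0, 30))))
                else:
                    end_s = _date_str(onset - _dt.timedelta(days=int(rng.integers(0, 7))))
                start_s = _date_str(start)
            case_drug_rows.append((cid, name, route, start_s, end_s))

        filters: list[str] = []
        if injectable[i]:
            filters.append("injectable")
        if late_start[i] and not missing_onset[i]:
            unused = [d for d in concomitant_vocab if d not in drug_set]
            if unused:
                extra = unused[int(rng.integers(0, len(unused)))]
                start_s = _date_str(onset + _dt.timedelta(days=int(rng.integers(1, 60))))
                case_drug_rows.append((cid, extra, "oral", start_s, ""))
                filters.append(f"late-start:{extra}")

        onset_s = "" if missing_onset[i] else _date_str(onset)
        pt_code, pt_name = EVENT_PT if event else OTHER_PT
        case_reac_rows = [(cid, pt_code, pt_name, onset_s)]

        demo_rows.append((cid, sex, age))
        drug_rows.extend(case_drug_rows)
        reac_rows.extend(case_reac_rows)
        truth.event_prob[cid] = p_event
        truth.event[cid] = event
        truth.drug_sets[cid] = drug_set
        if filters:
            truth.expected_filters[cid] = filters

        if duplicate[i]:
            dup_queue.append((cid, sex, age, case_drug_rows, case_reac_rows))

    # duplicates registered after all originals so the original is first
    for j, (orig, sex, age, d_rows, r_rows) in enumerate(dup_queue):
        dup_id = f"D{j + 1:0{width}d}"
        demo_rows.append((dup_id, sex, age))
        drug_rows.extend((dup_id, *row[1:]) for row in d_rows)
        reac_rows.extend((dup_id, *row[1:]) for row in r_rows)
        truth.expected_filters[dup_id] = [f"duplicate-of:{orig}"]

    demo = pd.DataFrame(demo_rows, columns=["case_id", "sex", "age"])
    drug = pd.DataFrame(
        drug_rows, columns=["case_id", "drug_name", "route", "start_date", "end_date"]
    )
    reac = pd.DataFrame(
        reac_rows, columns=["case_id", "pt_code", "pt_name", "onset_date"]
    )
    return dataset_from_frames(demo, drug, reac), truth


# ---------------------------------------------------------------------------
# Hand-traceable worked fixture
# ---------------------------------------------------------------------------

#: Expected outcome of running the cleaning cascade and analysis on the
#: worked fixture, established by hand-tracing every rule (see the rows in
#: :func:`make_worked_fixture`).
WORKED_FIXTURE_EXPECTED: dict = {
    "surviving_case_ids": [
        "C01", "C03", "C05", "C06", "C08", "C09", "C10", "C11", "C12",
    ],
    "duplicates_removed": {"C02": "C01", "C07": "C06"},
    "injectable_removed": ["C04"],
    "concomitant_sets": {
        "C01": {"allopurinol"},
        "C03": {"valsartan"},
        "C05": {"allopurinol"},  # amlodipine started after onset -> dropped
        "C06": {"benzbromarone"},
        "C08": {"furosemide"},  # stopped 5 days before onset -> kept
        "C09": set(),  # famotidine open-ended start 405 days before onset -> dropped
        "C10": {"allopurinol", "valsartan"},
        "C11": {"loxoprofen"},
        "C12": set(),  # registered as monotherapy
    },
    "analysis_case_ids": ["C01", "C03", "C05", "C06", "C08", "C10", "C11"],
    "n_total": 7,
    "k_total": 3,  # rhabdomyolysis in C01, C05, C10
    "headline_rows": [],  # 7 cases cannot split with min_node=10 -> IR row only
}


def make_worked_fixture() -> tuple[ReportDataset, dict]:
    """A 12-case hand-traceable fixture exercising every cleaning rule.

    Cases (index drug pitavastatin, target PT 10039020, onset 2017-06-10
    unless noted):

    * C01 event case, pitavastatin + allopurinol — survives.
    * C02 duplicate of C01 (same sex/age/drug set, registered later) — removed.
    * C03 pitavastatin + valsartan, non-target event — survives.
    * C04 pitavastatin + metformin by intravenous drip — whole case removed.
    * C05 event case; amlodipine started 2017-06-15, after onset — drug
      dropped, case survives with allopurinol.
    * C06 no onset date registered — all drugs kept; survives.
    * C07 duplicate of C06 — removed.
    * C08 furosemide ended 2017-06-05, 5 days before onset (within the
      7-day discontinuation window) — kept.
    * C09 famotidine started 2016-05-01 with no end date, 405 days before
      onset (outside the 1-year window) — dropped; case survives the
      cascade as monotherapy and is excluded at the monotherapy step.
    * C10 event case, pitavastatin + allopurinol + valsartan — survives.
    * C11 pitavastatin + loxoprofen — survives.
    * C12 pitavastatin only — survives the cascade, excluded as monotherapy.

    Nine cases survive extraction; seven remain after monotherapy
    exclusion, three of them with the target event (IR 3/7).  With fewer
    than twice the minimum node size the tree cannot split, so the expected
    report is the IR row alone.
    """
    demo = [
        ("C01", "male", "60s"),
        ("C02", "male", "60s"),
        ("C03", "female", "70s"),
        ("C04", "male", "50s"),
        ("C05", "female", "60s"),
        ("C06", "male", "40s"),
        ("C07", "male", "40s"),
        ("C08", "female", "80s"),
        ("C09", "male", "70s"),
        ("C10", "female", "50s"),
        ("C11", "male", "60s"),
        ("C12", "female", "70s"),
    ]
    o = "20170610"
    drug = [
        ("C01", "pitavastatin", "oral", "20170201", ""),
        ("C01", "allopurinol", "oral", "20170201", ""),
        ("C02", "pitavastatin", "oral", "20170210", ""),
        ("C02", "allopurinol", "oral", "20170210", ""),
        ("C03", "pitavastatin", "oral", "20170101", ""),
        ("C03", "valsartan", "oral", "20170101", ""),
        ("C04", "pitavastatin", "oral", "20170301", ""),
        ("C04", "metformin", "intravenous drip", "20170301", ""),
        ("C05", "pitavastatin", "oral", "20170115", ""),
        ("C05", "allopurinol", "oral", "20170115", ""),
        ("C05", "amlodipine", "oral", "20170615", ""),
        ("C06", "pitavastatin", "oral", "", ""),
        ("C06", "benzbromarone", "oral", "", ""),
        ("C07", "pitavastatin", "oral", "", ""),
        ("C07", "benzbromarone", "oral", "", ""),
        ("C08", "pitavastatin", "oral", "20170110", ""),
        ("C08", "furosemide", "oral", "20170110", "20170605"),
        ("C09", "pitavastatin", "oral", "20170201", ""),
        ("C09", "famotidine", "oral", "20160501", ""),
        ("C10", "pitavastatin", "oral", "20170301", ""),
        ("C10", "allopurinol", "oral", "20170301", ""),
        ("C10", "valsartan", "oral", "20170301", ""),
        ("C11", "pitavastatin", "oral", "20170401", ""),
        ("C11", "loxoprofen", "oral", "20170401", ""),
        ("C12", "pitavastatin", "oral", "20170501", ""),
    ]
    rhabdo = EVENT_PT
    other = OTHER_PT
    reac = [
        ("C01", *rhabdo, o),
        ("C02", *rhabdo, o),
        ("C03", *other, "20170501"),
        ("C04", *other, o),
        ("C05", *rhabdo, o),
        ("C06", *other, ""),
        ("C07", *other, ""),
        ("C08", *other, o),
        ("C09", *other, o),
        ("C10", *rhabdo, "20170620"),
        ("C11", *other, o),
        ("C12", *other, o),
    ]
    dataset = dataset_from_frames(
        pd.DataFrame(demo, columns=["case_id", "sex", "age"]),
        pd.DataFrame(
            drug, columns=["case_id", "drug_name", "route", "start_date", "end_date"]
        ),
        pd.DataFrame(reac, columns=["case_id", "pt_code", "pt_name", "onset_date"]),
    )
    return dataset, WORKED_FIXTURE_EXPECTED
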