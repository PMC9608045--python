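"""Analysis-matrix construction.

Turns cleaned cases into the matrix the partitioning step consumes: one
binary indicator column per concomitant drug (1 = present in the case's
retained drug set), the per-case drug count as an ordered numeric covariate,
the binary event outcome, and the initial rate (IR) — the event proportion
over all analyzed cases before any stratification.  Index-drug monotherapy
cases carry no concomitant-drug information and are excluded first.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .case_extraction import AnalysisCase

__all__ = [
    "FeatureMatrix",
    "exclude_monotherapy",
    "build_feature_matrix",
    "compute_rate",
    "round_half_up",
    "format_rate",
]


def exclude_monotherapy(cases: Sequence[AnalysisCase]) -> list[AnalysisCase]:
    """Drop cases whose concomitant drug set is empty."""
    out = [c for c in cases if c.concomitant_drugs]
    if not out:
        raise ValueError("all cases are index-drug monotherapy; nothing to analyze")
    return out


@dataclass
class FeatureMatrix:
    """Cases-by-drugs binary design with the drug-count covariate.

    ``drug_columns`` is sorted lexicographically so output is byte-stable
    across runs; all-zero columns are kept for auditability (the splitter
    never selects them because a child below the minimum node size results).
    """

    case_ids: list[str]
    drug_columns: list[str]
    indicators: np.ndarray  # (n_cases, n_drugs) int8
    drug_count: np.ndarray  # (n_cases,) int64
    event: np.ndarray  # (n_cases,) bool

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def initial_rate(self) -> float:
        return compute_rate(self.n_cases, self.n_events)


def build_feature_matrix(cases: Sequence[AnalysisCase]) -> FeatureMatrix:
    """Binary drug indicators + drug count + event vector for the cases."""
    if not cases:
        raise ValueError("no cases to build a feature matrix from")
    drug_columns = sorted(set().union(*(c.concomitant_drugs for c in cases)))
    col_index = {d: j for j, d in enumerate(drug_columns)}
    X = np.zeros((len(cases), len(drug_columns)), dtype=np.int8)
    for i, c in enumerate(cases):
        for d in c.concomitant_drugs:
            X[i, col_index[d]] = 1
    return FeatureMatrix(
        case_ids=[c.case_id for c in cases],
        drug_columns=drug_columns,
        indicators=X,
        drug_count=np.array([c.n_drugs for c in cases], dtype=np.int64),
        event=np.array([c.event_flag for c in cases], dtype=bool),
    )


def compute_rate(n_cases: int, n_events: int) -> float:
    """Reporting rate ``n_events / n_cases`` (full precision)."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0 <= n_events <= n_cases:
        raise ValueError("n_events must be between 0 and n_cases")
    return n_events / n_cases


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, e.g. 5/13 -> 0.38 and 7/16 -> 0.44."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_rate(value: float, ndigits: int = 2) -> str:
    """Display helper: half-up rounded, fixed decimals (``0.09``-style)."""
    return f"{round_half_up(value, ndigits):.{ndigits}f}"
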