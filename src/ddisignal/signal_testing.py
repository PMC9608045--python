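"""Node-wise reporting-rate tests and the signal report.

Every non-root node of a grown tree is tested against the initial rate (IR)
with a two-sided exact binomial test (the node's event count as successes,
the IR as the null proportion), the resulting p-values are adjusted by the
Benjamini-Hochberg step-up across the per-index-drug node family, and the
headline report lists — after the IR row — the significant nodes whose path
consists solely of drug-presence conditions and whose rate exceeds the IR,
labelled by the drug combination joined with ``" + "``.

Nodes with mixed presence/absence or drug-count conditions stay in the
machine-readable output but not in the headline table: only a pure presence
path reads as a drug combination.

Because the tested nodes were *selected* greedily by the same data, these
tests are anticonservative; no nominal FDR guarantee is claimed.  The null
behaviour is characterised empirically (see the calibration utilities).
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .dditree import Condition, TreeNode, enumerate_nodes
from .feature_builder import format_rate

__all__ = [
    "NodeTest",
    "SignalTable",
    "node_proportion_test",
    "benjamini_hochberg",
    "extract_signals",
    "write_signal_table",
    "signal_table_to_json",
]

_TINY = float(np.nextafter(0, 1))


def node_proportion_test(
    k: int, n: int, ir: float, method: Literal["exact", "chi2"] = "exact"
) -> float:
    """Two-sided test of ``k`` events in ``n`` cases against rate ``ir``.

    ``exact`` (default) is the exact binomial test: the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    ``chi2`` is a one-sample chi-square approximation kept for sensitivity
    analysis.  Degenerate nulls (``ir`` of 0 or 1) that the data contradict
    would give p = 0; the smallest positive float is returned instead and a
    warning raised, so downstream adjustment stays well-defined.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if not 0.0 <= ir <= 1.0:
        raise ValueError("ir must be a proportion")
    if ir in (0.0, 1.0):
        observed_matches_null = (ir == 0.0 and k == 0) or (ir == 1.0 and k == n)
        if observed_matches_null:
            return 1.0
        warnings.warn(
            "observed events contradict a degenerate null rate; "
            "returning the smallest positive p-value",
            stacklevel=2,
        )
        return _TINY
    if method == "exact":
        return float(_stats.binomtest(k, n, ir).pvalue)
    if method == "chi2":
        z2 = (k - n * ir) ** 2 / (n * ir * (1.0 - ir))
        return float(_stats.chi2.sf(z2, df=1))
    raise ValueError(f"unknown test method {method!r}")


def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, reject)`` in the input order; rejection is
    ``adjusted <= q``.  Adjusted values are always >= the raw values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass(frozen=True)
class NodeTest:
    """One tested decision node."""

    path_conditions: tuple[Condition, ...]
    n: int
    k: int
    rate: float
    p_raw: float
    p_adj: float
    significant: bool
    direction: Literal["above", "below", "equal"]
    presence_only: bool
    label: Optional[str]  # " + "-joined combination, presence-only paths

    @property
    def depth(self) -> int:
        return len(self.path_conditions)


@dataclass
class SignalTable:
    """The per-index-drug signal report.

    ``rows`` is the headline table (significant, presence-only paths with
    rate above the IR); ``all_nodes`` keeps every tested node for audit.
    """

    index_drug: str
    n_total: int
    k_total: int
    initial_rate: float
    fdr_q: float
    rows: list[NodeTest] = field(default_factory=list)
    all_nodes: list[NodeTest] = field(default_factory=list)
    tree_root: Optional[TreeNode] = None


def _combination_label(conditions: tuple[Condition, ...]) -> Optional[str]:
    drugs = []
    for c in conditions:
        if c.kind != "binary" or not c.present:
            return None
        drugs.append(c.variable)
    return " + ".join(drugs) if drugs else None


def extract_signals(
    root: TreeNode,
    ir: float,
    n_total: int,
    k_total: int,
    q: float = 0.05,
    index_drug: str = "",
    test_method: Literal["exact", "chi2"] = "exact",
) -> SignalTable:
    """Test every non-root node against the IR and assemble the report.

    The BH family is the set of all non-root nodes of this one tree: each
    index drug is analyzed separately and adjusted separately.
    """
    nodes = enumerate_nodes(root)
    p_raw = [node_proportion_test(nd.k, nd.n, ir, test_method) for nd in nodes]
    p_adj, reject = benjamini_hochberg(p_raw, q)

    tests: list[NodeTest] = []
    for nd, pr, pa, rej in zip(nodes, p_raw, p_adj, reject):
        rate = nd.k / nd.n
        label = _combination_label(nd.path_conditions)
        tests.append(
            NodeTest(
                path_conditions=nd.path_conditions,
                n=nd.n,
                k=nd.k,
                rate=rate,
                p_raw=pr,
                p_adj=float(pa),
                significant=bool(rej),
                direction="above" if rate > ir else ("below" if rate < ir else "equal"),
                presence_only=label is not None,
                label=label,
            )
        )

    rows = [
        t
        for t in tests
        if t.significant and t.presence_only and t.rate > ir
    ]
    return SignalTable(
        index_drug=index_drug,
        n_total=n_total,
        k_total=k_total,
        initial_rate=ir,
        fdr_q=q,
        rows=rows,
        all_nodes=tests,
    )


def _table_lines(table: SignalTable) -> list[list[str]]:
    lines = [
        ["combination", "cases", "cases_positive", "rate", "p_raw", "p_adj", "significant"]
    ]
    lines.append(
        [
            "-",
            str(table.n_total),
            str(table.k_total),
            f"{format_rate(table.initial_rate)} (IR)",
            "",
            "",
            "",
        ]
    )
    for t in table.rows:
        lines.append(
            [
                t.label or "",
                str(t.n),
                str(t.k),
                format_rate(t.rate),
                f"{t.p_raw:.6g}",
                f"{t.p_adj:.6g}",
                "yes",
            ]
        )
    return lines


def write_signal_table(table: SignalTable, path: str | Path) -> None:
    """Write the headline report as a TSV (IR row first), byte-stable."""
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    for line in _table_lines(table):
        w.writerow(line)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def signal_table_to_json(table: SignalTable, indent: int = 2) -> str:
    """Machine-readable sidecar with every tested node, full precision."""
    payload = {
        "index_drug": table.index_drug,
        "n_total": table.n_total,
        "k_total": table.k_total,
        "initial_rate": table.initial_rate,
        "fdr_q": table.fdr_q,
        "nodes": [
            {
                "path": [c.describe() for c in t.path_conditions],
                "label": t.label,
                "n": t.n,
                "k": t.k,
                "rate": t.rate,
                "p_raw": t.p_raw,
                "p_adj": t.p_adj,
                "significant": t.significant,
                "direction": t.direction,
                "presence_only": t.presence_only,
            }
            for t in table.all_nodes
        ],
    }
    return json.dumps(payload, indent=indent, sort_keys=True)
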