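"""Pairwise Mann-Whitney comparison of gap lengths across contexts.

Do gaps arising in short homopolymers follow the same length distribution as
gaps in long ones?  Each pair of context groups is compared with a two-sided
two-sample Mann-Whitney (Wilcoxon rank-sum) test.  The result is rendered as
an upper-triangular reject/accept matrix: red cells (reject at alpha = 0.01)
indicate context-dependent gap lengths, blank cells mark pairs where a group
had no data.  No multiple-testing correction is applied by default; a
Bonferroni option exists.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GapRecord

__all__ = [
    "TestOutcome",
    "TestMatrix",
    "mann_whitney_u",
    "pairwise_tests",
]

#: Below this per-group size the normal approximation is flagged unreliable.
SMALL_SAMPLE = 8


@dataclass(frozen=True)
class TestOutcome:
    group_a: object
    group_b: object
    U: float | None
    p_value: float | None
    decision: str  # "reject" | "accept" | "not_performed"
    method: str = ""  # "exact" | "asymptotic" | ""
    unreliable: bool = False

    def __post_init__(self) -> None:
        if (self.decision == "not_performed") != (self.p_value is None):
            raise ValueError("decision is not_performed iff p_value is missing")


@dataclass
class TestMatrix:
    """Upper-triangular matrix of pairwise test outcomes."""

    labels: list
    outcomes: dict = field(default_factory=dict)  # (label_a, label_b) -> TestOutcome
    alpha: float = 0.01
    kind: str = ""

    def get(self, a, b) -> TestOutcome:
        i, j = self.labels.index(a), self.labels.index(b)
        if i > j:
            a, b = b, a
        return self.outcomes[(a, b)]

    def to_frame(self) -> pd.DataFrame:
        """Cell grid with entries {reject, accept, NA} (NA = not performed)."""
        cells = {}
        for a in self.labels:
            row = {}
            for b in self.labels:
                o = self.get(a, b)
                row[b] = "NA" if o.decision == "not_performed" else o.decision
            cells[a] = row
        return pd.DataFrame(cells).T.loc[self.labels, self.labels]

    def to_records(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": o.group_a,
                    "group_b": o.group_b,
                    "U": o.U,
                    "p_value": o.p_value,
                    "decision": o.decision,
                    "method": o.method,
                    "unreliable": o.unreliable,
                }
                for o in self.outcomes.values()
            ]
        )


def mann_whitney_u(x: Sequence[int], y: Sequence[int]) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U with midranks.

    Exact null enumeration when both samples have at most ``SMALL_SAMPLE``
    observations and no value occurs in both samples (cross-sample ties are
    what distort the exact null; within-sample duplicates do not affect U);
    otherwise the normal approximation with tie and continuity corrections.
    Returns ``(U, p, method)`` where U is the statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # all observations equal: the statistic is degenerate, never reject
        return float(x.size * y.size / 2.0), 1.0, "degenerate"
    has_ties = bool(np.intersect1d(np.unique(x), np.unique(y)).size)
    if x.size <= SMALL_SAMPLE and y.size <= SMALL_SAMPLE and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), method


def group_gaps(
    gaps: Sequence[GapRecord], group_by: str = "context_length", kind: str | None = None
) -> dict:
    """Group gap lengths by context key.

    ``group_by='context_length'`` pools bases (groups are integers);
    ``group_by='context'`` keeps ``(base, context_length)`` pairs.  ``kind``
    optionally restricts to insertions or deletions, which are analysed
    separately.
    """
    if group_by not in ("context", "context_length"):
        raise ValueError("group_by must be 'context' or 'context_length'")
    groups: dict = defaultdict(list)
    for g in gaps:
        if kind is not None and g.kind != kind:
            continue
        key = (g.base, g.context_length) if group_by == "context" else g.context_length
        groups[key].append(g.length)
    return dict(groups)


def pairwise_tests(
    gaps: Sequence[GapRecord],
    group_by: str = "context_length",
    alpha: float = 0.01,
    kind: str | None = None,
    labels: Sequence | None = None,
    bonferroni: bool = False,
) -> TestMatrix:
    """Mann-Whitney matrix over every unordered pair of context groups.

    ``labels`` fixes the group axes (e.g. all context lengths 1..L so empty
    groups appear as blank rows); by default the sorted observed groups are
    used, padded to a contiguous 1..max range when grouping by context
    length.  Reject iff p < alpha (optionally Bonferroni-divided by the
    number of performed off-diagonal tests).  A pair with an empty group is
    ``not_performed``.
    """
    groups = group_gaps(gaps, group_by=group_by, kind=kind)
    if labels is None:
        if group_by == "context_length" and groups:
            labels = list(range(1, max(groups) + 1))
        else:
            labels = sorted(groups)
    labels = list(labels)

    raw: dict[tuple, tuple] = {}
    n_performed = 0
    for i, a in enumerate(labels):
        for b in labels[i:]:
            xa = groups.get(a, [])
            xb = groups.get(b, [])
            if not xa or not xb:
                raw[(a, b)] = (None, None, "")
            else:
                raw[(a, b)] = mann_whitney_u(xa, xb)
                if a != b:
                    n_performed += 1

    threshold = alpha / n_performed if (bonferroni and n_performed) else alpha
    matrix = TestMatrix(labels=labels, alpha=alpha, kind=kind or "all")
    for (a, b), (U, p, method) in raw.items():
        if p is None:
            outcome = TestOutcome(a, b, None, None, "not_performed")
        else:
            decision = "reject" if p < threshold else "accept"
            small = len(groups[a]) < SMALL_SAMPLE or len(groups[b]) < SMALL_SAMPLE
            outcome = TestOutcome(
                a, b, U, p, decision, method=method,
                unreliable=(method == "asymptotic" and small),
            )
        matrix.outcomes[(a, b)] = outcome
    return matrix
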