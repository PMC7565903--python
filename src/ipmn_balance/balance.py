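"""Balance-point cutoff selection.

The core decision rule: a malignancy-probability cutoff is "balanced" for
a given complication severity when the number of malignancies the cutoff
would miss (false negatives, FN) equals the expected number of
complication-weighted unnecessary surgeries — the benign patients it
would send to surgery (false positives, FP) times the complication rate:

    FN = FP x complication rate

On integer counts the equality is almost never exact, so the selected
cutoff is the grid point minimizing |FN - FP x rate|, with ties broken
toward the lower cutoff (favoring sensitivity).  Because FN is weakly
increasing and FP weakly decreasing in the cutoff, the selected cutoff is
weakly increasing in the complication rate: riskier operations justify a
higher bar for surgery.

Decision convention: a patient with malignancy probability at or above
the cutoff is operated on (>= operates).  Cutoffs are percents at the
interface and fractions internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import SEVERITY_THRESHOLDS, ComplicationRateSet
from .errors import ConfigurationError

__all__ = [
    "BalanceRow",
    "BalanceTable",
    "CutoffSelection",
    "count_errors",
    "balance_product",
    "build_balance_table",
    "select_cutoff",
]


def _as_arrays(labels, mp) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    mp = np.asarray(mp, dtype=float)
    if labels.shape != mp.shape or labels.ndim != 1:
        raise ValueError("labels and mp must be 1-D arrays of equal length")
    if labels.size == 0:
        raise ValueError("empty cohort")
    if np.any(~np.isfinite(mp)) or mp.min() < 0.0 or mp.max() > 1.0:
        raise ValueError("mp must be probabilities in [0, 1]")
    return labels, mp


def count_errors(labels, mp, cutoff: float) -> tuple[int, int]:
    """(FP, FN) at a percent cutoff.

    FP counts benign patients with probability at or above the cutoff
    (operated unnecessarily); FN counts malignant patients below it
    (malignancy missed).
    """
    labels, mp = _as_arrays(labels, mp)
    if not 0.0 < cutoff < 100.0:
        raise ValueError(f"cutoff {cutoff} must lie in (0, 100) percent")
    thr = cutoff / 100.0
    operate = mp >= thr
    fp = int(np.sum(operate & ~labels))
    fn = int(np.sum(~operate & labels))
    return fp, fn


def balance_product(fp: int, rate: float) -> float:
    """FP x complication rate: the expected complication-weighted count of
    unnecessary surgeries, on the same count scale as FN."""
    if fp < 0:
        raise ValueError(f"fp must be non-negative, got {fp}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} must lie in [0, 1]")
    return fp * rate


@dataclass(frozen=True)
class BalanceRow:
    """One worksheet row: error counts at a cutoff plus weighted FP per
    severity threshold."""

    cutoff: float  # percent
    fp: int
    fn: int
    weighted_fp: Mapping[str, float]


@dataclass(frozen=True)
class CutoffSelection:
    severity: str
    cutoff: float  # percent
    residual: float  # |fn - fp*rate| at the selected row
    at_boundary: bool  # minimizer is the first or last grid point


@dataclass
class BalanceTable:
    """The balance worksheet for one surgery group.

    Rows are ordered by ascending cutoff; FP is weakly decreasing and FN
    weakly increasing down the table.
    """

    group: str
    rows: list[BalanceRow]
    rate_set: ComplicationRateSet
    selected: dict[str, CutoffSelection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("a balance table needs at least one row")
        cutoffs = [r.cutoff for r in self.rows]
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError("rows must be strictly increasing in cutoff")

    @classmethod
    def from_counts(
        cls,
        group: str,
        rows: Sequence[tuple[float, int, int]],
        rate_set: ComplicationRateSet,
    ) -> "BalanceTable":
        """Build a table from pre-tabulated (cutoff, FP, FN) triples."""
        built = [
            BalanceRow(
                cutoff=float(c),
                fp=int(fp),
                fn=int(fn),
                weighted_fp={s: balance_product(int(fp), rate_set.rate_ge[s]) for s in SEVERITY_THRESHOLDS},
            )
            for c, fp, fn in rows
        ]
        return cls(group=group, rows=built, rate_set=rate_set)

    def select_all(self) -> dict[str, CutoffSelection]:
        """Selected cutoff per severity threshold; cached on the table."""
        self.selected = {s: select_cutoff(self, s) for s in SEVERITY_THRESHOLDS}
        return self.selected

    def to_frame(self) -> pd.DataFrame:
        data = {
            "cutoff": [r.cutoff for r in self.rows],
            "fp": [r.fp for r in self.rows],
            "fn": [r.fn for r in self.rows],
        }
        for s in SEVERITY_THRESHOLDS:
            data[f"weighted_fp_ge_{s}"] = [r.weighted_fp[s] for r in self.rows]
        return pd.DataFrame(data)


def build_balance_table(
    labels,
    mp,
    cutoff_grid: Sequence[float],
    rate_set: ComplicationRateSet,
    group: str | None = None,
) -> BalanceTable:
    """Tabulate (FP, FN, FP x rate) over a strictly increasing percent grid."""
    grid = list(cutoff_grid)
    if not grid:
        raise ValueError("cutoff_grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("cutoff_grid must be strictly increasing")
    counts = [count_errors(labels, mp, c) for c in grid]
    return BalanceTable.from_counts(
        group or rate_set.group,
        [(c, fp, fn) for c, (fp, fn) in zip(grid, counts)],
        rate_set,
    )


def select_cutoff(table: BalanceTable, severity: str) -> CutoffSelection:
    """Cutoff closest to the balance point FN = FP x rate for ``severity``.

    Ties go to the lower cutoff.  ``at_boundary`` flags a minimizer at the
    first or last grid point, meaning the balance point was not bracketed
    by the grid (the residual is one-sided there).
    """
    if severity not in table.rate_set.rate_ge:
        raise ConfigurationError(
            f"severity '{severity}' not in rate set (known: {SEVERITY_THRESHOLDS})"
        )
    rate = float(table.rate_set.rate_ge[severity])
    resid = np.array([abs(r.fn - balance_product(r.fp, rate)) for r in table.rows])
    i = int(np.argmin(resid))  # argmin takes the first minimum: lower cutoff
    return CutoffSelection(
        severity=severity,
        cutoff=table.rows[i].cutoff,
        residual=float(resid[i]),
        at_boundary=i in (0, len(table.rows) - 1),
    )
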