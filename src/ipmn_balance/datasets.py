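"""Bundled reference worksheets.

Published risk–benefit worksheets from a resected branch/mixed-type IPMN
series at a high-volume pancreatic surgery center: for each candidate
malignancy-probability cutoff (percent), the number of benign patients at
or above the cutoff (false positives, FP) and the number of malignant
patients below it (false negatives, FN), tabulated separately for the
pancreaticoduodenectomy group (n = 464, 116 malignant) and the distal
pancreatectomy group (n = 293, 54 malignant), together with each group's
Clavien–Dindo complication exceedance rates.

These rows are inputs to the balance analysis, not outputs of this
package; they let the cutoff-selection rule be exercised on real published
counts without patient-level data.
"""

from __future__ import annotations

from .balance import BalanceTable
from .cohort import DP_RATES, PD_RATES, ComplicationRateSet

__all__ = [
    "PD_WORKSHEET_ROWS",
    "DP_WORKSHEET_ROWS",
    "pd_worksheet",
    "dp_worksheet",
]

#: (cutoff %, FP, FN) for the pancreaticoduodenectomy group (n = 464).
PD_WORKSHEET_ROWS: tuple[tuple[int, int, int], ...] = (
    (10, 319, 2),
    (13, 288, 6),
    (14, 274, 8),
    (15, 266, 8),
    (20, 208, 13),
    (21, 203, 14),
    (22, 196, 15),
    (30, 148, 22),
    (32, 131, 23),
    (33, 125, 26),
    (34, 117, 29),
    (40, 89, 35),
    (41, 86, 37),
    (42, 82, 38),
)

#: (cutoff %, FP, FN) for the distal pancreatectomy group (n = 293).
DP_WORKSHEET_ROWS: tuple[tuple[int, int, int], ...] = (
    (10, 188, 0),
    (13, 149, 2),
    (14, 138, 3),
    (15, 127, 4),
    (16, 118, 4),
    (17, 107, 4),
    (18, 103, 5),
    (20, 86, 6),
    (21, 82, 7),
    (22, 78, 8),
    (25, 59, 11),
    (26, 56, 13),
    (27, 54, 16),
    (30, 46, 20),
)


def pd_worksheet(rate_set: ComplicationRateSet = PD_RATES) -> BalanceTable:
    """The pancreaticoduodenectomy worksheet as a ready BalanceTable."""
    return BalanceTable.from_counts("PD", PD_WORKSHEET_ROWS, rate_set)


def dp_worksheet(rate_set: ComplicationRateSet = DP_RATES) -> BalanceTable:
    """The distal-pancreatectomy worksheet as a ready BalanceTable."""
    return BalanceTable.from_counts("DP", DP_WORKSHEET_ROWS, rate_set)
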