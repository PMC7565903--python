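"""Direct per-patient decision rule: operate when the malignancy
probability exceeds the patient's own predicted surgical risk.

Unlike the cohort-level balance cutoff, this rule uses each patient's
surgical-risk prediction as their personal cutoff.  The comparison is
strict — a patient whose malignancy probability merely equals their
surgical risk stays on surveillance (conservative toward non-operation).

Note on invariance: shifting both scores' logits by the same constant
leaves every operate/surveil decision unchanged (the logit is strictly
monotone), but it does change the continuous difference score mp - sc and
hence its ranking and AUC.  Only the binary rule is shift-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .diagnostics import AucResult, DiagnosticSummary, roc_auc

__all__ = ["DirectDecisionSummary", "direct_decision", "summarize_direct"]


def direct_decision(mp: float, sc: float) -> bool:
    """Operate iff malignancy probability strictly exceeds surgical risk."""
    if mp is None or sc is None or not (np.isfinite(mp) and np.isfinite(sc)):
        raise ValueError("both mp and sc must be finite probabilities")
    if not (0.0 <= mp <= 1.0 and 0.0 <= sc <= 1.0):
        raise ValueError("mp and sc must lie in [0, 1]")
    return mp > sc


@dataclass
class DirectDecisionSummary:
    """Cohort-level view of the per-patient rule.

    ``auc_difference`` is the AUC of the continuous score mp - sc;
    ``auc_binary_point`` is the trapezoid AUC through the rule's single
    ROC point, (sensitivity + specificity) / 2.  A binary rule has one
    operating point, so both conventions are reported.
    """

    n: int
    n_operate: int
    operate_frac: float
    surgery_reduction: float  # fraction spared surgery = 1 - operate_frac
    diagnostics: DiagnosticSummary
    auc_difference: Optional[AucResult]
    auc_binary_point: Optional[float]


def summarize_direct(labels, mp, sc) -> DirectDecisionSummary:
    """Apply mp > sc per patient and summarize against pathology labels."""
    labels = np.asarray(labels).astype(bool)
    mp = np.asarray(mp, dtype=float)
    sc = np.asarray(sc, dtype=float)
    if not (labels.shape == mp.shape == sc.shape) or labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels, mp and sc must be non-empty 1-D arrays of equal length")
    for name, arr in (("mp", mp), ("sc", sc)):
        if np.any(~np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"{name} must be probabilities in [0, 1]")
    operate = mp > sc
    tp = int(np.sum(operate & labels))
    fp = int(np.sum(operate & ~labels))
    tn = int(np.sum(~operate & ~labels))
    fn = int(np.sum(~operate & labels))

    def ratio(num, den):
        return num / den if den > 0 else None

    diag = DiagnosticSummary(
        cutoff=float("nan"),  # the cutoff is per-patient here
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_under_count=tn + fn,
        n_under_frac=(tn + fn) / labels.size,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )
    both_classes = labels.any() and (~labels).any()
    auc_diff = roc_auc(labels, mp - sc) if both_classes else None
    auc_point = (
        (diag.sensitivity + diag.specificity) / 2.0
        if diag.sensitivity is not None and diag.specificity is not None
        else None
    )
    n_op = int(operate.sum())
    return DirectDecisionSummary(
        n=labels.size,
        n_operate=n_op,
        operate_frac=n_op / labels.size,
        surgery_reduction=1.0 - n_op / labels.size,
        diagnostics=diag,
        auc_difference=auc_diff,
        auc_binary_point=auc_point,
    )
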