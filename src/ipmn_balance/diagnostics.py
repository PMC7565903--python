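"""Discrimination and calibration statistics.

Confusion metrics at a percent cutoff (same >=-operates convention as the
balance worksheet), ROC/AUC with a DeLong 95% confidence interval, and the
Hosmer–Lemeshow goodness-of-fit test over quantile bins of predicted
probability (10 bins for the 10% quantile scale, 5 for the 20% scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiagnosticSummary",
    "AucResult",
    "CalibrationResult",
    "confusion_at_cutoff",
    "roc_auc",
    "roc_points",
    "hosmer_lemeshow",
    "calibration_bins",
]

log = logging.getLogger(__name__)

#: Serialized placeholder for metrics with an empty denominator.
NOT_AVAILABLE = "NA"


def _as_arrays(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels and scores must be non-empty 1-D arrays of equal length")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return labels, scores


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci: tuple[float, float]  # 95% by default


@dataclass
class DiagnosticSummary:
    """Confusion-matrix characteristics at one cutoff.

    Ratios with an empty denominator are ``None`` (serialized as "NA"),
    never silently zero.
    """

    cutoff: float  # percent
    tp: int
    fp: int
    tn: int
    fn: int
    n_under_count: int  # patients below the cutoff = TN + FN
    n_under_frac: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    auc: Optional[AucResult] = None

    @property
    def degenerate(self) -> bool:
        """True when a class is absent or a predicted arm is empty."""
        return None in (self.sensitivity, self.specificity, self.ppv, self.npv)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_at_cutoff(labels, mp, cutoff: float) -> DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV and number-under-cutoff at a percent
    cutoff, treating probability >= cutoff as the call to operate."""
    labels, mp = _as_arrays(labels, mp)
    if mp.min() < 0.0 or mp.max() > 1.0:
        raise ValueError("mp must be probabilities in [0, 1]")
    operate = mp >= cutoff / 100.0
    tp = int(np.sum(operate & labels))
    fp = int(np.sum(operate & ~labels))
    tn = int(np.sum(~operate & ~labels))
    fn = int(np.sum(~operate & labels))
    return DiagnosticSummary(
        cutoff=float(cutoff),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_under_count=tn + fn,
        n_under_frac=(tn + fn) / labels.size,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def roc_auc(labels, scores, alpha: float = 0.05) -> AucResult:
    """AUC with a DeLong confidence interval.

    The point estimate is the Mann–Whitney probability that a malignant
    patient outscores a benign one, counting ties as one half; the
    variance comes from DeLong's structural components (placement values),
    so no bootstrap is needed.
    """
    labels, scores = _as_arrays(labels, scores)
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("roc_auc requires both classes present")
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores, method="average")
    r_pos = stats.rankdata(pos, method="average")
    r_neg = stats.rankdata(neg, method="average")
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # placement values: per-positive and per-negative component AUCs
    v01 = (r_all[:m] - r_pos) / n
    v10 = 1.0 - (r_all[m:] - r_neg) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return AucResult(auc=float(auc), se=se, ci=(float(lo), float(hi)))


def roc_points(labels, scores) -> pd.DataFrame:
    """ROC curve over the unique score thresholds (for plotting)."""
    labels, scores = _as_arrays(labels, scores)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    m = labels.sum()
    n = labels.size - m
    rows = []
    for t in thresholds:
        call = scores >= t
        rows.append(
            {
                "threshold": t,
                "tpr": np.sum(call & labels) / m if m else np.nan,
                "fpr": np.sum(call & ~labels) / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    n_bins: int  # effective bin count after any merging
    chi2: float
    df: int
    p_value: float
    bin_table: pd.DataFrame  # columns: n, observed, expected, mean_pred


def _quantile_bins(probs: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index per patient using ties-kept quantile edges.

    Tied probabilities always land in the same bin; duplicate quantile
    edges therefore reduce the effective bin count.
    """
    edges = np.quantile(probs, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges[1:-1])
    return np.searchsorted(edges, probs, side="right")


def calibration_bins(labels, probs, n_bins: int = 10) -> pd.DataFrame:
    """Observed vs expected events per quantile bin of predicted probability."""
    labels, probs = _as_arrays(labels, probs)
    if n_bins < 3:
        raise ValueError("n_bins must be at least 3")
    if labels.size < n_bins:
        raise ValueError("cohort smaller than the requested number of bins")
    idx = _quantile_bins(probs, n_bins)
    table = (
        pd.DataFrame({"bin": idx, "observed": labels.astype(int), "expected": probs})
        .groupby("bin")
        .agg(n=("observed", "size"), observed=("observed", "sum"), expected=("expected", "sum"), mean_pred=("expected", "mean"))
        .reset_index(drop=True)
    )
    # mean_pred aggregated over 'expected' column pre-sum; recompute properly
    table["mean_pred"] = table["expected"] / table["n"]
    return table


def hosmer_lemeshow(labels, probs, n_bins: int = 10, df: int | None = None) -> CalibrationResult:
    """Hosmer–Lemeshow chi-square test over quantile bins.

    Per bin, chi2 accumulates (O - E)^2 / (E (1 - E/n)); the reference
    distribution has ``n_bins - 2`` degrees of freedom by default, the
    standard choice when the probabilities come from a model fitted on the
    same data.  For probabilities fixed in advance (external validation),
    pass ``df=n_bins`` instead.  Bins whose expected variance is zero are
    merged into a neighbor and logged.
    """
    table = calibration_bins(labels, probs, n_bins)
    # merge zero-variance bins (all-0 or all-1 predictions) into a neighbor
    merged = []
    pending = None
    for row in table.itertuples(index=False):
        row = {"n": row.n, "observed": row.observed, "expected": row.expected}
        if pending is not None:
            for k in row:
                row[k] += pending[k]
            pending = None
        var = row["expected"] * (1.0 - row["expected"] / row["n"])
        if var <= 1e-12:
            log.warning("hosmer_lemeshow: merging zero-variance bin into neighbor")
            pending = row
        else:
            merged.append(row)
    if pending is not None:
        if merged:
            for k in pending:
                merged[-1][k] += pending[k]
        else:
            merged.append(pending)
    chi2 = 0.0
    for row in merged:
        var = row["expected"] * (1.0 - row["expected"] / row["n"])
        if var > 1e-12:
            chi2 += (row["observed"] - row["expected"]) ** 2 / var
    g = len(merged)
    dof = df if df is not None else g - 2
    if dof < 1:
        # too few distinct probability levels to test; report a null result
        log.warning("hosmer_lemeshow: fewer than 3 effective bins; test is vacuous")
        dof = max(dof, 1)
        p = 1.0 if chi2 <= 1e-12 else float(stats.chi2.sf(chi2, dof))
    else:
        p = float(stats.chi2.sf(chi2, dof))
    table["mean_pred"] = table["expected"] / table["n"]
    return CalibrationResult(n_bins=g, chi2=float(chi2), df=dof, p_value=p, bin_table=table)
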