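"""End-to-end driver: simulate (or load) -> score -> balance -> diagnose
-> compare, writing every result table plus a run log to an output
directory.  Deterministic given the config seed."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .balance import BalanceTable, build_balance_table
from .cohort import (
    SEVERITY_THRESHOLDS,
    CohortConfig,
    ComplicationRateSet,
    PatientRecord,
)
from .compare import DirectDecisionSummary, summarize_direct
from .diagnostics import (
    NOT_AVAILABLE,
    CalibrationResult,
    DiagnosticSummary,
    confusion_at_cutoff,
    hosmer_lemeshow,
    roc_auc,
)
from .errors import ConfigurationError
from .io import write_cohort, write_scored_cohort
from .risk import (
    DEFAULT_MP_SPEC,
    DEFAULT_SC_SPEC,
    LogisticModelSpec,
    SurgicalRiskSpec,
    sc_scores,
    score_records,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)

_DEFAULT_GRID = tuple(range(1, 100))


@dataclass
class PipelineConfig:
    """Everything one run needs; fully serializable and echoed to disk."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: Optional[str] = None  # when set, read instead of simulate
    mp_spec: LogisticModelSpec = DEFAULT_MP_SPEC
    sc_spec: SurgicalRiskSpec = DEFAULT_SC_SPEC
    cutoff_grid: Sequence[float] = _DEFAULT_GRID
    out_dir: str = "ipmn_balance_out"
    seed: int = 0

    def effective(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "cohort": plain(self.cohort),
            "cohort_path": self.cohort_path,
            "mp_spec": plain(self.mp_spec),
            "sc_spec": plain(self.sc_spec),
            "cutoff_grid": list(self.cutoff_grid),
            "out_dir": self.out_dir,
            "seed": self.seed,
            "version": __version__,
        }


@dataclass
class PipelineResult:
    records: list[PatientRecord]
    mp: np.ndarray
    sc: np.ndarray
    balance_tables: dict[str, BalanceTable]
    diagnostics: dict[str, dict[str, DiagnosticSummary]]  # group -> severity -> summary
    calibration: dict[str, CalibrationResult]  # "10pct" and "20pct" scales
    direct: Optional[DirectDecisionSummary]
    out_dir: Path


def _fmt(x, places: int) -> str:
    return NOT_AVAILABLE if x is None else f"{x:.{places}f}"


def _write_balance_tsv(table: BalanceTable, path: Path) -> None:
    sel = {s.cutoff for s in table.selected.values()}
    with open(path, "w") as fh:
        cols = ["cutoff", "fp", "fn"] + [f"weighted_fp_ge_{s}" for s in SEVERITY_THRESHOLDS] + ["selected"]
        fh.write("\t".join(cols) + "\n")
        for row in table.rows:
            cells = [f"{row.cutoff:g}", str(row.fp), str(row.fn)]
            cells += [f"{row.weighted_fp[s]:.3f}" for s in SEVERITY_THRESHOLDS]
            cells.append("*" if row.cutoff in sel else "")
            fh.write("\t".join(cells) + "\n")


def _write_diagnostics_tsv(diag: Mapping[str, Mapping[str, DiagnosticSummary]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "group\tseverity\tcutoff\tn_under\tn_under_frac\tsensitivity\t"
            "specificity\tppv\tnpv\tauc\tauc_lo\tauc_hi\n"
        )
        for group, per_sev in diag.items():
            for sev, d in per_sev.items():
                auc = d.auc
                fh.write(
                    "\t".join(
                        [
                            group,
                            sev,
                            f"{d.cutoff:g}",
                            str(d.n_under_count),
                            _fmt(d.n_under_frac, 4),
                            _fmt(d.sensitivity, 4),
                            _fmt(d.specificity, 4),
                            _fmt(d.ppv, 4),
                            _fmt(d.npv, 4),
                            _fmt(auc.auc if auc else None, 4),
                            _fmt(auc.ci[0] if auc else None, 4),
                            _fmt(auc.ci[1] if auc else None, 4),
                        ]
                    )
                    + "\n"
                )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run both arms of the risk-benefit analysis and write all outputs.

    Emits, per surgery group, the balance worksheet with selected cutoffs
    per severity and confusion diagnostics at each selected cutoff; plus
    calibration tables (10% and 20% quantile scales), the direct
    mp-vs-sc comparison summary, the scored cohort, and a run log echoing
    the effective config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_path is not None:
        from .io import read_cohort

        records = read_cohort(config.cohort_path)
        if not records:
            raise ConfigurationError(f"cohort_path: {config.cohort_path} holds no patients")
    else:
        from .cohort import generate_cohort

        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        records = generate_cohort(cohort_cfg).records
        write_cohort(records, out / "cohort.csv")

    labels = np.array([r.malignant for r in records], dtype=bool)
    mp = np.asarray(score_records(records, config.mp_spec))
    sc_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    sc = np.asarray(
        sc_scores(records, config.sc_spec, noise_sd=config.cohort.sc_noise_sd, rng=sc_rng)
    )
    write_scored_cohort(records, mp, sc, out / "scored_cohort.csv")

    groups = [g for g in ("PD", "DP") if any(r.surgery == g for r in records)]
    balance_tables: dict[str, BalanceTable] = {}
    diagnostics: dict[str, dict[str, DiagnosticSummary]] = {}
    selected_lines = ["group\tseverity\trate\tcutoff\tresidual\tat_boundary"]
    for group in groups:
        mask = np.array([r.surgery == group for r in records])
        if labels[mask].all() or not labels[mask].any():
            log.warning("group %s has a single pathology class; skipping balance", group)
            continue
        rate_set = config.cohort.rate_sets[group]
        table = build_balance_table(labels[mask], mp[mask], config.cutoff_grid, rate_set, group)
        table.select_all()
        balance_tables[group] = table
        _write_balance_tsv(table, out / f"balance_{group}.tsv")
        auc = roc_auc(labels[mask], mp[mask])
        per_sev = {}
        for sev, sel in table.selected.items():
            d = confusion_at_cutoff(labels[mask], mp[mask], sel.cutoff)
            d.auc = auc
            per_sev[sev] = d
            selected_lines.append(
                f"{group}\t{sev}\t{rate_set.rate_ge[sev]:g}\t{sel.cutoff:g}"
                f"\t{sel.residual:.3f}\t{int(sel.at_boundary)}"
            )
        diagnostics[group] = per_sev
    (out / "selected_cutoffs.tsv").write_text("\n".join(selected_lines) + "\n")
    _write_diagnostics_tsv(diagnostics, out / "diagnostics.tsv")

    calibration: dict[str, CalibrationResult] = {}
    if 0 < labels.sum() < labels.size and labels.size >= 10:
        for name, bins in (("10pct", 10), ("20pct", 5)):
            res = hosmer_lemeshow(labels, mp, n_bins=bins)
            calibration[name] = res
            res.bin_table.to_csv(out / f"calibration_{name}.csv", index=False)
        with open(out / "calibration.tsv", "w") as fh:
            fh.write("scale\tn_bins\tchi2\tdf\tp_value\n")
            for name, res in calibration.items():
                fh.write(f"{name}\t{res.n_bins}\t{res.chi2:.4f}\t{res.df}\t{res.p_value:.4f}\n")

    direct = None
    if 0 < labels.sum() < labels.size:
        direct = summarize_direct(labels, mp, sc)
        d = direct.diagnostics
        with open(out / "direct_comparison.tsv", "w") as fh:
            fh.write(
                "n\tn_operate\toperate_frac\tsurgery_reduction\tsensitivity\t"
                "specificity\tppv\tnpv\tauc_difference\tauc_binary_point\n"
            )
            fh.write(
                "\t".join(
                    [
                        str(direct.n),
                        str(direct.n_operate),
                        _fmt(direct.operate_frac, 4),
                        _fmt(direct.surgery_reduction, 4),
                        _fmt(d.sensitivity, 4),
                        _fmt(d.specificity, 4),
                        _fmt(d.ppv, 4),
                        _fmt(d.npv, 4),
                        _fmt(direct.auc_difference.auc if direct.auc_difference else None, 4),
                        _fmt(direct.auc_binary_point, 4),
                    ]
                )
                + "\n"
            )

    (out / "run_config.yaml").write_text(yaml.safe_dump(config.effective(), sort_keys=True))
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "n_patients": len(records),
                "groups": groups,
                "seed": config.seed,
                "config": config.effective(),
            },
            indent=2,
            default=str,
        )
    )
    return PipelineResult(
        records=records,
        mp=mp,
        sc=sc,
        balance_tables=balance_tables,
        diagnostics=diagnostics,
        calibration=calibration,
        direct=direct,
        out_dir=out,
    )
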