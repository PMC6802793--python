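"""End-to-end analysis of one experiment: ANOVA, OC%, paired comparisons.

Reproduces the published analysis structure for each design:

* eligibility bookkeeping (ANOVA vs OC% participant sets),
* per-participant cell means of MGA over size x judgement-correctness x
  block (single-vision designs) or x vision (closed/open-loop design),
* the fully-within repeated-measures ANOVA with partial eta squared,
* Bonferroni-corrected small-vs-big follow-ups within each
  judgement-correctness level (decomposing the size-by-report interaction),
* per-participant verbal accuracy and OC% (pooled across blocks within a
  vision condition by default),
* a Shapiro-Wilk check on the paired differences and a paired t-test of
  verbal accuracy against OC%, per vision condition.

Every analysis choice the original description leaves open (OC% pooling
mode, sphericity reporting) is a config key with the faithful default, so
replication against deposited data can sweep variants rather than guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classification, inferential, trial_data
from .trial_data import ParticipantSet, TrialRecord

logger = logging.getLogger(__name__)

DESIGN_FACTORS = {
    "E1": ("block", "size", "verbal"),
    "E2": ("block", "size", "verbal"),
    "E3": ("vision", "size", "verbal"),
}

DEFAULT_CONFIG = {
    "occ_pooling": "pooled",   # or "per_block"
    "follow_up_alpha": 0.05,
}


@dataclass
class AnalysisReport:
    """All result tables of one experiment's analysis."""

    experiment: str
    anova: pd.DataFrame
    pairwise: pd.DataFrame
    per_vision_anovas: dict[str, pd.DataFrame]
    occ: pd.DataFrame
    verbal: pd.DataFrame
    occ_summary: pd.DataFrame
    paired_tests: pd.DataFrame
    exclusion_log: dict[str, int] = field(default_factory=dict)


def _occ_frame(results: Sequence[classification.CutoffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "condition_label": r.condition_label,
                "cutoff_mm": r.cutoff_mm,
                "oc_proportion": r.oc_proportion,
                "n_small": r.n_small,
                "n_big": r.n_big,
                "candidate_count": r.candidate_count,
            }
            for r in results
        ],
        columns=[
            "participant_id", "condition_label", "cutoff_mm", "oc_proportion",
            "n_small", "n_big", "candidate_count",
        ],
    )


def run_experiment_analysis(
    records: Sequence[TrialRecord], design: str, config: dict | None = None
) -> AnalysisReport:
    """Full analysis of one experiment's trials; see module docstring."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    design = design.upper()
    if design not in DESIGN_FACTORS:
        raise ValueError(f"unknown design {design!r}")
    experiments = {r.experiment for r in records if r.valid}
    if experiments != {design}:
        raise ValueError(f"trials are from {sorted(experiments)}, expected {design}")

    pset = trial_data.partition_eligibility(records)
    factors = list(DESIGN_FACTORS[design])
    cells = inferential.cell_means(pset, factors)
    anova = inferential.rm_anova(cells, within=factors)

    # decompose the size x verbal-report interaction: small vs big within
    # each judgement-correctness level (Bonferroni family = 2)
    pairwise = inferential.bonferroni_pairwise(
        cells.groupby(["participant_id", "size", "verbal"], sort=True)["mga_mm"]
        .mean()
        .reset_index(),
        compare="size",
        within_levels_of="verbal",
    )

    per_vision: dict[str, pd.DataFrame] = {}
    if design == "E3":
        # follow-up of the three-way interaction: size x verbal per vision
        for vision in ("closed_loop", "open_loop"):
            sub = cells[cells["vision"] == vision]
            per_vision[vision] = inferential.rm_anova(sub, within=["size", "verbal"])

    occ = _occ_frame(classification.occ_by_participant(pset, pooling=cfg["occ_pooling"]))
    valid = [r for r in pset.records if r.valid and r.participant_id in pset.occ_eligible]
    verbal = classification.verbal_accuracy(valid, by_vision=(design == "E3"))

    summary_rows, paired_rows = [], []
    conditions = ("closed_loop", "open_loop") if design == "E3" else ("all",)
    for cond in conditions:
        occ_label = design if cond == "all" else f"{design}/{cond}"
        occ_c = occ[occ["condition_label"] == occ_label].set_index("participant_id")
        verbal_c = verbal[verbal["condition_label"] == cond].set_index("participant_id")
        both = sorted(set(occ_c.index) & set(verbal_c.index))
        v = verbal_c.loc[both, "accuracy"].to_numpy(dtype=float)
        o = occ_c.loc[both, "oc_proportion"].to_numpy(dtype=float)
        summary_rows.append(
            {
                "condition": cond,
                "n": len(both),
                "verbal_mean": float(v.mean()),
                "verbal_sd": float(v.std(ddof=1)),
                "occ_mean": float(o.mean()),
                "occ_sd": float(o.std(ddof=1)),
            }
        )
        diffs = v - o
        try:
            W, W_p = inferential.shapiro_wilk(diffs)
        except ValueError:
            W, W_p = np.nan, np.nan
        t_res = inferential.paired_t(v, o)
        paired_rows.append(
            {
                "condition": cond,
                "n": len(both),
                "t": t_res.t,
                "df": t_res.df,
                "p": t_res.p,
                "mean_diff": t_res.mean_diff,
                "sd_diff": t_res.sd_diff,
                "shapiro_W": W,
                "shapiro_p": W_p,
            }
        )

    n_all = len(pset.participants)
    exclusions = {
        "participants_total": n_all,
        "anova_eligible": len(pset.anova_eligible),
        "occ_eligible": len(pset.occ_eligible),
        "excluded_from_anova_only": len(pset.occ_eligible - pset.anova_eligible),
        "invalid_trials": sum(1 for r in pset.records if not r.valid),
        "missing_mga_trials": sum(
            1 for r in pset.records if r.valid and r.mga_mm is None
        ),
    }
    logger.info("exclusion log: %s", exclusions)
    return AnalysisReport(
        experiment=design,
        anova=anova,
        pairwise=pairwise,
        per_vision_anovas=per_vision,
        occ=occ,
        verbal=verbal,
        occ_summary=pd.DataFrame(summary_rows),
        paired_tests=pd.DataFrame(paired_rows),
        exclusion_log=exclusions,
    )


def _fmt_float(v: float) -> str:
    return "nan" if pd.isna(v) else f"{v:.4f}"


def make_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Persist every table as tidy CSV plus a human-readable markdown summary.

    Deterministic: the same report writes byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables = {
        "anova.csv": report.anova,
        "pairwise.csv": report.pairwise,
        "occ.csv": report.occ,
        "verbal_accuracy.csv": report.verbal,
        "occ_summary.csv": report.occ_summary,
        "paired_tests.csv": report.paired_tests,
    }
    for vision, table in sorted(report.per_vision_anovas.items()):
        tables[f"anova_{vision}.csv"] = table
    for name, table in tables.items():
        path = out / name
        table.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    lines = [f"# Analysis summary: {report.experiment}", ""]
    lines.append("## Exclusions")
    for key in sorted(report.exclusion_log):
        lines.append(f"- {key}: {report.exclusion_log[key]}")
    lines.append("")
    lines.append("## Repeated-measures ANOVA (cell-mean MGA)")
    for _, r in report.anova.iterrows():
        lines.append(
            f"- {r['effect']}: F({int(r['df_effect'])},{int(r['df_error'])}) = "
            f"{_fmt_float(r['F'])}, p = {_fmt_float(r['p'])} "
            f"(GG p = {_fmt_float(r['p_gg'])}), partial eta^2 = "
            f"{_fmt_float(r['partial_eta_sq'])}"
        )
    lines.append("")
    lines.append("## Verbal accuracy vs OC% (means, SEM)")
    for _, r in report.occ_summary.iterrows():
        n = int(r["n"])
        sem_v = r["verbal_sd"] / np.sqrt(n) if n > 1 else np.nan
        sem_o = r["occ_sd"] / np.sqrt(n) if n > 1 else np.nan
        lines.append(
            f"- {r['condition']} (n={n}): verbal {_fmt_float(r['verbal_mean'])} "
            f"(SEM {_fmt_float(sem_v)}), OC% {_fmt_float(r['occ_mean'])} "
            f"(SEM {_fmt_float(sem_o)})"
        )
    lines.append("")
    lines.append("## Paired tests (verbal - OC%)")
    for _, r in report.paired_tests.iterrows():
        lines.append(
            f"- {r['condition']}: t({int(r['df'])}) = {_fmt_float(r['t'])}, "
            f"p = {_fmt_float(r['p'])}, mean diff = {_fmt_float(r['mean_diff'])}, "
            f"Shapiro-Wilk W = {_fmt_float(r['shapiro_W'])} (p = {_fmt_float(r['shapiro_p'])})"
        )
    lines.append("")
    summary = out / "summary.md"
    summary.write_text("\n".join(lines))
    written.append(summary)
    return written
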