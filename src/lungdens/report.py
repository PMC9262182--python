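"""Cohort-level report: descriptives, regressions, odds ratios, ROC panel.

Mirrors the four-table layout of a diagnostic densitometry study:

1. group descriptives with BO-vs-control p-values,
2. age/sex-adjusted linear regressions of each LDI on the PFTs
   (univariate and backward-selected multivariable columns),
3. age/sex-adjusted logistic odds ratios of BO per variable,
4. ROC panel (cutoff, sensitivity, specificity, PPV, NPV, AUC with CI).

Variables that cannot be analysed (all-missing, separated, degenerate)
appear in the tables with a recorded reason instead of silently dropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import LDI_VARIABLES, PFT_VARIABLES, validate_cohort
from . import stats as ldstats

__all__ = ["ReportBundle", "build_report", "plot_roc_curves"]

#: PFT predictors entering the LDI regression table.
REGRESSION_PFTS = ("fev1_pct", "fev1_fvc_pct", "fef2575_pct", "rv_pct", "sraw_pct")

#: LDI outcomes in the regression table.
REGRESSION_LDIS = (
    "exp_mld_hu",
    "mldd_hu",
    "ei_mld_pct",
    "ei_volume_pct",
    "e950_pct",
    "e900_pct",
    "e850_pct",
    "e650_pct",
    "e600_pct",
)


@dataclass
class ReportBundle:
    """The four report tables plus per-variable complete-case counts."""

    descriptives: pd.DataFrame
    linear_regression: pd.DataFrame
    logistic_or: pd.DataFrame
    roc: pd.DataFrame
    complete_case_counts: pd.DataFrame
    notes: Dict[str, str] = field(default_factory=dict)

    def to_text(self) -> str:
        parts = []
        for title, df in [
            ("Group descriptives", self.descriptives),
            ("Adjusted linear regression (LDI ~ PFT + age + sex)", self.linear_regression),
            ("Adjusted logistic odds ratios for BO", self.logistic_or),
            ("ROC analysis", self.roc),
            ("Complete-case counts", self.complete_case_counts),
        ]:
            parts.append(f"== {title} ==")
            parts.append(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
            parts.append("")
        if self.notes:
            parts.append("== Notes ==")
            parts.extend(f"- {k}: {v}" for k, v in sorted(self.notes.items()))
        return "\n".join(parts) + "\n"

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(out / "table1_descriptives.csv", index=False)
        self.linear_regression.to_csv(out / "table2_linear_regression.csv", index=False)
        self.logistic_or.to_csv(out / "table3_logistic_or.csv", index=False)
        self.roc.to_csv(out / "table4_roc.csv", index=False)
        self.complete_case_counts.to_csv(out / "complete_case_counts.csv", index=False)
        (out / "report.txt").write_text(self.to_text())


def _descriptives(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    rows = []
    for var in ["age_years", "sex", *variables]:
        try:
            cmp = ldstats.compare_groups(table, var)
        except ValueError as err:
            rows.append({"variable": var, "test": "unavailable", "note": str(err)})
            continue
        row: Dict[str, object] = {
            "variable": var,
            "test": cmp.test,
            "p_value": cmp.p_value,
        }
        if cmp.test == "mann-whitney":
            for g in ("control", "BO"):
                s = cmp.group_summaries[g]
                row[f"{g}_n"] = int(s["n"])
                row[f"{g}_mean"] = s["mean"]
                row[f"{g}_sd"] = s["sd"]
                row[f"{g}_median"] = s["median"]
        else:
            for g, counts in cmp.group_summaries.items():
                row[f"{g}_counts"] = "; ".join(f"{k}={int(v)}" for k, v in counts.items())
        rows.append(row)
    return pd.DataFrame(rows)


def _linear_table(
    table: pd.DataFrame,
    outcomes: Sequence[str],
    predictors: Sequence[str],
    stay_threshold: float,
    notes: Dict[str, str],
) -> pd.DataFrame:
    rows = []
    for outcome in outcomes:
        try:
            uni = ldstats.adjusted_linear_fit(table, outcome, predictors, "univariate")
            multi = ldstats.adjusted_linear_fit(
                table, outcome, predictors, "backward", stay_threshold=stay_threshold
            )
        except (ValueError, ldstats.RankDeficiencyError) as err:
            notes[f"linear:{outcome}"] = str(err)
            continue
        retained = {r.predictor: r for r in multi}
        for r in uni:
            row = {
                "outcome": outcome,
                "predictor": r.predictor,
                "beta": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n_used": r.n_used,
            }
            m = retained.get(r.predictor)
            if m is not None:
                row.update(
                    multi_beta=m.estimate,
                    multi_ci_low=m.ci_low,
                    multi_ci_high=m.ci_high,
                    multi_p_value=m.p_value,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _logistic_table(
    table: pd.DataFrame, variables: Sequence[str], notes: Dict[str, str]
) -> pd.DataFrame:
    rows = []
    for var in variables:
        try:
            r = ldstats.adjusted_logistic_or(table, var)
        except (ValueError, ldstats.SeparationError, ldstats.RankDeficiencyError) as err:
            notes[f"logistic:{var}"] = str(err)
            rows.append({"variable": var, "note": str(err)})
            continue
        rows.append(
            {
                "variable": var,
                "odds_ratio": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n_used": r.n_used,
            }
        )
    return pd.DataFrame(rows)


def _roc_table(
    table: pd.DataFrame,
    variables: Sequence[str],
    ci_method: str,
    seed: int,
    notes: Dict[str, str],
) -> pd.DataFrame:
    rows = []
    for var in variables:
        try:
            r = ldstats.roc_analysis(table, var, ci_method=ci_method, seed=seed)
        except ValueError as err:
            notes[f"roc:{var}"] = str(err)
            rows.append({"variable": var, "note": str(err)})
            continue
        rows.append(
            {
                "variable": var,
                "orientation": r.orientation.value,
                "cutoff": r.cutoff,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "ppv": r.ppv if r.ppv is not None else np.nan,
                "npv": r.npv if r.npv is not None else np.nan,
                "auc": r.auc,
                "auc_ci_low": r.auc_ci[0],
                "auc_ci_high": r.auc_ci[1],
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "tn": r.tn,
                "n_used": r.n_used,
            }
        )
    return pd.DataFrame(rows)


def build_report(
    table: pd.DataFrame,
    ldi_variables: Sequence[str] = LDI_VARIABLES,
    pft_variables: Sequence[str] = PFT_VARIABLES,
    regression_outcomes: Sequence[str] = REGRESSION_LDIS,
    regression_predictors: Sequence[str] = REGRESSION_PFTS,
    ci_method: str = "delong",
    stay_threshold: float = 0.05,
    seed: int = 0,
) -> ReportBundle:
    """Assemble the full four-table diagnostic report for a cohort.

    Per-variable failures (all-missing columns, separated logistic fits)
    are recorded in ``bundle.notes`` and the affected rows carry a
    ``note`` entry; the remaining analyses still run.
    """
    validate_cohort(table)
    for g in ("control", "BO"):
        if (table["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    notes: Dict[str, str] = {}
    present_pfts = [v for v in pft_variables if v in table.columns]
    present_ldis = [v for v in ldi_variables if v in table.columns]
    for v in set(pft_variables) - set(present_pfts):
        notes[f"missing-column:{v}"] = "PFT column absent from table"
    all_vars = [*present_pfts, *present_ldis]
    counts = pd.DataFrame(
        {
            "variable": all_vars,
            "n_complete": [int(table[v].notna().sum()) for v in all_vars],
            "n_control": [
                int(table.loc[table["group"] == "control", v].notna().sum())
                for v in all_vars
            ],
            "n_bo": [
                int(table.loc[table["group"] == "BO", v].notna().sum()) for v in all_vars
            ],
        }
    )
    return ReportBundle(
        descriptives=_descriptives(table, all_vars),
        linear_regression=_linear_table(
            table,
            [o for o in regression_outcomes if o in table.columns],
            [p for p in regression_predictors if p in table.columns],
            stay_threshold,
            notes,
        ),
        logistic_or=_logistic_table(table, all_vars, notes),
        roc=_roc_table(table, all_vars, ci_method, seed, notes),
        complete_case_counts=counts,
        notes=notes,
    )


def plot_roc_curves(
    table: pd.DataFrame,
    variables: Sequence[str],
    path: str | Path,
    title: Optional[str] = None,
) -> None:
    """Static summary plot of empirical ROC curves for selected variables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for var in variables:
        sub = table[["group", var]].dropna()
        pos = sub.loc[sub["group"] == "BO", var].to_numpy(dtype=float)
        neg = sub.loc[sub["group"] == "control", var].to_numpy(dtype=float)
        if pos.size == 0 or neg.size == 0:
            continue
        auc = ldstats.auc_mann_whitney(pos, neg)
        sign = 1.0 if auc >= 0.5 else -1.0
        scores = np.unique(np.concatenate([sign * pos, sign * neg]))[::-1]
        tpr = [0.0] + [float((sign * pos >= c).mean()) for c in scores] + [1.0]
        fpr = [0.0] + [float((sign * neg >= c).mean()) for c in scores] + [1.0]
        ax.plot(fpr, tpr, label=f"{var} (AUC {max(auc, 1 - auc):.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
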