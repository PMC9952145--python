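"""Per-feature healthy-vs-CVD t-test screen and tabular report rendering.

Each subject-level column is screened with a Welch (unequal-variance)
two-sample t-test at alpha = 0.05. No multiple-testing correction is
applied to the significance flag — the screen is descriptive — but a
Benjamini-Hochberg adjusted p-value column is emitted alongside for an
honest reading of the 36+ simultaneous tests.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mlpipe import ClassificationReport, SelectionResult

ALPHA = 0.05


def ttest_features(
    healthy: pd.DataFrame,
    cvd: pd.DataFrame,
    alpha: float = ALPHA,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Welch t-test per shared numeric column, sorted by p-value.

    Columns with fewer than two finite values in either group are skipped
    with a warning. Identical degenerate groups (zero variance, equal means)
    are reported as t = 0, p = 1: the null is exactly true.
    """
    if columns is None:
        columns = [
            c
            for c in healthy.columns
            if c in cvd.columns and pd.api.types.is_numeric_dtype(healthy[c])
        ]
    rows = []
    for col in columns:
        x = healthy[col].dropna().to_numpy(dtype=float)
        y = cvd[col].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"skipping {col!r}: fewer than 2 values in a group",
                          stacklevel=2)
            continue
        if np.var(x) == 0 and np.var(y) == 0:
            t, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                "feature": col,
                "t_statistic": float(t),
                "p_value": float(p),
                "mean_healthy": float(np.mean(x)),
                "mean_cvd": float(np.mean(y)),
                "significant": bool(p < alpha),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = stats.false_discovery_control(out["p_value"], method="bh")
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


def selection_table(selections: dict[str, SelectionResult]) -> pd.DataFrame:
    """One row per classifier: its selected feature subset, in order."""
    rows = []
    for name, sel in selections.items():
        rows.append(
            {
                "classifier": name,
                "selected_features": ", ".join(sel.selected_features),
                "n_selected": len(sel.selected_features),
                "final_cv_accuracy": sel.final_cv_accuracy,
                "direction": sel.direction,
            }
        )
    return pd.DataFrame(rows)


def accuracy_table(reports: dict[str, ClassificationReport]) -> pd.DataFrame:
    """One row per classifier: CV accuracy and macro recall."""
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "classifier": name,
                "accuracy_pct": rep.accuracy,
                "macro_recall": rep.macro_recall,
            }
        )
    return pd.DataFrame(rows)


def render_reports(
    out_dir: str | Path,
    stage: int,
    selections: dict[str, SelectionResult] | None = None,
    reports: dict[str, ClassificationReport] | None = None,
    ttests: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the selection / accuracy / t-test tables as CSV + plain text.

    Regenerating from the same inputs is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        csv_path = out / f"{name}.csv"
        df.to_csv(csv_path, index=False, float_format="%.6g")
        txt_path = out / f"{name}.txt"
        txt_path.write_text(df.to_string(index=False, float_format="%.4g".__mod__) + "\n")
        written.extend([csv_path, txt_path])

    if selections is not None:
        emit(selection_table(selections), f"selection_stage{stage}")
    if reports is not None:
        emit(accuracy_table(reports), f"accuracy_stage{stage}")
        for name, rep in reports.items():
            p = out / f"confusion_stage{stage}_{name}.csv"
            rep.confusion.to_csv(p)
            written.append(p)
    if ttests is not None:
        emit(ttests, "ttests")
    return written
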