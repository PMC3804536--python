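"""Group comparison and table rendering: mean ± SD, Student t, percent change.

Everything here follows the reporting conventions of small-cohort animal
studies: sample SD with the n-1 denominator, two-tailed pooled-variance
Student t-tests (not Welch), significance marks 'a' for P<0.001 and 'b' for
P<0.05, and percent differences rounded to integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupSummary:
    variable: str
    groups: dict  # name -> {"n": int, "mean": float, "sd": float}
    p_value: float
    mark: str  # "" | "a" (P<0.001) | "b" (P<0.05)


def _mark(p: float) -> str:
    if p < 0.001:
        return "a"
    if p < 0.05:
        return "b"
    return ""


def summarize(variable: str, values_by_group: dict) -> GroupSummary:
    """Per-group mean ± SD plus a two-tailed pooled-variance t-test.

    Exactly two groups are required (the comparison is pairwise).
    """
    if len(values_by_group) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(values_by_group)}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    (na, a), (nb, b) = arrays.items()
    if np.var(a) == 0.0 and np.var(b) == 0.0 and np.mean(a) == np.mean(b):
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    groups = {
        k: {"n": int(v.size), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
        for k, v in arrays.items()
    }
    return GroupSummary(variable=variable, groups=groups, p_value=p, mark=_mark(p))


def percent_difference(mean_a: float, mean_b: float, digits: int = 0) -> float:
    """100*(mean_a - mean_b)/mean_b, rounded for reporting."""
    if mean_b == 0:
        raise ValueError("reference mean must be non-zero")
    return round(100.0 * (mean_a - mean_b) / mean_b, digits) if digits else round(
        100.0 * (mean_a - mean_b) / mean_b
    )


def summary_table(
    data: pd.DataFrame, group_col: str = "group", digits: int = 2
) -> pd.DataFrame:
    """Mean ± SD per group with p-values and marks for every numeric column."""
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    rows = []
    for col in data.columns:
        if col == group_col or not pd.api.types.is_numeric_dtype(data[col]):
            continue
        s = summarize(
            col, {g: data.loc[data[group_col] == g, col].to_numpy() for g in groups}
        )
        row = {"variable": col}
        for g in groups:
            gs = s.groups[g]
            row[f"{g} (n={gs['n']})"] = (
                f"{gs['mean']:.{digits}f} ± {gs['sd']:.{digits}f}"
            )
            row[f"{g}_mean"] = gs["mean"]
            row[f"{g}_sd"] = gs["sd"]
        row["p_value"] = s.p_value
        row["mark"] = s.mark
        rows.append(row)
    return pd.DataFrame(rows)


def render_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering with superscript-style significance marks."""
    display_cols = [c for c in table.columns if not c.endswith(("_mean", "_sd"))]
    df = table[display_cols].copy()
    shown = [c for c in df.columns if "(n=" in c]
    if shown and "mark" in df.columns:
        # the mark annotates the test group (first column), read as
        # "significantly different from the reference group"
        first = shown[0]
        df[first] = [
            f"{v} ^{m}^" if m else str(v) for v, m in zip(df[first], df["mark"])
        ]
    df["p_value"] = df["p_value"].map(lambda p: f"{p:.4f}")
    df = df.drop(columns=["mark"])
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = "\n".join("| " + " | ".join(str(v) for v in row) + " |" for row in df.to_numpy())
    return "\n".join([header, sep, body])
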