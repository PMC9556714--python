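"""Behavioral gating-cost statistics for the reference-back task.

Gate opening cost = switch_reference - nonswitch_reference;
gate closing cost = switch_comparison - nonswitch_comparison,
computed per subject for mean RT (correct trials only) and accuracy
(percent correct among responded trials), then compared with a paired t
test. Cohen's d uses the paired-design conversion d = t / sqrt(n), the
convention that reproduces the reported effect sizes from the reported
t statistics.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CONDITIONS


def condition_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition mean RT (correct trials) and accuracy.

    ``trials`` needs columns subject, condition, rt_ms, correct; rows
    without a condition label (block-initial no-response reference
    trials) are ignored. Accuracy is 100 * correct / responded; trials
    with no response count toward neither numerator nor denominator.
    """
    df = trials[trials["condition"].isin(CONDITIONS)].copy()
    rows = []
    for (subj, cond), grp in df.groupby(["subject", "condition"], sort=True):
        responded = grp[np.isfinite(grp["rt_ms"].to_numpy(dtype=float))]
        correct = responded[responded["correct"].astype(bool)]
        rows.append(
            {
                "subject": subj,
                "condition": cond,
                "n_trials": len(grp),
                "n_responded": len(responded),
                "mean_rt": correct["rt_ms"].mean() if len(correct) else np.nan,
                "accuracy": 100.0 * len(correct) / len(responded)
                if len(responded)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def gating_costs(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject gate opening/closing costs for RT and accuracy.

    Raises if any subject is missing one of the four condition cells.
    """
    out = []
    for subj, grp in table.groupby("subject", sort=True):
        cells: Dict[str, pd.Series] = {
            row["condition"]: row for _, row in grp.iterrows()
        }
        for cond in CONDITIONS:
            if cond not in cells or not np.isfinite(cells[cond]["mean_rt"]):
                raise ValueError(f"subject {subj}: missing condition cell {cond}")
        out.append(
            {
                "subject": subj,
                "opening_rt": cells["switch_reference"]["mean_rt"]
                - cells["nonswitch_reference"]["mean_rt"],
                "closing_rt": cells["switch_comparison"]["mean_rt"]
                - cells["nonswitch_comparison"]["mean_rt"],
                "opening_acc": cells["switch_reference"]["accuracy"]
                - cells["nonswitch_reference"]["accuracy"],
                "closing_acc": cells["switch_comparison"]["accuracy"]
                - cells["nonswitch_comparison"]["accuracy"],
            }
        )
    return pd.DataFrame(out)


def paired_t_and_d(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Classical paired t test plus the paired-design effect size d = t/sqrt(n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences: t undefined")
    t, p = stats.ttest_rel(x, y)
    n = len(x)
    return {"t": float(t), "df": n - 1, "p": float(p), "d": float(t) / np.sqrt(n)}


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size from a reported t statistic."""
    return float(t) / np.sqrt(n)


def normality_check(values: Sequence[float]) -> float:
    """Kolmogorov-Smirnov p-value against a fitted normal (diagnostic
    only; never used as a gate)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest((v - v.mean()) / sd, "norm").pvalue)
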