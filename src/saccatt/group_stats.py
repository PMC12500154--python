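"""Condition-level inference and behavioral summaries.

One-way repeated-measures ANOVA (uncorrected df, partial η²), paired /
one-sample t-tests with Cohen's d and Bonferroni adjustment, and the
two-step response-time trimming (absolute 3,000 ms ceiling first, then
a 2.5 SD cutoff around each participant's mean of the surviving
trials, pooled across classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from . import defaults


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p_value: float
    partial_eta_sq: float


@dataclass
class TTestResult:
    comparison: str
    t: float
    df: int
    cohen_d: float
    p_raw: float
    p_bonferroni: float


def rm_anova(values: np.ndarray | pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA on a participants × classes table.

    Uncorrected degrees of freedom (k−1, (k−1)(n−1)); partial η² =
    SS_effect / (SS_effect + SS_error).  Missing cells are an error —
    no imputation.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("values must be participants × classes")
    n, k = arr.shape
    if k < 2 or n < 3:
        raise ValueError("need ≥ 2 classes and ≥ 3 participants")
    if not np.isfinite(arr).all():
        raise ValueError("missing cells are not allowed")
    cols = list(values.columns) if isinstance(values, pd.DataFrame) else list(range(k))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "cond": np.tile(cols, n),
        "y": arr.ravel(),
    })
    if np.allclose(arr, arr[:, [0]]):
        # identical conditions: SS_effect = SS_error = 0; take the F → 0 limit
        return AnovaResult(F=0.0, df=(k - 1, (k - 1) * (n - 1)), p_value=1.0,
                           partial_eta_sq=0.0)
    res = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                      detailed=True, effsize="np2")
    row = res.loc[res["Source"] == "cond"].iloc[0]
    return AnovaResult(F=float(row["F"]), df=(int(row["DF"]), int(k - 1) * (n - 1)),
                       p_value=float(row["p_unc"]), partial_eta_sq=float(row["np2"]))


def paired_tests(
    values: pd.DataFrame | np.ndarray,
    comparisons: list[tuple] | None = None,
    m_corrections: int | None = None,
) -> list[TTestResult]:
    """Two-sided paired (or vs-zero) t-tests with Bonferroni adjustment.

    ``comparisons`` is a list of ``(a, b)`` column pairs (paired test of
    a − b) or ``(a,)`` / ``(a, None)`` for a one-sample test of column a
    against zero.  ``m_corrections`` defaults to the number of
    comparisons.  Cohen's d = mean(diff) / sd(diff).
    """
    df_vals = pd.DataFrame(values)
    if comparisons is None:
        cols = list(df_vals.columns)
        comparisons = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    m = m_corrections if m_corrections is not None else len(comparisons)
    out = []
    for comp in comparisons:
        a = df_vals[comp[0]].to_numpy(dtype=float)
        if len(comp) > 1 and comp[1] is not None:
            diff = a - df_vals[comp[1]].to_numpy(dtype=float)
            name = f"{comp[0]} - {comp[1]}"
        else:
            diff = a
            name = f"{comp[0]} vs 0"
        sd = diff.std(ddof=1)
        n = diff.size
        if sd == 0:
            if np.all(diff == 0):
                # identical vectors: the t → 0 limit is well defined
                out.append(TTestResult(comparison=name, t=0.0, df=n - 1, cohen_d=0.0,
                                       p_raw=1.0, p_bonferroni=1.0))
                continue
            raise ValueError(f"zero-variance differences in comparison {name!r}")
        t = diff.mean() / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
        out.append(TTestResult(comparison=name, t=float(t), df=n - 1,
                               cohen_d=float(diff.mean() / sd), p_raw=float(p),
                               p_bonferroni=float(min(1.0, p * m))))
    return out


def trim_rts(
    rt_table: pd.DataFrame,
    ceiling_ms: float = defaults.RT_CEILING_MS,
    sd_cutoff: float = defaults.RT_SD_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step RT trimming, then per-class behavioral summaries.

    Step 1 drops trials with ``rt_ms`` above the absolute ceiling.
    Step 2 drops trials outside mean ± ``sd_cutoff`` SD, where mean and
    SD are computed per participant over step-1 survivors pooled across
    classes; a zero SD (e.g. all RTs identical) trims nothing.
    Returns (trimmed table, summary) where the summary holds
    per-participant per-class mean RT and accuracy.
    """
    req = {"participant", "class", "rt_ms", "correct"}
    missing = req - set(rt_table.columns)
    if missing:
        raise ValueError(f"rt table missing columns: {missing}")
    step1 = rt_table[rt_table["rt_ms"] <= ceiling_ms].copy()
    keep = []
    for p, grp in step1.groupby("participant"):
        mu, sd = grp["rt_ms"].mean(), grp["rt_ms"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            keep.append(grp)
            continue
        keep.append(grp[(grp["rt_ms"] - mu).abs() <= sd_cutoff * sd])
    trimmed = pd.concat(keep, ignore_index=True) if keep else step1.iloc[:0]
    summary = (
        trimmed.groupby(["participant", "class"], as_index=False)
        .agg(mean_rt_ms=("rt_ms", "mean"), accuracy=("correct", "mean"),
             n_trials=("rt_ms", "size"))
    )
    return trimmed, summary
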