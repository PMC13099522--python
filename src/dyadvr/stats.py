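"""Group-comparison harness: Wilcoxon rank tests and standardized effect size.

Paired condition contrasts (e.g. no-shock vs shock within the same fish)
use the Wilcoxon signed-rank test on per-unit values; unpaired group
contrasts (e.g. WT vs TG fish) use the Wilcoxon rank-sum test. Exact
small-sample p-values are used where the data permit. The effect size is
the standardized mean difference (mu1 - mu2) / sigma with sigma the
population standard deviation of the concatenation of both groups
(pooled-within-group SD available as an option). Two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # 'signed_rank' | 'rank_sum'
    p_value: float
    effect_size: float | None
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    group1: str = "group1"
    group2: str = "group2"


def effect_size(
    group1: Sequence[float],
    group2: Sequence[float],
    sd_mode: str = "population",
) -> float | None:
    """Standardized mean difference (mu1 - mu2) / sigma.

    ``sd_mode='population'`` (default): sigma is the ddof=0 SD of the
    concatenation of both groups. ``sd_mode='pooled_within'``: classical
    pooled within-group SD. Returns None when the spread is zero.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if sd_mode == "population":
        sigma = float(np.std(np.concatenate([x, y]), ddof=0))
    elif sd_mode == "pooled_within":
        n1, n2 = len(x), len(y)
        if n1 + n2 < 3:
            raise ValueError("pooled-within SD needs at least 3 values")
        sigma = float(
            np.sqrt(
                ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1))
                / (n1 + n2 - 2)
            )
        )
    else:
        raise ValueError("sd_mode must be 'population' or 'pooled_within'")
    if sigma == 0.0:
        return None
    return float((np.mean(x) - np.mean(y)) / sigma)


def _coerce_records(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        missing = {"unit", "condition", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"records are missing columns {sorted(missing)}")
    else:
        df = pd.DataFrame(list(records), columns=["unit", "condition", "value"])
    return df


def compare_conditions(records, paired: bool, sd_mode: str = "population") -> ComparisonResult:
    """Two-sided rank test over per-unit (unit, condition, value) records.

    Exactly two condition labels are required. Paired mode pairs values by
    unit (every unit must appear in both conditions; >= 3 units) and runs
    the signed-rank test; unpaired mode runs the rank-sum test on the two
    groups. Identical paired samples (all zero differences) are reported
    with p = 1 (no evidence of a shift; degenerate for the signed-rank
    statistic).
    """
    df = _coerce_records(records)
    conditions = sorted(df["condition"].astype(str).unique())
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {conditions}")
    c1, c2 = conditions
    if paired:
        wide = (
            df.groupby(["unit", "condition"])["value"].mean().unstack("condition")
        )
        if wide[[c1, c2]].isna().any().any():
            raise ValueError("paired mode requires both conditions for every unit")
        if len(wide) < 3:
            raise ValueError("paired mode needs at least 3 units")
        x = wide[c1].to_numpy(float)
        y = wide[c2].to_numpy(float)
        diffs = x - y
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(x, y, alternative="two-sided").pvalue)
        test = "signed_rank"
        n1 = n2 = len(wide)
    else:
        x = df.loc[df["condition"].astype(str) == c1, "value"].to_numpy(float)
        y = df.loc[df["condition"].astype(str) == c2, "value"].to_numpy(float)
        if len(x) < 1 or len(y) < 1 or len(x) + len(y) < 3:
            raise ValueError("need at least 3 values across both groups")
        p = float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue
        )
        test = "rank_sum"
        n1, n2 = len(x), len(y)
    try:
        es = effect_size(x, y, sd_mode=sd_mode)
    except ValueError:
        es = None
    return ComparisonResult(
        test=test,
        p_value=p,
        effect_size=es,
        n1=n1,
        n2=n2,
        mean1=float(np.mean(x)),
        mean2=float(np.mean(y)),
        sd1=float(np.std(x, ddof=0)),
        sd2=float(np.std(y, ddof=0)),
        group1=c1,
        group2=c2,
    )


def comparison_table(
    table: pd.DataFrame,
    metrics: Iterable[str],
    group_col: str,
    unit_col: str,
    paired: bool,
) -> pd.DataFrame:
    """One comparison row per metric column of a tidy metrics table."""
    rows = []
    for metric in metrics:
        sub = table[[unit_col, group_col, metric]].dropna()
        records = sub.rename(
            columns={unit_col: "unit", group_col: "condition", metric: "value"}
        )
        res = compare_conditions(records, paired=paired)
        rows.append(
            {
                "metric": metric,
                "test": res.test,
                "group1": res.group1,
                "group2": res.group2,
                "n1": res.n1,
                "n2": res.n2,
                "mean1": res.mean1,
                "mean2": res.mean2,
                "p_value": res.p_value,
                "effect_size": res.effect_size,
            }
        )
    return pd.DataFrame(rows)
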