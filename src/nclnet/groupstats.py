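"""Pre/post statistical comparison of network features.

Each (subject, band, feature) cell is tested with a two-group one-way ANOVA
comparing all pre-condition values against all post-condition values — with
two groups this is equivalent to the square of the pooled-variance t test.
Significance marks follow the usual convention: '**' for p < 0.01, '*' for
0.01 <= p < 0.05, 'n.s.' otherwise.

Two sampling granularities are supported: ``"window"`` (every trial x window
value is an observation; the default, matching the 7-windows-per-condition
feature granularity used for decoding) and ``"trial"`` (windows averaged
within each trial first, which removes the serial dependence between
overlapping windows).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

__all__ = ["one_way_anova", "compare_conditions", "summarize", "significance_mark"]

FEATURES = ("k_bar", "Q")


def significance_mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def one_way_anova(group_a, group_b) -> tuple[float, float]:
    """Two-group fixed-effects one-way ANOVA; returns (F, p).

    Degenerate inputs (zero pooled within-group variance) return F = 0,
    p = 1 when the means are also equal, and F = inf, p = 0 otherwise, each
    with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ss_within == 0.0:
        if a.mean() == b.mean():
            warnings.warn("degenerate ANOVA: identical constant groups (F=0, p=1)", stacklevel=2)
            return 0.0, 1.0
        warnings.warn(
            "degenerate ANOVA: zero within-group variance, unequal means (p=0)", stacklevel=2
        )
        return float("inf"), 0.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)


def _check_granularity(granularity: str) -> None:
    if granularity not in ("window", "trial"):
        raise ParameterError(
            f"granularity must be 'window' or 'trial', got {granularity!r}"
        )


def _cell_values(df: pd.DataFrame, feature: str, granularity: str) -> pd.Series:
    if granularity == "trial":
        return df.groupby(["condition", "trial"], observed=True)[feature].mean()
    return df.set_index("condition")[feature]


def compare_conditions(
    features: pd.DataFrame, granularity: str = "window"
) -> pd.DataFrame:
    """One ANOVA per (subject, band, feature): pre values vs post values.

    Returns a DataFrame with columns subject_id, band, feature, n_pre,
    n_post, F, p, mark.  Cells missing one of the two conditions are skipped
    with a warning.
    """
    _check_granularity(granularity)
    rows = []
    features = features.sort_values(["subject_id", "band", "trial", "window"], kind="stable")
    for (subject, band), cell in features.groupby(["subject_id", "band"], sort=True):
        conditions = set(cell["condition"])
        if not {"pre", "post"} <= conditions:
            warnings.warn(
                f"({subject}, {band}): missing condition {sorted({'pre', 'post'} - conditions)}; skipped",
                stacklevel=2,
            )
            continue
        for feature in FEATURES:
            values = _cell_values(cell, feature, granularity)
            pre = np.asarray(values.loc["pre"], dtype=float).ravel()
            post = np.asarray(values.loc["post"], dtype=float).ravel()
            f, p = one_way_anova(pre, post)
            rows.append(
                {
                    "subject_id": subject,
                    "band": band,
                    "feature": feature,
                    "n_pre": pre.size,
                    "n_post": post.size,
                    "F": f,
                    "p": p,
                    "mark": significance_mark(p),
                }
            )
    return pd.DataFrame(rows)


def summarize(features: pd.DataFrame, granularity: str = "window") -> pd.DataFrame:
    """Mean ± sample standard deviation (ddof=1) per (subject, band, condition, feature).

    The layout mirrors a summary table of bands x condition x subjects; the
    ``formatted`` column renders "mean ± sd" to two decimals.
    """
    if features.empty:
        raise DataError("empty feature table")
    _check_granularity(granularity)
    rows = []
    for (subject, band, condition), cell in features.groupby(
        ["subject_id", "band", "condition"], sort=True
    ):
        for feature in FEATURES:
            if granularity == "trial":
                vals = cell.groupby("trial")[feature].mean().to_numpy()
            else:
                vals = cell[feature].to_numpy()
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            rows.append(
                {
                    "subject_id": subject,
                    "band": band,
                    "condition": condition,
                    "feature": feature,
                    "n": vals.size,
                    "mean": mean,
                    "sd": sd,
                    "formatted": f"{mean:.2f} ± {sd:.2f}",
                }
            )
    return pd.DataFrame(rows)
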