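"""Pooled two-sample t statistics from group summaries or raw values."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["GroupSummary", "pooled_t", "summarize", "table_report"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation (ddof=1) and size of one group."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise InputError("sd must be non-negative")
        if self.n < 2:
            raise InputError("group size must be >= 2")


def summarize(values, label: str = "") -> GroupSummary:
    """Summary statistics of raw values (sample sd, ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise InputError("need a 1-d array of at least 2 values")
    return GroupSummary(label, float(v.mean()), float(v.std(ddof=1)), len(v))


def pooled_t(a: GroupSummary, b: GroupSummary):
    """Pooled-variance two-sample t test, signed as a minus b.

    ``s_p^2 = ((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2)``;
    ``t = (mean_a - mean_b) / (s_p sqrt(1/n_a + 1/n_b))``;
    two-sided p from the t distribution with ``n_a + n_b - 2`` df.
    Zero pooled variance gives t = 0 for equal means and an infinite t
    (signed) otherwise.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    diff = a.mean - b.mean
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def table_report(rows) -> pd.DataFrame:
    """Apply :func:`pooled_t` to (variable, GroupSummary, GroupSummary) rows."""
    rows = list(rows)
    if not rows:
        raise InputError("need at least one row")
    out = []
    for variable, a, b in rows:
        t, df, p = pooled_t(a, b)
        out.append(
            {
                "variable": variable,
                "mean_a": a.mean, "sd_a": a.sd, "n_a": a.n,
                "mean_b": b.mean, "sd_b": b.sd, "n_b": b.n,
                "t": t, "df": df, "p": p,
            }
        )
    return pd.DataFrame(out)
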