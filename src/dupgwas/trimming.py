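"""Trimming of duplicate trait measurements.

Univariate trimming removes the tails of one measurement's distribution,
the usual guard against gross recording errors.  Bivariate trimming uses
the other measurement as a cross-check and removes pairs whose divergence
statistic is large: ``diff1 = (y1 - y2)^2`` (mm²) or its size-scaled
variant ``diff2 = (y1 - y2)^2 / (0.5 (y1 + y2))`` (mm).  Averaging the two
measurements is the third error-control option.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "pair_divergence",
    "bivariate_trim",
    "univariate_trim",
    "mean_measurement",
    "trim_report",
]


def pair_divergence(
    y1: np.ndarray | pd.Series | float,
    y2: np.ndarray | pd.Series | float | None = None,
    metric: str = "diff1",
):
    """Divergence between paired measurements.

    ``diff1 = (y1 - y2)^2`` (mm²); ``diff2 = diff1 / (0.5 (y1 + y2))`` (mm).
    Accepts scalars, arrays or aligned Series; ``diff2`` requires y1+y2 > 0.
    """
    if y2 is None:  # allow pair_divergence((y1, y2))
        y1, y2 = y1
    a = np.asarray(y1, dtype=float)
    b = np.asarray(y2, dtype=float)
    d1 = (a - b) ** 2
    if metric == "diff1":
        out = d1
    elif metric == "diff2":
        s = 0.5 * (a + b)
        if np.any(s <= 0):
            raise ZeroDivisionError("diff2 undefined where y1 + y2 <= 0")
        out = d1 / s
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if np.isscalar(y1) or np.ndim(y1) == 0:
        return float(out)
    if isinstance(y1, pd.Series):
        return pd.Series(out, index=y1.index)
    return out


def bivariate_trim(
    pairs: pd.DataFrame,
    threshold: float,
    metric: str = "diff1",
    y1_col: str = "m1",
    y2_col: str = "m2",
) -> list:
    """Ids of pairs whose divergence is strictly below ``threshold``.

    ``pairs`` is indexed by animal id with the two measurement columns;
    input order is preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = pair_divergence(pairs[y1_col], pairs[y2_col], metric=metric)
    return list(pairs.index[np.asarray(d) < threshold])


def univariate_trim(
    values: pd.Series,
    lower_frac: float = 0.05,
    upper_frac: float = 0.05,
) -> list:
    """Ids retained after removing the distribution's tails.

    Cut points are nearest-rank empirical quantiles and removal is strict
    (values *equal* to a cut point are retained), so heavy ties at the cut
    — routine with heaped integer data — are kept rather than dropped.
    """
    if len(values) == 0:
        raise ValueError("empty input")
    if lower_frac < 0 or upper_frac < 0 or lower_frac + upper_frac >= 1:
        raise ValueError("invalid trimming fractions")
    v = values.to_numpy(dtype=float)
    n = len(v)
    srt = np.sort(v)
    keep = np.ones(n, dtype=bool)
    if lower_frac > 0:
        lo = srt[math.ceil(lower_frac * n) - 1]  # nearest-rank quantile
        keep &= v >= lo
    if upper_frac > 0:
        hi = srt[n - math.ceil(upper_frac * n)]
        keep &= v <= hi
    return list(values.index[keep])


def mean_measurement(
    pairs: pd.DataFrame, y1_col: str = "m1", y2_col: str = "m2"
) -> pd.Series:
    """Per-animal arithmetic mean of the two measurements (mm).

    Animals missing either measurement are excluded.
    """
    both = pairs[[y1_col, y2_col]].dropna()
    return ((both[y1_col] + both[y2_col]) / 2.0).rename("mean_measurement")


def trim_report(
    pairs: pd.DataFrame,
    retained: Iterable,
    y_cols: Sequence[str] = ("m1", "m2"),
) -> pd.DataFrame:
    """Before/after summary of a trimming step, one row per measurement."""
    from .concordance import trait_summary

    retained = list(retained)
    rows = []
    for col in y_cols:
        for label, frame in (("before", pairs), ("after", pairs.loc[retained])):
            s = trait_summary(frame[col].dropna())
            rows.append({"measurement": col, "stage": label, **s.as_dict()})
    return pd.DataFrame(rows)
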