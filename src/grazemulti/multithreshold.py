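"""Multithreshold multifunctionality: counts of functions beyond thresholds.

Averaging many functions into one index can mask trade-offs, so the
multithreshold approach instead counts, per plot and per threshold t (25%,
50%, 75%, 90% by default), how many functions attain at least t times a
per-function benchmark. In the default (standardized) mode the count is of
standardized values EF >= t, consistent with a pipeline where min-max
standardization precedes every index; raw mode compares raw values against
t times a raw benchmark (the observed maximum, or the mean of the top-k
values for outlier robustness).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from grazemulti.standardization import minmax_standardize
from grazemulti.tables_io import RawFunctionTable

DEFAULT_THRESHOLDS = (0.25, 0.5, 0.75, 0.9)


def functions_beyond_threshold(raw: RawFunctionTable,
                               thresholds=DEFAULT_THRESHOLDS,
                               benchmark: str = "max",
                               k: int = 2,
                               use_standardized: bool = True) -> pd.DataFrame:
    """Count, per plot and threshold, the functions at or beyond the threshold.

    Returns a long-format frame (plot_id, threshold, n_functions_beyond).
    The boundary is inclusive: a function exactly at t * benchmark counts.

    With ``use_standardized=True`` (default) the standardized value EF is
    compared against t directly. With ``use_standardized=False`` the raw
    value is compared against t times the per-function benchmark: the
    observed maximum (``benchmark='max'``) or the mean of the k largest
    values (``benchmark='top_k_mean'``).
    """
    thresholds = list(thresholds)
    if any(not (0 < t < 1) for t in thresholds):
        raise ValueError("thresholds must lie strictly between 0 and 1")

    if use_standardized:
        std = minmax_standardize(raw)
        vals = std.data.set_index("plot_id")[std.variables]
        bench = pd.Series(1.0, index=std.variables)
    else:
        vals = raw.data.set_index("plot_id")[raw.functions]
        if benchmark == "max":
            bench = vals.max(axis=0)
        elif benchmark == "top_k_mean":
            bench = vals.apply(lambda c: c.nlargest(k).mean(), axis=0)
        else:
            raise ValueError(f"unknown benchmark {benchmark!r}")
        if (vals.max(axis=0) == vals.min(axis=0)).any():
            const = vals.columns[(vals.max(axis=0) == vals.min(axis=0))].tolist()
            raise ValueError(f"degenerate (constant) function column(s): {const}")

    rows = []
    for t in thresholds:
        counts = (vals.to_numpy() >= t * bench.to_numpy()).sum(axis=1)
        rows.append(pd.DataFrame({"plot_id": vals.index, "threshold": t,
                                  "n_functions_beyond": counts}))
    return pd.concat(rows, ignore_index=True)


def threshold_regressions(profile: pd.DataFrame, predictor: pd.Series) -> pd.DataFrame:
    """OLS of the per-plot function count on a diversity index, per threshold.

    ``predictor`` is indexed by plot_id. Returns one row per threshold with
    slope, intercept, R, R2, p (two-sided, t with n-2 df) and n.
    """
    out = []
    for t, grp in profile.groupby("threshold"):
        x = predictor.reindex(grp["plot_id"]).to_numpy(dtype=float)
        y = grp["n_functions_beyond"].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"threshold {t}: need at least 3 plots")
        if np.var(x) == 0:
            raise ValueError(f"threshold {t}: predictor has zero variance")
        fit = stats.linregress(x, y)
        out.append({"threshold": t, "slope": fit.slope, "intercept": fit.intercept,
                    "R": fit.rvalue, "R2": fit.rvalue ** 2, "p": fit.pvalue,
                    "n": len(x)})
    return pd.DataFrame(out)
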