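"""Diversity-function associations: OLS fits and leave-one-group-out screens.

The headline biodiversity-ecosystem-function relationship is an ordinary
least-squares regression of multifunctionality on multidiversity (or on the
above-/below-ground aggregates or a single group's richness). A
leave-one-group-out sensitivity recomputes multidiversity without one
organism group to check that no single group drives the association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from grazemulti.indices import average_index
from grazemulti.standardization import StandardizedTable


@dataclass
class OlsFit:
    predictor: str
    response: str
    slope: float
    intercept: float
    R: float
    R2: float
    p: float
    n: int
    excluded_group: str | None = None

    def as_dict(self) -> dict:
        d = {"predictor": self.predictor, "response": self.response,
             "slope": self.slope, "intercept": self.intercept,
             "R": self.R, "R2": self.R2, "p": self.p, "n": self.n}
        if self.excluded_group is not None:
            d["excluded_group"] = self.excluded_group
        return d


def ols_fit(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray,
            predictor: str = "x", response: str = "y",
            method: str = "pearson") -> OlsFit:
    """Simple OLS of y on x with Pearson R and a two-sided slope test.

    The p-value is for slope != 0 from the t distribution with n - 2 df.
    ``method='spearman'`` swaps the reported R (and its p) for Spearman's
    rank correlation while keeping the OLS slope/intercept.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        y = y.reindex(x.index)
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) < 3:
        raise ValueError("ols_fit: need at least 3 observations")
    if np.var(xv) == 0:
        raise ValueError("ols_fit: predictor has zero variance (undefined slope)")
    fit = stats.linregress(xv, yv)
    if method == "pearson":
        R, p = fit.rvalue, fit.pvalue
    elif method == "spearman":
        R, p = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return OlsFit(predictor, response, float(fit.slope), float(fit.intercept),
                  float(R), float(R) ** 2, float(p), len(xv))


def leave_one_group_out(richness_std: StandardizedTable, groups: list[str],
                        emf: pd.Series, exclude: str,
                        response: str = "EMF_avg") -> OlsFit:
    """Refit EMF ~ multidiversity with one organism group excluded.

    Multidiversity is recomputed as the mean standardized richness over
    ``groups`` minus ``exclude``, then regressed against the supplied EMF.
    """
    if exclude not in groups:
        raise ValueError(f"{exclude!r} is not one of the groups {groups}")
    remaining = [g for g in groups if g != exclude]
    if len(remaining) < 2:
        raise ValueError("leave_one_group_out: at least 2 groups must remain")
    idx = average_index(richness_std, remaining, name="multidiversity_loo")
    fit = ols_fit(idx.values, emf, predictor="multidiversity_loo", response=response)
    fit.excluded_group = exclude
    return fit


def correlation_screen(predictors: pd.DataFrame, responses: pd.DataFrame,
                       method: str = "pearson",
                       bh_correct: bool = False) -> pd.DataFrame:
    """All predictor x response OLS fits as a tidy table.

    Raw p-values by default (no multiplicity correction); ``bh_correct``
    appends Benjamini-Hochberg adjusted p-values across the whole grid.
    """
    rows = []
    for px in predictors.columns:
        for ry in responses.columns:
            fit = ols_fit(predictors[px], responses[ry], px, ry, method)
            rows.append(fit.as_dict())
    out = pd.DataFrame(rows)
    if bh_correct:
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
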