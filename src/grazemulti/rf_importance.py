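"""Random-forest predictor screening with permutation-derived significance.

Ranks candidate predictors of multifunctionality (livestock diversity, soil
pH, electrical conductivity, bulk density, diversity indices) by random-forest
permutation importance, and attaches a significance level to each importance
by refitting the forest on response-permuted data: the null distribution of
each predictor's importance is built from ``n_permutations`` refits, and

    p_perm = (1 + #{null importance >= observed}) / (n_permutations + 1)

so p_perm is never zero (add-one rule). A regression forest is the default:
multifunctionality is a continuous response. A classification switch exists
for a user-supplied discretization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance


@dataclass
class RFImportanceResult:
    table: pd.DataFrame  # predictor, importance, p_perm
    n_trees: int
    n_permutations: int
    seed: int

    def top_predictor(self) -> str:
        return self.table.sort_values(
            ["importance", "predictor"], ascending=[False, True]
        )["predictor"].iloc[0]


def _fit_importance(X: np.ndarray, y: np.ndarray, columns, n_trees: int,
                    rng: np.random.RandomState, classification: bool,
                    n_repeats: int) -> np.ndarray:
    cls = RandomForestClassifier if classification else RandomForestRegressor
    forest = cls(n_estimators=n_trees,
                 random_state=rng.randint(0, 2**31 - 1))
    forest.fit(X, y)
    imp = permutation_importance(forest, X, y, n_repeats=n_repeats,
                                 random_state=rng.randint(0, 2**31 - 1))
    return imp.importances_mean


def rf_screen(X: pd.DataFrame, y: pd.Series, n_trees: int = 1000,
              n_permutations: int = 500, seed: int = 0,
              classification: bool = False,
              n_repeats: int = 5) -> RFImportanceResult:
    """Rank predictors by forest importance with permutation significance.

    Parameters
    ----------
    X
        Plots x predictors; categorical predictors must be dummy-coded.
    y
        Per-plot response (continuous multifunctionality by default).
    n_trees, n_permutations
        Forest size and number of response-permutation refits for the null.
    seed
        Single seed controlling the forest, the importance shuffles and the
        response permutations; identical seed + data gives identical output.
    """
    if len(X) < 8:
        raise ValueError("rf_screen: need at least 8 plots")
    yv = np.asarray(y, dtype=float) if not classification else np.asarray(y)
    if not classification and np.var(yv) == 0:
        raise ValueError("rf_screen: constant response")
    if n_permutations < 20:
        warnings.warn("rf_screen: fewer than 20 permutations gives an unstable "
                      "p-value floor", stacklevel=2)

    rng = np.random.RandomState(seed)
    Xv = X.to_numpy(dtype=float)
    observed = _fit_importance(Xv, yv, X.columns, n_trees, rng,
                               classification, n_repeats)

    exceed = np.zeros(len(X.columns))
    for _ in range(n_permutations):
        y_perm = rng.permutation(yv)
        null_imp = _fit_importance(Xv, y_perm, X.columns, n_trees, rng,
                                   classification, n_repeats)
        exceed += null_imp >= observed
    p_perm = (1.0 + exceed) / (n_permutations + 1.0)

    table = pd.DataFrame({"predictor": list(X.columns),
                          "importance": observed,
                          "p_perm": p_perm})
    return RFImportanceResult(table, n_trees, n_permutations, seed)
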