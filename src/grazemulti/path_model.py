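"""Recursive observed-variable path analysis (SEM without latent variables).

A path model is a DAG over observed variables. For recursive models with
uncorrelated disturbances, maximum-likelihood estimation decomposes into one
least-squares regression per endogenous variable on its parents; the solved
coefficients and disturbance variances assemble the implied covariance

    Sigma_hat = (I - B)^-1 Psi (I - B)^-T

where B holds the path coefficients and Psi the free exogenous
(co)variances plus the diagonal disturbance variances. Model fit is the
Wishart ML discrepancy

    F_ML = ln|Sigma_hat| - ln|S| + tr(S Sigma_hat^-1) - p,    chi2 = (n - 1) F_ML

with df = p(p+1)/2 minus the number of free parameters. Variables are
standardized to unit variance first, so coefficients are standardized path
coefficients and total effects are sums over directed paths of coefficient
products, computed in closed form as (I - B)^-1 - I. Close fit is assessed
via RMSEA with its noncentral-chi-square test of RMSEA <= 0.05, and the
Bollen-Stine bootstrap provides a model-based empirical null for chi2:
the data are rotated to satisfy the fitted model exactly
(Z S^-1/2 Sigma_hat^1/2), rows are resampled with replacement, and the
refit chi2 values form the reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from grazemulti.tables_io import DesignTable

#: RMSEA value whose tail probability defines the close-fit test.
RMSEA_CLOSE = 0.05


class SpecificationError(ValueError):
    """The path-model DAG is malformed (cycle, unknown variable, ...)."""


@dataclass
class PathModelSpec:
    """Directed acyclic graph over named observed variables."""

    variables: list[str]
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        known = set(self.variables)
        for s, t in self.edges:
            if s not in known or t not in known:
                raise SpecificationError(f"edge {s} -> {t} uses unknown variable")
        if len(set(self.edges)) != len(self.edges):
            raise SpecificationError("duplicate edge in model spec")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise SpecificationError("path model contains a cycle")
        self._graph = g

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.variables if self._graph.in_degree(v) == 0]

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.variables if self._graph.in_degree(v) > 0]

    def parents(self, v: str) -> list[str]:
        return sorted(self._graph.predecessors(v))

    def n_free_parameters(self) -> int:
        n_exog = len(self.exogenous)
        return len(self.edges) + len(self.endogenous) + n_exog * (n_exog + 1) // 2

    @classmethod
    def from_dict(cls, d: dict) -> "PathModelSpec":
        """Build from a config mapping: {variables: [...], edges: ["A -> B", ...]}."""
        edges = []
        for e in d["edges"]:
            if isinstance(e, str):
                s, t = (part.strip() for part in e.split("->"))
            else:
                s, t = e
            edges.append((s, t))
        return cls(list(d["variables"]), edges)


def default_model() -> PathModelSpec:
    """The shipped livestock -> diversity -> multifunctionality model.

    Livestock diversity acts on above- and below-ground diversity, both act
    on EMF, and a direct livestock -> EMF path remains; the above/below
    disturbances are uncorrelated, leaving one untested moment (df = 1).
    This topology is a documented reconstruction of the reported model.
    """
    return PathModelSpec(
        variables=["livestock", "above_diversity", "below_diversity", "EMF"],
        edges=[("livestock", "above_diversity"),
               ("livestock", "below_diversity"),
               ("above_diversity", "EMF"),
               ("below_diversity", "EMF"),
               ("livestock", "EMF")],
    )


@dataclass
class PathFitResult:
    spec: PathModelSpec
    direct: pd.DataFrame    # [target, source] standardized coefficients
    indirect: pd.DataFrame
    total: pd.DataFrame
    R2: dict[str, float]
    chi2: float
    df: int
    p_chi2: float
    rmsea: float
    p_close: float
    n: int
    p_bollen_stine: float | None = None
    n_bootstrap: int = 0
    implied_cov: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> dict:
        out = {"chi2": self.chi2, "df": self.df, "p_chi2": self.p_chi2,
               "rmsea": self.rmsea, "p_close": self.p_close, "n": self.n}
        if self.p_bollen_stine is not None:
            out["p_bollen_stine"] = self.p_bollen_stine
        for v, r2 in self.R2.items():
            out[f"R2_{v}"] = r2
        return out


def dummy_code(design: DesignTable, level: str) -> pd.Series:
    """0/1 indicator of one grazing management type vs. all others.

    Codes 1 for plots under ``level`` (e.g. MG) and 0 for the remaining
    management types plus the ungrazed control.
    """
    if level not in design.treatments:
        raise ValueError(f"unknown treatment level {level!r}; "
                         f"known: {design.treatments}")
    coded = (design.data["treatment"] == level).astype(float)
    coded.index = design.data["plot_id"].to_numpy()
    if coded.nunique() == 1:
        import logging
        logging.getLogger("grazemulti").warning(
            "dummy_code: indicator for %s is constant (zero variance)", level)
    return coded.rename(f"is_{level}")


def residualize_by_block(y: pd.Series, design: DesignTable) -> pd.Series:
    """Remove block means from a per-plot variable.

    Equivalent to taking residuals of an ANOVA with block as the only
    predictor; residuals sum to zero within every block. Used to confirm
    that block structure does not drive the path-model conclusions.
    """
    df = design.data.copy()
    vals = y.reindex(df["plot_id"]).to_numpy(dtype=float)
    blocks = df["block"].to_numpy()
    if len(set(blocks)) < 2:
        raise ValueError("residualize_by_block: need at least 2 blocks")
    out = vals.copy()
    for b in set(blocks):
        mask = blocks == b
        if mask.sum() == 1:
            import warnings
            warnings.warn(f"block {b!r} has a single plot; residual is 0 "
                          "by construction", stacklevel=2)
        out[mask] = vals[mask] - vals[mask].mean()
    return pd.Series(out, index=df["plot_id"].to_numpy(), name=y.name)


def _fit_matrices(S: np.ndarray, spec: PathModelSpec
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Solve the per-equation ML estimates from a covariance matrix.

    Returns (B, Psi): B[i, j] is the coefficient on variable j in the
    equation for variable i; Psi holds the exogenous covariances (fitted at
    their sample values) and the diagonal disturbance variances.
    """
    order = {v: i for i, v in enumerate(spec.variables)}
    p = len(spec.variables)
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))

    exog_idx = [order[v] for v in spec.exogenous]
    Psi[np.ix_(exog_idx, exog_idx)] = S[np.ix_(exog_idx, exog_idx)]

    for v in spec.endogenous:
        i = order[v]
        par = [order[u] for u in spec.parents(v)]
        Spp = S[np.ix_(par, par)]
        Spy = S[np.ix_(par, [i])].ravel()
        coef = np.linalg.solve(Spp, Spy)
        B[i, par] = coef
        Psi[i, i] = S[i, i] - coef @ Spy
    return B, Psi


def _chi2_from_cov(S: np.ndarray, spec: PathModelSpec, n: int) -> float:
    B, Psi = _fit_matrices(S, spec)
    p = S.shape[0]
    inv_IB = np.linalg.inv(np.eye(p) - B)
    Sigma = inv_IB @ Psi @ inv_IB.T
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0:
        raise np.linalg.LinAlgError(
            f"sample covariance not positive definite "
            f"(condition number {np.linalg.cond(S):.3g})")
    if sign_m <= 0:
        raise np.linalg.LinAlgError("implied covariance not positive definite")
    F_ml = logdet_m - logdet_s + np.trace(S @ np.linalg.inv(Sigma)) - p
    return max(float((n - 1) * F_ml), 0.0)


def _matrix_power_half(M: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    if np.any(vals <= 0):
        raise np.linalg.LinAlgError("matrix not positive definite")
    return vecs @ np.diag(vals ** power) @ vecs.T


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec,
                   bootstrap: int = 0, seed: int = 0,
                   standardize: bool = True) -> PathFitResult:
    """Fit a recursive path model by per-equation ML and assess its fit.

    Parameters
    ----------
    data
        Plots x variables; must contain every variable of ``spec``.
    bootstrap
        Number of Bollen-Stine bootstrap resamples (0 disables).
    seed
        Seed for the bootstrap row resampling.
    standardize
        Scale variables to unit variance first (default), so coefficients
        and effects are standardized; fit statistics are unaffected.
    """
    missing = [v for v in spec.variables if v not in data.columns]
    if missing:
        raise KeyError(f"data lacks model variable(s) {missing}")
    X = data[spec.variables].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > {p} observations, got {n}")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [v for v, s in zip(spec.variables, sd) if s == 0]
        raise ValueError(f"constant column(s) {const} cannot enter the model")
    Z = X - X.mean(axis=0)
    if standardize:
        Z = Z / sd

    S = (Z.T @ Z) / (n - 1)
    B, Psi = _fit_matrices(S, spec)

    inv_IB = np.linalg.inv(np.eye(p) - B)
    Sigma = inv_IB @ Psi @ inv_IB.T

    df = p * (p + 1) // 2 - spec.n_free_parameters()
    if df < 0:
        raise SpecificationError(f"over-parameterized model: df = {df}")
    chi2 = _chi2_from_cov(S, spec, n)
    if df == 0:
        chi2 = 0.0
        p_chi2, rmsea, p_close = 1.0, 0.0, 1.0
    else:
        p_chi2 = float(stats.chi2.sf(chi2, df))
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        lam = RMSEA_CLOSE ** 2 * df * (n - 1)
        p_close = float(stats.ncx2.sf(chi2, df, lam))

    names = spec.variables
    direct = pd.DataFrame(B, index=names, columns=names)
    total_mat = inv_IB - np.eye(p)
    total = pd.DataFrame(total_mat, index=names, columns=names)
    indirect = total - direct

    order = {v: i for i, v in enumerate(names)}
    R2 = {v: float(1.0 - Psi[order[v], order[v]] / S[order[v], order[v]])
          for v in spec.endogenous}

    p_bs = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        # rotate the data so the fitted model holds exactly in population
        Y = Z @ _matrix_power_half(S, -0.5) @ _matrix_power_half(Sigma, 0.5)
        exceed = 0
        for _ in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            Yb = Y[idx]
            Sb = np.cov(Yb, rowvar=False, ddof=1)
            try:
                chi2_b = _chi2_from_cov(Sb, spec, n)
            except np.linalg.LinAlgError:
                continue  # degenerate resample: skip, conservative
            if chi2_b >= chi2:
                exceed += 1
        p_bs = (1.0 + exceed) / (bootstrap + 1.0)

    return PathFitResult(spec, direct, indirect, total, R2, chi2, df,
                         p_chi2, rmsea, p_close, n, p_bs, bootstrap,
                         pd.DataFrame(Sigma, index=names, columns=names))


def total_effects_table(fit: PathFitResult, outcome: str) -> pd.Series:
    """Standardized total effects (direct + indirect) of every ancestor on
    an endogenous outcome, as plotted in effect-decomposition panels."""
    if outcome not in fit.spec.variables:
        raise KeyError(f"unknown variable {outcome!r}")
    if outcome not in fit.spec.endogenous:
        raise ValueError(f"{outcome!r} is exogenous; it has no predictors")
    col = fit.total.loc[outcome].drop(outcome)
    ancestors = nx.ancestors(fit.spec._graph, outcome)
    return col[[v for v in col.index if v in ancestors]].rename("STE")


def chi2_tail_probability(chi2: float, df: int) -> float:
    """P(X >= chi2) for X ~ central chi-square with df degrees of freedom."""
    return float(stats.chi2.sf(chi2, df))
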