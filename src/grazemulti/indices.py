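"""Multifunctionality and multidiversity indices.

The averaging index (EMF) is the per-plot mean of min-max standardized
ecosystem functions; multidiversity and the above-/below-ground diversity
aggregates are the same construction over richness groups. A weighted EMF
variant down-weights highly correlated functions: functions are clustered by
average-linkage on the distance 1 - |r|, and each of the k clusters receives
total weight 1/k, split equally among its m_c members (weight 1/(k * m_c)).
In the limit where every cluster is a singleton the weighted index reduces
exactly to the unweighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from grazemulti.standardization import StandardizedTable


@dataclass
class IndexResult:
    """Per-plot values of one composite index with its component weights."""

    index_name: str
    values: pd.Series  # indexed by plot_id
    weights: dict[str, float]  # variable -> weight, summing to 1

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"IndexResult: weights sum to {total}, expected 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("IndexResult: negative weight")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"plot_id": self.values.index,
                             self.index_name: self.values.to_numpy()})


@dataclass
class WeightingScheme:
    """Variable weights, either uniform or from correlation clustering."""

    method: str = "correlation_clusters"  # or "uniform"
    correlation_metric: str = "spearman"  # or "pearson"
    cluster_height: float = 0.5
    weights: dict[str, float] = field(default_factory=dict)


def _columns(std: StandardizedTable, variables: list[str]) -> pd.DataFrame:
    missing = [v for v in variables if v not in std.variables]
    if missing:
        raise KeyError(f"unknown variable(s) {missing}; available: {std.variables}")
    return std.data.set_index("plot_id")[list(variables)]


def average_index(std: StandardizedTable, variables: list[str],
                  name: str = "EMF_avg") -> IndexResult:
    """Unweighted mean of the named standardized columns, per plot."""
    if len(variables) < 1:
        raise ValueError("average_index: need at least one variable")
    cols = _columns(std, variables)
    w = 1.0 / len(variables)
    return IndexResult(name, cols.mean(axis=1), {v: w for v in variables})


def derive_weights(std: StandardizedTable, variables: list[str],
                   scheme: WeightingScheme | None = None) -> WeightingScheme:
    """Derive correlation-down-weighting weights for the weighted EMF.

    Pairwise correlation (Spearman by default) among the function columns is
    converted to the distance 1 - |r|; average-linkage clusters are cut at
    ``cluster_height`` (default 0.5, i.e. functions merging at |r| >= 0.5
    share a cluster). Each variable's weight is 1/(k * m_c) for k clusters
    and cluster size m_c, so weights sum to 1. Variables are processed in
    lexicographic order so ties resolve identically on every platform.
    """
    scheme = scheme or WeightingScheme()
    if scheme.method == "uniform":
        w = 1.0 / len(variables)
        return WeightingScheme("uniform", scheme.correlation_metric,
                               scheme.cluster_height, {v: w for v in variables})

    ordered = sorted(variables)
    cols = _columns(std, ordered)
    if len(cols) < 2:
        raise ValueError("derive_weights: need at least 2 plots")
    if len(ordered) < 2:
        raise ValueError("derive_weights: need at least 2 variables")

    if scheme.correlation_metric == "spearman":
        corr, _ = spearmanr(cols.to_numpy())
        corr = np.atleast_2d(corr)
    elif scheme.correlation_metric == "pearson":
        corr = np.corrcoef(cols.to_numpy(), rowvar=False)
    else:
        raise ValueError(f"unknown correlation metric {scheme.correlation_metric!r}")

    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # enforce exact symmetry
    labels = fcluster(average(squareform(dist, checks=False)),
                      t=scheme.cluster_height, criterion="distance")

    k = len(np.unique(labels))
    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    weights = {v: 1.0 / (k * sizes[lab]) for v, lab in zip(ordered, labels)}
    return WeightingScheme("correlation_clusters", scheme.correlation_metric,
                           scheme.cluster_height, weights)


def weighted_index(std: StandardizedTable, scheme: WeightingScheme,
                   name: str = "EMF_weighted") -> IndexResult:
    """Weighted mean of standardized functions under a weighting scheme."""
    variables = sorted(scheme.weights)
    if not variables:
        raise ValueError("weighted_index: scheme has no weights")
    cols = _columns(std, variables)
    w = np.array([scheme.weights[v] for v in variables])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weighted_index: weights must sum to 1")
    vals = pd.Series(cols.to_numpy() @ w, index=cols.index)
    return IndexResult(name, vals, dict(scheme.weights))
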