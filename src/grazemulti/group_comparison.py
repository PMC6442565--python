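"""Blocked ANOVA of treatment effects with Tukey HSD post hoc letters.

The experiment is a balanced randomized complete block design (RCBD): every
grazing treatment appears exactly once in every block. The additive model

    y_bt = mu + block_b + treatment_t + e_bt

is fitted by its closed-form sums-of-squares decomposition. Treating block as
a fixed additive factor gives the identical treatment F-test to the
random-block mixed model in a balanced RCBD, which is the inferential target;
no variance components are estimated. Tukey's studentized-range test compares
all treatment pairs, and a compact letter display summarizes the outcome at
alpha = 0.1, the significance convention used for all treatment contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from grazemulti.tables_io import DesignTable


class UnbalancedDesignError(ValueError):
    """The design is not a balanced complete block layout."""


@dataclass
class AnovaResult:
    response: str
    F_treatment: float
    df_treatment: int
    df_residual: int
    p_treatment: float
    block_SS: float
    treatment_SS: float
    residual_SS: float
    treatment_means: dict[str, float]
    ms_residual: float
    n_blocks: int
    perfect_separation: bool = False

    def summary(self) -> dict:
        return {"response": self.response, "F_treatment": self.F_treatment,
                "df_treatment": self.df_treatment, "df_residual": self.df_residual,
                "p_treatment": self.p_treatment, "block_SS": self.block_SS,
                "treatment_SS": self.treatment_SS, "residual_SS": self.residual_SS}


def _aligned(y: pd.Series, design: DesignTable) -> pd.DataFrame:
    df = design.data.copy()
    df["y"] = y.reindex(df["plot_id"]).to_numpy(dtype=float)
    if df["y"].isna().any():
        missing = df.loc[df["y"].isna(), "plot_id"].tolist()
        raise ValueError(f"response missing for plot(s) {missing}")
    return df


def block_anova(y: pd.Series, design: DesignTable, response: str = "y") -> AnovaResult:
    """Two-way additive ANOVA (treatment + block) for a balanced RCBD.

    ``y`` is indexed by plot_id. F_treatment = MS_treatment / MS_residual
    with (t-1, (t-1)(b-1)) degrees of freedom. Unbalanced layouts raise
    :class:`UnbalancedDesignError` rather than silently switching the
    sums-of-squares type.
    """
    if not design.is_balanced():
        raise UnbalancedDesignError(
            "block_anova requires every (block, treatment) cell exactly once")
    df = _aligned(y, design)
    b, t = len(design.blocks), len(design.treatments)
    if b < 2 or t < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")

    grand = df["y"].mean()
    block_means = df.groupby("block")["y"].mean()
    treat_means = df.groupby("treatment")["y"].mean()

    ss_block = t * float(((block_means - grand) ** 2).sum())
    ss_treat = b * float(((treat_means - grand) ** 2).sum())
    ss_total = float(((df["y"] - grand) ** 2).sum())
    ss_resid = ss_total - ss_block - ss_treat

    df_treat, df_resid = t - 1, (t - 1) * (b - 1)
    ms_treat = ss_treat / df_treat
    ms_resid = max(ss_resid, 0.0) / df_resid

    if ms_resid == 0.0:
        # all variation explained by block + treatment: perfect separation
        F = np.inf if ms_treat > 0 else 0.0
        p = 0.0 if ms_treat > 0 else 1.0
        sep = ms_treat > 0
    else:
        F = ms_treat / ms_resid
        p = float(stats.f.sf(F, df_treat, df_resid))
        sep = False

    return AnovaResult(response, float(F), df_treat, df_resid, p,
                       ss_block, ss_treat, max(ss_resid, 0.0),
                       treat_means.to_dict(), ms_resid, b, sep)


def tukey_hsd(y: pd.Series, design: DesignTable, alpha: float = 0.1,
              response: str = "y") -> tuple[pd.DataFrame, dict[str, str]]:
    """All pairwise treatment comparisons by Tukey's studentized-range test.

    For each treatment pair, q = |mean_i - mean_j| / sqrt(MS_residual / b)
    with b plots (blocks) per treatment; the adjusted p comes from the
    studentized-range distribution with (t, df_residual). Returns the pair
    table and a compact letter display: two treatments share a letter iff
    their difference is not significant at ``alpha``.
    """
    res = block_anova(y, design, response)
    if res.ms_residual == 0.0:
        raise ValueError("tukey_hsd: residual mean square is zero (degenerate)")
    t = len(res.treatment_means)
    se = np.sqrt(res.ms_residual / res.n_blocks)

    names = sorted(res.treatment_means)
    rows = []
    sig_pairs: set[frozenset[str]] = set()
    for i, a in enumerate(names):
        for b_ in names[i + 1:]:
            diff = res.treatment_means[a] - res.treatment_means[b_]
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, t, res.df_residual))
            p_adj = min(p_adj, 1.0)
            rows.append({"treatment_a": a, "treatment_b": b_, "difference": diff,
                         "q": q, "p_adj": p_adj})
            if p_adj < alpha:
                sig_pairs.add(frozenset((a, b_)))
    letters = compact_letter_display(res.treatment_means, sig_pairs)
    return pd.DataFrame(rows), letters


def compact_letter_display(means: dict[str, float],
                           sig_pairs: set[frozenset[str]]) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Treatments ordered by mean descending; each letter marks a maximal set of
    treatments with no significant difference among them. Deterministic for a
    given mean ordering and significance set.
    """
    order = sorted(means, key=lambda k: (-means[k], k))
    groups: list[set[str]] = [set(order)]
    for pair in sorted(sig_pairs, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        for g in list(groups):
            if a in g and b in g:
                groups.remove(g)
                for newg in (g - {a}, g - {b}):
                    # absorb: keep only sets not contained in an existing one
                    if not any(newg <= other for other in groups):
                        groups.append(newg)
    # deterministic letter assignment: groups ordered by their best-ranked member
    groups.sort(key=lambda g: min(order.index(m) for m in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in order}
    for letter, g in zip(alphabet, groups):
        for name in order:
            if name in g:
                out[name] += letter
    return out
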