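"""Min-max standardization and derived raw-function utilities.

Every ecosystem function and richness count is rescaled to [0, 1] over the
whole experiment before any index is formed:

    EF = (rawEF - min(rawEF)) / (max(rawEF) - min(rawEF))

Two raw functions are themselves derived quantities: in-situ soil nitrogen
availability from ion-exchange resin membranes, and the relative abundance of
a fungal guild (ectomycorrhizal fungi) summed over annotated OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grazemulti.tables_io import RawFunctionTable, RichnessTable

#: Slack on [0, 1] bound checks, absorbing float round-off.
BOUND_TOL = 1e-9


class DegenerateColumnError(ValueError):
    """A column is constant over the standardization scope (max == min)."""


@dataclass
class StandardizedTable:
    """plots x variables table of values in [0, 1] with per-column provenance."""

    data: pd.DataFrame  # plot_id + one column per variable
    provenance: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.drop(columns="plot_id")
        if ((vals < -BOUND_TOL) | (vals > 1 + BOUND_TOL)).any().any():
            raise ValueError("StandardizedTable: values outside [0, 1]")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c != "plot_id"]


def minmax_standardize(table: RawFunctionTable | RichnessTable | pd.DataFrame,
                       scope: list[str] | None = None,
                       reflect: list[str] | None = None) -> StandardizedTable:
    """Min-max standardize every column over the given plot scope.

    Parameters
    ----------
    table
        Raw function or richness table (or a bare plot_id + numeric frame).
    scope
        Plot ids over which min and max are taken; default is all plots in
        the table (the experiment-wide scope used for all reported indices).
    reflect
        Columns for which 1 - EF is returned (an "undesirable" function).
        Off by default: all functions are treated as desirable as measured.

    Raises
    ------
    DegenerateColumnError
        If a column is constant over the scope, naming the column. The caller
        may drop such a column explicitly; it is never dropped silently.
    """
    df = table.data if not isinstance(table, pd.DataFrame) else table
    if scope is not None:
        df = df[df["plot_id"].isin(set(scope))]
    reflect = set(reflect or [])

    out = {"plot_id": df["plot_id"].to_numpy()}
    provenance: dict[str, tuple[float, float]] = {}
    for col in df.columns:
        if col == "plot_id":
            continue
        x = df[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(
                f"minmax_standardize: column {col!r} has missing values; "
                "resolve them explicitly (drop the plot or impute) first")
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            raise DegenerateColumnError(
                f"column {col!r} is constant (value {lo}) over the scope")
        ef = (x - lo) / (hi - lo)
        if col in reflect:
            ef = 1.0 - ef
        out[col] = ef
        provenance[col] = (lo, hi)
    return StandardizedTable(pd.DataFrame(out), provenance)


def impute(table: RawFunctionTable | RichnessTable, policy: str):
    """Resolve missing cells by an explicit policy: 'drop_plot' or 'column_mean'."""
    df = table.data
    if policy == "drop_plot":
        out = df.dropna().reset_index(drop=True)
    elif policy == "column_mean":
        out = df.copy()
        for col in out.columns:
            if col != "plot_id":
                out[col] = out[col].fillna(out[col].mean())
    else:
        raise ValueError(f"unknown imputation policy {policy!r}")
    return type(table)(out)


def resin_n_flux(nh4_conc, no3_conc, days,
                 extract_volume: float = 70.0, strip_area: float = 50.0):
    """Soil N availability from an ion-exchange resin membrane pair.

    Concentrations are in ug N per mL of KCl extract; the default 70 mL
    extract volume and 50 cm^2 strip area match the field deployment. Returns
    the combined ammonium + nitrate flux in ug N per cm^2 per day:

        (nh4 + no3) * extract_volume / (strip_area * days)
    """
    nh4 = np.asarray(nh4_conc, dtype=float)
    no3 = np.asarray(no3_conc, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(days <= 0):
        raise ValueError("resin_n_flux: days in the ground must be > 0")
    if np.any(nh4 < 0) or np.any(no3 < 0):
        raise ValueError("resin_n_flux: concentrations must be >= 0")
    result = (nh4 + no3) * extract_volume / (strip_area * days)
    return float(result) if result.ndim == 0 else result


def guild_relative_abundance(otu_rel_abund: pd.DataFrame,
                             guild_map: dict[str, str],
                             guild: str,
                             tol: float = 1e-6) -> pd.Series:
    """Per-plot relative abundance of a fungal guild (e.g. ectomycorrhizal).

    Sums, per plot, the relative abundances of all OTUs annotated with
    ``guild`` in ``guild_map``. OTUs absent from the map contribute zero
    (their count is logged, not an error).
    """
    import logging

    otus = [c for c in otu_rel_abund.columns if c != "plot_id"]
    totals = otu_rel_abund[otus].sum(axis=1)
    if (totals > 1 + tol).any():
        raise ValueError("guild_relative_abundance: per-plot relative abundances "
                         "sum to more than 1")
    unannotated = [o for o in otus if o not in guild_map]
    if unannotated:
        logging.getLogger("grazemulti").info(
            "guild_relative_abundance: %d OTU(s) lack a guild annotation",
            len(unannotated))
    members = [o for o in otus if guild_map.get(o) == guild]
    out = otu_rel_abund[members].sum(axis=1) if members else pd.Series(
        0.0, index=otu_rel_abund.index)
    out.index = otu_rel_abund["plot_id"].to_numpy()
    return out


def sheep_per_cow(sheep_intake_kg: float = 1.5, cattle_intake_kg: float = 6.0) -> float:
    """Sheep-unit equivalence from pretrial daily forage intakes.

    With sheep eating 1.5 kg/d and cattle 6.0 kg/d, one beef cow is
    equivalent to 4 sheep — the stocking-rate currency used to equalize
    grazing intensity across single- and mixed-livestock treatments.
    """
    if sheep_intake_kg <= 0 or cattle_intake_kg <= 0:
        raise ValueError("intakes must be positive")
    return cattle_intake_kg / sheep_intake_kg
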