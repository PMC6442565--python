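"""Tabular data model of the grazing experiment, with validated CSV/TSV I/O.

Three plot-level tables describe an experiment: a design table mapping each
plot to its block and grazing treatment, a raw ecosystem-function table and a
species/OTU richness table. ``plot_id`` is the single join key; block and
treatment live only in the design table.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("grazemulti")

#: Grazing treatments of the reference design: no grazing, sheep, cattle, mixed.
TREATMENTS = ("NG", "SG", "CG", "MG")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """Table contents violate a declared invariant."""


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def _check_unique_plots(df: pd.DataFrame, table: str) -> None:
    dup = df["plot_id"][df["plot_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"{table}: duplicate plot_id values {sorted(set(dup))}")
    if df["plot_id"].isna().any():
        raise ValidationError(f"{table}: missing plot_id values")


@dataclass
class DesignTable:
    """plot -> (block, treatment) mapping for a randomized complete block design."""

    data: pd.DataFrame  # columns: plot_id, block, treatment
    complete_block: bool = True

    def __post_init__(self) -> None:
        _require_columns(self.data, ["plot_id", "block", "treatment"], "DesignTable")
        self.data = self.data.astype({"plot_id": str, "block": str, "treatment": str})
        _check_unique_plots(self.data, "DesignTable")
        if self.complete_block:
            counts = self.data.groupby(["block", "treatment"]).size()
            bad = counts[counts > 1]
            if len(bad):
                raise ValidationError(
                    "DesignTable: complete randomized block design declared but "
                    f"(block, treatment) combinations repeated: {list(bad.index)}")

    @property
    def plot_ids(self) -> list[str]:
        return self.data["plot_id"].tolist()

    @property
    def blocks(self) -> list[str]:
        return sorted(self.data["block"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    def is_balanced(self) -> bool:
        counts = self.data.groupby(["block", "treatment"]).size()
        full = len(self.blocks) * len(self.treatments)
        return len(counts) == full and (counts == 1).all()


def _numeric_frame(df: pd.DataFrame, table: str, integer: bool = False) -> pd.DataFrame:
    """Coerce all non-plot_id columns to numeric; flag (keep) unparseable cells as NaN."""
    out = df.copy()
    out["plot_id"] = out["plot_id"].astype(str)
    for col in out.columns:
        if col == "plot_id":
            continue
        coerced = pd.to_numeric(out[col], errors="coerce")
        newly_missing = coerced.isna() & out[col].notna()
        if newly_missing.any():
            # "NA"/text cells become explicit missing values, never silent drops
            logger.warning("%s: column %r has %d non-numeric cell(s), flagged as missing",
                           table, col, int(newly_missing.sum()))
        if integer and coerced.notna().any():
            vals = coerced.dropna()
            if not ((vals >= 0) & (vals == vals.round())).all():
                raise ValidationError(
                    f"{table}: column {col!r} must hold nonnegative integers")
        out[col] = coerced
    return out


@dataclass
class RawFunctionTable:
    """plots x functions matrix of raw ecosystem-function measurements."""

    data: pd.DataFrame  # plot_id + one numeric column per function
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_columns(self.data, ["plot_id"], "RawFunctionTable")
        if self.data.shape[1] < 2:
            raise SchemaError("RawFunctionTable: needs at least one function column")
        self.data = _numeric_frame(self.data, "RawFunctionTable")
        _check_unique_plots(self.data, "RawFunctionTable")

    @property
    def functions(self) -> list[str]:
        return [c for c in self.data.columns if c != "plot_id"]


@dataclass
class RichnessTable:
    """plots x organism-group richness counts (nonnegative integers)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.data, ["plot_id"], "RichnessTable")
        if self.data.shape[1] < 2:
            raise SchemaError("RichnessTable: needs at least one group column")
        self.data = _numeric_frame(self.data, "RichnessTable", integer=True)
        _check_unique_plots(self.data, "RichnessTable")

    @property
    def groups(self) -> list[str]:
        return [c for c in self.data.columns if c != "plot_id"]


@dataclass
class GroupPartition:
    """Above-/below-ground split of the richness groups."""

    above_groups: list[str]
    below_groups: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.above_groups) & set(self.below_groups)
        if overlap:
            raise ValidationError(f"GroupPartition: groups in both lists: {sorted(overlap)}")

    @property
    def all_groups(self) -> list[str]:
        return list(self.above_groups) + list(self.below_groups)


#: Default partition used by the synthetic generator and pipeline.
DEFAULT_PARTITION = GroupPartition(
    above_groups=["plants", "herbivores", "predators"],
    below_groups=["bacteria", "fungi", "nematodes"],
)


def _read_csv(path, delimiter: str | None = None) -> pd.DataFrame:
    if delimiter is None:
        delimiter = None  # pandas sniffing below
        with open(path) as fh:
            first = fh.readline()
            while first.startswith("#"):
                first = fh.readline()
        delimiter = "\t" if first.count("\t") > first.count(",") else ","
    return pd.read_csv(path, sep=delimiter, comment="#", dtype={"plot_id": str})


def read_tables(design_path, functions_path, richness_path,
                delimiter: str | None = None,
                complete_block: bool = True,
                ) -> tuple[DesignTable, RawFunctionTable, RichnessTable]:
    """Read and validate the three experiment tables, aligning plots.

    Plot alignment uses the intersection of the three plot_id sets; dropped
    plots are logged as a warning, never silently discarded row-by-row.
    """
    design = DesignTable(_read_csv(design_path, delimiter), complete_block=complete_block)
    raw = RawFunctionTable(_read_csv(functions_path, delimiter))
    rich = RichnessTable(_read_csv(richness_path, delimiter))

    common = (set(design.plot_ids) & set(raw.data["plot_id"]) & set(rich.data["plot_id"]))
    for name, tbl in (("design", design.data), ("functions", raw.data),
                      ("richness", rich.data)):
        dropped = sorted(set(tbl["plot_id"]) - common)
        if dropped:
            logger.warning("read_tables: dropping %d plot(s) from %s table not present "
                           "in all three tables: %s", len(dropped), name, dropped)

    def _align(df: pd.DataFrame) -> pd.DataFrame:
        out = df[df["plot_id"].isin(common)].copy()
        return out.sort_values("plot_id", kind="mergesort").reset_index(drop=True)

    design = DesignTable(_align(design.data), complete_block=complete_block)
    raw = RawFunctionTable(_align(raw.data))
    rich = RichnessTable(_align(rich.data))
    return design, raw, rich


def config_hash(obj) -> str:
    """Stable short hash of a config-like object (dicts, lists, scalars)."""
    canon = repr(_canonical(obj)).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def _canonical(obj):
    if isinstance(obj, dict):
        return tuple(sorted((k, _canonical(v)) for k, v in obj.items()))
    if isinstance(obj, (list, tuple)):
        return tuple(_canonical(v) for v in obj)
    return obj


def write_results(result, path, seed: int | None = None,
                  meta: dict | None = None, precision: int = 6) -> None:
    """Write a tabular result to CSV with a run-metadata comment header.

    Column order and row order are deterministic (rows sorted by plot_id when
    present); floats are serialized at ``precision`` significant digits so the
    same result always produces byte-identical files.
    """
    from grazemulti import __version__

    if isinstance(result, (DesignTable, RawFunctionTable, RichnessTable)):
        df = result.data
    elif isinstance(result, pd.DataFrame):
        df = result
    else:  # flat key/value mapping (fit summaries etc.)
        df = pd.DataFrame({"key": list(result.keys()),
                           "value": [result[k] for k in result]})
    df = df.copy()
    if "plot_id" in df.columns:
        df = df.sort_values("plot_id", kind="mergesort").reset_index(drop=True)

    header = io.StringIO()
    header.write(f"# grazemulti version={__version__}\n")
    if seed is not None:
        header.write(f"# seed={seed}\n")
    if meta:
        header.write(f"# config_hash={config_hash(meta)}\n")
    df.to_csv(header, index=False, float_format=f"%.{precision}g")
    with open(path, "w") as fh:
        fh.write(header.getvalue())


def read_results(path) -> pd.DataFrame:
    """Read back a file written by :func:`write_results` (comments skipped)."""
    return pd.read_csv(path, comment="#")
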