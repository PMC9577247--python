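"""Data model, validation and CSV I/O for hierarchical material experiments.

The experimental hierarchy follows a biomass-to-nanopaper design: biomass
variety -> plant section (nested within variety) -> mechanical homogenisation
energy level (crossed) -> nanopaper duplicate -> tensile-test strip.
Observations live in long format (one row per strip per metric); sample-level
summaries are wide matrices of samples x characterisation metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Factor columns of the design, outermost to innermost.
FACTORS: tuple[str, ...] = ("variety", "section", "energy", "nanopaper", "strip")
KEY_COLUMNS: tuple[str, ...] = FACTORS + ("metric",)

#: Separator used to build sample identifiers like "Sugargraze|Leaf|Low".
SAMPLE_SEP = "|"

AGGREGATION_LEVELS = ("strip", "nanopaper", "sample")
_LEVEL_KEYS = {
    "sample": ["variety", "section", "energy"],
    "nanopaper": ["variety", "section", "energy", "nanopaper"],
    "strip": list(FACTORS),
}


class SchemaError(ValueError):
    """An input file lacks a column the schema requires."""


class ValidationError(ValueError):
    """A table or spec violates a structural invariant."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(labels) == 0:
        raise ValidationError(f"{what} must be non-empty")
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{what} contains duplicate labels: {list(labels)}")


@dataclass(frozen=True)
class DesignSpec:
    """Factor structure of a balanced biomass-to-nanopaper experiment.

    Parameters
    ----------
    varieties:
        Biomass variety labels (the "genetic" factor).
    sections_by_variety:
        Plant-section labels per variety (sections are nested within variety).
    energy_levels:
        Ordered homogenisation energy labels (low to high).
    n_duplicates:
        Nanopaper duplicates fabricated per (variety, section, energy) sample.
    n_strips:
        Tensile strips cut per nanopaper duplicate.
    """

    varieties: tuple[str, ...]
    sections_by_variety: Mapping[str, tuple[str, ...]]
    energy_levels: tuple[str, ...]
    n_duplicates: int
    n_strips: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "varieties", tuple(str(v) for v in self.varieties))
        object.__setattr__(
            self,
            "sections_by_variety",
            {str(v): tuple(str(s) for s in secs)
             for v, secs in dict(self.sections_by_variety).items()},
        )
        object.__setattr__(self, "energy_levels",
                           tuple(str(e) for e in self.energy_levels))
        _check_unique(self.varieties, "varieties")
        _check_unique(self.energy_levels, "energy_levels")
        for v in self.varieties:
            if v not in self.sections_by_variety:
                raise ValidationError(f"no sections given for variety {v!r}")
            _check_unique(self.sections_by_variety[v], f"sections of {v!r}")
        if self.n_duplicates < 1 or self.n_strips < 1:
            raise ValidationError("n_duplicates and n_strips must be >= 1")

    @classmethod
    def sorghum(cls) -> "DesignSpec":
        """The default 4 x 3 x 3 x 2 x 8 sorghum-to-nanopaper design."""
        varieties = ("Sugargraze", "Yemen", "GreenleafBMR", "Graingrass")
        sections = ("Leaf", "Sheath", "Stem")
        return cls(
            varieties=varieties,
            sections_by_variety={v: sections for v in varieties},
            energy_levels=("Low", "Medium", "High"),
            n_duplicates=2,
            n_strips=8,
        )

    @property
    def cells(self) -> list[tuple[str, str, str]]:
        """(variety, section, energy) combinations, in design order."""
        return [
            (v, s, e)
            for v in self.varieties
            for s in self.sections_by_variety[v]
            for e in self.energy_levels
        ]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_rows_per_metric(self) -> int:
        return self.n_cells * self.n_duplicates * self.n_strips


class ObservationTable:
    """Long-format measurements keyed by the five design factors plus metric.

    Invariants enforced at construction: mandatory columns present, all values
    numeric (blanks -> NaN are admitted, infinities are not), and no duplicated
    (variety, section, energy, nanopaper, strip, metric) key.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in (*KEY_COLUMNS, "value") if c not in data.columns]
        if missing:
            raise SchemaError("missing mandatory column(s): " + ", ".join(missing))
        df = data.loc[:, [*KEY_COLUMNS, "value"]].copy()
        for c in KEY_COLUMNS:
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"]).astype(float)
        if np.isinf(df["value"].to_numpy()).any():
            raise ValidationError("non-finite value(s) in observation table")
        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            key = df.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
            raise ValidationError("duplicate observation key: " + "/".join(key))
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def metrics(self) -> list[str]:
        return sorted(self.data["metric"].unique())

    def subset(self, metric: str) -> pd.DataFrame:
        """Rows of one metric; errors if the metric is absent."""
        out = self.data[self.data["metric"] == metric]
        if out.empty:
            raise ValidationError(
                f"metric {metric!r} not present; available: {self.metrics}")
        return out

    def equals(self, other: "ObservationTable") -> bool:
        a = self.data.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        return a.equals(b)


def read_observations(path, schema: Mapping[str, str] | None = None) -> ObservationTable:
    """Read a long-format observation CSV.

    ``schema`` maps canonical column names (``variety`` ... ``strip``,
    optionally ``metric``/``value``) to the column names used in the file.
    Files may be metric-long (explicit ``metric``/``value`` columns) or
    metric-wide (any non-factor column is taken as a numeric metric column).
    Blank cells are admitted and become missing values; any other non-numeric
    cell is reported with its file row number.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in FACTORS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s): " + ", ".join(missing))

    def _parse(col: pd.Series, colname: str) -> pd.Series:
        cleaned = col.replace("", np.nan)
        parsed = pd.to_numeric(cleaned, errors="coerce")
        bad = parsed.isna() & cleaned.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path.name}: non-numeric value {col.iloc[i]!r} in column "
                f"{colname!r} at file row {i + 2}")
        return parsed

    if "metric" in raw.columns and "value" in raw.columns:
        long = raw[[*KEY_COLUMNS, "value"]].copy()
        long["value"] = _parse(raw["value"], "value")
    else:
        metric_cols = [c for c in raw.columns if c not in FACTORS]
        if not metric_cols:
            raise SchemaError(f"{path.name}: no metric columns found")
        parsed = {c: _parse(raw[c], c) for c in metric_cols}
        wide = pd.concat([raw[list(FACTORS)], pd.DataFrame(parsed)], axis=1)
        long = wide.melt(id_vars=list(FACTORS), value_vars=metric_cols,
                         var_name="metric", value_name="value")
    return ObservationTable(long)


def write_observations(table: ObservationTable, path) -> None:
    """Write a table in the long CSV format ``read_observations`` accepts."""
    table.data.to_csv(path, index=False)


class MetricMatrix:
    """Samples x characterisation-metrics matrix.

    ``directions`` optionally records, per metric, whether larger values are
    better (+1) or worse (-1); ``zero_spread`` flags metrics found constant
    during standardisation.
    """

    def __init__(self, data: pd.DataFrame,
                 directions: Mapping[str, int] | None = None,
                 zero_spread: tuple[str, ...] = ()):
        if data.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate metric names")
        df = data.astype(float)
        if np.isinf(df.to_numpy()).any():
            raise ValidationError("infinite entries in metric matrix")
        if directions:
            unknown = set(directions) - set(df.columns)
            if unknown:
                raise ValidationError(
                    f"directions reference unknown metrics: {sorted(unknown)}")
            if any(d not in (-1, 1) for d in directions.values()):
                raise ValidationError("directions must be +1 or -1")
        self.data = df
        self.directions = dict(directions) if directions else {}
        self.zero_spread = tuple(zero_spread)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def metric_names(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="sample_id")


def read_metric_matrix(path) -> MetricMatrix:
    df = pd.read_csv(path, index_col=0)
    return MetricMatrix(df)


def aggregate_to_samples(table: ObservationTable,
                         level: str = "sample") -> MetricMatrix:
    """Average observations up to strip, nanopaper or sample level.

    Missing values are dropped per metric (complete-case) before averaging.
    Sample identifiers join the grouping labels with ``"|"``; rows and columns
    come out sorted so the result is order-independent.
    """
    if level not in _LEVEL_KEYS:
        raise ValidationError(
            f"level must be one of {AGGREGATION_LEVELS}, got {level!r}")
    df = table.data.dropna(subset=["value"])
    if df.empty:
        raise ValidationError("cannot aggregate an empty observation table")
    keys = _LEVEL_KEYS[level]
    wide = (df.groupby([*keys, "metric"], sort=True)["value"]
              .mean().unstack("metric"))
    wide.index = [SAMPLE_SEP.join(t) for t in wide.index]
    return MetricMatrix(wide.sort_index().sort_index(axis=1))


@dataclass
class BalanceReport:
    """Observed vs expected replicate counts per design cell and metric."""

    is_balanced: bool
    expected_per_cell: int
    cells: pd.DataFrame  # variety, section, energy, metric, count, expected, status

    def flagged(self) -> pd.DataFrame:
        return self.cells[self.cells["status"] != "ok"]

    def to_json(self) -> str:
        return json.dumps({
            "is_balanced": self.is_balanced,
            "expected_per_cell": self.expected_per_cell,
            "cells": self.cells.to_dict(orient="records"),
        }, indent=2)


def validate_balance(table: ObservationTable, design: DesignSpec) -> BalanceReport:
    """Compare per-cell non-missing counts with n_duplicates * n_strips.

    A reporting operation: never raises on imbalance. Cells absent from the
    data are flagged ``missing``; cells in the data but not in the design are
    flagged ``unexpected``.
    """
    expected = design.n_duplicates * design.n_strips
    df = table.data.dropna(subset=["value"])
    metrics = sorted(df["metric"].unique()) or [""]
    counts = (df.groupby(["variety", "section", "energy", "metric"])
                .size().to_dict() if not df.empty else {})
    design_cells = set(design.cells)
    rows = []
    for (v, s, e) in design.cells:
        for m in metrics:
            c = counts.pop((v, s, e, m), 0)
            status = ("ok" if c == expected
                      else "missing" if c == 0 else "short" if c < expected
                      else "excess")
            rows.append((v, s, e, m, c, expected, status))
    for (v, s, e, m), c in counts.items():  # leftovers: not in the design
        rows.append((v, s, e, m, c, 0, "unexpected"))
    cells = pd.DataFrame(rows, columns=["variety", "section", "energy",
                                        "metric", "count", "expected", "status"])
    return BalanceReport(
        is_balanced=bool((cells["status"] == "ok").all()),
        expected_per_cell=expected,
        cells=cells,
    )
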