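"""Tabular I/O and validation for site-by-species and covariate data.

The interchange formats are deliberately minimal: comma-separated UTF-8 CSV
with a mandatory header row and plot identifiers in a first column named
``plot_id``. The occurrence matrix holds strictly binary incidence (plots as
rows, species as columns); the covariate table holds one row per plot with
numeric and categorical environmental variables, among them a designated soil
organic carbon column (Mg C ha⁻¹ to 30 cm depth). Rows with missing values
are rejected with a report rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "OccurrenceMatrix",
    "CovariateTable",
    "read_occurrence",
    "write_occurrence",
    "read_covariates",
    "write_covariates",
    "read_threatened",
    "write_threatened",
    "encode_covariates",
]

PLOT_ID = "plot_id"


class FormatError(ValueError):
    """Raised when an input table violates the interchange contract."""


def _check_unique(ids: Iterable, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} IDs: {dupes[:5]}")


@dataclass
class OccurrenceMatrix:
    """Plot × species binary incidence with a threatened-species flag.

    Parameters
    ----------
    data
        DataFrame of 0/1 incidence, index = plot IDs, columns = species IDs.
    threatened_mask
        Boolean Series aligned to ``data.columns``; True marks species listed
        as threatened. Defaults to all-False when no list is supplied.
    """

    data: pd.DataFrame
    threatened_mask: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "plot")
        _check_unique(self.data.columns, "species")
        values = self.data.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary cell at plot {self.data.index[i]!r}, "
                f"species {self.data.columns[j]!r}: {values[i, j]!r}"
            )
        self.data = self.data.astype(np.int8)
        if self.threatened_mask is None:
            self.threatened_mask = pd.Series(False, index=self.data.columns)
        else:
            self.threatened_mask = (
                pd.Series(self.threatened_mask).reindex(self.data.columns).fillna(False).astype(bool)
            )

    @property
    def plot_ids(self) -> pd.Index:
        return self.data.index

    @property
    def species_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def threatened_ids(self) -> list:
        return self.data.columns[self.threatened_mask.to_numpy()].tolist()

    @property
    def n_plots(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def set_threatened(self, species: Sequence) -> None:
        missing = set(species) - set(self.data.columns)
        if missing:
            raise FormatError(f"threatened species absent from matrix: {sorted(missing)[:5]}")
        self.threatened_mask = pd.Series(self.data.columns.isin(list(species)), index=self.data.columns)


@dataclass
class CovariateTable:
    """Plot-level environmental covariates with a designated soil-carbon column."""

    data: pd.DataFrame
    soil_carbon_name: str = "soil_carbon"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "plot")
        if self.soil_carbon_name not in self.data.columns:
            raise FormatError(f"designated soil-carbon column {self.soil_carbon_name!r} not found")
        if not pd.api.types.is_numeric_dtype(self.data[self.soil_carbon_name]):
            raise FormatError(f"soil-carbon column {self.soil_carbon_name!r} must be numeric")
        if self.data.isna().any().any():
            bad_rows = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise FormatError(
                f"missing values in covariate table; offending plots: {bad_rows[:10]} "
                f"({len(bad_rows)} total). Rows with missing values are rejected, not imputed."
            )

    @property
    def plot_ids(self) -> pd.Index:
        return self.data.index

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def is_numeric(self) -> bool:
        return all(pd.api.types.is_numeric_dtype(self.data[c]) for c in self.data.columns)


def read_occurrence(path: str | Path, threatened_path: str | Path | None = None) -> OccurrenceMatrix:
    """Read a plot × species incidence CSV, optionally flagging threatened species."""
    df = pd.read_csv(path, index_col=0)
    df.index.name = PLOT_ID
    occ = OccurrenceMatrix(df)
    if threatened_path is not None:
        occ.set_threatened(read_threatened(threatened_path))
    return occ


def write_occurrence(occ: OccurrenceMatrix, path: str | Path) -> None:
    out = occ.data.copy()
    out.index.name = PLOT_ID
    out.to_csv(path)


def read_covariates(path: str | Path, soil_carbon_name: str = "soil_carbon") -> CovariateTable:
    df = pd.read_csv(path, index_col=0)
    df.index.name = PLOT_ID
    return CovariateTable(df, soil_carbon_name=soil_carbon_name)


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = PLOT_ID
    out.to_csv(path)


def read_threatened(path: str | Path) -> list[str]:
    """Read the one-column threatened-species list (header row required)."""
    col = pd.read_csv(path).iloc[:, 0].astype(str).tolist()
    _check_unique(col, "threatened species")
    return col


def write_threatened(species: Sequence, path: str | Path) -> None:
    pd.DataFrame({"species_id": list(species)}).to_csv(path, index=False)


def encode_covariates(table: CovariateTable) -> CovariateTable:
    """Indicator-encode categorical covariates, keeping numerics unchanged.

    Each categorical column is expanded to one 0/1 indicator per level minus a
    reference level (the alphabetically first level), named
    ``<column>=<level>``. Single-level columns carry no information and are
    dropped with a warning. Row count and plot order are preserved.
    """
    pieces: list[pd.DataFrame | pd.Series] = []
    for col in table.data.columns:
        s = table.data[col]
        if pd.api.types.is_numeric_dtype(s):
            pieces.append(s)
            continue
        levels = sorted(s.astype(str).unique())
        if len(levels) < 2:
            logger.warning("dropping single-level categorical covariate %r (level %r)", col, levels)
            continue
        for lev in levels[1:]:  # alphabetically first level is the reference
            pieces.append((s.astype(str) == lev).astype(np.int8).rename(f"{col}={lev}"))
    if not pieces:
        raise FormatError("no covariates remain after encoding")
    out = pd.concat(pieces, axis=1)
    return CovariateTable(out, soil_carbon_name=table.soil_carbon_name)
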