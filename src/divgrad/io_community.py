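"""Reading, validation and writing of community incidence data.

The central object is :class:`IncidenceMatrix`, a binary plots x species
presence/absence table backed by a pandas DataFrame.  Plot metadata (location,
elevation, forest-use habitat, optional climate covariates) and species
attributes (endemism flags) are carried as plain DataFrames with a fixed
column contract, validated on load.

The sampling design these loaders enforce is a nested one: locations along an
elevational gradient, each holding one stand per forest-use habitat
(old-growth OG, degraded DE, secondary SE), each stand sampled with several
fixed-area plots.  All-zero plots (no species recorded) are legal data and are
retained; downstream analyses decide how to treat them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceMatrix",
    "DesignSummary",
    "FormatError",
    "ValidationError",
    "HABITATS",
    "load_incidence",
    "write_incidence",
    "load_metadata",
    "write_metadata",
    "load_species",
    "write_species",
    "validate_dataset",
]

#: Canonical forest-use habitat codes, ordered by increasing use intensity.
HABITATS = ("OG", "DE", "SE")

_HABITAT_ALIASES = {
    "og": "OG",
    "old-growth": "OG",
    "old growth": "OG",
    "oldgrowth": "OG",
    "old-growth forest": "OG",
    "de": "DE",
    "degraded": "DE",
    "degraded forest": "DE",
    "se": "SE",
    "secondary": "SE",
    "secondary forest": "SE",
}

METADATA_COLUMNS = ("plot_id", "location", "elevation", "habitat")
OPTIONAL_METADATA_COLUMNS = ("mat", "map")


class FormatError(ValueError):
    """A file does not parse as the expected delimited layout."""


class ValidationError(ValueError):
    """Parsed data violates a dataset invariant."""


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary plots x species presence/absence matrix.

    Parameters
    ----------
    data:
        DataFrame with plot ids as index, species ids as columns and values
        strictly in {0, 1}.  Row and column order is meaningful and preserved;
        all iteration downstream derives from it.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate plot ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        values = df.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary cell at plot {df.index[i]!r}, "
                f"species {df.columns[j]!r}: {values[i, j]!r}"
            )
        object.__setattr__(self, "data", df.astype(np.int8))

    @property
    def plot_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_plots(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def plot_vector(self, plot_id) -> np.ndarray:
        """Presence vector of a single plot."""
        return self.data.loc[plot_id].to_numpy()

    def subset(self, plot_ids) -> "IncidenceMatrix":
        """Row subset preserving given order."""
        return IncidenceMatrix(self.data.loc[list(plot_ids)])

    def empty_plots(self) -> list:
        """Ids of plots with no recorded species (legal, retained)."""
        sums = self.data.sum(axis=1)
        return list(sums.index[sums == 0])

    def __eq__(self, other) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class DesignSummary:
    """Counts describing the nested sampling design (never mutates inputs)."""

    n_plots: int
    n_species: int
    locations: list
    habitats_per_location: dict
    plots_per_cell: dict = field(repr=False)
    empty_plots: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.plots_per_cell)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"location": loc, "habitat": hab, "n_plots": n}
            for (loc, hab), n in self.plots_per_cell.items()
        ]
        return pd.DataFrame(rows, columns=["location", "habitat", "n_plots"])


def load_incidence(path, orientation: str = "plots_as_rows") -> IncidenceMatrix:
    """Read a delimited site-by-species matrix.

    First column holds identifiers (plots for ``plots_as_rows``, species for
    ``species_as_rows``); remaining cells must parse as 0/1.  The supporting
    data file of the original field survey can be ingested in either
    orientation via the flag.
    """
    if orientation not in ("plots_as_rows", "species_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if orientation == "species_as_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | ~coerced.isin((0, 1))
        if bad.any():
            row = df.index[int(np.argmax(bad.to_numpy()))]
            raise FormatError(
                f"non-binary cell at row {row!r}, column {col!r}: "
                f"{df[col][bad].iloc[0]!r}"
            )
        df[col] = coerced.astype(np.int8)
    return IncidenceMatrix(df)


def write_incidence(matrix: IncidenceMatrix, path) -> None:
    """Write matrix as CSV (plots as rows); round-trips bit-exactly."""
    matrix.data.to_csv(path, index_label="plot_id")


def _normalize_habitat(value) -> str:
    key = str(value).strip().lower()
    if key in _HABITAT_ALIASES:
        return _HABITAT_ALIASES[key]
    raise ValidationError(f"unknown habitat code: {value!r}")


def load_metadata(path) -> pd.DataFrame:
    """Read the plot metadata table.

    Required columns: plot_id, location, elevation, habitat.  Optional: mat
    (mean annual temperature, degC), map (mean annual precipitation, mm/a).
    Habitat strings are normalized to the canonical codes OG/DE/SE.
    """
    df = pd.read_csv(path)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate an in-memory metadata table."""
    df = df.copy()
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    df["plot_id"] = df["plot_id"].astype(str)
    if df["plot_id"].duplicated().any():
        dups = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValidationError(f"duplicate plot ids in metadata: {dups}")
    df["location"] = df["location"].astype(str)
    df["elevation"] = pd.to_numeric(df["elevation"])
    if (df["elevation"] <= 0).any():
        raise ValidationError("elevation must be positive (meters a.s.l.)")
    df["habitat"] = df["habitat"].map(_normalize_habitat)
    for col in OPTIONAL_METADATA_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def load_species(path) -> pd.DataFrame:
    """Read the species attribute table (columns: species_id, endemic)."""
    df = pd.read_csv(path)
    return validate_species(df)


def validate_species(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("species_id", "endemic"):
        if col not in df.columns:
            raise ValidationError(f"species table missing column: {col}")
    df["species_id"] = df["species_id"].astype(str)
    if df["species_id"].duplicated().any():
        raise ValidationError("duplicate species ids in species table")
    df["endemic"] = df["endemic"].astype(bool)
    return df.reset_index(drop=True)


def write_species(species: pd.DataFrame, path) -> None:
    species.to_csv(path, index=False)


def check_plots_covered(matrix: IncidenceMatrix, meta: pd.DataFrame) -> None:
    """Every plot in the matrix must have exactly one metadata record."""
    matrix_ids = set(matrix.plot_ids)
    meta_ids = set(meta["plot_id"])
    orphans = sorted(matrix_ids - meta_ids)
    if orphans:
        raise ValidationError(f"plots missing from metadata: {orphans}")


def validate_dataset(matrix: IncidenceMatrix, meta: pd.DataFrame) -> DesignSummary:
    """Summarize the nested design; warn about (but keep) empty plots."""
    check_plots_covered(matrix, meta)
    meta_idx = meta.set_index("plot_id").loc[matrix.plot_ids]
    cells: dict = {}
    habitats_per_location: dict = {}
    for plot_id, row in meta_idx.iterrows():
        key = (row["location"], row["habitat"])
        cells[key] = cells.get(key, 0) + 1
        habitats_per_location.setdefault(row["location"], set()).add(row["habitat"])
    empty = matrix.empty_plots()
    if empty:
        warnings.warn(
            f"{len(empty)} plot(s) without any recorded species: {empty}",
            stacklevel=2,
        )
    return DesignSummary(
        n_plots=matrix.n_plots,
        n_species=matrix.n_species,
        locations=sorted(habitats_per_location),
        habitats_per_location={
            loc: sorted(habs) for loc, habs in habitats_per_location.items()
        },
        plots_per_cell=cells,
        empty_plots=empty,
    )
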