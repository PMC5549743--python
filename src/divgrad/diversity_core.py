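"""Plot-level and pooled species richness, and per-plot endemic proportion.

alpha-diversity is plot-based species richness (number of species recorded in
one fixed-area plot).  gamma-diversity is the richness of the pooled species
set of a group of plots — per forest-use habitat (one stand, 5 plots) or per
location (all 15 plots of an elevational belt).  The endemic proportion of a
plot is the fraction of its recorded species that carry the endemic flag;
empty plots have no defined proportion (0/0) and yield a missing value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_community import IncidenceMatrix, ValidationError, check_plots_covered

__all__ = ["alpha_richness", "gamma_richness", "endemic_proportion"]


def alpha_richness(matrix: IncidenceMatrix) -> pd.Series:
    """Per-plot species richness (count of presences per row)."""
    return matrix.data.sum(axis=1).astype(int).rename("alpha")


def gamma_richness(matrix: IncidenceMatrix, meta: pd.DataFrame, level: str) -> pd.Series:
    """Pooled richness of the union of presences within each group.

    ``level`` is ``"location"`` (all plots of an elevational belt) or
    ``"habitat"`` (one (location, habitat) cell); for habitat the returned
    series has a (location, habitat) MultiIndex.
    """
    if level not in ("location", "habitat"):
        raise ValueError(f"unknown grouping level: {level!r}")
    check_plots_covered(matrix, meta)
    meta_idx = meta.set_index("plot_id").loc[matrix.plot_ids]
    if level == "location":
        keys = meta_idx["location"]
    else:
        keys = pd.MultiIndex.from_frame(meta_idx[["location", "habitat"]])
    pooled = matrix.data.groupby(keys, sort=True).max()
    return pooled.sum(axis=1).astype(int).rename("gamma" if level == "location" else "pooled_richness")


def endemic_proportion(matrix: IncidenceMatrix, species: pd.DataFrame) -> pd.Series:
    """Fraction of each plot's recorded species flagged endemic.

    The denominator is the plot's own richness, so the value is a within-plot
    fraction in [0, 1].  Plots with zero species return NaN with a warning —
    a 0/0 proportion is undefined and beta-family models cannot take it.
    """
    flags = species.set_index("species_id")["endemic"]
    missing = [s for s in matrix.species_ids if s not in flags.index]
    if missing:
        raise ValidationError(f"species lacking endemic flag: {missing[:5]}")
    endemic_vec = flags.loc[matrix.species_ids].to_numpy().astype(float)
    counts = matrix.values @ endemic_vec
    alpha = matrix.values.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(alpha > 0, counts / np.maximum(alpha, 1.0), np.nan)
    n_empty = int((alpha == 0).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} empty plot(s): endemic proportion undefined, set to NaN",
            stacklevel=2,
        )
    return pd.Series(prop, index=matrix.data.index, name="endemic_proportion")
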