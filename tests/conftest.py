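import numpy as np
import pandas as pd
import pytest

from divgrad.io_community import IncidenceMatrix, validate_metadata, validate_species
from divgrad.synthetic_data import LandscapeConfig, generate_landscape


def make_matrix(array, plots=None, species=None) -> IncidenceMatrix:
    array = np.asarray(array)
    plots = plots or [f"p{i}" for i in range(array.shape[0])]
    species = species or [f"s{j}" for j in range(array.shape[1])]
    return IncidenceMatrix(pd.DataFrame(array, index=plots, columns=species))


def make_meta(plot_ids, locations, habitats, elevations=None, **extra) -> pd.DataFrame:
    n = len(plot_ids)
    df = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "location": locations,
            "elevation": elevations if elevations is not None else [100.0] * n,
            "habitat": habitats,
            **extra,
        }
    )
    return validate_metadata(df)


def one_location_design(n_per_habitat=5, location="L", elevation=100.0):
    """plot ids + metadata for one location with 3 habitats."""
    plot_ids, habitats = [], []
    for hab in ("OG", "DE", "SE"):
        for i in range(n_per_habitat):
            plot_ids.append(f"{location}-{hab}-{i}")
            habitats.append(hab)
    meta = make_meta(plot_ids, [location] * len(plot_ids), habitats,
                     [elevation] * len(plot_ids))
    return plot_ids, meta


@pytest.fixture(scope="session")
def default_landscape():
    """One default synthetic landscape shared across tests (seed fixed)."""
    return generate_landscape(LandscapeConfig(seed=42))


@pytest.fixture()
def species_table():
    def build(species_ids, endemic_flags):
        return validate_species(
            pd.DataFrame({"species_id": species_ids, "endemic": endemic_flags})
        )

    return build
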