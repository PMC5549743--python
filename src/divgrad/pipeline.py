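"""Pipeline orchestration: validate -> richness -> beta -> partition ->
Hill profiles -> GLM selection, from one config, with one seed.

Every stage writes a CSV into the output directory and appends to a plain
run log.  Outputs are a pure function of (input files, config, seed):
per-stage sub-seeds are derived by stable hashing of the stage name so a
stage rerun in isolation reproduces its output.
"""

from __future__ import annotations

import dataclasses
import datetime
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beta_dissimilarity import TRANSITIONS, transition_means, transition_pairs
from .diversity_core import alpha_richness, endemic_proportion, gamma_richness
from .gradient_glm import RESPONSES, fit_candidates, rank_models
from .hill_profiles import DEFAULT_Q_GRID, asymptotic_hill_profile, incidence_frequencies
from .io_community import (
    IncidenceMatrix,
    load_incidence,
    load_metadata,
    load_species,
    validate_dataset,
)
from .partitioning import partition_all
from .synthetic_data import LandscapeConfig, generate_landscape

__all__ = [
    "RunConfig",
    "run_pipeline",
    "alpha_table",
    "endemic_table",
    "beta_table",
    "stage_seed",
]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31), stable across runs."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """One full-pipeline run: file inputs XOR a simulation config."""

    matrix_path: str | None = None
    meta_path: str | None = None
    species_path: str | None = None
    simulate: LandscapeConfig | None = None
    exclude_locations: tuple = ()
    reps: int = 1000
    seed: int = 0
    q_grid: tuple = DEFAULT_Q_GRID
    outdir: str | None = None

    def __post_init__(self) -> None:
        file_mode = self.matrix_path is not None
        if file_mode == (self.simulate is not None):
            raise ValueError("set exactly one of (matrix_path+meta_path, simulate)")
        if file_mode and self.meta_path is None:
            raise ValueError("file mode needs both matrix_path and meta_path")


def alpha_table(matrix: IncidenceMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Plot-level analysis table for the richness GLMs."""
    alpha = alpha_richness(matrix)
    df = meta.set_index("plot_id").loc[matrix.plot_ids].reset_index()
    df["y"] = alpha.to_numpy()
    return df


def endemic_table(
    matrix: IncidenceMatrix, meta: pd.DataFrame, species: pd.DataFrame
) -> pd.DataFrame:
    """Plot-level analysis table for the endemic-proportion GLMs (NaN rows
    for empty plots are dropped at fit time)."""
    prop = endemic_proportion(matrix, species)
    df = meta.set_index("plot_id").loc[matrix.plot_ids].reset_index()
    df["y"] = prop.to_numpy()
    return df


def beta_table(
    matrix: IncidenceMatrix, meta: pd.DataFrame, exclude_locations=()
) -> pd.DataFrame:
    """Pair-level analysis table for the beta-diversity GLMs.

    One row per defined pairwise comparison across all six habitat
    transitions of every non-excluded location; location-level covariates
    (elevation, MAT, MAP) attach to each pair.
    """
    loc_cov = (
        meta.drop_duplicates("location")
        .set_index("location")[
            [c for c in ("elevation", "mat", "map") if c in meta.columns]
        ]
    )
    rows = []
    for t in TRANSITIONS:
        for pc in transition_pairs(matrix, meta, t, exclude_locations):
            if not pc.defined:
                continue
            row = {"y": pc.beta, "transition": pc.transition,
                   "plot_a": pc.plot_a, "plot_b": pc.plot_b}
            row.update(loc_cov.loc[pc.location].to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return the result bundle and write files if
    ``config.outdir`` is set."""
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    note(f"divgrad {__version__} — run at {datetime.datetime.now().isoformat()}")
    note(f"seed={config.seed} reps={config.reps} "
         f"exclude_locations={list(config.exclude_locations)}")

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=stage_seed(config.seed, "simulate"))
        landscape = generate_landscape(sim_cfg)
        matrix, meta, species = landscape.matrix, landscape.meta, landscape.species
        note(f"simulated landscape: {matrix.n_plots} plots, pool {matrix.n_species}")
    else:
        matrix = load_incidence(config.matrix_path)
        meta = load_metadata(config.meta_path)
        species = load_species(config.species_path) if config.species_path else None
        note(f"loaded {config.matrix_path}: {matrix.n_plots} plots x "
             f"{matrix.n_species} species")

    summary = validate_dataset(matrix, meta)
    note(f"design: {len(summary.locations)} locations, {summary.n_cells} cells, "
         f"{len(summary.empty_plots)} empty plot(s)")

    richness = alpha_table(matrix, meta).rename(columns={"y": "alpha"})
    gamma = gamma_richness(matrix, meta, "location")
    note(f"gamma per location: {gamma.to_dict()}")

    transitions = transition_means(
        matrix, meta,
        exclude_locations=config.exclude_locations,
        reps=config.reps,
        seed=stage_seed(config.seed, "beta"),
    )
    partitions = partition_all(matrix, meta)

    profile_frames = []
    for label, freq in incidence_frequencies(matrix, meta, "location").items():
        if freq.U == 0:  # no species recorded in the whole belt
            note(f"hill: skipping {label} (no incidences)")
            continue
        profile_frames.append(
            asymptotic_hill_profile(freq, config.q_grid, group=label).to_frame()
        )
    profiles = pd.concat(profile_frames, ignore_index=True)

    tables = {"alpha": alpha_table(matrix, meta)}
    if species is not None:
        tables["endemic"] = endemic_table(matrix, meta, species)
    tables["beta"] = beta_table(matrix, meta, config.exclude_locations)
    rankings = {}
    for response in RESPONSES:
        if response not in tables:
            continue
        ranking = rank_models(fit_candidates(response, tables[response]))
        rankings[response] = ranking
        sel = ranking.loc[ranking["selected"]].iloc[0]
        note(f"{response}: selected [{sel['terms']}] "
             f"AICc={sel['aicc']:.2f} R2={sel['pseudo_r2']:.3f}")

    bundle = {
        "matrix": matrix,
        "meta": meta,
        "species": species,
        "design": summary,
        "richness": richness,
        "gamma": gamma,
        "transitions": transitions,
        "partitions": partitions,
        "profiles": profiles,
        "rankings": rankings,
        "log": log,
    }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        richness.to_csv(out / "richness.csv", index=False)
        gamma.rename("gamma").to_csv(out / "gamma.csv")
        transitions.to_csv(out / "transitions.csv", index=False)
        partitions.to_csv(out / "partition.csv", index=False)
        profiles.to_csv(out / "hill_profiles.csv", index=False)
        for response, ranking in rankings.items():
            ranking.to_csv(out / f"models_{response}.csv", index=False)
        (out / "run.log").write_text("\n".join(log) + "\n")
    return bundle
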