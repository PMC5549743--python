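"""Pairwise Sørensen beta-diversity and habitat-transition summaries.

beta-diversity between two plots is the Sørensen dissimilarity

    beta = 1 - S,      S = 2C / (A + B)

with A and B the species counts of the two plots and C the count of shared
species.  S = 1 means identical species sets, S = 0 disjoint ones.

Two comparison schemes mirror a nested elevation x forest-use design:

* within-habitat — all unordered plot pairs inside one (location, habitat)
  cell: C(n, 2) comparisons, each plot compared to the other n-1;
* between-habitat — the full plot-by-plot cross product between two habitat
  cells of the same location: n_a * n_b comparisons.

Pooling all pairs of one *habitat transition* (the unordered pair of habitat
codes, six levels for three habitats) across locations gives the mean beta
per transition; standard errors come from a bootstrap that resamples plots
within each contributing cell (respecting the dependence among pairs that
share a plot) and recomputes everything.

A pair of two empty plots has an undefined Sørensen index (A + B = 0) and is
excluded from all summaries; a pair with exactly one empty member has S = 0,
beta = 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_community import HABITATS, IncidenceMatrix, check_plots_covered

__all__ = [
    "PairComparison",
    "sorensen",
    "within_habitat_pairs",
    "between_habitat_pairs",
    "transition_code",
    "transition_pairs",
    "transition_means",
    "bootstrap_se",
    "TRANSITIONS",
]

_HAB_ORDER = {h: i for i, h in enumerate(HABITATS)}

#: Canonical transition codes, within-habitat first, then between-habitat.
TRANSITIONS = ("OG-OG", "DE-DE", "SE-SE", "OG-DE", "OG-SE", "DE-SE")


def transition_code(habitat_a: str, habitat_b: str) -> str:
    """Canonical unordered transition label (OG < DE < SE ordering)."""
    a, b = sorted((habitat_a, habitat_b), key=_HAB_ORDER.__getitem__)
    return f"{a}-{b}"


@dataclass(frozen=True)
class PairComparison:
    """One plot-by-plot Sørensen comparison."""

    plot_a: str
    plot_b: str
    A: int
    B: int
    C: int
    S: float
    beta: float
    transition: str | None = None
    location: str | None = None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.beta)


def sorensen(
    vec_a: np.ndarray,
    vec_b: np.ndarray,
    plot_a: str = "a",
    plot_b: str = "b",
    transition: str | None = None,
    location: str | None = None,
) -> PairComparison:
    """Sørensen comparison of two presence vectors from the same matrix.

    Both plots empty -> S and beta are NaN (undefined, excluded downstream).
    Exactly one empty -> S = 0, beta = 1.
    """
    a = np.asarray(vec_a, dtype=bool)
    b = np.asarray(vec_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors must come from the same matrix")
    A = int(a.sum())
    B = int(b.sum())
    C = int((a & b).sum())
    if A + B == 0:
        S = beta = float("nan")
    else:
        S = 2.0 * C / (A + B)
        beta = 1.0 - S
    return PairComparison(plot_a, plot_b, A, B, C, S, beta, transition, location)


def _cell_plots(meta: pd.DataFrame, location, habitat) -> list:
    sel = meta[(meta["location"] == str(location)) & (meta["habitat"] == habitat)]
    return list(sel["plot_id"])


def _pairwise_beta(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Matrix of beta values between rows of X and rows of Y (NaN: undefined)."""
    X = X.astype(np.float64)
    Y = Y.astype(np.float64)
    A = X.sum(axis=1)[:, None]
    B = Y.sum(axis=1)[None, :]
    C = X @ Y.T
    denom = A + B
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = 1.0 - 2.0 * C / denom
    beta[denom == 0] = np.nan
    return beta


def within_habitat_pairs(
    matrix: IncidenceMatrix, meta: pd.DataFrame, location, habitat
) -> list[PairComparison]:
    """All C(n, 2) unordered pairs inside one (location, habitat) cell."""
    plots = _cell_plots(meta, location, habitat)
    if len(plots) < 2:
        raise ValueError(
            f"within-habitat beta needs >=2 plots in ({location}, {habitat}), "
            f"found {len(plots)}"
        )
    code = transition_code(habitat, habitat)
    out = []
    for pa, pb in itertools.combinations(plots, 2):
        out.append(
            sorensen(
                matrix.plot_vector(pa), matrix.plot_vector(pb),
                pa, pb, code, str(location),
            )
        )
    return out


def between_habitat_pairs(
    matrix: IncidenceMatrix, meta: pd.DataFrame, location, habitat_a, habitat_b
) -> list[PairComparison]:
    """Full plot-by-plot cross product between two habitats of one location."""
    if habitat_a == habitat_b:
        raise ValueError("between-habitat comparison needs two distinct habitats")
    plots_a = _cell_plots(meta, location, habitat_a)
    plots_b = _cell_plots(meta, location, habitat_b)
    if not plots_a or not plots_b:
        raise ValueError(
            f"empty habitat cell at ({location}, {habitat_a}/{habitat_b})"
        )
    code = transition_code(habitat_a, habitat_b)
    out = []
    for pa in plots_a:
        for pb in plots_b:
            out.append(
                sorensen(
                    matrix.plot_vector(pa), matrix.plot_vector(pb),
                    pa, pb, code, str(location),
                )
            )
    return out


def transition_pairs(
    matrix: IncidenceMatrix,
    meta: pd.DataFrame,
    transition: str,
    exclude_locations=(),
) -> list[PairComparison]:
    """All pairs of one transition type pooled over non-excluded locations."""
    ha, hb = transition.split("-")
    excluded = {str(x) for x in exclude_locations}
    out = []
    for loc in meta["location"].drop_duplicates():
        if str(loc) in excluded:
            continue
        if ha == hb:
            out.extend(within_habitat_pairs(matrix, meta, loc, ha))
        else:
            out.extend(between_habitat_pairs(matrix, meta, loc, ha, hb))
    return out


# ---------------------------------------------------------------------------
# bootstrap machinery
#
# A "block" is the pairwise beta matrix of one contributing location:
# within-habitat -> square matrix over one cell's plots (diagonal = the
# self-comparison: 0 for a non-empty plot, NaN for an empty one);
# between-habitat -> rectangular matrix between the two cells' plots.
# Plot resampling draws plot indices with replacement per cell and re-reads
# the betas, so pairs sharing a plot stay dependent within a replicate.
# ---------------------------------------------------------------------------


def _transition_blocks(matrix, meta, transition, exclude_locations=()):
    ha, hb = transition.split("-")
    excluded = {str(x) for x in exclude_locations}
    blocks, locations = [], []
    for loc in meta["location"].drop_duplicates():
        if str(loc) in excluded:
            continue
        Xa = matrix.subset(_cell_plots(meta, loc, ha)).values
        if ha == hb:
            D = _pairwise_beta(Xa, Xa)
            blocks.append(("within", D))
        else:
            Xb = matrix.subset(_cell_plots(meta, loc, hb)).values
            blocks.append(("between", _pairwise_beta(Xa, Xb)))
        locations.append(str(loc))
    return blocks, locations


def _observed_values(blocks) -> np.ndarray:
    vals = []
    for kind, D in blocks:
        if kind == "within":
            iu = np.triu_indices(D.shape[0], k=1)
            vals.append(D[iu])
        else:
            vals.append(D.ravel())
    return np.concatenate(vals) if vals else np.array([])


def bootstrap_se(
    blocks,
    reps: int = 1000,
    seed: int | None = None,
    resample: str = "plots",
) -> float:
    """Bootstrap SE of the pooled mean beta over a set of blocks.

    ``resample="plots"`` (default) draws plots with replacement within each
    contributing cell and recomputes every pairwise beta of the replicate;
    ``resample="values"`` naively resamples the pooled pair values.  The SE is
    the standard deviation of the ``reps`` replicate means.
    """
    if reps < 2:
        raise ValueError("bootstrap needs reps >= 2")
    if resample not in ("plots", "values"):
        raise ValueError(f"unknown resample scheme: {resample!r}")
    rng = np.random.default_rng(seed)
    if resample == "values":
        pool = _observed_values(blocks)
        pool = pool[~np.isnan(pool)]
        if pool.size == 0:
            raise ValueError("no defined pairs to bootstrap")
        means = rng.choice(pool, size=(reps, pool.size), replace=True).mean(axis=1)
        return float(np.std(means, ddof=1))

    means = np.empty(reps)
    for r in range(reps):
        vals = []
        for kind, D in blocks:
            if kind == "within":
                n = D.shape[0]
                idx = rng.integers(0, n, size=n)
                iu, ju = np.triu_indices(n, k=1)
                vals.append(D[idx[iu], idx[ju]])
            else:
                na, nb = D.shape
                ia = rng.integers(0, na, size=na)
                ib = rng.integers(0, nb, size=nb)
                vals.append(D[np.ix_(ia, ib)].ravel())
        pooled = np.concatenate(vals)
        pooled = pooled[~np.isnan(pooled)]
        means[r] = pooled.mean() if pooled.size else np.nan
    means = means[~np.isnan(means)]
    if means.size < 2:
        raise ValueError("bootstrap produced fewer than 2 defined replicates")
    return float(np.std(means, ddof=1))


def transition_means(
    matrix: IncidenceMatrix,
    meta: pd.DataFrame,
    exclude_locations=(),
    reps: int = 1000,
    seed: int | None = None,
    resample: str = "plots",
) -> pd.DataFrame:
    """Mean beta +/- bootstrap SE for each of the six habitat transitions.

    Pools every defined pairwise beta of a transition across all non-excluded
    locations.  Returns one row per transition (canonical order) with columns
    transition, mean_beta, se, n_pairs, locations_used; a transition with no
    defined pairs gets NaN mean and se.
    """
    check_plots_covered(matrix, meta)
    ss = np.random.SeedSequence(seed).spawn(len(TRANSITIONS))
    rows = []
    for t, child in zip(TRANSITIONS, ss):
        blocks, locations = _transition_blocks(matrix, meta, t, exclude_locations)
        vals = _observed_values(blocks)
        defined = vals[~np.isnan(vals)]
        if defined.size == 0:
            rows.append(
                {"transition": t, "mean_beta": np.nan, "se": np.nan,
                 "n_pairs": 0, "locations_used": ",".join(locations)}
            )
            continue
        se = bootstrap_se(blocks, reps=reps, seed=child, resample=resample)
        rows.append(
            {
                "transition": t,
                "mean_beta": float(defined.mean()),
                "se": se,
                "n_pairs": int(defined.size),
                "locations_used": ",".join(locations),
            }
        )
    return pd.DataFrame(rows, columns=["transition", "mean_beta", "se", "n_pairs", "locations_used"])
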