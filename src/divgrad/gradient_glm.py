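"""Candidate GLMs, maximum-likelihood fits, AICc ranking and pseudo-R².

Three response variables, each with an error structure matched to its
nature:

* per-plot species richness (``alpha``) — negative binomial counts;
* per-plot endemic proportion (``endemic``) — beta regression on (0, 1),
  with exact 0/1 squeezed by (y (n - 1) + 0.5) / n before fitting;
* pairwise Sørensen dissimilarity (``beta``) — log-normal, fitted as
  Gaussian ML on log(y) with the log-Jacobian included in the likelihood so
  AICc values are comparable across candidates of the same response.

Explanatory variables are elevation, elevation², a forest-use factor
(habitat for plot-level responses; the six-level habitat *transition* for the
pairwise beta response), mean annual temperature (MAT), MAT², mean annual
precipitation (MAP), MAP², and selected two- and three-way interactions.
Continuous predictors are z-standardized internally before fitting (squares
are squares of the z-scores); this only affects coefficient scale, never
likelihoods of the model family, AICc ranks or pseudo-R².

The candidate set holds exactly 31 models, generated deterministically:
the 30 simplest hierarchical main-effects combinations of the blocks
{elevation, +elevation²} x {factor} x {MAT, +MAT²} x {MAP, +MAP²} —
ordered by term count, then lexicographically; the simplest is the
intercept-only model — plus one richer model per response whose term set
includes the response's reported best structure (interaction hierarchy is
completed by adding any missing main effects).

Ranking uses the small-sample-corrected Akaike criterion

    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)

and a deviance-based pseudo-R² = 1 - D_model / D_null with
D = 2 (loglik_saturated - loglik), the saturated likelihood evaluated at the
model's own dispersion estimate.  Within a delta-AICc < 2 band the model
with fewest parameters is selected (parsimony convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "CandidateModel",
    "FitResult",
    "RESPONSES",
    "build_candidate_set",
    "fit_model",
    "fit_candidates",
    "aicc",
    "rank_models",
    "pseudo_r2",
]

RESPONSES = ("alpha", "endemic", "beta")

_FAMILY = {"alpha": "negative-binomial", "endemic": "beta", "beta": "log-normal"}

# canonical term ordering used for display and deduplication
_TERM_ORDER = [
    "elevation", "elevation2", "habitat", "transition",
    "mat", "mat2", "map", "map2",
]

_PATSY = {
    "elevation": "elevation_z",
    "elevation2": "I(elevation_z**2)",
    "habitat": "C(habitat, Treatment('OG'))",
    "transition": "C(transition)",
    "mat": "mat_z",
    "mat2": "I(mat_z**2)",
    "map": "map_z",
    "map2": "I(map_z**2)",
}

# reported best-model term sets per response (interaction hierarchy is
# completed in _complete_hierarchy when the candidate set is built)
_BEST_SETS = {
    "alpha": (
        "elevation", "elevation2", "habitat", "mat", "map2",
        "elevation:mat", "elevation:elevation2", "elevation2:map",
    ),
    "endemic": (
        "elevation", "elevation2", "habitat", "mat", "map2",
        "elevation:mat", "elevation:elevation2", "elevation:mat2",
        "elevation:elevation2:mat",
    ),
    "beta": (
        "elevation", "elevation2", "transition", "mat", "map",
        "elevation:transition", "elevation:mat",
        "elevation2:transition", "elevation2:mat",
        "transition:mat", "mat:map",
        "elevation:transition:mat", "elevation2:transition:mat",
    ),
}


def _term_sort_key(term: str):
    parts = term.split(":")
    return (len(parts), tuple(_TERM_ORDER.index(p) for p in parts))


@dataclass(frozen=True)
class CandidateModel:
    """One candidate: a response, a term set and its error family."""

    response: str
    terms: tuple
    family: str

    @property
    def label(self) -> str:
        return " + ".join(self.terms) if self.terms else "1"

    def formula(self) -> str:
        rhs = " + ".join(
            ":".join(_PATSY[p] for p in t.split(":")) for t in self.terms
        )
        return f"y ~ {rhs}" if rhs else "y ~ 1"

    def satisfies_hierarchy(self) -> bool:
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            if ":" in t and not set(t.split(":")) <= mains:
                return False
        return True


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate."""

    model: CandidateModel
    loglik: float
    k: int
    n: int
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)
    deviance: float = np.nan
    aicc: float = np.nan
    delta_aicc: float = np.nan
    pseudo_r2: float = np.nan


def _complete_hierarchy(terms) -> tuple:
    """Add main effects required by interactions; canonical order."""
    out = set(terms)
    for t in terms:
        if ":" in t:
            out.update(t.split(":"))
    return tuple(sorted(out, key=_term_sort_key))


def build_candidate_set(response: str) -> list[CandidateModel]:
    """The 31 candidates for one response (see module docstring)."""
    if response not in RESPONSES:
        raise ValueError(f"unknown response: {response!r}")
    factor = "transition" if response == "beta" else "habitat"
    family = _FAMILY[response]

    elev_levels = [(), ("elevation",), ("elevation", "elevation2")]
    fac_levels = [(), (factor,)]
    mat_levels = [(), ("mat",), ("mat", "mat2")]
    map_levels = [(), ("map",), ("map", "map2")]
    combos = [
        tuple(sorted(e + f + m + p, key=_term_sort_key))
        for e, f, m, p in product(elev_levels, fac_levels, mat_levels, map_levels)
    ]
    combos.sort(key=lambda ts: (len(ts), tuple(_term_sort_key(t) for t in ts)))
    models = [CandidateModel(response, ts, family) for ts in combos[:30]]

    best = CandidateModel(response, _complete_hierarchy(_BEST_SETS[response]), family)
    assert best.terms not in {m.terms for m in models}
    models.append(best)
    assert len(models) == 31 and all(m.satisfies_hierarchy() for m in models)
    return models


def _standardize(data: pd.DataFrame) -> pd.DataFrame:
    df = data.copy()
    for col in ("elevation", "mat", "map"):
        if col in df.columns:
            x = df[col].astype(float)
            sd = x.std(ddof=0)
            df[f"{col}_z"] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return df


def _squeeze_unit_interval(y: np.ndarray) -> np.ndarray:
    """(y (n-1) + 0.5) / n — pulls exact 0/1 into the open interval."""
    n = y.size
    return (y * (n - 1) + 0.5) / n


def fit_model(model: CandidateModel, data: pd.DataFrame) -> FitResult:
    """Maximum-likelihood fit; non-convergence is flagged, not raised.

    ``data`` must hold a ``y`` column plus every variable the terms use
    (elevation, habitat or transition, mat, map); rows with missing values
    are dropped (complete-case analysis).
    """
    needed = ["y"] + sorted(
        {c for t in model.terms for c in t.split(":")
         if c in ("elevation", "habitat", "transition", "mat", "map")}
        | {c[:-1] for t in model.terms for c in t.split(":") if c.endswith("2")}
    )
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"analysis table missing columns: {missing}")
    df = data.dropna(subset=needed).reset_index(drop=True)
    df = _standardize(df)
    n = len(df)
    y = df["y"].to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if model.family == "negative-binomial":
                res = smf.negativebinomial(model.formula(), df).fit(
                    disp=0, maxiter=200
                )
                converged = bool(res.mle_retvals.get("converged", True))
                llf, k = float(res.llf), len(res.params)
                mu = np.asarray(res.predict(df))
                alpha = max(float(res.params[-1]), 1e-8)
                dev = 2.0 * (_nb_loglik(y, y, alpha) - _nb_loglik(y, mu, alpha))
            elif model.family == "beta":
                df = df.copy()
                if (y <= 0).any() or (y >= 1).any():
                    df["y"] = _squeeze_unit_interval(y)
                res = BetaModel.from_formula(model.formula(), df).fit(disp=0)
                converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
                llf, k = float(res.llf), len(res.params)
                yv = df["y"].to_numpy(dtype=float)
                mu = np.asarray(res.predict(df))
                phi = float(np.exp(res.params[-1]))
                dev = 2.0 * (_beta_sat_loglik(yv, phi) - _beta_loglik(yv, mu, phi))
            elif model.family == "log-normal":
                df = df.copy()
                if (y <= 0).any():
                    df["y"] = _squeeze_unit_interval(y)
                yv = df["y"].to_numpy(dtype=float)
                df["log_y"] = np.log(yv)
                res = smf.ols(model.formula().replace("y ~", "log_y ~"), df).fit()
                converged = True
                jacobian = float(np.sum(np.log(yv)))
                llf = float(res.llf) - jacobian
                k = len(res.params) + 1  # + sigma
                dev = float(np.sum(res.resid**2))  # prop. to gaussian deviance
                mu = np.asarray(res.predict(df))
            else:  # pragma: no cover
                raise ValueError(f"unknown family: {model.family!r}")
        except (np.linalg.LinAlgError, ValueError, RuntimeError):
            return FitResult(model, np.nan, 0, n, converged=False)
    if not np.isfinite(llf):
        return FitResult(model, np.nan, 0, n, converged=False)
    return FitResult(model, llf, k, n, converged=converged, fitted=mu, deviance=float(dev))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; mu is clipped away from 0 for y's own fit."""
    mu = np.clip(np.asarray(mu, dtype=float), 1e-10, None)
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(st.nbinom.logpmf(np.round(y).astype(int), r, p).sum())


def _beta_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.clip(np.asarray(mu, dtype=float), 1e-10, 1 - 1e-10)
    return float(st.beta.logpdf(y, mu * phi, (1.0 - mu) * phi).sum())


def _beta_sat_loglik(y: np.ndarray, phi: float) -> float:
    """Per-observation maximum of the beta log-density over the mean.

    Unlike the NB and Gaussian cases, mu = y does not maximize the beta
    density at y; the maximizing mean solves
    digamma(mu phi) - digamma((1-mu) phi) = logit(y), which is monotone in
    mu and solved by bisection (cached per distinct y).
    """
    from scipy.optimize import brentq
    from scipy.special import digamma

    lo, hi = 1e-9, 1.0 - 1e-9
    total = 0.0
    cache: dict[float, float] = {}
    for yi in y:
        if yi not in cache:
            target = np.log(yi / (1.0 - yi))
            f = lambda m: digamma(m * phi) - digamma((1.0 - m) * phi) - target
            mu_star = brentq(f, lo, hi) if f(lo) < 0 < f(hi) else (lo if target < 0 else hi)
            cache[yi] = float(st.beta.logpdf(yi, mu_star * phi, (1.0 - mu_star) * phi))
        total += cache[yi]
    return total


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def pseudo_r2(fit: FitResult, null_fit: FitResult) -> float:
    """Deviance-based R² = 1 - D_model / D_null, clamped to [0, 1]."""
    if not (np.isfinite(fit.deviance) and np.isfinite(null_fit.deviance)):
        return np.nan
    if null_fit.deviance <= 0:
        return np.nan
    return float(np.clip(1.0 - fit.deviance / null_fit.deviance, 0.0, 1.0))


def required_columns(model: CandidateModel) -> set:
    """Data columns a candidate needs (squares need their base column)."""
    cols = set()
    for t in model.terms:
        for c in t.split(":"):
            cols.add(c[:-1] if c.endswith("2") else c)
    return cols


def fit_candidates(response: str, data: pd.DataFrame) -> list[FitResult]:
    """Fit the candidates of a response on one analysis table.

    Candidates needing covariates the table does not carry (e.g. MAT/MAP
    when no climate data exist) are skipped with a warning.
    """
    fits = []
    for m in build_candidate_set(response):
        if not required_columns(m) <= set(data.columns):
            warnings.warn(f"skipping candidate lacking covariates: {m.label}")
            continue
        fits.append(fit_model(m, data))
    return fits


def rank_models(fits: list[FitResult]) -> pd.DataFrame:
    """AICc ranking table; flags the selected (parsimonious best) model.

    Non-converged fits and fits with undefined AICc are excluded with a
    warning.  ``delta_aicc`` is relative to the best model; ``selected``
    marks the model with fewest parameters among those within delta < 2 of
    the best (ties broken by lower AICc).
    """
    usable = []
    for f in fits:
        if not f.converged or not np.isfinite(f.loglik):
            warnings.warn(f"excluding non-converged model: {f.model.label}")
            continue
        if f.n <= f.k + 1:
            warnings.warn(f"excluding model with n <= k+1: {f.model.label}")
            continue
        f.aicc = aicc(f.loglik, f.k, f.n)
        usable.append(f)
    if not usable:
        raise ValueError("no converged candidate models")

    null = next((f for f in usable if not f.model.terms), None)
    best_aicc = min(f.aicc for f in usable)
    for f in usable:
        f.delta_aicc = f.aicc - best_aicc
        f.pseudo_r2 = pseudo_r2(f, null) if null is not None else np.nan
    usable.sort(key=lambda f: (f.aicc, f.k))
    in_band = [f for f in usable if f.delta_aicc < 2.0]
    selected = min(in_band, key=lambda f: (f.k, f.aicc))

    worst = usable[-1].aicc
    rows = []
    for i, f in enumerate(usable):
        rows.append(
            {
                "terms": f.model.label,
                "family": f.model.family,
                "k": f.k,
                "n": f.n,
                "loglik": f.loglik,
                "aicc": f.aicc,
                "delta_aicc": f.delta_aicc,
                "delta_next_best": (usable[i + 1].aicc - f.aicc) if i + 1 < len(usable) else np.nan,
                "delta_worst": worst - f.aicc,
                "pseudo_r2": f.pseudo_r2,
                "selected": f is selected,
            }
        )
    return pd.DataFrame(rows)
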