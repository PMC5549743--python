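"""Hill-number diversity profiles for incidence (presence/absence) data.

For a group of T pooled sampling units (plots), species i has incidence
frequency Y_i (number of plots it occurs in), U = sum Y_i, and Q_k counts the
species with incidence exactly k (Q_1 singletons, Q_2 doubletons).

Empirical profile — with relative incidences pi_i = Y_i / U:

    qD = (sum_i pi_i^q)^(1/(1-q))     (q != 1)
    1D = exp(-sum_i pi_i ln pi_i)     (continuous limit at q = 1)

Asymptotic profile — an incidence-data estimator of the asymptote of the
sampling curve at each order q, built from the frequency counts:

    qD_hat = (U/T)^(q/(q-1)) * [ sum_{k=0}^{T-1} C(q-1, k) (-1)^k Delta_k
                                 + tail(q) ]^(1/(1-q))

    Delta_k  = sum_i (Y_i/T) * C(T-Y_i, k) / C(T-1, k)
    tail(q)  = (Q_1/T) (1-A)^(1-T) [ A^(q-1)
                                     - sum_{r=0}^{T-1} C(q-1, r) (A-1)^r ]
    A        = Q_1 / (Q_1 + T * Q0_hat)
    Q0_hat   = ((T-1)/T) * Q_1 (Q_1 - 1) / (2 (Q_2 + 1))

where C(q-1, k) is the generalized binomial coefficient.  Q0_hat is the
bias-corrected Chao2 estimate of the number of undetected species (the
(Q_2 + 1) denominator also guards Q_2 = 0), and A is parameterized so the
estimator is exactly consistent with it.  Closed-form checks: at q = 0 the
expression collapses to S_obs + Q0_hat (bias-corrected Chao2 richness); at
q = 2 the tail vanishes and it collapses to the classical unbiased incidence
Simpson estimator (U/T)^2 / [ sum_i Y_i (Y_i - 1) / (T (T - 1)) ].  The
value at q = 1 is the numerical limit of the same expression, so the profile
is continuous there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_community import IncidenceMatrix, check_plots_covered

__all__ = [
    "IncidenceFrequencies",
    "DiversityProfile",
    "incidence_frequencies",
    "empirical_hill",
    "asymptotic_hill",
    "asymptotic_hill_profile",
    "chao2_richness",
    "DEFAULT_Q_GRID",
]

#: Orders 0, 0.25, ..., 3 (13 values, endpoints inclusive).
DEFAULT_Q_GRID = tuple(np.round(np.arange(0.0, 3.0 + 1e-9, 0.25), 2))


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Incidence frequency counts of one pooled group of plots."""

    T: int
    Y: np.ndarray  # per-species incidence counts, each in 1..T

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=int)
        Y = Y[Y > 0]
        if (Y > self.T).any():
            raise ValueError("incidence count exceeds number of sampling units")
        object.__setattr__(self, "Y", Y)

    @property
    def U(self) -> int:
        return int(self.Y.sum())

    @property
    def s_obs(self) -> int:
        return int(self.Y.size)

    @property
    def Q(self) -> np.ndarray:
        """Q[k] = number of species with incidence exactly k, k = 0..T."""
        return np.bincount(self.Y, minlength=self.T + 1)

    @property
    def Q1(self) -> int:
        return int((self.Y == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.Y == 2).sum())


@dataclass(frozen=True)
class DiversityProfile:
    """Empirical and asymptotic Hill numbers over a grid of orders q."""

    q_grid: np.ndarray
    empirical: np.ndarray
    asymptotic: np.ndarray
    group: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "q": self.q_grid,
                "empirical": self.empirical,
                "asymptotic": self.asymptotic,
            }
        )


def incidence_frequencies(
    matrix: IncidenceMatrix, meta: pd.DataFrame, group: str = "location"
) -> dict[str, IncidenceFrequencies]:
    """Frequency counts per group, plots as incidence sampling units.

    ``group`` is ``"location"`` (T = all plots of a belt, 15 in the default
    design) or ``"habitat"`` ((location, habitat) cells, keyed
    ``"location/habitat"``).
    """
    if group not in ("location", "habitat"):
        raise ValueError(f"unknown grouping: {group!r}")
    check_plots_covered(matrix, meta)
    meta_idx = meta.set_index("plot_id").loc[matrix.plot_ids]
    if group == "location":
        keys = meta_idx["location"]
    else:
        keys = meta_idx["location"] + "/" + meta_idx["habitat"]
    out: dict[str, IncidenceFrequencies] = {}
    for label, sub in matrix.data.groupby(keys, sort=False):
        if sub.shape[0] < 1:
            raise ValueError(f"empty group: {label!r}")
        Y = sub.sum(axis=0).to_numpy()
        out[str(label)] = IncidenceFrequencies(T=sub.shape[0], Y=Y)
    return out


def empirical_hill(freq: IncidenceFrequencies, q: float) -> float:
    """Empirical Hill number of order q from relative incidences Y/U."""
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    if freq.U == 0:
        raise ValueError("no incidences: empirical diversity undefined")
    pi = freq.Y / freq.U
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(pi * np.log(pi))))
    return float(np.sum(pi**q) ** (1.0 / (1.0 - q)))


def _delta_k(freq: IncidenceFrequencies) -> np.ndarray:
    """Delta_k = sum_i (Y_i/T) C(T-Y_i, k) / C(T-1, k), k = 0..T-1."""
    T, Y = freq.T, freq.Y
    ratio = np.ones_like(Y, dtype=float)  # C(T-Yi,k)/C(T-1,k) at k=0
    deltas = np.empty(T)
    w = Y / T
    for k in range(T):
        deltas[k] = float(np.sum(w * ratio))
        # advance ratio k -> k+1: multiply by (T-Yi-k)/(T-1-k)
        if k < T - 1:
            num = T - Y - k
            den = T - 1 - k
            ratio = np.where(num > 0, ratio * num / den, 0.0)
    return deltas


def _log_delta_q(freq: IncidenceFrequencies, q: float) -> float:
    """log of the bracketed series in the asymptotic estimator."""
    T = freq.T
    deltas = _delta_k(freq)
    # signed generalized binomials (-1)^k C(q-1, k), product recurrence
    b = np.empty(T)
    b[0] = 1.0
    for k in range(1, T):
        b[k] = b[k - 1] * (k - q) / k
    total = float(np.sum(b * deltas))

    Q1, Q2 = freq.Q1, freq.Q2
    q0_hat = (T - 1) / T * Q1 * (Q1 - 1) / (2.0 * (Q2 + 1))
    if Q1 > 0 and q0_hat > 0:
        A = Q1 / (Q1 + T * q0_hat)
        r = np.arange(T)
        br = np.empty(T)
        br[0] = 1.0
        for k in range(1, T):
            br[k] = br[k - 1] * (q - k) / k  # C(q-1, r) recurrence
        series = float(np.sum(br * (A - 1.0) ** r))
        tail = (Q1 / T) * (1.0 - A) ** (1 - T) * (A ** (q - 1.0) - series)
        total += tail
    if total <= 0:
        raise ArithmeticError(f"non-positive profile series at q={q}")
    return float(np.log(total))


def asymptotic_hill(freq: IncidenceFrequencies, q: float) -> float:
    """Asymptotic Hill-number estimate of order q (see module docstring)."""
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    if freq.T < 2:
        warnings.warn("T < 2: asymptotic estimator undefined, returning empirical")
        return empirical_hill(freq, q)
    log_ut = np.log(freq.U / freq.T)
    if abs(q - 1.0) < 1e-9:
        eps = 1e-5
        lo = _log_qd(freq, 1.0 - eps, log_ut)
        hi = _log_qd(freq, 1.0 + eps, log_ut)
        return float(np.exp(0.5 * (lo + hi)))
    return float(np.exp(_log_qd(freq, q, log_ut)))


def _log_qd(freq: IncidenceFrequencies, q: float, log_ut: float) -> float:
    # log qD = (1/(1-q)) * (log delta(q) - q log(U/T))
    return (_log_delta_q(freq, q) - q * log_ut) / (1.0 - q)


def asymptotic_hill_profile(
    freq: IncidenceFrequencies,
    q_grid=DEFAULT_Q_GRID,
    group: str | None = None,
) -> DiversityProfile:
    """Empirical and asymptotic profiles over a grid of orders."""
    q_grid = np.asarray(q_grid, dtype=float)
    emp = np.array([empirical_hill(freq, q) for q in q_grid])
    if freq.T < 2:
        warnings.warn("T < 2: asymptotic profile falls back to empirical")
        asy = emp.copy()
    else:
        asy = np.array([asymptotic_hill(freq, q) for q in q_grid])
    return DiversityProfile(q_grid=q_grid, empirical=emp, asymptotic=asy, group=group)


def chao2_richness(freq: IncidenceFrequencies) -> float:
    """Bias-corrected Chao2 asymptotic richness (the q = 0 profile value)."""
    T, Q1, Q2 = freq.T, freq.Q1, freq.Q2
    return freq.s_obs + (T - 1) / T * Q1 * (Q1 - 1) / (2.0 * (Q2 + 1))
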