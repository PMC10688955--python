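"""Exhaustive hybrid Bayesian-network comparison by BIC.

Each candidate model is a nine-node directed acyclic graph: seven root
nodes for the manipulated factors (Bernoulli(1/2) by design, no free
parameters), one Gaussian node for the subjective indicator and one
compound Poisson-gamma (Tweedie) node for the SCR indicator.  Factors may
not point at each other, each indicator may take at most three factor
parents, and at most one edge may link the two indicators (in either
direction), which gives 3 * (sum_{i<=3} C(7, i))^2 = 12,288 candidate
structures per indicator pair.

The joint likelihood decomposes over node families, so each distinct
(child, parent set) family is fitted exactly once and every structure's
BIC is assembled by summation.  Structures are ranked ascending by
BIC = -2 log L + k ln n (lower is better) and differences to the best
model are graded on Raftery's evidence scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, log

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import FACTORS, FACTOR_NAMES
from .simulate import PAIR_COLUMNS
from .tweedie import DEFAULT_P_GRID, fit_glm, log_density

__all__ = [
    "EDGE_STATES",
    "NetworkStructure",
    "count_structures",
    "enumerate_structures",
    "raftery_grade",
    "score_network",
    "score_network_monolithic",
    "BICNetworkSearch",
]

EDGE_STATES = ("none", "sa_to_scr", "scr_to_sa")
_FACTOR_HIGH = {f.name: f.level_high for f in FACTORS}


@dataclass(frozen=True)
class NetworkStructure:
    """One candidate DAG: factor parents per indicator + inter-indicator edge."""

    sa_parents: tuple[str, ...]
    scr_parents: tuple[str, ...]
    inter_edge: str = "none"

    def __post_init__(self):
        if self.inter_edge not in EDGE_STATES:
            raise ValueError(f"unknown inter-indicator edge {self.inter_edge!r}")

    def describe(self) -> str:
        sa = "{" + ", ".join(self.sa_parents) + "}"
        scr = "{" + ", ".join(self.scr_parents) + "}"
        return f"SA<-{sa} SCR<-{scr} edge={self.inter_edge}"


def count_structures(n_factors: int, max_parents: int) -> int:
    """Closed-form size of the candidate space.

    Two independent parent-set choices of at most ``max_parents`` of the
    ``n_factors`` factors, times the three inter-indicator edge states.
    """
    if not 0 <= max_parents <= n_factors:
        raise ValueError("need 0 <= max_parents <= n_factors")
    subsets = sum(comb(n_factors, i) for i in range(max_parents + 1))
    return 3 * subsets * subsets


def _parent_subsets(factors, max_parents):
    out = []
    for size in range(max_parents + 1):
        out.extend(itertools.combinations(factors, size))
    return out


def enumerate_structures(
    factors=FACTOR_NAMES, max_parents: int = 3
) -> list[NetworkStructure]:
    """All candidate structures in deterministic canonical order.

    Parent sets are ordered by size then lexicographically (in the order
    the factors are listed); the inter-indicator edge cycles through
    none < sa_to_scr < scr_to_sa innermost.
    """
    factors = tuple(factors)
    if not 0 <= max_parents <= len(factors):
        raise ValueError("need 0 <= max_parents <= n_factors")
    subsets = _parent_subsets(factors, max_parents)
    return [
        NetworkStructure(sa, scr, edge)
        for sa in subsets
        for scr in subsets
        for edge in EDGE_STATES
    ]


def raftery_grade(delta_bic: float) -> str:
    """Raftery's evidence grade for a nonnegative BIC difference.

    [0, 2] Weak, (2, 6] Positive, (6, 10] Strong, > 10 Very Strong; the
    interval bounds at 2, 6 and 10 belong to the lower grade.
    """
    if delta_bic < 0:
        raise ValueError("BIC difference must be nonnegative")
    if delta_bic <= 2:
        return "Weak"
    if delta_bic <= 6:
        return "Positive"
    if delta_bic <= 10:
        return "Strong"
    return "Very Strong"


# --------------------------------------------------------------------------
# Node-family fits
# --------------------------------------------------------------------------

def _cell_ids(df: pd.DataFrame, parents) -> tuple[np.ndarray, list]:
    """Integer cell index per record over the parents' level combinations."""
    if not parents:
        return np.zeros(len(df), dtype=int), [()]
    codes, uniques = pd.factorize(
        pd.MultiIndex.from_frame(df[list(parents)]), sort=True
    )
    cells = [tuple(u) if isinstance(u, tuple) else (u,) for u in uniques]
    expected = 2 ** len(parents)
    if len(cells) < expected:
        raise ValueError(
            f"missing factor-level cells for parents {parents}: "
            f"found {len(cells)} of {expected}"
        )
    counts = np.bincount(codes)
    if counts.min() != counts.max():
        raise ValueError(
            f"unbalanced cells for parents {parents}: counts {counts.tolist()}"
        )
    return codes, cells


def gaussian_family(
    df: pd.DataFrame, sa_col: str, parents, scr_col: str | None = None
) -> dict:
    """Gaussian node fit: one mean per parent cell, shared variance.

    With a ``scr_col`` the SCR indicator enters as one additive linear
    covariate alongside the cell means.  Returns the exact maximum
    log-likelihood, the free-parameter count k (cells + 1 for the variance,
    + 1 for the covariate slope if present), the fitted values and the
    cell means.
    """
    y = df[sa_col].to_numpy(dtype=float)
    n = y.size
    codes, cells = _cell_ids(df, parents)
    n_cells = len(cells)
    if scr_col is None:
        sums = np.bincount(codes, weights=y, minlength=n_cells)
        counts = np.bincount(codes, minlength=n_cells)
        means = sums / counts
        fitted = means[codes]
        k = n_cells + 1
        coef = means
    else:
        X = np.zeros((n, n_cells + 1))
        X[np.arange(n), codes] = 1.0
        X[:, -1] = df[scr_col].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        means = coef[:-1]
        k = n_cells + 2
    sse = float(np.sum((y - fitted) ** 2))
    sigma2 = max(sse / n, 1e-300)
    loglik = -0.5 * n * (log(2.0 * np.pi * sigma2) + 1.0)
    return {
        "loglik": loglik,
        "k": k,
        "sigma2": sigma2,
        "fitted": fitted,
        "cells": cells,
        "cell_means": dict(zip(cells, means)),
        "codes": codes,
    }


def tweedie_family(
    df: pd.DataFrame,
    scr_col: str,
    parents,
    sa_col: str | None = None,
    p: float | None = None,
    p_grid=DEFAULT_P_GRID,
) -> dict:
    """Tweedie node fit: log-link GLM on dummy-coded factor parents.

    The subjective indicator, when it is a parent, enters as-is.  ``p``
    fixes the power parameter (as in the shared-p search mode); otherwise
    p is profiled over ``p_grid`` with local refinement.  k counts the
    coefficients plus the dispersion and power parameters.
    """
    y = df[scr_col].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    for f in parents:
        cols.append((df[f] == _FACTOR_HIGH[f]).to_numpy(dtype=float))
    if sa_col is not None:
        cols.append(df[sa_col].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if p is not None:
        fit = fit_glm(y, X, p_grid=[p], refine=False)
    else:
        fit = fit_glm(y, X, p_grid=p_grid)
    mu = np.exp(np.clip(X @ fit.coef, -30.0, 30.0))
    return {"loglik": fit.loglik, "k": fit.k, "fit": fit, "mu": mu}


def _drop_collisions(df: pd.DataFrame, collision_col: str) -> pd.DataFrame:
    if collision_col in df:
        return df[~df[collision_col].astype(bool)].reset_index(drop=True)
    return df


def _resolve_columns(indicator_pair, sa_col, scr_col):
    if sa_col is None or scr_col is None:
        if indicator_pair not in PAIR_COLUMNS:
            raise ValueError(f"unknown indicator pair {indicator_pair!r}")
        return PAIR_COLUMNS[indicator_pair]
    return sa_col, scr_col


def score_network(
    structure: NetworkStructure,
    df: pd.DataFrame,
    indicator_pair: str = "dynamics",
    sa_col: str | None = None,
    scr_col: str | None = None,
    p: float | None = None,
    collision_col: str = "is_collision",
    n_factors: int = len(FACTOR_NAMES),
) -> dict:
    """Total BIC of one structure (fresh family fits, no cache).

    The factor roots contribute the structure-independent constant
    n * n_factors * ln 2 to -2 log L with k = 0; it is retained so the
    total is a genuine joint-likelihood BIC, and it cancels in every
    BIC difference.
    """
    df = _drop_collisions(df, collision_col)
    sa_col, scr_col = _resolve_columns(indicator_pair, sa_col, scr_col)
    n = len(df)
    g = gaussian_family(
        df, sa_col, structure.sa_parents,
        scr_col=scr_col if structure.inter_edge == "scr_to_sa" else None,
    )
    t = tweedie_family(
        df, scr_col, structure.scr_parents,
        sa_col=sa_col if structure.inter_edge == "sa_to_scr" else None,
        p=p,
    )
    ll = n * n_factors * log(0.5) + g["loglik"] + t["loglik"]
    k = g["k"] + t["k"]
    return {
        "loglik": ll,
        "k": k,
        "bic": -2.0 * ll + k * log(n),
        "gaussian": g,
        "tweedie": t,
        "n": n,
    }


def score_network_monolithic(
    structure: NetworkStructure,
    df: pd.DataFrame,
    indicator_pair: str = "dynamics",
    sa_col: str | None = None,
    scr_col: str | None = None,
    p: float | None = None,
    collision_col: str = "is_collision",
    n_factors: int = len(FACTOR_NAMES),
) -> float:
    """Joint-likelihood BIC evaluated record by record (decomposition oracle).

    Fits the node families, then sums the per-record joint log density
    (factor pmfs x Gaussian pdf x Tweedie density) over the whole table
    rather than adding family log-likelihood totals.
    """
    parts = score_network(
        structure, df,
        indicator_pair=indicator_pair, sa_col=sa_col, scr_col=scr_col,
        p=p, collision_col=collision_col, n_factors=n_factors,
    )
    df = _drop_collisions(df, collision_col)
    sa_col, scr_col = _resolve_columns(indicator_pair, sa_col, scr_col)
    n = len(df)
    g, t = parts["gaussian"], parts["tweedie"]
    y_sa = df[sa_col].to_numpy(dtype=float)
    resid = y_sa - g["fitted"]
    log_gauss = -0.5 * (
        log(2.0 * np.pi * g["sigma2"]) + resid ** 2 / g["sigma2"]
    )
    y_scr = df[scr_col].to_numpy(dtype=float)
    fit = t["fit"]
    log_tw = log_density(y_scr, t["mu"], fit.phi, fit.p)
    joint = float(np.sum(n_factors * log(0.5) + log_gauss + log_tw))
    return -2.0 * joint + parts["k"] * log(n)


# --------------------------------------------------------------------------
# Exhaustive search
# --------------------------------------------------------------------------

class BICNetworkSearch(BaseEstimator):
    """Exhaustive BIC ranking of the candidate hybrid networks.

    Parameters
    ----------
    indicator_pair : {"dynamics", "maxima"}
        Selects the indicator columns (iSA/nSCR or mSA/mSCR) unless
        ``sa_col``/``scr_col`` are given explicitly.
    max_parents : int, default 3
        Cap on factor parents per indicator node.
    p_mode : {"shared", "per-family"}
        "shared" profiles the Tweedie power once (on the family with the
        subjective covariate as sole predictor) and holds it fixed across
        the SCR families; "per-family" profiles p inside every family fit.
    p_grid : sequence of float
        Profile grid for the power parameter.

    Attributes
    ----------
    results_ : DataFrame ranked ascending by BIC with columns
        sa_parents, scr_parents, inter_edge, loglik, k, bic, delta_bic,
        grade.
    best_structure_ : NetworkStructure
    p_ : Tweedie power used (shared mode) or None
    n_structures_ : int
    sa_cell_means_ : cell means of the best structure's Gaussian node
    """

    def __init__(
        self,
        indicator_pair: str = "dynamics",
        sa_col: str | None = None,
        scr_col: str | None = None,
        factors=FACTOR_NAMES,
        max_parents: int = 3,
        p_mode: str = "shared",
        p_grid=DEFAULT_P_GRID,
        collision_col: str = "is_collision",
    ):
        self.indicator_pair = indicator_pair
        self.sa_col = sa_col
        self.scr_col = scr_col
        self.factors = factors
        self.max_parents = max_parents
        self.p_mode = p_mode
        self.p_grid = p_grid
        self.collision_col = collision_col

    def fit(self, X: pd.DataFrame, y=None):
        if self.p_mode not in ("shared", "per-family"):
            raise ValueError("p_mode must be 'shared' or 'per-family'")
        df = _drop_collisions(X, self.collision_col)
        sa_col, scr_col = _resolve_columns(
            self.indicator_pair, self.sa_col, self.scr_col
        )
        factors = tuple(self.factors)
        n = len(df)
        subsets = _parent_subsets(factors, self.max_parents)

        if self.p_mode == "shared":
            probe = tweedie_family(
                df, scr_col, (), sa_col=sa_col, p_grid=self.p_grid
            )
            self.p_ = float(probe["fit"].p)
            shared_p = self.p_
        else:
            self.p_ = None
            shared_p = None

        sa_scores: dict[tuple, tuple[float, int]] = {}
        scr_scores: dict[tuple, tuple[float, int]] = {}
        self._sa_fits = {}
        for parents in subsets:
            for with_scr in (False, True):
                g = gaussian_family(
                    df, sa_col, parents,
                    scr_col=scr_col if with_scr else None,
                )
                sa_scores[(parents, with_scr)] = (g["loglik"], g["k"])
                self._sa_fits[(parents, with_scr)] = g
        for parents in subsets:
            for with_sa in (False, True):
                t = tweedie_family(
                    df, scr_col, parents,
                    sa_col=sa_col if with_sa else None,
                    p=shared_p, p_grid=self.p_grid,
                )
                scr_scores[(parents, with_sa)] = (t["loglik"], t["k"])

        ll_factors = n * len(factors) * log(0.5)
        log_n = log(n)
        structures = enumerate_structures(factors, self.max_parents)
        records = []
        for idx, s in enumerate(structures):
            ll_sa, k_sa = sa_scores[(s.sa_parents, s.inter_edge == "scr_to_sa")]
            ll_t, k_t = scr_scores[(s.scr_parents, s.inter_edge == "sa_to_scr")]
            ll = ll_factors + ll_sa + ll_t
            k = k_sa + k_t
            records.append((idx, s.sa_parents, s.scr_parents, s.inter_edge,
                            ll, k, -2.0 * ll + k * log_n))
        res = pd.DataFrame(
            records,
            columns=["order", "sa_parents", "scr_parents", "inter_edge",
                     "loglik", "k", "bic"],
        )
        res = res.sort_values(
            ["bic", "order"], kind="stable", ignore_index=True
        )
        res["delta_bic"] = res["bic"] - res["bic"].iloc[0]
        res["grade"] = [raftery_grade(d) for d in res["delta_bic"]]
        self.results_ = res.drop(columns="order")
        best = res.iloc[0]
        self.best_structure_ = NetworkStructure(
            tuple(best.sa_parents), tuple(best.scr_parents), best.inter_edge
        )
        self.n_structures_ = len(res)
        self.n_ = n
        self.sa_col_, self.scr_col_ = sa_col, scr_col
        self.sa_cell_means_ = self._sa_fits[
            (self.best_structure_.sa_parents,
             self.best_structure_.inter_edge == "scr_to_sa")
        ]["cell_means"]
        return self

    def top(self, m: int = 20) -> pd.DataFrame:
        """The ``m`` best structures as a readable summary table."""
        res = self.results_.head(m).copy()
        res["sa_parents"] = res["sa_parents"].map(lambda t: "+".join(t) or "-")
        res["scr_parents"] = res["scr_parents"].map(lambda t: "+".join(t) or "-")
        return res
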