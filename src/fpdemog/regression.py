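"""Distinctiveness regressions and the functional-phylogenetic sweep.

The response is the per-species competition effect size (log response
ratio of growth rates); the predictors are a distinctiveness metric and
z-scored competitor biomass.  Functional and phylogenetic distances are
blended as

    FPD = sqrt(a * PD^2 + (1 - a) * FD^2),    a in [0, 1],

with both matrices first divided by their own maximum off-diagonal
entry so they share a common scale; ``a`` is swept on a grid (0.025
steps by default, 41 points) and the adjusted R^2 of the regression is
recorded at each value.  Demographic uncertainty is propagated by
re-fitting the regression once per bootstrap effect-size draw and
reporting percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distance import DistanceMatrix
from .distinct import focal_distinctiveness

__all__ = [
    "combine_fpd",
    "DistinctivenessRegression",
    "RegressionResult",
    "sweep_a",
    "bootstrap_regression",
    "a_grid",
]


# ---------------------------------------------------------------------------
# combined functional-phylogenetic distance
# ---------------------------------------------------------------------------

def combine_fpd(
    PD: DistanceMatrix,
    FD: DistanceMatrix,
    a: float,
    standardization: str = "max_scale",
) -> DistanceMatrix:
    """Blend phylogenetic and functional distances with weight ``a``.

    With ``max_scale`` (default) each matrix is first divided by its
    own maximum off-diagonal entry; ``none`` combines the raw values.
    ``a = 1`` returns the (standardized) phylogenetic matrix exactly
    and ``a = 0`` the functional one.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must lie in [0, 1]")
    if set(PD.labels) != set(FD.labels):
        raise ValueError("matrices must share the same label set")
    FD = FD.submatrix(list(PD.labels))
    if standardization == "max_scale":
        pmax, fmax = PD.max_offdiag(), FD.max_offdiag()
        if pmax == 0 or fmax == 0:
            raise ValueError("all-zero matrix cannot be max-scaled")
        p = PD.values / pmax
        f = FD.values / fmax
    elif standardization == "none":
        p, f = PD.values, FD.values
    else:
        raise ValueError(f"unknown standardization {standardization!r}")
    vals = np.sqrt(a * p**2 + (1.0 - a) * f**2)
    return DistanceMatrix(PD.labels, vals, "raw")


def a_grid(a_step: float = 0.025) -> np.ndarray:
    """The sweep grid from 0 to 1 inclusive."""
    n = round(1.0 / a_step)
    if abs(n * a_step - 1.0) > 1e-12:
        raise ValueError("a_step must divide 1 exactly")
    return np.linspace(0.0, 1.0, n + 1)


# ---------------------------------------------------------------------------
# OLS model / results
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """OLS fit of effect size on distinctiveness and z-scored biomass."""

    params: pd.Series
    adj_r2: float
    r2: float
    n: int
    resid: np.ndarray = field(repr=False)
    bootstrap_draws: pd.DataFrame | None = field(default=None, repr=False)
    ci: pd.DataFrame | None = None

    @property
    def distinctiveness_slope(self) -> float:
        return float(self.params["distinctiveness"])

    def summary(self) -> str:
        lines = [
            "Distinctiveness regression (OLS)",
            f"  n = {self.n}, R^2 = {self.r2:.5f}, adj R^2 = {self.adj_r2:.5f}",
            "  coefficients:",
        ]
        for name, val in self.params.items():
            line = f"    {name:<16s} {val: .5f}"
            if self.ci is not None and name in self.ci.index:
                lo, hi = self.ci.loc[name, "lower"], self.ci.loc[name, "upper"]
                line += f"   95% CI [{lo: .5f}, {hi: .5f}]"
            lines.append(line)
        if self.ci is not None and "adj_r2" in self.ci.index:
            lo, hi = self.ci.loc["adj_r2", "lower"], self.ci.loc["adj_r2", "upper"]
            lines.append(f"  adj R^2 95% CI [{lo:.5f}, {hi:.5f}]")
        return "\n".join(lines)


class DistinctivenessRegression:
    """Linear model of competition effect size on distinctiveness and
    standardized competitor biomass.

    Parameters are per-species vectors aligned by position (or a
    DataFrame via :meth:`from_dataframe`).  Biomass is z-scored across
    the focal-species set before entering the design.
    """

    def __init__(self, effect_sizes, distinctiveness, biomass):
        y = np.asarray(effect_sizes, dtype=float)
        d = np.asarray(distinctiveness, dtype=float)
        bm = np.asarray(biomass, dtype=float)
        if not (len(y) == len(d) == len(bm)):
            raise ValueError("inputs must have equal length")
        n = len(y)
        if n < 4:
            raise ValueError("need n >= 4 species (adjusted R^2 undefined below)")
        if np.ptp(d) == 0 or np.ptp(bm) == 0:
            raise ValueError("predictors must be non-constant")
        self.endog = y
        self.distinctiveness = d
        self.biomass_z = (bm - bm.mean()) / bm.std(ddof=1)
        self.exog = sm.add_constant(
            np.column_stack([d, self.biomass_z]), has_constant="raise"
        )
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("rank-deficient design")
        self.names = ["intercept", "distinctiveness", "biomass"]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, effect_col: str = "effect_size",
                       distinct_col: str = "distinctiveness",
                       biomass_col: str = "biomass") -> "DistinctivenessRegression":
        return cls(df[effect_col], df[distinct_col], df[biomass_col])

    def fit(self) -> RegressionResult:
        res = sm.OLS(self.endog, self.exog).fit()
        return RegressionResult(
            params=pd.Series(res.params, index=self.names),
            adj_r2=float(res.rsquared_adj),
            r2=float(res.rsquared),
            n=len(self.endog),
            resid=np.asarray(res.resid),
        )

    def fit_bootstrap(self, effect_size_draws: np.ndarray,
                      n_boot: int = 1000, seed: int = 0) -> RegressionResult:
        """Delegates to :func:`bootstrap_regression` on this design."""
        return bootstrap_regression(effect_size_draws, self.distinctiveness,
                                    self.biomass_z, n_boot=n_boot, seed=seed,
                                    _biomass_is_standardized=True)


# ---------------------------------------------------------------------------
# the a-sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    table: pd.DataFrame  # columns: a, intercept, distinctiveness, biomass, adj_r2
    best_a: float
    best_adj_r2: float
    fits: dict[float, RegressionResult] = field(repr=False, default_factory=dict)


def sweep_a(
    PD: DistanceMatrix,
    FD: DistanceMatrix,
    communities: dict[str, list[str]],
    effect_sizes: dict[str, float],
    biomass: dict[str, float],
    metric: str = "NND",
    a_step: float = 0.025,
    weights: dict[str, np.ndarray] | None = None,
    standardization: str = "max_scale",
) -> SweepResult:
    """Re-fit the distinctiveness regression along the ``a`` grid.

    For each grid value the per-focal-species community matrices are
    re-combined (standardized per community), the distinctiveness
    metric recomputed, and the observed-effect-size regression re-fit;
    the argmax ``a`` is reported at grid resolution.
    """
    grid = a_grid(a_step)
    focals = list(communities)
    y = np.array([effect_sizes[s] for s in focals])
    bm = np.array([biomass[s] for s in focals])
    # pre-slice per-community matrices once
    subs = {}
    for sp in focals:
        members = list(communities[sp])
        labels = [sp] + members
        subs[sp] = (PD.submatrix(labels), FD.submatrix(labels), members)
    rows = []
    fits: dict[float, RegressionResult] = {}
    for a in grid:
        dvals = np.empty(len(focals))
        for k, sp in enumerate(focals):
            pd_sub, fd_sub, members = subs[sp]
            comb = combine_fpd(pd_sub, fd_sub, float(a), standardization)
            w = None if weights is None else weights.get(sp)
            dvals[k] = focal_distinctiveness(comb, sp, members, weights=w,
                                             metric=metric)
        fit = DistinctivenessRegression(y, dvals, bm).fit()
        fits[float(a)] = fit
        rows.append({
            "a": float(a),
            "intercept": fit.params["intercept"],
            "distinctiveness": fit.params["distinctiveness"],
            "biomass": fit.params["biomass"],
            "adj_r2": fit.adj_r2,
        })
    table = pd.DataFrame(rows)
    best = table.loc[table["adj_r2"].idxmax()]
    return SweepResult(table, float(best["a"]), float(best["adj_r2"]), fits)


# ---------------------------------------------------------------------------
# bootstrap propagation
# ---------------------------------------------------------------------------

def bootstrap_regression(
    effect_size_draws,
    distinctiveness,
    biomass,
    n_boot: int = 1000,
    seed: int = 0,
    _biomass_is_standardized: bool = False,
) -> RegressionResult:
    """Propagate demographic uncertainty through the regression.

    ``effect_size_draws`` is (n_species, >= n_boot): replicate ``b``
    regresses draw column ``b`` on the fixed predictors.  95% CIs are
    the 2.5/97.5 percentiles of each coefficient and of adjusted R^2
    across replicates; the reported point estimates come from the mean
    effect-size vector.
    """
    E = np.asarray(effect_size_draws, dtype=float)
    d = np.asarray(distinctiveness, dtype=float)
    bm = np.asarray(biomass, dtype=float)
    n, total = E.shape
    if not (len(d) == len(bm) == n):
        raise ValueError("draws must align with predictor vectors")
    if total < n_boot:
        raise ValueError(f"every species needs >= {n_boot} draws, got {total}")
    cols = (np.arange(n_boot) if total == n_boot
            else np.random.default_rng(seed).choice(total, n_boot, replace=False))
    bz = bm if _biomass_is_standardized else (bm - bm.mean()) / bm.std(ddof=1)
    X = np.column_stack([np.ones(n), d, bz])
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    Y = E[:, cols]
    coefs = pinv @ Y  # (3, n_boot)
    fittedY = X @ coefs
    ssr = ((Y - fittedY) ** 2).sum(axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - ssr / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    names = ["intercept", "distinctiveness", "biomass"]
    draws = pd.DataFrame(coefs.T, columns=names)
    draws["adj_r2"] = adj
    lo = draws.quantile(0.025)
    hi = draws.quantile(0.975)
    ci = pd.DataFrame({"lower": lo, "upper": hi})
    point = DistinctivenessRegression(E[:, cols].mean(axis=1), d, bz).fit() \
        if np.ptp(d) != 0 else None
    return RegressionResult(
        params=point.params if point is not None else draws[names].mean(),
        adj_r2=point.adj_r2 if point is not None else float(adj.mean()),
        r2=point.r2 if point is not None else float(r2.mean()),
        n=n,
        resid=point.resid if point is not None else np.array([]),
        bootstrap_draws=draws,
        ci=ci,
    )
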