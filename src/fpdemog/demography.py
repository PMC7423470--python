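"""Structured population models and the demographic effect of competitor
removal.

Census records (one row per individual and transition year) are turned
into either a matrix population model (MPM; discrete stages, transition
frequencies plus per-capita fecundities) or an integral projection
model (IPM; size-structured vital-rate regressions discretized by the
midpoint rule).  The population growth rate lambda is the dominant
eigenvalue of the resulting projection matrix.  The effect of
competitor removal on a species is the log response ratio

    effect = ln((lambda_removal + 0.5) / (lambda_control + 0.5)),

with the +0.5 guarding against growth rates near zero in the control
treatment.  Uncertainty is propagated by resampling individuals with
replacement within species x treatment strata and re-fitting the whole
model for each replicate.

Census table schema (columns; unused ones may be absent or NaN):

=============  =====================================================
individual_id  opaque id (the bootstrap resampling unit)
species        species name
treatment      "control" or "removal"
plot_id        opaque plot id
stage_t        stage label at t (MPM)
stage_t1       stage label at t+1 or "DEAD" (MPM)
size_t         size at t, log scale (IPM); NaN for new recruits
size_t1        size at t+1 (IPM); NaN if dead
surv           1 survived / 0 died (IPM)
repro_count    offspring (MPM: recruits; IPM: seeds) produced
year           census year
=============  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._rng import substream

__all__ = [
    "DEAD",
    "TREATMENTS",
    "SeedBankParams",
    "ProjectionMatrix",
    "VitalRateCoefficients",
    "EffectSize",
    "SpeciesModelSpec",
    "build_mpm",
    "fit_vital_rates",
    "build_ipm_kernel",
    "dominant_lambda",
    "effect_size_of_competition",
    "bootstrap_effect_sizes",
    "treatment_lambdas",
    "MatrixPopulationModel",
    "IntegralProjectionModel",
    "ProjectionModelResults",
]

DEAD = "DEAD"
TREATMENTS = ("control", "removal")


@dataclass(frozen=True)
class SeedBankParams:
    """Discrete seed-bank stage: offspring enter the bank with
    ``entry_prob``, persist with ``stasis_prob`` and germinate into the
    recruit stage with ``germination_prob``.  Treated as fixed
    (literature-derived) constants during bootstrapping."""

    entry_prob: float
    stasis_prob: float
    germination_prob: float

    def __post_init__(self) -> None:
        for name in ("entry_prob", "stasis_prob", "germination_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ProjectionMatrix:
    """A nonnegative square projection matrix with stage labels (MPM) or
    mesh midpoints plus bin width (discretized IPM)."""

    entries: np.ndarray = field(repr=False)
    labels: tuple = ()
    model_kind: str = "MPM"
    mesh: np.ndarray | None = field(default=None, repr=False)
    bin_width: float | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.entries, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("projection matrix must be square")
        if not np.all(np.isfinite(A)):
            raise ValueError("projection matrix has non-finite entries")
        if np.any(A < 0):
            raise ValueError("projection matrix has negative entries")
        object.__setattr__(self, "entries", A)

    @property
    def dim(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class VitalRateCoefficients:
    """Size-structured vital rates on the log-size scale.

    Survival is logistic in size, growth is Gaussian about a linear
    mean, per-capita seed production is log-linear in size and is
    thinned by an establishment probability; recruits enter at a
    Gaussian size.  ``fec_intercept = -inf`` encodes no reproduction.
    """

    surv_intercept: float
    surv_slope: float
    growth_intercept: float
    growth_slope: float
    growth_sd: float
    fec_intercept: float
    fec_slope: float
    establishment: float
    recruit_mean: float
    recruit_sd: float
    seed_bank: SeedBankParams | None = None

    def __post_init__(self) -> None:
        if self.growth_sd <= 0:
            raise ValueError("growth residual sd must be > 0")
        if not 0.0 <= self.establishment <= 1.0:
            raise ValueError("establishment probability must lie in [0, 1]")
        if self.recruit_sd <= 0 and np.isfinite(self.fec_intercept):
            raise ValueError("recruit size sd must be > 0")


@dataclass(frozen=True)
class EffectSize:
    species: str
    value: float
    lambda_control: float
    lambda_removal: float


# ---------------------------------------------------------------------------
# MPM construction
# ---------------------------------------------------------------------------

def build_mpm(
    records: pd.DataFrame,
    stages: list[str],
    fecundity_map: dict[str, str],
    seed_bank: SeedBankParams | None = None,
) -> ProjectionMatrix:
    """Transition-frequency MPM from individual stage fates.

    Entry ``[j, i]`` is the share of stage-``i`` individuals observed in
    stage ``j`` a year later; per-capita recruit production of each
    reproducing stage (``fecundity_map``: stage -> recruit stage) is
    added to the recruit-stage row.  With a seed bank, offspring are
    split between direct recruitment and the bank, and a bank
    row/column is appended.
    """
    stages = list(stages)
    idx = {s: k for k, s in enumerate(stages)}
    unknown = set(fecundity_map) - set(stages) | set(fecundity_map.values()) - set(stages)
    if unknown:
        raise ValueError(f"fecundity_map references unknown stages: {sorted(unknown)}")
    S = len(stages)
    stage_t = records["stage_t"].to_numpy()
    stage_t1 = records["stage_t1"].to_numpy()
    counts = np.array([(stage_t == s).sum() for s in stages], dtype=float)
    empty = [s for s, c in zip(stages, counts) if c == 0]
    if empty:
        raise ValueError(
            f"no individuals observed at t in stage(s) {empty}; "
            "merge stages or supply more data"
        )
    T = np.zeros((S, S))
    for i, si in enumerate(stages):
        mask = stage_t == si
        for j, sj in enumerate(stages):
            T[j, i] = (stage_t1[mask] == sj).sum() / counts[i]
    F = np.zeros((S, S))
    repro = records["repro_count"].to_numpy(dtype=float)
    if np.any(repro < 0):
        raise ValueError("repro_count must be nonnegative")
    direct = 1.0 if seed_bank is None else 1.0 - seed_bank.entry_prob
    percap = {}
    for s_from, s_to in fecundity_map.items():
        m = repro[stage_t == s_from].mean()
        percap[s_from] = m
        F[idx[s_to], idx[s_from]] += direct * m
    A = T + F
    labels: tuple = tuple(stages)
    if seed_bank is not None:
        B = np.zeros((S + 1, S + 1))
        B[:S, :S] = A
        for s_from, s_to in fecundity_map.items():
            B[S, idx[s_from]] = seed_bank.entry_prob * percap[s_from]
            B[idx[s_to], S] = seed_bank.germination_prob
        B[S, S] = seed_bank.stasis_prob
        A = B
        labels = tuple(stages) + ("seedbank",)
    return ProjectionMatrix(A, labels, "MPM")


# ---------------------------------------------------------------------------
# IPM vital-rate fitting
# ---------------------------------------------------------------------------

def _fit_logistic(z: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                  max_iter: int = 100) -> tuple[np.ndarray, bool]:
    """Newton-Raphson logistic MLE with an optional ridge on the slope."""
    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    pen = np.diag([0.0, ridge])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = np.clip(p * (1 - p), 1e-12, None)
        grad = X.T @ (y - p) - pen @ beta
        H = (X.T * W) @ X + pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            return beta, True
        if np.abs(beta).max() > 1e6:
            return beta, False
    return beta, False


def fit_vital_rates(
    records: pd.DataFrame,
    establishment: float | None = None,
    seed_bank: SeedBankParams | None = None,
) -> VitalRateCoefficients:
    """Fit size-structured vital rates from an IPM census table.

    Survival: maximum-likelihood logistic regression of survival on
    size (ridge 1e-6 fallback on the slope under separation).  Growth:
    least squares of size at t+1 on size at t among survivors, residual
    sd from the residuals.  Fecundity: log-linear least squares of seed
    counts on size over reproducing individuals.  Recruit sizes come
    from recruit rows (``size_t`` NaN); the establishment probability
    is estimated as recruits observed per seed produced unless
    supplied.
    """
    obs = records[records["size_t"].notna()]
    recruits = records[records["size_t"].isna() & records["size_t1"].notna()]
    if len(obs) == 0:
        raise ValueError("no measured individuals at t")
    z = obs["size_t"].to_numpy(dtype=float)
    y = obs["surv"].to_numpy(dtype=float)
    if np.all(y == 1) or np.all(y == 0):
        raise ValueError(
            "degenerate survival (all alive or all dead); "
            "supply a fixed survival probability instead of fitting"
        )
    surv_ok = obs[(obs["surv"] == 1) & obs["size_t1"].notna()]
    if len(surv_ok) < 10:
        raise ValueError("need >= 10 survivors with sizes at t and t+1")
    beta, converged = _fit_logistic(z, y)
    if not converged or np.abs(beta).max() > 30:
        beta, _ = _fit_logistic(z, y, ridge=1e-6, max_iter=500)

    zg = surv_ok["size_t"].to_numpy(dtype=float)
    zg1 = surv_ok["size_t1"].to_numpy(dtype=float)
    Xg = np.column_stack([np.ones_like(zg), zg])
    gcoef, *_ = np.linalg.lstsq(Xg, zg1, rcond=None)
    resid = zg1 - Xg @ gcoef
    dof = max(len(zg) - 2, 1)
    growth_sd = float(np.sqrt((resid**2).sum() / dof))
    if growth_sd < 1e-8:
        raise ValueError(
            "growth residual sd is zero (sizes lie exactly on a line); "
            "a degenerate growth kernel cannot be built"
        )

    rep = obs[obs["repro_count"] > 0]
    if len(rep) == 0:
        fec_i, fec_s = -np.inf, 0.0
    else:
        zr = rep["size_t"].to_numpy(dtype=float)
        lr = np.log(rep["repro_count"].to_numpy(dtype=float))
        if np.unique(zr).size < 2:
            fec_i, fec_s = float(lr.mean()), 0.0
        else:
            Xr = np.column_stack([np.ones_like(zr), zr])
            fcoef, *_ = np.linalg.lstsq(Xr, lr, rcond=None)
            fec_i, fec_s = float(fcoef[0]), float(fcoef[1])

    if establishment is None:
        total_seeds = float(obs["repro_count"].sum())
        establishment = (
            min(len(recruits) / total_seeds, 1.0) if total_seeds > 0 else 1.0
        )
    if len(recruits) > 0:
        rs = recruits["size_t1"].to_numpy(dtype=float)
        recruit_mean = float(rs.mean())
        recruit_sd = float(rs.std(ddof=1)) if len(rs) > 1 else 0.1
        recruit_sd = max(recruit_sd, 1e-3)
    else:
        recruit_mean, recruit_sd = float(z.mean()), max(float(z.std() or 0.1), 1e-3)

    return VitalRateCoefficients(
        surv_intercept=float(beta[0]),
        surv_slope=float(beta[1]),
        growth_intercept=float(gcoef[0]),
        growth_slope=float(gcoef[1]),
        growth_sd=growth_sd,
        fec_intercept=fec_i,
        fec_slope=fec_s,
        establishment=float(establishment),
        recruit_mean=recruit_mean,
        recruit_sd=recruit_sd,
        seed_bank=seed_bank,
    )


def size_bounds(records: pd.DataFrame, extension: float = 0.1) -> tuple[float, float]:
    """Observed size range extended by ``extension`` of the range on
    each side (the standard guard against mesh eviction)."""
    sizes = pd.concat([records["size_t"], records["size_t1"]]).dropna().to_numpy(float)
    lo, hi = float(sizes.min()), float(sizes.max())
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate size range")
    return lo - extension * span, hi + extension * span


def build_ipm_kernel(
    coeffs: VitalRateCoefficients,
    bounds: tuple[float, float],
    meshpoints: int = 500,
) -> ProjectionMatrix:
    """Midpoint-rule discretization of the IPM kernel
    ``K(z', z) = s(z) g(z'|z) + f(z) c(z')``.

    The mesh has ``meshpoints`` midpoints on ``bounds``; each kernel
    value is multiplied by the bin width.  A discrete seed-bank stage
    is appended when configured on the coefficients.
    """
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError("bounds must be finite with lower < upper")
    if meshpoints < 10:
        raise ValueError("meshpoints must be >= 10")
    m = int(meshpoints)
    h = (hi - lo) / m
    z = lo + h * (np.arange(m) + 0.5)
    s = expit(coeffs.surv_intercept + coeffs.surv_slope * z)
    G = norm.pdf(z[:, None], loc=coeffs.growth_intercept + coeffs.growth_slope * z[None, :],
                 scale=coeffs.growth_sd) * h
    P = G * s[None, :]
    if np.isfinite(coeffs.fec_intercept):
        f = np.exp(coeffs.fec_intercept + coeffs.fec_slope * z) * coeffs.establishment
        c = norm.pdf(z, loc=coeffs.recruit_mean, scale=coeffs.recruit_sd) * h
    else:
        f = np.zeros(m)
        c = np.zeros(m)
    bank = coeffs.seed_bank
    direct = 1.0 if bank is None else 1.0 - bank.entry_prob
    K = P + direct * np.outer(c, f)
    if not np.all(np.isfinite(K)):
        raise ValueError(f"non-finite kernel values from coefficients {coeffs}")
    mesh = z
    labels: tuple = tuple(np.round(z, 10))
    if bank is not None:
        B = np.zeros((m + 1, m + 1))
        B[:m, :m] = K
        B[m, :m] = bank.entry_prob * f
        B[:m, m] = bank.germination_prob * c
        B[m, m] = bank.stasis_prob
        K = B
        labels = labels + ("seedbank",)
    return ProjectionMatrix(K, labels, "IPM", mesh=mesh, bin_width=h)


# ---------------------------------------------------------------------------
# lambda and effect size
# ---------------------------------------------------------------------------

def dominant_lambda(P: ProjectionMatrix | np.ndarray) -> float:
    """Spectral radius (Perron root) of a nonnegative projection matrix.

    Full eigendecomposition for dimension <= 600; power iteration
    (tolerance 1e-10, at most 1e5 iterations) above.  The dominant
    eigenvalue must be real to within 1e-8.
    """
    A = P.entries if isinstance(P, ProjectionMatrix) else np.asarray(P, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix has non-finite entries")
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    n = A.shape[0]
    if n <= 600:
        ev = np.linalg.eigvals(A)
        lead = ev[np.argmax(np.abs(ev))]
        if abs(lead.imag) > 1e-8 * max(1.0, abs(lead.real)):
            raise ValueError("dominant eigenvalue has a non-negligible imaginary part")
        return float(lead.real)
    v = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(100_000):
        w = A @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        w /= nw
        lam_new = float(w @ (A @ w))
        if abs(lam_new - lam) < 1e-10 * max(1.0, abs(lam_new)):
            return abs(lam_new)
        lam, v = lam_new, w
    return abs(lam)


def effect_size_of_competition(
    lambda_removal: float,
    lambda_control: float,
    variant: str = "log_ratio",
) -> float:
    """Log response ratio of growth rates between treatments.

    ``log_ratio`` (default): ln((lambda_removal + 0.5) /
    (lambda_control + 0.5)), the standard log response ratio with a
    +0.5 offset on both growth rates.  ``ratio_of_logs`` is an
    alternative reading, ln(lambda_removal + 0.5) /
    ln(lambda_control + 0.5); it is exposed because the offset also
    keeps the denominator log away from 0 under that reading.
    """
    if lambda_removal < 0 or lambda_control < 0:
        raise ValueError("growth rates must be nonnegative")
    if variant == "log_ratio":
        return float(np.log((lambda_removal + 0.5) / (lambda_control + 0.5)))
    if variant == "ratio_of_logs":
        den = np.log(lambda_control + 0.5)
        if den == 0:
            raise ValueError("ratio_of_logs undefined when lambda_control + 0.5 == 1")
        return float(np.log(lambda_removal + 0.5) / den)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# model classes (statsmodels-style surface)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesModelSpec:
    """How one species' census is turned into a projection model."""

    kind: str  # "MPM" or "IPM"
    stages: tuple[str, ...] = ()
    fecundity_map: dict[str, str] = field(default_factory=dict)
    seed_bank: SeedBankParams | None = None
    meshpoints: int = 500
    bounds: tuple[float, float] | None = None
    establishment: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("MPM", "IPM"):
            raise ValueError("kind must be 'MPM' or 'IPM'")


class ProjectionModelResults:
    """Fitted projection model: the matrix, lambda and (for IPMs) the
    vital-rate coefficients."""

    def __init__(self, model, matrix: ProjectionMatrix,
                 coefficients: VitalRateCoefficients | None = None):
        self.model = model
        self.matrix = matrix
        self.coefficients = coefficients
        self.lambda_ = dominant_lambda(matrix)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} results",
            f"  kind:       {self.matrix.model_kind}",
            f"  dimension:  {self.matrix.dim}",
            f"  lambda:     {self.lambda_:.6f}",
        ]
        if self.matrix.model_kind == "MPM":
            lines.append(f"  stages:     {', '.join(map(str, self.matrix.labels))}")
        if self.coefficients is not None:
            c = self.coefficients
            lines += [
                f"  survival:   logit^-1({c.surv_intercept:.4f} + {c.surv_slope:.4f} z)",
                f"  growth:     N({c.growth_intercept:.4f} + {c.growth_slope:.4f} z, "
                f"{c.growth_sd:.4f})",
                f"  fecundity:  exp({c.fec_intercept:.4f} + {c.fec_slope:.4f} z) "
                f"x {c.establishment:.4f}",
                f"  recruits:   N({c.recruit_mean:.4f}, {c.recruit_sd:.4f})",
            ]
        return "\n".join(lines)


class MatrixPopulationModel:
    """Stage-structured model built from census records.

    ``fit()`` tallies transition frequencies and per-capita
    fecundities into a projection matrix and computes lambda.
    """

    def __init__(self, records: pd.DataFrame, stages, fecundity_map,
                 seed_bank: SeedBankParams | None = None):
        self.records = records
        self.stages = tuple(stages)
        self.fecundity_map = dict(fecundity_map)
        self.seed_bank = seed_bank

    def fit(self) -> ProjectionModelResults:
        mat = build_mpm(self.records, list(self.stages), self.fecundity_map,
                        self.seed_bank)
        return ProjectionModelResults(self, mat)


class IntegralProjectionModel:
    """Size-structured model built from census records.

    ``fit()`` estimates the vital-rate regressions, discretizes the
    kernel by the midpoint rule and computes lambda.  Bounds default to
    the observed size range extended by 10% on each side.
    """

    def __init__(self, records: pd.DataFrame, meshpoints: int = 500,
                 bounds: tuple[float, float] | None = None,
                 establishment: float | None = None,
                 seed_bank: SeedBankParams | None = None):
        self.records = records
        self.meshpoints = meshpoints
        self.bounds = bounds
        self.establishment = establishment
        self.seed_bank = seed_bank

    def fit(self) -> ProjectionModelResults:
        coeffs = fit_vital_rates(self.records, establishment=self.establishment,
                                 seed_bank=self.seed_bank)
        bounds = self.bounds if self.bounds is not None else size_bounds(self.records)
        mat = build_ipm_kernel(coeffs, bounds, self.meshpoints)
        return ProjectionModelResults(self, mat, coefficients=coeffs)


def _model_for(records: pd.DataFrame, spec: SpeciesModelSpec):
    if spec.kind == "MPM":
        return MatrixPopulationModel(records, spec.stages, spec.fecundity_map,
                                     spec.seed_bank)
    return IntegralProjectionModel(records, spec.meshpoints, spec.bounds,
                                   spec.establishment, spec.seed_bank)


def treatment_lambdas(records: pd.DataFrame, spec: SpeciesModelSpec) -> dict[str, float]:
    """Point-estimate lambda per treatment for one species' census."""
    out = {}
    for trt in TREATMENTS:
        sub = records[records["treatment"] == trt]
        if len(sub) == 0:
            raise ValueError(f"no records for treatment {trt!r}")
        out[trt] = _model_for(sub, spec).fit().lambda_
    return out


def point_effect_size(records: pd.DataFrame, spec: SpeciesModelSpec,
                      species: str = "", variant: str = "log_ratio") -> EffectSize:
    lams = treatment_lambdas(records, spec)
    val = effect_size_of_competition(lams["removal"], lams["control"], variant)
    return EffectSize(species, val, lams["control"], lams["removal"])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_effect_sizes(
    records: pd.DataFrame,
    spec: SpeciesModelSpec,
    n_boot: int = 1000,
    seed: int = 0,
    resample: bool = True,
    variant: str = "log_ratio",
    max_redraws: int = 100,
) -> np.ndarray:
    """Bootstrap distribution of the competition effect size for one
    species.

    Each replicate resamples individuals (whole fate trajectories) with
    replacement within each treatment stratum, re-fits the projection
    model per treatment and recomputes lambda and the effect size.
    Replicates that empty a required stage are redrawn, up to
    ``max_redraws`` attempts each.  ``resample=False`` returns the
    point estimate in every replicate (identity resample).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if spec.kind == "IPM" and spec.bounds is None:
        # freeze bounds at the full-data range so replicates share a mesh
        spec = replace(spec, bounds=size_bounds(records))
    if not resample:
        val = point_effect_size(records, spec, variant=variant).value
        return np.full(n_boot, val)
    rng = substream(seed, "demog-bootstrap", spec.kind)
    by_trt = {trt: records[records["treatment"] == trt].reset_index(drop=True)
              for trt in TREATMENTS}
    if spec.kind == "MPM":
        lams = {trt: _bootstrap_mpm_lambdas(by_trt[trt], spec, n_boot, rng, max_redraws)
                for trt in TREATMENTS}
    else:
        lams = {trt: _bootstrap_ipm_lambdas(by_trt[trt], spec, n_boot, rng, max_redraws)
                for trt in TREATMENTS}
    out = np.array([
        effect_size_of_competition(lams["removal"][b], lams["control"][b], variant)
        for b in range(n_boot)
    ])
    return out


def _bootstrap_mpm_lambdas(records: pd.DataFrame, spec: SpeciesModelSpec,
                           n_boot: int, rng: np.random.Generator,
                           max_redraws: int) -> np.ndarray:
    stages = list(spec.stages)
    S = len(stages)
    sidx = {s: k for k, s in enumerate(stages)}
    stage_t = records["stage_t"].map(sidx).to_numpy()
    fate = records["stage_t1"].map(lambda s: sidx.get(s, S)).to_numpy()  # S == dead
    repro = records["repro_count"].to_numpy(dtype=float)
    N = len(records)
    fec_from = np.array([sidx[s] for s in spec.fecundity_map], dtype=int)
    fec_to = np.array([sidx[t] for t in spec.fecundity_map.values()], dtype=int)
    lams = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            take = rng.integers(0, N, size=N)
            st, ft, rp = stage_t[take], fate[take], repro[take]
            counts = np.bincount(st, minlength=S).astype(float)
            if np.all(counts > 0):
                break
        else:
            raise RuntimeError(
                f"bootstrap replicate emptied a stage {max_redraws} times in a row"
            )
        M = np.zeros((S + 1, S))  # last row collects deaths
        np.add.at(M, (ft, st), 1.0)
        A = M[:S] / counts[None, :]
        direct = 1.0 if spec.seed_bank is None else 1.0 - spec.seed_bank.entry_prob
        percap = np.zeros(S)
        for s_i in fec_from:
            percap[s_i] = rp[st == s_i].mean()
        Afull = A.copy()
        for s_i, s_j in zip(fec_from, fec_to):
            Afull[s_j, s_i] += direct * percap[s_i]
        if spec.seed_bank is not None:
            bank = spec.seed_bank
            B = np.zeros((S + 1, S + 1))
            B[:S, :S] = Afull
            for s_i, s_j in zip(fec_from, fec_to):
                B[S, s_i] = bank.entry_prob * percap[s_i]
                B[s_j, S] = bank.germination_prob
            B[S, S] = bank.stasis_prob
            Afull = B
        lams[b] = dominant_lambda(Afull)
    return lams


_SQRT2PI = float(np.sqrt(2.0 * np.pi))


def _power_radius(K: np.ndarray, tol: float = 1e-13, max_iter: int = 10_000) -> float:
    """Perron root of a nonnegative matrix by power iteration; falls back
    to the dense eigensolver if convergence stalls."""
    n = K.shape[0]
    v = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        w = K @ v
        nw = float(np.linalg.norm(w))
        if nw == 0.0:
            return 0.0
        w /= nw
        lam_new = float(w @ (K @ w))
        if abs(lam_new - lam) < tol * max(1.0, abs(lam_new)):
            return abs(lam_new)
        lam, v = lam_new, w
    return dominant_lambda(K)


def _ipm_lambda_from_arrays(z, y, z1, seeds, rec_sizes, spec: SpeciesModelSpec,
                            mesh, h) -> float:
    """Array fast path: identical math to fit_vital_rates + build_ipm_kernel
    (see test suite for the equivalence check), without DataFrame overhead."""
    if np.all(y == 1) or np.all(y == 0):
        raise ValueError("degenerate survival")
    grew = (y == 1) & np.isfinite(z1)
    if grew.sum() < 10:
        raise ValueError("need >= 10 survivors with sizes at t and t+1")
    beta, converged = _fit_logistic(z, y)
    if not converged or np.abs(beta).max() > 30:
        beta, _ = _fit_logistic(z, y, ridge=1e-6, max_iter=500)
    zg, zg1 = z[grew], z1[grew]
    Xg = np.column_stack([np.ones_like(zg), zg])
    gcoef, *_ = np.linalg.lstsq(Xg, zg1, rcond=None)
    resid = zg1 - Xg @ gcoef
    growth_sd = float(np.sqrt((resid**2).sum() / max(len(zg) - 2, 1)))
    if growth_sd < 1e-8:
        raise ValueError("zero growth residual sd")
    rep_mask = seeds > 0
    if not rep_mask.any():
        fec_i, fec_s = -np.inf, 0.0
    else:
        zr, lr = z[rep_mask], np.log(seeds[rep_mask])
        if np.unique(zr).size < 2:
            fec_i, fec_s = float(lr.mean()), 0.0
        else:
            Xr = np.column_stack([np.ones_like(zr), zr])
            fcoef, *_ = np.linalg.lstsq(Xr, lr, rcond=None)
            fec_i, fec_s = float(fcoef[0]), float(fcoef[1])
    if spec.establishment is not None:
        estab = spec.establishment
    else:
        total = float(seeds.sum())
        estab = min(len(rec_sizes) / total, 1.0) if total > 0 else 1.0
    if len(rec_sizes) > 0:
        rmean = float(rec_sizes.mean())
        rsd = max(float(rec_sizes.std(ddof=1)) if len(rec_sizes) > 1 else 0.1, 1e-3)
    else:
        rmean, rsd = float(z.mean()), max(float(z.std() or 0.1), 1e-3)

    s = expit(beta[0] + beta[1] * mesh)
    dev = (mesh[:, None] - (gcoef[0] + gcoef[1] * mesh[None, :])) / growth_sd
    G = np.exp(-0.5 * dev * dev) * (h / (growth_sd * _SQRT2PI))
    K = G * s[None, :]
    if np.isfinite(fec_i):
        f = np.exp(fec_i + fec_s * mesh) * estab
        rdev = (mesh - rmean) / rsd
        c = np.exp(-0.5 * rdev * rdev) * (h / (rsd * _SQRT2PI))
        bank = spec.seed_bank
        direct = 1.0 if bank is None else 1.0 - bank.entry_prob
        K = K + direct * np.outer(c, f)
        if bank is not None:
            m = len(mesh)
            B = np.zeros((m + 1, m + 1))
            B[:m, :m] = K
            B[m, :m] = bank.entry_prob * f
            B[:m, m] = bank.germination_prob * c
            B[m, m] = bank.stasis_prob
            K = B
    if not np.all(np.isfinite(K)):
        raise ValueError("non-finite kernel")
    return _power_radius(K)


def _bootstrap_ipm_lambdas(records: pd.DataFrame, spec: SpeciesModelSpec,
                           n_boot: int, rng: np.random.Generator,
                           max_redraws: int) -> np.ndarray:
    size_t = records["size_t"].to_numpy(dtype=float)
    size_t1 = records["size_t1"].to_numpy(dtype=float)
    surv = records["surv"].to_numpy(dtype=float)
    seeds = records["repro_count"].to_numpy(dtype=float)
    is_obs = np.isfinite(size_t)
    is_rec = ~is_obs & np.isfinite(size_t1)
    N = len(records)
    lo, hi = spec.bounds
    m = int(spec.meshpoints)
    h = (hi - lo) / m
    mesh = lo + h * (np.arange(m) + 0.5)
    lams = np.empty(n_boot)
    for b in range(n_boot):
        last_err: Exception | None = None
        for attempt in range(max_redraws + 1):
            take = rng.integers(0, N, size=N)
            obs = take[is_obs[take]]
            rec = take[is_rec[take]]
            try:
                lams[b] = _ipm_lambda_from_arrays(
                    size_t[obs], surv[obs], size_t1[obs], seeds[obs],
                    size_t1[rec], spec, mesh, h,
                )
                last_err = None
                break
            except ValueError as err:
                last_err = err
        if last_err is not None:
            raise RuntimeError(
                f"bootstrap replicate failed {max_redraws} times: {last_err}"
            )
    return lams
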