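"""Synthetic scenarios with known ground truth.

The generator emulates the design of a competitor-removal field study:
a regional species pool on an ultrametric phylogeny, plot-level
communities with percent cover around each focal alien species, traits
with tunable phylogenetic signal, and two-treatment demographic
censuses whose control-vs-removal difference in growth rate is, in
expectation, a planted linear function of the focal species'
phylogenetic distinctiveness:

    E[effect_i] = treatment_effect_slope * (d_i - max_j d_j) + base_effect

where ``d_i`` is the focal's small-grain mean pairwise distance on the
square-root cophenetic scale.  A negative ``treatment_effect_slope``
therefore plants a negative distinctiveness coefficient in the
downstream regression (distinct species suffer less from competition);
a slope of 0 with ``base_effect = 0`` is an exact null.  Competitor
removal acts through recruitment: per-treatment fecundity parameters
are solved so the generating projection model hits the planted growth
rate exactly, and those generating models are recorded in a
ground-truth side table.

Community assembly mixes each focal's nearest relatives with a
background sampled around the pool-median distance, with mixing
fractions stratified across the focal set and focal species chosen to
have comparable neighbourhood profiles.  Small-grain distinctiveness
therefore varies widely across focal species independently of their
position in the regional pool, and the large-grain (whole-pool)
distinctiveness is uncoupled from the planted effect by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from ._rng import substream
from .demography import (
    ProjectionMatrix,
    SpeciesModelSpec,
    VitalRateCoefficients,
    build_ipm_kernel,
    dominant_lambda,
)
from .distinct import focal_distinctiveness
from .traits import TraitTable
from .tree import PhyloTree, cophenetic_matrix, simulate_phylogeny

__all__ = [
    "ScenarioConfig",
    "CommunitySample",
    "DemographicDataset",
    "ScenarioBundle",
    "simulate_phylogeny",
    "simulate_traits",
    "simulate_communities",
    "simulate_demography",
    "simulate_scenario",
    "DEFAULT_TRAITS",
]

# trait name -> kind, mirroring a typical field campaign: three measured
# continuous traits, flowering phenology as a circular month, two binary
# literature traits and two categorical ones
DEFAULT_TRAITS: tuple[tuple[str, str], ...] = (
    ("height", "continuous"),
    ("sla", "continuous"),
    ("toughness", "continuous"),
    ("flowering_month", "circular_month"),
    ("n_fixer", "binary"),
    ("clonal", "binary"),
    ("growth_form", "categorical"),
    ("dispersal", "categorical"),
)

_CATEGORY_LEVELS = {
    "growth_form": ("forb", "graminoid", "woody"),
    "dispersal": ("unassisted", "wind", "animal"),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    ``treatment_effect_slope`` is the planted regression coefficient of
    the competition effect size on small-grain distinctiveness (the
    square-root cophenetic scale); ``trait_signal`` maps traits to
    Brownian-signal strength in [0, 1] (1 = pure Brownian motion,
    0 = tip-shuffled).
    """

    n_regional_species: int = 80
    n_focal: int = 14
    community_richness_range: tuple[int, int] = (11, 18)
    treatment_effect_slope: float = -0.07
    base_effect: float = 0.0
    trait_signal: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.02
    seed: int = 0
    # plumbing that a field design would fix in advance
    congener_fraction: float = 0.3
    ipm_fraction: float = 4 / 14
    n_plots: int = 8            # per treatment per species
    n_per_plot: int = 20        # individuals per plot
    cover_missing_fraction: float = 0.15
    tree_depth: float = 100.0
    meshpoints: int = 60        # discretization for synthetic IPM species

    def __post_init__(self) -> None:
        if self.n_focal > self.n_regional_species:
            raise ValueError("n_focal must not exceed n_regional_species")
        lo, hi = self.community_richness_range
        if lo < 11:
            raise ValueError("community richness must be >= 11 (rarefaction at k=11)")
        if hi < lo:
            raise ValueError("invalid richness range")
        if hi > self.n_regional_species - 1:
            raise ValueError("richness range exceeds the species pool")
        if self.n_plots < 2:
            raise ValueError("need >= 2 plots per treatment per species")
        if self.n_per_plot < 1:
            raise ValueError("n_per_plot must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class CommunitySample:
    """One focal species plus its co-occurring species at a grain.

    ``cover`` maps each member to percent cover, or NaN for members
    recorded without abundance (e.g. canopy species)."""

    focal: str
    members: tuple[str, ...]
    cover: dict[str, float]
    grain: str = "small"

    @property
    def members_with_cover(self) -> list[str]:
        return [m for m in self.members if np.isfinite(self.cover.get(m, np.nan))]

    def weights(self) -> np.ndarray:
        return np.array([self.cover[m] for m in self.members_with_cover])


@dataclass
class DemographicDataset:
    """Simulated censuses plus the generating models and planted truth."""

    census: pd.DataFrame
    biomass: pd.DataFrame
    ground_truth: pd.DataFrame
    model_specs: dict[str, SpeciesModelSpec]
    generating_matrices: dict[tuple[str, str], ProjectionMatrix]
    generating_coefficients: dict[tuple[str, str], VitalRateCoefficients]


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    tree: PhyloTree
    traits: TraitTable
    communities: list[CommunitySample]
    demography: DemographicDataset


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(
    tree: PhyloTree,
    trait_spec=DEFAULT_TRAITS,
    signal=1.0,
    seed: int = 0,
    missing_fraction: float = 0.0,
) -> TraitTable:
    """Evolve traits on the tree with tunable phylogenetic signal.

    ``signal`` is a scalar or per-trait mapping in [0, 1].  At 1 a
    continuous trait is pure Brownian motion; at 0 the Brownian values
    are shuffled across tips (signal destroyed, distribution kept);
    intermediate values blend the Brownian trait with matched-variance
    white noise.  Circular months, binary and categorical traits derive
    from a latent trait built the same way, via quantile mapping,
    median thresholding and quantile binning respectively.
    """
    from .signal import simulate_bm

    if tree.n_tips < 3:
        raise ValueError("tree must have >= 3 tips")
    labels = tree.tip_labels
    n = len(labels)
    data: dict[str, np.ndarray | list] = {}
    kinds: dict[str, str] = {}
    for name, kind in trait_spec:
        if kind not in ("continuous", "circular_month", "binary", "categorical"):
            raise ValueError(f"unknown trait kind {kind!r} for {name!r}")
        s = float(signal.get(name, 1.0)) if isinstance(signal, dict) else float(signal)
        if not 0.0 <= s <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        rng = substream(seed, "trait", name)
        _, bm = simulate_bm(tree, rng, n_reps=1)
        x = bm[:, 0]
        if s == 0.0:
            x = x[rng.permutation(n)]
        elif s < 1.0:
            noise = rng.standard_normal(n) * x.std(ddof=1)
            x = np.sqrt(s) * x + np.sqrt(1.0 - s) * noise
        u = ndtr((x - x.mean()) / max(x.std(ddof=1), 1e-12))
        if kind == "continuous":
            vals: np.ndarray | list = x
        elif kind == "circular_month":
            vals = np.minimum(np.floor(12 * u) + 1, 12).astype(float)
        elif kind == "binary":
            vals = (x >= np.median(x)).astype(float)
        else:
            levels = _CATEGORY_LEVELS.get(name, ("A", "B", "C"))
            q = len(levels)
            idx = np.minimum((u * q).astype(int), q - 1)
            vals = [levels[i] for i in idx]
        if missing_fraction > 0:
            miss = rng.random(n) < missing_fraction
            if kind == "categorical":
                vals = [None if m else v for v, m in zip(vals, miss)]
            else:
                vals = np.where(miss, np.nan, vals)
        data[name] = vals
        kinds[name] = kind
    df = pd.DataFrame(data, index=labels)
    return TraitTable(df, kinds)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _select_focals(D, labels, n_focal, r_ref, rng) -> list[str]:
    """Focal species with comparable neighbourhood profiles.

    Candidates are ranked by how close their nearest-``r_ref`` mean
    distance sits to the pool median of that quantity; the focal set is
    drawn at random from the central half of that ranking, so focal
    choice does not covary with how crowded a species' corner of the
    tree is."""
    near_means = []
    for i, sp in enumerate(labels):
        d = np.delete(D.values[i], i)
        d = np.sort(d)
        near_means.append(d[:r_ref].mean())
    near_means = np.asarray(near_means)
    dev = np.abs(near_means - np.median(near_means))
    order = np.argsort(dev, kind="stable")
    band = order[: max(len(labels) // 2, n_focal)]
    take = rng.choice(band, size=n_focal, replace=False)
    return sorted(labels[i] for i in take)


def simulate_communities(
    tree: PhyloTree,
    config: ScenarioConfig,
    focal_species: list[str] | None = None,
) -> list[CommunitySample]:
    """One community sample per focal species.

    Communities mix close relatives with a distance-anchored
    background: each focal species draws a mixing weight
    pi ~ Uniform(0, 1), takes the pi * r nearest species (square-root
    cophenetic scale) and fills the remaining members by weighted
    sampling centred on the pool-wide median pairwise distance.
    Because pi varies independently across focal species, realized
    small-grain distinctiveness spans a wide range; because focal
    species are chosen (when not supplied) with comparable
    neighbourhood profiles and the background anchor is global rather
    than focal-specific, community distinctiveness is driven by
    assembly, not by each focal's position in the regional pool —
    keeping the small grain decoupled from the large grain.  Percent
    covers are Dirichlet-distributed and a configurable fraction of
    members is flagged as recorded without abundance.
    """
    rng = substream(config.seed, "communities")
    labels = tree.tip_labels
    D = cophenetic_matrix(tree, transform="sqrt")
    lo, hi = config.community_richness_range
    if focal_species is None:
        focal_species = _select_focals(D, labels, config.n_focal, lo, rng)
    offdiag = D.values[~np.eye(len(labels), dtype=bool)]
    anchor = float(np.median(offdiag))
    kappa = 0.1 * float(np.quantile(offdiag, 0.85) - np.quantile(offdiag, 0.15))
    # stratified mixing weights: the focal set spans assembly intensities
    # evenly (shuffled order), which keeps the cross-species spread of
    # community distinctiveness stable from scenario to scenario
    n_f = len(focal_species)
    pis = (np.arange(n_f) + 0.5) / n_f
    pis = pis[rng.permutation(n_f)]
    samples = []
    for j, sp in enumerate(focal_species):
        r = int(rng.integers(lo, hi + 1))
        pool = [x for x in labels if x != sp]
        d = D.distances_from(sp, pool)
        order = np.argsort(d, kind="stable")
        pi = float(pis[j])
        n_near = min(int(round(pi * r)), r)
        rest_pool = order[n_near:]
        logw = -0.5 * ((d[rest_pool] - anchor) / kappa) ** 2
        keys = logw + rng.gumbel(size=len(rest_pool))
        rest = rest_pool[np.argsort(keys)[::-1][: r - n_near]]
        take = np.concatenate([order[:n_near], rest]).astype(int)
        members = tuple(pool[i] for i in take)
        covers = 100.0 * rng.dirichlet(np.ones(r))
        cover = dict(zip(members, covers))
        n_missing = int(round(config.cover_missing_fraction * r))
        if n_missing >= r:
            n_missing = r - 1
        for m in rng.choice(members, size=n_missing, replace=False):
            cover[m] = float("nan")
        samples.append(CommunitySample(sp, members, cover, grain="small"))
    return samples


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

# canonical 3-stage structure: seedling / juvenile / adult
_MPM_STAGES = ("sdl", "juv", "adult")
_MPM_TRANSITIONS = np.array([
    #  sdl   juv  adult   (columns: from-stage)
    [0.00, 0.00, 0.00],   # to sdl (recruitment added separately)
    [0.30, 0.20, 0.00],   # to juv
    [0.00, 0.50, 0.60],   # to adult
])
_MPM_STAGE_MIX = np.array([0.40, 0.35, 0.25])

# canonical size-structured vital rates (log-size scale); survival is kept
# moderate so the survival-growth kernel alone has spectral radius well
# below any planted growth rate, leaving recruitment as the channel that
# the treatment contrast acts through
_IPM_BASE = dict(
    surv_intercept=-0.5, surv_slope=0.3,
    growth_intercept=0.4, growth_slope=0.9, growth_sd=0.3,
    fec_slope=0.3, establishment=0.3,
    recruit_mean=-0.5, recruit_sd=0.3,
)
_IPM_BOUNDS = (-2.5, 4.0)
_IPM_SIZE_MEAN, _IPM_SIZE_SD = 0.5, 0.8


def _mpm_matrix(fecundity: float) -> np.ndarray:
    A = _MPM_TRANSITIONS.copy()
    A[0, 2] += fecundity
    return A


def _solve_mpm_fecundity(target_lambda: float) -> float:
    f = brentq(lambda f: dominant_lambda(_mpm_matrix(f)) - target_lambda,
               0.0, 1e4, xtol=1e-12)
    return float(f)


def _ipm_coeffs(fec_intercept: float) -> VitalRateCoefficients:
    return VitalRateCoefficients(fec_intercept=fec_intercept, **_IPM_BASE)


_ipm_parts_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, float]] = {}


def _ipm_parts(meshpoints: int):
    """Survival-growth kernel P and the rank-one fecundity factors.

    The full kernel is K = P + exp(a_f) * outer(c, f0) with
    f0 = establishment * exp(fec_slope * z) and c the recruit-size
    density times the bin width.
    """
    if meshpoints not in _ipm_parts_cache:
        base = build_ipm_kernel(_ipm_coeffs(-np.inf), _IPM_BOUNDS, meshpoints)
        z, h = base.mesh, base.bin_width
        from scipy.stats import norm

        f0 = _IPM_BASE["establishment"] * np.exp(_IPM_BASE["fec_slope"] * z)
        c = norm.pdf(z, _IPM_BASE["recruit_mean"], _IPM_BASE["recruit_sd"]) * h
        rho = dominant_lambda(base)
        _ipm_parts_cache[meshpoints] = (base.entries, c, f0, rho)
    return _ipm_parts_cache[meshpoints]


def _solve_ipm_fecundity(target_lambda: float, meshpoints: int) -> float:
    """Fecundity intercept whose kernel hits ``target_lambda`` exactly.

    Because fecundity enters the discretized kernel as a rank-one term
    exp(a_f) * c f0', the Perron root equals the target exactly when
    exp(a_f) * f0' (target*I - P)^-1 c = 1, a closed-form solve.
    """
    P, c, f0, rho = _ipm_parts(meshpoints)
    if target_lambda <= rho + 1e-8:
        raise ValueError(
            f"planted growth rate {target_lambda:.4f} is below the "
            f"survival-only spectral radius {rho:.4f}; unreachable via recruitment"
        )
    m = P.shape[0]
    x = np.linalg.solve(target_lambda * np.eye(m) - P, c)
    theta = 1.0 / float(f0 @ x)
    return float(np.log(theta))


def simulate_demography(
    communities: list[CommunitySample],
    tree: PhyloTree,
    config: ScenarioConfig,
) -> DemographicDataset:
    """Simulate two-treatment censuses whose planted growth-rate
    contrast follows the configured distinctiveness slope.

    The planted predictor is the focal's realized community MPD on the
    square-root cophenetic scale (the same quantity the downstream
    regression measures); the expected treatment contrast is
    ``treatment_effect_slope * (MPD_i - max_j MPD_j) + base_effect``
    plus Gaussian species-level noise.  Because focal species are
    selected with comparable neighbourhood profiles, that predictor is
    driven by community assembly rather than by pool position, leaving
    large-grain distinctiveness uncoupled from the planted effect.

    Per focal species the generating model's per-treatment fecundity is
    solved so the generating lambda equals the planted value exactly;
    individuals then realize stochastic fates under that model.
    Competitor biomass is lognormal(meanlog 0, sdlog 0.5) per removal
    plot, independent of everything else (a nuisance covariate).
    """
    rng = substream(config.seed, "demography")
    D = cophenetic_matrix(tree, transform="sqrt")
    focals = [c.focal for c in communities]
    dvals = np.array([
        focal_distinctiveness(D, c.focal, list(c.members), metric="MPD")
        for c in communities
    ])
    d_max = dvals.max()
    es = (config.treatment_effect_slope * (dvals - d_max)
          + config.base_effect
          + rng.normal(0.0, config.noise_sd, size=len(focals)))
    lam_c = rng.uniform(0.85, 1.05, size=len(focals))
    lam_cr = (lam_c + 0.5) * np.exp(es) - 0.5

    n_ipm = int(round(config.ipm_fraction * config.n_focal))
    ipm_set = set(rng.choice(focals, size=n_ipm, replace=False).tolist())

    census_rows = []
    biomass_rows = []
    truth_rows = []
    specs: dict[str, SpeciesModelSpec] = {}
    gen_mats: dict[tuple[str, str], ProjectionMatrix] = {}
    gen_coefs: dict[tuple[str, str], VitalRateCoefficients] = {}

    for k, sp in enumerate(focals):
        lams = {"control": float(lam_c[k]), "removal": float(lam_cr[k])}
        if min(lams.values()) < 0:
            raise ValueError(
                f"planted growth rate negative for {sp}; reduce the slope or noise"
            )
        kind = "IPM" if sp in ipm_set else "MPM"
        srng = substream(config.seed, "census", sp)
        if kind == "MPM":
            specs[sp] = SpeciesModelSpec(
                kind="MPM", stages=_MPM_STAGES,
                fecundity_map={"adult": "sdl"},
            )
            for trt, lam in lams.items():
                f = _solve_mpm_fecundity(lam)
                A = _mpm_matrix(f)
                gen_mats[(sp, trt)] = ProjectionMatrix(A, _MPM_STAGES, "MPM")
                census_rows += _simulate_mpm_census(sp, trt, A, f, config, srng)
        else:
            specs[sp] = SpeciesModelSpec(
                kind="IPM", meshpoints=config.meshpoints, bounds=_IPM_BOUNDS,
            )
            for trt, lam in lams.items():
                a_f = _solve_ipm_fecundity(lam, config.meshpoints)
                coeffs = _ipm_coeffs(a_f)
                gen_coefs[(sp, trt)] = coeffs
                gen_mats[(sp, trt)] = build_ipm_kernel(
                    coeffs, _IPM_BOUNDS, config.meshpoints
                )
                census_rows += _simulate_ipm_census(sp, trt, coeffs, config, srng)
        brng = substream(config.seed, "biomass", sp)
        for p in range(config.n_plots):
            biomass_rows.append({
                "species": sp,
                "plot_id": f"{sp}-removal-{p}",
                "biomass": float(brng.lognormal(mean=0.0, sigma=0.5)),
            })
        truth_rows.append({
            "species": sp,
            "model_kind": kind,
            "distinctiveness": float(dvals[k]),
            "lambda_control": lams["control"],
            "lambda_removal": lams["removal"],
            "effect_size": float(
                np.log((lams["removal"] + 0.5) / (lams["control"] + 0.5))
            ),
        })

    census = pd.DataFrame(census_rows)
    biomass = pd.DataFrame(biomass_rows)
    truth = pd.DataFrame(truth_rows)
    return DemographicDataset(census, biomass, truth, specs, gen_mats, gen_coefs)


def _simulate_mpm_census(sp, trt, A, fecundity, config, rng) -> list[dict]:
    rows = []
    S = len(_MPM_STAGES)
    surv_probs = [A[:, i].copy() for i in range(S)]
    surv_probs[2][0] -= fecundity  # reproduction is not a transition
    uid = 0
    for p in range(config.n_plots):
        plot = f"{sp}-{trt}-{p}"
        stages = rng.choice(S, size=config.n_per_plot, p=_MPM_STAGE_MIX)
        for st in stages:
            probs = np.append(surv_probs[st], 1.0 - surv_probs[st].sum())
            fate = int(rng.choice(S + 1, p=np.clip(probs, 0, 1) / np.clip(probs, 0, 1).sum()))
            repro = int(rng.poisson(fecundity)) if _MPM_STAGES[st] == "adult" else 0
            rows.append({
                "individual_id": f"{plot}-i{uid}", "species": sp,
                "treatment": trt, "plot_id": plot,
                "stage_t": _MPM_STAGES[st],
                "stage_t1": _MPM_STAGES[fate] if fate < S else "DEAD",
                "size_t": np.nan, "size_t1": np.nan, "surv": float(fate < S),
                "repro_count": repro, "year": 1,
            })
            uid += 1
    return rows


def _simulate_ipm_census(sp, trt, coeffs, config, rng) -> list[dict]:
    rows = []
    uid = 0
    total_seeds = 0
    for p in range(config.n_plots):
        plot = f"{sp}-{trt}-{p}"
        z = rng.normal(_IPM_SIZE_MEAN, _IPM_SIZE_SD, size=config.n_per_plot)
        z = np.clip(z, _IPM_BOUNDS[0] + 0.1, _IPM_BOUNDS[1] - 0.6)
        surv = rng.random(config.n_per_plot) < expit(
            coeffs.surv_intercept + coeffs.surv_slope * z
        )
        z1 = rng.normal(coeffs.growth_intercept + coeffs.growth_slope * z,
                        coeffs.growth_sd)
        z1 = np.clip(z1, _IPM_BOUNDS[0] + 0.05, _IPM_BOUNDS[1] - 0.05)
        seeds = rng.poisson(np.exp(coeffs.fec_intercept + coeffs.fec_slope * z))
        total_seeds += int(seeds.sum())
        for i in range(config.n_per_plot):
            rows.append({
                "individual_id": f"{plot}-i{uid}", "species": sp,
                "treatment": trt, "plot_id": plot,
                "stage_t": None, "stage_t1": None,
                "size_t": float(z[i]),
                "size_t1": float(z1[i]) if surv[i] else np.nan,
                "surv": float(surv[i]),
                "repro_count": int(seeds[i]), "year": 1,
            })
            uid += 1
    n_rec = int(rng.binomial(total_seeds, coeffs.establishment))
    rec_sizes = rng.normal(coeffs.recruit_mean, coeffs.recruit_sd, size=n_rec)
    for i, rz in enumerate(rec_sizes):
        rows.append({
            "individual_id": f"{sp}-{trt}-rec{i}", "species": sp,
            "treatment": trt, "plot_id": f"{sp}-{trt}-0",
            "stage_t": None, "stage_t1": None,
            "size_t": np.nan, "size_t1": float(rz), "surv": np.nan,
            "repro_count": 0, "year": 1,
        })
    return rows


# ---------------------------------------------------------------------------
# whole-scenario orchestration
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Generate tree, traits, communities and demography in one bundle."""
    tree = simulate_phylogeny(
        config.n_regional_species, config.seed,
        depth=config.tree_depth, congener_fraction=config.congener_fraction,
    )
    traits = simulate_traits(tree, DEFAULT_TRAITS,
                             signal=config.trait_signal or 1.0, seed=config.seed)
    communities = simulate_communities(tree, config)
    demography = simulate_demography(communities, tree, config)
    return ScenarioBundle(config, tree, traits, communities, demography)
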