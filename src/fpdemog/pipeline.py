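"""Configuration-driven orchestration of the full analysis chain.

``run_pipeline`` reads delimited inputs (tree, communities, traits,
census, biomass), then per focal species fits projection models for
both treatments, bootstraps the effect size of competitor removal,
computes distinctiveness at both spatial grains, runs the
phylogenetic-signal diagnostics, fits the per-metric regressions with
bootstrap propagation, sweeps the functional-phylogenetic weighting
parameter, and writes every result as tab-separated text plus a JSON
manifest that records seeds and the config echo.  ``make_report``
turns a completed run into figures and a compact text summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from ._rng import spawn_seed
from .demography import bootstrap_effect_sizes, point_effect_size
from .distinct import focal_distinctiveness, rarefied_distinctiveness
from .regression import DistinctivenessRegression, bootstrap_regression, sweep_a
from .signal import blombergs_K, fritz_purvis_D, mantel_test
from .traits import correlation_screen, gower_distance, read_traits
from .tree import cophenetic_matrix, read_newick

logger = logging.getLogger("fpdemog")

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

SMALL_METRICS = ("MPD", "NND", "AW_MPD", "AW_NND")
LARGE_METRICS = ("MPD", "NND")


@dataclass
class PipelineConfig:
    tree: str
    communities: str
    traits: str
    census: str
    biomass: str
    species_specs: str
    output_dir: str
    seed: int = 0
    n_boot: int = 1000
    rarefy_k: int = 11
    n_rarefy_reps: int = 1000
    a_step: float = 0.025
    sweep_metric: str = "NND"
    sweep_traits: list[str] = field(
        default_factory=lambda: ["height", "sla", "toughness", "flowering_month"]
    )
    effect_variant: str = "log_ratio"
    signal_n_perm: int = 199
    correlation_threshold: float = 0.8
    exclude_species: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("tree", "communities", "traits", "census", "biomass",
                    "species_specs"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"config field {key!r}: no such file {p}")
        if self.n_boot < 1 or self.n_rarefy_reps < 1:
            raise ValueError("replicate counts must be positive")


def _stage(name):
    """Decorator-free stage wrapper: re-raises with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a result bundle of DataFrames and
    writes every table under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "outputs": [], "status": "running"}
    bundle: dict = {}

    with _stage("inputs"):
        tree = read_newick(config.tree)
        communities = [c for c in fio.read_communities(config.communities)
                       if c.focal not in set(config.exclude_species)]
        traits = read_traits(config.traits)
        census = fio.read_census(config.census)
        biomass_df = fio.read_biomass(config.biomass)
        specs = fio.read_species_specs(config.species_specs)
        focals = [c.focal for c in communities]
        missing = [sp for sp in focals if sp not in specs]
        if missing:
            raise ValueError(f"no model spec for focal species {missing}")

    with _stage("demography"):
        lam_rows, draws = [], {}
        for sp in focals:
            rec = census[census["species"] == sp]
            eff = point_effect_size(rec, specs[sp], species=sp,
                                    variant=config.effect_variant)
            lam_rows.append({
                "species": sp,
                "lambda_control": eff.lambda_control,
                "lambda_removal": eff.lambda_removal,
                "effect_size": eff.value,
            })
            draws[sp] = bootstrap_effect_sizes(
                rec, specs[sp], n_boot=config.n_boot,
                seed=spawn_seed(config.seed, "boot", sp),
                variant=config.effect_variant,
            )
        lambda_table = pd.DataFrame(lam_rows).set_index("species")
        draw_table = pd.DataFrame(draws).T
        draw_table.columns = [f"b{j}" for j in range(config.n_boot)]
        bundle["lambda_table"] = lambda_table
        bundle["effect_draws"] = draw_table

    with _stage("distinctiveness"):
        D = cophenetic_matrix(tree, transform="sqrt")
        dist_rows = []
        pool = tree.tip_labels
        for c in communities:
            members = list(c.members)
            covered = c.members_with_cover
            for metric in SMALL_METRICS:
                aw = metric.startswith("AW_")
                use = covered if aw else members
                w = c.weights() if aw else None
                if len(use) >= config.rarefy_k:
                    val = rarefied_distinctiveness(
                        D, c.focal, use, k=config.rarefy_k,
                        n_reps=config.n_rarefy_reps, metric=metric,
                        seed=spawn_seed(config.seed, "rarefy", c.focal, metric),
                        weights=w,
                    )
                    rarefied = True
                else:
                    val = focal_distinctiveness(D, c.focal, use, weights=w,
                                                metric=metric)
                    rarefied = False
                logt = aw
                dist_rows.append({
                    "species": c.focal, "metric": metric, "grain": "small",
                    "rarefied": rarefied, "log_transformed": logt,
                    "value": float(np.log(val)) if logt else val,
                })
            regional = [s for s in pool if s != c.focal]
            for metric in LARGE_METRICS:
                val = focal_distinctiveness(D, c.focal, regional, metric=metric)
                dist_rows.append({
                    "species": c.focal, "metric": metric, "grain": "large",
                    "rarefied": False, "log_transformed": False, "value": val,
                })
        distinct_table = pd.DataFrame(dist_rows)
        bundle["distinctiveness"] = distinct_table

    with _stage("traits"):
        screen = correlation_screen(traits, config.correlation_threshold)
        bundle["trait_screen"] = screen
        signal_rows = []
        for t in traits.continuous_traits():
            col = traits.data[t].dropna()
            res = blombergs_K(tree, col.to_dict(),
                              n_perm=config.signal_n_perm,
                              seed=spawn_seed(config.seed, "K", t))
            signal_rows.append({"trait": t, "statistic": "K", "value": res.value,
                                "p_value": res.p_value, "p_secondary": np.nan,
                                "n_perm": res.n_perm})
        binary_like = [t for t in traits.traits if traits.kinds[t] == "binary"]
        for t in binary_like:
            col = traits.data[t].dropna()
            if col.nunique() < 2:
                continue
            res = fritz_purvis_D(tree, col.astype(int).to_dict(),
                                 n_sim=max(config.signal_n_perm, 100),
                                 seed=spawn_seed(config.seed, "D", t))
            signal_rows.append({"trait": t, "statistic": "D", "value": res.value,
                                "p_value": res.p_value,
                                "p_secondary": res.p_value_secondary,
                                "n_perm": res.n_perm})
        circ = [t for t in traits.traits if traits.kinds[t] == "circular_month"]
        for t in circ:
            sub = traits.data[t].dropna()
            FD = gower_distance(traits.subset_species(list(sub.index)), traits=[t])
            PDt = D.submatrix(list(sub.index))
            res = mantel_test(PDt, FD, n_perm=config.signal_n_perm,
                              seed=spawn_seed(config.seed, "mantel", t))
            signal_rows.append({"trait": t, "statistic": "mantel_r",
                                "value": res.value, "p_value": res.p_value,
                                "p_secondary": np.nan, "n_perm": res.n_perm})
        FD_all = gower_distance(traits)
        res = mantel_test(D.submatrix(list(traits.species)), FD_all,
                          n_perm=config.signal_n_perm,
                          seed=spawn_seed(config.seed, "mantel", "all"))
        signal_rows.append({"trait": "all_traits", "statistic": "mantel_r",
                            "value": res.value, "p_value": res.p_value,
                            "p_secondary": np.nan, "n_perm": res.n_perm})
        signal_table = pd.DataFrame(signal_rows)
        bundle["signal_tests"] = signal_table

    with _stage("regressions"):
        sp_biomass = biomass_df.groupby("species")["biomass"].mean()
        bm = np.array([sp_biomass[sp] for sp in focals])
        y = lambda_table.loc[focals, "effect_size"].to_numpy()
        E = draw_table.loc[focals].to_numpy()
        reg_rows, draw_rows = [], []
        combos = ([("small", m) for m in SMALL_METRICS]
                  + [("large", m) for m in LARGE_METRICS])
        for grain, metric in combos:
            sub = distinct_table[(distinct_table["grain"] == grain)
                                 & (distinct_table["metric"] == metric)]
            dv = sub.set_index("species").loc[focals, "value"].to_numpy()
            obs = DistinctivenessRegression(y, dv, bm).fit()
            boot = bootstrap_regression(E, dv, bm, n_boot=config.n_boot,
                                        seed=spawn_seed(config.seed, "reg", metric, grain))
            for param in ("distinctiveness", "adj_r2"):
                observed = obs.adj_r2 if param == "adj_r2" else obs.params[param]
                reg_rows.append({
                    "grain": grain, "metric": metric, "parameter": param,
                    "observed": float(observed),
                    "lower": float(boot.ci.loc[param, "lower"]),
                    "upper": float(boot.ci.loc[param, "upper"]),
                })
            bd = boot.bootstrap_draws.copy()
            bd.insert(0, "rep", np.arange(len(bd)))
            bd.insert(0, "metric", metric)
            bd.insert(0, "grain", grain)
            draw_rows.append(bd)
        reg_table = pd.DataFrame(reg_rows)
        coef_draws = pd.concat(draw_rows, ignore_index=True)
        bundle["regressions"] = reg_table
        bundle["coef_draws"] = coef_draws

    with _stage("fpd_sweep"):
        comm_map = {c.focal: list(c.members) for c in communities}
        trait_species = set(traits.species)
        usable = {sp: [m for m in ms if m in trait_species]
                  for sp, ms in comm_map.items() if sp in trait_species}
        FD_sweep = gower_distance(traits, traits=[t for t in config.sweep_traits
                                                  if t in traits.traits])
        eff = {sp: float(lambda_table.loc[sp, "effect_size"]) for sp in focals}
        bmmap = {sp: float(sp_biomass[sp]) for sp in focals}
        sweep = sweep_a(D, FD_sweep,
                        {sp: ms for sp, ms in usable.items() if len(ms) >= 2},
                        eff, bmmap, metric=config.sweep_metric,
                        a_step=config.a_step)
        bundle["sweep"] = sweep

    with _stage("write"):
        writes = {
            "lambda_effects.tsv": lambda_table.reset_index(),
            "effect_draws.tsv": draw_table.reset_index(names="species"),
            "distinctiveness.tsv": distinct_table,
            "signal_tests.tsv": signal_table,
            "regressions.tsv": reg_table,
            "coef_draws.tsv": coef_draws,
            "sweep.tsv": sweep.table,
        }
        for name, df in writes.items():
            df.to_csv(out / name, sep="\t", index=False)
            manifest["outputs"].append(name)
        manifest["best_a"] = sweep.best_a
        manifest["best_adj_r2"] = sweep.best_adj_r2
        manifest["seed"] = config.seed
        manifest["status"] = "complete"
        import fpdemog

        manifest["version"] = getattr(fpdemog, "__version__", "unknown")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        manifest["outputs"].append("manifest.json")

    return bundle


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

REQUIRED_TABLES = ["regressions.tsv", "coef_draws.tsv", "sweep.tsv"]


def make_report(run_dir) -> dict[str, Path]:
    """Figures + text summary from a completed pipeline run.

    Produces one coefficient histogram per metric x grain, the adjusted
    R^2 curve along the weighting-parameter grid, and a text summary in
    the shape of a coefficients-and-CI table.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    missing = [t for t in REQUIRED_TABLES if not (run_dir / t).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete result bundle; missing {missing}")
    reg = pd.read_csv(run_dir / "regressions.tsv", sep="\t")
    draws = pd.read_csv(run_dir / "coef_draws.tsv", sep="\t")
    sweep = pd.read_csv(run_dir / "sweep.tsv", sep="\t")
    figdir = run_dir / "figures"
    figdir.mkdir(exist_ok=True)
    outputs: dict[str, Path] = {}

    for (grain, metric), grp in draws.groupby(["grain", "metric"]):
        vals = grp["distinctiveness"].to_numpy()
        fig, ax = plt.subplots(figsize=(4, 3))
        if len(vals) and np.ptp(vals) > 0:
            ax.hist(vals, bins=30, color="steelblue")
        elif len(vals) == 0:
            logger.warning("no bootstrap draws for %s/%s; histogram skipped",
                           grain, metric)
            plt.close(fig)
            continue
        else:
            ax.hist(vals, bins=1, color="steelblue")
        ax.axvline(0.0, color="red", lw=1)
        ax.set_xlabel(f"{metric} coefficient ({grain} grain)")
        ax.set_ylabel("bootstrap count")
        fig.tight_layout()
        p = figdir / f"hist_{metric}_{grain}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        outputs[f"hist_{metric}_{grain}"] = p

    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(sweep["a"], sweep["adj_r2"], marker="o", ms=2.5)
    ax.set_xlabel("phylogenetic weight a")
    ax.set_ylabel("adjusted R$^2$")
    fig.tight_layout()
    p = figdir / "r2_curve.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    outputs["r2_curve"] = p

    lines = ["grain\tmetric\tparameter\tobserved\tlower CI\tupper CI"]
    for _, row in reg.iterrows():
        lines.append(
            f"{row['grain']}\t{row['metric']}\t{row['parameter']}\t"
            f"{row['observed']:.5f}\t{row['lower']:.5f}\t{row['upper']:.5f}"
        )
    best = sweep.loc[sweep["adj_r2"].idxmax()]
    lines.append("")
    lines.append(f"best a = {best['a']:.3f} with adj R^2 = {best['adj_r2']:.3f}")
    summary = run_dir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    outputs["summary"] = summary
    return outputs
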