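"""Delimited-text readers and writers for scenario and pipeline data.

Everything is tab-separated plain text so that runs are diffable and
reproducible; the only non-tabular format is Newick for trees.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .demography import SpeciesModelSpec
from .simulate import CommunitySample, ScenarioBundle
from .traits import read_traits, write_traits
from .tree import read_newick, write_newick

__all__ = [
    "write_scenario",
    "read_communities",
    "write_communities",
    "read_species_specs",
    "write_species_specs",
    "read_census",
    "read_biomass",
]

CENSUS_COLUMNS = [
    "individual_id", "species", "treatment", "plot_id",
    "stage_t", "stage_t1", "size_t", "size_t1", "surv", "repro_count", "year",
]


def write_communities(samples: list[CommunitySample], path) -> None:
    rows = []
    for s in samples:
        for m in s.members:
            c = s.cover.get(m, np.nan)
            rows.append({
                "focal": s.focal, "grain": s.grain, "member": m,
                "cover": "" if not np.isfinite(c) else c,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_communities(path) -> list[CommunitySample]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (focal, grain), grp in df.groupby(["focal", "grain"], sort=False):
        members = tuple(grp["member"])
        cover = {
            m: (float(c) if pd.notna(c) else float("nan"))
            for m, c in zip(grp["member"], grp["cover"])
        }
        out.append(CommunitySample(str(focal), members, cover, grain=str(grain)))
    return out


def write_species_specs(specs: dict[str, SpeciesModelSpec], path) -> None:
    rows = []
    for sp, spec in specs.items():
        rows.append({
            "species": sp,
            "kind": spec.kind,
            "stages": ";".join(spec.stages),
            "fecundity_map": ";".join(f"{k}:{v}" for k, v in spec.fecundity_map.items()),
            "meshpoints": spec.meshpoints,
            "bounds_lo": "" if spec.bounds is None else spec.bounds[0],
            "bounds_hi": "" if spec.bounds is None else spec.bounds[1],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_species_specs(path) -> dict[str, SpeciesModelSpec]:
    df = pd.read_csv(path, sep="\t")
    specs = {}
    for _, row in df.iterrows():
        fmap = {}
        if isinstance(row.get("fecundity_map"), str) and row["fecundity_map"]:
            for part in row["fecundity_map"].split(";"):
                k, v = part.split(":")
                fmap[k] = v
        bounds = None
        if pd.notna(row.get("bounds_lo")) and str(row.get("bounds_lo")) != "":
            bounds = (float(row["bounds_lo"]), float(row["bounds_hi"]))
        stages = tuple(str(row["stages"]).split(";")) if pd.notna(row.get("stages")) and str(row["stages"]) else ()
        specs[str(row["species"])] = SpeciesModelSpec(
            kind=str(row["kind"]), stages=stages, fecundity_map=fmap,
            meshpoints=int(row["meshpoints"]) if pd.notna(row.get("meshpoints")) else 500,
            bounds=bounds,
        )
    return specs


def read_census(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"stage_t": "string", "stage_t1": "string"})
    missing = set(CENSUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"census file lacks columns: {sorted(missing)}")
    df["stage_t"] = df["stage_t"].astype(object).where(df["stage_t"].notna(), None)
    df["stage_t1"] = df["stage_t1"].astype(object).where(df["stage_t1"].notna(), None)
    return df


def read_biomass(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"species", "plot_id", "biomass"}
    if not need <= set(df.columns):
        raise ValueError(f"biomass file lacks columns: {sorted(need - set(df.columns))}")
    return df


def write_scenario(bundle: ScenarioBundle, out_dir) -> dict[str, Path]:
    """Write a complete scenario as plain-text files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "traits": out / "traits.tsv",
        "communities": out / "communities.tsv",
        "census": out / "census.tsv",
        "biomass": out / "biomass.tsv",
        "species_specs": out / "species_specs.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_newick(bundle.tree, paths["tree"])
    write_traits(bundle.traits, paths["traits"])
    write_communities(bundle.communities, paths["communities"])
    census = bundle.demography.census.reindex(columns=CENSUS_COLUMNS)
    census.to_csv(paths["census"], sep="\t", index=False)
    bundle.demography.biomass.to_csv(paths["biomass"], sep="\t", index=False)
    write_species_specs(bundle.demography.model_specs, paths["species_specs"])
    bundle.demography.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
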