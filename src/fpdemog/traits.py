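"""Species-by-trait tables and mixed-type (Gower-style) trait distances.

Traits come in four kinds:

``continuous``
    measured values in arbitrary units (e.g. SLA in mm^2/mg, height in
    m, leaf toughness in N, wood density in g/cm^3); dissimilarity is
    the absolute difference divided by the observed range.
``circular_month``
    month of first flowering, 1-12; dissimilarity is the shorter way
    around the annual circle divided by 6 (the largest possible
    circular gap), so January and December differ by 1/6, not 11/11.
``binary``
    0/1; simple mismatch.
``categorical``
    labels, expanded to 0/1 dummy variables; the trait's weight is
    split equally over its dummies so a categorical trait counts as a
    single trait.

Per-pair distance is the weighted mean of per-trait dissimilarities
over traits observed in BOTH species (pairwise deletion with
renormalized weights), and always lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = [
    "TRAIT_KINDS",
    "TraitTable",
    "gower_distance",
    "correlation_screen",
    "read_traits",
    "write_traits",
]

TRAIT_KINDS = ("continuous", "circular_month", "binary", "categorical")


@dataclass
class TraitTable:
    """Species x trait values plus a kind annotation per trait.

    ``data`` is indexed by species name; missing values are NaN (or
    None for categorical labels).
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.kinds.values()) - set(TRAIT_KINDS)
        if unknown:
            raise ValueError(f"unknown trait kind(s): {sorted(unknown)}")
        missing = set(self.data.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"traits without kind annotation: {sorted(missing)}")
        for trait, kind in self.kinds.items():
            if trait not in self.data.columns:
                raise ValueError(f"kind given for absent trait {trait!r}")
            col = self.data[trait]
            if kind == "circular_month":
                vals = col.dropna()
                if not vals.between(1, 12).all():
                    raise ValueError(f"circular trait {trait!r} has values outside 1..12")
            elif kind == "binary":
                vals = col.dropna()
                if not vals.isin([0, 1]).all():
                    raise ValueError(f"binary trait {trait!r} has values outside {{0,1}}")

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def continuous_traits(self) -> list[str]:
        return [t for t in self.traits if self.kinds[t] == "continuous"]

    def subset_species(self, species) -> "TraitTable":
        return TraitTable(self.data.loc[list(species)].copy(), dict(self.kinds))


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------

def _trait_components(table: TraitTable, trait: str):
    """Yield (dissimilarity matrix, missing mask, weight fraction) parts."""
    kind = table.kinds[trait]
    col = table.data[trait]
    if kind == "categorical":
        labels = col.astype(object)
        observed = labels.dropna().unique()
        cats = sorted(str(c) for c in observed)
        if not cats:
            return
        miss = labels.isna().to_numpy()
        for cat in cats:
            x = (labels.astype(str) == cat).to_numpy(dtype=float)
            x[miss] = np.nan
            dis = np.abs(x[:, None] - x[None, :])
            yield dis, miss, 1.0 / len(cats)
        return
    x = col.to_numpy(dtype=float)
    miss = np.isnan(x)
    diff = np.abs(x[:, None] - x[None, :])
    if kind == "continuous":
        span = np.nanmax(x) - np.nanmin(x)
        if not span > 0:
            return  # zero observed range: range-normalization undefined
        dis = diff / span
    elif kind == "circular_month":
        dis = np.minimum(diff, 12.0 - diff) / 6.0
    else:  # binary
        dis = diff
    yield dis, miss, 1.0


def gower_distance(
    table: TraitTable,
    traits: list[str] | None = None,
    weights: dict[str, float] | None = None,
) -> DistanceMatrix:
    """Mixed-type trait distance matrix over all species in ``table``.

    ``traits`` restricts the calculation to a subset of columns (all by
    default); ``weights`` assigns per-trait weights (1 by default).
    Raises if some pair of species shares no observed trait.
    """
    traits = list(traits) if traits is not None else table.traits
    if len(table.species) < 2:
        raise ValueError("need >= 2 species")
    unknown = set(traits) - set(table.traits)
    if unknown:
        raise KeyError(f"traits not in table: {sorted(unknown)}")
    if not traits:
        raise ValueError("no traits selected")
    n = len(table.species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    coverage = np.zeros((n, n))  # counts shared observed traits, informative or not
    for trait in traits:
        w = 1.0 if weights is None else float(weights.get(trait, 1.0))
        if w < 0:
            raise ValueError(f"negative weight for trait {trait!r}")
        obs = ~table.data[trait].isna().to_numpy()
        coverage += np.outer(obs, obs)
        for dis, miss, frac in _trait_components(table, trait):
            ok = ~(miss[:, None] | miss[None, :])
            num[ok] += w * frac * dis[ok]
            den[ok] += w * frac
    bad = coverage == 0
    np.fill_diagonal(bad, False)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "no shared observed traits for pair "
            f"({table.species[i]!r}, {table.species[j]!r})"
        )
    with np.errstate(invalid="ignore"):
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(tuple(table.species), vals, "raw")


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenDecision:
    trait_a: str
    trait_b: str
    r: float
    dropped: str | None


@dataclass
class ScreenReport:
    retained: list[str]
    dropped: list[str]
    constant: list[str]
    pairs: list[ScreenDecision]


def correlation_screen(table: TraitTable, threshold: float = 0.8) -> ScreenReport:
    """Drop redundant continuous traits by pairwise Pearson correlation.

    Traits are examined in table order; from any pair with
    ``|r| > threshold`` the later-listed trait is dropped.  Constant
    traits (correlation undefined) are flagged and excluded.  Returns a
    report listing every pair examined and the decision taken.
    """
    cont = table.continuous_traits()
    if len(cont) < 2:
        raise ValueError("correlation screen needs >= 2 continuous traits")
    constant = [
        t for t in cont if table.data[t].dropna().nunique() <= 1
    ]
    candidates = [t for t in cont if t not in constant]
    retained: list[str] = []
    dropped: list[str] = []
    pairs: list[ScreenDecision] = []
    for t in candidates:
        drop = False
        for kept in retained:
            sub = table.data[[kept, t]].dropna()
            r = float(sub[kept].corr(sub[t]))
            decision = t if abs(r) > threshold else None
            pairs.append(ScreenDecision(kept, t, r, decision))
            if decision is not None:
                drop = True
        (dropped if drop else retained).append(t)
    return ScreenReport(retained, dropped, constant, pairs)


# ---------------------------------------------------------------------------
# I/O: delimited text with a trait-kind header block
# ---------------------------------------------------------------------------

def write_traits(table: TraitTable, path) -> None:
    with open(path, "w") as fh:
        for trait in table.traits:
            fh.write(f"# kind\t{trait}\t{table.kinds[trait]}\n")
        table.data.to_csv(fh, sep="\t", index_label="species")


def read_traits(path) -> TraitTable:
    kinds: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# kind\t"):
            _, trait, kind = line.rstrip("\n").split("\t")
            kinds[trait] = kind
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col="species")
    df.index.name = None
    return TraitTable(df, kinds)
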