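"""Focal-species distinctiveness relative to a community.

Four metrics are supported, all measured from a focal species to the
members of its co-occurring community on a (typically square-root
transformed) cophenetic or combined distance matrix:

``MPD``
    mean pairwise distance from the focal to community members;
``NND``
    distance to the nearest neighbour (the minimum);
``AW_MPD``
    abundance-weighted mean, weighting members by relative percent
    cover;
``AW_NND``
    nearest-neighbour distance restricted to members with recorded
    cover.  A minimum cannot be abundance-weighted without an arbitrary
    rule, so weights enter only through which species are eligible;
    this choice is exposed via ``aw_nnd_strategy``.

Rarefied versions resample ``k`` community members without replacement
and average the metric over draws, removing richness effects when
communities of different sizes are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from ._rng import substream

__all__ = [
    "METRICS",
    "DistinctivenessValue",
    "focal_distinctiveness",
    "rarefied_distinctiveness",
]

METRICS = ("MPD", "NND", "AW_MPD", "AW_NND")


@dataclass(frozen=True)
class DistinctivenessValue:
    species: str
    metric: str
    grain: str
    value: float
    rarefied: bool = False
    log_transformed: bool = False


def _check_inputs(D, focal, community, weights, metric):
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    community = list(community)
    if not community:
        raise ValueError("empty community")
    if focal in community:
        raise ValueError("focal species must not appear in its own community")
    if metric.startswith("AW_"):
        if weights is None:
            raise ValueError(f"{metric} requires abundance weights")
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(community),):
            raise ValueError("weights must align with community members")
        if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
            raise ValueError("weights must be positive and finite")
    return community, weights


def focal_distinctiveness(
    D: DistanceMatrix,
    focal: str,
    community,
    weights=None,
    metric: str = "MPD",
) -> float:
    """Distinctiveness of ``focal`` with respect to ``community``.

    ``weights`` are percent covers (any positive scale; they are
    normalized internally) aligned with ``community``, required for the
    abundance-weighted metrics and ignored otherwise.
    """
    community, weights = _check_inputs(D, focal, community, weights, metric)
    d = D.distances_from(focal, community)
    if metric == "MPD":
        return float(d.mean())
    if metric == "NND":
        return float(d.min())
    if metric == "AW_MPD":
        w = weights / weights.sum()
        return float(np.dot(w, d))
    # AW_NND: weights determine eligibility only (see module docstring)
    return float(d.min())


def rarefied_distinctiveness(
    D: DistanceMatrix,
    focal: str,
    community,
    k: int = 11,
    n_reps: int = 1000,
    metric: str = "NND",
    seed: int = 0,
    weights=None,
) -> float:
    """Mean of ``metric`` over ``n_reps`` uniform draws of ``k`` members.

    Subsets are drawn without replacement; with ``|community| == k``
    every draw is the whole community and the exact metric is returned.
    """
    community, weights = _check_inputs(D, focal, community, weights, metric)
    m = len(community)
    if m < k:
        raise ValueError(f"community of size {m} cannot be rarefied to k={k}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    d = D.distances_from(focal, community)
    if m == k:
        return _metric_on(d, weights, metric)
    rng = substream(seed, "rarefy", focal, metric)
    # vectorized k-subsets without replacement: first k of a random order
    keys = rng.random((n_reps, m))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    sub = d[idx]  # (n_reps, k)
    if metric == "MPD":
        vals = sub.mean(axis=1)
    elif metric in ("NND", "AW_NND"):
        vals = sub.min(axis=1)
    else:  # AW_MPD
        w = weights[idx]
        vals = (sub * w).sum(axis=1) / w.sum(axis=1)
    return float(vals.mean())


def _metric_on(d: np.ndarray, weights, metric: str) -> float:
    if metric == "MPD":
        return float(d.mean())
    if metric in ("NND", "AW_NND"):
        return float(d.min())
    w = weights / weights.sum()
    return float(np.dot(w, d))
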