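"""Phylogenetic signal diagnostics for traits.

Three complementary statistics are provided:

* :func:`blombergs_K` for continuous traits.  K compares the observed
  ratio of tip variance to phylogenetically corrected variance with its
  expectation under Brownian motion on the same tree; K ~ 1 indicates
  Brownian-like signal, K << 1 no signal.  Significance comes from
  tip-label permutations of the variance ratio.
* :func:`fritz_purvis_D` for binary traits.  D rescales the sum of
  state changes at internal nodes so that Brownian-threshold evolution
  gives D ~ 0 and phylogenetic randomness gives D ~ 1; clumping beyond
  Brownian expectation drives D below 0.
* :func:`mantel_test` for anything expressible as a distance matrix
  (e.g. the circular flowering-month distance vs the square-root
  cophenetic distance, or a full multi-trait Gower matrix).

All permutation p-values use the add-one correction
``(1 + #extreme) / (n_perm + 1)`` so that p is never exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from .tree import PhyloTree
from ._rng import substream

__all__ = [
    "SignalResult",
    "phylo_vcv",
    "simulate_bm",
    "blombergs_K",
    "fritz_purvis_D",
    "mantel_test",
]


@dataclass(frozen=True)
class SignalResult:
    trait: str
    statistic: str  # "K", "D" or "mantel_r"
    value: float
    p_value: float
    n_perm: int
    p_value_secondary: float | None = None


# ---------------------------------------------------------------------------
# Brownian-motion machinery
# ---------------------------------------------------------------------------

def phylo_vcv(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Phylogenetic variance-covariance matrix.

    ``C[i, j]`` is the shared root-to-MRCA path length of tips i and j;
    the diagonal holds root-to-tip depths.
    """
    dtree = tree.dendropy_tree
    labels = tree.tip_labels
    pos = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depth_cache: dict[int, float] = {}
    tipsets: dict[int, list[int]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = pos[node.taxon.label]
            tipsets[id(node)] = [i]
            C[i, i] = node.distance_from_root()
        else:
            d = node.distance_from_root()
            depth_cache[id(node)] = d
            child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = np.asarray(child_sets[a])
                    ib = np.asarray(child_sets[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            tipsets[id(node)] = [i for s in child_sets for i in s]
    return labels, C


def simulate_bm(
    tree: PhyloTree, rng: np.random.Generator, n_reps: int = 1, sigma2: float = 1.0
) -> tuple[list[str], np.ndarray]:
    """Simulate Brownian-motion tip values; returns (labels, (n_tips, n_reps))."""
    labels, C = phylo_vcv(tree)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))
    z = rng.standard_normal((len(labels), n_reps))
    return labels, np.sqrt(sigma2) * (L @ z)


def _align(tree: PhyloTree, trait: dict[str, float]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels, C = phylo_vcv(tree)
    matched = [lab for lab in labels if lab in trait]
    if len(matched) < 4:
        raise ValueError("need >= 4 species matched between tree and trait")
    if len(matched) < len(labels):
        idx = [labels.index(lab) for lab in matched]
        C = C[np.ix_(idx, idx)]
    x = np.array([float(trait[lab]) for lab in matched])
    return x, C, matched


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def _variance_ratio(X: np.ndarray, Cinv: np.ndarray, ones_Cinv: np.ndarray,
                    denom: float) -> tuple[np.ndarray, np.ndarray]:
    """MSE0 and MSE (columns of X are trait vectors)."""
    n = X.shape[0]
    ahat = (ones_Cinv @ X) / denom
    R = X - ahat
    mse0 = (R * R).sum(axis=0) / (n - 1)
    mse = (R * (Cinv @ R)).sum(axis=0) / (n - 1)
    return mse0, mse


def blombergs_K(
    tree: PhyloTree,
    trait: dict[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K is the observed MSE0/MSE ratio (variance about the
    phylogenetically corrected mean over phylogenetically corrected
    variance) divided by its Brownian-motion expectation on this tree.
    The p-value is the add-one-corrected share of tip permutations with
    phylogenetic mean squared error no larger than observed (signal
    shows up as low MSE).
    """
    x, C, matched = _align(tree, trait)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; K undefined")
    n = len(x)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    ones_Cinv = ones @ Cinv
    denom = float(ones_Cinv @ ones)
    mse0, mse = _variance_ratio(x[:, None], Cinv, ones_Cinv, denom)
    expected = (np.trace(C) - n / denom) / (n - 1)
    K = float((mse0[0] / mse[0]) / expected)

    rng = substream(seed, "blombergK", n, n_perm)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = x[rng.permutation(n)]
    _, mse_perm = _variance_ratio(perms, Cinv, ones_Cinv, denom)
    p = (1 + int((mse_perm <= mse[0]).sum())) / (n_perm + 1)
    return SignalResult("", "K", K, float(p), n_perm)


# ---------------------------------------------------------------------------
# Fritz-Purvis D
# ---------------------------------------------------------------------------

def _tree_arrays(tree: PhyloTree) -> tuple[list[str], list[tuple[int, list[int]]], int]:
    """Flatten the tree: postorder list of (node_index, child indices)."""
    dtree = tree.dendropy_tree
    labels = tree.tip_labels
    pos = {lab: k for k, lab in enumerate(labels)}
    index: dict[int, int] = {}
    order: list[tuple[int, list[int]]] = []
    next_idx = len(labels)
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            index[id(node)] = pos[node.taxon.label]
        else:
            index[id(node)] = next_idx
            order.append((next_idx, [index[id(c)] for c in node.child_nodes()]))
            next_idx += 1
    return labels, order, next_idx


def _sum_state_changes(states: np.ndarray, order, n_total: int) -> np.ndarray:
    """Sum over edges of |estimated state change| for each trait column.

    Internal states are the unweighted mean of child states, estimated
    tip-to-root; the statistic adds |parent - child| over every edge.
    """
    n_tips, n_cols = states.shape
    node = np.zeros((n_total, n_cols))
    node[:n_tips] = states
    total = np.zeros(n_cols)
    for idx, children in order:
        vals = node[children]
        node[idx] = vals.mean(axis=0)
        total += np.abs(vals - node[idx]).sum(axis=0)
    return total


def fritz_purvis_D(
    tree: PhyloTree,
    trait: dict[str, int],
    n_sim: int = 1000,
    seed: int = 0,
) -> SignalResult:
    """Fritz-Purvis D for a binary trait.

    D rescales the observed sum of estimated state changes against two
    reference distributions with matched prevalence: Brownian-threshold
    simulations (D = 0 on average) and random tip shuffles (D = 1 on
    average).  ``p_value`` is the share of shuffle simulations at least
    as clumped as observed (tests signal vs randomness);
    ``p_value_secondary`` is the share of Brownian simulations at least
    as dispersed as observed (tests departure from Brownian clumping).
    """
    x, C, matched = _align(tree, {k: float(v) for k, v in trait.items()})
    if not set(np.unique(x)) == {0.0, 1.0}:
        raise ValueError("trait must be binary with both states present")
    sub = tree if len(matched) == len(tree.tip_labels) else None
    if sub is None:
        from .tree import prune_to

        sub = prune_to(tree, matched)
    labels, order, n_total = _tree_arrays(sub)
    obs = np.array([float(trait[lab]) for lab in labels])
    k = int(obs.sum())
    d_obs = float(_sum_state_changes(obs[:, None], order, n_total)[0])

    rng = substream(seed, "fritzD", len(labels), n_sim)
    # random reference: tip shuffles
    shuf = np.empty((len(labels), n_sim))
    for b in range(n_sim):
        shuf[:, b] = obs[rng.permutation(len(labels))]
    d_rand = _sum_state_changes(shuf, order, n_total)
    # Brownian reference: threshold latent BM at the observed prevalence
    _, latent = simulate_bm(sub, rng, n_reps=n_sim)
    # top-k latent values per column become state 1
    thresh_idx = np.argpartition(-latent, k - 1, axis=0)[:k]
    bm_states = np.zeros_like(latent)
    np.put_along_axis(bm_states, thresh_idx, 1.0, axis=0)
    d_bm = _sum_state_changes(bm_states, order, n_total)

    mean_r, mean_b = float(d_rand.mean()), float(d_bm.mean())
    if mean_r == mean_b:
        raise ValueError("degenerate reference distributions; tree too small")
    D = (d_obs - mean_b) / (mean_r - mean_b)
    p_rand = (1 + int((d_rand <= d_obs).sum())) / (n_sim + 1)
    p_bm = (1 + int((d_bm >= d_obs).sum())) / (n_sim + 1)
    return SignalResult("", "D", float(D), float(p_rand), n_sim, p_value_secondary=float(p_bm))


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of strictly-lower-triangle entries;
    the p-value permutes the labels of ``D2`` and counts permuted r at
    least as large as observed (one-tailed, add-one corrected).
    """
    if set(D1.labels) != set(D2.labels):
        raise ValueError("matrices must share the same label set")
    if len(D1) < 4:
        raise ValueError("need >= 4 labels")
    D2 = D2.submatrix(list(D1.labels))
    n = len(D1)
    i, j = np.tril_indices(n, k=-1)
    v1 = D1.values[i, j]
    B = D2.values
    v2 = B[i, j]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("zero-variance distance triangle; r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = substream(seed, "mantel", n, n_perm)
    v1c = v1 - v1.mean()
    s1 = np.sqrt((v1c**2).sum())
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        v2p = B[p[:, None], p[None, :]][i, j]
        v2c = v2p - v2p.mean()
        r_p = float((v1c @ v2c) / (s1 * np.sqrt((v2c**2).sum())))
        if r_p >= r_obs:
            count += 1
    p_val = (1 + count) / (n_perm + 1)
    return SignalResult("", "mantel_r", r_obs, float(p_val), n_perm)
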