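"""Rooted ultrametric phylogenies: I/O, pruning, congeneric grafting,
cophenetic distances and pure-birth simulation.

Trees are carried as :class:`PhyloTree`, a thin wrapper around a
:class:`dendropy.Tree` that enforces the conventions used throughout
the package: unique ``Genus_species`` tip labels, branch lengths on
every edge, and (for simulated trees) ultrametricity.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .distance import DistanceMatrix
from ._rng import substream

__all__ = [
    "PhyloTree",
    "read_newick",
    "write_newick",
    "prune_to",
    "congeneric_merge",
    "cophenetic_matrix",
    "simulate_phylogeny",
]


class PhyloTree:
    """A rooted tree with branch lengths and binomial-style tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise ValueError("tree has unlabelled tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges without branch lengths")
            if edge.length < 0:
                raise ValueError("negative branch length")

    # -- basic structure ---------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        out = {}
        for leaf in self._tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        return max(self.tip_depths().values())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(depths) <= tol * max(depths.max(), 1.0))

    def genus_of(self, species: str) -> str:
        return species.split("_", 1)[0]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- I/O ---------------------------------------------------------------
    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"could not parse Newick: {exc}") from exc
        tree.is_rooted = True
        return cls(tree)

    def __repr__(self) -> str:
        return f"<PhyloTree with {self.n_tips} tips, depth {self.depth:.4g}>"


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())


# ---------------------------------------------------------------------------
# pruning and grafting
# ---------------------------------------------------------------------------

def prune_to(tree: PhyloTree, species) -> PhyloTree:
    """Prune to a subset of tips, preserving pairwise cophenetic distances."""
    species = list(dict.fromkeys(species))
    present = set(tree.tip_labels)
    unknown = sorted(set(species) - present)
    if unknown:
        raise KeyError(f"species not in tree: {unknown}")
    if len(species) < 2:
        raise ValueError("pruning to fewer than 2 species leaves distances undefined")
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(
        labels=species, suppress_unifurcations=True
    )
    return PhyloTree(sub)


@dataclass
class MergeReport:
    """Outcome of a congeneric merge: which species were grafted, already
    present, or could not be placed for lack of a congener."""

    added: list[str]
    already_present: list[str]
    unplaceable: list[str]


def congeneric_merge(tree: PhyloTree, species) -> tuple[PhyloTree, MergeReport]:
    """Graft missing species next to their congeners.

    A species with two or more congeners in the tree is attached at the
    crown node (MRCA) of those congeners, with pendant length equal to
    that node's height, so ultrametricity is preserved.  With a single
    congener the new tip is attached at the midpoint of the congener's
    pendant edge with a matching pendant length.  Species with no
    congener are reported as unplaceable, never silently dropped.
    """
    work = tree.copy()
    dtree = work.dendropy_tree
    added, present_already, unplaceable = [], [], []
    for sp in species:
        tips = {leaf.taxon.label for leaf in dtree.leaf_node_iter()}
        if sp in tips:
            present_already.append(sp)
            continue
        genus = sp.split("_", 1)[0]
        congeners = [lab for lab in tips if lab.split("_", 1)[0] == genus]
        if not congeners:
            unplaceable.append(sp)
            continue
        taxon = dtree.taxon_namespace.require_taxon(label=sp)
        if len(congeners) == 1:
            leaf = next(
                l for l in dtree.leaf_node_iter() if l.taxon.label == congeners[0]
            )
            half = leaf.edge.length / 2.0
            parent = leaf.parent_node
            mid = dendropy.Node(edge_length=leaf.edge.length - half)
            parent.add_child(mid)
            parent.remove_child(leaf)
            leaf.edge.length = half
            mid.add_child(leaf)
            mid.new_child(taxon=taxon, edge_length=half)
        else:
            mrca = dtree.mrca(taxon_labels=congeners)
            height = max(
                leaf.distance_from_root() for leaf in mrca.leaf_iter()
            ) - mrca.distance_from_root()
            mrca.new_child(taxon=taxon, edge_length=height)
        added.append(sp)
    out = PhyloTree(dtree)
    return out, MergeReport(added, present_already, unplaceable)


# ---------------------------------------------------------------------------
# cophenetic distances
# ---------------------------------------------------------------------------

def cophenetic_matrix(tree: PhyloTree, transform: str = "raw") -> DistanceMatrix:
    """All-pairs tip-to-tip path-length (cophenetic) distances.

    ``transform="sqrt"`` applies an element-wise square root, the scale
    used when phylogenetic distances are combined with trait distances.
    """
    if tree.n_tips < 2:
        raise ValueError("need >= 2 tips for a distance matrix")
    if transform not in ("raw", "sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    labels = tree.tip_labels
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            vals[i, j] = vals[j, i] = d
    dm = DistanceMatrix(tuple(labels), vals, "raw")
    return dm.sqrt_transform() if transform == "sqrt" else dm


# ---------------------------------------------------------------------------
# pure-birth (Yule) simulation
# ---------------------------------------------------------------------------

def simulate_phylogeny(
    n_tips: int,
    seed: int,
    depth: float = 100.0,
    congener_fraction: float = 0.3,
) -> PhyloTree:
    """Simulate an ultrametric pure-birth tree with congener structure.

    A Yule process with unit speciation rate is run forward until
    ``n_tips`` lineages exist, then all pendant branches are extended by
    one further exponential waiting time and the whole tree is rescaled
    to the requested root-to-tip ``depth`` (default 100, the order of
    Myr-deep angiosperm phylogenies).  Approximately
    ``congener_fraction`` of tips are labelled as congeners sharing a
    genus within small clades, enabling congeneric grafting; remaining
    tips receive unique genera.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if not 0.0 <= congener_fraction <= 1.0:
        raise ValueError("congener_fraction must lie in [0, 1]")
    rng = substream(seed, "yule", n_tips)

    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)
    root = dtree.seed_node
    birth: dict[dendropy.Node, float] = {}
    t = 0.0
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = root.new_child()
        birth[child] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - birth[node]
        for _ in range(2):
            child = node.new_child()
            birth[child] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length = t - birth[node]

    # rescale to the requested depth
    scale = depth / t
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale

    _assign_labels(dtree, rng, congener_fraction)
    dtree.is_rooted = True
    return PhyloTree(dtree)


def _assign_labels(dtree: dendropy.Tree, rng: np.random.Generator,
                   congener_fraction: float) -> None:
    """Binomial-style labels: small clades may share a genus."""
    leaves = dtree.leaf_nodes()
    n = len(leaves)
    target = int(round(congener_fraction * n))
    # candidate clades of 2-3 tips, disjoint, in randomized order
    clades = []
    for node in dtree.postorder_internal_node_iter():
        tips = node.leaf_nodes()
        if 2 <= len(tips) <= 3:
            clades.append(tips)
    order = rng.permutation(len(clades))
    used: set[int] = set()
    groups: list[list] = []
    covered = 0
    for k in order:
        if covered >= target:
            break
        tips = clades[k]
        ids = {id(tp) for tp in tips}
        if ids & used:
            continue
        used |= ids
        groups.append(tips)
        covered += len(tips)

    genus_idx = 0
    for tips in groups:
        genus_idx += 1
        for s, leaf in enumerate(tips, start=1):
            leaf.taxon = dtree.taxon_namespace.require_taxon(
                label=f"Genus{genus_idx}_sp{s}"
            )
    grouped = {id(tp) for tips in groups for tp in tips}
    for leaf in leaves:
        if id(leaf) not in grouped:
            genus_idx += 1
            leaf.taxon = dtree.taxon_namespace.require_taxon(
                label=f"Genus{genus_idx}_sp1"
            )
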