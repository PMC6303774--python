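"""Graft unsequenced species into a dated tree sample under clade constraints.

Species lacking molecular data are attached inside their taxonomic section
(the clade spanned by a set of anchor tips) at a random position: an edge is
chosen uniformly among the edges strictly inside the section's MRCA subtree
(never the stem), the attachment height is uniform along that edge, and the
new tip's pendant length is forced by ultrametry so the tree stays dated.
Grafting only subdivides existing edges, so pairwise distances among the
original tips are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import dendropy
import numpy as np

from .config import derive_seed

__all__ = [
    "SectionAssignment",
    "TreeSet",
    "sample_trees",
    "graft_species",
    "build_augmented_set",
    "node_ages",
    "is_ultrametric",
    "audit_placements",
]


@dataclass(frozen=True)
class SectionAssignment:
    """Mapping of each species to add onto the anchor tips of its section.

    The constraint clade for a species is the MRCA subtree of its anchors
    (>= 2 distinct tip labels present in every input tree).
    """

    constraints: Dict[str, Tuple[str, ...]]

    def __post_init__(self) -> None:
        for sp, anchors in self.constraints.items():
            if len(set(anchors)) < 2:
                raise ValueError(f"species {sp!r} needs >= 2 distinct anchor tips")
            if sp in anchors:
                raise ValueError(f"species {sp!r} cannot anchor itself")

    @property
    def species(self) -> List[str]:
        return list(self.constraints)

    def validate_against(self, tree: dendropy.Tree) -> None:
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        for sp, anchors in self.constraints.items():
            missing = set(anchors) - labels
            if missing:
                raise ValueError(f"anchors {sorted(missing)} for {sp!r} not in tree")
            if sp in labels:
                raise ValueError(f"species to add {sp!r} already present in tree")


@dataclass
class TreeSet:
    """Ordered collection of dated trees sharing one tip set, with provenance."""

    trees: List[dendropy.Tree]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("TreeSet must contain at least one tree")
        ref = self.tip_labels(0)
        for i, t in enumerate(self.trees[1:], start=1):
            if self.tip_labels(i) != ref:
                raise ValueError(f"tree {i} has a different tip set than tree 0")

    def tip_labels(self, i: int = 0) -> frozenset:
        return frozenset(l.taxon.label for l in self.trees[i].leaf_node_iter())

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def node_ages(tree: dendropy.Tree) -> dict:
    """Age (time before present) of every node, taking tree height from tips."""
    depth = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    height = max(depth[l] for l in tree.leaf_node_iter())
    return {nd: height - d for nd, d in depth.items()}


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-8) -> bool:
    ages = node_ages(tree)
    height = max(ages.values())
    tip_ages = [ages[l] for l in tree.leaf_node_iter()]
    return max(abs(a) for a in tip_ages) <= rel_tol * max(height, 1.0)


def sample_trees(
    source: TreeSet, n: int, burn_in_fraction: float = 0.1, seed: int = 0
) -> TreeSet:
    """Sample ``n`` trees from the post-burn-in portion of a posterior set.

    Sampling is without replacement when the pool is large enough, with
    replacement otherwise; the sampled indices are logged in the provenance.
    """
    if not 0 <= burn_in_fraction <= 1:
        raise ValueError("burn_in_fraction must lie in [0, 1]")
    start = int(np.floor(burn_in_fraction * len(source.trees)))
    pool = source.trees[start:]
    if not pool:
        raise ValueError("post-burn-in pool is empty")
    rng = np.random.default_rng(derive_seed(seed, 0))
    replace = n > len(pool)
    idx = rng.choice(len(pool), size=n, replace=replace)
    return TreeSet(
        trees=[pool[i] for i in idx],
        provenance={
            "sampled_indices": [int(i + start) for i in idx],
            "with_replacement": bool(replace),
            "burn_in_fraction": burn_in_fraction,
            "seed": int(seed),
        },
    )


def _candidate_edges(mrca: dendropy.Node) -> list:
    """Edges strictly inside the MRCA subtree (the stem edge is excluded)."""
    return [nd for nd in mrca.preorder_iter() if nd is not mrca]


def graft_species(
    tree: dendropy.Tree,
    assignments: SectionAssignment,
    seed: int = 0,
    clone: bool = True,
) -> dendropy.Tree:
    """Attach every assigned species inside its section at a random position.

    Species are grafted sequentially in randomized order, so a later species
    may attach to an edge created by an earlier graft in the same section
    (added congeners can become sisters). The output keeps all original tips,
    stays ultrametric, and leaves original pairwise tip distances unchanged.
    """
    assignments.validate_against(tree)
    t = tree.clone(depth=1) if clone else tree
    rng = np.random.default_rng(derive_seed(seed, 1))
    order = list(assignments.species)
    rng.shuffle(order)
    for sp in order:
        anchors = assignments.constraints[sp]
        taxa = [t.taxon_namespace.get_taxon(a) for a in anchors]
        if any(tx is None for tx in taxa):
            raise ValueError(f"unknown anchor among {anchors} for {sp!r}")
        mrca = t.mrca(taxa=taxa)
        if mrca is None or mrca.is_leaf():
            raise ValueError(f"constraint clade for {sp!r} has no internal structure")
        ages = node_ages(t)
        cand = _candidate_edges(mrca)
        child = cand[rng.integers(len(cand))]
        parent = child.parent_node
        lo, hi = ages[child], ages[parent]
        attach_age = rng.uniform(lo, hi)
        splice = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(splice)
        splice.edge.length = hi - attach_age
        splice.add_child(child)
        child.edge.length = attach_age - lo
        tip = dendropy.Node(taxon=t.taxon_namespace.require_taxon(label=sp))
        splice.add_child(tip)
        tip.edge.length = attach_age
    return t


def build_augmented_set(
    source: TreeSet,
    assignments: SectionAssignment,
    n: int = 1000,
    burn_in_fraction: float = 0.1,
    seed: int = 0,
) -> TreeSet:
    """Sample ``n`` trees and graft the assigned species into each.

    Each tree slot gets its own deterministically derived grafting seed, so a
    fixed master seed reproduces the whole random-addition set bit for bit.
    """
    sampled = sample_trees(source, n=n, burn_in_fraction=burn_in_fraction, seed=seed)
    graft_seeds = derive_seed(seed, 2).generate_state(n).tolist()
    trees = [
        graft_species(t, assignments, seed=int(s))
        for t, s in zip(sampled.trees, graft_seeds)
    ]
    prov = dict(sampled.provenance)
    prov["n_added_species"] = len(assignments.species)
    return TreeSet(trees=trees, provenance=prov)


def audit_placements(
    tree: dendropy.Tree, assignments: SectionAssignment
) -> Dict[str, bool]:
    """Check that every added tip lies inside its constraint clade."""
    out = {}
    for sp, anchors in assignments.constraints.items():
        mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(a) for a in anchors])
        inside = {l.taxon.label for l in mrca.leaf_iter()}
        out[sp] = sp in inside
    return out
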