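"""MPD, richness-matched permutation nulls, NRI, and tree-set averages.

The net relatedness index compares the observed mean pairwise phylogenetic
distance (MPD) of an assemblage against a null distribution of assemblages of
identical richness drawn from the species pool:

    NRI = -1 * (MPD_obs - mean(MPD_null)) / sd(MPD_null)

Positive NRI means the co-occurring species are more closely related than
expected (phylogenetic clustering); values beyond +/-1.96 are conventionally
read as significant clustering / overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .config import NullModelSpec, derive_seed
from .grid_assembly import CommunityMatrix
from .tree_augmentation import TreeSet

__all__ = [
    "DistanceMatrix",
    "NRIResult",
    "cophenetic_distances",
    "mpd",
    "nri",
    "mean_nri",
]

SIGNIFICANCE_Z = 1.96


@dataclass
class DistanceMatrix:
    """Symmetric tip-to-tip patristic distances (time units) with label index."""

    values: np.ndarray
    labels: List[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        try:
            return np.fromiter((self._index[l] for l in labels), dtype=int)
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} not in distance matrix") from exc


@dataclass
class NRIResult:
    cell_id: str
    n_species: int
    mpd_observed: float
    null_mean: float
    null_sd: float
    nri: float
    significance: str  # clustered | overdispersed | ns
    degenerate_null: bool = False


def cophenetic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic distances between all tip pairs.

    For an ultrametric tree the distance between two tips equals twice the
    age of their MRCA, which lets the whole matrix be filled in one postorder
    sweep instead of per-pair path sums.
    """
    leaves = [l for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 tips")
    labels = [l.taxon.label for l in leaves]
    idx = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    depth = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    leaf_depth = np.array([depth[l] for l in leaves])
    d = np.zeros((n, n))
    # postorder: pair tips across the child subtrees meeting at each node;
    # d(i, j) = depth_i + depth_j - 2 * depth(mrca)  (non-ultrametric-safe)
    below: Dict[dendropy.Node, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = np.array([idx[nd]])
            continue
        kids = [below.pop(c) for c in nd.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ii = kids[a][:, None]
                jj = kids[b][None, :]
                dm = leaf_depth[ii] + leaf_depth[jj] - 2.0 * depth[nd]
                d[ii, jj] = dm
                d[jj.T, ii.T] = dm.T
        below[nd] = np.concatenate(kids)
    return DistanceMatrix(values=d, labels=labels)


def mpd(assemblage: Sequence[str], dist: DistanceMatrix) -> float:
    """Unweighted mean pairwise distance over unordered distinct species pairs."""
    idx = dist.indices(assemblage)
    k = len(idx)
    if k < 2:
        raise ValueError("MPD is undefined for assemblages of fewer than 2 species")
    sub = dist.values[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def _null_mpds(
    dist: DistanceMatrix, k: int, n_rand: int, rng: np.random.Generator
) -> np.ndarray:
    """MPDs of ``n_rand`` uniform k-subsets of the pool (vectorized)."""
    n = len(dist.labels)
    keys = rng.random((n_rand, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    sub = dist.values[idx[:, :, None], idx[:, None, :]]
    return sub.sum(axis=(1, 2)) / (k * (k - 1))


def nri(
    assemblage: Sequence[str],
    dist: DistanceMatrix,
    null: NullModelSpec,
    cell_id: str = "",
    rng: Optional[np.random.Generator] = None,
) -> NRIResult:
    """NRI of one assemblage against a richness-matched label-shuffle null.

    The null draws assemblages of the same richness uniformly without
    replacement from the full pool of the distance matrix. A zero null
    standard deviation (e.g. assemblage = entire pool) yields NRI = 0 with a
    degenerate-null flag rather than a division error.
    """
    obs = mpd(assemblage, dist)
    k = len(set(assemblage))
    if rng is None:
        rng = np.random.default_rng(derive_seed(null.seed))
    sims = _null_mpds(dist, k, null.n_randomizations, rng)
    null_mean = float(sims.mean())
    null_sd = float(sims.std(ddof=1)) if len(sims) > 1 else 0.0
    if null_sd > 0:
        z = -(obs - null_mean) / null_sd
        degenerate = False
    else:
        z, degenerate = 0.0, True
    if degenerate or abs(z) <= SIGNIFICANCE_Z:
        sig = "ns"
    else:
        sig = "clustered" if z > 0 else "overdispersed"
    return NRIResult(
        cell_id=cell_id,
        n_species=k,
        mpd_observed=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        nri=float(z),
        significance=sig,
        degenerate_null=degenerate,
    )


def mean_nri(
    community: CommunityMatrix,
    trees: TreeSet,
    null: NullModelSpec,
    return_per_tree: bool = False,
):
    """Per-cell NRI averaged over a tree set.

    NRI is computed per (cell, tree) with the null redrawn for every tree
    using a seed derived from (master seed, cell index, tree index), then
    averaged arithmetically over trees. Species present in the community but
    absent from any tree abort with an error naming the species.
    """
    species = community.species
    tree_labels = trees.tip_labels(0)
    missing = sorted(set(species) - set(tree_labels))
    if missing:
        raise ValueError(f"species missing from trees: {missing}")
    dists = [cophenetic_distances(t) for t in trees]
    rows = []
    per_tree = []
    inc = community.incidence
    for ci, cell in enumerate(inc.index):
        members = list(inc.columns[inc.loc[cell].to_numpy().astype(bool)])
        per_cell = []
        for ti, dist in enumerate(dists):
            rng = np.random.default_rng(derive_seed(null.seed, ci, ti))
            res = nri(members, dist, null, cell_id=cell, rng=rng)
            per_cell.append(res)
            if return_per_tree:
                per_tree.append(
                    {"cell_id": cell, "tree": ti, "mpd_observed": res.mpd_observed,
                     "null_mean": res.null_mean, "null_sd": res.null_sd, "nri": res.nri}
                )
        z = float(np.mean([r.nri for r in per_cell]))
        if abs(z) <= SIGNIFICANCE_Z:
            sig = "ns"
        else:
            sig = "clustered" if z > 0 else "overdispersed"
        rows.append(
            {
                "cell_id": cell,
                "n_species": per_cell[0].n_species,
                "mpd_observed": float(np.mean([r.mpd_observed for r in per_cell])),
                "null_mean": float(np.mean([r.null_mean for r in per_cell])),
                "null_sd": float(np.mean([r.null_sd for r in per_cell])),
                "nri": z,
                "significance": sig,
            }
        )
    table = pd.DataFrame(rows).set_index("cell_id")
    if return_per_tree:
        return table, pd.DataFrame(per_tree)
    return table
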