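"""Ward agglomeration and dendrogram heterogeneity statistics.

The discrimination question — do root spectra of two species fall into two
species-pure clusters, and how far apart are those clusters relative to the
spread within each species? — is answered with hierarchical agglomeration
under Ward's minimum-variance criterion on Euclidean distances.

Heights here are the Ward merge cost on the squared-distance scale: the
cost of fusing clusters p and q is the Lance-Williams-updated squared
distance D(p, q), which equals twice the growth in total within-cluster sum
of squares caused by the fusion. This is a monotone transform of the
variance growth, so merge order, cluster membership and height *ratios* are
meaningful; absolute heights depend on this scaling convention and are not
comparable across software.

Statistics reported:

* intraspecific heterogeneity — the height at which all samples of one
  species first sit in a single cluster;
* interspecific heterogeneity — the height at which the two species' groups
  join (the lowest node covering both species);
* their ratio, the discriminability index (well above 1 when species
  separate cleanly);
* cluster purity after cutting the dendrogram into k groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ContractError

__all__ = [
    "LinkageTree",
    "HeterogeneityReport",
    "pairwise_distances",
    "ward_linkage",
    "heterogeneity_ratio",
    "heterogeneity_report",
    "cut_and_purity",
    "to_newick",
]


@dataclass(frozen=True)
class LinkageTree:
    """Agglomeration record: n-1 merges over n leaves.

    Nodes are numbered like scipy: leaves ``0..n-1``, the i-th merge creates
    node ``n + i``. Each merge is ``(left, right, height, size)`` with height
    on the squared-distance Ward scale and size the number of leaves in the
    new cluster.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    leaf_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ContractError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ContractError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices below a node (a leaf is below itself)."""
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                left, right, _, _ = self.merges[v - n]
                stack.extend((left, right))
        return sorted(out)

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n_leaves else self.merges[node - self.n_leaves][2]

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage matrix in scipy's convention (heights on distance scale).

        Heights are the square roots of this tree's squared-scale heights,
        matching ``scipy.cluster.hierarchy.linkage(..., method="ward")``.
        """
        Z = np.array(
            [[l, r, np.sqrt(max(h, 0.0)), s] for l, r, h, s in self.merges], dtype=float
        )
        return Z


def pairwise_distances(features: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between feature rows."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ContractError("need a 2-D matrix with at least two rows")
    if not np.all(np.isfinite(features)):
        raise ContractError("features contain missing or non-finite values")
    return squareform(pdist(features, metric="euclidean"))


def ward_linkage(
    distances: np.ndarray, labels: Sequence[str] | None = None
) -> LinkageTree:
    """Agglomerate under Ward's minimum-variance criterion.

    ``distances`` is a square Euclidean distance matrix between singleton
    leaves. At every step the pair of active clusters with the smallest
    Lance-Williams-updated squared distance is fused (smallest growth in
    within-cluster heterogeneity); distances to all other clusters i are
    updated by the Ward recurrence on squared distances

        D(r, i) = [ (n_p + n_i) D(p, i) + (n_q + n_i) D(q, i)
                    - n_i D(p, q) ] / (n_p + n_q + n_i)

    where r is the fusion of p and q. Ties are broken toward the smallest
    (left, right) node-id pair, making the result order-stable.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ContractError("distance matrix must be square")
    n = D.shape[0]
    if n < 2:
        raise ContractError("need at least two leaves")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ContractError("distance matrix must be symmetric with zero diagonal")
    if labels is None:
        labels = tuple(f"leaf{i}" for i in range(n))
    elif len(labels) != n:
        raise ContractError("one label per leaf required")

    sq = {}  # squared distances between active clusters, key frozenset of ids
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    for i in range(n):
        for j in range(i + 1, n):
            sq[(i, j)] = D[i, j] ** 2

    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        ids = sorted(active)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                d = sq[(a, b)]
                if best is None or d < best[0] - 1e-15 or (
                    abs(d - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])
                ):
                    best = (d, a, b)
        d_pq, p, q = best
        size = active[p] + active[q]
        merges.append((p, q, d_pq, size))
        for i in ids:
            if i in (p, q):
                continue
            n_p, n_q, n_i = active[p], active[q], active[i]
            d_pi = sq[tuple(sorted((p, i)))]
            d_qi = sq[tuple(sorted((q, i)))]
            sq[(i, next_id) if i < next_id else (next_id, i)] = (
                (n_p + n_i) * d_pi + (n_q + n_i) * d_qi - n_i * d_pq
            ) / (n_p + n_q + n_i)
        del active[p], active[q]
        active[next_id] = size
        next_id += 1
    return LinkageTree(merges=tuple(merges), leaf_labels=tuple(str(x) for x in labels))


def heterogeneity_ratio(inter: float, intra: float) -> float:
    """Inter/intra heterogeneity multiplier, rounded to one decimal.

    Rounding is half-away-from-zero (so 3.97 / 2.29 = 1.733... reports 1.7
    and 1.56 / 0.60 = 2.6), the convention consistent with the reported
    multipliers.
    """
    if intra <= 0:
        raise ContractError("intraspecific heterogeneity must be positive")
    value = Decimal(inter) / Decimal(intra)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HeterogeneityReport:
    """Dendrogram heterogeneity summary for a two-species comparison."""

    per_species_intra: dict[str, float]
    interspecific: float
    ratio: float  # interspecific / max intraspecific, 1 decimal
    per_species_ratio: dict[str, float]
    pure: bool
    singleton_species: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_species_intra": dict(self.per_species_intra),
            "interspecific": self.interspecific,
            "ratio": self.ratio,
            "per_species_ratio": dict(self.per_species_ratio),
            "pure": self.pure,
            "singleton_species": list(self.singleton_species),
        }


def _lowest_covering_node(tree: LinkageTree, leaf_set: set[int]) -> int:
    """Lowest node whose subtree contains every leaf in leaf_set."""
    if len(leaf_set) == 1:
        return next(iter(leaf_set))
    n = tree.n_leaves
    for idx in range(n - 1):  # heights non-decreasing: first cover is lowest
        node = n + idx
        if leaf_set.issubset(tree.leaves_under(node)):
            return node
    raise AssertionError("root covers all leaves")  # pragma: no cover


def heterogeneity_report(
    tree: LinkageTree, labels: Sequence[str]
) -> HeterogeneityReport:
    """Intra-/interspecific heterogeneity for a dendrogram of two species.

    Intraspecific heterogeneity of a species is the height of the lowest
    node covering all its leaves; interspecific heterogeneity is the height
    of the lowest node covering both species. ``pure`` is true when each
    species' covering node contains no foreign leaf — i.e. each species
    forms a contiguous subtree below the join. Species represented by a
    single sample get intra = 0 and are flagged.
    """
    labels = [str(x) for x in labels]
    if len(labels) != tree.n_leaves:
        raise ContractError("one species label per leaf required")
    species = sorted(set(labels))
    if len(species) != 2:
        raise ContractError(f"pairwise report requires exactly 2 species, got {len(species)}")
    leaf_sets = {sp: {i for i, lab in enumerate(labels) if lab == sp} for sp in species}
    intra: dict[str, float] = {}
    singletons = []
    pure = True
    for sp, leaves in leaf_sets.items():
        node = _lowest_covering_node(tree, leaves)
        intra[sp] = tree.node_height(node)
        if len(leaves) == 1:
            singletons.append(sp)
        if set(tree.leaves_under(node)) - leaves:
            pure = False
    join = _lowest_covering_node(tree, leaf_sets[species[0]] | leaf_sets[species[1]])
    inter = tree.node_height(join)
    per_ratio = {
        sp: heterogeneity_ratio(inter, h) if h > 0 else float("inf")
        for sp, h in intra.items()
    }
    max_intra = max(intra.values())
    ratio = heterogeneity_ratio(inter, max_intra) if max_intra > 0 else float("inf")
    return HeterogeneityReport(
        per_species_intra=intra,
        interspecific=inter,
        ratio=ratio,
        per_species_ratio=per_ratio,
        pure=pure,
        singleton_species=tuple(singletons),
    )


def cut_and_purity(
    tree: LinkageTree, k: int, labels: Sequence[str]
) -> tuple[float, pd.DataFrame]:
    """Cut the dendrogram into k clusters and score species separation.

    The k clusters are the subtrees left after removing the k-1 highest
    merges. Separation is the percentage of leaves that sit in a
    species-pure cluster whose species occupies no other cluster — 100%
    means a perfect one-cluster-per-species partition.

    Returns ``(separation_percent, contingency)`` with the contingency table
    indexed by cluster id, columns the species.
    """
    labels = [str(x) for x in labels]
    n = tree.n_leaves
    if len(labels) != n:
        raise ContractError("one species label per leaf required")
    if not 1 <= k <= n:
        raise ContractError(f"k = {k} outside [1, {n}]")
    # union-find over the first n-1-(k-1) merges
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx in range(n - k):
        left, right, _, _ = tree.merges[idx]
        node = n + idx
        parent[find(left)] = node
        parent[find(right)] = node
    assignment = [find(i) for i in range(n)]
    cluster_ids = sorted(set(assignment))
    relabel = {c: i for i, c in enumerate(cluster_ids)}
    clusters = [relabel[a] for a in assignment]
    contingency = pd.crosstab(
        pd.Series(clusters, name="cluster"), pd.Series(labels, name="species")
    )
    pure_clusters = {
        c for c in contingency.index if (contingency.loc[c] > 0).sum() == 1
    }
    clusters_per_species = (contingency > 0).sum(axis=0)
    good = 0
    for leaf, (c, sp) in enumerate(zip(clusters, labels)):
        if c in pure_clusters and clusters_per_species[sp] == 1:
            good += 1
    return 100.0 * good / n, contingency


def _newick_node(tree: LinkageTree, node: int, parent_height: float) -> str:
    length = parent_height - tree.node_height(node)
    if node < tree.n_leaves:
        return f"{tree.leaf_labels[node]}:{length:.12g}"
    left, right, height, _ = tree.merges[node - tree.n_leaves]
    return (
        f"({_newick_node(tree, left, height)},{_newick_node(tree, right, height)})"
        f":{length:.12g}"
    )


def to_newick(tree: LinkageTree) -> str:
    """Serialize the dendrogram as a Newick string.

    Leaf names are the sample ids; branch lengths are parent-minus-child
    height differences, so every root-to-leaf path length equals the root
    height. Parses with any standard Newick reader.
    """
    left, right, height, _ = tree.merges[-1]
    body = f"({_newick_node(tree, left, height)},{_newick_node(tree, right, height)})"
    return body + ";"
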