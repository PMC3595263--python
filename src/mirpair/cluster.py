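"""Hierarchical clustering with Pearson-correlation distance and UPGMA linkage.

Used to cluster the patients x miRNA fold-change matrix in both orientations
(patients by their fold-change profiles, miRNAs by their behavior across
patients). The distance between two profiles is ``d = 1 - r`` with r the
Pearson correlation, so d in [0, 2]: 0 for perfectly correlated profiles, 2
for perfectly anti-correlated ones.

UPGMA (unweighted pair-group method with arithmetic mean) merges the closest
pair of clusters at each step; the distance between two clusters is the
unweighted average of all cross-pair leaf distances, maintained here through
the exact Lance-Williams size-weighted update. Ties in the minimum distance
are broken by the lexicographically smallest member id so runs are
reproducible. Merge heights are nondecreasing (UPGMA is monotone) and the
resulting tree is ultrametric: each leaf sits at depth height/2 below a merge.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric Pearson-distance matrix over named items."""

    ids: list[str]
    values: np.ndarray
    pairwise_complete_used: bool = False

    def validate(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.nanmin(v) < 0 or np.nanmax(v) > 2:
            raise ValidationError("Pearson distances must lie in [0, 2]")


def pearson_distance(matrix: pd.DataFrame, min_overlap: int = 3) -> DistanceMatrix:
    """d(i, j) = 1 - Pearson r between rows i and j of an items x features
    matrix. Missing cells are handled pairwise-complete (flagged in the
    result) with at least ``min_overlap`` shared features required per pair."""
    if matrix.shape[1] < 2:
        raise ValidationError("need >=2 features per item")
    ids = [str(i) for i in matrix.index]
    x = matrix.to_numpy(float)

    for item, row in zip(ids, x):
        obs = row[~np.isnan(row)]
        if len(obs) >= 2 and np.all(obs == obs[0]):
            raise ComputationError(f"item {item!r} has zero variance across features")

    has_nan = bool(np.isnan(x).any())
    if not has_nan:
        r = np.corrcoef(x)
    else:
        n = len(ids)
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                mask = ~np.isnan(x[i]) & ~np.isnan(x[j])
                if mask.sum() < min_overlap:
                    raise ComputationError(
                        f"items {ids[i]!r} and {ids[j]!r} share only "
                        f"{int(mask.sum())} complete features (< {min_overlap})"
                    )
                xi, xj = x[i, mask], x[j, mask]
                if np.all(xi == xi[0]) or np.all(xj == xj[0]):
                    raise ComputationError(
                        f"zero variance in pairwise-complete subset for "
                        f"{ids[i]!r} / {ids[j]!r}"
                    )
                r[i, j] = r[j, i] = np.corrcoef(xi, xj)[0, 1]

    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    out = DistanceMatrix(ids=ids, values=d, pairwise_complete_used=has_nan)
    out.validate()
    return out


@dataclasses.dataclass
class LinkageTree:
    """Merge history of agglomerative clustering.

    Nodes follow the usual convention: leaves are 0..n-1 in input order and
    the i-th merge creates node n+i. ``merges`` holds
    (child_a, child_b, height, size) with child_a the child containing the
    lexicographically smallest member id.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]

    def members(self, node: int) -> list[str]:
        n = self.n_leaves
        if node < n:
            return [self.leaves[node]]
        a, b, _, _ = self.merges[node - n]
        return self.members(a) + self.members(b)

    def cut(self, k: int) -> pd.Series:
        """Cluster assignments from the k clusters left after undoing the
        top k-1 merges; each cluster is labelled by its smallest member id."""
        n = self.n_leaves
        if not (1 <= k <= n):
            raise ValidationError(f"k must be in [1, {n}], got {k}")
        parent = list(range(2 * n - 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for idx, (a, b, _, _) in enumerate(self.merges[: n - k]):
            node = n + idx
            parent[find(a)] = node
            parent[find(b)] = node

        roots: dict[int, list[str]] = {}
        for leaf in range(n):
            roots.setdefault(find(leaf), []).append(self.leaves[leaf])
        labels = {}
        for group in roots.values():
            label = min(group)
            for leaf_id in group:
                labels[leaf_id] = label
        return pd.Series([labels[leaf] for leaf in self.leaves], index=self.leaves,
                         name="cluster")

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (leaf depth =
        merge height / 2). Spaces in ids become underscores."""
        n = self.n_leaves

        def depth(node: int) -> float:
            return 0.0 if node < n else self.merges[node - n][2] / 2.0

        def render(node: int, parent_depth: float) -> str:
            bl = parent_depth - depth(node)
            if node < n:
                name = self.leaves[node].replace(" ", "_")
                return f"{name}:{bl:.10g}"
            a, b, h, _ = self.merges[node - n]
            inner = ",".join(render(c, h / 2.0) for c in (a, b))
            return f"({inner}):{bl:.10g}"

        if n == 1:
            return f"{self.leaves[0].replace(' ', '_')}:0;"
        root = 2 * n - 2
        a, b, h, _ = self.merges[-1]
        inner = ",".join(render(c, h / 2.0) for c in (a, b))
        return f"({inner});"


def upgma(dist: DistanceMatrix) -> LinkageTree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the closest active pair merges at a height equal to the
    unweighted average of all cross-pair leaf distances; distances to the new
    cluster follow the exact update
    ``d(new, k) = (n_a d(a, k) + n_b d(b, k)) / (n_a + n_b)``.
    """
    dist.validate()
    n = len(dist.ids)
    if n < 2:
        raise ValidationError("need at least 2 items to cluster")

    total = 2 * n - 1
    big = np.full((total, total), np.inf)
    big[:n, :n] = dist.values
    np.fill_diagonal(big, np.inf)

    sizes = np.ones(total, dtype=int)
    min_id = list(dist.ids) + [""] * (n - 1)
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        act = sorted(active)
        sub = big[np.ix_(act, act)]
        dmin = sub.min()
        ii, jj = np.nonzero(sub == dmin)
        candidates = [(act[a], act[b]) for a, b in zip(ii, jj) if act[a] < act[b]]
        # tie-break: lexicographically smallest member id, then its partner's
        a, b = min(
            candidates,
            key=lambda p: tuple(sorted((min_id[p[0]], min_id[p[1]]))),
        )
        if min_id[b] < min_id[a]:
            a, b = b, a

        new = n + step
        size = sizes[a] + sizes[b]
        for k in active - {a, b}:
            d_new = (sizes[a] * big[a, k] + sizes[b] * big[b, k]) / size
            big[new, k] = big[k, new] = d_new
        sizes[new] = size
        min_id[new] = min(min_id[a], min_id[b])
        merges.append((a, b, float(dmin), int(size)))
        active -= {a, b}
        active.add(new)

    return LinkageTree(leaves=list(dist.ids), merges=merges)


def cut_tree(tree: LinkageTree, k: int) -> pd.Series:
    return tree.cut(k)


def write_newick(tree: LinkageTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_clusters(assignments: pd.Series, path) -> None:
    out = assignments.rename("cluster").to_frame()
    out.index.name = "item"
    out.to_csv(path, sep="\t")
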