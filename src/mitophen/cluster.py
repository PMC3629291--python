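"""Similarity metrics, agglomerative clustering and cophenetic validation.

Diseases are compared as symptom vectors over the full parameter union.
The default metric is *uncentered similarity* — the cosine of the angle
between two vectors, without mean-centering — turned into a distance as
``1 - s``; the default linkage is group-average (UPGMA).  The cophenetic
correlation between the original distances and the tree-implied distances
quantifies how faithfully the dendrogram represents the data.

The agglomeration is implemented directly so that tie-breaking (smallest
index pair first) is deterministic across platforms; on tie-free inputs it
agrees with :func:`scipy.cluster.hierarchy.linkage` to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.spatial.distance import cityblock as _cityblock, euclidean as _euclidean
from scipy.stats import kendalltau, pearsonr, spearmanr

from .errors import UndefinedSimilarityError, ValidationError
from .phenodb import PhenotypeMatrix

SIMILARITY_METRICS = (
    "uncentered",
    "pearson",
    "spearman",
    "kendall",
    "absolute-uncentered",
    "absolute-pearson",
)
DISTANCE_METRICS = ("euclidean", "cityblock")
METRICS = SIMILARITY_METRICS + DISTANCE_METRICS
LINKAGE_METHODS = ("average", "single", "complete", "centroid")

__all__ = [
    "METRICS",
    "LINKAGE_METHODS",
    "DistanceMatrix",
    "LinkageTree",
    "similarity",
    "pairwise_distances",
    "linkage",
    "cophenetic_distances",
    "cophenetic_correlation",
    "cut_tree",
    "to_newick",
    "from_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise disease distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12) or np.any(self.d < -1e-12):
            raise ValidationError("distances must be nonnegative with zero diagonal")

    def condensed(self) -> np.ndarray:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return self.d[iu]


@dataclass
class LinkageTree:
    """Binary merge tree.

    Leaves are numbered ``0..n-1`` in ``leaves`` order; merge ``m`` creates
    internal node ``n + m``.  Each merge records the two child node ids and
    the height (distance) at which they were joined.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValidationError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        if not self.sizes:
            self.sizes = [1] * n
            for a, b, _h in self.merges:
                self.sizes.append(self.sizes[a] + self.sizes[b])

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_leaves(self, node: int) -> list[int]:
        """Leaf indices under a node id."""
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                a, b, _ = self.merges[v - n]
                stack.extend((b, a))
        return out

    def height_of(self, node: int) -> float:
        return 0.0 if node < self.n_leaves else self.merges[node - self.n_leaves][2]


def _as_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValidationError("similarity requires two equal-length vectors")
    return x, y


def _uncentered(x: np.ndarray, y: np.ndarray) -> float:
    nx = np.dot(x, x)
    ny = np.dot(y, y)
    if nx == 0 or ny == 0:
        raise UndefinedSimilarityError("undefined similarity: all-zero symptom vector")
    return float(np.dot(x, y) / np.sqrt(nx * ny))


def similarity(x, y, metric: str = "uncentered") -> float:
    """Similarity (or, for ``euclidean``/``cityblock``, distance) of two vectors."""
    x, y = _as_vectors(x, y)
    if metric == "euclidean":
        return float(_euclidean(x, y))
    if metric == "cityblock":
        return float(_cityblock(x, y))
    base = metric.removeprefix("absolute-")
    if metric not in SIMILARITY_METRICS:
        raise ValidationError(f"unknown metric {metric!r} (expected one of {METRICS})")
    if base == "uncentered":
        r = _uncentered(x, y)
    else:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedSimilarityError(
                f"undefined similarity: constant vector under {base!r}"
            )
        if base == "pearson":
            r = float(pearsonr(x, y).statistic)
        elif base == "spearman":
            r = float(spearmanr(x, y).statistic)
        else:  # kendall
            r = float(kendalltau(x, y).statistic)
    return abs(r) if metric.startswith("absolute-") else r


def pairwise_distances(matrix: PhenotypeMatrix, metric: str = "uncentered") -> DistanceMatrix:
    """All-pairs distances between disease rows.

    Correlation-type similarities ``s`` become distances ``1 - s``
    (range [0, 2]; absolute variants give ``1 - |s|`` in [0, 1]);
    euclidean/cityblock are used as-is.
    """
    n = len(matrix.diseases)
    d = np.zeros((n, n))
    is_similarity = metric in SIMILARITY_METRICS
    for i in range(n):
        for j in range(i + 1, n):
            v = similarity(matrix.values[i], matrix.values[j], metric)
            d[i, j] = d[j, i] = (1.0 - v) if is_similarity else v
    d[d < 0] = 0.0  # clamp -eps from floating-point cancellation
    return DistanceMatrix(labels=list(matrix.diseases), d=d)


def linkage(dm: DistanceMatrix, method: str = "average") -> LinkageTree:
    """Agglomerative clustering of a distance matrix.

    Lance-Williams updates for ``average`` (size-weighted, UPGMA),
    ``single``, ``complete`` and ``centroid``.  The pair with the smallest
    distance is merged at each step; exact ties are broken by the smallest
    (older, older) node-id pair, making the merge sequence deterministic.
    """
    if method not in LINKAGE_METHODS:
        raise ValidationError(f"unknown linkage {method!r} (expected one of {LINKAGE_METHODS})")
    n = len(dm.labels)
    if n < 2:
        raise ValidationError("linkage requires at least 2 leaves")
    # active cluster node ids -> index into the working distance array
    sq = method == "centroid"
    dist = {}  # (id_a, id_b) with id_a < id_b -> distance
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = dm.d[i, j] ** 2 if sq else dm.d[i, j]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                key = (active[ai], active[bi])
                val = dist[key]
                if best is None or val < best[0] or (val == best[0] and key < best[1]):
                    best = (val, key)
        dmin, (a, b) = best
        height = float(np.sqrt(max(dmin, 0.0))) if sq else float(dmin)
        merges.append((a, b, height))
        na, nb = sizes[a], sizes[b]
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            dca = dist[(min(a, c), max(a, c))]
            dcb = dist[(min(b, c), max(b, c))]
            if method == "single":
                dnew = min(dca, dcb)
            elif method == "complete":
                dnew = max(dca, dcb)
            elif method == "average":
                dnew = (na * dca + nb * dcb) / (na + nb)
            else:  # centroid, on squared distances
                dnew = (na * dca + nb * dcb) / (na + nb) - (na * nb * dmin) / (na + nb) ** 2
            dist[(c, new)] = dnew
        active = [c for c in active if c not in (a, b)] + [new]
        sizes[new] = na + nb
    return LinkageTree(leaves=list(dm.labels), merges=merges)


def cophenetic_distances(tree: LinkageTree) -> np.ndarray:
    """Condensed tree-implied distances: height of each pair's lowest common merge."""
    n = tree.n_leaves
    coph = np.zeros((n, n))
    for a, b, h in tree.merges:
        left = tree.node_leaves(a)
        right = tree.node_leaves(b)
        for i in left:
            for j in right:
                coph[i, j] = coph[j, i] = h
    return coph[np.triu_indices(n, k=1)]


def cophenetic_correlation(tree: LinkageTree, dm: DistanceMatrix) -> float:
    """Pearson correlation between original and cophenetic pair distances."""
    if tree.leaves != dm.labels:
        raise ValidationError("tree leaves do not match distance-matrix labels")
    if tree.n_leaves < 3:
        raise ValidationError("cophenetic undefined: fewer than 3 leaves")
    orig = dm.condensed()
    coph = cophenetic_distances(tree)
    if np.ptp(orig) == 0 or np.ptp(coph) == 0:
        raise UndefinedSimilarityError("cophenetic undefined: zero variance in distances")
    return float(pearsonr(orig, coph).statistic)


def cut_tree(tree: LinkageTree, k: int) -> dict[str, int]:
    """Partition the leaves into k clusters by removing the k-1 highest merges.

    Cluster ids are assigned deterministically: the cluster containing the
    first leaf (in leaf order) gets id 0, the next unseen cluster id 1, etc.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    order = sorted(range(len(tree.merges)), key=lambda m: (tree.merges[m][2], m))
    keep = set(order[: n - k])  # lowest n-k merges survive the cut
    parent = list(range(n))

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for m in sorted(keep):
        a, b, _ = tree.merges[m]
        ra = find(min(tree.node_leaves(a)))
        rb = find(min(tree.node_leaves(b)))
        parent[max(ra, rb)] = min(ra, rb)
    ids: dict[int, int] = {}
    out: dict[str, int] = {}
    for i, leaf in enumerate(tree.leaves):
        root = find(i)
        if root not in ids:
            ids[root] = len(ids)
        out[leaf] = ids[root]
    return out


_NEWICK_RESERVED = set("(),:;'\" \t\n[]")


def _quote(name: str) -> str:
    if any(c in _NEWICK_RESERVED for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: LinkageTree) -> str:
    """Serialize as Newick; branch lengths are parent-child height differences."""

    def render(node: int, parent_height: float) -> str:
        h = tree.height_of(node)
        if node < tree.n_leaves:
            body = _quote(tree.leaves[node])
        else:
            a, b, _ = tree.merges[node - tree.n_leaves]
            body = f"({render(a, h)},{render(b, h)})"
        return f"{body}:{parent_height - h:.12g}"

    root = tree.n_leaves + len(tree.merges) - 1
    rh = tree.height_of(root)
    a, b, _ = tree.merges[-1]
    return f"({render(a, rh)},{render(b, rh)});"


def from_newick(text: str) -> LinkageTree:
    """Parse a binary ultrametric Newick string back into a LinkageTree.

    The inverse of :func:`to_newick` up to merge order: cophenetic distances
    and topology are reproduced exactly; internal node heights are taken as
    the maximum root-path-corrected leaf depth below each node.
    """
    dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    leaves = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    index = {name: i for i, name in enumerate(leaves)}
    events: list[tuple[float, int, int]] = []  # (height, rep_a, rep_b) postorder

    def walk(node) -> tuple[int, float]:
        """Return (representative leaf index, node height)."""
        children = node.child_nodes()
        if not children:
            return index[node.taxon.label], 0.0
        if len(children) != 2:
            raise ValidationError("from_newick supports binary trees only")
        (ra, ha), (rb, hb) = (walk(c) for c in children)
        la = children[0].edge.length or 0.0
        lb = children[1].edge.length or 0.0
        h = max(ha + la, hb + lb)
        events.append((h, ra, rb))
        return min(ra, rb), h

    walk(dtree.seed_node)
    n = len(leaves)
    events.sort(key=lambda e: e[0])
    node_of = list(range(n))  # current node id of each leaf's cluster
    parent = list(range(n))

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    merges: list[tuple[int, int, float]] = []
    for m, (h, ra, rb) in enumerate(events):
        fa, fb = find(ra), find(rb)
        merges.append((node_of[fa], node_of[fb], float(h)))
        parent[max(fa, fb)] = min(fa, fb)
        node_of[min(fa, fb)] = n + m
    return LinkageTree(leaves=leaves, merges=merges)
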