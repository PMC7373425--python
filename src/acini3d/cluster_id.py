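"""Identify clusters of transduced cells within each acinus.

Pipeline per acinus: pairwise Euclidean distances between transduced cells
-> complete-linkage dendrogram -> adaptive (dynamic) tree cut -> cluster
labels.  A cluster is a group of transduced cells closer to each other than
to the other transduced cells of the same acinus; an isolated transduced
cell forms a singleton cluster.

The linkage is implemented directly (rather than delegated) so that ties in
merge height break deterministically: on equal heights the pair with the
lexicographically smallest (min leaf id, max leaf id) merges first.  Heights
stay in physical µm; no normalisation is applied before cutting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, DataError
from .io_tables import CohortTable


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix (µm) over ordered cell ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape does not match ids")


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` lists (left, right, height) with nodes numbered like scipy:
    leaves are 0..n-1, the i-th merge creates node n+i.  Heights are
    nondecreasing for complete linkage.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaves_of(self, node: int) -> list[int]:
        """Leaf indices under a node (a leaf is its own set)."""
        n = self.n_leaves
        if node < n:
            return [node]
        left, right, _ = self.merges[node - n]
        return self.leaves_of(left) + self.leaves_of(right)

    def height_of(self, node: int) -> float:
        return 0.0 if node < self.n_leaves else self.merges[node - self.n_leaves][2]


@dataclass
class ClusterAssignment:
    """Partition of transduced cells into clusters (singletons allowed)."""

    labels: dict[str, str] = field(default_factory=dict)  # cell_id -> cluster_id
    members: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class Cluster:
    """A group of transduced cells from one acinus.

    ``sphere_diameter`` is the distance between the two farthest members
    (0 for singletons); ``center_of_mass`` the unweighted member centroid.
    """

    acinus_id: str
    cluster_id: str
    members: list[str]
    center_of_mass: np.ndarray
    sphere_diameter: float
    tumor: bool | None = None


@dataclass(frozen=True)
class CutParams:
    """Adaptive tree-cut parameters.

    ``min_cluster_size``: branches smaller than this are not made clusters
    by the cut; their leaves become singletons.  ``gap_ratio``: a merge is
    split when its height exceeds gap_ratio times the internal height of
    its tighter multi-leaf sub-branch, i.e. when at least one branch is
    markedly more cohesive than the join.  ``height_floor_frac``: merges
    lower than this fraction of the tree's root height are never split —
    the anchor that keeps locally uneven but low-lying branches (cells of
    one spatial group) together.  ``max_merge_height`` (µm): optional
    ceiling above which a merge is always split (default: none).
    """

    min_cluster_size: int = 2
    gap_ratio: float = 2.0
    height_floor_frac: float = 0.3
    max_merge_height: float | None = None

    def validate(self) -> None:
        if self.min_cluster_size < 1:
            raise ConfigError("min_cluster_size must be >= 1")
        if self.gap_ratio < 1.0:
            raise ConfigError("gap_ratio must be >= 1")
        if not (0.0 <= self.height_floor_frac < 1.0):
            raise ConfigError("height_floor_frac must be in [0, 1)")
        if self.max_merge_height is not None and self.max_merge_height <= 0:
            raise ConfigError("max_merge_height must be > 0")


def pairwise_distances(cells: pd.DataFrame, subset: str = "transduced") -> DistanceMatrix:
    """Exact Euclidean distances on (x, y, z) for one acinus.

    ``subset`` is "transduced" (oncogene-expressing cells only) or "all".
    """
    if subset == "transduced":
        sub = cells[cells["transduced"].astype(bool)]
    elif subset == "all":
        sub = cells
    else:
        raise ConfigError(f"unknown subset {subset!r}")
    if len(sub) == 0:
        raise DataError("no cells in requested subset")
    ids = sub["cell_id"].astype(str).tolist()
    coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
    if len(sub) == 1:
        return DistanceMatrix(ids, np.zeros((1, 1)))
    return DistanceMatrix(ids, squareform(pdist(coords)))


def complete_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    Each merge height equals the maximum pairwise distance between the two
    merged leaf sets.  Equal heights break on the lexicographically
    smallest (min leaf index, max leaf index) of the candidate pair, which
    makes duplicate coordinates merge first and the whole history
    deterministic.
    """
    n = len(dm.ids)
    merges: list[tuple[int, int, float]] = []
    if n == 1:
        return Dendrogram(list(dm.ids), merges)
    # active node -> (leaf set, representative key for tie-breaking)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])
    next_node = n
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                d = dist[(a, b) if a < b else (b, a)]
                la, lb = active[a], active[b]
                key = (d, min(min(la), min(lb)), max(min(la), min(lb)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        active[next_node] = active.pop(a) + active.pop(b)
        merges.append((a, b, d))
        for other in list(active):
            if other == next_node:
                continue
            da = dist.pop((min(a, other), max(a, other)))
            db = dist.pop((min(b, other), max(b, other)))
            dist[(min(next_node, other), max(next_node, other))] = max(da, db)
        next_node += 1
    return Dendrogram(list(dm.ids), merges)


def _cut_node(
    dend: Dendrogram,
    node: int,
    params: CutParams,
    floor: float,
    out: list[list[int]],
) -> None:
    """Recursive adaptive cut; appends leaf-index groups (clusters) to out.

    ``floor`` is the absolute height (µm) below which merges are cohesive
    by fiat, derived once from the root height.
    """
    n = dend.n_leaves
    if node < n:
        out.append([node])
        return
    left, right, h = dend.merges[node - n]
    # cohesion reference: the tighter sub-branch that is itself a group
    # (leaves carry no internal height and cannot anchor the comparison)
    child_heights = [
        dend.height_of(c) for c in (left, right) if len(dend.leaves_of(c)) >= 2
    ]
    force = params.max_merge_height is not None and h > params.max_merge_height
    split = force or (
        h > floor
        and bool(child_heights)
        and h > params.gap_ratio * min(child_heights)
    )
    if not split:
        out.append(dend.leaves_of(node))
        return
    for child in (left, right):
        leaves = dend.leaves_of(child)
        if len(leaves) < params.min_cluster_size:
            # too small to stand as a cut branch: promote to singletons
            for leaf in leaves:
                out.append([leaf])
        else:
            _cut_node(dend, child, params, floor, out)


def dynamic_tree_cut(
    dend: Dendrogram, dm: DistanceMatrix, params: CutParams | None = None
) -> ClusterAssignment:
    """Branch-shape-adaptive cut of a complete-linkage dendrogram.

    Top-down decomposition: starting at the root, a branch is split where
    its merge height stands out against the internal structure of its
    sub-branches (see CutParams).  Leaves detached by the cut become
    singleton clusters, so every transduced cell ends in exactly one
    cluster.  n=1 yields one singleton; n=2 one two-cell cluster.
    """
    params = params or CutParams()
    params.validate()
    if dend.leaf_ids != dm.ids:
        raise DataError("dendrogram was not built from this distance matrix")
    n = dend.n_leaves
    groups: list[list[int]] = []
    if n == 1:
        groups = [[0]]
    else:
        root = n + len(dend.merges) - 1
        floor = params.height_floor_frac * dend.height_of(root)
        _cut_node(dend, root, params, floor, groups)
    # canonical labels: clusters sorted by their minimum member cell_id
    groups.sort(key=lambda g: min(dend.leaf_ids[i] for i in g))
    assignment = ClusterAssignment()
    for k, g in enumerate(groups):
        cid = f"cluster_{k}"
        ids = sorted(dend.leaf_ids[i] for i in g)
        assignment.members[cid] = ids
        for cell in ids:
            assignment.labels[cell] = cid
    return assignment


def _build_cluster(acinus_id: str, cid: str, members: list[str], cells: pd.DataFrame) -> Cluster:
    sub = cells[cells["cell_id"].isin(members)]
    coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
    com = coords.mean(axis=0)
    diam = 0.0 if len(coords) < 2 else float(pdist(coords).max())
    return Cluster(acinus_id, cid, sorted(members), com, diam)


def identify_clusters(
    cohort: CohortTable, params: CutParams | None = None
) -> dict[str, list[Cluster]]:
    """Run distances -> linkage -> cut per acinus; return clusters per acinus.

    Acini with no transduced cells yield an empty list.  Cluster ids are
    stable: clusters are ordered by their minimum member cell_id.
    """
    out: dict[str, list[Cluster]] = {}
    for acinus_id in cohort.acinus_ids:
        cells = cohort.acinus(acinus_id)
        if not cells["transduced"].astype(bool).any():
            out[acinus_id] = []
            continue
        dm = pairwise_distances(cells, subset="transduced")
        dend = complete_linkage(dm)
        assignment = dynamic_tree_cut(dend, dm, params)
        out[acinus_id] = [
            _build_cluster(acinus_id, cid, members, cells)
            for cid, members in assignment.members.items()
        ]
    return out


def clusters_to_table(clusters: dict[str, list[Cluster]]) -> pd.DataFrame:
    """One row per cluster member: acinus_id, cluster_id, cell_id."""
    rows = [
        {"acinus_id": c.acinus_id, "cluster_id": c.cluster_id, "cell_id": m}
        for acinus in sorted(clusters)
        for c in clusters[acinus]
        for m in c.members
    ]
    return pd.DataFrame(rows, columns=["acinus_id", "cluster_id", "cell_id"])
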