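"""AV-Groups, AV-Subgroups and DSU codes.

Within each disentangled space, AVs whose reconstructed residual exceeds the
significance threshold are linked; the connected components of that graph
(size >= 2) are the AV-Groups, so every member is significantly associated
with at least one other member.  Each group is then refined into
AV-Subgroups by average-linkage agglomeration on the Dice overlap of the
AVs' entity covers; a subgroup is a disentangled-space unit (DSU) coded
``[#DS #AVG #AVSG]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .association import SRMatrix
from .dataset import AV, AddressTable, eid_intersection
from .disentangle import DEFAULT_THRESHOLD, DisentangledSpace


@dataclass
class AVGroup:
    ds_index: int
    avg_index: int  # 1-based ordinal within the DS
    members: Set[AV]
    max_score: float = 0.0  # max |projection| over members, used for ordering


@dataclass
class AVSubgroup:
    """A DSU: one AV-Subgroup with its triple code ``(#DS, #AVG, #AVSG)``."""

    code: Tuple[int, int, int]
    members: Set[AV]
    parent: AVGroup | None = None

    @property
    def label(self) -> str:
        return "DSU[%d %d %d]" % self.code

    def sorted_members(self) -> List[AV]:
        return sorted(self.members)


class _UnionFind:
    def __init__(self):
        self.parent: Dict[int, int] = {}

    def find(self, x: int) -> int:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def av_clustering(
    ds: DisentangledSpace,
    sr: SRMatrix,
    threshold: float = DEFAULT_THRESHOLD,
) -> List[AVGroup]:
    """Group AVs of one DS into statistically connected AV-Groups.

    Equivalent to the connected components (size >= 2) of the graph whose
    edges are distinct-attribute AV pairs with reconstructed residual above
    ``threshold``; the result is therefore independent of edge insertion
    order.  Groups are ordered by descending maximum |score| of members.
    """
    mask = sr.association_mask()
    rsr = ds.rsr
    k = rsr.shape[0]
    uf = _UnionFind()
    in_graph = np.zeros(k, dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            if mask[i, j] and rsr[i, j] > threshold:
                uf.union(i, j)
                in_graph[i] = in_graph[j] = True
    comps: Dict[int, List[int]] = {}
    for i in range(k):
        if in_graph[i]:
            comps.setdefault(uf.find(i), []).append(i)
    groups = []
    for idxs in comps.values():
        members = {sr.av_index[i] for i in idxs}
        score = float(np.max(np.abs(ds.pc.scores[idxs])))
        groups.append((score, sorted(members), members))
    # descending max score; lexical member order breaks exact ties
    groups.sort(key=lambda t: (-t[0], t[1]))
    return [
        AVGroup(ds.ds_index, i, members, score)
        for i, (score, _, members) in enumerate(groups, start=1)
    ]


def av_similarity(table: AddressTable, av_i: AV, av_j: AV) -> float:
    """Dice overlap of two AV covers: 2|cov_i n cov_j| / (|cov_i| + |cov_j|)."""
    ci, cj = table.cover(av_i), table.cover(av_j)
    denom = ci.size + cj.size
    if denom == 0:
        raise ValueError("similarity undefined for two empty covers")
    inter = np.intersect1d(ci, cj, assume_unique=True).size
    return 2.0 * inter / denom


def subgroup_clustering(
    group: AVGroup,
    table: AddressTable,
    cutoff: float = 0.5,
    method: str = "average",
) -> List[AVSubgroup]:
    """Split one AV-Group into AV-Subgroups by entity-cover overlap.

    Agglomerative clustering (``method`` linkage, default average) on the
    pairwise Dice similarity of member covers; merging stops once no
    inter-cluster similarity reaches ``cutoff``.  Subgroup ordinals are by
    descending member count, then lexical AV order.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    members = sorted(group.members)
    if len(members) == 1:
        clusters = [members]
    else:
        n = len(members)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - av_similarity(table, members[i], members[j])
                dist[i, j] = dist[j, i] = d
        z = linkage(squareform(dist, checks=False), method=method)
        flat = fcluster(z, t=1.0 - cutoff, criterion="distance")
        by_cluster: Dict[int, List[AV]] = {}
        for m, c in zip(members, flat):
            by_cluster.setdefault(int(c), []).append(m)
        clusters = list(by_cluster.values())
    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    return [
        AVSubgroup((group.ds_index, group.avg_index, i), set(c), group)
        for i, c in enumerate(clusters, start=1)
    ]


def dsu_cover(table: AddressTable, dsu: AVSubgroup) -> np.ndarray:
    """Entities containing every AV of the subgroup."""
    return eid_intersection(table, dsu.members)
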