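"""Entity clustering, class status assignment and wCL/nCL integration.

Each entity is placed in the cluster of the DSU whose AV set it shares most
(sharing = |entity AVs n DSU AVs| / |DSU AVs|); entities sharing nothing go
to an explicit outlier cluster.  Class status compares, per entity, the
number of accepted patterns of its given class (f_i) against those of every
other class: Cor / Inc / Und / OL / Cra (class readjusted).  Runs with the
class labels exploited (wCL) and ignored (nCL) are then integrated: the
ground truth stands unless a label discrepancy is spotted and confirmed by a
pattern of the other class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .dataset import CategoricalDataset
from .grouping import AVSubgroup
from .patterns import Pattern

OUTLIER_CODE: Tuple[int, int, int] = (0, 0, 0)  # explicit outlier cluster

COR = "Cor"
CRA = "Cra"
UND = "Und"
INC = "Inc"
OL = "OL"
STATUSES = (COR, CRA, UND, INC, OL)


@dataclass
class EntityCluster:
    dsu_code: Tuple[int, int, int]
    members: List[int]
    sharing: Dict[int, float] = field(default_factory=dict)

    @property
    def is_outlier(self) -> bool:
        return self.dsu_code == OUTLIER_CODE


@dataclass
class ClassStatusRecord:
    eid: int
    f: Dict[str, int]
    given_class: Optional[str]
    status: str
    adjusted_class: Optional[str]
    mode: str  # "wCL" or "nCL"
    final_status: Optional[str] = None
    final_class: Optional[str] = None

    @property
    def confirmed_class(self) -> Optional[str]:
        """The class this mode attests by at least one accepted pattern."""
        if self.status == COR:
            return self.given_class
        if self.status == CRA:
            return self.adjusted_class
        return None


def cluster_entities(
    dataset: CategoricalDataset, dsus: List[AVSubgroup]
) -> List[EntityCluster]:
    """Assign every entity to the DSU maximizing its AV-sharing score.

    Ties break to the lowest DSU code; all-zero sharing goes to the outlier
    cluster (code ``(0, 0, 0)``).
    """
    if not dsus:
        raise ValueError("entity clustering needs at least one DSU")
    dsus_sorted = sorted(dsus, key=lambda d: d.code)
    clusters: Dict[Tuple[int, int, int], EntityCluster] = {
        d.code: EntityCluster(d.code, []) for d in dsus_sorted
    }
    outlier = EntityCluster(OUTLIER_CODE, [])
    for eid in dataset.entity_ids:
        e_avs = dataset.entity_avs(eid)
        best_code, best_share = None, 0.0
        for d in dsus_sorted:
            share = len(e_avs & d.members) / len(d.members)
            if share > best_share:  # ties keep the lowest code (first seen)
                best_code, best_share = d.code, share
        if best_code is None:
            outlier.members.append(eid)
            outlier.sharing[eid] = 0.0
        else:
            clusters[best_code].members.append(eid)
            clusters[best_code].sharing[eid] = best_share
    out = [c for c in clusters.values()]
    if outlier.members:
        out.append(outlier)
    return out


def assign_class_status(
    f: Dict[str, int], given_class: Optional[str]
) -> Tuple[str, Optional[str]]:
    """Map an entity's per-class pattern counts to a class status.

    With f_g the count for the given class and f_k the other classes:
    Cor when f_g beats every other count; Inc when some f_k exceeds a
    non-zero f_g; Und when the non-zero maximum is shared; OL when all
    counts are zero; Cra (readjusted to argmax f_k) when f_g = 0 but some
    f_k > 0 — a tie at that argmax falls back to Und.
    """
    if given_class is None:
        raise ValueError("class status needs a given (or implicit) class")
    counts = dict(f)
    counts.setdefault(given_class, 0)
    mx = max(counts.values())
    if mx == 0:
        return OL, None
    fg = counts[given_class]
    top = sorted(c for c, n in counts.items() if n == mx)
    if fg == 0:
        return (CRA, top[0]) if len(top) == 1 else (UND, None)
    if fg < mx:
        return INC, None
    if len(top) > 1:
        return UND, None
    return COR, given_class


def status_records(
    dataset: CategoricalDataset,
    patterns: List[Pattern],
    labels: Dict[int, str],
    mode: str,
) -> List[ClassStatusRecord]:
    """Per-entity class-status records for one mode.

    ``labels`` are the given labels in wCL mode, the implicit (cluster
    majority) labels in nCL mode.  Every accepted pattern counts once in f,
    whatever its order.
    """
    classes = sorted(set(labels.values()))
    cover_sets = [(p, set(int(e) for e in p.cover)) for p in patterns]
    records = []
    for eid in dataset.entity_ids:
        f = {c: 0 for c in classes}
        for p, cov in cover_sets:
            if p.class_label is not None and eid in cov:
                f[p.class_label] += 1
        status, adj = assign_class_status(f, labels[eid])
        records.append(ClassStatusRecord(eid, f, labels[eid], status, adj, mode))
    return records


def implicit_labels(
    dataset: CategoricalDataset, clusters: List[EntityCluster]
) -> Dict[int, str]:
    """Implicit class of each entity: the majority given label of its cluster.

    Labels are used for evaluation only, never during discovery.  Without
    given labels the cluster code itself names the implicit group.  The
    majority tie-break is lexical, and entities in the outlier cluster keep
    their own label (a cluster of leftovers carries no class evidence).
    """
    given = dataset.class_labels
    out: Dict[int, str] = {}
    for cl in clusters:
        if given is None:
            name = "EC[%d %d %d]" % cl.dsu_code
            for eid in cl.members:
                out[eid] = name
            continue
        if cl.is_outlier:
            for eid in cl.members:
                out[eid] = given[eid]
            continue
        counts: Dict[str, int] = {}
        for eid in cl.members:
            counts[given[eid]] = counts.get(given[eid], 0) + 1
        if counts:
            best = max(counts.values())
            name = sorted(c for c, n in counts.items() if n == best)[0]
            for eid in cl.members:
                out[eid] = name
    return out


def integrate_class_status(
    wcl: ClassStatusRecord, ncl: ClassStatusRecord
) -> Tuple[str, Optional[str]]:
    """Merge the wCL and nCL statuses of one entity (Rules 1 and 2).

    Cor from wCL stands.  A confirmed readjustment (a class attested by at
    least one accepted pattern) from either mode overrides OL / Und / Inc in
    the other, with wCL preferred on conflict.  When neither mode confirms a
    class, the wCL status stands as is.
    """
    if wcl.eid != ncl.eid:
        raise ValueError("cannot integrate records of different entities")
    if wcl.status == COR:
        return COR, wcl.given_class
    w_conf = wcl.confirmed_class
    n_conf = ncl.confirmed_class
    if wcl.status == CRA and w_conf is not None:
        return CRA, w_conf
    if n_conf is not None:  # wCL is OL/Und/Inc here; nCL confirms a class
        return CRA, n_conf
    return wcl.status, None


def finalize_records(
    wcl_records: List[ClassStatusRecord],
    ncl_records: Optional[List[ClassStatusRecord]],
) -> List[ClassStatusRecord]:
    """Attach final status/class to the wCL records (in place) and return them."""
    if ncl_records is None:
        for r in wcl_records:
            r.final_status, r.final_class = r.status, r.confirmed_class
        return wcl_records
    by_eid = {r.eid: r for r in ncl_records}
    for r in wcl_records:
        r.final_status, r.final_class = integrate_class_status(r, by_eid[r.eid])
    return wcl_records


def compute_accuracy(records: List[ClassStatusRecord], readjusted: bool = True) -> float:
    """Class-association accuracy as a percentage.

    ``100 * (#Cor + #confirmed readjusted) / N``; Inc, Und and OL count as
    incorrect.  With ``readjusted=False`` the confirmed readjustments are
    not yet credited (the "before correction" figure).
    """
    if not records:
        raise ValueError("no records")
    n = len(records)
    good = 0
    for r in records:
        status = r.final_status if r.final_status is not None else r.status
        cls = r.final_class if r.final_status is not None else r.confirmed_class
        if status == COR:
            good += 1
        elif readjusted and status == CRA and cls is not None:
            good += 1
    return 100.0 * good / n


def cluster_placement_accuracy(
    clusters: List[EntityCluster], records: List[ClassStatusRecord]
) -> float:
    """Percentage of entities whose final class matches their cluster majority.

    A member is misplaced when its final class differs from the majority
    final class of its cluster; entities without a final class (OL/Und/Inc)
    count as misplaced.
    """
    by_eid = {r.eid: r for r in records}
    total, good = 0, 0
    for cl in clusters:
        classes = []
        for eid in cl.members:
            r = by_eid[eid]
            c = r.final_class or (r.given_class if (r.final_status or r.status) == COR else None)
            classes.append(c)
        counts: Dict[str, int] = {}
        for c in classes:
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
        majority = None
        if counts:
            best = max(counts.values())
            majority = sorted(c for c, n in counts.items() if n == best)[0]
        for c in classes:
            total += 1
            if c is not None and c == majority:
                good += 1
    return 100.0 * good / total if total else 0.0
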