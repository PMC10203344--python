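"""High-order pattern discovery inside each DSU.

A candidate is any subset (order >= 2) of a DSU's AVs.  Its significance is
tested with the pattern residual

    SR(P) = R(P) / sqrt(V(P)),   R(P) = (Occ(P) - Exp(P)) / sqrt(Exp(P)),

with the mutual-independence expectation Exp(P) = M * prod(Occ(AV)/M) and the
adjustment V(P) = 1 - prod(Occ(AV)/M) over the constituent AVs.  Accepted
patterns are reduced to delta-closed ones: a pattern is dropped when an
accepted strict superset supports it within ``delta`` occurrences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import prod, sqrt
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .dataset import AV, AddressTable, eid_intersection
from .disentangle import DEFAULT_THRESHOLD
from .grouping import AVSubgroup


@dataclass
class Pattern:
    avs: FrozenSet[AV]
    occ: int
    exp: float
    residual: float
    variance: float
    sr: float
    dsu_code: Tuple[int, int, int]
    cover: np.ndarray
    class_label: Optional[str] = None

    @property
    def order(self) -> int:
        return len(self.avs)

    def sorted_avs(self) -> List[AV]:
        return sorted(self.avs)


@dataclass
class UnionPattern:
    """Union of all accepted patterns' AVs within one DSU."""

    dsu_code: Tuple[int, int, int]
    avs: FrozenSet[AV]
    n_patterns: int


def pattern_sr(avs, table: AddressTable, n_entities: int):
    """Occurrence statistics and adjusted residual of one AV set.

    Returns ``(occ, exp, residual, variance, sr)``.  When some constituent
    AV occurs on every entity the adjustment vanishes and the raw residual
    is reported with a warning.
    """
    avs = list(avs)
    if len(avs) < 2:
        raise ValueError("a pattern candidate needs at least two AVs")
    m = n_entities
    occs = [table.occ(av) for av in avs]
    if any(o == 0 for o in occs):
        raise ValueError("every candidate AV must have a non-empty cover")
    occ = int(eid_intersection(table, avs).size)
    frac = prod(o / m for o in occs)
    exp = m * frac
    residual = (occ - exp) / sqrt(exp)
    variance = 1.0 - frac
    if variance <= 0:
        warnings.warn("pattern variance <= 0 (an AV covers every entity); SR = residual")
        sr = residual
    else:
        sr = residual / sqrt(variance)
    return occ, exp, residual, variance, sr


def discover_patterns(
    dsu: AVSubgroup,
    table: AddressTable,
    n_entities: int,
    threshold: float = DEFAULT_THRESHOLD,
    delta: int = 0,
) -> List[Pattern]:
    """Breadth-first candidate growth over subsets of one DSU's members.

    Candidates start at order 2; supersets of zero-support sets are pruned
    (support is anti-monotone), every remaining candidate is tested with
    :func:`pattern_sr`, and accepted patterns are passed through
    :func:`delta_closed_filter`.  For small DSUs this is exactly exhaustive
    enumeration.  Output is sorted by descending order then descending SR.
    """
    members = sorted(dsu.members)
    accepted: List[Pattern] = []
    if len(members) < 2:
        return accepted
    m = n_entities
    # level-wise growth keyed by sorted AV tuples; keep only support > 0
    level: Dict[Tuple[AV, ...], int] = {}
    for pair in combinations(members, 2):
        cov = eid_intersection(table, pair)
        if cov.size > 0:
            level[pair] = int(cov.size)
            _test_and_collect(pair, table, m, threshold, dsu, accepted)
    order = 2
    while level and order < len(members):
        order += 1
        nxt: Dict[Tuple[AV, ...], int] = {}
        keys = sorted(level)
        for a, b in combinations(keys, 2):
            if a[:-1] != b[:-1]:
                continue  # classic prefix join on sorted tuples
            cand = a + (b[-1],)
            # all (order-1)-subsets must have support > 0
            if any(
                tuple(sub) not in level for sub in combinations(cand, order - 1)
            ):
                continue
            cov = eid_intersection(table, cand)
            if cov.size == 0:
                continue
            # support anti-monotonicity: a superset never gains support
            assert cov.size <= min(level[a], level[b])
            nxt[cand] = int(cov.size)
            _test_and_collect(cand, table, m, threshold, dsu, accepted)
        level = nxt
    accepted = delta_closed_filter(accepted, delta)
    accepted.sort(key=lambda p: (-p.order, -p.sr, p.sorted_avs()))
    return accepted


def _test_and_collect(avs, table, m, threshold, dsu, accepted) -> None:
    occ, exp, residual, variance, sr = pattern_sr(avs, table, m)
    if sr > threshold:
        accepted.append(
            Pattern(
                frozenset(avs),
                occ,
                exp,
                residual,
                variance,
                sr,
                dsu.code,
                eid_intersection(table, avs),
            )
        )


def delta_closed_filter(patterns: List[Pattern], delta: int = 0) -> List[Pattern]:
    """Keep only delta-closed patterns.

    A pattern is removed when some accepted strict superset occurs at least
    ``occ - delta`` times; ``delta = 0`` gives classical closed patterns.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    out = []
    for p in patterns:
        closed = True
        for q in patterns:
            if p.avs < q.avs and q.occ >= p.occ - delta:
                closed = False
                break
        if closed:
            out.append(p)
    return out


def associate_pattern_class(pattern: Pattern, labels: Dict[int, str]) -> Optional[str]:
    """Class holding the plurality of the pattern's covering entities.

    Returns ``None`` (unassigned) when the top count is tied between
    classes.  The cover of an accepted pattern is never empty.
    """
    if pattern.cover.size == 0:
        raise ValueError("accepted pattern with empty cover")
    counts: Dict[str, int] = {}
    for eid in pattern.cover:
        c = labels[int(eid)]
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else None


def union_pattern(dsu_code, patterns: List[Pattern]) -> UnionPattern:
    avs: FrozenSet[AV] = frozenset()
    for p in patterns:
        avs = avs | p.avs
    return UnionPattern(dsu_code, avs, len(patterns))
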