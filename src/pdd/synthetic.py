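"""Synthetic mixed-mode tables with implanted AV associations.

The generator emulates the kind of illustrative dataset used throughout the
method's exposition: a uniform-random categorical background over M entities
and N attributes, with a handful of AV associations implanted on known
entity-ID ranges, optional label-flip noise, implant-cell corruption, and
rare groups spanning several classes.  The ground-truth manifest records
every implanted cell, true class and flipped label, so expected pattern
covers can be recomputed independently of the discovery pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import AV, CategoricalDataset

DEFAULT_ALPHABET = ["P", "Q", "R", "S", "T"]


@dataclass(frozen=True)
class Implant:
    """One AV association assigned to a block of entities.

    ``class_label=None`` keeps the target entities' existing labels
    (used for rare groups spanning several classes).
    """

    avs: Dict[str, str]
    eids: Tuple[int, ...]
    class_label: Optional[str] = None


@dataclass
class SyntheticSpec:
    m_entities: int
    attributes: List[Tuple[str, List[str]]]  # (name, alphabet)
    implants: List[Implant] = field(default_factory=list)
    classes: List[str] = field(default_factory=list)
    label_flip_rate: float = 0.0
    cell_noise_rate: float = 0.0
    labeled: bool = True
    exclusive_implants: bool = True
    seed: int = 0

    def validate(self) -> None:
        attr_alpha = dict(self.attributes)
        for imp in self.implants:
            for a, v in imp.avs.items():
                if a not in attr_alpha:
                    raise ValueError(f"implant references unknown attribute {a!r}")
                if v not in attr_alpha[a]:
                    raise ValueError(f"implant value {a}={v} outside the alphabet")
            for e in imp.eids:
                if not (1 <= e <= self.m_entities):
                    raise ValueError(f"implant EID {e} outside 1..{self.m_entities}")
        if not (0.0 <= self.label_flip_rate < 1.0):
            raise ValueError("label_flip_rate must be in [0, 1)")
        if not (0.0 <= self.cell_noise_rate < 1.0):
            raise ValueError("cell_noise_rate must be in [0, 1)")
        # no two implants may assign different values to one cell
        assigned: Dict[Tuple[int, str], str] = {}
        for imp in self.implants:
            for e in imp.eids:
                for a, v in imp.avs.items():
                    prev = assigned.get((e, a))
                    if prev is not None and prev != v:
                        raise ValueError(
                            f"conflicting implant values for cell (EID{e}, {a}): "
                            f"{prev} vs {v}"
                        )
                    assigned[(e, a)] = v


def generate(spec: SyntheticSpec) -> Tuple[CategoricalDataset, dict]:
    """Draw one dataset (plus ground-truth manifest) from a spec.

    Background cells are i.i.d. uniform over each attribute's alphabet;
    implant cells overwrite their targets and are then corrupted at
    ``cell_noise_rate``; labels come from implant classes (background
    entities uniform over the declared classes) and are flipped at
    ``label_flip_rate``.  With ``exclusive_implants`` any background entity
    that happens to contain a full implant AV set has one of those cells
    redrawn, so each implant's cover is exactly its target block, as in the
    illustrative address-table example.  Fully reproducible from the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.m_entities
    eids = list(range(1, m + 1))
    names = [a for a, _ in spec.attributes]
    cells = pd.DataFrame(index=eids, columns=names, dtype=object)
    for a, alphabet in spec.attributes:
        cells[a] = rng.choice(alphabet, size=m)
    implanted_cells: List[Tuple[int, str, str]] = []
    for imp in spec.implants:
        for e in imp.eids:
            for a, v in imp.avs.items():
                cells.loc[e, a] = v
                implanted_cells.append((e, a, v))
    if spec.exclusive_implants:
        alpha = dict(spec.attributes)
        for _ in range(16):  # a redraw could complete another implant; iterate
            dirty = False
            for imp in spec.implants:
                targets = set(imp.eids)
                items = sorted(imp.avs.items())
                spoil_attr = items[0][0]
                for e in eids:
                    if e in targets:
                        continue
                    if all(cells.loc[e, a] == v for a, v in items):
                        others = [
                            x for x in alpha[spoil_attr] if x != imp.avs[spoil_attr]
                        ]
                        cells.loc[e, spoil_attr] = others[int(rng.integers(len(others)))]
                        dirty = True
            if not dirty:
                break
    noised: List[Tuple[int, str]] = []
    if spec.cell_noise_rate > 0:
        alpha = dict(spec.attributes)
        for e, a, _v in implanted_cells:
            if rng.random() < spec.cell_noise_rate:
                cells.loc[e, a] = rng.choice(alpha[a])
                noised.append((e, a))
    labels: Optional[Dict[int, str]] = None
    true_classes: Dict[int, str] = {}
    flipped: List[int] = []
    if spec.labeled:
        classes = list(spec.classes) or sorted(
            {imp.class_label for imp in spec.implants if imp.class_label}
        )
        if not classes:
            raise ValueError("a labeled spec needs declared or implant classes")
        drawn = rng.choice(classes, size=m)
        labels = {e: str(c) for e, c in zip(eids, drawn)}
        for imp in spec.implants:
            if imp.class_label is None:
                continue
            for e in imp.eids:
                labels[e] = imp.class_label
        true_classes = dict(labels)
        if spec.label_flip_rate > 0:
            for e in eids:
                if rng.random() < spec.label_flip_rate:
                    others = [c for c in classes if c != labels[e]]
                    if others:
                        labels[e] = others[int(rng.integers(len(others)))]
                        flipped.append(e)
    dataset = CategoricalDataset(eids, names, cells, labels)
    manifest = {
        "seed": spec.seed,
        "implants": [
            {
                "avs": {a: v for a, v in sorted(imp.avs.items())},
                "eids": list(imp.eids),
                "class": imp.class_label,
            }
            for imp in spec.implants
        ],
        "implanted_cells": [[e, a, v] for e, a, v in implanted_cells],
        "noised_cells": [[e, a] for e, a in noised],
        "flipped_eids": flipped,
        "true_classes": {str(e): c for e, c in true_classes.items()},
    }
    return dataset, manifest


def implant_av_set(imp: Implant) -> frozenset:
    return frozenset(AV(a, v) for a, v in imp.avs.items())


def fig1_spec(
    seed: int = 0,
    label_flip_rate: float = 0.0,
    cell_noise_rate: float = 0.0,
) -> SyntheticSpec:
    """Replica of the illustrative 400 x 6 dataset with 3 implanted associations.

    The known triple {A2=P, A3=Q, A5=R} sits on EID75-129 (cover 55) and is
    *entangled* with a second association {A1=S, A4=T, A6=P} on EID100-189:
    thirty entities carry both, which is the phenomenon the method exists to
    disentangle.  A third association {A2=Q, A3=R, A5=P} occupies
    EID240-339.  The three AV sets are pairwise disjoint.  Entangled
    implants use disjoint attribute sets so no cell is contested; the
    overlap entities take the label of the smaller (later-listed) implant,
    which keeps every implant's cover label-majority of its own class.
    See docs/methods.md for the spectral sizing rationale.
    """
    attrs = [(f"A{i}", list(DEFAULT_ALPHABET)) for i in range(1, 7)]
    implants = [
        Implant({"A1": "S", "A4": "T", "A6": "P"}, tuple(range(100, 190)), "C2"),
        Implant({"A2": "P", "A3": "Q", "A5": "R"}, tuple(range(75, 130)), "C1"),
        Implant({"A2": "Q", "A3": "R", "A5": "P"}, tuple(range(240, 340)), "C3"),
    ]
    return SyntheticSpec(
        m_entities=400,
        attributes=attrs,
        implants=implants,
        classes=["C1", "C2", "C3"],
        label_flip_rate=label_flip_rate,
        cell_noise_rate=cell_noise_rate,
        seed=seed,
    )


def make_rare_group_spec(
    base: SyntheticSpec, group_size: int, pattern: Dict[str, str]
) -> SyntheticSpec:
    """Add a rare-group implant spanning entities of distinct classes.

    Picks one target entity from each of ``group_size`` distinct existing
    implant classes (the first EID of each block, deterministically) and
    implants ``pattern`` there while keeping the original labels, mimicking
    a small cross-class group carrying a common motif.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size > base.m_entities:
        raise ValueError("group_size exceeds the number of entities")
    by_class: Dict[str, int] = {}
    for imp in base.implants:
        if imp.class_label is not None and imp.class_label not in by_class:
            by_class[imp.class_label] = min(imp.eids)
    hosts = [by_class[c] for c in sorted(by_class)][:group_size]
    if len(hosts) < group_size:
        # fall back to leading background entities for the remainder
        used = set(hosts)
        extra = [e for e in range(1, base.m_entities + 1) if e not in used]
        hosts += extra[: group_size - len(hosts)]
    rare = Implant(dict(pattern), tuple(sorted(hosts)), None)
    return replace(base, implants=list(base.implants) + [rare])
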