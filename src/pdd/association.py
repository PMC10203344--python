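"""Pairwise AV association: frequency matrix and adjusted standardized residuals.

For two attribute values a and b with marginal occurrences Occ(a), Occ(b) and
co-occurrence Occ(a<->b) among T records, the adjusted standardized residual is

    SR(a<->b) = (Occ(a<->b) - Exp) / sqrt(Exp) * (1 - Occ(a)*Occ(b) / T^2)

with the independence expectation Exp = Occ(a)*Occ(b)/T.  Values of the same
attribute are structurally exclusive (their co-occurrence is always zero), so
their entries are forced to 0 rather than reported as strong anti-association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt
from typing import List

import numpy as np
import pandas as pd

from .dataset import AV, AddressTable, CategoricalDataset, eid_intersection


@dataclass
class FrequencyMatrix:
    """K x K symmetric integer matrix of pairwise AV co-occurrence counts."""

    av_index: List[AV]
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [str(av) for av in self.av_index]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


@dataclass
class SRMatrix:
    """K x K symmetric matrix of adjusted standardized residuals.

    Each row is the *AV-vector* of its AV: its coordinates are the residuals
    of that AV's association with every other AV.  Diagonal and
    same-attribute entries are fixed at 0.
    """

    av_index: List[AV]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [str(av) for av in self.av_index]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def association_mask(self) -> np.ndarray:
        """Boolean K x K mask of the meaningful entries: off-diagonal pairs
        of *different* attributes."""
        attrs = [av.attribute for av in self.av_index]
        k = len(attrs)
        mask = np.ones((k, k), dtype=bool)
        np.fill_diagonal(mask, False)
        for i in range(k):
            for j in range(k):
                if attrs[i] == attrs[j]:
                    mask[i, j] = False
        return mask


def sr_pair(
    occ_a: int,
    occ_b: int,
    occ_ab: int,
    total: int,
    variant: str = "printed",
) -> float:
    """Adjusted standardized residual for one AV pair.

    ``variant="printed"`` multiplies the raw residual by
    ``1 - occ_a*occ_b/total**2``; ``variant="haberman"`` instead divides by
    ``sqrt((1-occ_a/total)(1-occ_b/total))`` (the classical adjusted
    residual) for sensitivity analysis.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    exp = occ_a * occ_b / total
    if exp == 0:
        warnings.warn("Exp=0 for an AV pair (an AV never occurs); SR set to 0")
        return 0.0
    base = (occ_ab - exp) / sqrt(exp)
    if variant == "printed":
        return base * (1.0 - occ_a * occ_b / total**2)
    if variant == "haberman":
        denom = (1.0 - occ_a / total) * (1.0 - occ_b / total)
        if denom <= 0:
            warnings.warn("degenerate Haberman denominator; SR set to raw residual")
            return base
        return base / sqrt(denom)
    raise ValueError(f"unknown residual variant {variant!r}")


def build_sr_matrix(
    dataset: CategoricalDataset,
    table: AddressTable,
    variant: str = "printed",
):
    """Build the frequency and SR matrices over all distinct AVs.

    Co-occurrence counts come from Address-Table intersections, never from
    rescanning rows.  Returns ``(FrequencyMatrix, SRMatrix)``.
    """
    av_index = dataset.av_universe()
    k = len(av_index)
    if k < 2:
        raise ValueError("need at least two distinct AVs to build an SR matrix")
    total = dataset.n_entities
    counts = np.zeros((k, k), dtype=np.int64)
    values = np.zeros((k, k), dtype=float)
    occs = [table.occ(av) for av in av_index]
    for i in range(k):
        for j in range(i + 1, k):
            if av_index[i].attribute == av_index[j].attribute:
                continue  # structurally exclusive; stays 0
            c = int(eid_intersection(table, (av_index[i], av_index[j])).size)
            counts[i, j] = counts[j, i] = c
            s = sr_pair(occs[i], occs[j], c, total, variant=variant)
            values[i, j] = values[j, i] = s
    return FrequencyMatrix(av_index, counts), SRMatrix(av_index, values)
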