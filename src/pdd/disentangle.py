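"""Association disentanglement: PCA of the SR matrix and significant spaces.

The symmetric SR matrix is eigendecomposed *without centering or rescaling*
(its entries are already standardized residuals; centering would destroy the
interpretation of rows as association vectors).  Each principal component
yields a rank-1 reconstructed SR matrix (RSR); components whose RSR contains
at least one statistically significant positive association between AVs of
different attributes are retained as disentangled spaces (DS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .association import SRMatrix

DEFAULT_THRESHOLD = 1.96  # 95% confidence on a standardized residual


@dataclass
class PrincipalComponent:
    index: int  # 1-based rank by descending eigenvalue
    eigenvalue: float
    loading: np.ndarray  # unit vector, length K
    scores: np.ndarray  # projection of each AV-vector onto the loading


@dataclass
class DisentangledSpace:
    pc: PrincipalComponent
    rsr: np.ndarray  # K x K rank-1 reconstructed SR matrix
    significant: bool
    max_assoc: float = float("-inf")  # max RSR over distinct-attribute pairs
    ds_index: int = 0  # 1-based ordinal among significant spaces only


def decompose(sr: SRMatrix) -> List[PrincipalComponent]:
    """Full eigendecomposition of the (uncentered) symmetric SR matrix.

    Components are ordered by descending eigenvalue.  The sign of each
    eigenvector is fixed by making its largest-magnitude coordinate
    positive, so downstream DS numbering is reproducible.
    """
    values = np.asarray(sr.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("SR matrix contains non-finite entries")
    if values.shape[0] < 2:
        raise ValueError("need K >= 2 AVs")
    w, v = np.linalg.eigh(values)
    order = np.argsort(w)[::-1]
    pcs: List[PrincipalComponent] = []
    for rank, idx in enumerate(order, start=1):
        loading = v[:, idx].copy()
        pivot = int(np.argmax(np.abs(loading)))
        if loading[pivot] < 0:
            loading = -loading
        scores = values @ loading  # equals eigenvalue * loading
        pcs.append(PrincipalComponent(rank, float(w[idx]), loading, scores))
    return pcs


def reconstruct_rsr(sr: SRMatrix, pc: PrincipalComponent) -> np.ndarray:
    """Rank-1 reconstructed SR matrix for one PC (scores outer loading).

    Row i is AV-vector i's projection on the PC expressed in the original
    coordinates; summing over all PCs reproduces the SR matrix.
    """
    return np.outer(pc.scores, pc.loading)


def build_spaces(
    sr: SRMatrix,
    pcs: List[PrincipalComponent] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    use_abs: bool = False,
) -> List[DisentangledSpace]:
    """Reconstruct every PC and flag significance.

    A space is significant when the maximum reconstructed residual over
    distinct-attribute AV pairs exceeds ``threshold``; with ``use_abs`` the
    magnitude is tested instead of the signed value.
    """
    if pcs is None:
        pcs = decompose(sr)
    mask = sr.association_mask()
    spaces = []
    for pc in pcs:
        rsr = reconstruct_rsr(sr, pc)
        assoc = np.abs(rsr[mask]) if use_abs else rsr[mask]
        mx = float(np.max(assoc)) if assoc.size else float("-inf")
        spaces.append(DisentangledSpace(pc, rsr, mx > threshold, mx))
    return spaces


def select_significant_ds(
    spaces: List[DisentangledSpace], threshold: float = DEFAULT_THRESHOLD
) -> List[DisentangledSpace]:
    """Keep spaces whose maximum association exceeds ``threshold`` and
    re-index them 1..D in original eigenvalue order."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    selected = []
    for s in spaces:
        s.significant = s.max_assoc > threshold
        if s.significant:
            s.ds_index = len(selected) + 1
            selected.append(s)
    return selected
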