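"""Dataset ingestion, discretization and the Entity-ID Address Table.

A relational table of M entities by N attributes is reduced to purely
categorical *attribute values* (AVs).  Numeric columns are quantized into
equal-frequency intervals so that every attribute assumes a finite alphabet.
The Address Table lists, for every distinct AV, the sorted entity IDs whose
record contains that AV; the support of any AV set is then the cardinality
of the intersection of the member lists, which is the counting primitive
used by every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd


class AV(NamedTuple):
    """One categorical value of one attribute, e.g. ``AV("A2", "P")``."""

    attribute: str
    value: str

    def __str__(self) -> str:  # "Attr=Value" label used in exports
        return f"{self.attribute}={self.value}"


MISSING = None  # canonical in-memory missing marker


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    if isinstance(x, str) and x == "":
        return True
    return pd.isna(x)


@dataclass
class CategoricalDataset:
    """Discretized M x N table with entity IDs and an optional class column.

    Parameters
    ----------
    entity_ids : ordered unique entity identifiers (1-based integers by default).
    attributes : ordered attribute names.
    cells : DataFrame indexed by entity id, one column per attribute, values
        are strings or missing.
    class_labels : optional map entity id -> class name, covering every entity.
    """

    entity_ids: List[int]
    attributes: List[str]
    cells: pd.DataFrame
    class_labels: Optional[Dict[int, str]] = None
    discretization: Dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entity_ids) == 0:
            raise ValueError("dataset needs at least one entity")
        if len(self.attributes) == 0:
            raise ValueError("dataset needs at least one attribute")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("entity ids must be unique")
        if list(self.cells.index) != list(self.entity_ids):
            self.cells = self.cells.loc[self.entity_ids]
        if list(self.cells.columns) != list(self.attributes):
            self.cells = self.cells[self.attributes]
        if self.class_labels is not None:
            missing = set(self.entity_ids) - set(self.class_labels)
            if missing:
                raise ValueError(f"class labels missing for entities {sorted(missing)[:5]}")

    @property
    def n_entities(self) -> int:
        """M, also the total record count T of the residual formula."""
        return len(self.entity_ids)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    def entity_avs(self, eid: int) -> frozenset:
        """The set of AVs present on one entity (missing cells contribute none)."""
        row = self.cells.loc[eid]
        return frozenset(
            AV(a, str(v)) for a, v in row.items() if not _is_missing(v)
        )

    def av_universe(self) -> List[AV]:
        """All distinct AVs, attribute order then lexical value order."""
        out: List[AV] = []
        for a in self.attributes:
            vals = sorted(
                {str(v) for v in self.cells[a] if not _is_missing(v)}
            )
            out.extend(AV(a, v) for v in vals)
        return out

    @property
    def classes(self) -> List[str]:
        if self.class_labels is None:
            return []
        return sorted(set(self.class_labels.values()))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        eid_col: Optional[str] = None,
        class_col: Optional[str] = None,
        numeric_cols: Optional[Sequence[str]] = None,
        n_bins: int | Dict[str, int] = 3,
        missing_as_av: bool = False,
    ) -> "CategoricalDataset":
        """Build a dataset from a raw mixed-mode DataFrame.

        Numeric columns (``numeric_cols``, or auto-detected float/int columns
        when None) are discretized into ``n_bins`` equal-frequency intervals;
        ``n_bins`` may be a per-attribute dict.  When ``missing_as_av`` is
        true, missing cells become an explicit ``"<missing>"`` value instead
        of being excluded from all covers.
        """
        df = df.copy()
        if eid_col is not None:
            eids = [int(e) for e in df[eid_col]]
            df = df.drop(columns=[eid_col])
        else:
            eids = list(range(1, len(df) + 1))
        labels = None
        if class_col is not None:
            labels = {e: str(v) for e, v in zip(eids, df[class_col])}
            df = df.drop(columns=[class_col])
        attributes = list(df.columns)
        if numeric_cols is None:
            numeric_cols = [c for c in attributes if pd.api.types.is_numeric_dtype(df[c])]
        disc_map: Dict[str, list] = {}
        cells = pd.DataFrame(index=eids)
        for col in attributes:
            series = df[col]
            if col in numeric_cols:
                bins = n_bins[col] if isinstance(n_bins, dict) else n_bins
                vals = series.to_numpy(dtype=float)
                if np.all(np.isnan(vals)):
                    raise ValueError(f"attribute {col!r} has no non-missing values")
                lab, bounds = discretize_numeric(vals, bins)
                disc_map[col] = [float(b) for b in bounds]
                cells[col] = lab
            else:
                cells[col] = [
                    None if _is_missing(v) else str(v) for v in series
                ]
        if missing_as_av:
            cells = cells.where(cells.notna(), "<missing>")
        return cls(eids, attributes, cells, labels, disc_map)


def discretize_numeric(values, n_bins: int):
    """Equal-frequency quantization of one numeric attribute.

    Returns ``(labels, boundaries)`` where labels are ``"bin1".."binK"``
    (missing stays missing) and boundaries are the interior quantile cuts.
    Values exactly on a boundary fall in the lower bin, so the mapping is
    deterministic under ties; a constant column collapses to a single bin.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        raise ValueError("cannot discretize an all-missing column")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    qs = np.quantile(finite, [i / n_bins for i in range(1, n_bins)])
    labels: List[Optional[str]] = []
    for v in arr:
        if np.isnan(v):
            labels.append(None)
        else:
            # ties at a boundary go to the lower bin: count strict q < v
            k = int(np.sum(qs < v))
            labels.append(f"bin{k + 1}")
    return labels, list(qs)


@dataclass
class AddressTable:
    """Per-AV sorted entity-ID lists (Entity-ID Address Table).

    ``entries[av]`` is a strictly increasing int64 array of the EIDs whose
    record contains ``av``; its length is the marginal occurrence Occ(av).
    """

    entries: Dict[AV, np.ndarray]

    def occ(self, av: AV) -> int:
        cov = self.entries.get(av)
        return 0 if cov is None else int(cov.size)

    def cover(self, av: AV) -> np.ndarray:
        return self.entries.get(av, np.empty(0, dtype=np.int64))

    def avs(self) -> List[AV]:
        return list(self.entries.keys())


def build_address_table(dataset: CategoricalDataset) -> AddressTable:
    """Scan the table once and list, for each AV, its covering entity IDs."""
    entries: Dict[AV, List[int]] = {}
    eids = np.asarray(dataset.entity_ids, dtype=np.int64)
    for a in dataset.attributes:
        col = dataset.cells[a].to_numpy(dtype=object)
        for eid, v in zip(eids, col):
            if _is_missing(v):
                continue
            entries.setdefault(AV(a, str(v)), []).append(int(eid))
    return AddressTable(
        {av: np.asarray(sorted(lst), dtype=np.int64) for av, lst in entries.items()}
    )


def eid_intersection(table: AddressTable, av_set: Iterable[AV]) -> np.ndarray:
    """EIDs of entities containing *all* AVs in ``av_set`` (sorted ascending).

    The cardinality of the result is the co-occurrence count used by every
    statistic downstream.  An AV absent from the table has an empty cover,
    which absorbs the whole intersection.
    """
    avs = list(av_set)
    if not avs:
        raise ValueError("eid_intersection of an empty AV set is undefined")
    # intersect smallest-first to keep intermediate arrays short
    covers = sorted((table.cover(av) for av in avs), key=len)
    out = covers[0]
    for cov in covers[1:]:
        if out.size == 0:
            break
        out = np.intersect1d(out, cov, assume_unique=True)
    return out


def load_csv(
    path,
    eid_col: Optional[str] = None,
    class_col: Optional[str] = None,
    numeric_cols: Optional[Sequence[str]] = None,
    n_bins: int | Dict[str, int] = 3,
    sep: Optional[str] = None,
    missing_as_av: bool = False,
) -> CategoricalDataset:
    """Read a CSV/TSV with a header row into a :class:`CategoricalDataset`."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return CategoricalDataset.from_dataframe(
        df,
        eid_col=eid_col,
        class_col=class_col,
        numeric_cols=numeric_cols,
        n_bins=n_bins,
        missing_as_av=missing_as_av,
    )
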