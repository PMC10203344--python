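"""End-to-end orchestration and the three-space knowledge base.

The pipeline runs: address table -> SR matrix -> PCA disentanglement ->
AV-Group / AV-Subgroup (DSU) formation -> per-DSU pattern discovery ->
entity clustering -> class status in wCL (labels exploited) and nCL (labels
ignored) modes -> status integration.  Discovery (steps 1-5) never touches
the labels, so the two modes share everything up to status assignment.

The resulting knowledge base links three views: the *knowledge space*
(DSU x class pattern-occurrence counts), the *pattern space* (accepted and
union patterns per DSU) and the *entity space* (per-entity pattern
indicators and class statuses).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .association import FrequencyMatrix, SRMatrix, build_sr_matrix
from .dataset import AV, AddressTable, CategoricalDataset, build_address_table
from .disentangle import build_spaces, decompose, select_significant_ds
from .entity_class import (
    ClassStatusRecord,
    EntityCluster,
    cluster_entities,
    cluster_placement_accuracy,
    compute_accuracy,
    finalize_records,
    implicit_labels,
    status_records,
)
from .grouping import AVSubgroup, av_clustering, subgroup_clustering
from .patterns import (
    Pattern,
    UnionPattern,
    associate_pattern_class,
    discover_patterns,
    union_pattern,
)

SCHEMA_VERSION = 1


@dataclass
class PDDConfig:
    """Tunable parameters of the pipeline.

    sr_threshold : significance gate on standardized residuals (1.96 ~ 95%).
    sim_cutoff : minimum entity-cover Dice overlap for AVs to share a subgroup.
    delta : closedness slack; 0 keeps classical closed patterns only.
    n_bins : default equal-frequency bins for numeric attributes.
    residual_variant : "printed" multiplier form or "haberman" classical form.
    linkage : subgroup agglomeration linkage (average/single/complete).
    use_abs_rsr : test |RSR| instead of signed RSR for DS significance.
    mode : "both", "wcl" or "ncl".
    """

    n_bins: int = 3
    sr_threshold: float = 1.96
    sim_cutoff: float = 0.5
    delta: int = 0
    residual_variant: str = "printed"
    linkage: str = "average"
    use_abs_rsr: bool = False
    missing_as_av: bool = False
    mode: str = "both"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class KnowledgeBase:
    knowledge_space: pd.DataFrame  # DSU label x class -> pattern-occurrence counts
    pattern_space: List[dict]
    entity_space: pd.DataFrame
    provenance: dict
    # rich in-memory objects (not serialized verbatim)
    dsus: List[AVSubgroup] = field(default_factory=list)
    patterns: List[Pattern] = field(default_factory=list)
    union_patterns: List[UnionPattern] = field(default_factory=list)
    clusters: List[EntityCluster] = field(default_factory=list)
    wcl_records: Optional[List[ClassStatusRecord]] = None
    ncl_records: Optional[List[ClassStatusRecord]] = None
    accuracy_before: Optional[float] = None
    accuracy_after: Optional[float] = None
    placement_accuracy: Optional[float] = None


def _dsu_label(code: Tuple[int, int, int]) -> str:
    return "DSU[%d %d %d]" % code


def run_pipeline(dataset: CategoricalDataset, config: Optional[PDDConfig] = None) -> KnowledgeBase:
    """Execute the full discovery-and-correction pipeline on one dataset."""
    config = config or PDDConfig()
    table = build_address_table(dataset)
    _freq, sr = build_sr_matrix(dataset, table, variant=config.residual_variant)
    pcs = decompose(sr)
    spaces = build_spaces(sr, pcs, config.sr_threshold, use_abs=config.use_abs_rsr)
    significant = select_significant_ds(spaces, config.sr_threshold)

    dsus: List[AVSubgroup] = []
    for ds in significant:
        for group in av_clustering(ds, sr, config.sr_threshold):
            dsus.extend(
                subgroup_clustering(group, table, config.sim_cutoff, config.linkage)
            )

    patterns: List[Pattern] = []
    unions: List[UnionPattern] = []
    for dsu in dsus:
        found = discover_patterns(
            dsu, table, dataset.n_entities, config.sr_threshold, config.delta
        )
        patterns.extend(found)
        if found:
            unions.append(union_pattern(dsu.code, found))

    clusters = cluster_entities(dataset, dsus) if dsus else []

    wcl_records = ncl_records = None
    eval_labels: Optional[Dict[int, str]] = None
    has_labels = dataset.class_labels is not None
    run_wcl = config.mode in ("both", "wcl") and has_labels
    run_ncl = config.mode in ("both", "ncl")

    if run_wcl:
        for p in patterns:
            p.class_label = associate_pattern_class(p, dataset.class_labels)
        wcl_records = status_records(dataset, patterns, dataset.class_labels, "wCL")

    ncl_patterns = patterns
    if run_ncl and clusters:
        impl = implicit_labels(dataset, clusters)
        # re-associate pattern classes against implicit labels on copies of
        # the class field only; discovery itself is label-free
        ncl_patterns = [copy.copy(p) for p in patterns]
        for p in ncl_patterns:
            p.class_label = associate_pattern_class(p, impl)
        ncl_records = status_records(dataset, ncl_patterns, impl, "nCL")

    records: Optional[List[ClassStatusRecord]] = None
    if wcl_records is not None:
        records = finalize_records(wcl_records, ncl_records)
    elif ncl_records is not None:
        records = finalize_records(ncl_records, None)

    accuracy_before = accuracy_after = placement = None
    if records is not None:
        accuracy_before = compute_accuracy(records, readjusted=False)
        accuracy_after = compute_accuracy(records, readjusted=True)
        if clusters:
            placement = cluster_placement_accuracy(clusters, records)
        eval_labels = {
            r.eid: (r.final_class or r.given_class) for r in records
        }

    ks = _knowledge_space(dsus, patterns if run_wcl else ncl_patterns, eval_labels)
    ps = _pattern_space(dsus, patterns if run_wcl else ncl_patterns, unions)
    es = _entity_space(dataset, dsus, patterns if run_wcl else ncl_patterns, records, ncl_records)
    provenance = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.to_dict(),
        "n_entities": dataset.n_entities,
        "n_attributes": dataset.n_attributes,
        "n_avs": len(sr.av_index),
        "n_significant_ds": len(significant),
        "n_dsus": len(dsus),
        "n_patterns": len(patterns),
        "discretization": dataset.discretization,
    }
    return KnowledgeBase(
        knowledge_space=ks,
        pattern_space=ps,
        entity_space=es,
        provenance=provenance,
        dsus=dsus,
        patterns=patterns if run_wcl else ncl_patterns,
        union_patterns=unions,
        clusters=clusters,
        wcl_records=wcl_records,
        ncl_records=ncl_records,
        accuracy_before=accuracy_before,
        accuracy_after=accuracy_after,
        placement_accuracy=placement,
    )


def _knowledge_space(
    dsus: List[AVSubgroup],
    patterns: List[Pattern],
    eval_labels: Optional[Dict[int, str]],
) -> pd.DataFrame:
    rows = pd.Index(
        [_dsu_label(d.code) for d in sorted(dsus, key=lambda d: d.code)], name="DSU"
    )
    if eval_labels is None:
        return pd.DataFrame(index=rows)
    classes = sorted(set(eval_labels.values()))
    ks = pd.DataFrame(0, index=rows, columns=classes, dtype=np.int64)
    for p in patterns:
        row = _dsu_label(p.dsu_code)
        for eid in p.cover:
            ks.loc[row, eval_labels[int(eid)]] += 1
    return ks


def _pattern_space(
    dsus: List[AVSubgroup],
    patterns: List[Pattern],
    unions: List[UnionPattern],
) -> List[dict]:
    union_by_code = {u.dsu_code: u for u in unions}
    out = []
    for dsu in sorted(dsus, key=lambda d: d.code):
        pats = [p for p in patterns if p.dsu_code == dsu.code]
        u = union_by_code.get(dsu.code)
        out.append(
            {
                "dsu": _dsu_label(dsu.code),
                "members": [str(av) for av in dsu.sorted_members()],
                "union_pattern": sorted(str(av) for av in u.avs) if u else [],
                "n_patterns": len(pats),
                "patterns": [
                    {
                        "avs": [str(av) for av in p.sorted_avs()],
                        "order": p.order,
                        "occ": p.occ,
                        "exp": round(p.exp, 6),
                        "sr": round(p.sr, 6),
                        "class": p.class_label,
                        "cover_size": int(p.cover.size),
                    }
                    for p in pats
                ],
            }
        )
    return out


def _entity_space(
    dataset: CategoricalDataset,
    dsus: List[AVSubgroup],
    patterns: List[Pattern],
    records: Optional[List[ClassStatusRecord]],
    ncl_records: Optional[List[ClassStatusRecord]],
) -> pd.DataFrame:
    codes = [d.code for d in sorted(dsus, key=lambda d: d.code)]
    cover_sets = {
        code: [set(int(e) for e in p.cover) for p in patterns if p.dsu_code == code]
        for code in codes
    }
    data: Dict[str, list] = {"EID": list(dataset.entity_ids)}
    for code in codes:
        data[_dsu_label(code)] = [
            sum(1 for cov in cover_sets[code] if eid in cov)
            for eid in dataset.entity_ids
        ]
    if dataset.class_labels is not None:
        data["given_class"] = [dataset.class_labels[e] for e in dataset.entity_ids]
    if records is not None:
        by_eid = {r.eid: r for r in records}
        data["status"] = [by_eid[e].status for e in dataset.entity_ids]
        if ncl_records is not None:
            ncl_by = {r.eid: r for r in ncl_records}
            data["ncl_status"] = [ncl_by[e].status for e in dataset.entity_ids]
        data["final_status"] = [
            by_eid[e].final_status or by_eid[e].status for e in dataset.entity_ids
        ]
        data["final_class"] = [
            by_eid[e].final_class or "" for e in dataset.entity_ids
        ]
    return pd.DataFrame(data)


def export_kb(kb: KnowledgeBase, directory) -> List[Path]:
    """Write the knowledge base as TSV/JSON files with stable ordering."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    p = directory / "knowledge_space.tsv"
    kb.knowledge_space.to_csv(p, sep="\t", index_label="DSU")
    paths.append(p)
    p = directory / "pattern_space.json"
    p.write_text(json.dumps(kb.pattern_space, indent=1, sort_keys=True) + "\n")
    paths.append(p)
    p = directory / "entity_space.tsv"
    kb.entity_space.to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = directory / "provenance.json"
    p.write_text(json.dumps(kb.provenance, indent=1, sort_keys=True) + "\n")
    paths.append(p)
    return paths


def load_kb(directory) -> KnowledgeBase:
    """Reload an exported knowledge base (the serialized views only)."""
    directory = Path(directory)
    ks = pd.read_csv(directory / "knowledge_space.tsv", sep="\t", index_col="DSU")
    ps = json.loads((directory / "pattern_space.json").read_text())
    es = pd.read_csv(directory / "entity_space.tsv", sep="\t")
    prov = json.loads((directory / "provenance.json").read_text())
    return KnowledgeBase(ks, ps, es, prov)
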