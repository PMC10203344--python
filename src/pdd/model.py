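"""Model/Results front end over the discovery pipeline.

``PDD`` holds a categorical dataset plus configuration; ``fit`` runs the
pipeline and returns a :class:`PDDResults` carrying the knowledge base, the
discovered patterns, class statuses and accuracy figures, with a
``summary()`` text table in the style of classical statistical modelling
packages.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import pandas as pd

from .dataset import CategoricalDataset
from .knowledge import KnowledgeBase, PDDConfig, run_pipeline


class PDD:
    """Pattern discovery and disentanglement model for one dataset."""

    def __init__(self, dataset: CategoricalDataset, config: Optional[PDDConfig] = None):
        self.dataset = dataset
        self.config = config or PDDConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        eid_col: Optional[str] = None,
        class_col: Optional[str] = None,
        numeric_cols: Optional[Sequence[str]] = None,
        config: Optional[PDDConfig] = None,
        **config_kwargs,
    ) -> "PDD":
        """Build the model straight from a raw mixed-mode DataFrame."""
        if config is None:
            config = PDDConfig(**config_kwargs)
        elif config_kwargs:
            raise ValueError("pass either a config object or keyword overrides")
        dataset = CategoricalDataset.from_dataframe(
            df,
            eid_col=eid_col,
            class_col=class_col,
            numeric_cols=numeric_cols,
            n_bins=config.n_bins,
            missing_as_av=config.missing_as_av,
        )
        return cls(dataset, config)

    def fit(self) -> "PDDResults":
        kb = run_pipeline(self.dataset, self.config)
        return PDDResults(self, kb)


class PDDResults:
    """Fitted results: knowledge base, patterns, statuses, accuracies."""

    def __init__(self, model: PDD, kb: KnowledgeBase):
        self.model = model
        self.kb = kb

    # -- convenient views -------------------------------------------------
    @property
    def knowledge_space(self) -> pd.DataFrame:
        return self.kb.knowledge_space

    @property
    def entity_space(self) -> pd.DataFrame:
        return self.kb.entity_space

    @property
    def patterns(self) -> pd.DataFrame:
        rows = [
            {
                "dsu": "DSU[%d %d %d]" % p.dsu_code,
                "avs": " ".join(str(av) for av in p.sorted_avs()),
                "order": p.order,
                "occ": p.occ,
                "exp": p.exp,
                "sr": p.sr,
                "class": p.class_label,
            }
            for p in self.kb.patterns
        ]
        return pd.DataFrame(rows)

    @property
    def accuracy_before(self) -> Optional[float]:
        return self.kb.accuracy_before

    @property
    def accuracy_after(self) -> Optional[float]:
        return self.kb.accuracy_after

    @property
    def placement_accuracy(self) -> Optional[float]:
        return self.kb.placement_accuracy

    def status_counts(self) -> Dict[str, int]:
        col = "final_status"
        if col not in self.kb.entity_space:
            return {}
        return self.kb.entity_space[col].value_counts().to_dict()

    def save(self, directory) -> None:
        from .knowledge import export_kb

        export_kb(self.kb, directory)

    # -- report -----------------------------------------------------------
    def summary(self) -> str:
        prov = self.kb.provenance
        lines = []
        bar = "=" * 64
        lines.append(bar)
        lines.append("Pattern Discovery and Disentanglement Results".center(64))
        lines.append(bar)
        lines.append(f"No. entities (M):      {prov['n_entities']}")
        lines.append(f"No. attributes (N):    {prov['n_attributes']}")
        lines.append(f"Distinct AVs (K):      {prov['n_avs']}")
        lines.append(f"Significant spaces:    {prov['n_significant_ds']}")
        lines.append(f"DS units (DSU):        {prov['n_dsus']}")
        lines.append(f"Accepted patterns:     {prov['n_patterns']}")
        cfg = prov["config"]
        lines.append(
            f"SR threshold: {cfg['sr_threshold']}   sim cutoff: {cfg['sim_cutoff']}"
            f"   delta: {cfg['delta']}"
        )
        if self.kb.accuracy_before is not None:
            lines.append("-" * 64)
            lines.append(
                f"Class association accuracy: {self.kb.accuracy_before:.2f}% before"
                f" / {self.kb.accuracy_after:.2f}% after readjustment"
            )
            counts = self.status_counts()
            if counts:
                lines.append(
                    "Status counts: "
                    + "  ".join(f"{k}={v}" for k, v in sorted(counts.items()))
                )
        if self.kb.placement_accuracy is not None:
            lines.append(
                f"Cluster placement accuracy: {self.kb.placement_accuracy:.2f}%"
            )
        if self.kb.patterns:
            lines.append("-" * 64)
            lines.append("Top patterns (by order, SR):")
            for p in self.kb.patterns[:8]:
                avs = " ".join(str(av) for av in p.sorted_avs())
                cls = f"  class={p.class_label}" if p.class_label else ""
                lines.append(
                    f"  DSU[%d %d %d]  {{{avs}}}  occ={p.occ}  SR={p.sr:.2f}{cls}"
                    % p.dsu_code
                )
        lines.append(bar)
        return "\n".join(lines)
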