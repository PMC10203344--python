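"""pdd: pattern discovery and disentanglement for mixed-mode tabular data.

Turns a relational table into statistically significant, source-disentangled
attribute-value association patterns, pattern/entity clusters, auto-corrected
class associations and a linked three-space knowledge base.
"""

__version__ = "0.1.0"

from .dataset import (  # noqa: F401
    AV,
    AddressTable,
    CategoricalDataset,
    build_address_table,
    discretize_numeric,
    eid_intersection,
    load_csv,
)
from .association import FrequencyMatrix, SRMatrix, build_sr_matrix, sr_pair  # noqa: F401
from .disentangle import (  # noqa: F401
    DisentangledSpace,
    PrincipalComponent,
    build_spaces,
    decompose,
    reconstruct_rsr,
    select_significant_ds,
)
from .grouping import (  # noqa: F401
    AVGroup,
    AVSubgroup,
    av_clustering,
    av_similarity,
    subgroup_clustering,
)
from .patterns import (  # noqa: F401
    Pattern,
    UnionPattern,
    associate_pattern_class,
    delta_closed_filter,
    discover_patterns,
    pattern_sr,
)
from .entity_class import (  # noqa: F401
    ClassStatusRecord,
    EntityCluster,
    assign_class_status,
    cluster_entities,
    compute_accuracy,
    integrate_class_status,
)
from .knowledge import KnowledgeBase, PDDConfig, export_kb, load_kb, run_pipeline  # noqa: F401
from .model import PDD, PDDResults  # noqa: F401
from .synthetic import (  # noqa: F401
    Implant,
    SyntheticSpec,
    fig1_spec,
    generate,
    make_rare_group_spec,
)
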