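"""Bundled reference data: the eight published marine-heterotroph niche clusters.

A compact transcription of the published per-cluster summary for marine
heterotrophic bacteria — genome counts, growth-strategy label, fast-grower
percentage, mean dCUB, mean growth sensitivity and the growth-limiting
substrate classes — used both as regression input and to parameterize the
synthetic archetype generator.
"""
from __future__ import annotations

import pandas as pd

from .classes import ORGANIC_CLASSES
from .growth import ClusterSummary
from .simulate import ArchetypeSpec

#: Sensitivity assigned to a cluster's limiting classes when reconstructing
#: class-wise archetype means from the published per-cluster mean.
LIMITING_CLASS_S = 0.9

_ROWS = [
    # cluster, n_genomes, strategy, fast_pct, mean_dcub, mean_sensitivity, limiting classes
    (1, 97, "slow-intermediate", 42.3, -0.117, 0.222, ("carboxylic_acids", "peptides")),
    (2, 175, "intermediate", 60.6, -0.152, 0.166, ("amino_acids",)),
    (3, 295, "intermediate-fast", 71.9, -0.190, 0.128, ("carboxylic_acids",)),
    (4, 108, "intermediate", 67.6, -0.150, 0.119, ("carbohydrates",)),
    (5, 68, "slow", 38.2, -0.085, 0.322, ("amino_acids", "peptides")),
    (6, 478, "fast", 79.5, -0.235, 0.028, ()),
    (7, 129, "intermediate", 60.5, -0.158, 0.225, ("b_vitamins",)),
    (8, 128, "slow-intermediate", 47.7, -0.120, 0.248, ("carboxylic_acids", "amino_acids")),
]


def reference_clusters() -> pd.DataFrame:
    """The eight niche clusters as a DataFrame (one row per cluster)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "cluster",
            "n_genomes",
            "strategy",
            "fast_pct",
            "mean_dcub",
            "mean_sensitivity",
            "limiting_classes",
        ],
    )


def reference_summaries() -> list[ClusterSummary]:
    """Published cluster summaries as :class:`ClusterSummary` records."""
    return [
        ClusterSummary(
            cluster_id=c,
            n_genomes=n,
            mean_dcub=d,
            mean_sensitivity=s,
            fast_fraction=f / 100.0,
        )
        for c, n, _, f, d, s, _ in _ROWS
    ]


def archetype_mean_vector(
    mean_sensitivity: float, limiting: tuple[str, ...]
) -> tuple[float, ...]:
    """Spread a per-cluster mean into an 11-class sensitivity vector.

    Limiting classes are pinned at :data:`LIMITING_CLASS_S`; the remaining
    classes share the rest evenly so the 11-class mean equals the published
    per-cluster mean. All eight published rows land inside [0, 1].
    """
    n = len(ORGANIC_CLASSES)
    n_lim = len(limiting)
    rest = (mean_sensitivity * n - LIMITING_CLASS_S * n_lim) / (n - n_lim) if n > n_lim else 0.0
    rest = max(0.0, min(1.0, rest))
    return tuple(
        LIMITING_CLASS_S if cls in limiting else rest for cls in ORGANIC_CLASSES
    )


def reference_archetypes(
    sensitivity_sd: float = 0.02,
    dcub_sd: float = 0.03,
    n_genomes: int | None = None,
) -> list[ArchetypeSpec]:
    """Archetype specs mirroring the eight published clusters.

    ``n_genomes`` overrides every cluster's genome count (handy for scaled
    recovery experiments); by default the published counts are kept.
    """
    specs = []
    for c, n, _, _, d, s, limiting in _ROWS:
        specs.append(
            ArchetypeSpec(
                cluster_id=c,
                mean_sensitivity=archetype_mean_vector(s, limiting),
                sensitivity_sd=sensitivity_sd,
                mean_dcub=d,
                dcub_sd=dcub_sd,
                n_genomes=n_genomes if n_genomes is not None else n,
            )
        )
    return specs
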