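"""Tissue-specific subnetworks via the above-average expression filter.

A factor enters a tissue subnetwork when its expression in that tissue is
strictly above the tissue mean, where the mean is taken over *all* genes on
the array (network genes plus background), not just network genes. The
subnetwork is the induced subgraph on the retained nodes, and the group
inedge densities are recomputed on it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import GroupDensity, inedge_density
from .models import RegulatoryNetwork


@dataclass
class ExpressionAtlas:
    """Gene × tissue expression matrix with per-tissue background means."""

    values: pd.DataFrame  # index: gene ids (network + background), columns: tissues

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression atlas contains non-finite values")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def tissue_mean(self, tissue: str) -> float:
        return float(self.values[tissue].mean())


def tissue_filter(
    atlas: ExpressionAtlas, network: RegulatoryNetwork, tissue: str
) -> list[str]:
    """Node ids expressed strictly above the tissue mean.

    Network genes missing from the atlas are excluded with a warning.
    """
    if tissue not in atlas.values.columns:
        raise KeyError(f"tissue {tissue!r} not in atlas")
    mean = atlas.tissue_mean(tissue)
    col = atlas.values[tissue]
    missing = [gid for gid in network.genes if gid not in col.index]
    if missing:
        warnings.warn(
            f"{len(missing)} network genes missing from atlas; excluded",
            stacklevel=2,
        )
    return sorted(
        gid for gid in network.genes if gid in col.index and col[gid] > mean
    )


def induce_subnetwork(
    network: RegulatoryNetwork, node_subset: list[str]
) -> tuple[RegulatoryNetwork, pd.DataFrame]:
    """Induced subgraph on ``node_subset`` plus its density table.

    The table reports mean ± sem splicing and transcription inedges for the
    SF and TF groups (the tissue-table layout); groups absent from the
    subset appear as NaN.
    """
    sub = network.subset(node_subset)
    rows = []
    for edge_type in ("splicing", "transcription"):
        dens = inedge_density(sub, edge_type)
        for grp in ("SF", "TF"):
            d: GroupDensity = dens[grp]
            rows.append(
                {
                    "edge_type": edge_type,
                    "group": grp,
                    "n": len(d.per_node_counts),
                    "mean": d.mean,
                    "sem": d.sem,
                }
            )
    return sub, pd.DataFrame(rows)
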