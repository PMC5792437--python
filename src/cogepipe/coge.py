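"""Clusters of gene expression (CoGE) and progression-consistent genes.

A gene's CoGE combines its regulation in two successive comparisons, the
predecessor (``prev``) and the focal one (they share the middle cell line).
Zero-expression and continuum behavior of the focal pair take precedence;
the remaining eight clusters cross the DOWN/UP status of the two
comparisons. Genes that are DEGs in neither comparison stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from cogepipe.differential import ComparisonResult, DirectionLabel
from cogepipe.io import DesignError


class CoGECluster(str, Enum):
    """The closed 11-name cluster vocabulary."""

    EXCLUSIVE_PARENTAL = "EXCLUSIVE_PARENTAL"
    EXCLUSIVE_DERIVED = "EXCLUSIVE_DERIVED"
    CONTINUUM = "CONTINUUM"
    EXCL_PARENTAL_DOWN = "EXCL_PARENTAL_DOWN"
    EXCL_PARENTAL_UP = "EXCL_PARENTAL_UP"
    EXCL_DERIVED_DOWN = "EXCL_DERIVED_DOWN"
    EXCL_DERIVED_UP = "EXCL_DERIVED_UP"
    COMMON_DOWN = "COMMON_DOWN"
    COMMON_UP = "COMMON_UP"
    COMMON_PDOWN_DUP = "COMMON_PDOWN_DUP"
    COMMON_PUP_DDOWN = "COMMON_PUP_DDOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Labels that count as "regulated" for the cross rules.
_REGULATED = {DirectionLabel.DOWN, DirectionLabel.UP}

#: Labels a consistent gene may carry.
CONSISTENT_LABELS = {
    DirectionLabel.DOWN,
    DirectionLabel.CONTINUUM,
    DirectionLabel.UP,
    DirectionLabel.EXCLUSIVE_PARENTAL,
    DirectionLabel.EXCLUSIVE_DERIVED,
}


@dataclass
class CoGETable:
    """Cluster assignment of every gene for one (predecessor, focal) pair."""

    prev_name: str
    focal_name: str
    clusters: pd.Series  # gene id -> cluster name or NaN when unassigned

    @property
    def assigned(self) -> pd.Series:
        return self.clusters.dropna()

    def members(self, cluster: CoGECluster | str) -> set[str]:
        value = cluster.value if isinstance(cluster, CoGECluster) else cluster
        return set(self.clusters.index[self.clusters == value])

    def counts(self) -> pd.Series:
        return (
            self.assigned.value_counts()
            .reindex([c.value for c in CoGECluster], fill_value=0)
        )


def classify_pair(
    prev_label: DirectionLabel,
    focal_label: DirectionLabel,
    continuum_requires_prev: bool = False,
) -> CoGECluster | None:
    """Map a (predecessor label, focal label) pair to a cluster.

    The single-comparison clusters (exclusive parental/derived, continuum)
    depend only on the focal label; the eight cross clusters need DOWN/UP
    status in at least one of the two comparisons. Pairs outside the rule
    domain return None (unassigned).
    """
    if focal_label is DirectionLabel.EXCLUSIVE_PARENTAL:
        return CoGECluster.EXCLUSIVE_PARENTAL
    if focal_label is DirectionLabel.EXCLUSIVE_DERIVED:
        return CoGECluster.EXCLUSIVE_DERIVED
    if focal_label is DirectionLabel.CONTINUUM:
        if continuum_requires_prev and prev_label is DirectionLabel.NOT_DEG:
            return None
        return CoGECluster.CONTINUUM
    prev_reg = prev_label in _REGULATED
    focal_reg = focal_label in _REGULATED
    if prev_reg and not focal_reg:
        return (
            CoGECluster.EXCL_PARENTAL_DOWN
            if prev_label is DirectionLabel.DOWN
            else CoGECluster.EXCL_PARENTAL_UP
        )
    if focal_reg and not prev_reg:
        return (
            CoGECluster.EXCL_DERIVED_DOWN
            if focal_label is DirectionLabel.DOWN
            else CoGECluster.EXCL_DERIVED_UP
        )
    if prev_reg and focal_reg:
        if prev_label is DirectionLabel.DOWN:
            return (
                CoGECluster.COMMON_DOWN
                if focal_label is DirectionLabel.DOWN
                else CoGECluster.COMMON_PDOWN_DUP
            )
        return (
            CoGECluster.COMMON_PUP_DDOWN
            if focal_label is DirectionLabel.DOWN
            else CoGECluster.COMMON_UP
        )
    return None


def assign_coge(
    prev: ComparisonResult,
    focal: ComparisonResult,
    continuum_requires_prev: bool = False,
) -> CoGETable:
    """Assign every gene of the focal comparison to a cluster (or leave it
    unassigned) given the predecessor comparison of the chain."""
    if prev.derived != focal.parental:
        raise DesignError(
            f"comparisons are not chained: {prev.name} then {focal.name}"
        )
    if prev.mode != focal.mode:
        raise DesignError(
            f"comparisons mix modes {prev.mode!r} and {focal.mode!r}"
        )
    if not prev.table.index.equals(focal.table.index):
        raise DesignError("comparisons cover different gene universes")

    clusters = pd.Series(np.nan, index=focal.table.index, dtype=object)
    prev_labels = prev.labels
    focal_labels = focal.labels
    for gene in clusters.index:
        cluster = classify_pair(
            DirectionLabel(prev_labels[gene]),
            DirectionLabel(focal_labels[gene]),
            continuum_requires_prev,
        )
        if cluster is not None:
            clusters[gene] = cluster.value
    return CoGETable(prev.name, focal.name, clusters)


def find_consistent_genes(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    """Genes that are DEGs in every comparison of a chained series and carry
    the identical direction label throughout.

    Returns a frame indexed by gene id with the shared ``label`` and one
    ``ratio_<i>`` column per comparison. An empty intersection yields an
    empty frame, not an error.
    """
    if len(comparisons) < 2:
        raise DesignError("need at least two comparisons")
    for left, right in zip(comparisons, comparisons[1:]):
        if left.derived != right.parental:
            raise DesignError(
                f"comparisons are not chained: {left.name} then {right.name}"
            )

    universe = comparisons[0].table.index
    keep = pd.Series(True, index=universe)
    shared = comparisons[0].labels
    for comp in comparisons:
        keep &= comp.deg_flags
        keep &= comp.labels == shared
    allowed = {label.value for label in CONSISTENT_LABELS}
    keep &= shared.isin(allowed)

    result = pd.DataFrame(index=universe[keep])
    result["label"] = shared[keep]
    for i, comp in enumerate(comparisons, start=1):
        result[f"ratio_{i}"] = comp.table.loc[keep, "ratio"]
    result.index.name = "gene_id"
    return result


def coge_export(table: CoGETable) -> pd.DataFrame:
    """Flat export frame (gene_id index; assigned genes only)."""
    assigned = table.assigned
    out = pd.DataFrame(
        {"focal_pair": table.focal_name, "cluster": assigned}
    )
    out.index.name = "gene_id"
    return out
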