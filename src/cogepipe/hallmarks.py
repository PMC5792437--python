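"""Hallmark gene sets and their contribution to a reference hallmark.

Absolute contribution counts the pathways and genes a hallmark shares with
the reference (invasion & metastasis by default). Relative contribution is
computed per cluster of gene expression: of the hallmark's DEGs falling in
a cluster, the percentage that also belongs to the reference hallmark's
DEG set. 0/0 is defined as 0.0 so the per-cluster means are always
defined; the reference itself therefore scores 100 wherever it has genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from cogepipe.coge import CoGECluster, CoGETable
from cogepipe.io import HallmarkAnnotation, REFERENCE_HALLMARK, ValidationError

CLUSTER_ORDER = [c.value for c in CoGECluster]


@dataclass
class HallmarkGeneSets:
    """Per-hallmark pathway and gene sets against a reference hallmark."""

    pathway_sets: dict[str, set[str]]
    gene_sets: dict[str, set[str]]
    reference: str

    @property
    def hallmarks(self) -> list[str]:
        return list(self.pathway_sets)


def build_hallmark_sets(
    annotation: HallmarkAnnotation,
    universe: set[str] | None = None,
    reference: str = REFERENCE_HALLMARK,
) -> HallmarkGeneSets:
    """P(h) = pathways mapped to hallmark h; G(h) = union of their gene
    sets, optionally intersected with ``universe`` (pass the DEG set for
    per-comparison analyses, None for the genome-wide view)."""
    if reference not in annotation.vocabulary:
        raise ValidationError(
            f"reference hallmark {reference!r} not in vocabulary"
        )
    pathway_sets: dict[str, set[str]] = {}
    gene_sets: dict[str, set[str]] = {}
    for hallmark in annotation.vocabulary:
        paths = annotation.hallmark_pathways(hallmark)
        genes: set[str] = set()
        for pathway in paths:
            genes |= annotation.pathways[pathway]
        if universe is not None:
            genes &= universe
        pathway_sets[hallmark] = paths
        gene_sets[hallmark] = genes
    return HallmarkGeneSets(pathway_sets, gene_sets, reference)


def absolute_contribution(sets: HallmarkGeneSets) -> pd.DataFrame:
    """Shared pathway/gene counts of every hallmark with the reference.

    The reference row carries its own totals.
    """
    ref_paths = sets.pathway_sets[sets.reference]
    ref_genes = sets.gene_sets[sets.reference]
    rows = {}
    for hallmark in sets.hallmarks:
        rows[hallmark] = {
            "shared_pathways": len(sets.pathway_sets[hallmark] & ref_paths),
            "shared_genes": len(sets.gene_sets[hallmark] & ref_genes),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "hallmark"
    return out


def relative_contribution(
    sets: HallmarkGeneSets, coge: CoGETable
) -> pd.DataFrame:
    """Per (hallmark, cluster): n = |G(h) & C(c)| and
    pct = 100 * |G(h) & G(ref) & C(c)| / n (0.0 when n = 0)."""
    ref_genes = sets.gene_sets[sets.reference]
    records = []
    for hallmark in sets.hallmarks:
        genes = sets.gene_sets[hallmark]
        for cluster in CLUSTER_ORDER:
            members = coge.members(cluster)
            n = len(genes & members)
            shared = len(genes & ref_genes & members)
            pct = 100.0 * shared / n if n > 0 else 0.0
            records.append(
                {
                    "hallmark": hallmark,
                    "cluster": cluster,
                    "n_genes": n,
                    "pct": pct,
                }
            )
    return pd.DataFrame.from_records(records)


def aggregate_and_rank(
    relative_tables: Mapping[str, pd.DataFrame],
    reference: str = REFERENCE_HALLMARK,
) -> pd.DataFrame:
    """Fold per-comparison relative tables into one summary.

    Per comparison, a hallmark's score is the unweighted mean of its 11
    cluster percentages; the overall score is the mean of the per-comparison
    scores; hallmarks are ranked descending by overall score with the
    reference excluded from the ranking (rank 0).
    """
    if not relative_tables:
        raise ValidationError("need at least one relative-contribution table")
    per_comparison = {}
    for name, table in relative_tables.items():
        per_comparison[name] = table.groupby("hallmark")["pct"].mean()
    summary = pd.DataFrame(per_comparison)
    summary["overall"] = summary.mean(axis=1)
    ranked = (
        summary.loc[summary.index != reference, "overall"]
        .rank(ascending=False, method="first")
        .astype(int)
    )
    summary["rank"] = ranked.reindex(summary.index, fill_value=0)
    summary.index.name = "hallmark"
    return summary
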