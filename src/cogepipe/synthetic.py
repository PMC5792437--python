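"""Synthetic progression-series expression data with known ground truth.

Generates an ordered series of cell lines (5 by default, mirroring a
parental line plus four increasingly invasive derivatives, each with 7
replicates) where every downstream behavior is planted: monotone DOWN/UP
genes, CONTINUUM genes (significant but with fold change inside
[0.8, 1.2]), zero-expression exclusive genes, and null genes sharing one
mean across all lines. Replicate noise is multiplicative lognormal with a
configurable coefficient of variation, so values stay positive and the
variance scales with the mean as in real FPKM data.

CONTINUUM genes get their own (much smaller) coefficient of variation so
that their small fold changes remain statistically detectable - by
construction they are meant to enter DEG lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cogepipe.differential import DirectionLabel
from cogepipe.io import (
    ExpressionMatrix,
    HALLMARK_VOCABULARY,
    HallmarkAnnotation,
    REFERENCE_HALLMARK,
)

PATTERNS = ("DOWN", "UP", "CONTINUUM", "EXCLUSIVE_PARENTAL", "EXCLUSIVE_DERIVED")
NULL_PATTERN = "NULL"

#: Hallmark guaranteed to share at least one pathway with the reference.
DESIGNATED_HALLMARK = "angiogenesis"
#: Hallmark guaranteed to share zero pathways with the reference.
ZERO_SHARE_HALLMARK = "chronic diseases"


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic progression series."""

    n_lines: int = 5
    replicates_per_line: int = 7
    n_null_genes: int = 200
    genes_per_pattern: dict[str, int] = field(
        default_factory=lambda: {
            "DOWN": 50,
            "UP": 50,
            "CONTINUUM": 50,
            "EXCLUSIVE_PARENTAL": 10,
            "EXCLUSIVE_DERIVED": 10,
        }
    )
    cv: float = 0.10
    continuum_cv: float = 5e-4
    ratio_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "DOWN": (0.2, 0.6),
            "UP": (1.5, 3.0),
            "CONTINUUM": (0.95, 1.05),
        }
    )
    base_expression_range: tuple[float, float] = (5.0, 50.0)
    genes_per_pathway: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 3:
            raise ConfigurationError("n_lines must be >= 3")
        if self.replicates_per_line < 2:
            raise ConfigurationError("replicates_per_line must be >= 2")
        if self.n_null_genes < 0:
            raise ConfigurationError("n_null_genes must be >= 0")
        if not self.cv > 0:
            raise ConfigurationError("cv must be > 0")
        if not self.continuum_cv > 0:
            raise ConfigurationError("continuum_cv must be > 0")
        for pattern, count in self.genes_per_pattern.items():
            if pattern not in PATTERNS:
                raise ConfigurationError(
                    f"genes_per_pattern: unknown pattern {pattern!r}"
                )
            if count < 0:
                raise ConfigurationError(
                    f"genes_per_pattern[{pattern!r}] must be >= 0"
                )
        for pattern in ("DOWN", "UP", "CONTINUUM"):
            if self.genes_per_pattern.get(pattern, 0) > 0:
                if pattern not in self.ratio_ranges:
                    raise ConfigurationError(
                        f"ratio_ranges missing entry for {pattern!r}"
                    )
        for pattern, (low, high) in self.ratio_ranges.items():
            if low > high or low <= 0:
                raise ConfigurationError(
                    f"ratio_ranges[{pattern!r}] must satisfy 0 < low <= high"
                )
            if pattern == "DOWN" and high >= 0.8:
                raise ConfigurationError(
                    f"ratio_ranges[{pattern!r}] must lie below 0.8"
                )
            if pattern == "CONTINUUM" and (low < 0.8 or high > 1.2):
                raise ConfigurationError(
                    f"ratio_ranges[{pattern!r}] must lie within [0.8, 1.2]"
                )
            if pattern == "UP" and low <= 1.2:
                raise ConfigurationError(
                    f"ratio_ranges[{pattern!r}] must lie above 1.2"
                )
        lo, hi = self.base_expression_range
        if lo <= 0 or lo > hi:
            raise ConfigurationError(
                "base_expression_range must satisfy 0 < min <= max"
            )
        if self.genes_per_pathway < 1:
            raise ConfigurationError("genes_per_pathway must be >= 1")

    @property
    def line_names(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_lines)]

    @property
    def transition_names(self) -> list[str]:
        lines = self.line_names
        return [f"{a}_vs_{b}" for a, b in zip(lines, lines[1:])]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``patterns`` maps every gene to its planted pattern (or NULL);
    ``labels`` holds the intended direction label per (gene, transition);
    ``line_means`` the noise-free per-line means. The pathway fields are
    filled in by :func:`generate_annotation`.
    """

    patterns: pd.Series
    labels: pd.DataFrame
    line_means: pd.DataFrame
    gene_pathways: dict[str, list[str]] = field(default_factory=dict)
    pathway_hallmarks: dict[str, list[str]] = field(default_factory=dict)
    planted_shared_pathways: dict[str, int] = field(default_factory=dict)


def _label_from_means(prev: float, cur: float) -> str:
    if prev == 0 and cur == 0:
        return DirectionLabel.NOT_DEG.value
    if prev > 0 and cur == 0:
        return DirectionLabel.EXCLUSIVE_PARENTAL.value
    if prev == 0 and cur > 0:
        return DirectionLabel.EXCLUSIVE_DERIVED.value
    ratio = cur / prev
    if ratio < 0.8:
        return DirectionLabel.DOWN.value
    if ratio <= 1.2:
        return DirectionLabel.CONTINUUM.value
    return DirectionLabel.UP.value


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the replicate matrix and its ground truth.

    Identical seeds give identical output. Exclusive genes produce exact
    zeros for every replicate of their silent lines.
    """
    rng = np.random.default_rng(config.seed)
    lines = config.line_names
    n_transitions = config.n_lines - 1
    lo, hi = config.base_expression_range

    gene_ids: list[str] = []
    patterns: list[str] = []
    means_rows: list[np.ndarray] = []
    for pattern in PATTERNS:
        count = config.genes_per_pattern.get(pattern, 0)
        for k in range(count):
            base = rng.uniform(lo, hi)
            if pattern in ("DOWN", "UP", "CONTINUUM"):
                r_lo, r_hi = config.ratio_ranges[pattern]
                steps = rng.uniform(r_lo, r_hi, size=n_transitions)
                means = base * np.concatenate([[1.0], np.cumprod(steps)])
            elif pattern == "EXCLUSIVE_PARENTAL":
                means = np.zeros(config.n_lines)
                means[0] = base
            else:  # EXCLUSIVE_DERIVED
                means = np.zeros(config.n_lines)
                means[-1] = base
            gene_ids.append(f"{pattern}_{k:04d}")
            patterns.append(pattern)
            means_rows.append(means)
    for k in range(config.n_null_genes):
        base = rng.uniform(lo, hi)
        gene_ids.append(f"{NULL_PATTERN}_{k:04d}")
        patterns.append(NULL_PATTERN)
        means_rows.append(np.full(config.n_lines, base))

    if not gene_ids:
        raise ConfigurationError(
            "genes_per_pattern and n_null_genes produce zero genes"
        )

    line_means = pd.DataFrame(means_rows, index=gene_ids, columns=lines)

    n_rep = config.replicates_per_line
    columns: dict[str, np.ndarray] = {}
    values = np.zeros((len(gene_ids), config.n_lines * n_rep))
    cvs = np.where(
        np.asarray(patterns) == "CONTINUUM", config.continuum_cv, config.cv
    )
    sigma2 = np.log1p(cvs**2)
    mu_shift = sigma2 / 2.0
    sample_ids = []
    for i, line in enumerate(lines):
        for j in range(n_rep):
            sample_ids.append(f"{line}_r{j + 1}")
    for i, line in enumerate(lines):
        m = line_means[line].to_numpy()
        noise = rng.lognormal(
            mean=-mu_shift[:, None],
            sigma=np.sqrt(sigma2)[:, None],
            size=(len(gene_ids), n_rep),
        )
        block = m[:, None] * noise
        block[m == 0, :] = 0.0
        values[:, i * n_rep:(i + 1) * n_rep] = block

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        line_order=lines,
        samples_by_line={
            line: [f"{line}_r{j + 1}" for j in range(n_rep)] for line in lines
        },
    )

    labels = pd.DataFrame(
        {
            name: [
                _label_from_means(line_means.iloc[g, t], line_means.iloc[g, t + 1])
                if patterns[g] != NULL_PATTERN
                else DirectionLabel.NOT_DEG.value
                for g in range(len(gene_ids))
            ]
            for t, name in enumerate(config.transition_names)
        },
        index=gene_ids,
    )
    truth = SyntheticTruth(
        patterns=pd.Series(patterns, index=gene_ids, name="pattern"),
        labels=labels,
        line_means=line_means,
    )
    return matrix, truth


def generate_annotation(
    config: SimulationConfig, truth: SyntheticTruth
) -> HallmarkAnnotation:
    """Emit pathways (gene sets) and a pathway-to-hallmark map over the
    simulated genes, updating ``truth`` with the memberships.

    Construction guarantees at least one pathway shared between the
    designated hallmark (angiogenesis) and the reference, and zero shared
    pathways between the zero-share hallmark (chronic diseases) and the
    reference. The planted shared-pathway count per hallmark is recorded
    independently in ``truth.planted_shared_pathways``.
    """
    rng = np.random.default_rng((config.seed, 1))
    genes = list(truth.patterns.index)
    order = rng.permutation(len(genes))
    shuffled = [genes[i] for i in order]
    size = config.genes_per_pathway
    chunks = [shuffled[i:i + size] for i in range(0, len(shuffled), size)]

    pathways: dict[str, set[str]] = {}
    hallmark_map: set[tuple[str, str]] = set()
    shared = {h: 0 for h in HALLMARK_VOCABULARY}
    cycle = [h for h in HALLMARK_VOCABULARY]
    for i, chunk in enumerate(chunks):
        name = f"pw{i:04d}"
        pathways[name] = set(chunk)
        primary = cycle[i % len(cycle)]
        hallmark_map.add((name, primary))
        if primary == DESIGNATED_HALLMARK:
            # plant the designated overlap: the pathway belongs to the
            # reference hallmark too
            hallmark_map.add((name, REFERENCE_HALLMARK))
            shared[DESIGNATED_HALLMARK] += 1
    if chunks and shared[DESIGNATED_HALLMARK] == 0:
        name = "pw0000"
        hallmark_map.add((name, DESIGNATED_HALLMARK))
        hallmark_map.add((name, REFERENCE_HALLMARK))
        shared[DESIGNATED_HALLMARK] += 1

    annotation = HallmarkAnnotation(pathways, hallmark_map)
    shared[REFERENCE_HALLMARK] = len(
        annotation.hallmark_pathways(REFERENCE_HALLMARK)
    )
    truth.planted_shared_pathways = shared
    truth.pathway_hallmarks = {
        p: sorted(h for pp, h in hallmark_map if pp == p) for p in pathways
    }
    memberships: dict[str, list[str]] = {g: [] for g in genes}
    for pathway in sorted(pathways):
        for gene in pathways[pathway]:
            memberships[gene].append(pathway)
    truth.gene_pathways = memberships
    return annotation


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Flat TSV-ready view: gene_id, pattern, one label column per
    transition."""
    out = pd.DataFrame({"pattern": truth.patterns})
    for name in truth.labels.columns:
        out[f"label_{name}"] = truth.labels[name]
    out.index.name = "gene_id"
    return out
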