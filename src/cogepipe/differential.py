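"""Per-gene parental-vs-derived testing, FDR correction and direction labels.

Each successive pair of cell lines is compared gene by gene with a
two-sided pooled-variance (Student) t-test on the replicate FPKM values,
followed by Benjamini-Hochberg FDR correction within the pair. Significant
genes are labeled by the derived/parental mean-FPKM ratio: below 0.8 is
DOWN, within the closed interval [0.8, 1.2] is CONTINUUM, above 1.2 is UP,
and zero expression on exactly one side yields an EXCLUSIVE label.

Degenerate zero-variance conventions (common with FPKM ties at zero): a
gene whose values are identical across all replicates of both groups gets
p = 1; zero pooled variance with different means gets p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from cogepipe.io import DesignError, ExpressionMatrix, ValidationError

RATIO_LOW = 0.8
RATIO_HIGH = 1.2
DEFAULT_ALPHA = 0.05


class DirectionLabel(str, Enum):
    """Regulation status of a gene within one parental->derived comparison."""

    EXCLUSIVE_PARENTAL = "EXCLUSIVE_PARENTAL"
    EXCLUSIVE_DERIVED = "EXCLUSIVE_DERIVED"
    DOWN = "DOWN"
    CONTINUUM = "CONTINUUM"
    UP = "UP"
    NOT_DEG = "NOT_DEG"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class InvalidStateError(ValueError):
    """A gene cannot be significant with zero expression on both sides."""


@dataclass
class ComparisonResult:
    """Per-gene statistics for one parental->derived comparison.

    ``table`` is indexed by gene id with columns ``mean_parental``,
    ``mean_derived``, ``ratio`` (NaN when the parental mean is zero),
    ``p_value``, ``q_value``, ``deg_p``, ``deg_q`` and ``label``.
    """

    parental: str
    derived: str
    alpha: float
    mode: str
    table: pd.DataFrame

    @property
    def name(self) -> str:
        return f"{self.parental}_vs_{self.derived}"

    @property
    def deg_flags(self) -> pd.Series:
        return self.table["deg_q" if self.mode == "q" else "deg_p"]

    @property
    def deg_genes(self) -> set[str]:
        return set(self.table.index[self.deg_flags])

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def t_test_per_gene(
    expr: ExpressionMatrix, parental: str, derived: str
) -> pd.Series:
    """Two-sided equal-variance two-sample t-test per gene.

    Requires at least two replicates in each group. Zero-variance genes
    follow the documented conventions (identical values -> 1, disjoint
    constants -> 0) so no NaN ever escapes.
    """
    a = expr.line_values(parental).to_numpy(dtype=float)
    b = expr.line_values(derived).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DesignError(
            f"need >= 2 replicates per line for the t-test; got "
            f"{a.shape[1]} for {parental!r} and {b.shape[1]} for {derived!r}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(a, b, axis=1, equal_var=True)
        p = np.asarray(result.pvalue, dtype=float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    same_mean = a.mean(axis=1) == b.mean(axis=1)
    p[zero_var & same_mean] = 1.0
    p[zero_var & ~same_mean] = 0.0
    # scipy leaves NaN only in the zero-variance cases handled above, but be
    # defensive about equal-value groups with nonzero variance patterns
    p = np.nan_to_num(p, nan=1.0)
    return pd.Series(p, index=expr.genes, name="p_value")


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def label_direction(
    mean_parental: float,
    mean_derived: float,
    is_deg: bool,
    ratio_low: float = RATIO_LOW,
    ratio_high: float = RATIO_HIGH,
) -> DirectionLabel:
    """Label one gene's regulation in a single comparison.

    Precedence: non-significant genes are NOT_DEG; zero expression on one
    side wins over the ratio rule; otherwise the derived/parental ratio is
    binned with both interval ends belonging to CONTINUUM.
    """
    if mean_parental < 0 or mean_derived < 0:
        raise ValidationError("mean FPKM must be non-negative")
    if not is_deg:
        return DirectionLabel.NOT_DEG
    if mean_parental == 0 and mean_derived == 0:
        raise InvalidStateError(
            "gene flagged significant with zero expression in both lines"
        )
    if mean_parental > 0 and mean_derived == 0:
        return DirectionLabel.EXCLUSIVE_PARENTAL
    if mean_parental == 0 and mean_derived > 0:
        return DirectionLabel.EXCLUSIVE_DERIVED
    ratio = mean_derived / mean_parental
    if ratio < ratio_low:
        return DirectionLabel.DOWN
    if ratio <= ratio_high:
        return DirectionLabel.CONTINUUM
    return DirectionLabel.UP


def compare_lines(
    expr: ExpressionMatrix,
    parental: str,
    derived: str,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "p",
    ratio_low: float = RATIO_LOW,
    ratio_high: float = RATIO_HIGH,
    min_expression: float = 0.0,
) -> ComparisonResult:
    """Full per-gene comparison: t-test, BH correction, DEG flags, labels.

    ``mode`` selects whether the DEG flag (and thus the labels) follows the
    raw p-value or the q-value, both at ``alpha``. ``min_expression`` keeps
    genes out of the test (and out of the BH family) when neither line's
    mean reaches the threshold; such genes carry NaN statistics and
    NOT_DEG labels. The default of 0 tests every gene.
    """
    if mode not in ("p", "q"):
        raise ValidationError(f"mode must be 'p' or 'q', got {mode!r}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    for line in (parental, derived):
        if line not in expr.samples_by_line:
            raise DesignError(f"unknown cell line: {line!r}")

    mean_parental = expr.line_values(parental).mean(axis=1)
    mean_derived = expr.line_values(derived).mean(axis=1)
    tested = (mean_parental >= min_expression) | (mean_derived >= min_expression)

    p = pd.Series(np.nan, index=expr.genes, dtype=float)
    q = pd.Series(np.nan, index=expr.genes, dtype=float)
    if tested.any():
        p_tested = t_test_per_gene(expr, parental, derived)[tested]
        p[tested] = p_tested
        q[tested] = fdr_correct(p_tested.to_numpy())

    deg_p = (p < alpha).fillna(False)
    deg_q = (q < alpha).fillna(False)
    flags = deg_q if mode == "q" else deg_p

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = mean_derived / mean_parental
    ratio[mean_parental == 0] = np.nan

    labels = [
        label_direction(mp, md, bool(flag), ratio_low, ratio_high).value
        for mp, md, flag in zip(mean_parental, mean_derived, flags)
    ]
    table = pd.DataFrame(
        {
            "mean_parental": mean_parental,
            "mean_derived": mean_derived,
            "ratio": ratio,
            "p_value": p,
            "q_value": q,
            "deg_p": deg_p,
            "deg_q": deg_q,
            "label": labels,
        }
    )
    return ComparisonResult(parental, derived, alpha, mode, table)


def comparisons_from_means(
    means: pd.DataFrame,
    line_order: list[str] | None = None,
    assume_deg: bool = True,
    ratio_low: float = RATIO_LOW,
    ratio_high: float = RATIO_HIGH,
) -> list[ComparisonResult]:
    """Build the chain of comparisons from a genes x lines table of mean
    FPKM values, without any testing.

    Intended for published mean-expression tables where significance was
    already established: with ``assume_deg`` every gene is flagged as a DEG
    (p = q = 0) and only the ratio labeling runs.
    """
    if line_order is None:
        line_order = list(means.columns)
    if len(line_order) < 2:
        raise DesignError("need at least two lines to compare")
    results = []
    for parental, derived in zip(line_order, line_order[1:]):
        mean_parental = means[parental].astype(float)
        mean_derived = means[derived].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = mean_derived / mean_parental
        ratio[mean_parental == 0] = np.nan
        stat = 0.0 if assume_deg else 1.0
        labels = [
            label_direction(mp, md, assume_deg, ratio_low, ratio_high).value
            for mp, md in zip(mean_parental, mean_derived)
        ]
        table = pd.DataFrame(
            {
                "mean_parental": mean_parental,
                "mean_derived": mean_derived,
                "ratio": ratio,
                "p_value": stat,
                "q_value": stat,
                "deg_p": assume_deg,
                "deg_q": assume_deg,
                "label": labels,
            }
        )
        results.append(
            ComparisonResult(parental, derived, DEFAULT_ALPHA, "p", table)
        )
    return results


def deg_table(result: ComparisonResult) -> pd.DataFrame:
    """Flat export frame for one comparison (gene_id index)."""
    out = result.table.copy()
    out.insert(0, "parental", result.parental)
    out.insert(1, "derived", result.derived)
    out.index.name = "gene_id"
    return out
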