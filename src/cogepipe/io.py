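"""Readers and writers for the pipeline's file formats.

Formats handled here: expression matrix TSV plus sample sheet, GMT pathway
gene sets, the pathway-to-hallmark map TSV, and the result tables
(``deg_table.tsv``, ``coge_table.tsv``, ``contributions_*.csv``,
``consistent_genes.tsv``, ``summary.json``).

Numeric parsing is strict except for one documented tolerance: decimal
commas in expression tables (``0,4972``) are normalized to dot-decimal,
because published FPKM tables frequently use them.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight consensual tumor capabilities plus the two extra categories
#: ("other cancer types", "chronic diseases") used by the hallmark analysis.
HALLMARK_VOCABULARY: tuple[str, ...] = (
    "proliferative signaling",
    "evading growth suppressors",
    "resisting cell death",
    "replicative immortality",
    "angiogenesis",
    "invasion and metastasis",
    "energy metabolism",
    "evading immune destruction",
    "other cancer types",
    "chronic diseases",
)

REFERENCE_HALLMARK = "invasion and metastasis"

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


class DesignError(ValueError):
    """Raised when an operation is asked to run on an incompatible design."""


@dataclass
class ExpressionMatrix:
    """FPKM values for genes x samples with an ordered cell-line design.

    Parameters
    ----------
    values
        Non-negative FPKM values, genes as rows, samples as columns.
    line_order
        Cell-line names in progression order (total order, explicit).
    samples_by_line
        For every cell line, the ordered list of its member samples.
    """

    values: pd.DataFrame
    line_order: list[str]
    samples_by_line: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        neg = self.values.lt(0)
        if neg.any().any():
            gene = self.values.index[neg.any(axis=1)][0]
            col = self.values.columns[neg.any(axis=0)][0]
            raise ValidationError(
                f"negative FPKM at gene {gene!r}, sample {col!r}"
            )
        if sorted(self.line_order) != sorted(self.samples_by_line):
            raise ValidationError("line_order and samples_by_line disagree")
        seen: dict[str, str] = {}
        for line, samples in self.samples_by_line.items():
            for s in samples:
                if s in seen:
                    raise ValidationError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {line!r}"
                    )
                if s not in self.values.columns:
                    raise ValidationError(
                        f"sample {s!r} in sample sheet but not in matrix"
                    )
                seen[s] = line
        unassigned = set(self.values.columns) - set(seen)
        if unassigned:
            raise ValidationError(
                f"samples not assigned to any cell line: {sorted(unassigned)}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_lines(self) -> int:
        return len(self.line_order)

    def line_values(self, line: str) -> pd.DataFrame:
        """Replicate FPKM values (genes x replicates) for one cell line."""
        if line not in self.samples_by_line:
            raise DesignError(f"unknown cell line: {line!r}")
        return self.values[self.samples_by_line[line]]

    def line_means(self) -> pd.DataFrame:
        """Per-line mean FPKM, columns ordered by ``line_order``."""
        return pd.DataFrame(
            {line: self.line_values(line).mean(axis=1) for line in self.line_order}
        )


@dataclass
class HallmarkAnnotation:
    """Pathway gene sets plus a many-to-many pathway-to-hallmark map."""

    pathways: dict[str, set[str]]
    hallmark_map: set[tuple[str, str]]
    vocabulary: tuple[str, ...] = HALLMARK_VOCABULARY

    def __post_init__(self) -> None:
        for pathway, hallmark in self.hallmark_map:
            if pathway not in self.pathways:
                raise ValidationError(
                    f"hallmark map references unknown pathway {pathway!r}"
                )
            if hallmark not in self.vocabulary:
                raise ValidationError(
                    f"hallmark {hallmark!r} not in vocabulary"
                )

    def hallmark_pathways(self, hallmark: str) -> set[str]:
        return {p for p, h in self.hallmark_map if h == hallmark}


def _parse_fpkm(raw: str, gene: str, sample: str) -> float:
    """Parse one FPKM cell; decimal commas are normalized, anything else
    malformed is rejected rather than coerced."""
    text = raw.strip()
    if _DECIMAL_COMMA.match(text):
        text = text.replace(",", ".")
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(
            f"malformed FPKM {raw!r} at gene {gene!r}, sample {sample!r}"
        ) from None
    if not np.isfinite(value):
        raise ValidationError(
            f"non-finite FPKM {raw!r} at gene {gene!r}, sample {sample!r}"
        )
    return value


def read_expression(path_matrix, path_sample_sheet) -> ExpressionMatrix:
    """Read an expression TSV (``gene_id`` column then sample columns) and a
    sample sheet TSV (``sample_id``, ``cell_line``, ``replicate`` and an
    optional ``line_order`` column; otherwise line order follows first
    appearance)."""
    raw = pd.read_csv(path_matrix, sep="\t", dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise ValidationError(f"empty expression matrix: {path_matrix}")
    if raw.columns[0] != "gene_id":
        raise ValidationError(
            f"first column must be 'gene_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("gene_id")
    values = pd.DataFrame(
        {
            sample: [
                _parse_fpkm(v, g, sample)
                for g, v in zip(raw.index, raw[sample])
            ]
            for sample in raw.columns
        },
        index=raw.index,
    )

    sheet = pd.read_csv(path_sample_sheet, sep="\t", dtype=str)
    required = {"sample_id", "cell_line", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if "line_order" in sheet.columns:
        order_key = sheet.groupby("cell_line")["line_order"].first().astype(int)
        line_order = list(order_key.sort_values().index)
    else:
        line_order = list(dict.fromkeys(sheet["cell_line"]))
    samples_by_line = {
        line: list(sheet.loc[sheet["cell_line"] == line, "sample_id"])
        for line in line_order
    }
    return ExpressionMatrix(values, line_order, samples_by_line)


def write_expression(matrix: ExpressionMatrix, path_matrix, path_sample_sheet) -> None:
    """Write the matrix and sample sheet back in the format read_expression
    accepts (dot decimals, full float precision)."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path_matrix, sep="\t", float_format="%.17g")
    rows = []
    for order, line in enumerate(matrix.line_order):
        for rep, sample in enumerate(matrix.samples_by_line[line], start=1):
            rows.append(
                {
                    "sample_id": sample,
                    "cell_line": line,
                    "replicate": rep,
                    "line_order": order,
                }
            )
    pd.DataFrame(rows).to_csv(path_sample_sheet, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT (name TAB description TAB gene ids); duplicate genes within
    a set are deduplicated; an empty file yields an empty map with a logged
    warning."""
    pathways: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, genes...)"
                )
            name = fields[0]
            if name in pathways:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway {name!r}")
            pathways[name] = {g for g in fields[2:] if g}
    if not pathways:
        logger.warning("GMT file %s contains no pathways", path)
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as handle:
        for name in sorted(pathways):
            genes = "\t".join(sorted(set(pathways[name])))
            handle.write(f"{name}\t{name}\t{genes}\n")


def read_hallmark_map(
    path,
    vocabulary: tuple[str, ...] = HALLMARK_VOCABULARY,
    allow_unknown: bool = False,
) -> set[tuple[str, str]]:
    """Read the pathway-to-hallmark TSV (columns ``pathway_id``,
    ``hallmark``); repeated pairs collapse; unknown hallmark names are
    rejected unless ``allow_unknown`` is set."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "hallmark"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"hallmark map missing columns: {sorted(missing)}")
    pairs: set[tuple[str, str]] = set()
    for row in frame.itertuples(index=False):
        hallmark = row.hallmark
        if not allow_unknown and hallmark not in vocabulary:
            raise ValidationError(
                f"unknown hallmark {hallmark!r}; expected one of {list(vocabulary)}"
            )
        pairs.add((row.pathway_id, hallmark))
    return pairs


def write_hallmark_map(pairs: Iterable[tuple[str, str]], path) -> None:
    frame = pd.DataFrame(sorted(pairs), columns=["pathway_id", "hallmark"])
    frame.to_csv(path, sep="\t", index=False)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir, summary: dict | None = None) -> list[Path]:
    """Write result tables with deterministic column order and row sort.

    ``tables`` maps a base name to a frame; names ending in ``.csv`` are
    written comma-separated, everything else tab-separated. A ``summary``
    dict, when given, is written as ``summary.json``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: list[Path] = []
    for name, frame in sorted(tables.items()):
        target = out_dir / name
        sep = "," if name.endswith(".csv") else "\t"
        frame = frame.sort_index(axis=0, kind="stable")
        frame.to_csv(target, sep=sep, float_format="%.17g")
        written.append(target)
    if summary is not None:
        target = out_dir / "summary.json"
        with open(target, "w") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
            handle.write("\n")
        written.append(target)
    return written


def read_summary(path) -> dict:
    with open(path) as handle:
        return json.load(handle)
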