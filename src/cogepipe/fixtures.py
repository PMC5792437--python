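"""Packaged worked-example tables for regression testing and demos.

Two fixtures ship with the package:

* a 26-gene x 4-cell-line mean-FPKM table of progression-consistent genes
  (15 common-down, 10 continuum, 1 common-up), transcribed with its
  original decimal commas;
* the per-(hallmark, cluster, comparison) gene counts and contribution
  percentages of the hallmark analysis, for both the p-value and q-value
  panels.

Both files carry recorded checksums so a corrupted installation fails
loudly instead of producing silently shifted numbers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from cogepipe.io import ValidationError

TABLE3_FILE = "table3_fpkm.tsv"
TABLE2_FILE = "table2_contributions.tsv"

_CHECKSUMS = {
    TABLE3_FILE: "9104004bf86ac92e67fcbfda9f9d9fcda3c28031e84806e81e23728d8e450f3e",
    TABLE2_FILE: "2ab8e101bc9897843044e6f6191f3c5791915029e1c0a477148798a1e00eac13",
}

LINE_ORDER = ["ZsG", "LN1", "LN2", "LN3"]
COMPARISONS = ["ZsG_vs_LN1", "LN1_vs_LN2", "LN2_vs_LN3"]


class IntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


@dataclass
class Table3Fixture:
    """26 progression-consistent genes with per-line mean FPKM."""

    values: pd.DataFrame  # genes x lines (ZsG, LN1, LN2, LN3)
    groups: pd.Series  # gene -> common_down | continuum | common_up


@dataclass
class Table2Fixture:
    """Gene counts and contribution percentages for one panel (p or q)."""

    mode: str
    frame: pd.DataFrame  # columns: hallmark, cluster, comparison, n_genes, pct

    def pct(self, hallmark: str, comparison: str, cluster: str) -> float:
        return float(self._cell(hallmark, comparison, cluster)["pct"])

    def count(self, hallmark: str, comparison: str, cluster: str) -> int:
        return int(self._cell(hallmark, comparison, cluster)["n_genes"])

    def _cell(self, hallmark: str, comparison: str, cluster: str) -> pd.Series:
        mask = (
            (self.frame["hallmark"] == hallmark)
            & (self.frame["comparison"] == comparison)
            & (self.frame["cluster"] == cluster)
        )
        match = self.frame[mask]
        if len(match) != 1:
            raise KeyError((hallmark, comparison, cluster))
        return match.iloc[0]

    def relative_tables(self) -> dict[str, pd.DataFrame]:
        """Per-comparison tables shaped like relative_contribution output."""
        return {
            comp: group[["hallmark", "cluster", "n_genes", "pct"]].reset_index(
                drop=True
            )
            for comp, group in self.frame.groupby("comparison")
        }


def _read_verified(name: str) -> str:
    data = (
        resources.files("cogepipe").joinpath("data", name).read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise IntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {_CHECKSUMS[name]}"
        )
    return data.decode()


def load_table3() -> Table3Fixture:
    """Load the 26-gene FPKM table (decimal commas normalized)."""
    from io import StringIO

    frame = pd.read_csv(StringIO(_read_verified(TABLE3_FILE)), sep="\t", dtype=str)
    frame = frame.set_index("gene_id")
    values = frame[LINE_ORDER].apply(
        lambda col: col.str.replace(",", ".", regex=False).astype(float)
    )
    if (values < 0).any().any():
        raise ValidationError("fixture contains negative FPKM")
    return Table3Fixture(values=values, groups=frame["group"])


def load_table2(mode: str = "p") -> Table2Fixture:
    """Load one panel ('p' or 'q') of the contribution grid."""
    if mode not in ("p", "q"):
        raise ValidationError(f"mode must be 'p' or 'q', got {mode!r}")
    from io import StringIO

    frame = pd.read_csv(StringIO(_read_verified(TABLE2_FILE)), sep="\t")
    panel = frame[frame["panel"] == mode].drop(columns="panel")
    return Table2Fixture(mode=mode, frame=panel.reset_index(drop=True))
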