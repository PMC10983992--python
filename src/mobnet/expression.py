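"""Differential-expression tables: IO, up/down classification, category summaries.

A :class:`DeTable` holds one condition x timepoint worth of per-gene log2
fold changes and adjusted p-values (the shape DESeq2 emits). Genes are
classified as ``up`` / ``down`` / ``unchanged`` with an inclusive linear
fold cutoff and a strict adjusted-p cutoff, and differentially expressed
genes can be tallied per functional category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig

log = logging.getLogger(__name__)

UP, DOWN, UNCHANGED = "up", "down", "unchanged"

#: Default functional-category vocabulary for B. subtilis mobilization studies.
DEFAULT_CATEGORIES = (
    "Purine biosynthesis and salvage",
    "Purine catabolism",
    "Pyrimidine metabolism",
    "Utilization of nitrogen sources",
    "Carbon metabolism",
    "Amino acid metabolism",
    "Ribosomal biogenesis and translation",
    "Secondary metabolism",
    "Metabolism of cofactors",
    "Stress response",
    "Sporulation and germination",
    "Others",
    "unknown",
)


@dataclass(frozen=True)
class DeRecord:
    """One gene's differential-expression result (log2 treated/control)."""

    gene: str
    log2fc: float
    padj: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene identifier must be nonempty")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj for {self.gene} outside [0,1]: {self.padj}")


@dataclass
class DeTable:
    """Per-gene DE results for one condition x timepoint.

    ``data`` has columns ``gene``, ``log2fc``, ``padj`` with one row per
    gene; ``padj`` may be NaN (treated as missing and never significant).
    """

    condition: str
    timepoint: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.condition or not self.timepoint:
            raise ValueError("condition and timepoint labels must be nonempty")
        required = {"gene", "log2fc", "padj"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DeTable missing columns: {sorted(missing)}")
        dup = self.data["gene"][self.data["gene"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene id(s): {sorted(set(dup))[:5]}")

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene"])

    def records(self) -> Iterable[DeRecord]:
        for row in self.data.itertuples(index=False):
            padj = None if pd.isna(row.padj) else float(row.padj)
            yield DeRecord(row.gene, float(row.log2fc), padj)

    def lookup(self) -> dict[str, tuple[float, Optional[float]]]:
        """gene -> (log2fc, padj or None) mapping for fast member lookups."""
        out: dict[str, tuple[float, Optional[float]]] = {}
        for row in self.data.itertuples(index=False):
            out[row.gene] = (
                float(row.log2fc),
                None if pd.isna(row.padj) else float(row.padj),
            )
        return out


def read_de_table(
    path: str | Path,
    condition: str,
    timepoint: str,
    linear_fc: bool = False,
) -> DeTable:
    """Read a DE table TSV with columns ``gene``, ``log2fc``, ``padj``.

    With ``linear_fc=True`` the fold-change column is interpreted as a
    linear ratio and converted to log2 (signed convention: values in (0,1)
    become negative log2 fold changes).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    fc_col = "fc" if linear_fc and "fc" in df.columns else "log2fc"
    for col in ("gene", fc_col, "padj"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.rename(columns={fc_col: "log2fc"})
    df["gene"] = df["gene"].str.strip()
    for col in ("log2fc", "padj"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] + 2 if len(bad) else "?"
            raise ValueError(f"{path}: unparseable {col!r} at file row {row}") from exc
    if linear_fc:
        if (df["log2fc"] <= 0).any():
            raise ValueError(f"{path}: linear fold changes must be positive")
        df["log2fc"] = np.log2(df["log2fc"])
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id {sorted(set(dup))[0]!r}")
    bad_p = df["padj"].dropna()
    if ((bad_p < 0) | (bad_p > 1)).any():
        raise ValueError(f"{path}: padj values outside [0,1]")
    return DeTable(condition=condition, timepoint=timepoint,
                   data=df[["gene", "log2fc", "padj"]].reset_index(drop=True))


def write_de_table(table: DeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def classify_gene(record: DeRecord, config: AnalysisConfig) -> str:
    """Classify one gene as ``up``/``down``/``unchanged``.

    ``up`` iff log2fc >= log2(fc_threshold) and padj < padj_threshold;
    ``down`` with the mirrored fold cutoff; everything else (including a
    missing padj) is ``unchanged``.
    """
    return classify_values(record.log2fc, record.padj, config)


def classify_values(log2fc: float, padj: Optional[float], config: AnalysisConfig) -> str:
    if padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return UNCHANGED
    if padj >= config.padj_threshold:
        return UNCHANGED
    cut = math.log2(config.fc_threshold)
    if log2fc >= cut:
        return UP
    if log2fc <= -cut:
        return DOWN
    return UNCHANGED


def classify_table(table: DeTable, config: AnalysisConfig) -> pd.DataFrame:
    """Vectorized classification of a whole table; adds a ``direction`` column."""
    df = table.data.copy()
    cut = math.log2(config.fc_threshold)
    sig = df["padj"].notna() & (df["padj"] < config.padj_threshold)
    df["direction"] = UNCHANGED
    df.loc[sig & (df["log2fc"] >= cut), "direction"] = UP
    df.loc[sig & (df["log2fc"] <= -cut), "direction"] = DOWN
    return df


@dataclass
class CategoryMap:
    """gene -> functional-category mapping; unmapped genes are ``unknown``."""

    mapping: Mapping[str, str]
    vocabulary: tuple[str, ...] = DEFAULT_CATEGORIES

    def category(self, gene: str) -> str:
        return self.mapping.get(gene, "unknown")


def read_category_map(path: str | Path) -> CategoryMap:
    """Read a ``gene<TAB>category`` TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["gene"] = df["gene"].str.strip()
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: gene {sorted(set(dup))[0]!r} mapped twice")
    vocab = tuple(dict.fromkeys(list(DEFAULT_CATEGORIES) + sorted(set(df["category"]))))
    return CategoryMap(dict(zip(df["gene"], df["category"])), vocabulary=vocab)


def summarize_categories(
    table: DeTable, cats: CategoryMap, config: AnalysisConfig
) -> pd.DataFrame:
    """Per-category (n_up, n_down) counts over differentially expressed genes.

    Every category in the vocabulary appears in the output (zeros where no
    DE gene maps to it); genes without a mapping count under ``unknown``.
    """
    classified = classify_table(table, config)
    de = classified[classified["direction"] != UNCHANGED]
    counts = {c: [0, 0] for c in cats.vocabulary}
    for row in de.itertuples(index=False):
        cat = cats.category(row.gene)
        if cat not in counts:
            counts[cat] = [0, 0]
        counts[cat][0 if row.direction == UP else 1] += 1
    out = pd.DataFrame(
        [(c, n[0], n[1]) for c, n in counts.items()],
        columns=["category", "n_up", "n_down"],
    )
    return out


def write_category_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False)
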