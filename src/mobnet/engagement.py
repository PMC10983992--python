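"""Regulon engagement scoring.

Engagement of a regulon is the fraction of its member genes that are
differentially expressed (at least 2-fold up or down with adjusted
p < 0.05, by default) in one condition. A regulator enters the downstream
network when its engagement reaches a cutoff (30% by default, inclusive).

The denominator is the full regulon size as given in the regulon
definition file: members absent from the DE table count as not engaged
(and are logged), matching quoted denominators like 101/272 or 76/188
that equal whole regulon sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .config import AnalysisConfig
from .expression import DOWN, UP, DeTable, classify_values

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Regulon:
    """A transcriptional regulator and the set of genes it controls."""

    regulator: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.regulator:
            raise ValueError("regulator name must be nonempty")
        if not self.members:
            raise ValueError(f"regulon {self.regulator} has no members")


@dataclass
class RegulonSet:
    """A collection of regulons with unique regulator names."""

    regulons: list[Regulon]

    def __post_init__(self) -> None:
        names = [r.regulator for r in self.regulons]
        if len(names) != len(set(names)):
            raise ValueError("regulator names must be unique")
        self._by_name = {r.regulator: r for r in self.regulons}

    def __iter__(self):
        return iter(self.regulons)

    def __len__(self) -> int:
        return len(self.regulons)

    def __getitem__(self, regulator: str) -> Regulon:
        return self._by_name[regulator]

    def __contains__(self, regulator: str) -> bool:
        return regulator in self._by_name

    @property
    def regulators(self) -> list[str]:
        return sorted(self._by_name)

    def overlap_index(self) -> dict[tuple[str, str], int]:
        """Pairwise shared-member counts for all pairs sharing >= 1 gene."""
        out: dict[tuple[str, str], int] = {}
        regs = sorted(self.regulons, key=lambda r: r.regulator)
        for i, a in enumerate(regs):
            for b in regs[i + 1:]:
                n = len(a.members & b.members)
                if n:
                    out[(a.regulator, b.regulator)] = n
        return out


def read_regulons(path: str | Path) -> RegulonSet:
    """Read a ``regulator<TAB>gene`` TSV (one pair per row, header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("regulator", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["regulator"] = df["regulator"].str.strip()
    df["gene"] = df["gene"].str.strip()
    regulons = [
        Regulon(reg, frozenset(sub["gene"]))
        for reg, sub in df.groupby("regulator", sort=True)
    ]
    return RegulonSet(regulons)


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    rows = [
        (r.regulator, g)
        for r in sorted(regulons, key=lambda r: r.regulator)
        for g in sorted(r.members)
    ]
    pd.DataFrame(rows, columns=["regulator", "gene"]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EngagementResult:
    """Engagement statistics for one regulon in one condition x timepoint.

    ``fraction`` is n_engaged / n_total (full regulon size); ``included``
    records the inclusive cutoff decision. ``fc_range`` is the (min, max)
    linear |fold change| over engaged genes, absent when nothing engages.
    """

    regulator: str
    n_total: int
    n_detected: int
    n_engaged: int
    n_up: int
    n_down: int
    fraction: float
    included: bool
    fc_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (self.n_up + self.n_down == self.n_engaged <= self.n_detected <= self.n_total):
            raise ValueError(
                f"{self.regulator}: inconsistent counts "
                f"({self.n_up}+{self.n_down}, {self.n_engaged}, "
                f"{self.n_detected}, {self.n_total})"
            )
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"{self.regulator}: fraction outside [0,1]")


def engaged_genes(
    regulon: Regulon, table: DeTable, config: AnalysisConfig
) -> set[tuple[str, str]]:
    """The regulon members classified up or down, as (gene, direction) pairs."""
    lut = table.lookup()
    out = set()
    for gene in regulon.members:
        if gene in lut:
            d = classify_values(*lut[gene], config)
            if d in (UP, DOWN):
                out.add((gene, d))
    return out


def score_regulon(
    regulon: Regulon, table: DeTable, config: AnalysisConfig
) -> EngagementResult:
    """Engagement statistics for one regulon against one DE table."""
    lut = table.lookup()
    n_detected = n_up = n_down = 0
    folds: list[float] = []
    for gene in regulon.members:
        if gene not in lut:
            continue
        n_detected += 1
        log2fc, padj = lut[gene]
        d = classify_values(log2fc, padj, config)
        if d == UP:
            n_up += 1
            folds.append(2.0 ** abs(log2fc))
        elif d == DOWN:
            n_down += 1
            folds.append(2.0 ** abs(log2fc))
    n_total = len(regulon.members)
    if n_detected == 0:
        log.warning("regulon %s: no members detected in DE table", regulon.regulator)
    n_engaged = n_up + n_down
    fraction = n_engaged / n_total
    return EngagementResult(
        regulator=regulon.regulator,
        n_total=n_total,
        n_detected=n_detected,
        n_engaged=n_engaged,
        n_up=n_up,
        n_down=n_down,
        fraction=fraction,
        included=fraction >= config.engagement_threshold,
        fc_range=(min(folds), max(folds)) if folds else None,
    )


def score_all(
    regulons: RegulonSet, table: DeTable, config: AnalysisConfig
) -> tuple[list[EngagementResult], int]:
    """Score every regulon, ordered by regulator name.

    Returns the result list and the count of included regulators.
    """
    results = [
        score_regulon(regulons[name], table, config) for name in regulons.regulators
    ]
    n_included = sum(r.included for r in results)
    return results, n_included


def results_to_frame(results: Iterable[EngagementResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        fc_min, fc_max = r.fc_range if r.fc_range else (float("nan"), float("nan"))
        rows.append(
            (r.regulator, r.n_total, r.n_detected, r.n_engaged, r.n_up, r.n_down,
             r.fraction, r.included, fc_min, fc_max)
        )
    return pd.DataFrame(
        rows,
        columns=["regulator", "n_total", "n_detected", "n_engaged", "n_up",
                 "n_down", "fraction", "included", "fc_min", "fc_max"],
    )


def write_results(results: Iterable[EngagementResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> list[EngagementResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        fc_range = None
        if not pd.isna(row.fc_min):
            fc_range = (float(row.fc_min), float(row.fc_max))
        out.append(
            EngagementResult(
                regulator=str(row.regulator), n_total=int(row.n_total),
                n_detected=int(row.n_detected), n_engaged=int(row.n_engaged),
                n_up=int(row.n_up), n_down=int(row.n_down),
                fraction=float(row.fraction), included=bool(row.included),
                fc_range=fc_range,
            )
        )
    return out
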