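"""Cross-condition comparison: regulator Venn partitions, shared-gene
breakdowns for regulator pairs, and direction-switch detection between
timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import AnalysisConfig
from .engagement import EngagementResult, Regulon
from .expression import DeTable, UP, DOWN, classify_values
from .network import EngagementNetwork

MAJORITY_UP, MAJORITY_DOWN = "majority_up", "majority_down"
BALANCED, NOT_ENGAGED = "balanced", "not_engaged"


@dataclass(frozen=True)
class VennPartition:
    """Two-set partition of regulator identifiers."""

    label_a: str
    label_b: str
    only_a: frozenset[str]
    only_b: frozenset[str]
    shared: frozenset[str]

    def __post_init__(self) -> None:
        if self.only_a & self.only_b or self.only_a & self.shared or self.only_b & self.shared:
            raise ValueError("Venn partition sets must be pairwise disjoint")


def compare_regulator_sets(
    net_a: EngagementNetwork, net_b: EngagementNetwork
) -> VennPartition:
    """Partition the union of two networks' regulator sets."""
    a, b = net_a.node_names, net_b.node_names
    return VennPartition(
        label_a=f"{net_a.condition}_{net_a.timepoint}",
        label_b=f"{net_b.condition}_{net_b.timepoint}",
        only_a=frozenset(a - b),
        only_b=frozenset(b - a),
        shared=frozenset(a & b),
    )


@dataclass(frozen=True)
class SharedGeneReport:
    """Shared-member breakdown for one regulator pair in one condition."""

    regulator_a: str
    regulator_b: str
    n_shared: int
    n_shared_de: int
    directions: tuple[tuple[str, str], ...]  # (gene, up/down/unchanged/absent)

    def __post_init__(self) -> None:
        if self.n_shared_de > self.n_shared:
            raise ValueError("n_shared_de cannot exceed n_shared")


def pair_shared_genes(
    reg_a: Regulon, reg_b: Regulon, table: DeTable, config: AnalysisConfig
) -> SharedGeneReport:
    """Count shared members of two regulons and how many are DE.

    Symmetric in its regulon arguments (up to label order).
    """
    shared = sorted(reg_a.members & reg_b.members)
    lut = table.lookup()
    directions = []
    n_de = 0
    for gene in shared:
        if gene in lut:
            d = classify_values(*lut[gene], config)
        else:
            d = "absent"
        if d in (UP, DOWN):
            n_de += 1
        directions.append((gene, d))
    return SharedGeneReport(
        regulator_a=reg_a.regulator, regulator_b=reg_b.regulator,
        n_shared=len(shared), n_shared_de=n_de,
        directions=tuple(directions),
    )


@dataclass(frozen=True)
class SwitchCall:
    """Direction-switch decision for one regulator between two timepoints.

    A switch is called only when one timepoint shows a strict majority of
    engaged genes up and the other a strict majority down; ties
    (``balanced``) and unengaged states never switch.
    """

    regulator: str
    state_t1: str
    state_t2: str
    switch: bool


def _majority_state(res: EngagementResult) -> str:
    if res.n_engaged == 0:
        return NOT_ENGAGED
    if res.n_up > res.n_down:
        return MAJORITY_UP
    if res.n_down > res.n_up:
        return MAJORITY_DOWN
    return BALANCED


def detect_switch(res_t1: EngagementResult, res_t2: EngagementResult) -> SwitchCall:
    """Call an up/down reversal of a regulon between two timepoints."""
    if res_t1.regulator != res_t2.regulator:
        raise ValueError(
            f"regulator mismatch: {res_t1.regulator!r} vs {res_t2.regulator!r}"
        )
    s1, s2 = _majority_state(res_t1), _majority_state(res_t2)
    switch = {s1, s2} == {MAJORITY_UP, MAJORITY_DOWN}
    return SwitchCall(regulator=res_t1.regulator, state_t1=s1, state_t2=s2,
                      switch=switch)


def venn_to_frame(p: VennPartition) -> pd.DataFrame:
    rows = (
        [(r, "only_a") for r in sorted(p.only_a)]
        + [(r, "only_b") for r in sorted(p.only_b)]
        + [(r, "shared") for r in sorted(p.shared)]
    )
    df = pd.DataFrame(rows, columns=["regulator", "partition"])
    df.attrs["label_a"], df.attrs["label_b"] = p.label_a, p.label_b
    return df


def write_venn(p: VennPartition, path: str | Path) -> None:
    venn_to_frame(p).to_csv(path, sep="\t", index=False)


def write_shared_genes(report: SharedGeneReport, path: str | Path) -> None:
    df = pd.DataFrame(report.directions, columns=["gene", "direction"])
    df.insert(0, "regulator_b", report.regulator_b)
    df.insert(0, "regulator_a", report.regulator_a)
    df.to_csv(path, sep="\t", index=False)


def write_switches(calls: list[SwitchCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.regulator, c.state_t1, c.state_t2, c.switch) for c in calls],
        columns=["regulator", "state_t1", "state_t2", "switch"],
    )
    df.to_csv(path, sep="\t", index=False)
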