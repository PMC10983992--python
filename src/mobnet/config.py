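"""Analysis thresholds shared across the pipeline.

All numeric cutoffs used by the expression, engagement, network and
metabolomics stages live in a single :class:`AnalysisConfig` so that a run
is fully described by one object (and one config file).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping


DEFAULT_METABOLITE_FC = {"6h": 1.5, "24h": 2.0}


@dataclass(frozen=True)
class AnalysisConfig:
    """Numeric thresholds for the whole analysis.

    Parameters
    ----------
    fc_threshold
        Linear fold-change cutoff for calling a gene differentially
        expressed; the comparison is inclusive (|fold| >= threshold).
    padj_threshold
        Adjusted p-value cutoff; strict (padj < threshold).
    engagement_threshold
        Minimum engaged fraction of a regulon for the regulator to enter
        the network; inclusive (fraction >= threshold).
    metabolite_fc_threshold
        Per-timepoint linear fold cutoff for the metabolite differential
        filter (symmetric: increase >= t or decrease <= 1/t).
    metabolite_p_threshold
        p-value cutoff for the metabolite filter; strict.
    ppm_window
        Half-width, in parts per million of the reference mass, of the
        m/z window used for ion-chromatogram extraction.
    """

    fc_threshold: float = 2.0
    padj_threshold: float = 0.05
    engagement_threshold: float = 0.30
    metabolite_fc_threshold: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METABOLITE_FC)
    )
    metabolite_p_threshold: float = 0.05
    ppm_window: float = 75.0

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1 (linear fold ratio)")
        if not 0 < self.padj_threshold < 1:
            raise ValueError("padj_threshold must lie in (0, 1)")
        if not 0 < self.engagement_threshold < 1:
            raise ValueError("engagement_threshold must lie in (0, 1)")
        if not 0 < self.metabolite_p_threshold < 1:
            raise ValueError("metabolite_p_threshold must lie in (0, 1)")
        if self.ppm_window <= 0:
            raise ValueError("ppm_window must be positive")
        for tp, t in self.metabolite_fc_threshold.items():
            if t < 1:
                raise ValueError(
                    f"metabolite fold threshold for {tp!r} must be >= 1, got {t}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metabolite_fc_threshold"] = dict(self.metabolite_fc_threshold)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        return cls(**dict(d))
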