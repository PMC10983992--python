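"""Stable-isotope-dilution metabolite quantitation.

Each analyte is quantified as the ratio of the area under its extracted
ion chromatogram (XIC) to that of its co-analyzed, fully 13C/15N-labeled
internal standard. XICs are extracted from profile-mode point lists over
a ppm-relative m/z window around the light and heavy [M-H]- reference
masses, restricted to a per-analyte retention-time window, and integrated
by the trapezoid rule with no baseline subtraction. Differential filtering
applies symmetric linear fold cutoffs (timepoint-specific) with a Welch
two-sample t-test on replicate ratios.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

log = logging.getLogger(__name__)

# Mass difference between the heavy and light isotope, Da (AME atomic masses:
# 13C 13.00335484 - 12C 12 exactly; 15N 15.00010890 - 14N 14.00307401).
DELTA_13C = 1.00335484
DELTA_15N = 0.99703489

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse a molecular formula like ``C5H10N2O3`` into element counts."""
    if isinstance(formula, Mapping):
        counts = dict(formula)
    else:
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"unparseable formula {formula!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(formula):
            raise ValueError(f"unparseable formula {formula!r}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("element counts must be nonnegative")
    return counts


def heavy_mz(formula: str | Mapping[str, int], mz_light: float) -> float:
    """m/z of the fully 13C/15N-labeled species given the light m/z."""
    counts = parse_formula(formula)
    return mz_light + counts.get("C", 0) * DELTA_13C + counts.get("N", 0) * DELTA_15N


def mz_window(mz_ref: float, ppm: float) -> tuple[float, float]:
    """Symmetric m/z window of half-width ``ppm`` parts-per-million."""
    if mz_ref <= 0:
        raise ValueError("reference m/z must be positive")
    if ppm < 0:
        raise ValueError("ppm half-width must be nonnegative")
    delta = mz_ref * ppm * 1e-6
    return mz_ref - delta, mz_ref + delta


@dataclass(frozen=True)
class ReferenceMass:
    """Reference entry for one analyte: formula, light/heavy m/z, RT window."""

    metabolite: str
    formula: Mapping[str, int]
    mz_light: float
    rt_window: tuple[float, float]
    mz_heavy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rt_window[1] <= self.rt_window[0]:
            raise ValueError(f"{self.metabolite}: empty retention-time window")
        heavy = self.mz_heavy
        if heavy is None:
            heavy = heavy_mz(self.formula, self.mz_light)
            object.__setattr__(self, "mz_heavy", heavy)
        counts = parse_formula(self.formula)
        if (counts.get("C", 0) or counts.get("N", 0)) and heavy <= self.mz_light:
            raise ValueError(
                f"{self.metabolite}: heavy m/z must exceed light m/z "
                "for a C/N-containing analyte"
            )


def read_reference_masses(path: str | Path) -> list[ReferenceMass]:
    """Read a reference TSV: ``metabolite, formula, mz_light, rt_start, rt_end``."""
    df = pd.read_csv(path, sep="\t", dtype={"metabolite": str, "formula": str})
    for col in ("metabolite", "formula", "mz_light", "rt_start", "rt_end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        ReferenceMass(
            metabolite=row.metabolite,
            formula=parse_formula(row.formula),
            mz_light=float(row.mz_light),
            rt_window=(float(row.rt_start), float(row.rt_end)),
        )
        for row in df.itertuples(index=False)
    ]


@dataclass
class Trace:
    """Profile-mode point list for one sample: (rt s, m/z Da, intensity)."""

    sample: str
    points: pd.DataFrame  # columns rt_s, mz, intensity

    def __post_init__(self) -> None:
        for col in ("rt_s", "mz", "intensity"):
            if col not in self.points.columns:
                raise ValueError(f"trace missing column {col!r}")
        if not np.isfinite(self.points["intensity"]).all():
            raise ValueError("trace intensities must be finite")


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read a long-format trace TSV.

    Columns: ``sample, metabolite, channel, rt_s, mz, intensity``; channel
    is ``light`` or ``heavy`` (metadata only — extraction is by m/z).
    """
    df = pd.read_csv(path, sep="\t",
                     dtype={"sample": str, "metabolite": str, "channel": str})
    required = {"sample", "metabolite", "channel", "rt_s", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def extract_xic(
    trace: Trace,
    window: tuple[float, float],
    rt_window: tuple[float, float],
) -> pd.DataFrame:
    """Extracted ion chromatogram: per-RT summed intensity inside both windows.

    Returns a two-column frame (``rt_s``, ``intensity``) sorted by RT;
    empty when no point falls in the windows (a warning is logged).
    """
    lo, hi = window
    t0, t1 = rt_window
    pts = trace.points
    mask = (
        (pts["mz"] >= lo) & (pts["mz"] <= hi)
        & (pts["rt_s"] >= t0) & (pts["rt_s"] <= t1)
    )
    sel = pts[mask]
    if sel.empty:
        log.warning("empty XIC for sample %s in m/z [%g, %g]", trace.sample, lo, hi)
        return pd.DataFrame({"rt_s": [], "intensity": []})
    xic = (
        sel.groupby("rt_s", sort=True)["intensity"].sum().reset_index()
    )
    return xic


def integrate_auc(xic: pd.DataFrame) -> float:
    """Trapezoidal area under an XIC (intensity * seconds); 0 below 2 points."""
    if len(xic) < 2:
        return 0.0
    rt = np.asarray(xic["rt_s"], dtype=float)
    if np.any(np.diff(rt) < 0):
        raise ValueError("XIC must be sorted by retention time")
    return float(np.trapezoid(np.asarray(xic["intensity"], dtype=float), rt))


@dataclass(frozen=True)
class MetaboliteQuant:
    """Light/heavy AUC ratio for one analyte in one sample."""

    sample: str
    metabolite: str
    auc_light: float
    auc_heavy: float
    ratio: Optional[float]  # None when the heavy channel integrates to zero

    def __post_init__(self) -> None:
        if self.auc_light < 0 or self.auc_heavy < 0:
            raise ValueError("areas must be nonnegative")


def quantify(
    trace: Trace, ref: ReferenceMass, config: AnalysisConfig
) -> MetaboliteQuant:
    """Quantify one analyte in one sample by stable-isotope dilution."""
    w_light = mz_window(ref.mz_light, config.ppm_window)
    w_heavy = mz_window(ref.mz_heavy, config.ppm_window)
    auc_l = integrate_auc(extract_xic(trace, w_light, ref.rt_window))
    auc_h = integrate_auc(extract_xic(trace, w_heavy, ref.rt_window))
    ratio = auc_l / auc_h if auc_h > 0 else None
    if ratio is None:
        log.warning(
            "heavy channel empty for %s in sample %s; ratio undefined",
            ref.metabolite, trace.sample,
        )
    return MetaboliteQuant(
        sample=trace.sample, metabolite=ref.metabolite,
        auc_light=auc_l, auc_heavy=auc_h, ratio=ratio,
    )


def quantify_all(
    traces: pd.DataFrame, refs: Sequence[ReferenceMass], config: AnalysisConfig
) -> pd.DataFrame:
    """Quantify every (sample, analyte) pair present in a long trace table."""
    rows = []
    ref_by_name = {r.metabolite: r for r in refs}
    for (sample, metabolite), sub in traces.groupby(["sample", "metabolite"], sort=True):
        if metabolite not in ref_by_name:
            log.warning("no reference mass for %s; skipped", metabolite)
            continue
        q = quantify(Trace(sample=sample, points=sub), ref_by_name[metabolite], config)
        rows.append((q.sample, q.metabolite, q.auc_light, q.auc_heavy,
                     np.nan if q.ratio is None else q.ratio))
    return pd.DataFrame(
        rows, columns=["sample", "metabolite", "auc_light", "auc_heavy", "ratio"]
    )


@dataclass(frozen=True)
class MetaboliteDiff:
    """Differential-filter decision for one analyte at one timepoint."""

    metabolite: str
    fold_change: float
    p_value: float
    retained: bool

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


def diff_metabolites(
    quants: pd.DataFrame,
    timepoint: str,
    config: AnalysisConfig,
    treated: str = "treated",
    control: str = "control",
    fdr: bool = False,
) -> list[MetaboliteDiff]:
    """Apply the timepoint-specific fold and p-value filters.

    ``quants`` needs columns ``metabolite``, ``condition``, ``ratio`` with
    >= 2 replicate rows per group. fold_change = mean(treated ratios) /
    mean(control ratios); the p-value is a two-sided Welch t-test on the
    replicate ratios. An analyte is retained when the fold change reaches
    the timepoint's cutoff in either direction (>= t or <= 1/t) and
    p < the p cutoff. ``fdr=True`` applies Benjamini-Hochberg across
    analytes before thresholding (off by default).
    """
    if timepoint not in config.metabolite_fc_threshold:
        raise ValueError(f"no metabolite fold threshold configured for {timepoint!r}")
    if control not in set(quants["condition"]):
        raise ValueError(f"missing control group {control!r}")
    threshold = config.metabolite_fc_threshold[timepoint]

    prelim = []
    for metabolite, sub in quants.groupby("metabolite", sort=True):
        t = sub.loc[sub["condition"] == treated, "ratio"].dropna()
        c = sub.loc[sub["condition"] == control, "ratio"].dropna()
        if len(t) < 2 or len(c) < 2:
            log.warning("%s: fewer than 2 defined replicates per group; excluded",
                        metabolite)
            continue
        fold = t.mean() / c.mean()
        p = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
        prelim.append((metabolite, float(fold), p))

    if fdr and prelim:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([p for _, _, p in prelim], method="fdr_bh")
        prelim = [(m, f, float(q)) for (m, f, _), q in zip(prelim, p_adj)]

    out = []
    for metabolite, fold, p in prelim:
        retained = (
            (fold >= threshold or fold <= 1.0 / threshold)
            and p < config.metabolite_p_threshold
        )
        out.append(MetaboliteDiff(metabolite=metabolite, fold_change=fold,
                                  p_value=p, retained=retained))
    return out


def diffs_to_frame(diffs: Sequence[MetaboliteDiff]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.metabolite, d.fold_change, d.p_value, d.retained) for d in diffs],
        columns=["metabolite", "fold_change", "p_value", "retained"],
    )


def heatmap_matrix(
    diff_frames: Mapping[str, pd.DataFrame], retained_only: bool = True
) -> pd.DataFrame:
    """Metabolite x condition matrix of log2 fold changes, heatmap-ready.

    ``diff_frames`` maps a condition/timepoint label to a diff table; rows
    are restricted to metabolites retained in at least one column unless
    ``retained_only=False``.
    """
    cols = {}
    keep: set[str] = set()
    for label, df in diff_frames.items():
        cols[label] = df.set_index("metabolite")["fold_change"].apply(np.log2)
        keep |= set(df.loc[df["retained"], "metabolite"])
    mat = pd.DataFrame(cols).sort_index()
    if retained_only:
        mat = mat.loc[sorted(keep & set(mat.index))]
    return mat
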