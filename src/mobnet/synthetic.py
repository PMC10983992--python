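"""Synthetic regulon-structured DE tables and isotope-pair chromatograms.

The generator plants known ground truth so every downstream stage can be
validated end to end: regulons with controlled pairwise overlap over a
gene universe sized like the B. subtilis genome, DE tables in which a
chosen fraction of each regulon's members is differentially expressed
with a chosen up/down bias, and paired light/heavy Gaussian
chromatographic peaks with known true area ratios.

Planting is deterministic by default — the engaged count is
round(planted fraction x regulon size) — so recovery tests are exact; a
Bernoulli mode (each member engaged independently) is available for
statistical tests. Genes belonging to several regulons receive their
engagement status from the first regulon that processes them, in
regulator-name lexicographic order; later regulons plant only over their
not-yet-assigned members. All randomness flows from one explicit seed;
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engagement import Regulon, RegulonSet
from .expression import DEFAULT_CATEGORIES, DeTable
from .metabolomics import heavy_mz


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters for the DE-table generator.

    ``planted_engagement`` maps regulator -> timepoint -> engaged fraction;
    ``up_bias`` maps regulator -> probability that an engaged gene is up.
    ``lfc_magnitude`` is the mean |log2FC| of engaged genes (log-normal,
    clipped below at 1.0 so planted genes always pass a 2-fold cutoff);
    null genes get Normal(0, ``null_lfc_sd``) log2FC. Engaged genes draw
    padj uniformly on (0, ``padj_engaged_max``]; null genes uniformly on
    (``padj_null_min``, 1].
    """

    seed: int
    n_genes: int = 4000
    n_regulons: int = 20
    regulon_size_range: tuple[int, int] = (10, 60)
    overlap_fraction: float = 0.1
    planted_engagement: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    up_bias: Mapping[str, float] = field(default_factory=dict)
    lfc_magnitude: float = 2.0
    null_lfc_sd: float = 0.4
    padj_engaged_max: float = 0.01
    padj_null_min: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.regulon_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("regulon sizes must satisfy 1 <= lo <= hi")
        if self.n_genes < hi:
            raise ConfigurationError("n_genes must cover the largest regulon")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ConfigurationError("overlap_fraction must lie in [0,1]")
        for reg, per_tp in self.planted_engagement.items():
            for tp, f in per_tp.items():
                if not 0.0 <= f <= 1.0:
                    raise ConfigurationError(
                        f"planted engagement for {reg}@{tp} outside [0,1]"
                    )
        for reg, b in self.up_bias.items():
            if not 0.0 <= b <= 1.0:
                raise ConfigurationError(f"up_bias for {reg} outside [0,1]")
        if self.lfc_magnitude <= 0 or self.null_lfc_sd <= 0:
            raise ConfigurationError("lfc_magnitude and null_lfc_sd must be positive")
        if not 0 < self.padj_engaged_max < 1 or not 0 < self.padj_null_min < 1:
            raise ConfigurationError("padj bounds must lie in (0,1)")


def regulator_names(n: int) -> list[str]:
    """Zero-padded regulator names whose lexicographic order is stable."""
    width = max(2, len(str(n)))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


def gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _subseed(seed: int, label: str) -> list[int]:
    return [seed, zlib.crc32(label.encode())]


def gen_regulons(config: SynthConfig) -> RegulonSet:
    """Draw ``n_regulons`` member sets over the gene universe.

    For each regulon after the first, round(overlap_fraction x size)
    members are drawn from genes already assigned to earlier regulons
    (capped by the size of that pool) and the remainder from fresh genes.
    Realized pairwise overlaps are recorded on the returned set's
    ``provenance`` attribute.
    """
    rng = np.random.default_rng(_subseed(config.seed, "regulons"))
    genes = gene_names(config.n_genes)
    lo, hi = config.regulon_size_range
    unassigned = list(genes)
    assigned_pool: list[str] = []
    regulons = []
    for name in regulator_names(config.n_regulons):
        size = int(rng.integers(lo, hi + 1))
        n_over = min(int(np.floor(config.overlap_fraction * size + 0.5)),
                     len(assigned_pool))
        n_fresh = size - n_over
        if n_fresh > len(unassigned):
            raise ConfigurationError(
                f"gene universe exhausted while building {name}: "
                f"need {n_fresh} fresh genes, {len(unassigned)} left"
            )
        members = list(rng.choice(assigned_pool, n_over, replace=False)) if n_over else []
        fresh = list(rng.choice(unassigned, n_fresh, replace=False)) if n_fresh else []
        members += fresh
        for g in fresh:
            unassigned.remove(g)
            assigned_pool.append(g)
        regulons.append(Regulon(regulator=name, members=frozenset(members)))
    rs = RegulonSet(regulons)
    rs.provenance = {
        "seed": config.seed,
        "sizes": {r.regulator: len(r.members) for r in regulons},
        "pairwise_overlaps": {
            f"{a}|{b}": n for (a, b), n in rs.overlap_index().items()
        },
    }
    return rs


def gen_de_table(
    config: SynthConfig,
    regulons: RegulonSet,
    timepoint: str,
    condition: str = "synthetic",
    bernoulli: bool = False,
) -> DeTable:
    """Emit a DE table with the configured engagement planted per regulon.

    Deterministic mode plants exactly round(fraction x size) engaged genes
    per regulon (over not-yet-assigned members for overlapping regulons);
    ``bernoulli=True`` instead engages each available member independently
    with the planted probability.
    """
    for reg in config.planted_engagement:
        if reg not in regulons:
            raise ConfigurationError(f"unknown regulator {reg!r} in planted_engagement")
    for name in regulons.regulators:
        per_tp = config.planted_engagement.get(name)
        if per_tp is None or timepoint not in per_tp:
            raise ConfigurationError(
                f"planted_engagement missing for {name!r} at {timepoint!r}"
            )

    rng = np.random.default_rng(_subseed(config.seed, f"de:{condition}:{timepoint}"))
    status: dict[str, str] = {}  # gene -> up / down / null
    for name in regulons.regulators:
        frac = config.planted_engagement[name][timepoint]
        bias = config.up_bias.get(name, 0.5)
        members = sorted(regulons[name].members)
        avail = [g for g in members if g not in status]
        if bernoulli:
            engaged = [g for g in avail if rng.random() < frac]
        else:
            n_eng = min(int(np.floor(frac * len(members) + 0.5)), len(avail))
            engaged = list(rng.choice(avail, n_eng, replace=False)) if n_eng else []
        engaged_set = set(engaged)
        for g in avail:
            if g in engaged_set:
                status[g] = "up" if rng.random() < bias else "down"
            else:
                status[g] = "null"

    genes = gene_names(config.n_genes)
    # log-normal |log2FC| with mean lfc_magnitude (sigma_log fixed at 0.25),
    # clipped below at 1.0 so every planted gene clears the 2-fold cutoff
    sigma_log = 0.25
    mu_log = np.log(config.lfc_magnitude) - sigma_log**2 / 2
    rows = []
    for g in genes:
        s = status.get(g, "null")
        if s == "null":
            lfc = rng.normal(0.0, config.null_lfc_sd)
            padj = rng.uniform(config.padj_null_min, 1.0)
        else:
            mag = max(1.0, rng.lognormal(mu_log, sigma_log))
            lfc = mag if s == "up" else -mag
            padj = rng.uniform(0.0, config.padj_engaged_max)
        rows.append((g, lfc, padj))
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])
    return DeTable(condition=condition, timepoint=timepoint, data=df)


def planted_truth(
    config: SynthConfig, regulons: RegulonSet, timepoint: str
) -> dict[str, dict]:
    """Expected engaged counts under deterministic planting.

    For disjoint regulons this equals the recovered count exactly; for
    overlapping regulons the count reflects the first-assignment
    precedence rule only through the cap on available members, so the
    planted count is a lower bound up to that cap.
    """
    out = {}
    for name in regulons.regulators:
        size = len(regulons[name].members)
        frac = config.planted_engagement[name][timepoint]
        out[name] = {
            "size": size,
            "planted_fraction": frac,
            "planted_engaged": int(np.floor(frac * size + 0.5)),
        }
    return out


@dataclass(frozen=True)
class PeakSpec:
    """Ground truth for one light/heavy Gaussian peak pair.

    ``true_area_light``/``true_area_heavy`` are the analytic areas
    (intensity x seconds) of the noiseless peaks; both channels share the
    same retention profile. ``noise_sd`` is a shot-noise coefficient: each
    sampled point receives Gaussian noise with standard deviation
    ``noise_sd * sqrt(intensity)``, so the baseline stays clean and the
    integrated area remains an unbiased estimate of the true area.
    ``mz_heavy`` defaults to the fully 13C/15N-labeled mass computed from
    the formula.
    """

    metabolite: str
    formula: str
    true_area_light: float
    true_area_heavy: float
    rt_center: float
    rt_sigma: float
    mz_light: float
    sampling_dt: float
    noise_sd: float = 0.0
    sample: str = "S1"
    mz_heavy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0 or self.sampling_dt <= 0:
            raise ConfigurationError("rt_sigma and sampling_dt must be positive")
        if self.mz_light <= 0:
            raise ConfigurationError("m/z values must be positive")
        if self.true_area_light <= 0 or self.true_area_heavy <= 0:
            raise ConfigurationError("true areas must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.mz_heavy is None:
            object.__setattr__(self, "mz_heavy", heavy_mz(self.formula, self.mz_light))


def gen_traces(
    specs: Sequence[PeakSpec], seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render Gaussian peak pairs as a long trace table plus reference masses.

    Each channel is sampled on a grid of step ``sampling_dt`` spanning
    rt_center +/- 5 sigma; the reference table's retention window covers
    the same span. Shot-like Gaussian noise (per-point sd
    ``noise_sd * sqrt(intensity)``) is clipped at zero to keep
    intensities nonnegative.
    """
    if not specs:
        raise ConfigurationError("specs must be nonempty")
    rng = np.random.default_rng(_subseed(seed, "traces"))
    trace_rows = []
    ref_rows = []
    for spec in specs:
        n = int(round(10 * spec.rt_sigma / spec.sampling_dt)) + 1
        t = spec.rt_center - 5 * spec.rt_sigma + np.arange(n) * spec.sampling_dt
        profile = np.exp(-((t - spec.rt_center) ** 2) / (2 * spec.rt_sigma**2))
        for channel, area, mz in (
            ("light", spec.true_area_light, spec.mz_light),
            ("heavy", spec.true_area_heavy, spec.mz_heavy),
        ):
            amp = area / (spec.rt_sigma * np.sqrt(2 * np.pi))
            intensity = amp * profile
            if spec.noise_sd > 0:
                sd = spec.noise_sd * np.sqrt(intensity)
                intensity = np.clip(intensity + rng.normal(0, 1, n) * sd, 0, None)
            for rt, y in zip(t, intensity):
                trace_rows.append(
                    (spec.sample, spec.metabolite, channel, float(rt), float(mz), float(y))
                )
        ref_rows.append(
            (spec.metabolite, spec.formula, spec.mz_light,
             spec.rt_center - 5 * spec.rt_sigma, spec.rt_center + 5 * spec.rt_sigma)
        )
    traces = pd.DataFrame(
        trace_rows,
        columns=["sample", "metabolite", "channel", "rt_s", "mz", "intensity"],
    )
    refs = (
        pd.DataFrame(
            ref_rows,
            columns=["metabolite", "formula", "mz_light", "rt_start", "rt_end"],
        )
        .drop_duplicates(subset="metabolite")
        .reset_index(drop=True)
    )
    return traces, refs


def gen_category_map(
    regulons: RegulonSet, seed: int, vocabulary: Sequence[str] = DEFAULT_CATEGORIES
) -> pd.DataFrame:
    """Assign each regulon one functional category (all members inherit it)."""
    rng = np.random.default_rng(_subseed(seed, "categories"))
    cats = [c for c in vocabulary if c != "unknown"]
    rows = []
    seen: set[str] = set()
    for name in regulons.regulators:
        cat = cats[int(rng.integers(0, len(cats)))]
        for g in sorted(regulons[name].members):
            if g not in seen:
                rows.append((g, cat))
                seen.add(g)
    return pd.DataFrame(rows, columns=["gene", "category"])


def default_study_config(seed: int, n_regulons: int = 20) -> SynthConfig:
    """A two-timepoint study emulating antibiotic exposure at 6 h and 24 h.

    Roughly a third of regulons engage strongly at 6 h (mostly repressed),
    engagement relaxes by 24 h for half of those, and a few regulons
    reverse direction — mirroring the early-repression / late-derepression
    pattern of master-regulator regulons under translational stress.
    """
    rng = np.random.default_rng(_subseed(seed, "study"))
    names = regulator_names(n_regulons)
    planted: dict[str, dict[str, float]] = {}
    bias: dict[str, float] = {}
    for i, name in enumerate(names):
        if i % 3 == 0:  # strongly engaged early, fading late
            planted[name] = {"6h": float(rng.uniform(0.35, 0.7)),
                             "24h": float(rng.uniform(0.05, 0.25))}
            bias[name] = 0.2
        elif i % 3 == 1:  # engaged at both times, direction reversal
            planted[name] = {"6h": float(rng.uniform(0.3, 0.5)),
                             "24h": float(rng.uniform(0.3, 0.5))}
            bias[name] = 0.25 if rng.random() < 0.5 else 0.75
        else:  # background regulons below the cutoff
            planted[name] = {"6h": float(rng.uniform(0.0, 0.15)),
                             "24h": float(rng.uniform(0.0, 0.15))}
            bias[name] = 0.5
    return SynthConfig(
        seed=seed, n_regulons=n_regulons,
        planted_engagement=planted, up_bias=bias,
    )


def simulate_study(seed: int, out_dir: str | Path, n_regulons: int = 20) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Produces regulons.tsv, de_synthetic_{6h,24h}.tsv, categories.tsv,
    traces.tsv, reference_masses.tsv and a truth.json with the planted
    ground truth; returns the manifest of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = default_study_config(seed, n_regulons=n_regulons)
    regulons = gen_regulons(config)

    from .engagement import write_regulons
    from .expression import write_de_table

    write_regulons(regulons, out_dir / "regulons.tsv")
    paths = {"regulons": str(out_dir / "regulons.tsv")}
    truth: dict = {"seed": seed, "regulons": regulons.provenance, "timepoints": {}}
    for tp in ("6h", "24h"):
        table = gen_de_table(config, regulons, tp)
        p = out_dir / f"de_synthetic_{tp}.tsv"
        write_de_table(table, p)
        paths[f"de_{tp}"] = str(p)
        truth["timepoints"][tp] = planted_truth(config, regulons, tp)

    cats = gen_category_map(regulons, seed)
    cats.to_csv(out_dir / "categories.tsv", sep="\t", index=False)
    paths["categories"] = str(out_dir / "categories.tsv")

    specs = default_peak_specs(seed)
    traces, refs = gen_traces(specs, seed)
    traces.to_csv(out_dir / "traces.tsv", sep="\t", index=False)
    refs.to_csv(out_dir / "reference_masses.tsv", sep="\t", index=False)
    paths["traces"] = str(out_dir / "traces.tsv")
    paths["reference_masses"] = str(out_dir / "reference_masses.tsv")
    truth["peaks"] = [
        {"sample": s.sample, "metabolite": s.metabolite,
         "true_ratio": s.true_area_light / s.true_area_heavy}
        for s in specs
    ]
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    paths["truth"] = str(out_dir / "truth.json")
    return paths


def default_peak_specs(seed: int) -> list[PeakSpec]:
    """Replicate peak pairs for a treated-vs-control metabolite panel.

    Three replicates per condition for three analytes: one ~8-fold up in
    treated samples (an allantoin-like purine-catabolism intermediate),
    one ~3-fold up (pyruvate-like), one unchanged. Heavy-standard areas
    are constant across samples, as for a spiked internal standard.
    """
    rng = np.random.default_rng(_subseed(seed, "peaks"))
    panel = [
        # metabolite, formula, light [M-H]- m/z, rt center, treated fold
        ("allantoin", "C4H6N4O3", 157.0367, 300.0, 8.0),
        ("pyruvate", "C3H4O3", 87.0088, 180.0, 3.0),
        ("citrate", "C6H8O7", 191.0192, 420.0, 1.0),
    ]
    specs = []
    for metabolite, formula, mz, rt, fold in panel:
        for cond, level in (("control", 1.0), ("treated", fold)):
            for rep in range(1, 4):
                jitter = float(rng.uniform(0.95, 1.05))
                specs.append(
                    PeakSpec(
                        metabolite=metabolite, formula=formula,
                        true_area_light=100.0 * level * jitter,
                        true_area_heavy=100.0,
                        rt_center=rt, rt_sigma=4.0, mz_light=mz,
                        sampling_dt=0.4, noise_sd=0.05,
                        sample=f"{cond}_{rep}",
                    )
                )
    return specs
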