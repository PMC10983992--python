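"""End-to-end orchestration with a single config file and a run manifest.

A run executes classify -> categories -> engage -> network -> compare and,
when chromatographic inputs are present, quantify -> metdiff, writing every
stage output under one directory plus a JSON manifest (config snapshot,
input digests, seed, output paths, version). Deterministic stages re-run
byte-identically from the same manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .compare import (compare_regulator_sets, detect_switch, write_switches,
                      write_venn)
from .config import AnalysisConfig
from .engagement import read_regulons, score_all, write_results
from .expression import read_category_map, read_de_table, summarize_categories
from .metabolomics import (diff_metabolites, diffs_to_frame, quantify_all,
                           read_reference_masses, read_traces)
from .network import build_network, export_attribute_tables, export_network
from .synthetic import simulate_study

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Raised when a pipeline config fails validation before any stage runs."""


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineConfigError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema and input-existence checks; raises before any stage runs."""
    if "inputs" not in cfg or not isinstance(cfg["inputs"], dict):
        raise PipelineConfigError("config requires an 'inputs' section")
    inputs = cfg["inputs"]
    timepoints = cfg.get("timepoints", ["6h", "24h"])
    if not timepoints:
        raise PipelineConfigError("timepoints must be nonempty")
    if not inputs.get("synthetic", False):
        for key in ("regulons", "de"):
            if key not in inputs:
                raise PipelineConfigError(f"inputs missing required key {key!r}")
        for tp in timepoints:
            if tp not in inputs["de"]:
                raise PipelineConfigError(f"inputs.de missing timepoint {tp!r}")
        paths = [inputs["regulons"], *inputs["de"].values()]
        for opt in ("categories", "traces", "reference_masses"):
            if opt in inputs:
                paths.append(inputs[opt])
        for p in paths:
            if not Path(p).exists():
                raise PipelineConfigError(f"input file not found: {p}")
    if "thresholds" in cfg:
        AnalysisConfig.from_dict(cfg["thresholds"])  # raises on bad values


def run_pipeline(
    config_path: str | Path,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> dict:
    """Execute every configured stage; returns the run manifest."""
    cfg = load_config(config_path)
    validate_config(cfg)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "mobnet_run"))
    out.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig.from_dict(cfg.get("thresholds", {}))
    timepoints = [str(t) for t in cfg.get("timepoints", ["6h", "24h"])]
    condition = str(cfg.get("condition", "synthetic"))

    inputs = dict(cfg["inputs"])
    if inputs.get("synthetic", False):
        log.info("stage simulate: writing synthetic study")
        paths = simulate_study(seed, out / "synthetic",
                               n_regulons=int(inputs.get("n_regulons", 20)))
        inputs = {
            "regulons": paths["regulons"],
            "de": {tp: paths[f"de_{tp}"] for tp in timepoints},
            "categories": paths["categories"],
            "traces": paths["traces"],
            "reference_masses": paths["reference_masses"],
        }

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {"analysis": analysis.to_dict(), "timepoints": timepoints,
                   "condition": condition},
        "inputs": {},
        "outputs": {},
    }
    for key, val in inputs.items():
        if isinstance(val, dict):
            manifest["inputs"][key] = {k: {"path": str(v), "sha256": _sha256(v)}
                                       for k, v in val.items()}
        elif isinstance(val, (str, Path)):
            manifest["inputs"][key] = {"path": str(val), "sha256": _sha256(val)}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    regulons = _stage("read_regulons", lambda: read_regulons(inputs["regulons"]))
    cats = None
    if "categories" in inputs:
        cats = _stage("read_categories",
                      lambda: read_category_map(inputs["categories"]))

    networks = {}
    results_by_tp = {}
    for tp in timepoints:
        table = _stage(f"classify[{tp}]",
                       lambda tp=tp: read_de_table(inputs["de"][tp], condition, tp))
        if cats is not None:
            summary = _stage(f"categories[{tp}]",
                             lambda: summarize_categories(table, cats, analysis))
            p = out / f"category_summary_{tp}.tsv"
            summary.to_csv(p, sep="\t", index=False)
            manifest["outputs"][f"category_summary_{tp}"] = str(p)
        results, n_included = _stage(f"engage[{tp}]",
                                     lambda: score_all(regulons, table, analysis))
        results_by_tp[tp] = results
        p = out / f"engagement_{tp}.tsv"
        write_results(results, p)
        manifest["outputs"][f"engagement_{tp}"] = str(p)
        net = _stage(f"network[{tp}]",
                     lambda: build_network(results, regulons, table, analysis))
        networks[tp] = net
        for fmt in ("json", "graphml", "sif"):
            p = out / f"network_{tp}.{fmt}"
            export_network(net, p, fmt)
            manifest["outputs"][f"network_{tp}_{fmt}"] = str(p)
        export_attribute_tables(net, out / f"network_{tp}")
        manifest["outputs"][f"n_included_{tp}"] = n_included

    if len(timepoints) >= 2:
        a, b = timepoints[0], timepoints[1]
        venn = _stage("compare", lambda: compare_regulator_sets(networks[a], networks[b]))
        p = out / "venn.tsv"
        write_venn(venn, p)
        manifest["outputs"]["venn"] = str(p)
        calls = [
            detect_switch(r1, r2)
            for r1, r2 in zip(results_by_tp[a], results_by_tp[b])
        ]
        p = out / "switches.tsv"
        write_switches(calls, p)
        manifest["outputs"]["switches"] = str(p)

    if "traces" in inputs and "reference_masses" in inputs:
        traces = _stage("read_traces", lambda: read_traces(inputs["traces"]))
        refs = _stage("read_refs",
                      lambda: read_reference_masses(inputs["reference_masses"]))
        quants = _stage("quantify", lambda: quantify_all(traces, refs, analysis))
        quants["condition"] = quants["sample"].str.rsplit("_", n=1).str[0]
        p = out / "metabolite_quant.tsv"
        quants.to_csv(p, sep="\t", index=False)
        manifest["outputs"]["metabolite_quant"] = str(p)
        met = cfg.get("metabolomics", {}) or {}
        for tp in timepoints:
            if tp not in analysis.metabolite_fc_threshold:
                continue
            diffs = _stage(f"metdiff[{tp}]", lambda tp=tp: diff_metabolites(
                quants, tp, analysis,
                treated=met.get("treated", "treated"),
                control=met.get("control", "control"),
            ))
            p = out / f"metabolite_diff_{tp}.tsv"
            diffs_to_frame(diffs).to_csv(p, sep="\t", index=False)
            manifest["outputs"][f"metabolite_diff_{tp}"] = str(p)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
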