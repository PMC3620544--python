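"""End-to-end orchestration: call -> group -> coexpress -> enrich ->
classify, with a manifest and a summary report.

The run config is a YAML mapping with three blocks::

    seed: 7
    outdir: results/
    thresholds: {alpha: 0.05, fold_threshold: 2.0, ...}   # PipelineConfig
    simulation: {genes_per_species: 2000, ...}            # generate inputs
    # -- or, instead of `simulation`, explicit inputs: --
    inputs:
      expression: {ath: expr_ath.tsv, ptr: ..., osa: ...}
      sample_sheet: sheet.tsv
      hits: hits.tsv
      species_map: species_map.tsv
      ontology: go.obo
      annotations: annotations.tsv
      process_map: process_map.tsv        # optional; packaged default
    coexpression_species: ath             # optional; first species

Stage outputs are pure functions of (inputs, config, seed); rerunning
an identical config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .calling import call_vascular_genes, write_vascular_calls
from .config import ConfigError, PipelineConfig
from .enrichment import (
    classification_summary,
    classify_groups,
    default_process_map,
    enrich,
    load_ontology,
    read_annotations,
    read_process_map,
)
from .expression import SampleSheet, read_expression, tissue_profile
from .network import export_network, extract_clusters, hrr_edges, pcc_matrix
from .orthology import (
    build_groups,
    group_summary,
    identify_cvgs,
    load_hits,
    read_species_map,
    write_groups,
)
from .simulate import SimulationParams, simulate_all

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed after validation succeeded."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    stage_counts: dict[str, Any] = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def load_run_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"run config {path} is not a mapping")
    return cfg


def _validate_run_config(cfg: dict[str, Any]) -> None:
    if "outdir" not in cfg:
        raise ConfigError("missing required config key: outdir")
    if ("simulation" in cfg) == ("inputs" in cfg):
        raise ConfigError(
            "config must provide exactly one of 'simulation' or 'inputs'"
        )
    if "inputs" in cfg:
        req = ("expression", "sample_sheet", "hits", "species_map",
               "ontology", "annotations")
        for key in req:
            if key not in cfg["inputs"]:
                raise ConfigError(f"missing required config key: inputs.{key}")
        for key, val in cfg["inputs"].items():
            paths = val.values() if isinstance(val, dict) else [val]
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"inputs.{key}: no such file: {p}")


def run_all(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    """Execute every stage; returns the summary dict.

    Raises ConfigError for invalid configuration and StageError when a
    stage fails mid-run (partial outputs and the manifest, with the
    failed stage marked, are retained).
    """
    if not isinstance(config, dict):
        config = load_run_config(config)
    _validate_run_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    pconf = PipelineConfig.from_dict(
        {**config.get("thresholds", {}), "seed": seed}
    )
    manifest = RunManifest(config={**config, "seed": seed})
    summary: dict[str, Any] = {"seed": seed}
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        stage = "inputs"
        t0 = time.perf_counter()
        truth = None
        if "simulation" in config:
            params = SimulationParams(
                **{**config.get("simulation", {}), "seed": seed}
            )
            sim = simulate_all(params, outdir / "simulated")
            matrices = sim["matrices"]
            sheet = sim["sheet"]
            truth = sim["truth_obj"]
            hits_path = sim["hits"]
            species_map = read_species_map(sim["species_map"])
            obo_path, annot_path = sim["ontology"], sim["annotations"]
            process_map = read_process_map(sim["process_map"])
            input_files = {
                k: Path(v) for k, v in sim.items() if isinstance(v, (str, Path))
            }
        else:
            inputs = config["inputs"]
            sheet = SampleSheet.read(inputs["sample_sheet"])
            matrices = {
                sp: read_expression(p, sheet)
                for sp, p in inputs["expression"].items()
            }
            hits_path = inputs["hits"]
            species_map = read_species_map(inputs["species_map"])
            obo_path, annot_path = inputs["ontology"], inputs["annotations"]
            process_map = (
                read_process_map(inputs["process_map"])
                if "process_map" in inputs
                else default_process_map()
            )
            input_files = {
                "sample_sheet": Path(inputs["sample_sheet"]),
                "hits": Path(hits_path),
                "species_map": Path(inputs["species_map"]),
                "ontology": Path(obo_path),
                "annotations": Path(annot_path),
                **{f"expression_{sp}": Path(p)
                   for sp, p in inputs["expression"].items()},
            }
        manifest.input_digests = {
            k: _sha256(p) for k, p in sorted(input_files.items()) if p.is_file()
        }
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- vascular calling ------------------------------------------
        stage = "call"
        t0 = time.perf_counter()
        vascular_sets: dict[str, set[str]] = {}
        species_summary = {}
        for sp in sorted(matrices):
            profile = tissue_profile(matrices[sp], sheet)
            calls = call_vascular_genes(profile, pconf)
            write_vascular_calls(calls, outdir / f"vascular_calls_{sp}.tsv")
            called = set(calls.index[calls["is_vascular"]])
            vascular_sets[sp] = called
            species_summary[sp] = {
                "n_genes": int(len(calls)),
                "n_vascular": len(called),
                "pct_vascular": round(100.0 * len(called) / len(calls), 1),
            }
        summary["species"] = species_summary
        manifest.stage_counts[stage] = {
            sp: s["n_vascular"] for sp, s in species_summary.items()
        }
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- CVG grouping ----------------------------------------------
        stage = "group"
        t0 = time.perf_counter()
        hits = load_hits(hits_path, pconf.evalue_cutoff, species_map)
        cvgs = identify_cvgs(
            vascular_sets, hits, require_reciprocal=pconf.require_reciprocal
        )
        groups, incomplete = build_groups(
            cvgs, hits, require_reciprocal=pconf.require_reciprocal
        )
        write_groups(
            groups, outdir / "cvg_groups.tsv", outdir / "group_summary.json"
        )
        gsum = group_summary(groups)
        summary["cvg_counts"] = gsum["cvg_counts"]
        summary["n_groups"] = gsum["n_groups"]
        summary["n_incomplete_components"] = len(incomplete)
        manifest.stage_counts[stage] = {
            "n_groups": gsum["n_groups"], "n_incomplete": len(incomplete)
        }
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- coexpression network --------------------------------------
        stage = "coexpress"
        t0 = time.perf_counter()
        net_sp = config.get("coexpression_species") or sorted(matrices)[0]
        net_genes = sorted(cvgs.get(net_sp, set()))
        if len(net_genes) >= 2:
            pcc = pcc_matrix(matrices[net_sp], net_genes)
            edges = hrr_edges(pcc, pconf.hrr_cutoff)
            clusters = extract_clusters(edges, pconf.min_cluster_size)
            export_network(edges, clusters, outdir, prefix=f"coexpr_{net_sp}")
            in_clusters = {g for c in clusters for g in c.members}
        else:
            edges, clusters, in_clusters = None, [], set()
        summary["network"] = {
            "species": net_sp,
            "n_cvgs": len(net_genes),
            "n_genes_in_network": len(in_clusters),
            "n_clusters": len(clusters),
            "cluster_sizes": [c.size for c in clusters],
        }
        manifest.stage_counts[stage] = {"n_clusters": len(clusters)}
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- GO enrichment ---------------------------------------------
        stage = "enrich"
        t0 = time.perf_counter()
        dag = load_ontology(obo_path)
        annotations = read_annotations(annot_path)
        background = set(matrices[net_sp].gene_ids)
        sample = set(cvgs.get(net_sp, set())) & background
        if sample:
            table = enrich(sample, background, dag, annotations, pconf)
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            n_sig = int(table["significant"].sum())
            sig_terms = list(table.loc[table["significant"], "term_id"])
        else:
            n_sig, sig_terms = 0, []
        summary["enrichment"] = {
            "species": net_sp,
            "n_significant_terms": n_sig,
            "significant_terms": sig_terms,
        }
        manifest.stage_counts[stage] = {"n_significant_terms": n_sig}
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        # ---- process classification ------------------------------------
        stage = "classify"
        t0 = time.perf_counter()
        assignments = classify_groups(groups, annotations, dag, process_map, pconf)
        assignments.to_csv(
            outdir / "process_assignments.tsv", sep="\t", index=False
        )
        csum = classification_summary(assignments)
        summary["classification"] = csum
        manifest.stage_counts[stage] = {
            "n_undefined": csum["n_undefined"],
            "undefined_percent": csum["undefined_percent"],
        }
        manifest.stage_seconds[stage] = time.perf_counter() - t0
    except (ConfigError, StageError):
        manifest.failed_stage = stage
        manifest.write(outdir / "manifest.json")
        raise
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.write(outdir / "manifest.json")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest.write(outdir / "manifest.json")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if truth is not None:
        summary["_truth"] = truth
        summary["_vascular_sets"] = vascular_sets
        summary["_groups"] = groups
    return summary
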