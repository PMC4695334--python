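"""End-to-end orchestration with a reproducible run manifest.

Stage order follows the analysis narrative: expression response ->
TF peak matching and binding modes -> differential chromatin ->
assisted/directed classification.  Every stage writes one or more TSV
tables; a YAML manifest records the config hash, input checksums, seed and
package version.  Re-running with the same config and inputs reproduces
byte-identical tables (the manifest timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binding import bound_fraction_enrichment, build_profiles, mode_enrichment
from .chromatin import (ALL_FACTORS, TF_FACTOR, build_epigenome_sets,
                        differential_test, gene_set_enrichment, quantify_window_counts)
from .classify import classify_context_genes, label_summary
from .expression import call_all_times, partition_context_sets
from .genome import derive_windows
from .io import (read_chrom_sizes, read_counts, read_expression, read_genes,
                 read_peaks, write_gene_table)
from .peaks import match_peaks, matches_to_frame
from .simulate import SimulationConfig, simulate

RESULT_TABLES = (
    "response_calls.tsv", "context_sets.tsv", "peak_matches.tsv",
    "gene_profiles.tsv", "bound_enrichment.tsv", "mode_enrichment.tsv",
    "differential_calls.tsv", "epigenome_sets.tsv", "gene_set_enrichment.tsv",
    "context_classification.tsv",
)

DEFAULTS = {
    "de_method": "moderated",
    "responsive_fdr": 0.1,
    "alpha": 0.05,
    "min_lfc": 1.0,
    "context_time": 24,
    "mode_times": [6, 24],
    "sharedness": "summit_in_interval",
    "assignment_rule": "overlap",
    "enrichment_test": "chi2",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()


def simulation_config_from_dict(overrides: dict, seed: int | None = None) -> SimulationConfig:
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    cfg = SimulationConfig(**overrides)
    if seed is not None:
        cfg.seed = seed
    return cfg


def _load_inputs(paths: dict):
    layout = read_chrom_sizes(paths["chrom_sizes"])
    genes = read_genes(paths["genes"])
    peaks = {}
    for cond in ("A", "B"):
        dialect = paths.get("peak_dialect", "narrowPeak")
        peaks[(TF_FACTOR, cond)] = read_peaks(paths[f"smad3_peaks_{cond}"], dialect)
    counts = {}
    for factor in ALL_FACTORS:
        counts[factor] = read_counts(paths[f"{factor}_counts"], paths[f"{factor}_libsizes"])
    expression = read_expression(paths["expression"])
    return layout, genes, peaks, counts, expression


def run_all(config: dict, outdir) -> dict:
    """Run every stage; returns the in-memory results keyed by stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULTS, **config}
    seed = int(cfg.get("seed", 0))
    results: dict = {}
    input_checksums: dict[str, str] = {}

    # --- stage: data ------------------------------------------------------
    try:
        if "simulate" in cfg:
            sim_cfg = simulation_config_from_dict(cfg["simulate"] or {}, seed=cfg.get("seed"))
            data = simulate(sim_cfg)
            layout, genes = data.layout, data.genes
            peaks, counts, expression = data.peaks, data.counts, data.expression
            results["truth"] = data.truth
            write_gene_table(data.truth, outdir / "truth.tsv")
        else:
            paths = cfg["inputs"]
            layout, genes, peaks, counts, expression = _load_inputs(paths)
            for key, p in paths.items():
                if isinstance(p, str) and Path(p).exists():
                    input_checksums[key] = _sha256(Path(p))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("data", str(exc)) from exc

    # --- stage: expression_response --------------------------------------
    try:
        calls_a = call_all_times(expression, "A", cfg["de_method"], cfg["responsive_fdr"])
        calls_b = call_all_times(expression, "B", cfg["de_method"], cfg["responsive_fdr"])
        context_sets = partition_context_sets(calls_a, calls_b)
        response_calls = pd.concat([calls_a, calls_b], ignore_index=True)
        write_gene_table(response_calls, outdir / "response_calls.tsv")
        write_gene_table(context_sets.to_frame(), outdir / "context_sets.tsv")
        results["response_calls"] = response_calls
        results["context_sets"] = context_sets
    except Exception as exc:
        raise PipelineError("expression_response", str(exc)) from exc

    # --- stage: peak_comparison -------------------------------------------
    try:
        matches = match_peaks(peaks[(TF_FACTOR, "A")], peaks[(TF_FACTOR, "B")], cfg["sharedness"])
        write_gene_table(matches_to_frame(matches), outdir / "peak_matches.tsv")
        results["matches"] = matches
    except Exception as exc:
        raise PipelineError("peak_comparison", str(exc)) from exc

    # --- stage: binding_modes ---------------------------------------------
    try:
        gp_windows = derive_windows(genes, layout, "gene_proximal")
        profiles = build_profiles(gp_windows, matches, cfg["assignment_rule"])
        write_gene_table(profiles, outdir / "gene_profiles.tsv")
        results["profiles"] = profiles

        background = context_sets.background
        bound_rows, mode_frames = [], []
        for t in cfg["mode_times"]:
            for cond, which in (("A", "A_unique"), ("B", "B_unique")):
                gene_set = context_sets.at(t, which)
                if not gene_set or not background:
                    continue
                row = bound_fraction_enrichment(gene_set, background, profiles,
                                                cond, cfg["enrichment_test"])
                row.update({"set": f"{which}_{t}h"})
                bound_rows.append(row)
                mode_frames.append(mode_enrichment(gene_set, background, profiles,
                                                   f"{which}_{t}h", cfg["enrichment_test"]))
        bound_enrichment = pd.DataFrame(bound_rows)
        modes_table = (pd.concat(mode_frames, ignore_index=True)
                       if mode_frames else pd.DataFrame())
        write_gene_table(bound_enrichment, outdir / "bound_enrichment.tsv")
        write_gene_table(modes_table, outdir / "mode_enrichment.tsv")
        results["bound_enrichment"] = bound_enrichment
        results["mode_enrichment"] = modes_table
    except Exception as exc:
        raise PipelineError("binding_modes", str(exc)) from exc

    # --- stage: differential_chromatin ------------------------------------
    try:
        gene_ids = [g.gene_id for g in genes]
        calls_by_factor = {}
        for factor in ALL_FACTORS:
            table = quantify_window_counts(gene_ids, counts[factor])
            calls_by_factor[factor] = differential_test(
                table, "A", "B", cfg["alpha"], cfg["min_lfc"], factor)
        differential = pd.concat(calls_by_factor.values(), ignore_index=True)
        epigenome_sets = build_epigenome_sets(calls_by_factor)
        write_gene_table(differential, outdir / "differential_calls.tsv")
        write_gene_table(epigenome_sets.to_frame(), outdir / "epigenome_sets.tsv")
        results["differential"] = calls_by_factor
        results["epigenome_sets"] = epigenome_sets

        universe = set(gene_ids)
        t = cfg["context_time"]
        enr_rows = []
        for cond, which in (("A", "A_unique"), ("B", "B_unique")):
            context = context_sets.at(t, which)
            if not context:
                continue
            for factor, calls in calls_by_factor.items():
                for direction in ("higher_A", "higher_B"):
                    dset = set(calls.loc[calls["direction"] == direction, "window_id"])
                    enr = gene_set_enrichment(dset, context, universe)
                    enr.update({"set": f"{which}_{t}h", "factor": factor, "direction": direction})
                    enr_rows.append(enr)
        gse = pd.DataFrame(enr_rows)
        write_gene_table(gse, outdir / "gene_set_enrichment.tsv")
        results["gene_set_enrichment"] = gse
    except Exception as exc:
        raise PipelineError("differential_chromatin", str(exc)) from exc

    # --- stage: context_classifier ----------------------------------------
    try:
        t = cfg["context_time"]
        context = {"A": context_sets.at(t, "A_unique"), "B": context_sets.at(t, "B_unique")}
        classification = classify_context_genes(context, epigenome_sets)
        write_gene_table(classification, outdir / "context_classification.tsv")
        results["classification"] = classification
        results["label_summary"] = label_summary(classification)
    except Exception as exc:
        raise PipelineError("context_classifier", str(exc)) from exc

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "config": cfg,
        "input_checksums": input_checksums,
        "tables": list(RESULT_TABLES),
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    results["manifest"] = manifest
    return results


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: pipeline config must be a mapping")
    return cfg


def write_report(truth: pd.DataFrame, results: dict, path) -> dict:
    """Truth-vs-result summary for a simulated run; returns the metrics."""
    from .simulate import truth_vs_result_report, truth_epigenome_sets, set_metrics

    profiles = results["profiles"].set_index("gene_id")
    preds = {"mode": profiles["mode"], "category": profiles["category"]}
    cls = results["classification"]
    preds["context_label"] = cls.set_index("gene_id")["label"]
    context_sets = results["context_sets"]
    for t in sorted(context_sets.per_time):
        lab = pd.Series("independent", index=pd.Index(sorted(context_sets.universe)))
        for which in ("A_unique", "B_unique", "shared"):
            lab.loc[sorted(context_sets.at(t, which))] = which
        preds[f"class_{t}"] = lab
    report = truth_vs_result_report(truth, preds)
    metrics = {family: entry["accuracy"] for family, entry in report.items()}
    truth_sets = truth_epigenome_sets(truth)
    measured = results["epigenome_sets"]
    for fam in ("smad3_high", "open_chromatin_high", "hypo_methylation"):
        for cond in ("A", "B"):
            m = set_metrics(getattr(truth_sets, fam)[cond], getattr(measured, fam).get(cond, set()))
            metrics[f"{fam}_{cond}_sensitivity"] = m["sensitivity"]
            metrics[f"{fam}_{cond}_precision"] = m["precision"]
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    return metrics
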