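"""Pipeline orchestration: run all stages from one YAML config, with a run
manifest, checksum-based stage skipping, and deterministic reports.

Stage order: io -> loops -> integration; io -> m6a; io -> tracing.  Every
threshold that affects results is snapshotted into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time
from dataclasses import asdict
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .genomic_io import (EXPRESSION_SCHEMA, M6A_PEAK_SCHEMA, read_gene_models,
                         read_loops, read_table, validate_expression,
                         write_table)
from .integration import (group_resample_logfc, intersect_enhanced_contacts,
                          select_mtc_dependent_genes)
from .loop_analytics import (assign_ep, count_ep_per_gene, define_promoters,
                             distance_distribution, filter_significant_loops)
from .m6a import (classify_polymethylated, count_unique_sites,
                  intersect_downregulated)
from .synthetic import GeneratorConfig, generate_all
from .tracing import (correct_isotopologue_table, labeled_fraction_table,
                      screen_metabolites)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": None,                 # required
    "inputs": None,               # directory of input files; None -> synthesize
    "assay": "H3K27Ac",
    "flank": 1000,                # promoter half-width, bp
    "delta_sign": "senescent_minus_growing",
    "group_size": 70,
    "reps": 200,
    "up_lfc": 1.0,
    "down_lfc": 1.0,
    "alpha": 0.05,
    "funnel_mode": "both",
    "min_sites_exclusive": 3,
    "p13c": 0.0107,
    "screen_alpha": 0.05,
    "m_label": 5,
}


class ConfigError(ValueError):
    pass


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **user}
    if cfg["seed"] is None:
        raise ConfigError("config field 'seed' is required")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(cfg: dict, input_paths: list[str]) -> str:
    payload = json.dumps({"cfg": cfg, "inputs": [
        (os.path.basename(p), _sha256(p)) for p in sorted(input_paths)
    ]}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config_path: str | os.PathLike,
                 outdir: str | os.PathLike) -> dict:
    """Execute all stages and write per-stage CSV outputs plus a manifest.

    Reruns with unchanged config and inputs skip up-to-date stages by
    checksum.  Returns the run manifest.
    """
    cfg = load_config(config_path)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    t0 = time.time()

    indir = cfg["inputs"]
    if indir is None:
        indir = os.path.join(outdir, "synthetic_inputs")
        if not os.path.exists(os.path.join(indir, "truth.json")):
            logger.info("synthesizing inputs into %s", indir)
            generate_all(GeneratorConfig(seed=cfg["seed"]), indir)

    input_files = sorted(
        os.path.join(indir, f) for f in os.listdir(indir)
        if f != "truth.json")
    manifest_path = os.path.join(outdir, "manifest.json")
    old_manifest = {}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            old_manifest = json.load(fh)

    manifest: dict[str, Any] = {
        "version": __version__,
        "config": cfg,
        "inputs": {os.path.basename(p): _sha256(p) for p in input_files},
        "stages": {},
    }
    stage_key = _stage_key(cfg, input_files)

    def _up_to_date(stage: str, outputs: list[str]) -> bool:
        prev = old_manifest.get("stages", {}).get(stage, {})
        return (prev.get("key") == stage_key
                and all(os.path.exists(os.path.join(outdir, f))
                        for f in outputs))

    def _record(stage: str, outputs: list[str], rows: dict[str, int],
                skipped: bool = False):
        manifest["stages"][stage] = {"key": stage_key, "outputs": outputs,
                                     "row_counts": rows, "skipped": skipped}

    # ---- loops stage -----------------------------------------------------
    loops_out = ["ep_counts.csv", "distance_distribution.csv"]
    if _up_to_date("loops", loops_out):
        logger.info("loops stage up to date; skipped")
        _record("loops", loops_out,
                old_manifest["stages"]["loops"]["row_counts"], skipped=True)
        ep_table = pd.read_csv(os.path.join(outdir, "ep_counts.csv"))
    else:
        catalog = read_gene_models(os.path.join(indir, "genes.gtf"), "gtf")
        promoters = define_promoters(catalog, flank=cfg["flank"])
        assignments = {}
        dist_frames = []
        for cond in ("growing", "senescent"):
            raw = read_loops(os.path.join(indir, f"loops_{cond}.bedpe"),
                             assay=cfg["assay"], condition=cond)
            sig = filter_significant_loops(raw, cfg["assay"])
            dist = distance_distribution(sig).reset_index(names="class")
            dist.insert(0, "condition", cond)
            dist_frames.append(dist)
            assignments[cond] = assign_ep(sig, promoters)
        ep_table = count_ep_per_gene(assignments, catalog,
                                     sign=cfg["delta_sign"])
        write_table(ep_table, os.path.join(outdir, "ep_counts.csv"))
        write_table(pd.concat(dist_frames, ignore_index=True),
                    os.path.join(outdir, "distance_distribution.csv"))
        _record("loops", loops_out, {"genes": len(ep_table)})

    # ---- integration stage ----------------------------------------------
    integ_out = ["resample_groups.csv", "candidates.csv", "integration.json"]
    if _up_to_date("integration", integ_out):
        logger.info("integration stage up to date; skipped")
        _record("integration", integ_out,
                old_manifest["stages"]["integration"]["row_counts"],
                skipped=True)
    else:
        expression = validate_expression(read_table(
            os.path.join(indir, "expression.csv"), EXPRESSION_SCHEMA))
        sen = expression[expression["contrast"] == "sen_vs_growing"]
        log_fc = sen.set_index("gene_id")["log_fc"]
        res = group_resample_logfc(ep_table, log_fc,
                                   group_size=cfg["group_size"],
                                   reps=cfg["reps"], seed=cfg["seed"])
        write_table(res.groups, os.path.join(outdir, "resample_groups.csv"))
        candidates = select_mtc_dependent_genes(
            expression, up_lfc=cfg["up_lfc"], down_lfc=cfg["down_lfc"],
            alpha=cfg["alpha"], mode=cfg["funnel_mode"])
        final = intersect_enhanced_contacts(candidates, ep_table, log_fc)
        write_table(final.pairs, os.path.join(outdir, "candidates.csv"))
        summary = {"resample_pearson_r": res.pearson_r,
                   "resample_p": res.p_value,
                   "n_up": len(final.up_in_senescence),
                   "n_intersection": len(final.intersection),
                   "n_enhanced": len(final.enhanced_contacts)}
        with open(os.path.join(outdir, "integration.json"), "w",
                  newline="\n") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _record("integration", integ_out,
                {"groups": len(res.groups), "candidates": len(final.pairs)})

    # ---- m6a stage -------------------------------------------------------
    m6a_out = ["m6a_calls.csv", "m6a_down.csv"]
    if _up_to_date("m6a", m6a_out):
        logger.info("m6a stage up to date; skipped")
        _record("m6a", m6a_out,
                old_manifest["stages"]["m6a"]["row_counts"], skipped=True)
    else:
        catalog = read_gene_models(os.path.join(indir, "genes.gtf"), "gtf")
        peaks = read_table(os.path.join(indir, "m6a_peaks.csv"),
                           M6A_PEAK_SCHEMA)
        m6a_expr = validate_expression(read_table(
            os.path.join(indir, "m6a_expression.csv"), EXPRESSION_SCHEMA))
        sites = count_unique_sites(peaks, catalog)
        calls = classify_polymethylated(
            sites, min_sites_exclusive=cfg["min_sites_exclusive"])
        write_table(calls, os.path.join(outdir, "m6a_calls.csv"))
        down = intersect_downregulated(calls, m6a_expr,
                                       down_lfc=cfg["down_lfc"],
                                       alpha=cfg["alpha"])
        write_table(pd.DataFrame({"transcript_id": sorted(down)}),
                    os.path.join(outdir, "m6a_down.csv"))
        _record("m6a", m6a_out, {"calls": len(calls), "down": len(down)})

    # ---- tracing stage ---------------------------------------------------
    trace_out = ["corrected_mids.csv", "screen.csv"]
    if _up_to_date("tracing", trace_out):
        logger.info("tracing stage up to date; skipped")
        _record("tracing", trace_out,
                old_manifest["stages"]["tracing"]["row_counts"], skipped=True)
    else:
        iso = pd.read_csv(os.path.join(indir, "isotopologues.csv"))
        corrected = correct_isotopologue_table(iso, p13c=cfg["p13c"])
        write_table(corrected.round(12),
                    os.path.join(outdir, "corrected_mids.csv"))
        fractions = labeled_fraction_table(corrected, cfg["m_label"])
        screen = screen_metabolites(fractions, alpha=cfg["screen_alpha"])
        write_table(screen.round(12), os.path.join(outdir, "screen.csv"))
        _record("tracing", trace_out,
                {"corrected": len(corrected), "screened": len(screen)})

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(manifest_path, "w", newline="\n") as fh:
        # elapsed time and skip flags are run-specific; excluded from the
        # written manifest so reruns stay byte-identical
        stable = {k: v for k, v in manifest.items() if k != "elapsed_s"}
        stable["stages"] = {
            name: {k: v for k, v in stage.items() if k != "skipped"}
            for name, stage in manifest["stages"].items()}
        json.dump(stable, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def make_report(outdir: str | os.PathLike) -> dict:
    """Deterministic JSON summary of whatever stage outputs exist.

    Missing stages produce warnings and a partial report rather than a
    failure; regeneration is idempotent.
    """
    outdir = str(outdir)
    report: dict[str, Any] = {"sections": {}, "warnings": []}

    def _try(name, fn):
        try:
            report["sections"][name] = fn()
        except FileNotFoundError:
            report["warnings"].append(f"stage output missing for {name!r}")

    def _loops():
        dist = pd.read_csv(os.path.join(outdir,
                                        "distance_distribution.csv"))
        ep = pd.read_csv(os.path.join(outdir, "ep_counts.csv"))
        return {"distance_distribution": dist.to_dict(orient="records"),
                "n_genes": int(len(ep)),
                "mean_delta_ep": float(ep["delta_ep"].mean())}

    def _integration():
        with open(os.path.join(outdir, "integration.json")) as fh:
            summary = json.load(fh)
        groups = pd.read_csv(os.path.join(outdir, "resample_groups.csv"))
        summary["resample_groups"] = groups.to_dict(orient="records")
        return summary

    def _m6a():
        calls = pd.read_csv(os.path.join(outdir, "m6a_calls.csv"))
        down = pd.read_csv(os.path.join(outdir, "m6a_down.csv"))
        return {"n_called": int(len(calls)),
                "n_polymethylated": int(calls["is_polymethylated"].sum()),
                "n_down": int(len(down))}

    def _tracing():
        screen = pd.read_csv(os.path.join(outdir, "screen.csv"))
        return {"n_metabolites": int(len(screen)),
                "n_pass": int(screen["passes_all"].sum()),
                "passing": sorted(
                    screen.loc[screen["passes_all"], "metabolite"])}

    _try("loops", _loops)
    _try("integration", _integration)
    _try("m6a", _m6a)
    _try("tracing", _tracing)

    with open(os.path.join(outdir, "report.json"), "w", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
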