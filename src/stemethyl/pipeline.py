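"""Configured, logged, resumable orchestration of the full analysis.

Stages run in dependency order::

    simulate -> call -> dmr -> profile -> integrate

A YAML file drives the run; every stage parameter defaults to the study
values (200/100 bp windows, coverage floor 4, q <= 0.05, per-context DMR
criteria, 2 kb flanks).  Each stage records a key (SHA-256 over its
parameters and input files) in ``manifest.json``; rerunning with
unchanged inputs skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import calling, integration, profiles, synthetic, windows
from . import io as mio

log = logging.getLogger("stemethyl")

DEFAULT_PARAMS: dict[str, Any] = {
    "window": 200,
    "step": 100,
    "min_coverage": 4,
    "q_threshold": 0.05,
    "contexts": ["CG", "CHG", "CHH", "ALL_C"],
    "flank": 2000,
    "density_bin": 100_000,
    "body_bins": 20,
    "flank_bin": 100,
    "deg_min_abs_log2fc": 1.0,
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries every detected problem."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _build_synthetic_config(section: Mapping[str, Any]) -> synthetic.SyntheticConfig:
    kwargs = dict(section)
    if "gene_structure" in kwargs:
        kwargs["gene_structure"] = synthetic.GeneStructure(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in kwargs["gene_structure"].items()})
    if "planted_dmrs" in kwargs:
        kwargs["planted_dmrs"] = [synthetic.PlantedDMR(**d)
                                  for d in kwargs["planted_dmrs"]]
    if "context_methylation" in kwargs:
        kwargs["context_methylation"] = {
            ctx: synthetic.BetaMixture(tuple(m["weights"]), tuple(m["means"]),
                                       tuple(m["concentrations"]))
            for ctx, m in kwargs["context_methylation"].items()}
    for key in ("te_length", "deg_log2fc_range", "condition_names"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return synthetic.SyntheticConfig(**kwargs)


def validate_config(path: str | os.PathLike) -> dict[str, Any]:
    """Load, validate and normalize a pipeline YAML config.

    All defaults are materialized; every detected error is reported at once
    via :class:`ConfigError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    cfg: dict[str, Any] = {}
    cfg["seed"] = int(raw.get("seed", 0))
    if "outdir" not in raw:
        errors.append("missing required key: outdir")
    else:
        cfg["outdir"] = str(raw["outdir"])
    params = dict(DEFAULT_PARAMS)
    params.update(raw.get("params", {}) or {})
    cfg["params"] = params

    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    if "simulate" in raw:
        section = dict(raw["simulate"] or {})
        section.setdefault("seed", cfg["seed"])
        try:
            sim = _build_synthetic_config(section)
            sim.validate()
            cfg["simulate"] = sim
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")
            cfg["simulate"] = None
        samples = list(cfg["simulate"].condition_names) if cfg.get("simulate") else []
    else:
        cfg["simulate"] = None
        samples = []
        for key in ("genome", "genes", "tes", "expression"):
            if key not in raw:
                errors.append(f"missing required path: {key}")
            else:
                p = resolve(raw[key])
                cfg[key] = p
                if not os.path.exists(p):
                    errors.append(f"{key} path does not exist: {p}")
        manifest = raw.get("samples") or {}
        if not manifest:
            errors.append("missing sample manifest: samples")
        for sid, spec in manifest.items():
            samples.append(sid)
            for p in [spec.get("lambda")] + list(spec.get("replicates", [])):
                if p is None:
                    errors.append(f"sample {sid}: missing lambda/replicates")
                elif not os.path.exists(resolve(p)):
                    errors.append(f"sample {sid}: path does not exist: {p}")
        cfg["samples"] = {
            sid: {"lambda": resolve(spec["lambda"]),
                  "replicates": [resolve(p) for p in spec.get("replicates", [])]}
            for sid, spec in manifest.items()
            if spec.get("lambda") and spec.get("replicates")}

    comparisons = [tuple(c) for c in (raw.get("comparisons") or [])]
    for pair in comparisons:
        if len(pair) != 2:
            errors.append(f"comparison must be a pair: {pair}")
        else:
            for s in pair:
                if samples and s not in samples:
                    errors.append(f"comparison references unknown sample {s!r}")
    if not comparisons:
        log.warning("no comparisons configured; running descriptive stages only")
    cfg["comparisons"] = comparisons
    if errors:
        raise ConfigError(errors)
    return cfg


# ---------------------------------------------------------------------------
# Manifest / resumability
# ---------------------------------------------------------------------------

def _hash_files(paths: list[str]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(os.path.basename(p).encode())
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    return h.hexdigest()


def _stage_key(params: Any, input_paths: list[str]) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob + _hash_files(input_paths).encode()).hexdigest()


class _Manifest:
    """Stage ledger; paths are stored relative to the output directory so
    identical runs in different locations produce identical bytes."""

    def __init__(self, outdir: str):
        self.outdir = outdir
        self.path = os.path.join(outdir, "manifest.json")
        self.data: dict[str, Any] = {}
        if os.path.exists(self.path):
            with open(self.path) as fh:
                self.data = json.load(fh)

    def _rel(self, paths: list[str]) -> list[str]:
        return [os.path.relpath(p, self.outdir) for p in paths]

    def fresh(self, stage: str, key: str, outputs: list[str]) -> bool:
        rec = self.data.get(stage)
        rel = self._rel(outputs)
        return bool(rec and rec.get("key") == key
                    and rec.get("outputs") == rel
                    and all(os.path.exists(os.path.join(self.outdir, p))
                            for p in rel))

    def record(self, stage: str, key: str, params: Any, outputs: list[str]) -> None:
        self.data[stage] = {"key": key, "params": params,
                            "outputs": self._rel(outputs)}
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Execute every stage; returns the manifest data.

    A stage failure propagates after completed outputs are preserved.
    """
    outdir = config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    manifest = _Manifest(outdir)
    params = config["params"]

    # --- simulate ---------------------------------------------------------
    if config.get("simulate") is not None:
        sim_cfg = config["simulate"]
        simdir = os.path.join(outdir, "sim")
        key = _stage_key({"config": sim_cfg}, [])
        sim_manifest_path = os.path.join(simdir, "sim_manifest.json")
        if manifest.fresh("simulate", key, [sim_manifest_path]):
            log.info("simulate: up to date, skipped")
        else:
            log.info("simulate: generating synthetic study (seed=%d)", sim_cfg.seed)
            sim_manifest = synthetic.simulate_study(sim_cfg, simdir)
            with open(sim_manifest_path, "w") as fh:
                json.dump(sim_manifest, fh, indent=1, sort_keys=True)
            manifest.record("simulate", key, {"seed": sim_cfg.seed},
                            [sim_manifest_path])
        with open(sim_manifest_path) as fh:
            sim_manifest = json.load(fh)
        config = dict(config)
        config["genome"] = os.path.join(simdir, sim_manifest["genome_fasta"])
        config["genes"] = os.path.join(simdir, sim_manifest["gene_gff3"])
        config["tes"] = os.path.join(simdir, sim_manifest["te_gff3"])
        config["expression"] = os.path.join(simdir, sim_manifest["expression"])
        config["samples"] = {
            sid: {"lambda": os.path.join(simdir, spec["lambda"]),
                  "replicates": [os.path.join(simdir, p)
                                 for p in spec["replicates"]]}
            for sid, spec in sim_manifest["samples"].items()}

    sequences = mio.read_fasta(config["genome"])
    chrom_sizes = {c: len(s) for c, s in sequences.items()}
    genes, gene_parts = mio.read_gene_gff3(config["genes"])
    tes = mio.read_te_gff3(config["tes"])
    features = mio.derive_features(genes, gene_parts, tes, chrom_sizes,
                                   flank=params["flank"])

    # --- call -------------------------------------------------------------
    sample_calls: dict[str, pd.DataFrame] = {}
    sample_pooled: dict[str, pd.DataFrame] = {}
    conv_rows = []
    for sid, spec in config["samples"].items():
        inputs = [spec["lambda"]] + spec["replicates"]
        key = _stage_key({"stage": "call", "params": params}, inputs)
        out_path = os.path.join(outdir, f"calls_{sid}.tsv")
        conv_path = os.path.join(outdir, f"conversion_{sid}.json")
        replicates = [mio.read_calls(p) for p in spec["replicates"]]
        pooled = mio.pool_replicates(replicates)
        sample_pooled[sid] = pooled
        if manifest.fresh(f"call:{sid}", key, [out_path, conv_path]):
            log.info("call %s: up to date, skipped", sid)
            df = pd.read_csv(out_path, sep="\t")
            df["pos"] -= 1
            sample_calls[sid] = df
            continue
        conv = calling.estimate_conversion(mio.read_calls(spec["lambda"]), sid)
        log.info("call %s: conversion rate %.4f%%", sid,
                 100 * conv.conversion_rate)
        called = calling.call_sites(pooled, conv.non_conversion_rate,
                                    q_threshold=params["q_threshold"],
                                    min_coverage=params["min_coverage"])
        out = called.copy()
        out["pos"] += 1
        out.to_csv(out_path, sep="\t", index=False)
        with open(conv_path, "w") as fh:
            json.dump({"sample_id": sid,
                       "converted_reads": conv.converted_reads,
                       "total_reads": conv.total_reads,
                       "conversion_rate": conv.conversion_rate}, fh, indent=1)
        conv_rows.append(conv)
        manifest.record(f"call:{sid}", key, params, [out_path, conv_path])
        sample_calls[sid] = called

    # --- dmr --------------------------------------------------------------
    dmgs_by_comparison: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in config["comparisons"]:
        cmp_name = f"{a}_vs_{b}"
        inputs = (config["samples"][a]["replicates"]
                  + config["samples"][b]["replicates"])
        key = _stage_key({"stage": "dmr", "params": params}, inputs)
        dmr_path = os.path.join(outdir, f"dmrs_{cmp_name}.tsv")
        bed_path = os.path.join(outdir, f"dmrs_{cmp_name}.bed")
        dmg_path = os.path.join(outdir, f"dmgs_{cmp_name}.tsv")
        if manifest.fresh(f"dmr:{cmp_name}", key, [dmr_path, bed_path, dmg_path]):
            log.info("dmr %s: up to date, skipped", cmp_name)
            dmgs_by_comparison[(a, b)] = pd.read_csv(dmg_path, sep="\t")
            continue
        all_dmrs = []
        for ctx in params["contexts"]:
            wa = windows.build_windows(
                [mio.read_calls(p) for p in config["samples"][a]["replicates"]],
                chrom_sizes, ctx, params["window"], params["step"],
                params["min_coverage"])
            wb = windows.build_windows(
                [mio.read_calls(p) for p in config["samples"][b]["replicates"]],
                chrom_sizes, ctx, params["window"], params["step"],
                params["min_coverage"])
            dmrs = windows.call_dmrs(wa, wb, ctx,
                                     q_threshold=params["q_threshold"])
            log.info("dmr %s %s: %d DMRs", cmp_name, ctx, len(dmrs))
            all_dmrs.append(dmrs)
        non_empty = [d for d in all_dmrs if len(d)]
        dmrs = (pd.concat(non_empty, ignore_index=True) if non_empty
                else all_dmrs[0])
        dmrs.to_csv(dmr_path, sep="\t", index=False)
        if len(dmrs):
            bed = dmrs.assign(
                score=(-np.log10(dmrs["q_value"].clip(lower=1e-300))).round(3),
                name=dmrs["context"] + ":" + dmrs["direction"])
        else:
            bed = dmrs.assign(score=[], name=[])
        mio.write_bed6(bed, bed_path)
        dmgs = windows.annotate_dmgs(dmrs, genes, flank=params["flank"])
        dmgs.to_csv(dmg_path, sep="\t", index=False)
        dmgs_by_comparison[(a, b)] = dmgs
        manifest.record(f"dmr:{cmp_name}", key, params,
                        [dmr_path, bed_path, dmg_path])

    # --- profile ----------------------------------------------------------
    for sid in config["samples"]:
        key = _stage_key({"stage": "profile", "params": params},
                         config["samples"][sid]["replicates"])
        paths = {name: os.path.join(outdir, f"{name}_{sid}.tsv")
                 for name in ("feature_levels", "te_levels", "histogram",
                              "metaprofile", "density", "summary")}
        prop_path = os.path.join(outdir, f"context_proportions_{sid}.json")
        outputs = sorted(paths.values()) + [prop_path]
        if manifest.fresh(f"profile:{sid}", key, outputs):
            log.info("profile %s: up to date, skipped", sid)
            continue
        pooled = sample_pooled[sid]
        calls = sample_calls[sid]
        profiles.feature_levels(pooled, features,
                                params["min_coverage"]).to_csv(
            paths["feature_levels"], sep="\t", index=False)
        profiles.feature_levels(
            pooled, features[features["kind"].str.startswith(("TE", "te_"))],
            params["min_coverage"], by_te_class=True).to_csv(
            paths["te_levels"], sep="\t", index=False)
        pd.concat([profiles.level_histogram(pooled, ctx, params["min_coverage"])
                   for ctx in mio.CONTEXTS], ignore_index=True).to_csv(
            paths["histogram"], sep="\t", index=False)
        pd.concat([profiles.metaprofile(
            pooled, genes.assign(kind="gene_body"), ctx,
            params["body_bins"], params["flank"], params["flank_bin"],
            params["min_coverage"]) for ctx in mio.CONTEXTS],
            ignore_index=True).to_csv(paths["metaprofile"], sep="\t", index=False)
        windows.chromosome_density(calls, params["density_bin"],
                                   chrom_sizes).to_csv(
            paths["density"], sep="\t", index=False)
        profiles.genome_summary(calls).to_csv(paths["summary"], sep="\t",
                                              index=False)
        with open(prop_path, "w") as fh:
            json.dump(profiles.context_proportions(calls), fh, indent=1,
                      sort_keys=True)
        manifest.record(f"profile:{sid}", key, params, outputs)

    # --- integrate --------------------------------------------------------
    expression = pd.read_csv(config["expression"], sep="\t")
    for sid in config["samples"]:
        key = _stage_key({"stage": "integrate", "params": params},
                         config["samples"][sid]["replicates"]
                         + [config["expression"]])
        gm_path = os.path.join(outdir, f"gene_methylation_{sid}.tsv")
        strat_path = os.path.join(outdir, f"stratified_{sid}.tsv")
        corr_path = os.path.join(outdir, f"correlation_{sid}.tsv")
        outputs = [gm_path, strat_path, corr_path]
        if manifest.fresh(f"integrate:{sid}", key, outputs):
            log.info("integrate %s: up to date, skipped", sid)
            continue
        expr_s = integration.bin_expression(
            expression[expression["sample"] == sid])
        gm = integration.gene_methylation(sample_pooled[sid], features,
                                          params["min_coverage"])
        gm.to_csv(gm_path, sep="\t", index=False)
        integration.stratified_levels(gm, expr_s).to_csv(strat_path, sep="\t",
                                                         index=False)
        corr_rows = []
        for region in integration.GENE_REGIONS:
            for ctx in mio.CONTEXTS:
                try:
                    rho, p = integration.methylation_expression_correlation(
                        gm, expr_s, region, ctx)
                except ValueError:
                    rho, p = float("nan"), float("nan")
                corr_rows.append((sid, region, ctx, rho, p))
        pd.DataFrame(corr_rows, columns=["sample", "region", "context",
                                         "rho", "p_value"]).to_csv(
            corr_path, sep="\t", index=False)
        manifest.record(f"integrate:{sid}", key, params, outputs)

    for (a, b), dmgs in dmgs_by_comparison.items():
        cmp_name = f"{a}_vs_{b}"
        key = _stage_key({"stage": "venn", "params": params},
                         [config["expression"]])
        venn_path = os.path.join(outdir, f"venn_{cmp_name}.json")
        common_path = os.path.join(outdir, f"common_genes_{cmp_name}.tsv")
        if manifest.fresh(f"venn:{cmp_name}", key, [venn_path, common_path]):
            continue
        degs = integration.call_degs_fold_change(
            expression, a, b, params["deg_min_abs_log2fc"])
        common, counts = integration.intersect_dmg_deg(dmgs, degs)
        common.to_csv(common_path, sep="\t", index=False)
        with open(venn_path, "w") as fh:
            json.dump({"comparison": cmp_name, "n_dmgs": int(len(dmgs)),
                       "n_degs": int(len(degs)), **counts}, fh, indent=1,
                      sort_keys=True)
        manifest.record(f"venn:{cmp_name}", key, params,
                        [venn_path, common_path])

    return manifest.data
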