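"""End-to-end orchestration: simulate/load -> QC -> clock -> EWAS -> enrichment.

A single YAML/dict config drives the run; every artifact is written once
into the output directory and listed in a run manifest together with the
seed, a hash of the config, and summary metrics, so a rerun with the same
config reproduces byte-identical statistics tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import AgeTransformSpec, fit_clock, loocv_evaluate
from .datamodel import (
    align_dataset,
    load_beta_matrix,
    load_manifest,
    load_sample_sheet,
    read_gmt,
    write_beta_matrix,
    write_manifest,
    write_sample_sheet,
)
from .enrichment import enrich
from .ewas import ewas_age, group_ewas, rank_hits
from .qc import qc_report
from .simulate import (
    SimulationConfig,
    SpeciesSpec,
    generate_gene_sets,
    generate_dataset,
)

logger = logging.getLogger(__name__)


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def simulation_config_from_dict(block: Mapping, seed: int) -> SimulationConfig:
    """Build a SimulationConfig from a plain config block (YAML-friendly)."""
    kwargs = dict(block)
    species = kwargs.pop("species_specs", None)
    if species is not None:
        specs = []
        for sp in species:
            sp = dict(sp)
            stocks = tuple(tuple(x) for x in sp.pop("stocks", ()))
            specs.append(SpeciesSpec(stocks=stocks, **sp))
        kwargs["species_specs"] = tuple(specs)
    for tuple_key in ("age_range", "hierarchy_sds"):
        if tuple_key in kwargs:
            kwargs[tuple_key] = tuple(kwargs[tuple_key])
    kwargs.setdefault("seed", seed)
    return SimulationConfig(**kwargs)


def _load_inputs(block: Mapping):
    beta = load_beta_matrix(block["beta"], dialect=block.get("dialect", "tsv"))
    samples = load_sample_sheet(block["samples"])
    manifest = load_manifest(block["manifest"]) if block.get("manifest") else []
    return align_dataset(beta, samples, manifest, keep_unmapped=True)


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages in dependency order; returns the run manifest.

    ``config`` is a dict or a path to a YAML file with optional blocks
    ``simulate`` or ``inputs`` (exactly one required), ``qc``, ``clock``,
    ``ewas``, ``group_ewas`` and ``enrichment``, plus a top-level ``seed``
    and ``out_dir``.  Stage failures abort with the stage name.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "peroclock_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "artifacts": {},
        "metrics": {},
        "stages": [],
    }

    def _stage(name: str):
        manifest["stages"].append({"stage": name, "start": time.time()})
        logger.info("stage %s", name)

    def _done(**metrics):
        entry = manifest["stages"][-1]
        entry["seconds"] = round(time.time() - entry.pop("start"), 3)
        manifest["metrics"].update(metrics)

    truth = None
    try:
        if "simulate" in config:
            _stage("simulate")
            sim_config = simulation_config_from_dict(config["simulate"], seed)
            dataset, truth = generate_dataset(sim_config)
            write_beta_matrix(dataset.beta, out / "beta.tsv")
            write_sample_sheet(dataset.samples, out / "samples.csv")
            write_manifest(dataset.manifest, out / "manifest.tsv")
            truth.to_json(out / "ground_truth.json", include_baselines=False)
            manifest["artifacts"].update(
                beta=str(out / "beta.tsv"), samples=str(out / "samples.csv"),
                probe_manifest=str(out / "manifest.tsv"),
                ground_truth=str(out / "ground_truth.json"),
            )
            _done(n_samples=dataset.n_samples, n_cpgs=dataset.n_cpgs)
        elif "inputs" in config:
            _stage("load")
            dataset = _load_inputs(config["inputs"])
            _done(n_samples=dataset.n_samples, n_cpgs=dataset.n_cpgs)
        else:
            raise ValueError("config needs a 'simulate' or an 'inputs' block")

        qc_block = dict(config.get("qc", {}))
        remove_flagged = bool(qc_block.pop("remove_flagged", False))
        _stage("qc")
        report = qc_report(dataset, **qc_block)
        (out / "qc_report.json").write_text(json.dumps(report, indent=2))
        manifest["artifacts"]["qc_report"] = str(out / "qc_report.json")
        flagged = report["flagged"]
        if remove_flagged and flagged:
            keep = [s.sample_id for s in dataset.samples if s.sample_id not in set(flagged)]
            dataset = dataset.subset_samples(keep)
            logger.info("removed %d flagged samples; %d remain", len(flagged), len(keep))
        _done(n_flagged=len(flagged), n_samples_after_qc=dataset.n_samples)

        if "clock" in config:
            _stage("clock")
            clock_block = dict(config["clock"])
            target = clock_block.pop("target", "chronological")
            tissue = clock_block.pop("tissue", "all")
            alpha = float(clock_block.pop("alpha", 0.5))
            folds = int(clock_block.pop("folds", 10))
            do_loocv = bool(clock_block.pop("loocv", True))
            clock_data = dataset
            if tissue != "all":
                keep = [s.sample_id for s in dataset.samples if s.tissue == tissue]
                clock_data = dataset.subset_samples(keep)
            transform = (
                AgeTransformSpec(kind="relative")
                if target == "relative"
                else AgeTransformSpec(kind="log_linear")
            )
            model = fit_clock(clock_data, transform, alpha=alpha, n_folds=folds, seed=seed)
            model.metadata["config_hash"] = manifest["config_hash"]
            model.to_json(out / "clock.json")
            manifest["artifacts"]["clock"] = str(out / "clock.json")
            metrics = {"clock_n_nonzero": model.n_nonzero, "clock_lambda": model.lambda_}
            if do_loocv:
                cv = loocv_evaluate(clock_data, transform, alpha=alpha, seed=seed, n_folds=folds)
                cv.predictions.to_csv(out / "clock_loocv.csv", index=False)
                manifest["artifacts"]["clock_loocv"] = str(out / "clock_loocv.csv")
                metrics.update(
                    clock_loocv_r=cv.pearson_r,
                    clock_loocv_mae_years=cv.median_abs_error_years,
                )
            _done(**metrics)

        age_stats = None
        if "ewas" in config:
            _stage("ewas")
            ewas_block = dict(config["ewas"])
            result = ewas_age(
                dataset,
                stratify=ewas_block.get("stratify", "tissue"),
                stratum_filter=ewas_block.get("stratum_filter"),
                min_n=int(ewas_block.get("min_n", 4)),
            )
            wide = result.to_frame()
            wide.to_csv(out / "ewas.tsv", sep="\t", float_format="%.10g")
            manifest["artifacts"]["ewas"] = str(out / "ewas.tsv")
            age_stats = result
            _done(ewas_strata=len(result.per_stratum))

        group_stats = None
        if "group_ewas" in config:
            _stage("group_ewas")
            gb = dict(config["group_ewas"])
            group_stats = group_ewas(
                dataset,
                group_field=gb["group_field"],
                positive_level=gb["positive_level"],
            )
            group_stats.table.to_csv(out / "group_ewas.tsv", sep="\t", float_format="%.10g")
            manifest["artifacts"]["group_ewas"] = str(out / "group_ewas.tsv")
            p_sig = float(gb.get("p_sig", 1e-4))
            hits = rank_hits(
                group_stats.table, dataset.manifest_frame, p_threshold=p_sig,
                top_k=int(gb.get("top_k", 15)),
            )
            _done(
                group_ewas_n_significant=sum(hits["n_significant"].values()),
                group_ewas_p_sig=p_sig,
            )

        if "enrichment" in config:
            _stage("enrichment")
            eb = dict(config["enrichment"])
            stats_table = (
                group_stats.table if group_stats is not None
                else next(iter(age_stats.per_stratum.values())) if age_stats is not None
                else None
            )
            if stats_table is None:
                raise ValueError("enrichment needs an ewas or group_ewas stage")
            if eb.get("gmt"):
                gene_sets = read_gmt(eb["gmt"])
            else:
                gene_names = sorted(dataset.manifest_frame["adjacent_gene"].unique())
                gene_sets = generate_gene_sets(gene_names, seed=seed)
            genes_table = eb.get("genes")
            if genes_table:
                genes = pd.read_csv(genes_table, sep="\t")
            else:
                from .simulate import generate_gene_annotation

                sim_block = config.get("simulate", {})
                n_cpg = int(sim_block.get("n_cpg", dataset.n_cpgs))
                genes = generate_gene_annotation(max(20, n_cpg // 5), seed=seed)
            results = enrich(
                stats_table, dataset.manifest_frame, genes, gene_sets,
                n_per_direction=int(eb.get("top", 500)),
            )
            for direction, table in results.items():
                path = out / f"enrich_{direction}.tsv"
                table.to_csv(path, sep="\t", float_format="%.10g")
                manifest["artifacts"][f"enrich_{direction}"] = str(path)
            _done(enrichment_directions=len(results))
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    manifest["artifacts"]["run_manifest"] = str(manifest_path)
    return manifest
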