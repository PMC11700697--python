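"""Orchestration of the full analysis: simulate -> process -> characterize
-> select -> classify, with stage-level resume and a machine-readable run
report.

A single master seed deterministically derives one sub-seed per stage
(``SeedSequence(master).generate_state``), so any stage re-run in isolation
with the same configuration reproduces its outputs byte-for-byte. Each
stage writes a small manifest carrying the stage seed, a hash of the
configuration block, and checksums of its outputs; on resume, a stage is
skipped when its manifest and outputs are intact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .classify import evaluate, make_classifier, stratified_kfold
from .config import RunConfig
from .dataset import SpectraSet
from .ga import GAConfig, run_ga, waveband_composition
from .spectral import ProcessingConfig, process_dataset
from .synth import GeneratorConfig, generate_dataset, load_dataset, save_dataset
from .unsupervised import (
    betweenness,
    hierarchical_partition,
    spearman_matrix,
    threshold_network,
    walktrap_communities,
    write_network,
)

log = logging.getLogger("pasa")

STAGES = ("simulate", "process", "characterize", "select", "classify")


def stage_seeds(master_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES)) % (2**31)
    return {stage: int(s) for stage, s in zip(STAGES, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(block) -> str:
    payload = json.dumps(asdict(block), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _Stage:
    """Bookkeeping for one resumable pipeline stage."""

    def __init__(self, outdir: Path, name: str, config_hash: str, seed: int):
        self.dir = outdir
        self.name = name
        self.manifest_path = outdir / f"{name}.manifest.json"
        self.identity = {"stage": name, "config_hash": config_hash, "seed": seed}

    def is_complete(self, outputs: list[str]) -> bool:
        if not self.manifest_path.exists():
            return False
        manifest = json.loads(self.manifest_path.read_text())
        if {k: manifest.get(k) for k in self.identity} != self.identity:
            return False
        for rel in outputs:
            path = self.dir / rel
            if not path.exists() or manifest["checksums"].get(rel) != _sha256(path):
                return False
        return True

    def finalize(self, outputs: list[str]) -> dict:
        manifest = dict(self.identity)
        manifest["checksums"] = {rel: _sha256(self.dir / rel) for rel in outputs}
        self.manifest_path.write_text(json.dumps(manifest, indent=2))
        return manifest


def _generator_config(cfg: RunConfig) -> GeneratorConfig:
    g = cfg.generator
    return GeneratorConfig(
        trace_length=g.trace_length,
        sampling_rate_hz=g.sampling_rate_hz,
        pulse_center_mhz=g.pulse_center_mhz,
        pulse_fractional_bw=g.pulse_fractional_bw,
        noise_sd=g.noise_sd,
        energy_jitter_sigma=g.energy_jitter_sigma,
        blackbody_amplitude=g.blackbody_amplitude,
        apply_hydrophone=g.apply_hydrophone,
        normal=g.normal,
        cancer=g.cancer,
    )


def _processing_config(cfg: RunConfig) -> ProcessingConfig:
    p = cfg.processing
    return ProcessingConfig(
        highpass_cutoff_hz=p.highpass_cutoff_hz,
        f0_mhz=p.f0_mhz,
        f1_mhz=p.f1_mhz,
        welch_window_fraction=p.welch_window_fraction,
        welch_overlap=p.welch_overlap,
    )


def run_pipeline(cfg: RunConfig, outdir: str | Path, resume: bool = True) -> dict:
    """Execute all five stages in order; returns the aggregated run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    report: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "stage_seeds": seeds,
        "stages": {},
        "headline": {},
    }

    # --- simulate ---------------------------------------------------------
    stage = _Stage(outdir, "simulate", _config_hash(cfg.generator), seeds["simulate"])
    outputs = ["raw.npz", "samples.csv"]
    if not (resume and stage.is_complete(outputs)):
        log.info("stage simulate: generating %d + %d samples",
                 cfg.generator.n_normal, cfg.generator.n_cancer)
        records = generate_dataset(
            cfg.generator.n_normal,
            cfg.generator.n_cancer,
            _generator_config(cfg),
            seed=seeds["simulate"],
        )
        save_dataset(records, outdir / "raw.npz", outdir / "samples.csv")
        stage.finalize(outputs)
    else:
        log.info("stage simulate: outputs intact, skipping")
        records = None
    report["stages"]["simulate"] = json.loads((outdir / "simulate.manifest.json").read_text())

    # --- process ----------------------------------------------------------
    stage = _Stage(outdir, "process", _config_hash(cfg.processing), seeds["process"])
    outputs = ["spectra.csv"]
    if not (resume and stage.is_complete(outputs)):
        if records is None:
            records = load_dataset(outdir / "raw.npz", outdir / "samples.csv")
        log.info("stage process: raw traces -> APSD spectra")
        spectra = process_dataset(records, _processing_config(cfg))
        spectra.to_csv(outdir / "spectra.csv")
        stage.finalize(outputs)
    else:
        log.info("stage process: outputs intact, skipping")
    spectra = SpectraSet.from_csv(outdir / "spectra.csv")
    report["stages"]["process"] = json.loads((outdir / "process.manifest.json").read_text())

    # --- characterize -----------------------------------------------------
    stage = _Stage(outdir, "characterize", _config_hash(cfg.unsupervised), seeds["characterize"])
    outputs = ["partition.csv", "correlation.csv", "network_edges.csv", "network_nodes.csv"]
    if not (resume and stage.is_complete(outputs)):
        log.info("stage characterize: waveband partition + correlation network")
        partition = hierarchical_partition(
            spectra.values,
            spectra.wavelengths,
            k=cfg.unsupervised.k_clusters,
            method=cfg.unsupervised.linkage,
        )
        partition.to_csv(outdir / "partition.csv")
        class_set = spectra.subset_labels(cfg.unsupervised.network_class)
        cm = spearman_matrix(class_set.values)
        np.savetxt(outdir / "correlation.csv", cm, delimiter=",")
        graph = threshold_network(cm, spectra.wavelengths, cfg.unsupervised.tau)
        communities = walktrap_communities(graph, cfg.unsupervised.walktrap_steps)
        centrality = betweenness(graph)
        write_network(
            graph, communities, centrality,
            outdir / "network_edges.csv", outdir / "network_nodes.csv",
        )
        stage.finalize(outputs)
    else:
        log.info("stage characterize: outputs intact, skipping")
    report["stages"]["characterize"] = json.loads(
        (outdir / "characterize.manifest.json").read_text()
    )

    # --- select -----------------------------------------------------------
    stage = _Stage(outdir, "select", _config_hash(cfg.ga), seeds["select"])
    outputs = ["ga_models.csv", "ga_summary.json"]
    if not (resume and stage.is_complete(outputs)):
        log.info("stage select: GA over %d runs x %d generations",
                 cfg.ga.runs, cfg.ga.generations)
        ga_cfg = GAConfig(
            population_size=cfg.ga.population_size,
            generations=cfg.ga.generations,
            runs=cfg.ga.runs,
            init_prob=cfg.ga.init_prob,
            mutation_rate=cfg.ga.mutation_rate,
            cv_folds=cfg.ga.cv_folds,
            seed=seeds["select"],
        )
        collection = run_ga(
            spectra.values, spectra.binary_response(), ga_cfg, spectra.wavelengths
        )
        collection.to_csv(outdir / "ga_models.csv")
        collection.to_json(outdir / "ga_summary.json")
        stage.finalize(outputs)
    else:
        log.info("stage select: outputs intact, skipping")
    ga_summary = json.loads((outdir / "ga_summary.json").read_text())
    report["stages"]["select"] = json.loads((outdir / "select.manifest.json").read_text())

    # --- classify ---------------------------------------------------------
    stage = _Stage(outdir, "classify", _config_hash(cfg.classification), seeds["classify"])
    outputs = ["reports.json", "scores.csv"]
    if not (resume and stage.is_complete(outputs)):
        log.info("stage classify: %s on full-range and feature spectra",
                 "/".join(cfg.classification.models))
        reports, score_rows = _run_classifiers(cfg, spectra, ga_summary, seeds["classify"])
        (outdir / "reports.json").write_text(json.dumps(reports, indent=2))
        _write_scores(outdir / "scores.csv", spectra, score_rows)
        stage.finalize(outputs)
    else:
        log.info("stage classify: outputs intact, skipping")
    reports = json.loads((outdir / "reports.json").read_text())
    report["stages"]["classify"] = json.loads((outdir / "classify.manifest.json").read_text())

    report["headline"] = {
        "n_samples": spectra.n_samples,
        "n_wavelengths": len(spectra.wavelengths),
        "ga_best_rmsecv": ga_summary["best_rmsecv"],
        "ga_best_wavelengths_nm": ga_summary["best_wavelengths_nm"],
        "classifiers": {
            key: rep["pooled_testing"] for key, rep in reports.items()
        },
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report


def _run_classifiers(cfg: RunConfig, spectra: SpectraSet, ga_summary: dict, seed: int):
    y = spectra.binary_response().astype(int)
    plan = stratified_kfold(y, k=cfg.classification.folds, seed=seed)
    feature_wl = np.array(ga_summary["best_wavelengths_nm"])
    feature_set = spectra.select_wavelengths(feature_wl)
    grid_exponents = np.linspace(
        cfg.classification.svm_grid_min_exp,
        cfg.classification.svm_grid_max_exp,
        cfg.classification.svm_grid_points,
    )
    reports: dict = {}
    score_rows: dict = {}
    for feature_tag, data in (("full_range", spectra), ("feature", feature_set)):
        for model_name in cfg.classification.models:
            kwargs = {}
            if model_name == "knn":
                kwargs["k"] = cfg.classification.knn_k
            if model_name == "svmda":
                kwargs["grid_exponents"] = grid_exponents
            clf = make_classifier(model_name, seed=seed, **kwargs)
            rep = evaluate(data.values, y, clf, plan)
            key = f"{model_name}_{feature_tag}"
            reports[key] = rep.to_dict()
            score_rows[key] = rep.test_scores
    return reports, score_rows


def _write_scores(path: Path, spectra: SpectraSet, score_rows: dict) -> None:
    import pandas as pd

    df = pd.DataFrame({"id": spectra.ids, "label": spectra.labels})
    for key, scores in score_rows.items():
        df[f"score_{key}"] = scores
    df.to_csv(path, index=False)
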