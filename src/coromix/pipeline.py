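"""End-to-end pipeline: simulate -> spectrograms -> train/evaluate -> report.

Every stage draws its seed from the master seed via the stage-name hash in
:class:`~coromix.config.PipelineConfig`, logs its timing, and persists its
artifacts under the configured output directory, so a run is reproducible
from the effective-config echo written next to the report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .ecg_io import read_record
from .evaluation import AblationConfig, run_ablation
from .spectrogram import record_to_tensor
from .synthetic import DatasetManifest, generate_dataset, load_manifest

log = logging.getLogger("coromix")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage %s: FAILED after %.1fs", name, time.time() - t0)
                raise
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return inner

    return wrap


@_stage("simulate")
def _simulate(config: PipelineConfig, out_dir: Path) -> DatasetManifest:
    gen = config.generator.build(seed=config.stage_seed("simulate"))
    log.info("generating %d records", sum(gen.per_class_counts))
    return generate_dataset(gen, out_dir / "data")


@_stage("spectrogram")
def manifest_to_tensors(
    manifest: DatasetManifest, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Read every record in the manifest and stack its 12 lead images."""
    params = config.spectrogram.build()
    tensors = []
    for path in manifest.frame["path"]:
        record = read_record(path)
        tensors.append(record_to_tensor(record, params).astype(np.float32))
    return np.stack(tensors), manifest.labels


def _ablation_config(config: PipelineConfig, arms=None, wsse_k=None) -> AblationConfig:
    from dataclasses import replace

    # inside cross-validation the whole training fold is used for fitting:
    # the validation split only feeds monitoring curves and nothing stops early
    train = replace(config.train.build(seed=config.stage_seed("train")),
                    validation_fraction=0.0)
    return AblationConfig(
        model=config.model.build(),
        train=train,
        relieff=config.relieff.build(),
        svm=config.wsse.svm_options(),
        folds=config.evaluation.folds,
        top_q=config.evaluation.top_q,
        wsse_k=config.wsse.k if wsse_k is None else wsse_k,
        vote_mode=config.wsse.vote_mode,
        seed=config.stage_seed("evaluate"),
        arms=tuple(arms or config.evaluation.arms),
    )


@_stage("evaluate")
def _evaluate(X, labels, config: PipelineConfig) -> dict:
    return run_ablation(X, labels, _ablation_config(config))


def run_pipeline(config: PipelineConfig, manifest: DatasetManifest | None = None) -> dict:
    """Run the full pipeline; returns the report (also written to disk).

    If ``manifest`` is given, simulation is skipped and those records are
    used instead.  With ``config.self_check`` the degenerate k=1 ensemble is
    re-run and asserted equal to the plain-SVM arm.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "effective_config.yaml").write_text(config.to_yaml())

    if manifest is None:
        manifest = _simulate(config, out_dir)
    X, labels = manifest_to_tensors(manifest, config)
    report = _evaluate(X, labels, config)
    report["config"] = json.loads(config.model_dump_json())

    if config.self_check:
        log.info("self-check: k=1 ensemble must equal the plain SVM arm")
        check = run_ablation(X, labels, _ablation_config(config, arms=("b", "d"),
                                                         wsse_k=1))
        cm_b = check["arms"]["b"]["confusion_matrix"]
        cm_d = check["arms"]["d"]["confusion_matrix"]
        report["self_check_passed"] = cm_b == cm_d
        if not report["self_check_passed"]:
            raise AssertionError("self-check failed: k=1 WSSE != single SVM")

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1))
    from .evaluation import write_confusion_csvs

    write_confusion_csvs(report, out_dir)
    log.info("report written to %s", report_path)
    return report


def load_or_generate(config: PipelineConfig) -> DatasetManifest:
    """Reuse an existing dataset under ``out_dir`` or generate a fresh one."""
    manifest_path = Path(config.out_dir) / "data" / "manifest.csv"
    if manifest_path.exists():
        return load_manifest(manifest_path)
    return _simulate(config, Path(config.out_dir))
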