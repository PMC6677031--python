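"""End-to-end pipeline: simulate -> kinematics -> classify -> spect -> fc
-> report, as one reproducible run.

Each stage writes CSV outputs plus a JSON manifest (seed, version, output
hashes, hash of the previous stage's manifest), so a run directory is a
verifiable, re-derivable record.  Reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import io as tio
from .classify import classify_cohort
from .fc import GroupContrastModel, bandpass_filter, compute_fc_matrix
from .kinematics import summarize_cohort
from .simulate import Cohort, CohortConfig, generate_cohort
from .report import build_report

logger = logging.getLogger("tapmark")

STAGES = ("simulate", "kinematics", "classify", "spect", "fc", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple = STAGES
    cutoff_hz: float = 20.0
    min_cycle_s: float = 0.1
    min_amplitude_mm: float = 5.0
    band: tuple = (0.008, 0.09)
    fdr_scope: str = "analysis"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        # stage order is fixed; configs only toggle membership
        self.stages = tuple(s for s in STAGES if s in self.stages)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_config = replace(config.cohort, seed=config.seed)
    prev_hash: str | None = None

    def finish_stage(stage: str, outputs: list) -> None:
        nonlocal prev_hash
        manifest = tio.write_manifest(
            out / stage / "manifest.json", stage, config.seed, outputs, previous=prev_hash
        )
        prev_hash = tio.sha256_file(manifest)
        logger.info("stage %s: %d output(s)", stage, len(outputs))

    cohort = generate_cohort(cohort_config)
    if "simulate" in config.stages:
        outputs = write_cohort(cohort, out / "simulate")
        finish_stage("simulate", outputs)

    tap_summaries = classification = uptake = contrasts = None
    fc_results = None

    if "kinematics" in config.stages:
        stage_dir = out / "kinematics"
        cycles, tap_summaries = summarize_cohort(
            cohort.waveforms.values(),
            cutoff=config.cutoff_hz,
            min_cycle_s=config.min_cycle_s,
            min_amplitude_mm=config.min_amplitude_mm,
        )
        outputs = [
            tio.write_table(cycles, stage_dir / "cycles.csv"),
            tio.write_table(tap_summaries, stage_dir / "tap_summaries.csv"),
        ]
        finish_stage("kinematics", outputs)

    if "classify" in config.stages:
        if tap_summaries is None:
            raise ValueError("classify stage requires the kinematics stage")
        stage_dir = out / "classify"
        classification, normative = classify_cohort(tap_summaries, cohort.subjects)
        stage_dir.mkdir(parents=True, exist_ok=True)
        model_path = stage_dir / "normative_model.json"
        normative.to_json(model_path)
        outputs = [tio.write_table(classification, stage_dir / "classification.csv"), model_path]
        finish_stage("classify", outputs)

    if "spect" in config.stages:
        from .spect import uptake_from_counts

        stage_dir = out / "spect"
        uptake = uptake_from_counts(cohort.voi_counts)
        outputs = [tio.write_table(uptake, stage_dir / "uptake.csv")]
        finish_stage("spect", outputs)

    if "fc" in config.stages:
        stage_dir = out / "fc"
        fc_results = {}
        z_rows = []
        for sid, series in cohort.roi_timeseries.items():
            filtered = bandpass_filter(series, band=config.band)
            res = compute_fc_matrix(filtered)
            fc_results[sid] = res
            tri = res.upper_triangle()
            tri.insert(0, "subject_id", sid)
            z_rows.append(tri)
        contrast_results = GroupContrastModel(fc_results, cohort.subjects).fit(
            fdr_scope=config.fdr_scope
        )
        contrasts = contrast_results.table
        outputs = [
            tio.write_table(pd.concat(z_rows, ignore_index=True), stage_dir / "z_matrices.csv"),
            tio.write_table(contrasts, stage_dir / "contrasts.csv"),
        ]
        finish_stage("fc", outputs)

    if "report" in config.stages:
        stage_dir = out / "report"
        tables = build_report(
            cohort.subjects,
            tap_summaries=tap_summaries,
            classification=classification,
            uptake=uptake,
            fc_contrasts=contrasts,
            fc_results=fc_results,
        )
        outputs = [
            tio.write_table(tbl, stage_dir / f"{name}.csv") for name, tbl in tables.items()
        ]
        summary = {
            "n_subjects": int(len(cohort.subjects)),
            "n_per_group": {
                g: int(n) for g, n in cohort.subjects["group"].value_counts().items()
            },
            "tables": sorted(tables),
        }
        if classification is not None and len(classification):
            summary["n_mmi"] = int(classification["is_mmi"].sum())
            summary["n_rbd_classified"] = int(len(classification))
        summary_path = stage_dir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        outputs.append(summary_path)
        finish_stage("report", outputs)

    return out


def write_cohort(cohort: Cohort, directory) -> list:
    """Write a cohort bundle to ``directory`` as CSV/JSON files."""
    directory = Path(directory)
    outputs = [tio.write_table(cohort.subjects, directory / "subjects.csv")]
    for rec in cohort.waveforms.values():
        outputs.append(tio.write_waveform(rec, directory / "waveforms"))
    outputs.append(tio.write_table(cohort.voi_counts, directory / "voi_counts.csv"))
    for series in cohort.roi_timeseries.values():
        outputs.append(tio.write_roi_timeseries(series, directory / "roi_timeseries"))
    config_path = directory / "cohort_config.json"
    cohort.config.to_json(config_path)
    outputs.append(config_path)
    return outputs


def make_fixtures(scale: str = "tiny", seed: int = 0) -> CohortConfig:
    """Pre-baked cohort configurations.

    ``tiny``: 3 subjects per group, 5-s waveforms, 40 volumes — runs the
    full pipeline in seconds (used by the test suite).
    ``paper-like``: 20/15/8 subjects, 15-s waveforms, 180 volumes.
    """
    if scale == "tiny":
        return CohortConfig(
            n_per_group={"HC": 3, "RBD-N": 3, "RBD-MMI": 3},
            seed=seed,
            tap_duration=5.0,
            n_volumes=40,
        )
    if scale == "paper-like":
        return CohortConfig(seed=seed)
    raise ValueError(f"unknown fixture scale {scale!r}; expected 'tiny' or 'paper-like'")
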