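"""Configured, seed-reproducible end-to-end pipeline.

Stages: simulate (or load) -> process into a bucket matrix -> Monte-Carlo
cross-validated classification per contrast -> univariate screening per
contrast. Every random stage derives its seed deterministically from the
master seed, and the run report embeds the config snapshot so a run can be
reproduced from its own output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .chemometrics import (SampleAnnotation, annotations_from_dataframe,
                           monte_carlo_cv)
from .simulate import CohortDesign, make_metabolite_library, simulate_cohort, write_cohort
from .spectra import (BucketMatrix, ProcessingParams, build_bucket_matrix,
                      read_spectral_matrix)
from .unistats import metabolite_table, parse_contrast, univariate_screen

log = logging.getLogger("ficollnmr")


class SimulationConfig(BaseModel):
    n_subjects_per_group: int = 20
    groups: tuple[str, str] = ("CRC", "LC")
    paired: bool = True
    effect_table: dict[str, dict[str, float]] = Field(default_factory=dict)
    anesthesia_decrease: float = 0.85
    subject_sd: float = 0.10
    noise_sd: float = 0.05
    n_metabolites: int = 20
    acquisition: str = "cpmg"
    ficoll_scale: float = 1.0
    axis_points: int = 16384


class ProcessingConfig(BaseModel):
    low: float = 0.20
    high: float = 10.00
    width: float = 0.02
    exclude: list[tuple[float, float]] = Field(default_factory=lambda: [(3.30, 6.00)])
    normalize: bool = True
    calibrate_to: float | None = None

    @field_validator("exclude")
    @classmethod
    def _check_ranges(cls, v):
        for low, high in v:
            if low >= high:
                raise ValueError(f"inverted exclusion range ({low}, {high})")
        return v


class ModelConfig(BaseModel):
    kind: str = "pls-ca"
    n_components: int | None = 2
    n_iterations: int = 500
    test_fraction: float = 0.1

    @field_validator("kind")
    @classmethod
    def _check_kind(cls, v):
        if v not in ("pls-ca", "mpls"):
            raise ValueError("model kind must be 'pls-ca' or 'mpls'")
        return v


class PipelineConfig(BaseModel):
    """Serializable pipeline configuration; YAML round trips exactly."""

    seed: int = 1
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    processing: ProcessingConfig = Field(default_factory=ProcessingConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    contrasts: list[str] = Field(default_factory=lambda: ["group:CRC,LC"])
    alpha: float = 0.05
    spectra_path: str | None = None      # load instead of simulating
    annotations_path: str | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"),
                                             sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def validate_design(annotations: Sequence[SampleAnnotation]) -> dict:
    """Summarize and sanity-check a cohort design table.

    Counts per group/timepoint/anesthetic, pairing completeness, and warnings
    naming subjects lacking a timepoint. Duplicate sample ids are an error.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("empty annotation table")
    ids = [a.sample_id for a in annotations]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample_id(s): {dupes}")
    per_subject: dict[str, set[str]] = {}
    for a in annotations:
        per_subject.setdefault(a.subject_id, set()).add(a.timepoint)
    incomplete = sorted(s for s, tps in per_subject.items()
                        if tps != {"pre", "post"})
    warnings = [f"subject {s!r} lacks a complete pre/post pair"
                for s in incomplete]

    def count(attr):
        out: dict[str, int] = {}
        for a in annotations:
            key = getattr(a, attr) or "(none)"
            out[key] = out.get(key, 0) + 1
        return out

    return {
        "n_samples": len(annotations),
        "n_subjects": len(per_subject),
        "per_group": count("group"),
        "per_timepoint": count("timepoint"),
        "per_anesthetic": count("anesthetic"),
        "pairing_complete": not incomplete,
        "warnings": warnings,
    }


def _design_from_config(cfg: PipelineConfig) -> CohortDesign:
    sim = cfg.simulation
    from .simulate import default_ppm_axis
    return CohortDesign(
        n_subjects_per_group=sim.n_subjects_per_group,
        groups=tuple(sim.groups), paired=sim.paired,
        effect_table=sim.effect_table,
        anesthesia_decrease=sim.anesthesia_decrease,
        subject_sd=sim.subject_sd, noise_sd=sim.noise_sd,
        n_metabolites=sim.n_metabolites, acquisition=sim.acquisition,
        ficoll_scale=sim.ficoll_scale,
        seed=stage_seed(cfg.seed, "simulate"),
        axis=default_ppm_axis(n_points=sim.axis_points))


def _subset_for_contrast(matrix: BucketMatrix,
                         annotations: Sequence[SampleAnnotation],
                         contrast: str):
    """Rows relevant to one contrast plus the labels/annotations to use."""
    kind, (a, b) = parse_contrast(contrast)
    anns = list(annotations)
    if kind == "paired":
        idx = list(range(len(anns)))
        return matrix.values, anns, "mpls", None
    attr = "group" if kind == "group" else "anesthetic"
    # group contrasts use pre-anesthesia samples unless the design is unpaired
    idx = [i for i, ann in enumerate(anns)
           if getattr(ann, attr) in (a, b)
           and (ann.timepoint == "pre" or attr == "anesthetic")]
    if attr == "anesthetic":
        idx = [i for i in idx if anns[i].timepoint == "post"]
    labels = np.array([getattr(anns[i], attr) for i in idx])
    return matrix.values[idx], labels, "pls-ca", [anns[i] for i in idx]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> process -> classify -> screen; return the RunReport.

    Raises the first stage error with stage context; writes JSON/CSV
    artifacts when ``config.out_dir`` is set.
    """
    report: dict = {
        "software": {"name": "ficollnmr", "version": __version__},
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        log.info("stage %s", name)
        return name

    try:
        stage = _stage("input")
        library = make_metabolite_library(config.simulation.n_metabolites,
                                          stage_seed(config.seed, "simulate"))
        if config.spectra_path:
            spectra = read_spectral_matrix(config.spectra_path,
                                           acquisition=config.simulation.acquisition)
            ann_df = pd.read_csv(config.annotations_path)
            annotations = annotations_from_dataframe(ann_df)
        else:
            design = _design_from_config(config)
            samples = simulate_cohort(design, library)
            spectra = [s.spectrum for s in samples]
            annotations = [s.annotation for s in samples]
            if out_dir:
                write_cohort(samples, out_dir / "cohort")
        report["stages"]["input"] = {"n_spectra": len(spectra),
                                     "n_points": int(spectra[0].ppm.size)}

        stage = _stage("validate")
        design_summary = validate_design(annotations)
        report["stages"]["validate"] = design_summary

        stage = _stage("process")
        params = ProcessingParams(
            low=config.processing.low, high=config.processing.high,
            width=config.processing.width,
            exclude=tuple(tuple(r) for r in config.processing.exclude),
            normalize=config.processing.normalize,
            calibrate_to=config.processing.calibrate_to)
        matrix = build_bucket_matrix(spectra, params)
        report["stages"]["process"] = {"n_samples": matrix.n_samples,
                                       "n_bins": matrix.n_bins}
        if out_dir:
            matrix.to_csv(out_dir / "buckets.csv")

        stage = _stage("classify")
        cv_reports = {}
        for contrast in config.contrasts:
            values, labels, kind, sub_ann = _subset_for_contrast(
                matrix, annotations, contrast)
            cv = monte_carlo_cv(
                values,
                labels if kind == "pls-ca" else annotations,
                model_kind=kind,
                n_iterations=config.model.n_iterations,
                test_fraction=config.model.test_fraction,
                seed=stage_seed(config.seed, f"cv:{contrast}"),
                n_components=config.model.n_components)
            cv_reports[contrast] = cv.to_dict()
        report["stages"]["classify"] = cv_reports

        stage = _stage("screen")
        table = metabolite_table(spectra, library)
        screens = {}
        for contrast in config.contrasts:
            kind, (a, b) = parse_contrast(contrast)
            if kind == "paired":
                sub = table
                sub_ann = annotations
            else:
                attr = "group" if kind == "group" else "anesthetic"
                tp = "pre" if attr == "group" else "post"
                keep = [ann.sample_id for ann in annotations
                        if getattr(ann, attr) in (a, b) and ann.timepoint == tp]
                sub = table.loc[keep]
                sub_ann = [ann for ann in annotations if ann.sample_id in set(keep)]
            res = univariate_screen(sub, sub_ann, contrast, alpha=config.alpha)
            screens[contrast] = res.to_dict(orient="records")
            if out_dir:
                safe = contrast.replace(":", "_").replace(",", "-")
                res.to_csv(out_dir / f"screen_{safe}.csv", index=False)
        report["stages"]["screen"] = screens
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    report["finished"] = datetime.now(timezone.utc).isoformat()
    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def comparable_report(report: dict) -> dict:
    """Report with volatile fields (timestamps) removed, for determinism checks."""
    out = {k: v for k, v in report.items() if k not in ("started", "finished")}
    return out
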