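"""Reproducible end-to-end pipeline: generate -> fit -> stratify -> diagnose
-> reliability -> report.

Every stage writes plain-text artifacts (CSV/JSON) into the output
directory and records a SHA-256 checksum in a run manifest; identical
configuration and seed give byte-identical outputs.  Timing and progress go
to stderr via logging, never to stdout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import day_distribution_check, summarize_demographics
from .diagnostics import residual_summary
from .reference import ReferenceCurveModel, Z_90, fit_crude_model
from .reliability import analyze_pairs
from .stratified import fit_stratified_model
from .synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_repeated_pairs,
    read_cohort_csv,
    write_cohort_csv,
)

logger = logging.getLogger("utaref")

ALL_STAGES = ("generate", "fit", "stratify", "diagnose", "reliability", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str | Path = "utaref_run"
    input_csv: str | Path | None = None  # if None, a cohort is generated
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    stages: tuple[str, ...] = ALL_STAGES
    trim_threshold: float = 3.0
    centile_ks: tuple[float, ...] = (-Z_90, 0.0, Z_90)
    n_pairs: int = 100
    pairs_between_sd: float = 0.55
    pairs_within_sd: float = 0.07
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {},
        "status": "incomplete",
    }
    outputs: dict[str, Path] = {}

    def register(name: str, path: Path) -> None:
        outputs[name] = path
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    stage = None
    try:
        cohort = None
        if "generate" in config.stages:
            stage = "generate"
            t0 = time.perf_counter()
            gen = dataclasses.replace(config.generator, seed=config.seed)
            cohort = generate_cohort(gen)
            path = outdir / "cohort.csv"
            write_cohort_csv(cohort, path)
            register("cohort", path)
            gen.to_file(outdir / "generator_config.json")
            register("generator_config", outdir / "generator_config.json")
            pairs = generate_repeated_pairs(
                config.n_pairs, config.pairs_between_sd, config.pairs_within_sd,
                seed=config.seed + 1,
            )
            pairs.to_csv(outdir / "pairs.csv", index=False)
            register("pairs", outdir / "pairs.csv")
            logger.info("generate: %d records in %.2fs", len(cohort),
                        time.perf_counter() - t0)
        elif config.input_csv is not None:
            cohort = read_cohort_csv(config.input_csv)

        model: ReferenceCurveModel | None = None
        trimmed = None
        needs_model = {"fit", "stratify", "diagnose"} & set(config.stages)
        if needs_model:
            if cohort is None:
                raise ValueError("fit requested but no cohort available "
                                 "(provide input_csv or run the generate stage)")
            stage = "fit"
            t0 = time.perf_counter()
            model = fit_crude_model(cohort, trim_threshold=config.trim_threshold)
            trimmed = cohort.loc[model.inlier_mask_]
            if "fit" in config.stages:
                _write_json(outdir / "crude_model.json", model.to_dict())
                register("crude_model", outdir / "crude_model.json")
                table = model.centile_table(records=trimmed)
                table.to_csv(outdir / "centiles.csv", index=False,
                             float_format="%.6g")
                register("centiles", outdir / "centiles.csv")
            logger.info("fit: n_used=%d n_removed=%d in %.2fs",
                        model.n_used_, model.n_removed_,
                        time.perf_counter() - t0)

        if "stratify" in config.stages:
            stage = "stratify"
            t0 = time.perf_counter()
            smodel = fit_stratified_model(trimmed)
            smodel.coefficient_table().to_csv(
                outdir / "stratified_coefficients.csv", index=False,
                float_format="%.6g")
            register("stratified_coefficients",
                     outdir / "stratified_coefficients.csv")
            smodel.centile_tables().to_csv(
                outdir / "stratified_centiles.csv", index=False,
                float_format="%.6g")
            register("stratified_centiles", outdir / "stratified_centiles.csv")
            logger.info("stratify: done in %.2fs", time.perf_counter() - t0)

        if "diagnose" in config.stages:
            stage = "diagnose"
            t0 = time.perf_counter()
            report = residual_summary(model, trimmed, seed=config.seed,
                                      strata="age_group" in trimmed.columns)
            _write_json(outdir / "diagnostics.json", report.to_dict())
            register("diagnostics", outdir / "diagnostics.json")
            if report.qq_points is not None:
                report.qq_points.to_csv(outdir / "qq_points.csv", index=False,
                                        float_format="%.6g")
                register("qq_points", outdir / "qq_points.csv")
            logger.info("diagnose: done in %.2fs", time.perf_counter() - t0)

        if "reliability" in config.stages:
            stage = "reliability"
            pairs_path = outdir / "pairs.csv"
            if not pairs_path.exists():
                raise ValueError("reliability requested but no pairs.csv; "
                                 "run the generate stage or provide pairs")
            pairs = pd.read_csv(pairs_path)
            rel = analyze_pairs(pairs)
            _write_json(outdir / "reliability.json", {
                "icc": rel.icc,
                "icc_ci": list(rel.icc_ci),
                "reliability_coefficient": rel.reliability_coefficient,
                "n_pairs": rel.n_pairs,
                "form": rel.form,
            })
            register("reliability", outdir / "reliability.json")

        if "report" in config.stages:
            stage = "report"
            if cohort is None:
                raise ValueError("report requested but no cohort available")
            demo = summarize_demographics(cohort)
            demo.to_frame().to_csv(outdir / "demographics.csv", index=False)
            register("demographics", outdir / "demographics.csv")
            check = day_distribution_check(cohort["cycle_day"])
            _write_json(outdir / "day_distribution.json", dataclasses.asdict(check))
            register("day_distribution", outdir / "day_distribution.json")

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(outdir / "manifest.json", manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json(outdir / "manifest.json", manifest)
    return manifest


def make_fixture_bundle(seed: int = 0) -> dict:
    """Small, fully specified dataset bundle for tests and examples.

    Returns a 200-row cohort, 20 repeated pairs, and the generating
    parameters (so recovered quantities can be compared with truth).
    """
    gen = GeneratorConfig(n_subjects=200, seed=seed)
    pairs_between, pairs_within = 0.55, 0.07
    return {
        "cohort": generate_cohort(gen),
        "pairs": generate_repeated_pairs(20, pairs_between, pairs_within,
                                         seed=seed + 1),
        "generator_config": gen,
        "pairs_between_sd": pairs_between,
        "pairs_within_sd": pairs_within,
    }
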