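"""End-to-end orchestration: simulate -> fit -> zscore -> classify -> report.

All randomness flows from one top-level seed that is split per stage inside
the generators, so re-running with the same configuration reproduces every
artifact bit-exactly; a manifest records the configuration hash, seed and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .exceptions import ConfigError
from .grouping import GroupingConfig, group_cohort
from .io import read_cohort_csv, write_cohort_csv
from .normative import NormativeZScorer, fit_normative_model
from .stats_report import build_report
from .synthetic import (CohortConfig, generate_patient_cohort,
                        generate_reference_cohort, generate_scanner_controls)
from .zscoring import z_profiles

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, region list and stage settings for one pipeline run."""

    out_dir: str = "artifacts"
    seed: int = 0
    regions: tuple = ("gm", "wm", "bp", "thalamus", "putamen", "caudate",
                      "corpus_callosum")
    cutoff: float = -1.96
    grouping_regions: tuple = ("thalamus", "bp")
    alpha: float = 0.05
    cohort: dict = field(default_factory=dict)   # CohortConfig overrides
    # optional pre-existing inputs; when unset the cohorts are simulated
    reference_csv: str | None = None
    controls_csv: str | None = None
    patients_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("regions", "grouping_regions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = list(d["regions"])
        d["grouping_regions"] = list(d["grouping_regions"])
        return d

    def config_hash(self) -> str:
        d = self.as_dict()
        d.pop("out_dir", None)  # where artifacts land is not part of the run
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cohort_config(cfg: PipelineConfig) -> CohortConfig:
    return CohortConfig(seed=cfg.seed, **cfg.cohort)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the artifact directory.

    Returns the output directory. Any stage failure aborts with the stage
    name in the message and leaves an INVALID marker file behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INVALID"
    marker.write_text("pipeline incomplete\n")
    stage = "init"
    try:
        stage = "simulate"
        cc = _cohort_config(config)
        if config.reference_csv:
            reference = read_cohort_csv(config.reference_csv)
        else:
            reference = generate_reference_cohort(cc)
            write_cohort_csv(reference, out / "reference.csv")
        if config.controls_csv:
            controls = read_cohort_csv(config.controls_csv)
        else:
            controls = generate_scanner_controls(cc)
            write_cohort_csv(controls, out / "controls.csv")
        if config.patients_csv:
            patients = read_cohort_csv(config.patients_csv)
        else:
            patients = generate_patient_cohort(cc)
            write_cohort_csv(patients, out / "patients.csv")

        stage = "fit"
        regions = [r for r in config.regions if r in reference.columns]
        model = fit_normative_model(reference, controls, regions=regions)
        model.save(out / "normative_model.json")

        stage = "zscore"
        profiles = z_profiles(patients, model)
        profiles.to_csv(out / "zscores.csv", index=False)

        stage = "classify"
        gcfg = GroupingConfig(cutoff=config.cutoff,
                              regions=tuple(config.grouping_regions))
        merged = profiles.merge(patients[["id", "cohort"]], on="id")
        labeled, summary = group_cohort(merged, gcfg)
        labeled.to_csv(out / "groups.csv", index=False)
        with open(out / "group_counts.json", "w") as fh:
            json.dump(summary, fh, indent=1)

        stage = "report"
        report = build_report(patients, profiles,
                              labeled[["id", "group"]],
                              regions=regions, alpha=config.alpha)
        report["phenotype_summary"].to_csv(
            out / "phenotype_summary.csv", index=False)
        report["group_summary"].to_csv(out / "group_summary.csv", index=False)
        tests = {
            "alpha": report["alpha"],
            "phenotype_tests": report["phenotype_tests"].to_dict(
                orient="records"),
            "region_tests": report["region_tests"].to_dict(orient="records"),
            "region_anova": report["region_anova"].to_dict()
            if report["region_anova"] is not None else None,
            "group_tests": report["group_tests"],
            "excluded": report["excluded"],
        }
        with open(out / "tests.json", "w") as fh:
            json.dump(tests, fh, indent=1, default=float)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.as_dict(),
            "cohort_sizes": {"reference": int(len(reference)),
                             "controls": int(len(controls)),
                             "patients": int(len(patients))},
            "model_provenance": model.provenance_,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    marker.unlink(missing_ok=True)
    return out
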