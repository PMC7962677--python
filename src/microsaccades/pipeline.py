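"""End-to-end orchestration: simulate/load -> detect -> analyze -> sensitivity.

Every stage writes its tab-separated table into the run's output directory
and a manifest records the full configuration and seed, so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .detect import DetectionParams, detect_dataset, events_to_records
from .io import (GazeTrial, read_samples_table, write_events_table,
                 write_samples_table, write_summary)
from .sensitivity import (DEFAULT_MINDUR_RANGE, DEFAULT_VFAC_RANGE,
                          bootstrap_trial_curves, parameter_sweep,
                          rates_by_participant)
from .simulate import (GroundTruth, SimulationConfig, StudyDataset,
                       ground_truth_to_records, simulate_study)
from .stats import StudyResult, analyze_study, counts_frame, trial_timecourse


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``samples_path`` (an existing samples.tsv) or ``simulation``
    (a SimulationConfig) provides the input data.
    """

    output_dir: str = "run_output"
    samples_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    trial_duration: float = 5.5          # s; used when loading from file
    sampling_rate: float = 500.0         # Hz; used when loading from file
    d_variant: str = "pooled"
    mindur_range: Sequence[int] = DEFAULT_MINDUR_RANGE
    vfac_range: Sequence[float] = DEFAULT_VFAC_RANGE
    k_range: Sequence[int] = tuple(range(3, 61))
    n_boot: int = 1000
    bootstrap_seed: int = 0
    run_sweep: bool = True
    run_bootstrap: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "simulation" in data and isinstance(data["simulation"], dict):
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        if "detection" in data and isinstance(data["detection"], dict):
            data["detection"] = DetectionParams(**data["detection"])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown RunConfig field(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.samples_path is not None and not Path(self.samples_path).exists():
            raise FileNotFoundError(f"samples_path not found: {self.samples_path}")
        if self.trial_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("trial_duration and sampling_rate must be positive")


@dataclass
class RunResult:
    """Everything a full run produced, with file locations."""

    config: RunConfig
    result: StudyResult
    counts: pd.DataFrame
    output_dir: Path
    ground_truth: GroundTruth | None = None


def load_or_simulate(config: RunConfig) -> tuple[list[GazeTrial], float,
                                                 GroundTruth | None]:
    if config.samples_path is not None:
        trials = read_samples_table(config.samples_path, config.sampling_rate)
        if not trials:
            raise ValueError(f"no trials in {config.samples_path}")
        return trials, config.trial_duration, None
    dataset, gt = simulate_study(config.simulation)
    return dataset.trials, dataset.trial_duration, gt


def run_full_analysis(config: RunConfig) -> RunResult:
    """Run every stage and write all tables into ``config.output_dir``.

    Stages: input (simulate or load), detection (events.tsv), study
    statistics (summary.yaml, timecourse.tsv), parameter sweep
    (surface.tsv) and trial-count bootstrap (curves.tsv), plus a manifest
    echoing the configuration, package version and seeds.  Validation runs
    before any file is written.
    """
    config.validate()
    trials, trial_duration, gt = load_or_simulate(config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.samples_path is None:
        write_samples_table(trials, out / "samples.tsv")
        if gt is not None:
            pd.DataFrame(ground_truth_to_records(gt)).to_csv(
                out / "ground_truth.tsv", sep="\t", index=False)

    detections = detect_dataset(trials, config.detection)
    write_events_table(pd.DataFrame(events_to_records(detections)),
                       out / "events.tsv")
    counts = counts_frame(detections, config.detection.count_mode)
    result = analyze_study(counts, trial_duration, config.d_variant)
    timecourse = trial_timecourse(counts, trial_duration)
    timecourse.to_csv(out / "timecourse.tsv", sep="\t", index=False)

    summary = {
        "pre_mean_rate": result.pre_mean, "post_mean_rate": result.post_mean,
        "pre_sd": result.pre_sd, "post_sd": result.post_sd,
        "t_statistic": result.t_statistic, "dof": result.dof,
        "p_value": result.p_value,
        "cohens_d": result.cohens_d, "d_variant": result.d_variant,
        **{f"cohens_d_{k}": v for k, v in result.d_all_variants.items()},
        "pearson_r": result.pearson_r, "r_p_value": result.r_p_value,
        "n_participants": result.n_participants,
        "n_trials_excluded": int(counts["excluded"].sum()),
    }

    if config.run_sweep:
        surface = parameter_sweep(
            trials, trial_duration,
            config.mindur_range, config.vfac_range,
            config.d_variant, config.detection)
        surface.to_frame().to_csv(out / "surface.tsv", sep="\t", index=False)

    if config.run_bootstrap:
        pre_rates, post_rates, _ = rates_by_participant(counts, trial_duration)
        d_curve, r_curve = bootstrap_trial_curves(
            pre_rates, post_rates, config.k_range, config.n_boot,
            config.bootstrap_seed, config.d_variant)
        pd.concat([d_curve.to_frame(), r_curve.to_frame()],
                  ignore_index=True).to_csv(out / "curves.tsv", sep="\t",
                                            index=False)
        summary["bootstrap_seed"] = config.bootstrap_seed
        summary["bootstrap_n_boot"] = config.n_boot
        summary["bootstrap_n_redrawn"] = d_curve.n_redrawn

    write_summary(summary, out / "summary.yaml")

    manifest = {
        "package_version": __version__,
        "detection": asdict(config.detection),
        "d_variant": config.d_variant,
        "trial_duration": trial_duration,
        "input": config.samples_path or "simulated",
        "simulation": (config.simulation.to_dict()
                       if config.samples_path is None else None),
        "bootstrap": {"n_boot": config.n_boot, "seed": config.bootstrap_seed,
                      "k_range": [int(k) for k in config.k_range]}
        if config.run_bootstrap else None,
        "sweep": {"mindur_range": [int(m) for m in config.mindur_range],
                  "vfac_range": [float(v) for v in config.vfac_range]}
        if config.run_sweep else None,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return RunResult(config=config, result=result, counts=counts,
                     output_dir=out, ground_truth=gt)
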