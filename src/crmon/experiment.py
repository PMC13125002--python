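"""End-to-end cohort harness: simulate -> predict -> detect -> evaluate.

Reproduces the full evaluation workflow on a seeded synthetic cohort.  Each
subject gets a child seed derived from the experiment seed, a simulated LBNP
run, a reserve-prediction pass (surrogate by default, or the protocol oracle
for recovery checks), the five-detector battery, and a per-subject report;
the cohort tables aggregate them.  Everything is determined by
(config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import TrendConfig, ZoneConfig, detect_all
from .engine import (CRMSeries, OraclePredictor, SurrogateConfig, SurrogatePredictor,
                     run_pipeline)
from .errors import ConfigurationError
from .evaluate import SubjectReport, cohort_summary, evaluate_subject
from .ingest import StreamWindowSpec
from .simulate import SimulatorConfig, SubjectDataset, simulate_subject

log = logging.getLogger(__name__)


def subject_seed(experiment_seed: int, index: int) -> int:
    """Deterministic child seed for subject ``index`` (kept below 2**31)."""
    ss = np.random.SeedSequence([int(experiment_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


@dataclass
class ExperimentConfig:
    n_subjects: int = 20
    seed: int = 0
    predictor: str = "surrogate"            # surrogate | oracle
    sim: SimulatorConfig = field(default_factory=SimulatorConfig)
    spec: StreamWindowSpec = field(default_factory=StreamWindowSpec)
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    trend: TrendConfig = field(default_factory=TrendConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    gate_window: int = 60
    gate_crossings: int = 45

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.predictor not in ("surrogate", "oracle"):
            raise ConfigurationError("predictor must be 'surrogate' or 'oracle'")


@dataclass
class ExperimentResult:
    reports: list[SubjectReport]
    datasets: list[SubjectDataset]
    predictions: list[CRMSeries]
    cohort: dict[str, pd.DataFrame]


def make_predictor(kind: str, dataset: SubjectDataset,
                   surrogate_cfg: SurrogateConfig = SurrogateConfig(),
                   model_rate: float = 100.0):
    if kind == "oracle":
        return OraclePredictor(dataset.reserve_at)
    return SurrogatePredictor(surrogate_cfg, model_rate=model_rate)


def run_subject(dataset: SubjectDataset, config: ExperimentConfig) -> tuple[SubjectReport, CRMSeries]:
    """Predict, detect and evaluate one simulated subject."""
    predictor = make_predictor(config.predictor, dataset, config.surrogate,
                               config.spec.model_rate)
    pred = run_pipeline(dataset.ppg, predictor, config.spec)
    events = detect_all(pred.times, pred.smoothed, dataset.protocol,
                        vitals_times=dataset.vitals.times,
                        heart_rate=dataset.vitals.heart_rate,
                        mean_arterial_pressure=dataset.vitals.mean_arterial_pressure,
                        zones=config.zones, gate_window=config.gate_window,
                        gate_crossings=config.gate_crossings, trend=config.trend)
    report = evaluate_subject(dataset.subject_id, pred, dataset.protocol,
                              zones=config.zones, detection_events=events)
    return report, pred


def run_experiment(config: ExperimentConfig = ExperimentConfig()) -> ExperimentResult:
    """Simulate and evaluate the full cohort; failures are logged per subject."""
    reports: list[SubjectReport] = []
    datasets: list[SubjectDataset] = []
    predictions: list[CRMSeries] = []
    for i in range(config.n_subjects):
        seed = subject_seed(config.seed, i)
        dataset = simulate_subject(config.sim, seed=seed, subject_id=f"subj{i:03d}")
        try:
            report, pred = run_subject(dataset, config)
        except Exception:
            log.exception("subject %s failed; continuing", dataset.subject_id)
            continue
        datasets.append(dataset)
        reports.append(report)
        predictions.append(pred)
    return ExperimentResult(reports=reports, datasets=datasets, predictions=predictions,
                            cohort=cohort_summary(reports))


def write_reports(result: ExperimentResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-subject and cohort CSV reports (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, float_format="%.6f", lineterminator="\n")
        paths[name] = path

    _write("subjects", result.cohort["subjects"])
    _write("cohort_metrics", result.cohort["metrics"])
    _write("confusion_mean", result.cohort["confusion_mean"])
    _write("zone_metrics", result.cohort["zone_metrics"])
    det_rows = []
    for r in result.reports:
        for e in r.detection_events:
            det_rows.append({"subject_id": r.subject_id, "method": e.method,
                             "flagged": e.flagged,
                             "flag_time_s": np.nan if e.flag_time is None else e.flag_time,
                             "early_min": e.early_minutes})
    _write("detections", pd.DataFrame(det_rows).set_index("subject_id"))
    _write("detections_cohort", result.cohort["detections"])
    return paths
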