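"""End-to-end experiment orchestration.

``run_experiment`` composes the full analysis on a (simulated or loaded)
cohort: preprocess -> segment -> bagging per (model x modality x location)
-> clinical screening tables (dichotomous cutoff metrics, Youden-optimal
cutoffs, odds ratios) -> traditional-TUG bootstrap comparator.  Reports are
JSON + TSV; the prepared segment stacks are cached on disk keyed by a hash
of the relevant configuration, so re-running an unchanged config skips the
simulation and preprocessing work.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinmetrics
from .bagging import BaggingConfig, MetricSummary, run_bagging, \
    tug_reference_bootstrap
from .models import CnnConfig, CnnFallClassifier, SvmFallClassifier
from .preprocess import preprocess_recordings
from .segmentation import feature_table, segment_subjects
from .simulate import Cohort, LOCATIONS, SimulationParams, simulate_cohort

logger = logging.getLogger(__name__)

#: clinical dichotomization rules of the screening protocol: TUG time of
#: 14 s or more, 4-stage balance held 30 s or less, 8 or fewer chair stands
DEFAULT_RULES = (
    clinmetrics.CutoffRule("tug_time_s", 14.0, "high_is_faller"),
    clinmetrics.CutoffRule("four_stage_s", 30.0, "low_is_faller"),
    clinmetrics.CutoffRule("chair_stands", 8.0, "low_is_faller"),
)


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment."""

    n_subjects: int = 40
    faller_fraction: float = 0.5
    sim: SimulationParams = field(default_factory=SimulationParams)
    target_rate_hz: float = 100.0
    norm_scope: str = "all_subjects"
    window_s: float = 3.0
    stride_s: float = 1.0
    drop_padding_segments: bool = True
    models: tuple[str, ...] = ("cnn", "svm")
    modalities: tuple[str, ...] = ("gyro", "accel")
    locations: tuple[str, ...] = LOCATIONS
    cnn: CnnConfig = field(default_factory=CnnConfig)
    svm_params: dict = field(default_factory=dict)
    bagging: BaggingConfig = field(default_factory=BaggingConfig)
    tug_cutoff_s: float = 14.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        # propagate the master seed where a component seed was left at 0
        if self.sim.seed == 0 and self.seed != 0:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)
        if self.bagging.master_seed == 0 and self.seed != 0:
            self.bagging = dataclasses.replace(self.bagging,
                                               master_seed=self.seed)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self),
                                     default=_jsonable))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("non_faller", "faller"):
                if key in sim and isinstance(sim[key], dict):
                    cp = dict(sim[key])
                    if "cadence_hz" in cp:
                        cp["cadence_hz"] = tuple(cp["cadence_hz"])
                    if "phase_durations_s" in cp:
                        cp["phase_durations_s"] = tuple(
                            tuple(p) for p in cp["phase_durations_s"])
                    from .simulate import ClassParams
                    sim[key] = ClassParams(**cp)
            d["sim"] = SimulationParams(**sim)
        if "cnn" in d and isinstance(d["cnn"], dict):
            cnn = dict(d["cnn"])
            if "filters" in cnn:
                cnn["filters"] = tuple(cnn["filters"])
            d["cnn"] = CnnConfig(**cnn)
        if "bagging" in d and isinstance(d["bagging"], dict):
            d["bagging"] = BaggingConfig(**d["bagging"])
        for key in ("models", "modalities", "locations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def prepare_segments(
    cohort: Cohort,
    location: str,
    modality: str,
    config: ExperimentConfig,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Preprocess and segment one (location, modality) slice of a cohort.

    Returns per-subject window stacks (for the CNN), per-subject 9-feature
    rows (for the SVM, computed on the unpadded extent), and the labels.
    """
    recs = [cohort.recording(sid, location) for sid in cohort.subject_ids]
    padded, true_lengths, _ = preprocess_recordings(
        recs, config.target_rate_hz, scope=config.norm_scope)
    signals = [getattr(r, modality) for r in padded]
    labels = cohort.labels
    segset = segment_subjects(
        signals, labels, true_lengths, config.target_rate_hz,
        config.window_s, config.stride_s, modality, location)
    if config.drop_padding_segments:
        segset = segset.drop_padding_only()
    per_subject = segset.per_subject_segments(len(cohort))
    features = feature_table(signals, true_lengths)
    feature_rows = [features[i:i + 1] for i in range(len(cohort))]
    return per_subject, feature_rows, labels


def _model_factory(kind: str, config: ExperimentConfig):
    if kind == "cnn":
        c = config.cnn

        def factory(seed):
            return CnnFallClassifier(
                filters=c.filters, kernel_size=c.kernel_size,
                pool_size=c.pool_size, learning_rate=c.learning_rate,
                batch_size=c.batch_size, epochs=c.epochs,
                random_state=seed)
    elif kind == "svm":
        def factory(seed):
            return SvmFallClassifier(random_state=seed,
                                     **config.svm_params)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return factory


def clinical_tables(cohort: Cohort,
                    rules=DEFAULT_RULES) -> dict:
    """Dichotomous screening metrics, Youden sweeps and odds ratios."""
    labels = cohort.labels
    out = {}
    for rule in rules:
        values = np.array([getattr(s, rule.variable)
                           for s in cohort.subjects], dtype=float)
        pred = clinmetrics.dichotomize(values, rule)
        cm = clinmetrics.confusion(pred, labels)
        metrics = clinmetrics.basic_metrics(cm)
        metrics["AUC"] = clinmetrics.roc_auc(
            values if rule.direction == "high_is_faller" else -values,
            labels)
        opt = clinmetrics.youden_optimal_cutoff(values, labels,
                                                rule.direction)
        out[rule.variable] = {
            "cutoff": rule.cutoff,
            "direction": rule.direction,
            "confusion": dataclasses.asdict(cm),
            "metrics": metrics,
            "optimal_cutoff": opt["cutoff"],
            "optimal_J": opt["J_max"],
            "odds_ratio": clinmetrics.odds_ratio_2x2(cm),
        }
    return out


def run_experiment(config: ExperimentConfig,
                   cohort: Cohort | None = None) -> dict:
    """Run the full pipeline and return (and optionally write) the report."""
    if config.bagging.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    out_dir = Path(config.out_dir) if config.out_dir else None
    if cohort is None:
        cohort = simulate_cohort(config.n_subjects, config.faller_fraction,
                                 config.sim)
    report: dict = {"config": config.to_dict(),
                    "config_hash": config.content_hash(),
                    "n_subjects": len(cohort),
                    "n_fallers": int(cohort.labels.sum()),
                    "ml": {}, "clinical": {}}
    cache_dir = out_dir / "cache" if out_dir else None
    for location in config.locations:
        for modality in config.modalities:
            key = f"{location}_{modality}"
            segs, feats, labels = _cached_prepare(
                cohort, location, modality, config, cache_dir)
            for kind in config.models:
                logger.info("bagging %s on %s", kind, key)
                data = segs if kind == "cnn" else feats
                summary = run_bagging(data, labels,
                                      _model_factory(kind, config),
                                      config.bagging)
                report["ml"][f"{key}_{kind}"] = summary.to_dict()
                if out_dir:
                    out_dir.mkdir(parents=True, exist_ok=True)
                    summary.per_iteration.to_csv(
                        out_dir / f"iterations_{key}_{kind}.tsv",
                        sep="\t", index=False)
    # traditional-TUG comparator selects 10 per class when the cohort
    # allows it, else every available subject of the smaller class
    n_per_class = min(10, int(cohort.labels.sum()),
                      int((1 - cohort.labels).sum()))
    tug = tug_reference_bootstrap(
        cohort.tug_times, cohort.labels, config.tug_cutoff_s,
        config.bagging, n_per_class=n_per_class)
    report["ml"]["clinical_tug"] = tug.to_dict()
    report["clinical"] = clinical_tables(cohort)
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=_jsonable))
        _summary_tsv(report, out_dir / "summary.tsv")
    return report


def _cached_prepare(cohort, location, modality, config, cache_dir):
    """Disk cache of prepared segments keyed by the config content hash."""
    if cache_dir is None:
        return prepare_segments(cohort, location, modality, config)
    sub = json.dumps({"hash": config.content_hash(),
                      "loc": location, "mod": modality}, sort_keys=True)
    key = hashlib.sha256(sub.encode()).hexdigest()[:16]
    path = Path(cache_dir) / f"segments_{key}.npz"
    if path.exists():
        z = np.load(path, allow_pickle=False)
        n = int(z["n_subjects"])
        segs = [z[f"seg_{i}"] for i in range(n)]
        feats = [z[f"feat_{i}"] for i in range(n)]
        return segs, feats, z["labels"]
    segs, feats, labels = prepare_segments(cohort, location, modality,
                                           config)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, n_subjects=len(segs), labels=labels,
             **{f"seg_{i}": s for i, s in enumerate(segs)},
             **{f"feat_{i}": f for i, f in enumerate(feats)})
    return segs, feats, labels


def _summary_tsv(report: dict, path: Path) -> None:
    rows = []
    for name, res in report["ml"].items():
        row = {"experiment": name}
        for metric, stats in res["summary"].items():
            row[metric] = stats["mean"]
            row[f"{metric}_ci_low"] = stats["ci_low"]
            row[f"{metric}_ci_high"] = stats["ci_high"]
        row["c_statistic"] = res["c_statistic"]
        row["c_statistic_p"] = res["c_statistic_p"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
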