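"""End-to-end orchestration: data → split → weights → deep features → classifier.

The canonical run mirrors the prediction stack's block diagram: acquire a
labeled table (synthetic or CSV), split 75/25 (stratified), optimize the
per-feature weights on the training split with IEMOA, fit the DBN on the
training split, assemble (original | weighted | deep) feature bundles for both
splits, pretrain and train the MS-CAGRU classifier on the training bundle,
and evaluate the full confusion-metric suite on the held-out bundle.

Every anchor, scaler and weight is a function of the training split only;
identical configuration and seeds reproduce identical reports.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from hydrosoil.data import (
    LabeledTable,
    SyntheticConfig,
    generate_synthetic_dataset,
    load_labeled_csv,
    minmax_scale,
    split_train_test,
)
from hydrosoil.dbn import DBNConfig, fit_dbn, transform_dbn
from hydrosoil.feature_weighting import (
    WeightVector,
    apply_weights,
    make_anchors,
    optimize_feature_weights,
)
from hydrosoil.iemoa import IEMOAConfig
from hydrosoil.metrics import MetricReport, confusion_counts, metric_suite
from hydrosoil.mscagru import (
    FeatureBundle,
    MSCAGRUConfig,
    TrainedModel,
    predict,
    train_mscagru,
)

__all__ = ["RunConfig", "RunReport", "run_experiment", "write_report", "make_bundle"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end experiment.

    Exactly one of ``synthetic`` or ``csv_path`` must be given. Sub-configs
    default to the study settings: population 10, 50 iterations, weight
    dimension = feature count, 75/25 stratified split.
    """

    synthetic: SyntheticConfig | None = None
    csv_path: str | None = None
    label_column: str = "label"
    train_fraction: float = 0.75
    split_seed: int = 0
    positive_class: str | None = None
    optimize_weights: bool = True
    use_deep_features: bool = True
    iemoa: IEMOAConfig = field(default_factory=IEMOAConfig)
    dbn: DBNConfig = field(default_factory=DBNConfig)
    mscagru: MSCAGRUConfig = field(default_factory=MSCAGRUConfig)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.csv_path is None):
            raise ValueError("specify exactly one data source: synthetic or csv_path")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class RunReport:
    config: RunConfig
    weights: WeightVector
    weight_trace: np.ndarray
    feature_names: list[str]
    dbn_reconstruction_mse: list[list[float]]
    pretrain_loss: list[list[float]]
    train_loss: list[float]
    metrics: MetricReport
    accuracy: float
    n_train: int
    n_test: int
    positive_class: str
    stage_seconds: dict[str, float]
    model: TrainedModel | None = None


def make_bundle(
    table: LabeledTable,
    weights: WeightVector,
    scale_reference: LabeledTable,
    dbn_model=None,
) -> FeatureBundle:
    """Assemble (original | weighted | deep) matrices for one split.

    Original and weighted matrices are min-max scaled against the training
    reference so all three feature sets share the [0, 1] range the network
    expects. With ``dbn_model=None`` the deep block degrades to a zero-width
    matrix (ablation mode).
    """
    scaled = minmax_scale(table, scale_reference)
    weighted = scaled.features * weights.weights
    if dbn_model is not None:
        deep = transform_dbn(dbn_model, table)
    else:
        deep = np.zeros((table.n_samples, 0))
    return FeatureBundle(original=scaled.features, weighted=weighted, deep=deep)


def run_experiment(config: RunConfig) -> RunReport:
    """Execute the full pipeline and evaluate on the held-out split."""
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.synthetic is not None:
        table = generate_synthetic_dataset(config.synthetic)
    else:
        table = load_labeled_csv(config.csv_path, config.label_column)
    train, test = split_train_test(
        table, config.train_fraction, seed=config.split_seed, stratified=True
    )
    timings["data"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    anchors = make_anchors(train)
    if config.optimize_weights:
        weights, trace_result = optimize_feature_weights(train, config.iemoa, anchors)
        weight_trace = trace_result.trace
    else:
        weights = WeightVector(np.full(train.n_features, 0.5))
        weight_trace = np.array([])
    timings["weights"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.use_deep_features:
        dbn_model = fit_dbn(train, config.dbn)
        dbn_mse = dbn_model.reconstruction_mse
    else:
        dbn_model, dbn_mse = None, []
    timings["dbn"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    train_bundle = make_bundle(train, weights, train, dbn_model)
    test_bundle = make_bundle(test, weights, train, dbn_model)
    model = train_mscagru(train_bundle, train.labels, config.mscagru)
    timings["classifier"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    y_pred, _ = predict(model, test_bundle)
    positive = config.positive_class or str(train.label_names[-1])
    counts = confusion_counts(test.labels, y_pred, positive)
    report_metrics = metric_suite(counts)
    timings["evaluate"] = time.perf_counter() - t0

    return RunReport(
        config=config,
        weights=weights,
        weight_trace=np.asarray(weight_trace),
        feature_names=list(train.feature_names),
        dbn_reconstruction_mse=dbn_mse,
        pretrain_loss=model.pretrain_loss,
        train_loss=model.train_loss,
        metrics=report_metrics,
        accuracy=float(report_metrics.accuracy),
        n_train=train.n_samples,
        n_test=test.n_samples,
        positive_class=positive,
        stage_seconds=timings,
        model=model,
    )


def _config_echo(config: RunConfig) -> dict:
    echo: dict = {
        "train_fraction": config.train_fraction,
        "split_seed": config.split_seed,
        "optimize_weights": config.optimize_weights,
        "use_deep_features": config.use_deep_features,
        "iemoa": dict(config.iemoa.__dict__),
        "dbn": {**config.dbn.__dict__, "layer_sizes": list(config.dbn.layer_sizes)},
        "mscagru": {
            **config.mscagru.__dict__,
            "branch_kernel_sizes": list(config.mscagru.branch_kernel_sizes),
        },
    }
    if config.synthetic is not None:
        echo["synthetic"] = dict(config.synthetic.__dict__)
    else:
        echo["csv_path"] = config.csv_path
        echo["label_column"] = config.label_column
    return echo


def write_report(report: RunReport, out_dir) -> list[Path]:
    """Persist config echo (YAML), metrics (JSON + CSV), weights and traces (CSV).

    Returns the manifest of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    p = out / "config.yaml"
    p.write_text(yaml.safe_dump(_config_echo(report.config), sort_keys=False))
    manifest.append(p)

    metrics_dict = report.metrics.as_dict()
    p = out / "metrics.json"
    p.write_text(json.dumps(
        {
            "positive_class": report.positive_class,
            "n_train": report.n_train,
            "n_test": report.n_test,
            "metrics": metrics_dict,
            "undefined": list(report.metrics.undefined),
        },
        indent=2,
    ))
    manifest.append(p)

    p = out / "metrics.csv"
    header = ",".join(metrics_dict.keys())
    row = ",".join(f"{v:.6g}" for v in metrics_dict.values())
    p.write_text(header + "\n" + row + "\n")
    manifest.append(p)

    p = out / "weights.csv"
    lines = ["feature_name,weight"] + [
        f"{name},{w:.6f}" for name, w in zip(report.feature_names, report.weights.weights)
    ]
    p.write_text("\n".join(lines) + "\n")
    manifest.append(p)

    p = out / "weight_trace.csv"
    lines = ["iteration,best_value"] + [
        f"{i},{v:.8g}" for i, v in enumerate(report.weight_trace)
    ]
    p.write_text("\n".join(lines) + "\n")
    manifest.append(p)

    p = out / "training.json"
    p.write_text(json.dumps(
        {
            "dbn_reconstruction_mse": report.dbn_reconstruction_mse,
            "pretrain_loss": report.pretrain_loss,
            "train_loss": report.train_loss,
            "stage_seconds": report.stage_seconds,
        },
        indent=2,
    ))
    manifest.append(p)
    return manifest
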