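"""Labeled tabular datasets: containers, synthetic generation, splitting, scaling.

The central container is :class:`LabeledTable`, a sample × feature matrix with
named columns and a class-label vector — the currency every other module trades
in. The synthetic generator emulates the structure of phytohormone panels
measured on plants grown hydroponically or in soil: a handful of positive
continuous compound concentrations (log-normal, with a class-conditional shift
on the log scale), optional 0/1 growth-condition indicators (earthworm
presence, growth medium), optional pure-noise columns, and a binary
cultivation-system label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledTable",
    "SyntheticConfig",
    "generate_synthetic_dataset",
    "load_labeled_csv",
    "write_labeled_csv",
    "split_train_test",
    "minmax_scale",
]


@dataclass
class LabeledTable:
    """A feature matrix with per-column names and a class label per row.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix; no missing entries allowed. Compound
        concentrations are in ng/g (or unitless after scaling); condition
        features are coded 0/1.
    feature_names : list of str
        Unique column labels, one per feature column.
    labels : ndarray of shape (n_samples,)
        Class identifier per row (any hashable dtype; strings typical).
    label_names : list of str
        The distinct class labels, in a fixed reporting order.
    """

    features: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contains missing or non-finite entries")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"row count {self.features.shape[0]} != label count {self.labels.shape[0]}"
            )
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError(
                f"feature_names length {len(self.feature_names)} != "
                f"feature columns {self.features.shape[1]}"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if not self.label_names:
            self.label_names = [str(v) for v in pd.unique(self.labels)]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_indicator(self, positive_class=None) -> np.ndarray:
        """0/1 vector marking membership of ``positive_class`` (default: last label name)."""
        if positive_class is None:
            positive_class = self.label_names[-1]
        return (self.labels.astype(str) == str(positive_class)).astype(int)

    def take(self, indices: np.ndarray) -> "LabeledTable":
        """Row subset preserving names and label order."""
        return LabeledTable(
            self.features[indices],
            list(self.feature_names),
            self.labels[indices],
            list(self.label_names),
        )

    def with_features(self, features: np.ndarray, feature_names=None) -> "LabeledTable":
        """Same rows/labels with a replaced feature matrix."""
        if feature_names is None:
            feature_names = list(self.feature_names)
        return LabeledTable(features, feature_names, self.labels, list(self.label_names))


# Compound roster the generator emulates: five phytohormones measured per gram
# of plant tissue, plus a baseline log-concentration for each (ng/g scale).
COMPOUND_NAMES = (
    "zeatin",
    "adenosine",
    "indole_3_acetic_acid",
    "abscisic_acid",
    "isopentenyl_adenosine",
)
_BASE_LOG_CONC = (2.3, 4.0, 3.2, 2.8, 1.9)
_LOG_SD = 0.5  # within-class spread of log concentration


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic phytohormone panel generator.

    ``effect_size`` is the standardized mean shift (in units of the log-scale
    standard deviation) between hydroponic and soil classes on every
    informative compound. ``condition_agreement`` is the probability that the
    earthworm-presence indicator agrees with the cultivation label.
    """

    n_samples: int
    n_compounds: int = 5
    n_noise_features: int = 0
    effect_size: float = 1.0
    class_balance: float = 0.5
    include_conditions: bool = False
    condition_agreement: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0.0 <= self.condition_agreement <= 1.0:
            raise ValueError("condition_agreement must lie in [0, 1]")


def generate_synthetic_dataset(config: SyntheticConfig) -> LabeledTable:
    """Draw a synthetic hydroponic-vs-soil phytohormone dataset.

    Informative compounds are log-normal with class-conditional log means
    separated by ``effect_size`` standard deviations; the shift direction
    alternates across compounds (hydroponic up on even columns, down on odd),
    mimicking hormones that respond in either direction to soil-free culture.
    Noise columns come from the same marginal family with no class dependence.
    Fully determined by ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # labels: 1 = hydroponic, 0 = soil; class_balance = P(hydroponic)
    y = (rng.random(n) < config.class_balance).astype(int)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for j in range(config.n_compounds):
        base = _BASE_LOG_CONC[j % len(_BASE_LOG_CONC)]
        direction = 1.0 if j % 2 == 0 else -1.0
        shift = direction * config.effect_size * _LOG_SD
        mu = base + shift * (y - 0.5)  # classes sit at base ± shift/2
        cols.append(np.exp(rng.normal(mu, _LOG_SD)))
        stem = COMPOUND_NAMES[j % len(COMPOUND_NAMES)]
        names.append(stem if j < len(COMPOUND_NAMES) else f"{stem}_{j}")
    for j in range(config.n_noise_features):
        base = _BASE_LOG_CONC[j % len(_BASE_LOG_CONC)]
        cols.append(np.exp(rng.normal(base, _LOG_SD, size=n)))
        names.append(f"noise_{j}")
    if config.include_conditions:
        agree = rng.random(n) < config.condition_agreement
        earthworm = np.where(agree, y, 1 - y).astype(float)
        medium = (rng.random(n) < 0.5).astype(float)
        cols.extend([earthworm, medium])
        names.extend(["earthworm_present", "growth_medium"])

    features = np.column_stack(cols)
    labels = np.where(y == 1, "hydroponic", "soil")
    return LabeledTable(features, names, labels, label_names=["soil", "hydroponic"])


def load_labeled_csv(path, label_column: str) -> LabeledTable:
    """Read a header-bearing CSV into a :class:`LabeledTable`.

    Every column except ``label_column`` must be numeric; the offending cell is
    identified by row and column on failure. Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise IOError(f"label column {label_column!r} not found in {path.name}")
    labels = df[label_column].astype(str).to_numpy()
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        bad = coerced.isna() & ~feats[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise IOError(f"non-numeric value in column {col!r}, row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise IOError(f"missing value in column {col!r}, row {row}")
        feats[col] = coerced
    return LabeledTable(feats.to_numpy(dtype=float), list(feats.columns), labels)


def write_labeled_csv(table: LabeledTable, path, label_column: str = "label") -> None:
    """Write a :class:`LabeledTable` to CSV (header row, UTF-8)."""
    df = pd.DataFrame(table.features, columns=table.feature_names)
    df[label_column] = table.labels
    df.to_csv(path, index=False)


def split_train_test(
    table: LabeledTable,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[LabeledTable, LabeledTable]:
    """Disjoint, exhaustive train/test row partition (default 75/25).

    Train size is ``round(train_fraction * n)``. In stratified mode each class
    contributes its proportional share (largest-remainder rounding, so class
    proportions are preserved to within one sample per class).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = table.n_samples
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)

    if not stratified:
        perm = rng.permutation(n)
        return table.take(np.sort(perm[:n_train])), table.take(np.sort(perm[n_train:]))

    labels = table.labels.astype(str)
    classes = [str(c) for c in pd.unique(labels)]
    counts = {c: int(np.sum(labels == c)) for c in classes}
    for c, k in counts.items():
        if k < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members; cannot stratify")
    quota = {c: train_fraction * counts[c] for c in classes}
    alloc = {c: int(np.floor(quota[c])) for c in classes}
    leftover = n_train - sum(alloc.values())
    for c in sorted(classes, key=lambda c: quota[c] - np.floor(quota[c]), reverse=True)[:leftover]:
        alloc[c] += 1

    train_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        perm = members[rng.permutation(len(members))]
        train_idx.extend(perm[: alloc[c]].tolist())
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True
    return table.take(np.flatnonzero(train_mask)), table.take(np.flatnonzero(~train_mask))


def minmax_scale(table: LabeledTable, fit_reference: LabeledTable) -> LabeledTable:
    """Map each column to [0, 1] using the reference table's min/max.

    Values outside the reference range clip to the interval ends; columns that
    are constant in the reference map to 0.5 everywhere.
    """
    if table.feature_names != fit_reference.feature_names:
        raise ValueError("column mismatch between table and fit_reference")
    lo = fit_reference.features.min(axis=0)
    hi = fit_reference.features.max(axis=0)
    span = hi - lo
    out = np.empty_like(table.features)
    const = span <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, ~const] = (table.features[:, ~const] - lo[~const]) / span[~const]
    out[:, const] = 0.5
    np.clip(out, 0.0, 1.0, out=out)
    return table.with_features(out)
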