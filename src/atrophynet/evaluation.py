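"""Slice-level model evaluation and the shuffled-label null comparison.

Per class, one-vs-rest confusion counts give accuracy (TP+TN)/total,
precision TP/(TP+FP), recall TP/(TP+FN) and F1 = 2PR/(P+R); "macro"
metrics are the unweighted three-class means. Model stability is assessed
by training many models on fresh random splits -- correctly labeled
("trained") and with permuted training labels ("shuffled") -- and
comparing the two test-accuracy distributions with the frequency
distribution comparison index (FDCI): the fraction of ordered pairs in
which a trained model's accuracy strictly exceeds a shuffled model's.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import SliceCNNClassifier
from .experiment import shuffle_training_labels, split_participants
from .preprocess import SliceDataset

__all__ = [
    "ClasswiseMetrics",
    "FDCIResult",
    "EnsembleReport",
    "confusion_counts",
    "classwise_metrics",
    "macro_metrics",
    "compute_fdci",
    "predict_slice_table",
    "evaluate_predictions",
    "run_single_experiment",
    "run_ensemble",
]

CLASSES = ("TLE", "AD", "HC")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


def confusion_counts(predictions: pd.DataFrame, cls: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) slice counts for class ``cls``.

    ``predictions`` needs columns ``true`` and ``predicted``.
    """
    truth = predictions["true"].to_numpy()
    pred = predictions["predicted"].to_numpy()
    known = set(truth) | set(pred)
    valid = set(predictions.attrs.get("classes", CLASSES)) | set(CLASSES)
    unknown = known - valid
    if unknown:
        raise ValueError(f"unknown labels in prediction table: {sorted(unknown)}")
    tp = int(np.sum((truth == cls) & (pred == cls)))
    tn = int(np.sum((truth != cls) & (pred != cls)))
    fp = int(np.sum((truth != cls) & (pred == cls)))
    fn = int(np.sum((truth == cls) & (pred != cls)))
    return tp, tn, fp, fn


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 defined as 0")
        return 0.0
    return num / den


@dataclass(frozen=True)
class ClasswiseMetrics:
    cls: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self):
        total = self.tp + self.tn + self.fp + self.fn
        if total <= 0:
            raise ValueError("empty prediction table")
        object.__setattr__(self, "accuracy", (self.tp + self.tn) / total)
        p = _safe_div(self.tp, self.tp + self.fp, f"precision[{self.cls}]")
        r = _safe_div(self.tp, self.tp + self.fn, f"recall[{self.cls}]")
        object.__setattr__(self, "precision", p)
        object.__setattr__(self, "recall", r)
        object.__setattr__(
            self, "f1", _safe_div(2 * p * r, p + r, f"f1[{self.cls}]")
        )


def classwise_metrics(predictions: pd.DataFrame, cls: str) -> ClasswiseMetrics:
    tp, tn, fp, fn = confusion_counts(predictions, cls)
    return ClasswiseMetrics(cls, tp, tn, fp, fn)


def macro_metrics(per_class: dict[str, dict[str, float]] | list) -> dict[str, float]:
    """Unweighted mean over classes, per metric.

    Accepts a mapping class -> {metric -> value} (or a list of
    ClasswiseMetrics); all three classes must be present.
    """
    if isinstance(per_class, dict):
        items = list(per_class.values())
        rows = [
            {m: v[m] for m in v if m in METRIC_NAMES} if isinstance(v, dict)
            else {m: getattr(v, m) for m in METRIC_NAMES}
            for v in items
        ]
    else:
        rows = [{m: getattr(v, m) for m in METRIC_NAMES} for v in per_class]
    if len(rows) != len(CLASSES):
        raise ValueError(f"expected {len(CLASSES)} classes, got {len(rows)}")
    out = {}
    for m in rows[0]:
        out[m] = float(np.mean([r[m] for r in rows]))
    return out


@dataclass(frozen=True)
class FDCIResult:
    fdci: float
    numerator: int
    denominator: int


def compute_fdci(accs_a, accs_b) -> FDCIResult:
    """Fraction of ordered pairs (a, b) with a strictly greater than b.

    ``accs_a`` are the properly trained models' accuracies, ``accs_b`` the
    shuffled-label null models'. Ties are not wins.
    """
    a = np.asarray(accs_a, dtype=float)
    b = np.asarray(accs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both accuracy lists must be nonempty")
    numerator = int((a[:, None] > b[None, :]).sum())
    denominator = int(a.size * b.size)
    return FDCIResult(numerator / denominator, numerator, denominator)


# ---------------------------------------------------------------------------
# Single experiment and ensembles
# ---------------------------------------------------------------------------

def predict_slice_table(
    model: SliceCNNClassifier, dataset: SliceDataset, rows: np.ndarray
) -> pd.DataFrame:
    """Per-slice prediction table (subject_id, z_mm, true, predicted and
    one softmax probability column per class)."""
    X = dataset.X[rows]
    meta = dataset.meta.loc[rows].reset_index(drop=True)
    proba = model.predict_proba(X)
    pred = model.classes_[proba.argmax(axis=1)]
    table = pd.DataFrame(
        {
            "subject_id": meta["subject_id"],
            "z_mm": meta["z_mm"],
            "true": meta["label"],
            "predicted": pred,
        }
    )
    for j, cls in enumerate(model.classes_):
        table[f"p_{cls}"] = proba[:, j]
    return table


def evaluate_predictions(predictions: pd.DataFrame) -> dict:
    """Per-class and macro metrics for one prediction table."""
    per_class = {c: classwise_metrics(predictions, c) for c in CLASSES}
    return {
        "per_class": {
            c: {m: getattr(v, m) for m in METRIC_NAMES}
            for c, v in per_class.items()
        },
        "macro": macro_metrics(per_class),
    }


def run_single_experiment(
    dataset: SliceDataset,
    mode: str = "trained",
    seed: int = 0,
    fractions=(0.60, 0.15, 0.25),
    cnn_params: dict | None = None,
    shuffle_granularity: str = "participant",
    return_model: bool = False,
):
    """One split + one model + test-set metrics.

    ``mode='shuffled'`` permutes the *training* labels (participant level
    by default; ``shuffle_granularity='slice'`` permutes per slice);
    validation and test labels stay correct, and metrics are always
    computed against the correct test labels.
    """
    if mode not in ("trained", "shuffled"):
        raise ValueError(f"mode must be 'trained' or 'shuffled', got {mode!r}")
    ss = np.random.SeedSequence(seed)
    split_seed, shuffle_seed, model_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    assignment = split_participants(dataset.demographics, fractions, seed=split_seed)
    labels = assignment.copy()
    labels["shuffled_group"] = labels["group"]
    if mode == "shuffled" and shuffle_granularity == "participant":
        labels = shuffle_training_labels(assignment, seed=shuffle_seed)

    part = labels.set_index("subject_id")["partition"]
    train_label = labels.set_index("subject_id")["shuffled_group"]

    meta = dataset.meta
    train_rows = np.flatnonzero(part[meta["subject_id"]].to_numpy() == "train")
    val_rows = np.flatnonzero(part[meta["subject_id"]].to_numpy() == "validation")
    test_rows = np.flatnonzero(part[meta["subject_id"]].to_numpy() == "test")

    y_train = train_label[meta.loc[train_rows, "subject_id"]].to_numpy()
    if mode == "shuffled" and shuffle_granularity == "slice":
        rng = np.random.default_rng(shuffle_seed)
        y_train = y_train[rng.permutation(len(y_train))]
    y_val = meta.loc[val_rows, "label"].to_numpy()

    params = dict(cnn_params or {})
    params["random_state"] = model_seed
    model = SliceCNNClassifier(**params)
    model.fit(
        dataset.X[train_rows], y_train,
        validation_data=(dataset.X[val_rows], y_val),
    )
    predictions = predict_slice_table(model, dataset, test_rows)
    result = evaluate_predictions(predictions)
    result["mode"] = mode
    result["seed"] = seed
    out = (result, predictions)
    return out + (model,) if return_model else out


@dataclass
class EnsembleReport:
    """Metrics of ``n_runs`` independently split-and-trained models."""

    mode: str
    runs: pd.DataFrame           # one row per run: macro + per-class metrics
    mean: dict
    sd: dict
    seeds: list[int]
    models: list = field(default_factory=list, repr=False)

    @property
    def macro_accuracies(self) -> np.ndarray:
        return self.runs["macro_accuracy"].to_numpy()


def run_ensemble(
    dataset: SliceDataset,
    n_runs: int = 100,
    mode: str = "trained",
    master_seed: int = 0,
    fractions=(0.60, 0.15, 0.25),
    cnn_params: dict | None = None,
    shuffle_granularity: str = "participant",
    keep_models: bool = False,
) -> EnsembleReport:
    """Train ``n_runs`` models on fresh random splits and aggregate their
    test metrics (mean and SD per metric across runs)."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    ss = np.random.SeedSequence(master_seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
    rows, models = [], []
    for seed in run_seeds:
        res = run_single_experiment(
            dataset, mode=mode, seed=seed, fractions=fractions,
            cnn_params=cnn_params, shuffle_granularity=shuffle_granularity,
            return_model=keep_models,
        )
        result = res[0]
        if keep_models:
            models.append(res[2])
        row = {f"macro_{m}": v for m, v in result["macro"].items()}
        for c, mm in result["per_class"].items():
            row.update({f"{c}_{m}": v for m, v in mm.items()})
        row["seed"] = seed
        rows.append(row)
    runs = pd.DataFrame(rows)
    metric_cols = [c for c in runs.columns if c != "seed"]
    mean = {c: float(runs[c].mean()) for c in metric_cols}
    sd = {c: float(runs[c].std(ddof=1)) for c in metric_cols}
    return EnsembleReport(
        mode=mode, runs=runs, mean=mean, sd=sd, seeds=run_seeds, models=models
    )
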