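"""Cross-validated evaluation protocol and classification metrics.

Implements the full assessment pipeline for the colony classifier: a
stratified 70/30 train/test split, stratified k-fold cross-validation
(default k=5, 25 epochs per run), aggregate confusion matrices in the
rows-predicted / columns-actual orientation, the seven per-species metrics
(sensitivity, specificity, accuracy, PPV, NPV, F1, MCC) with an unweighted
average row, one-vs-rest ROC curves with trapezoidal AUC, and the three
report figures (training curves, confusion heatmap, multiclass ROC).

Metric conventions: percentages are reported on a 0-100 scale, F1 and MCC
as dimensionless values; any metric with a zero denominator is *undefined*
(reported as missing, never coerced to 0), and averages skip missing
entries with a warning.  Reported values are rounded half-up to 2 decimal
places.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifier import (
    ClassProbabilities,
    LabeledDataset,
    ModelConfig,
    TrainingConfig,
    TrainingHistory,
    build_model,
    train_on_arrays,
)

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "MetricsRow",
    "ROCCurve",
    "PredictionRecord",
    "CVRunResult",
    "round_half_up",
    "split_70_30",
    "make_folds",
    "run_cross_validation",
    "confusion_from_predictions",
    "metrics_from_counts",
    "one_vs_rest_binarize",
    "roc_ovr",
    "summarize_table",
    "reconstruct_counts",
    "render_reports",
]

METRIC_COLUMNS = [
    "sensitivity",
    "specificity",
    "accuracy",
    "ppv",
    "npv",
    "f1",
    "mcc",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.005 -> 0.01), matching how the
    reported tables are formatted; banker's rounding would flip half-ulps."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# splits and folds
# ---------------------------------------------------------------------------


def _labels_of(dataset) -> list[str]:
    if isinstance(dataset, LabeledDataset):
        return [lab for _, lab in dataset.all_items()]
    return list(dataset)


def split_70_30(dataset, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 70/30 split; returns (train ids, test ids), disjoint.

    Per class, round(0.7 * n_class) items go to training; deterministic
    under ``seed``.  ``dataset`` may be a LabeledDataset or a sequence of
    per-item labels.
    """
    labels = np.asarray(_labels_of(dataset))
    if len(labels) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for cls in np.unique(labels):
        ids = np.nonzero(labels == cls)[0]
        if len(ids) < 1:
            raise ValueError(f"class {cls} has no images")
        perm = rng.permutation(ids)
        n_train = int(round(0.7 * len(ids)))
        train_ids.extend(perm[:n_train])
        test_ids.extend(perm[n_train:])
    return np.sort(np.array(train_ids)), np.sort(np.array(test_ids))


@dataclass
class FoldAssignment:
    """A k-fold partition: per-item fold index plus train/test id lists."""

    k: int
    fold_index: np.ndarray  # shape (n,), values in [0, k)
    test_ids: list[np.ndarray]
    train_ids: list[np.ndarray]


def make_folds(dataset, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold partition with fold sizes differing by at most 1.

    Items are shuffled within each class and dealt round-robin across the
    concatenated class blocks, so every class is spread as evenly as
    possible over folds while overall fold sizes stay balanced.  Classes
    with fewer than k items trigger a stratification warning (they cannot
    appear in every fold's test set); k greater than the dataset size is an
    error.
    """
    labels = np.asarray(_labels_of(dataset))
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    small = [str(c) for c in classes if (labels == c).sum() < k]
    if small:
        warnings.warn(
            f"classes {small} have fewer than {k} images; they will be "
            "missing from some folds' test sets",
            stacklevel=2,
        )
    order = np.concatenate(
        [rng.permutation(np.nonzero(labels == c)[0]) for c in classes]
    )
    fold_index = np.empty(n, dtype=np.int64)
    fold_index[order] = np.arange(n) % k
    test_ids = [np.nonzero(fold_index == f)[0] for f in range(k)]
    train_ids = [np.nonzero(fold_index != f)[0] for f in range(k)]
    return FoldAssignment(k=k, fold_index=fold_index, test_ids=test_ids,
                          train_ids=train_ids)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionRecord:
    """One classified test image: identity, truth, and the full softmax."""

    item_id: int
    true_label: str
    probabilities: ClassProbabilities
    run: int

    @property
    def predicted_label(self) -> str:
        return self.probabilities.predicted_label


@dataclass
class CVRunResult:
    run: int
    history: TrainingHistory | None
    predictions: list[PredictionRecord]
    error: str | None = None


def run_cross_validation(
    dataset: LabeledDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainingConfig,
    folds: FoldAssignment,
    arrays: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[CVRunResult]:
    """Train/test once per fold; every image is classified exactly once.

    For each of the k runs a fresh model is built (seeded from
    ``train_cfg.seed`` plus the run index), trained on the fold's training
    ids, and applied to the fold's test ids; the full probability vector is
    stored per test image.  A failed run is recorded with its error message
    without aborting the remaining runs.  ``arrays`` can supply
    pre-extracted (x, y) — e.g. plate crops — to avoid reloading images.
    """
    x, y = arrays if arrays is not None else dataset.load_arrays()
    labels = dataset.labels
    results: list[CVRunResult] = []
    for run, (tr, te) in enumerate(zip(folds.train_ids, folds.test_ids)):
        try:
            model = build_model(model_cfg, seed=train_cfg.seed + 1000 * run)
            model.labels = list(labels)
            run_cfg = TrainingConfig(
                epochs=train_cfg.epochs,
                batch_size=train_cfg.batch_size,
                learning_rate=train_cfg.learning_rate,
                early_stopping_patience=train_cfg.early_stopping_patience,
                checkpoint_path=None,
                seed=train_cfg.seed + 1000 * run,
                augmentation=train_cfg.augmentation,
            )
            model, history = train_on_arrays(model, x[tr], y[tr], run_cfg)
            probs = model.network.predict_proba(x[te])
            preds = [
                PredictionRecord(
                    item_id=int(i),
                    true_label=labels[y[i]],
                    probabilities=ClassProbabilities(
                        probabilities={
                            lab: float(p) for lab, p in zip(labels, pv / pv.sum())
                        }
                    ),
                    run=run,
                )
                for i, pv in zip(te, probs)
            ]
            results.append(CVRunResult(run=run, history=history, predictions=preds))
        except Exception as exc:  # noqa: BLE001 - record and continue
            results.append(
                CVRunResult(run=run, history=None, predictions=[], error=str(exc))
            )
    return results


# ---------------------------------------------------------------------------
# confusion matrix and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = predicted species, columns = actual."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.labels)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape must match label count")
        if (self.matrix < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot add confusion matrices with different labels")
        return ConfusionMatrix(self.matrix + other.matrix, list(self.labels))

    def column_normalized(self) -> np.ndarray:
        """Per-actual-class percentages (columns sum to 100 where nonempty)."""
        col = self.matrix.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(col > 0, 100.0 * self.matrix / col, np.nan)
        return out


def confusion_from_predictions(
    predictions: Sequence[PredictionRecord] | Sequence[tuple[str, str]],
    labels: Sequence[str],
) -> ConfusionMatrix:
    """Count (predicted, actual) pairs into the rows-predicted orientation.

    Accepts PredictionRecords or plain (true_label, predicted_label) pairs.
    Summing per-run matrices equals the matrix of the pooled predictions.
    """
    labels = list(labels)
    pairs = [
        (p.true_label, p.predicted_label) if isinstance(p, PredictionRecord) else p
        for p in predictions
    ]
    for true, pred in pairs:
        if true not in labels or pred not in labels:
            raise ValueError(f"unknown label in prediction ({true!r}, {pred!r})")
    if not pairs:
        return ConfusionMatrix(np.zeros((len(labels), len(labels)), dtype=int), labels)
    y_true = [t for t, _ in pairs]
    y_pred = [p for _, p in pairs]
    # sklearn counts rows=true; transpose into rows=predicted
    mat = _sk_confusion(y_true, y_pred, labels=labels).T
    return ConfusionMatrix(mat, labels)


@dataclass(frozen=True)
class MetricsRow:
    """Seven per-species metrics; None marks an undefined (0/0) entry."""

    species: str
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    mcc: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {c: getattr(self, c) for c in METRIC_COLUMNS}


def metrics_from_counts(
    tp: int, fn: int, fp: int, tn: int, species: str = ""
) -> MetricsRow:
    """The seven one-vs-rest metrics from a 2x2 table.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/N, PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    F1 = 2·PPV·sens/(PPV+sens),
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Rates are percentages (0-100); F1 and MCC dimensionless.  A zero
    denominator makes that metric undefined (None), never 0.
    """
    counts = (tp, fn, fp, tn)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    tp, fn, fp, tn = (int(c) for c in counts)
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("all four counts are zero")

    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    acc = 100.0 * (tp + tn) / n
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2.0 * (ppv / 100.0) * (sens / 100.0) / ((ppv + sens) / 100.0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else None
    return MetricsRow(
        species=species, sensitivity=sens, specificity=spec, accuracy=acc,
        ppv=ppv, npv=npv, f1=f1, mcc=float(mcc) if mcc is not None else None,
    )


def one_vs_rest_binarize(
    confusion: ConfusionMatrix, species: str
) -> tuple[int, int, int, int]:
    """Collapse a multiclass confusion matrix to (tp, fn, fp, tn) for one
    species: tp is the diagonal cell, fn the rest of its actual column,
    fp the rest of its predicted row, tn everything else.  The four counts
    always sum to the grand total."""
    if species not in confusion.labels:
        raise ValueError(f"unknown species {species!r}")
    i = confusion.labels.index(species)
    m = confusion.matrix
    tp = int(m[i, i])
    fn = int(m[:, i].sum() - tp)
    fp = int(m[i, :].sum() - tp)
    tn = int(m.sum() - tp - fn - fp)
    return tp, fn, fp, tn


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    """One-vs-rest ROC for a species; undefined when a class side is empty."""

    species: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float | None
    defined: bool = True


def roc_ovr(
    predictions: Sequence[PredictionRecord], species: str
) -> ROCCurve:
    """One-vs-rest ROC over pooled predictions.

    Positives are test images of ``species``; the score is that species'
    softmax probability.  The threshold sweep yields monotone (FPR, TPR)
    points from (0,0) to (1,1); AUC is their trapezoidal area, which equals
    the Mann-Whitney pair statistic (ties counted 1/2).  If the pooled test
    data contain no positives or no negatives the curve is flagged
    undefined.
    """
    y = np.array([p.true_label == species for p in predictions], dtype=int)
    scores = np.array(
        [p.probabilities.probabilities.get(species, 0.0) for p in predictions]
    )
    if len(y) == 0 or y.sum() == 0 or y.sum() == len(y):
        return ROCCurve(
            species=species, fpr=np.array([]), tpr=np.array([]),
            auc=None, defined=False,
        )
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(species=species, fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------


def summarize_table(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    """Per-species metric rows plus an unweighted 'Average results' row.

    Each column of the average row is the arithmetic mean over species;
    undefined entries are skipped with a warning.  All values are rounded
    half-up to 2 decimal places (percentages and F1/MCC alike).
    """
    if not rows:
        raise ValueError("need at least one metrics row")
    records = []
    for row in rows:
        rec = {"species": row.species}
        rec.update(row.as_dict())
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    avg = {"species": "Average results"}
    for col in METRIC_COLUMNS:
        vals = [r[col] for r in records if r[col] is not None]
        if len(vals) < len(records):
            warnings.warn(
                f"column {col!r}: {len(records) - len(vals)} undefined "
                "entries skipped in the average",
                stacklevel=2,
            )
        avg[col] = float(np.mean(vals)) if vals else None
    df = pd.concat([df, pd.DataFrame.from_records([avg])], ignore_index=True)
    for col in METRIC_COLUMNS:
        df[col] = df[col].map(
            lambda v: round_half_up(v, 2) if v is not None and not pd.isna(v) else None
        )
    return df


def reconstruct_counts(
    row: MetricsRow,
    max_positives: int = 300,
    max_negatives: int = 600,
    tol: float = 0.0051,
) -> tuple[int, int, int, int] | None:
    """Search for integer (tp, fn, fp, tn) reproducing a printed metric row.

    Scans positive-support p = tp+fn and negative-support n = tn+fp,
    proposing tp and tn from the printed sensitivity/specificity and
    checking all seven metrics at printed (2 dp) precision.  Returns the
    first consistent quadruple, or None.  Used to validate that a reported
    table is internally consistent, and to recover MCC from rate-only rows.
    """
    def close(value: float | None, target: float | None) -> bool:
        if target is None:
            return True
        if value is None:
            return False
        return abs(value - target) <= tol

    for p in range(1, max_positives + 1):
        if row.sensitivity is None:
            continue
        tp = int(round(row.sensitivity / 100.0 * p))
        if not close(100.0 * tp / p, row.sensitivity):
            continue
        fn = p - tp
        for n in range(1, max_negatives + 1):
            if row.specificity is not None:
                tn = int(round(row.specificity / 100.0 * n))
                if not close(100.0 * tn / n, row.specificity):
                    continue
            else:
                tn = n
            fp = n - tn
            cand = metrics_from_counts(tp, fn, fp, tn)
            if (
                close(cand.accuracy, row.accuracy)
                and close(cand.ppv, row.ppv)
                and close(cand.npv, row.npv)
                and close(cand.f1, row.f1)
                and close(cand.mcc, row.mcc)
            ):
                return tp, fn, fp, tn
    return None


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def render_reports(
    histories: Sequence[TrainingHistory],
    confusion: ConfusionMatrix,
    table: pd.DataFrame,
    rocs: Sequence[ROCCurve],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three evaluation figures and the metrics CSV.

    Emits: ``training_curves.png`` (4 panels — accuracy, loss, validation
    accuracy, validation loss — one coloured line per run),
    ``confusion_heatmap.png`` (column-normalized, cells annotated
    "count (pct%)", darker = higher percentage), ``roc_curves.png`` (one
    curve per species with AUC in the legend plus the chance diagonal),
    and ``metrics.csv``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- training curves ---
    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    panels = [
        ("accuracy", "Accuracy"),
        ("loss", "Loss"),
        ("val_accuracy", "Validation accuracy"),
        ("val_loss", "Validation loss"),
    ]
    cmap = plt.get_cmap("tab10")
    for ax, (attr, title) in zip(axes.ravel(), panels):
        for i, h in enumerate(histories):
            series = getattr(h, attr)
            ax.plot(range(1, len(series) + 1), series,
                    color=cmap(i % 10), label=f"run {i + 1}")
        ax.set_title(title)
        ax.set_xlabel("epoch")
        ax.grid(alpha=0.3)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    paths["curves"] = out_dir / "training_curves.png"
    fig.savefig(paths["curves"], dpi=120)
    plt.close(fig)

    # --- confusion heatmap ---
    pct = confusion.column_normalized()
    k = len(confusion.labels)
    fig, ax = plt.subplots(figsize=(1.0 * k + 3, 1.0 * k + 2))
    im = ax.imshow(np.nan_to_num(pct), cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(k), confusion.labels, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(k), confusion.labels, fontsize=8)
    ax.set_xlabel("Actual species")
    ax.set_ylabel("Predicted species")
    for i in range(k):
        for j in range(k):
            val = pct[i, j]
            txt = f"{confusion.matrix[i, j]} ({0.0 if np.isnan(val) else val:.2f}%)"
            ax.text(j, i, txt, ha="center", va="center", fontsize=7,
                    color="white" if (not np.isnan(val) and val > 50) else "black")
    fig.colorbar(im, ax=ax, label="% of actual class")
    fig.tight_layout()
    paths["heatmap"] = out_dir / "confusion_heatmap.png"
    fig.savefig(paths["heatmap"], dpi=120)
    plt.close(fig)

    # --- ROC curves ---
    fig, ax = plt.subplots(figsize=(7, 6))
    for i, roc in enumerate(rocs):
        if not roc.defined:
            continue
        ax.plot(roc.fpr, roc.tpr, color=cmap(i % 10),
                label=f"{roc.species} (AUC = {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="chance (AUC = 0.50)")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=8)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    paths["roc"] = out_dir / "roc_curves.png"
    fig.savefig(paths["roc"], dpi=120)
    plt.close(fig)

    # --- metrics table ---
    paths["metrics"] = out_dir / "metrics.csv"
    table.to_csv(paths["metrics"], index=False)
    return paths
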