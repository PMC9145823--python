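"""DLD separation-mode classification: CNB vs KNN vs SVM-RBF.

Each run of the detection pipeline yields a 14-feature record — flow rate
(mL/min), nominal particle size (µm), and the fractions of detected
particles in each of the 12 outlets — labeled with the separation mode
(zigzag / mixed / bumped).  Three classifier families are trained and
compared under stratified 5-fold cross-validation; per family, the model
refit on the best-accuracy split's training data is the one persisted.
KNN additionally sweeps the neighbor count k over [2, 55] on every split
and keeps the smallest k attaining that split's maximum accuracy.

Distance-based families (KNN, SVM-RBF) standardize features inside each
split's training fold; complement naive Bayes consumes the raw features,
which are non-negative by construction (fractions plus positive flow
rate and size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import ComplementNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "MODES",
    "FAMILIES",
    "KNN_K_RANGE",
    "RunRecord",
    "ModeDataset",
    "TrainedModel",
    "EvaluationReport",
    "assemble_dataset",
    "stratified_splits",
    "train_model",
    "evaluate",
    "predict_mode",
    "save_model",
    "load_model",
    "StratificationError",
    "LabelingError",
    "ConfigurationError",
]

MODES = ("zigzag", "mixed", "bumped")
FAMILIES = ("CNB", "KNN", "SVM_RBF")
KNN_K_RANGE = (2, 55)
N_FEATURES = 14

CSV_COLUMNS = (
    ["flow_rate_ml_min", "particle_size_um"]
    + [f"outlet_{i:02d}" for i in range(1, 13)]
    + ["mode"]
)


class StratificationError(ValueError):
    """A class has too few members for the requested fold count."""


class LabelingError(ValueError):
    """A record is missing or carries an unknown mode label."""


class ConfigurationError(ValueError):
    """Unknown classifier family or invalid training configuration."""


@dataclass(frozen=True)
class RunRecord:
    """One labeled run: operating conditions plus the outlet distribution
    as fractions of the total detected particles."""

    flow_rate: float
    particle_size: float
    distribution: tuple[float, ...]
    mode: str

    def __post_init__(self) -> None:
        if self.flow_rate <= 0 or self.particle_size <= 0:
            raise ValueError("flow_rate and particle_size must be positive")
        if len(self.distribution) != 12:
            raise ValueError("distribution must have 12 outlet fractions")
        if min(self.distribution) < -1e-9:
            raise ValueError("distribution fractions must be non-negative")
        if self.mode not in MODES:
            raise LabelingError(f"unknown mode label {self.mode!r}")

    def features(self) -> np.ndarray:
        return np.array(
            [self.flow_rate, self.particle_size, *self.distribution], dtype=float
        )


class ModeDataset:
    """A list of :class:`RunRecord` plus its n×14 feature matrix."""

    def __init__(self, records: list[RunRecord]):
        if not records:
            raise ValueError("empty dataset")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def feature_matrix(self) -> np.ndarray:
        return np.stack([r.features() for r in self.records])

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.mode for r in self.records])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                [r.flow_rate, r.particle_size, *r.distribution, r.mode]
                for r in self.records
            ],
            columns=CSV_COLUMNS,
        )
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ModeDataset":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset CSV missing columns: {missing}")
        records = []
        for i, row in df.iterrows():
            try:
                records.append(
                    RunRecord(
                        flow_rate=float(row["flow_rate_ml_min"]),
                        particle_size=float(row["particle_size_um"]),
                        distribution=tuple(
                            float(row[f"outlet_{j:02d}"]) for j in range(1, 13)
                        ),
                        mode=str(row["mode"]),
                    )
                )
            except (ValueError, LabelingError) as exc:
                raise ValueError(f"bad dataset row {i}: {exc}") from exc
        return cls(records)


def assemble_dataset(summaries) -> ModeDataset:
    """Build a :class:`ModeDataset` from detection-run summaries.

    ``summaries`` is an iterable of (RunSummary, flow_rate, particle_size,
    mode) tuples; per-outlet counts are converted to fractions of the
    assigned total.  Zero-total summaries are excluded with a warning.
    """
    import warnings

    records = []
    for summary, flow, size, mode in summaries:
        if mode is None:
            raise LabelingError("summary without a mode label")
        total = float(np.sum(summary.counts))
        if total == 0:
            warnings.warn("excluding zero-total run summary", stacklevel=2)
            continue
        counts = np.asarray(summary.counts, dtype=float)
        if len(counts) != 12:
            raise ValueError("run summary must cover 12 outlets")
        records.append(
            RunRecord(flow, size, tuple(counts / total), mode)
        )
    return ModeDataset(records)


def stratified_splits(
    dataset: ModeDataset, folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train_idx, test_idx) pairs; every fold serves
    once as the test set and class proportions are preserved as closely
    as integer counts allow."""
    y = dataset.labels
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < folds]
    if small.size:
        raise StratificationError(
            f"classes {list(small)} have fewer than {folds} records"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass
class TrainedModel:
    """A persisted classifier: the estimator refit on the training part of
    the best-accuracy CV split, plus the full CV accounting."""

    family: str
    estimator: object
    split_accuracies: list[float]
    best_split_index: int
    best_split_test_idx: np.ndarray
    seed: int
    chosen_k: int | None = None
    chosen_k_per_split: list[int] | None = None

    @property
    def best_split_accuracy(self) -> float:
        return max(self.split_accuracies)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature vector length {X.shape[1]}, expected {N_FEATURES}"
            )
        return self.estimator.predict(X)


def _make_estimator(family: str, k: int | None = None):
    if family == "CNB":
        return ComplementNB()
    if family == "KNN":
        return Pipeline(
            [("scale", StandardScaler()),
             ("knn", KNeighborsClassifier(n_neighbors=k or 5))]
        )
    if family == "SVM_RBF":
        return Pipeline(
            [("scale", StandardScaler()),
             ("svm", SVC(kernel="rbf", C=1.0, gamma="scale"))]
        )
    raise ConfigurationError(f"unknown classifier family {family!r}")


def train_model(
    dataset: ModeDataset,
    family: str,
    folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Cross-validate one classifier family and keep the best split's model.

    For every stratified split the family is fitted on the training part
    and scored on the test part.  KNN sweeps k over [2, 55] (capped at the
    training-fold size) per split, keeping the smallest k that attains the
    split's maximum accuracy.  The persisted estimator is refit on the
    training data of the highest-accuracy split (ties go to the lowest
    split index).
    """
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown classifier family {family!r}")
    X, y = dataset.feature_matrix, dataset.labels
    splits = stratified_splits(dataset, folds, seed)
    accs: list[float] = []
    ks: list[int] = []
    for tr, te in splits:
        if family == "KNN":
            k_lo, k_hi = KNN_K_RANGE
            k_hi = min(k_hi, len(tr))
            best_acc, best_k = -1.0, k_lo
            for k in range(k_lo, k_hi + 1):
                est = _make_estimator("KNN", k)
                est.fit(X[tr], y[tr])
                a = accuracy_score(y[te], est.predict(X[te]))
                if a > best_acc:  # strict: smallest k wins ties
                    best_acc, best_k = a, k
            accs.append(float(best_acc))
            ks.append(best_k)
        else:
            est = _make_estimator(family)
            est.fit(X[tr], y[tr])
            accs.append(float(accuracy_score(y[te], est.predict(X[te]))))
    best = int(np.argmax(accs))  # first max -> lowest split index
    tr, te = splits[best]
    chosen_k = ks[best] if family == "KNN" else None
    final = _make_estimator(family, chosen_k)
    final.fit(X[tr], y[tr])
    return TrainedModel(
        family=family,
        estimator=final,
        split_accuracies=accs,
        best_split_index=best,
        best_split_test_idx=np.asarray(te),
        seed=seed,
        chosen_k=chosen_k,
        chosen_k_per_split=ks if family == "KNN" else None,
    )


@dataclass
class EvaluationReport:
    """Confusion matrix (rows = true, cols = predicted, mode order
    zigzag/mixed/bumped) and the per-class classification report."""

    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float

    def to_json_dict(self) -> dict:
        return {
            "modes": list(MODES),
            "confusion_matrix": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "accuracy": self.accuracy,
        }

    def __str__(self) -> str:
        lines = ["mode      precision  recall  f1      support"]
        for m in MODES:
            lines.append(
                f"{m:<9} {self.precision[m]:9.3f} {self.recall[m]:7.3f} "
                f"{self.f1[m]:7.3f} {self.support[m]:8d}"
            )
        lines.append(f"accuracy  {self.accuracy:.3f}")
        lines.append("confusion (rows true / cols predicted, "
                     + "/".join(MODES) + "):")
        for row in self.confusion:
            lines.append("  " + "  ".join(f"{v:4d}" for v in row))
        return "\n".join(lines)


def evaluate(model: TrainedModel, records: list[RunRecord]) -> EvaluationReport:
    """Score a fitted model on labeled records."""
    if not records:
        raise ValueError("empty test set")
    X = np.stack([r.features() for r in records])
    y_true = np.array([r.mode for r in records])
    y_pred = model.predict(X)
    cm = confusion_matrix(y_true, y_pred, labels=list(MODES))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=list(MODES), zero_division=0
    )
    return EvaluationReport(
        confusion=cm,
        precision={m: float(p) for m, p in zip(MODES, prec)},
        recall={m: float(r) for m, r in zip(MODES, rec)},
        f1={m: float(v) for m, v in zip(MODES, f1)},
        support={m: int(s) for m, s in zip(MODES, supp)},
        accuracy=float(accuracy_score(y_true, y_pred)),
    )


def predict_mode(
    model: TrainedModel,
    flow_rate: float,
    particle_size: float,
    distribution,
) -> str:
    """Predict the separation mode for one run."""
    dist = np.asarray(distribution, dtype=float)
    if dist.shape != (12,):
        raise ValueError("distribution must have 12 entries")
    x = np.array([flow_rate, particle_size, *dist])
    return str(model.predict(x)[0])


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist the estimator (joblib) with a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, path)
    meta = {
        "family": model.family,
        "seed": model.seed,
        "split_accuracies": model.split_accuracies,
        "best_split_index": model.best_split_index,
        "best_split_test_idx": [int(i) for i in model.best_split_test_idx],
        "chosen_k": model.chosen_k,
        "chosen_k_per_split": model.chosen_k_per_split,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"model metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("family") not in FAMILIES:
        raise ValueError(f"model/metadata mismatch: bad family {meta.get('family')!r}")
    est = joblib.load(path)
    return TrainedModel(
        family=meta["family"],
        estimator=est,
        split_accuracies=meta["split_accuracies"],
        best_split_index=meta["best_split_index"],
        best_split_test_idx=np.asarray(meta["best_split_test_idx"]),
        seed=meta["seed"],
        chosen_k=meta["chosen_k"],
        chosen_k_per_split=meta["chosen_k_per_split"],
    )
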