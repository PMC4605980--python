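"""Multivariate pattern recognition on bucket matrices.

PLS-CA: partial least squares against a one-hot class response followed by a
Fisher linear discriminant on the latent scores; prediction is nearest class
in canonical space. MPLS: the same classifier applied to the within-subject
part of a paired design after subject-mean centering, so between-subject
variation is removed and only treatment-related within-subject variation
drives the model. Performance is estimated by Monte-Carlo cross-validation —
repeated random stratified train/test splits with pooled confusion counts —
resampling subjects (not samples) in the paired case so a subject's pre/post
pair never straddles the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import PairingError
from .spectra import BucketMatrix

TIMEPOINTS = ("pre", "post")


@dataclass(frozen=True)
class SampleAnnotation:
    """Design factors for one sample."""

    sample_id: str
    subject_id: str
    group: str
    timepoint: str = "pre"
    anesthetic: str = ""
    drugs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")


def annotations_from_dataframe(df: pd.DataFrame) -> list[SampleAnnotation]:
    required = {"sample_id", "subject_id", "group", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        drugs = row.get("drugs", "")
        drugs = tuple(d for d in str(drugs).split(";") if d and d != "nan")
        out.append(SampleAnnotation(
            sample_id=str(row["sample_id"]), subject_id=str(row["subject_id"]),
            group=str(row["group"]), timepoint=str(row["timepoint"]),
            anesthetic=str(row.get("anesthetic", "")), drugs=drugs))
    return out


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, BucketMatrix):
        return matrix.values
    return np.atleast_2d(np.asarray(matrix, dtype=float))


@dataclass
class LatentModel:
    """Fitted latent-variable model (PCA or PLS-CA/MPLS).

    ``loadings`` has one column per latent component; for supervised models
    ``discriminant_weights`` maps original variables to the canonical axis
    (per-variable influence on the class decision).
    """

    kind: str
    n_components: int
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray | None = None
    classes: np.ndarray | None = None
    class_means_canonical: np.ndarray | None = None
    discriminant_weights: np.ndarray | None = None
    preprocessing: dict = field(default_factory=dict)
    _pls: PLSRegression | None = None
    _lda: LinearDiscriminantAnalysis | None = None

    def transform(self, X) -> np.ndarray:
        X = _as_array(X)
        if self._pls is not None:
            return self._pls.transform(X)
        mean = self.preprocessing.get("mean")
        return (X - mean) @ self.loadings

    def predict(self, X) -> np.ndarray:
        if self._lda is None:
            raise ValueError("predict requires a supervised (PLS-CA/MPLS) model")
        return self._lda.predict(self.transform(X))


def pca(matrix, n_components: int = 2) -> LatentModel:
    """Principal component analysis of a (mean-centered) bucket matrix."""
    X = _as_array(matrix)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X)
    return LatentModel(
        kind="pca", n_components=n_components,
        loadings=model.components_.T, scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        preprocessing={"mean": model.mean_, "scale": None})


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (labels[:, None] == classes[None, :]).astype(float)


def pls_ca_fit(matrix, labels: Sequence[str], n_components: int = 2) -> LatentModel:
    """PLS dimension reduction against class membership + canonical analysis.

    Columns are mean-centered (no unit-variance scaling: the buckets are
    already total-area normalized). A linear discriminant is fit on the PLS
    score space; prediction is the nearest class in that canonical space.
    """
    X = _as_array(matrix)
    y = np.asarray(labels)
    if y.size != X.shape[0]:
        raise ValueError("labels length must match number of rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("PLS-CA requires at least 2 classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, _one_hot(y, classes))
    scores = pls.x_scores_
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, y)
    class_means = lda.transform(lda.means_)
    # per-variable influence on the canonical axes
    weights = pls.x_rotations_ @ lda.scalings_[:, : max(1, classes.size - 1)]
    return LatentModel(
        kind="pls-ca", n_components=n_components,
        loadings=pls.x_rotations_, scores=scores,
        classes=classes, class_means_canonical=class_means,
        discriminant_weights=weights,
        preprocessing={"mean": X.mean(axis=0), "scale": None},
        _pls=pls, _lda=lda)


# ---------------------------------------------------------------------------
# Multilevel (paired) analysis


@dataclass
class MultilevelSplit:
    """Decomposition of a paired matrix into between- and within-subject parts.

    ``between[subject_index[i]] + within[i]`` reconstructs row ``i`` exactly.
    """

    between: np.ndarray  # n_subjects x n_bins subject means
    within: np.ndarray   # n_samples x n_bins, row minus its subject mean
    subjects: list[str]
    subject_index: np.ndarray  # row -> subject position
    timepoints: np.ndarray     # row -> "pre" | "post"


def multilevel_split(matrix, annotations: Sequence[SampleAnnotation]) -> MultilevelSplit:
    """Subject-mean centering for a paired pre/post design.

    Every subject must contribute exactly one ``pre`` and one ``post`` row;
    within-subject rows of a pair are exact negatives of each other.
    """
    X = _as_array(matrix)
    if len(annotations) != X.shape[0]:
        raise ValueError("annotations length must match matrix rows")
    subjects: list[str] = []
    seen: dict[str, dict[str, int]] = {}
    for i, ann in enumerate(annotations):
        rec = seen.setdefault(ann.subject_id, {})
        if ann.timepoint in rec:
            raise PairingError(ann.subject_id,
                               f"subject {ann.subject_id!r} has duplicate "
                               f"{ann.timepoint!r} samples")
        rec[ann.timepoint] = i
        if ann.subject_id not in subjects:
            subjects.append(ann.subject_id)
    for subj in subjects:
        if set(seen[subj]) != set(TIMEPOINTS):
            raise PairingError(subj)
    pos = {s: k for k, s in enumerate(subjects)}
    subject_index = np.array([pos[a.subject_id] for a in annotations])
    between = np.zeros((len(subjects), X.shape[1]))
    for subj, rec in seen.items():
        between[pos[subj]] = X[list(rec.values())].mean(axis=0)
    within = X - between[subject_index]
    timepoints = np.array([a.timepoint for a in annotations])
    return MultilevelSplit(between=between, within=within, subjects=subjects,
                           subject_index=subject_index, timepoints=timepoints)


def mpls_fit(matrix, annotations: Sequence[SampleAnnotation],
             n_components: int = 2) -> LatentModel:
    """Multilevel PLS: PLS-CA on the within-subject part with timepoint labels."""
    split = multilevel_split(matrix, annotations)
    model = pls_ca_fit(split.within, split.timepoints, n_components)
    model.kind = "mpls"
    return model


# ---------------------------------------------------------------------------
# Performance reporting


def report_rates(confusion: np.ndarray, positive_index: int = 0,
                 ) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity (%) from a 2x2 confusion matrix.

    Rows are true classes, columns predicted, ordered consistently; row
    ``positive_index`` is the positive class. Undefined rates (zero
    denominator) are reported as NaN rather than 0.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (2, 2):
        raise ValueError("report_rates expects a 2x2 confusion matrix")
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion matrix must have positive total")
    p, n = positive_index, 1 - positive_index
    tp, fn = confusion[p, p], confusion[p, n]
    fp, tn = confusion[n, p], confusion[n, n]
    accuracy = (tp + tn) / total * 100.0
    sensitivity = tp / (tp + fn) * 100.0 if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) * 100.0 if (tn + fp) > 0 else float("nan")
    return accuracy, sensitivity, specificity


@dataclass
class CVReport:
    """Monte-Carlo cross-validation outcome with pooled confusion counts."""

    confusion: np.ndarray
    classes: np.ndarray
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    n_iterations: int
    test_fraction: float
    seed: int
    model_kind: str
    positive_label: str
    component_counts: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "classes": self.classes.tolist(),
            "positive_label": self.positive_label,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_iterations": self.n_iterations,
            "test_fraction": self.test_fraction,
            "seed": self.seed,
            "component_counts": {str(k): v for k, v in self.component_counts.items()},
        }


def _stratified_split(y: np.ndarray, test_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split; every class keeps >= 1 test and >= 2 train rows."""
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * idx.size)))
        if idx.size - n_test < 2:
            raise ValueError(f"class {cls!r} too small for test_fraction "
                             f"{test_fraction}")
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.concatenate(train), np.concatenate(test)


def select_n_components(X: np.ndarray, y: np.ndarray, max_components: int = 10,
                        n_folds: int = 5, seed: int = 0) -> int:
    """Pick the PLS component count by stratified k-fold CV accuracy.

    Ties break toward the smaller model.
    """
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    folds = [[] for _ in range(n_folds)]
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(i)
    folds = [np.array(f) for f in folds if len(f) > 0]
    upper = min(max_components, X.shape[0] - 1 - max(len(f) for f in folds),
                X.shape[1])
    upper = max(upper, 1)
    best_k, best_acc = 1, -1.0
    for k in range(1, upper + 1):
        correct = total = 0
        ok = True
        for f in folds:
            mask = np.ones(X.shape[0], dtype=bool)
            mask[f] = False
            ytr = y[mask]
            if np.unique(ytr).size < classes.size or np.bincount(
                    np.searchsorted(classes, ytr)).min() < 2:
                ok = False
                break
            model = pls_ca_fit(X[mask], ytr, n_components=k)
            correct += int((model.predict(X[f]) == y[f]).sum())
            total += f.size
        if not ok:
            continue
        acc = correct / total
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    return best_k


def _subjects_by_group(annotations: Sequence[SampleAnnotation]) -> dict[str, str]:
    return {a.subject_id: a.group for a in annotations}


def monte_carlo_cv(matrix, labels_or_annotations, model_kind: str = "pls-ca",
                   n_iterations: int = 500, test_fraction: float = 0.1,
                   seed: int = 0, n_components: int | None = None,
                   max_components: int = 10, positive_label: str | None = None,
                   ) -> CVReport:
    """Monte-Carlo cross-validation of a PLS-CA or MPLS classifier.

    Each iteration draws a random stratified train/test split, fits on the
    training part only, predicts the held-out part and accumulates pooled
    confusion counts. For ``mpls`` the resampling unit is the subject, so a
    pre/post pair never straddles the split; held-out pairs are centered on
    their own pair mean before prediction. ``n_components=None`` selects the
    component count by inner 5-fold CV inside every training split.
    """
    if model_kind not in ("pls-ca", "mpls"):
        raise ValueError("model_kind must be 'pls-ca' or 'mpls'")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    X = _as_array(matrix)
    rng = np.random.default_rng(seed)
    component_counts: dict[int, int] = {}

    if model_kind == "pls-ca":
        y = np.asarray(labels_or_annotations)
        if y.dtype == object and y.size and isinstance(y.ravel()[0], SampleAnnotation):
            y = np.array([a.group for a in labels_or_annotations])
        classes = np.unique(y)
        confusion = np.zeros((classes.size, classes.size), dtype=int)
        for _ in range(n_iterations):
            tr, te = _stratified_split(y, test_fraction, rng)
            k = n_components or select_n_components(
                X[tr], y[tr], max_components,
                seed=int(rng.integers(0, 2 ** 31 - 1)))
            component_counts[k] = component_counts.get(k, 0) + 1
            model = pls_ca_fit(X[tr], y[tr], n_components=k)
            pred = model.predict(X[te])
            for t, p in zip(y[te], pred):
                confusion[np.searchsorted(classes, t),
                          np.searchsorted(classes, p)] += 1
    else:
        annotations = list(labels_or_annotations)
        split = multilevel_split(X, annotations)
        classes = np.unique(split.timepoints)
        n_subj = len(split.subjects)
        subj_rows = {k: np.flatnonzero(split.subject_index == k)
                     for k in range(n_subj)}
        confusion = np.zeros((classes.size, classes.size), dtype=int)
        for _ in range(n_iterations):
            order = rng.permutation(n_subj)
            n_test = max(1, int(round(test_fraction * n_subj)))
            if n_subj - n_test < 2:
                raise ValueError("too few subjects for test_fraction")
            test_subj, train_subj = order[:n_test], order[n_test:]
            tr = np.concatenate([subj_rows[k] for k in train_subj])
            te = np.concatenate([subj_rows[k] for k in test_subj])
            # within-part of the training subjects only
            Xw_tr = split.within[tr]
            y_tr = split.timepoints[tr]
            k = n_components or select_n_components(
                Xw_tr, y_tr, max_components,
                seed=int(rng.integers(0, 2 ** 31 - 1)))
            component_counts[k] = component_counts.get(k, 0) + 1
            model = pls_ca_fit(Xw_tr, y_tr, n_components=k)
            # held-out pairs centered on their own pair mean (within-subject)
            Xw_te = split.within[te]
            pred = model.predict(Xw_te)
            for t, p in zip(split.timepoints[te], pred):
                confusion[np.searchsorted(classes, t),
                          np.searchsorted(classes, p)] += 1

    total = confusion.sum()
    accuracy = float(np.trace(confusion)) / total * 100.0
    sensitivity = specificity = None
    pos = positive_label if positive_label is not None else str(sorted(classes)[0])
    if classes.size == 2:
        pos_idx = int(np.flatnonzero(classes == pos)[0]) if pos in classes else 0
        accuracy, sensitivity, specificity = report_rates(confusion, pos_idx)
    return CVReport(confusion=confusion, classes=classes, accuracy=accuracy,
                    sensitivity=sensitivity, specificity=specificity,
                    n_iterations=n_iterations, test_fraction=test_fraction,
                    seed=seed, model_kind=model_kind, positive_label=pos,
                    component_counts=component_counts)
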