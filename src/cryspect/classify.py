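"""Two-group cry classification from fixed-length meter vectors.

Each recording contributes one instance: the first 30 s of its VU or PPM
trace, i.e. 300 values at 10 frames/s (shorter recordings are
right-padded with 0 U silence), labeled with the study group M or C.
Datasets round-trip through standard ARFF files.  Four classifier
families are provided — a single-nearest-neighbor learner (IB1), an
unpruned random tree, a decision table with greedy forward attribute
selection, and a nearest-generalized-exemplar learner (NNGE) — evaluated
under three protocols (training data, stratified 10-fold
cross-validation, 75% percentage split) with the canonical quality
quartet MAE / RMSE / RAE / RRSE plus accuracy and a confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import MeterTrace, Waveform, compute_ppm, compute_vu

CLASSIFIER_KINDS = ("RT", "DT", "IB1", "NNGE")
PROTOCOLS = ("training", "cv10", "split75")


class ArffParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class FeatureDataset:
    """Instances of fixed-length meter vectors (U) with a nominal class."""

    X: np.ndarray  # (n_instances, n_attributes)
    y: np.ndarray  # (n_instances,) of class labels
    meter: str  # "VU" or "PPM"
    attribute_names: list[str]
    classes: tuple[str, ...] = ("M", "C")
    relation: str = "cry"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        self.y = np.asarray(self.y, dtype=object)
        if self.X.shape[0] != self.y.size and not (self.X.size == 0 and self.y.size == 0):
            raise ValueError("X and y lengths differ")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("feature values must be finite (no missing values)")
        if self.y.size and not set(self.y) <= set(self.classes):
            raise ValueError("labels outside the declared class set")

    @property
    def n_instances(self) -> int:
        return int(self.y.size)

    @property
    def n_attributes(self) -> int:
        return self.X.shape[1] if self.X.size else len(self.attribute_names)


def build_feature_vectors(
    records: Sequence,
    meter: str = "VU",
    window_s: float = 30.0,
    frame_ms: float = 100.0,
) -> FeatureDataset:
    """One instance per recording: the first ``window_s`` of its meter trace.

    ``records`` are (waveform, metadata, ...) tuples (precomputed
    :class:`MeterTrace` objects in place of waveforms are accepted).
    Recordings longer than the window are truncated; shorter ones are
    right-padded with 0 U (silence).  The class label is the metadata
    group.
    """
    if meter not in ("VU", "PPM"):
        raise ValueError("meter must be 'VU' or 'PPM'")
    if not records:
        raise ValueError("empty cohort")
    n_attr = int(round(window_s * 1000.0 / frame_ms))
    rows, labels = [], []
    for rec in records:
        source, metadata = rec[0], rec[1]
        if isinstance(source, MeterTrace):
            trace = source
        elif isinstance(source, Waveform):
            trace = (compute_vu if meter == "VU" else compute_ppm)(source, frame_ms)
        else:
            raise TypeError(f"cannot extract a meter trace from {type(source)!r}")
        if trace.n_frames < 1:
            raise ValueError("recording shorter than one meter frame")
        v = trace.values[:n_attr]
        if v.size < n_attr:
            v = np.pad(v, (0, n_attr - v.size))
        rows.append(v)
        labels.append(metadata.group)
    names = [f"{meter.lower()}_{i:03d}" for i in range(n_attr)]
    return FeatureDataset(
        X=np.vstack(rows), y=np.array(labels, dtype=object), meter=meter,
        attribute_names=names, relation=f"cry_{meter.lower()}",
    )


# ---------------------------------------------------------------------------
# ARFF


def write_arff(d: FeatureDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"@relation {d.relation}\n\n")
        for name in d.attribute_names:
            fh.write(f"@attribute {name} numeric\n")
        fh.write(f"@attribute class {{{','.join(d.classes)}}}\n\n@data\n")
        for row, label in zip(d.X, d.y):
            fh.write(",".join(repr(float(v)) for v in row) + f",{label}\n")


def read_arff(path) -> FeatureDataset:
    relation = "cry"
    names: list[str] = []
    classes: tuple[str, ...] | None = None
    rows, labels = [], []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if not in_data:
                if low.startswith("@relation"):
                    parts = line.split(None, 1)
                    if len(parts) < 2:
                        raise ArffParseError("@relation needs a name", lineno)
                    relation = parts[1]
                elif low.startswith("@attribute"):
                    parts = line.split(None, 2)
                    if len(parts) < 3:
                        raise ArffParseError("malformed @attribute", lineno)
                    _, name, kind = parts
                    kind = kind.strip()
                    if kind.startswith("{"):
                        if not kind.endswith("}"):
                            raise ArffParseError("unterminated nominal spec", lineno)
                        classes = tuple(v.strip() for v in kind[1:-1].split(","))
                    elif kind.lower() in ("numeric", "real", "integer"):
                        names.append(name)
                    else:
                        raise ArffParseError(f"unsupported attribute type {kind!r}", lineno)
                elif low.startswith("@data"):
                    if classes is None:
                        raise ArffParseError("@data before a nominal class attribute", lineno)
                    in_data = True
                else:
                    raise ArffParseError(f"unexpected header line {line!r}", lineno)
            else:
                fields = [f.strip() for f in line.split(",")]
                if len(fields) != len(names) + 1:
                    raise ArffParseError(
                        f"expected {len(names) + 1} fields, got {len(fields)}", lineno)
                try:
                    rows.append([float(v) for v in fields[:-1]])
                except ValueError as exc:
                    raise ArffParseError(str(exc), lineno) from None
                if fields[-1] not in classes:
                    raise ArffParseError(f"unknown class {fields[-1]!r}", lineno)
                labels.append(fields[-1])
    if classes is None:
        raise ArffParseError("no class attribute found", 0)
    meter = "PPM" if "ppm" in relation.lower() else "VU"
    X = np.array(rows, dtype=np.float64) if rows else np.zeros((0, len(names)))
    return FeatureDataset(X=X, y=np.array(labels, dtype=object), meter=meter,
                          attribute_names=names, classes=classes, relation=relation)


# ---------------------------------------------------------------------------
# classifiers


class _Classifier:
    classes_: np.ndarray

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Classifier":
        raise NotImplementedError

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def _set_classes(self, y: np.ndarray, classes: Sequence[str] | None) -> None:
        if classes is not None:
            self.classes_ = np.asarray(classes, dtype=object)
        else:
            self.classes_ = np.asarray(sorted(set(y)), dtype=object)


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros((labels.size, classes.size))
    for r, lab in enumerate(labels):
        out[r, idx[lab]] = 1.0
    return out


class IB1Classifier(_Classifier):
    """Single nearest neighbor, Euclidean distance, first-found tie-break."""

    def __init__(self, classes: Sequence[str] | None = None):
        self._classes_arg = classes

    def fit(self, X, y):
        self.X_, self.y_ = np.asarray(X, dtype=float), np.asarray(y, dtype=object)
        self._set_classes(self.y_, self._classes_arg)
        return self

    def predict_proba(self, X):
        d = cdist(np.asarray(X, dtype=float), self.X_, metric="euclidean")
        nearest = np.argmin(d, axis=1)  # first occurrence on ties
        return _one_hot(self.y_[nearest], self.classes_)


class RandomTreeClassifier(_Classifier):
    """Unpruned decision tree on K randomly sampled attributes per node.

    K = ceil(log2(p) + 1); splits maximize information gain and the tree
    is grown until leaves are pure, so duplicate-free training data are
    memorized exactly.
    """

    def __init__(self, seed: int = 0, classes: Sequence[str] | None = None):
        self.seed = seed
        self._classes_arg = classes

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self._set_classes(y, self._classes_arg)
        k = int(math.ceil(math.log2(max(X.shape[1], 2)) + 1))
        self._tree = DecisionTreeClassifier(
            criterion="entropy", max_features=min(k, X.shape[1]),
            random_state=self.seed)
        self._tree.fit(X, y.astype(str))
        return self

    def predict_proba(self, X):
        proba = self._tree.predict_proba(np.asarray(X, dtype=float))
        order = [list(self._tree.classes_).index(str(c)) for c in self.classes_]
        return proba[:, order]


class PriorBaselineClassifier(_Classifier):
    """Predicts the training class distribution for every instance."""

    def __init__(self, classes: Sequence[str] | None = None):
        self._classes_arg = classes

    def fit(self, X, y):
        y = np.asarray(y, dtype=object)
        self._set_classes(y, self._classes_arg)
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        return self

    def predict_proba(self, X):
        return np.tile(self.priors_, (np.asarray(X).shape[0], 1))


class DecisionTableClassifier(_Classifier):
    """Lookup table over a greedily selected attribute subset.

    Attributes are discretized into equal-width bins (from the training
    range); forward selection adds the attribute that most improves
    leave-one-out accuracy of the table, stopping when no attribute
    helps.  Rows not matched by the table fall back to the majority
    class.
    """

    def __init__(self, n_bins: int = 10, max_attributes: int = 25,
                 classes: Sequence[str] | None = None):
        self.n_bins = n_bins
        self.max_attributes = max_attributes
        self._classes_arg = classes

    def _bin(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.hi_ > self.lo_, self.hi_ - self.lo_, 1.0)
        b = np.floor((X - self.lo_) / span * self.n_bins).astype(int)
        return np.clip(b, 0, self.n_bins - 1)

    def _table_scores(self, B: np.ndarray, yi: np.ndarray,
                      attrs: list[int]) -> tuple[float, float]:
        """(leave-one-out accuracy, resubstitution accuracy) of a table."""
        n, k = yi.size, self.classes_.size
        keys: dict[tuple, np.ndarray] = {}
        if attrs:
            for i in range(n):
                key = tuple(B[i, attrs])
                keys.setdefault(key, np.zeros(k))[yi[i]] += 1
        total = np.bincount(yi, minlength=k).astype(float)
        loo_correct = fit_correct = 0
        for i in range(n):
            if attrs:
                cell = keys[tuple(B[i, attrs])]
                loo_cell = cell - _unit(k, yi[i])
                loo_counts = loo_cell if loo_cell.sum() > 0 else total - _unit(k, yi[i])
                fit_counts = cell
            else:
                loo_counts = total - _unit(k, yi[i])
                fit_counts = total
            if int(np.argmax(loo_counts)) == yi[i]:
                loo_correct += 1
            if int(np.argmax(fit_counts)) == yi[i]:
                fit_correct += 1
        return loo_correct / n, fit_correct / n

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self._set_classes(y, self._classes_arg)
        cls_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([cls_index[v] for v in y])
        self.lo_, self.hi_ = X.min(axis=0), X.max(axis=0)
        B = self._bin(X)
        selected: list[int] = []
        # score = (LOO accuracy, training accuracy); the second component
        # breaks LOO ties so separable data are still memorized
        best = self._table_scores(B, yi, selected)
        improved = True
        while improved and len(selected) < self.max_attributes:
            improved = False
            best_attr, best_score = -1, best
            for a in range(X.shape[1]):
                if a in selected:
                    continue
                score = self._table_scores(B, yi, selected + [a])
                if (score[0] > best_score[0] + 1e-12
                        or (score[0] > best_score[0] - 1e-12
                            and score[1] > best_score[1] + 1e-12)):
                    best_attr, best_score = a, score
            if best_attr >= 0:
                selected.append(best_attr)
                best = best_score
                improved = True
        self.attributes_ = selected
        self.table_ = {}
        k = self.classes_.size
        for i in range(yi.size):
            key = tuple(B[i, selected])
            self.table_.setdefault(key, np.zeros(k))[yi[i]] += 1
        self.priors_ = np.bincount(yi, minlength=k).astype(float)
        return self

    def predict_proba(self, X):
        B = self._bin(np.asarray(X, dtype=float))
        out = np.zeros((B.shape[0], self.classes_.size))
        for i in range(B.shape[0]):
            counts = self.table_.get(tuple(B[i, self.attributes_]), self.priors_)
            out[i] = counts / counts.sum()
        return out


def _unit(k: int, j: int) -> np.ndarray:
    u = np.zeros(k)
    u[j] = 1.0
    return u


class NNGEClassifier(_Classifier):
    """Nearest-neighbor with generalized exemplars (axis-aligned boxes).

    Training is incremental: each instance either extends its nearest
    same-class exemplar into a hyperrectangle covering it (rejected if
    the extension would swallow an opposite-class instance) or is stored
    as a new point exemplar.  An instance falling inside an
    opposite-class rectangle first splits that rectangle to exclude it,
    which keeps the learner consistent on its training data.  Distances
    are Euclidean over per-dimension distances to the box, normalized by
    the training attribute ranges.
    """

    def __init__(self, classes: Sequence[str] | None = None):
        self._classes_arg = classes

    def _rect_dist(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([e[0] for e in self.exemplars_])
        hi = np.array([e[1] for e in self.exemplars_])
        d = np.maximum(np.maximum(lo - x, x - hi), 0.0) / self.range_
        return np.sqrt((d * d).sum(axis=1))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self._set_classes(y, self._classes_arg)
        rng_span = X.max(axis=0) - X.min(axis=0)
        self.range_ = np.where(rng_span > 0, rng_span, 1.0)
        # exemplar: [lo, hi, label]
        self.exemplars_: list[list] = []
        seen_X: list[np.ndarray] = []
        seen_y: list = []
        for x, label in zip(X, y):
            # split any opposite-class rectangle that contains x
            new_exemplars = []
            for lo, hi, lab in self.exemplars_:
                if lab != label and np.all(lo <= x) and np.all(x <= hi):
                    new_exemplars.extend(self._split(lo, hi, lab, x))
                else:
                    new_exemplars.append([lo, hi, lab])
            self.exemplars_ = new_exemplars
            if self.exemplars_:
                dists = self._rect_dist(x)
                j = int(np.argmin(dists))
                lo, hi, lab = self.exemplars_[j]
                if lab == label:
                    new_lo, new_hi = np.minimum(lo, x), np.maximum(hi, x)
                    conflict = any(
                        sl != label and np.all(new_lo <= sx) and np.all(sx <= new_hi)
                        for sx, sl in zip(seen_X, seen_y))
                    if not conflict:
                        self.exemplars_[j] = [new_lo, new_hi, lab]
                    else:
                        self.exemplars_.append([x.copy(), x.copy(), label])
                else:
                    self.exemplars_.append([x.copy(), x.copy(), label])
            else:
                self.exemplars_.append([x.copy(), x.copy(), label])
            seen_X.append(x)
            seen_y.append(label)
        return self

    def _split(self, lo, hi, lab, x):
        """Cut a rectangle along one dimension so it no longer covers x."""
        widths = (hi - lo) / self.range_
        d = int(np.argmax(widths))
        eps = 1e-9 * self.range_[d]
        parts = []
        lo1, hi1 = lo.copy(), hi.copy()
        hi1[d] = x[d] - eps
        if hi1[d] >= lo1[d]:
            parts.append([lo1, hi1, lab])
        lo2, hi2 = lo.copy(), hi.copy()
        lo2[d] = x[d] + eps
        if hi2[d] >= lo2[d]:
            parts.append([lo2, hi2, lab])
        return parts

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        labels = np.empty(X.shape[0], dtype=object)
        for i, x in enumerate(X):
            j = int(np.argmin(self._rect_dist(x)))
            labels[i] = self.exemplars_[j][2]
        return _one_hot(labels, self.classes_)


def train(kind: str, d: FeatureDataset, seed: int = 0) -> _Classifier:
    """Fit one classifier family on the full dataset."""
    if d.n_instances < 2:
        raise ValueError("need at least 2 instances")
    if len(set(d.y)) < 2:
        raise ValueError("training data must contain both classes")
    kind = kind.upper()
    present = [c for c in d.classes if c in set(d.y)]
    if kind == "IB1":
        clf = IB1Classifier(classes=present)
    elif kind == "RT":
        clf = RandomTreeClassifier(seed=seed, classes=present)
    elif kind == "DT":
        clf = DecisionTableClassifier(classes=present)
    elif kind == "NNGE":
        clf = NNGEClassifier(classes=present)
    elif kind == "PRIOR":
        clf = PriorBaselineClassifier(classes=present)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; expected one of "
                         f"{CLASSIFIER_KINDS}")
    return clf.fit(d.X, d.y)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    kind: str
    protocol: str
    seed: int
    n_instances: int
    correctly_classified_pct: float
    incorrectly_classified_pct: float
    mean_absolute_error: float
    root_mean_squared_error: float
    relative_absolute_error_pct: float
    root_relative_squared_error_pct: float
    confusion_matrix: np.ndarray  # rows = true class, cols = predicted
    classes: tuple[str, ...] = ("M", "C")


def _fit_for(kind: str, X, y, classes, seed) -> _Classifier:
    sub = FeatureDataset(X=X, y=y, meter="VU", attribute_names=[
        f"a{i}" for i in range(X.shape[1])], classes=tuple(classes))
    return train(kind, sub, seed=seed)


def evaluate(kind: str, d: FeatureDataset, protocol: str, seed: int = 0) -> EvalReport:
    """Evaluate a classifier under one of the three study protocols.

    ``training`` fits and tests on the full dataset; ``cv10`` pools
    predictions over a seeded stratified 10-fold cross-validation;
    ``split75`` trains on a seeded stratified 75% split and tests on the
    remaining 25%.  Errors are computed on class-probability vectors
    against one-hot truth, and RAE/RRSE normalize by a prior-probability
    baseline fitted on the same training portion(s).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    if d.n_instances < 2:
        raise ValueError("need at least 2 instances")
    classes = tuple(c for c in d.classes if c in set(d.y))
    cls_arr = np.asarray(classes, dtype=object)
    X, y = d.X, d.y

    if protocol == "training":
        model = _fit_for(kind, X, y, classes, seed)
        base = PriorBaselineClassifier(classes=classes).fit(X, y)
        y_true, proba, base_proba = y, model.predict_proba(X), base.predict_proba(X)
    elif protocol == "cv10":
        if d.n_instances < 10:
            raise ValueError("cv10 needs at least 10 instances")
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        idx_all, probas, bases = [], [], []
        for train_idx, test_idx in skf.split(X, y.astype(str)):
            model = _fit_for(kind, X[train_idx], y[train_idx], classes, seed)
            base = PriorBaselineClassifier(classes=classes).fit(
                X[train_idx], y[train_idx])
            probas.append(model.predict_proba(X[test_idx]))
            bases.append(base.predict_proba(X[test_idx]))
            idx_all.append(test_idx)
        order = np.concatenate(idx_all)
        y_true = y[order]
        proba = np.vstack(probas)
        base_proba = np.vstack(bases)
    else:  # split75
        train_idx, test_idx = train_test_split(
            np.arange(d.n_instances), test_size=0.25, random_state=seed,
            stratify=y.astype(str))
        model = _fit_for(kind, X[train_idx], y[train_idx], classes, seed)
        base = PriorBaselineClassifier(classes=classes).fit(X[train_idx], y[train_idx])
        y_true, proba = y[test_idx], model.predict_proba(X[test_idx])
        base_proba = base.predict_proba(X[test_idx])

    pred = cls_arr[np.argmax(proba, axis=1)]
    truth = _one_hot(np.asarray(y_true, dtype=object), cls_arr)
    correct = float(np.mean(pred == y_true)) * 100.0
    mae = float(np.mean(np.abs(proba - truth)))
    rmse = float(np.sqrt(np.mean((proba - truth) ** 2)))
    mae_b = float(np.mean(np.abs(base_proba - truth)))
    rmse_b = float(np.sqrt(np.mean((base_proba - truth) ** 2)))
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, pred):
        cm[pos[t], pos[p]] += 1
    return EvalReport(
        kind=kind.upper(), protocol=protocol, seed=seed,
        n_instances=int(y_true.size),
        correctly_classified_pct=correct,
        incorrectly_classified_pct=100.0 - correct,
        mean_absolute_error=mae,
        root_mean_squared_error=rmse,
        relative_absolute_error_pct=100.0 * mae / mae_b if mae_b > 0 else 0.0,
        root_relative_squared_error_pct=100.0 * rmse / rmse_b if rmse_b > 0 else 0.0,
        confusion_matrix=cm, classes=classes,
    )
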