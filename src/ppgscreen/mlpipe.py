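"""Wrapper feature selection and two-stage cascade classification.

Stage 1 screens healthy vs cardiovascular disease using the mean and
variance of every pulse-wave feature plus demographics; stage 2 types the
disease among the positives using feature means only (the variance columns
double the search space without helping the 5-way problem). Minority
classes are rebalanced by whole-subject replication; the leak-free default
replicates inside each training fold only, so no subject (or its copies)
ever appears on both sides of a CV split.

Feature subsets are chosen by a greedy stepwise wrapper: the candidate that
most improves the wrapped classifier's cross-validated accuracy is added
(forward) or removed (backward) until no step improves.

Seven classifier families are supported: pruned decision tree, random
forest, RIPPER-style sequential-covering rules, PART-style partial-tree
rules, multilayer perceptron, k-nearest neighbour and Gaussian naive Bayes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import BalanceError, FoldError, SchemaError
from .features import FEATURE_NAMES
from .synthgen import CVD_LABELS

ALGORITHMS = ("j48", "rf", "jrip", "part", "mlp", "knn", "nb")

DEMOGRAPHIC_COLS = (
    "age",
    "height",
    "weight",
    "bmi",
    "gender",
    "smoking",
    "respiratory_problem",
    "blood_pressure",
    "physical_activity",
    "others",
    "spo2",
    "pulse_rate",
)

MEAN_COLS = tuple(f"{name}_mean" for name in FEATURE_NAMES)
VAR_COLS = tuple(f"{name}_var" for name in FEATURE_NAMES)

#: Candidate order for greedy tie-breaking: pulse-wave features in their
#: declaration order (means, then variances), then demographics.
STAGE1_FEATURES = MEAN_COLS + VAR_COLS + DEMOGRAPHIC_COLS
STAGE2_FEATURES = MEAN_COLS + DEMOGRAPHIC_COLS


# --------------------------------------------------------------------------
# rule learners (no scikit-learn counterpart exists for these families)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Rule:
    conditions: tuple[tuple[int, str, float], ...]  # (feature, "<=" | ">", thr)
    label: object

    def covers(self, X: np.ndarray) -> np.ndarray:
        mask = np.ones(len(X), dtype=bool)
        for f, op, thr in self.conditions:
            mask &= X[:, f] <= thr if op == "<=" else X[:, f] > thr
        return mask


def _foil_gain(pos: np.ndarray, cov: np.ndarray, new_cov: np.ndarray) -> float:
    p1 = int((new_cov & pos).sum())
    if p1 == 0:
        return -np.inf
    n1 = int(new_cov.sum()) - p1
    p0 = int((cov & pos).sum())
    n0 = int(cov.sum()) - p0
    return p1 * (math.log2(p1 / (p1 + n1)) - math.log2(max(p0, 1) / (p0 + n0)))


class RipperRuleClassifier(ClassifierMixin, BaseEstimator):
    """Sequential-covering rule learner in the RIPPER family.

    Classes are handled from rarest to most frequent; for each, conjunctive
    rules are grown greedily by FOIL information gain over quantile
    thresholds, instances covered by an accepted rule are removed, and the
    most frequent class becomes the default.
    """

    def __init__(self, max_conditions=3, min_precision=0.6, n_thresholds=8,
                 random_state=None):
        self.max_conditions = max_conditions
        self.min_precision = min_precision
        self.n_thresholds = n_thresholds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        order = self.classes_[np.argsort(counts, kind="stable")]
        self.default_ = self.classes_[int(np.argmax(counts))]
        remaining = np.ones(len(y), dtype=bool)
        rules: list[_Rule] = []
        for label in order[:-1]:  # the most frequent class stays the default
            while True:
                rule = self._grow_rule(X, y, remaining, label)
                if rule is None:
                    break
                rules.append(rule)
                remaining &= ~rule.covers(X)
                if not (remaining & (y == label)).any():
                    break
        self.rules_ = rules
        if remaining.any():
            labels, c = np.unique(y[remaining], return_counts=True)
            self.default_ = labels[int(np.argmax(c))]
        self.n_features_in_ = X.shape[1]
        return self

    def _grow_rule(self, X, y, remaining, label) -> _Rule | None:
        pos = y == label
        if not (remaining & pos).any():
            return None
        cov = remaining.copy()
        conditions: list[tuple[int, str, float]] = []
        for _ in range(self.max_conditions):
            best = None
            best_gain = 0.0
            for f in range(X.shape[1]):
                vals = X[cov, f]
                qs = np.unique(
                    np.quantile(vals, np.linspace(0.1, 0.9, self.n_thresholds))
                )
                for thr in qs:
                    for op in ("<=", ">"):
                        new_cov = cov & (X[:, f] <= thr if op == "<=" else X[:, f] > thr)
                        gain = _foil_gain(pos, cov, new_cov)
                        if gain > best_gain:
                            best_gain = gain
                            best = (f, op, float(thr), new_cov)
            if best is None:
                break
            f, op, thr, new_cov = best
            conditions.append((f, op, thr))
            cov = new_cov
            if (pos[cov]).all():
                break
        if not conditions:
            return None
        n_cov = int(cov.sum())
        n_pos = int((cov & pos).sum())
        if n_pos == 0 or n_pos / n_cov < self.min_precision:
            return None
        return _Rule(tuple(conditions), label)

    def predict(self, X):
        check_is_fitted(self, "rules_")
        X = np.asarray(X, dtype=float)
        out = np.full(len(X), self.default_, dtype=object)
        assigned = np.zeros(len(X), dtype=bool)
        for rule in self.rules_:
            mask = rule.covers(X) & ~assigned
            out[mask] = rule.label
            assigned |= mask
        return out.astype(self.classes_.dtype)


class PartRuleClassifier(ClassifierMixin, BaseEstimator):
    """PART-style rules: repeatedly build a depth-limited tree on the
    not-yet-covered instances, turn its most populous leaf into a rule,
    remove what it covers, and repeat."""

    def __init__(self, max_depth=3, min_samples_leaf=2, max_rules=50,
                 random_state=None):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_rules = max_rules
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.default_ = self.classes_[int(np.argmax(counts))]
        remaining = np.ones(len(y), dtype=bool)
        rules: list[_Rule] = []
        while remaining.sum() >= 2 * self.min_samples_leaf and len(rules) < self.max_rules:
            if len(np.unique(y[remaining])) < 2:
                break
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                random_state=self.random_state,
            ).fit(X[remaining], y[remaining])
            rule = self._best_leaf_rule(tree)
            if rule is None:
                break
            rules.append(rule)
            remaining &= ~rule.covers(X)
        self.rules_ = rules
        if remaining.any():
            labels, c = np.unique(y[remaining], return_counts=True)
            self.default_ = labels[int(np.argmax(c))]
        self.n_features_in_ = X.shape[1]
        return self

    def _best_leaf_rule(self, tree: DecisionTreeClassifier) -> _Rule | None:
        t = tree.tree_
        leaves = [i for i in range(t.node_count) if t.children_left[i] == -1]
        if not leaves:
            return None
        leaf = max(leaves, key=lambda i: t.n_node_samples[i])
        # backtrack the root->leaf path to collect split conditions
        parent = {}
        for i in range(t.node_count):
            if t.children_left[i] != -1:
                parent[t.children_left[i]] = (i, "<=")
                parent[t.children_right[i]] = (i, ">")
        conditions = []
        node = leaf
        while node in parent:
            up, op = parent[node]
            conditions.append((int(t.feature[up]), op, float(t.threshold[up])))
            node = up
        label = tree.classes_[int(np.argmax(t.value[leaf]))]
        if not conditions:
            return None
        return _Rule(tuple(reversed(conditions)), label)

    def predict(self, X):
        check_is_fitted(self, "rules_")
        X = np.asarray(X, dtype=float)
        out = np.full(len(X), self.default_, dtype=object)
        assigned = np.zeros(len(X), dtype=bool)
        for rule in self.rules_:
            mask = rule.covers(X) & ~assigned
            out[mask] = rule.label
            assigned |= mask
        return out.astype(self.classes_.dtype)


# --------------------------------------------------------------------------
# classifier specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """One of the seven supported classifier families, plus its seed."""

    algorithm: str = "nb"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise SchemaError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )

    def build(self, n_features: int, n_classes: int):
        """Instantiate the estimator (a scikit-learn compatible object)."""
        hp = self.hyperparameters
        if self.algorithm == "j48":
            est = DecisionTreeClassifier(
                min_samples_leaf=hp.get("min_samples_leaf", 2),
                ccp_alpha=hp.get("ccp_alpha", 0.005),
                random_state=self.seed,
            )
        elif self.algorithm == "rf":
            est = RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 100), random_state=self.seed
            )
        elif self.algorithm == "jrip":
            est = RipperRuleClassifier(random_state=self.seed, **hp)
        elif self.algorithm == "part":
            est = PartRuleClassifier(random_state=self.seed, **hp)
        elif self.algorithm == "mlp":
            hidden = hp.get("hidden", max((n_features + n_classes) // 2, 2))
            est = Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "mlp",
                        MLPClassifier(
                            hidden_layer_sizes=(hidden,),
                            max_iter=hp.get("max_iter", 500),
                            random_state=self.seed,
                        ),
                    ),
                ]
            )
        elif self.algorithm == "knn":
            est = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("knn", KNeighborsClassifier(n_neighbors=hp.get("k", 1))),
                ]
            )
        else:  # nb
            est = GaussianNB(var_smoothing=hp.get("var_smoothing", 1e-9))
        return est


# --------------------------------------------------------------------------
# rebalancing and cross-validation
# --------------------------------------------------------------------------

def balance_classes(
    X: pd.DataFrame, y: pd.Series, subject_ids: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.Series | None]:
    """Replicate minority classes whole-subject-wise up to the majority size.

    Each class with n_c < n_max is tiled ceil(n_max / n_c) times and
    truncated to n_max rows. Deterministic; row order groups by class.
    """
    counts = y.value_counts()
    if len(counts) < 2:
        raise BalanceError("need at least two classes to balance")
    n_max = int(counts.max())
    parts_X, parts_y, parts_s = [], [], []
    for label in counts.index:
        idx = y.index[y == label]
        reps = math.ceil(n_max / len(idx))
        tiled = np.tile(idx.to_numpy(), reps)[:n_max]
        parts_X.append(X.loc[tiled])
        parts_y.append(y.loc[tiled])
        if subject_ids is not None:
            parts_s.append(subject_ids.loc[tiled])
    Xb = pd.concat(parts_X, ignore_index=True)
    yb = pd.concat(parts_y, ignore_index=True)
    sb = pd.concat(parts_s, ignore_index=True) if subject_ids is not None else None
    return Xb, yb, sb


@dataclass
class FoldRecord:
    fold: int
    train_subjects: list
    test_subjects: list


def _check_foldable(y: pd.Series, k: int) -> None:
    counts = y.value_counts()
    if int(counts.min()) < k:
        raise FoldError(
            f"class {counts.idxmin()!r} has {int(counts.min())} members, "
            f"fewer than k={k}; balance the classes first or lower k"
        )


def _impute_train_median(
    X_train: pd.DataFrame, X_test: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    med = X_train.median(numeric_only=True)
    med = med.fillna(0.0)  # feature entirely missing in a training fold
    return (
        X_train.fillna(med).to_numpy(dtype=float),
        X_test.fillna(med).to_numpy(dtype=float),
    )


def _cv_predictions(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ClassifierSpec,
    k: int,
    seed: int,
    mode: str,
    subject_ids: pd.Series | None,
) -> tuple[pd.Series, np.ndarray, list[FoldRecord]]:
    """Pooled out-of-fold predictions plus fold bookkeeping for audits."""
    if mode not in ("replicate-train-only", "replicate-global"):
        raise ValueError(f"unknown balance mode {mode!r}")
    X = X.reset_index(drop=True)
    y = y.reset_index(drop=True)
    if subject_ids is None:
        subject_ids = pd.Series([f"row{i}" for i in range(len(y))])
    subject_ids = subject_ids.reset_index(drop=True)

    if mode == "replicate-global":
        X, y, subject_ids = balance_classes(X, y, subject_ids)

    _check_foldable(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = pd.Series(index=y.index, dtype=object)
    records: list[FoldRecord] = []
    n_classes = y.nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            X_tr, y_tr = X.iloc[tr], y.iloc[tr]
            s_tr = subject_ids.iloc[tr]
            if mode == "replicate-train-only":
                X_tr, y_tr, s_tr = balance_classes(X_tr, y_tr, s_tr)
            Xa, Xb = _impute_train_median(X_tr, X.iloc[te])
            est = clone(spec.build(X.shape[1], n_classes))
            est.fit(Xa, y_tr.to_numpy())
            y_pred.iloc[te] = est.predict(Xb)
            records.append(
                FoldRecord(
                    fold=fold,
                    train_subjects=list(s_tr),
                    test_subjects=list(subject_ids.iloc[te]),
                )
            )
    return y_pred, y.to_numpy(), records


def cv_accuracy(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    mode: str = "replicate-train-only",
    subject_ids: pd.Series | None = None,
) -> float:
    """Stratified k-fold accuracy in percent; deterministic given the seed."""
    y_pred, y_true, _ = _cv_predictions(X, y, spec, k, seed, mode, subject_ids)
    return 100.0 * float((y_pred.to_numpy() == y_true).mean())


# --------------------------------------------------------------------------
# greedy stepwise wrapper selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    selected_features: tuple[str, ...]
    accuracy_trajectory: tuple[float, ...]
    direction: str
    final_cv_accuracy: float


def greedy_stepwise_select(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ClassifierSpec,
    direction: str = "forward",
    k: int = 10,
    seed: int = 0,
    tol: float = 0.0,
    mode: str = "replicate-train-only",
    subject_ids: pd.Series | None = None,
) -> SelectionResult:
    """Greedy stepwise wrapper search over feature subsets.

    Forward: start empty and add the candidate maximising the wrapped
    classifier's CV accuracy, while the best addition improves by more than
    ``tol`` over the incumbent (the empty-set incumbent is the
    majority-class rate). Backward: start full and remove symmetrically.
    Ties go to the earliest candidate in column order.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    candidates = list(X.columns)
    if len(candidates) < 2:
        raise SchemaError("need at least two candidate features")

    def score(subset: list[str]) -> float:
        return cv_accuracy(X[subset], y, spec, k, seed, mode, subject_ids)

    trajectory: list[float] = []
    if direction == "forward":
        selected: list[str] = []
        best = 100.0 * float(y.value_counts(normalize=True).max())
        while True:
            remaining = [c for c in candidates if c not in selected]
            if not remaining:
                break
            scores = [(score(selected + [c]), c) for c in remaining]
            best_acc = max(s for s, _ in scores)
            best_feat = next(c for s, c in scores if s == best_acc)
            if best_acc > best + tol:
                selected.append(best_feat)
                trajectory.append(best_acc)
                best = best_acc
            else:
                break
    else:
        selected = list(candidates)
        best = score(selected)
        trajectory.append(best)
        while len(selected) > 1:
            scores = [
                (score([f for f in selected if f != c]), c) for c in selected
            ]
            best_acc = max(s for s, _ in scores)
            best_feat = next(c for s, c in scores if s == best_acc)
            if best_acc > best + tol:
                selected.remove(best_feat)
                trajectory.append(best_acc)
                best = best_acc
            else:
                break
    return SelectionResult(
        selected_features=tuple(selected),
        accuracy_trajectory=tuple(trajectory),
        direction=direction,
        final_cv_accuracy=best,
    )


# --------------------------------------------------------------------------
# two-stage cascade
# --------------------------------------------------------------------------

def stage1_matrix(
    table: pd.DataFrame, features: tuple[str, ...] = STAGE1_FEATURES
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Healthy-vs-CVD view: means + variances + demographics."""
    missing = [c for c in features if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing[:5]}")
    y = table["label"].map(lambda l: "Healthy" if l == "Healthy" else "CVD")
    return table[list(features)], y, table["subject_id"]


def stage2_matrix(
    table: pd.DataFrame, features: tuple[str, ...] = STAGE2_FEATURES
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Five-way CVD-typing view: feature means + demographics, CVD rows only."""
    bad = [c for c in features if c.endswith("_var")]
    if bad:
        raise SchemaError(
            f"stage 2 uses feature means only; variance columns not allowed: {bad[:3]}"
        )
    missing = [c for c in features if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing[:5]}")
    cvd = table[table["label"] != "Healthy"]
    return cvd[list(features)], cvd["label"], cvd["subject_id"]


@dataclass
class FittedModel:
    """A trained stage model plus everything needed to apply it safely."""

    stage: int
    features: tuple[str, ...]
    estimator: object
    medians: pd.Series
    classes: tuple

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in table.columns]
        if missing:
            raise SchemaError(f"predict-time columns missing: {missing[:5]}")
        X = table[list(self.features)].fillna(self.medians).to_numpy(dtype=float)
        return self.estimator.predict(X)


def _fit_stage(
    X: pd.DataFrame, y: pd.Series, spec: ClassifierSpec, stage: int
) -> FittedModel:
    Xb, yb, _ = balance_classes(X, y)
    med = Xb.median(numeric_only=True).fillna(0.0)
    Xa = Xb.fillna(med).to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est = spec.build(X.shape[1], y.nunique()).fit(Xa, yb.to_numpy())
    return FittedModel(
        stage=stage,
        features=tuple(X.columns),
        estimator=est,
        medians=med,
        classes=tuple(sorted(y.unique())),
    )


def fit_stage1(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    features: tuple[str, ...] = STAGE1_FEATURES,
) -> FittedModel:
    """Train the healthy-vs-CVD screen on the full subject table."""
    X, y, _ = stage1_matrix(table, features)
    return _fit_stage(X, y, spec, stage=1)


def fit_stage2(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    features: tuple[str, ...] = STAGE2_FEATURES,
) -> FittedModel:
    """Train the 5-way CVD typer; refuses healthy rows and variance columns."""
    if (table["label"] == "Healthy").any():
        raise SchemaError(
            "stage 2 input contains Healthy-labeled rows; filter them first"
        )
    unknown = set(table["label"]) - set(CVD_LABELS)
    if unknown:
        raise SchemaError(f"unknown CVD labels: {sorted(unknown)}")
    bad = [c for c in features if c.endswith("_var")]
    if bad:
        raise SchemaError(
            f"stage 2 uses feature means only; variance columns not allowed: {bad[:3]}"
        )
    X = table[list(features)]
    y = table["label"]
    return _fit_stage(X, y, spec, stage=2)


def predict_two_stage(
    table: pd.DataFrame, model1: FittedModel, model2: FittedModel
) -> np.ndarray:
    """Cascade prediction: healthy stays healthy; positives get a CVD type."""
    stage1 = model1.predict(table)
    out = np.array(stage1, dtype=object)
    cvd_mask = stage1 != "Healthy"
    if cvd_mask.any():
        out[cvd_mask] = model2.predict(table.loc[cvd_mask])
    return out


# --------------------------------------------------------------------------
# evaluation and leakage audit
# --------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    accuracy: float                     # %
    per_class_recall: dict
    macro_recall: float
    confusion: pd.DataFrame             # rows: true, cols: predicted
    folds: list[FoldRecord]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
            "macro_recall": self.macro_recall,
            "confusion": self.confusion.to_dict(),
            "seed": self.seed,
        }


def evaluate(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    mode: str = "replicate-train-only",
    subject_ids: pd.Series | None = None,
) -> ClassificationReport:
    """Cross-validated report: accuracy, recalls, confusion matrix, folds."""
    y_pred, y_true, records = _cv_predictions(X, y, spec, k, seed, mode, subject_ids)
    labels = sorted(pd.unique(y_true))
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred.to_numpy()):
        confusion.loc[t, p] += 1
    accuracy = 100.0 * float(np.trace(confusion.to_numpy())) / len(y_true)
    recall = {
        lab: float(confusion.loc[lab, lab] / confusion.loc[lab].sum())
        for lab in labels
    }
    macro = float(np.mean(list(recall.values())))
    return ClassificationReport(
        accuracy=accuracy,
        per_class_recall=recall,
        macro_recall=macro,
        confusion=confusion,
        folds=records,
        seed=seed,
    )


def audit_leakage(report: ClassificationReport) -> set:
    """Subject ids appearing in both train and test of any fold (should be
    empty in replicate-train-only mode)."""
    shared: set = set()
    for rec in report.folds:
        shared |= set(rec.train_subjects) & set(rec.test_subjects)
    return shared
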