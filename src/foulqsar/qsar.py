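"""Activity labeling, splitting, class-balanced model training and metrics.

The central estimator is a balanced random forest: each tree is grown on a
per-class bootstrap whose size equals the minority-class count (the
``sampsize``-style balancing used for the antifouling model, where a 57:70
training set yields 57 + 57 draws per tree), with out-of-bag (OOB) votes
retained for internal validation and a permutation mean-decrease-accuracy
importance used for descriptor selection. scikit-learn supplies the
individual decision trees, the SVM and the multilayer perceptron; the
balancing, OOB bookkeeping and importance logic live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .chem_io import MoleculeRecord
from .descriptors import DescriptorMatrix

ACTIVE, INACTIVE = "A", "B"

#: Activity thresholds: percent inhibition strictly above this is active ...
PERCENT_INHIBITION_THRESHOLD = 52.0
#: ... and EC50/IC50 at or below this (in ug/mL) is active.
POTENCY_THRESHOLD_UGML = 25.0


class QsarError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Activity labeling
# ---------------------------------------------------------------------------

@dataclass
class ActivityRecord:
    """One measured endpoint and its derived binary class.

    endpoint_type: ``percent_inhibition``, ``EC50`` or ``IC50``;
    units: ``%`` for inhibition, ``ug/mL`` for potencies.
    """

    endpoint_type: str
    value: float
    units: str
    activity_class: str | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise QsarError(f"endpoint value must be >= 0, got {self.value}")
        if self.endpoint_type not in ("percent_inhibition", "EC50", "IC50"):
            raise QsarError(f"unknown endpoint type: {self.endpoint_type!r}")


def label_activity(rec: ActivityRecord) -> str:
    """Binary activity class from one endpoint.

    percent inhibition > 52% is active; EC50/IC50 <= 25 ug/mL is active
    (boundary included). The rule is applied per available endpoint; callers
    holding conflicting multiple endpoints for one compound should keep the
    strictest (inactive) outcome.
    """
    if rec.endpoint_type == "percent_inhibition":
        if rec.units != "%":
            raise QsarError(f"percent inhibition must be in %, got {rec.units!r}")
        cls = ACTIVE if rec.value > PERCENT_INHIBITION_THRESHOLD else INACTIVE
    else:
        if rec.units != "ug/mL":
            raise QsarError(
                f"{rec.endpoint_type} must be in ug/mL, got {rec.units!r}"
            )
        cls = ACTIVE if rec.value <= POTENCY_THRESHOLD_UGML else INACTIVE
    rec.activity_class = cls
    return cls


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class DataSplit:
    train_ids: list[str]
    test_ids: list[str]
    train_counts: dict[str, int]
    test_counts: dict[str, int]


def stratified_split(
    records: Sequence,
    test_counts: Mapping[str, int],
    seed: int,
) -> DataSplit:
    """Random within-class split into train/test with fixed per-class test counts.

    ``records`` may be MoleculeRecords with labeled activity, or plain
    ``(id, class)`` pairs. Sampling is uniform within each class at the given
    seed and reproducible.
    """
    pairs: list[tuple[str, str]] = []
    for r in records:
        if isinstance(r, MoleculeRecord):
            if r.activity is None or r.activity.activity_class is None:
                raise QsarError(f"record {r.molecule.id!r} has no activity class")
            pairs.append((r.molecule.id, r.activity.activity_class))
        else:
            pairs.append((r[0], r[1]))
    by_class: dict[str, list[str]] = {}
    for mid, cls in pairs:
        by_class.setdefault(cls, []).append(mid)
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for cls, want in test_counts.items():
        have = len(by_class.get(cls, []))
        if want > have:
            raise QsarError(
                f"cannot draw {want} test molecules from class {cls!r} of size {have}"
            )
        chosen = rng.choice(len(by_class[cls]), size=want, replace=False)
        test_ids.extend(by_class[cls][i] for i in sorted(chosen))
    test_set = set(test_ids)
    train_ids = [mid for mid, _ in pairs if mid not in test_set]
    cls_of = dict(pairs)
    return DataSplit(
        train_ids=train_ids,
        test_ids=[mid for mid, _ in pairs if mid in test_set],
        train_counts=_count_classes(train_ids, cls_of),
        test_counts=_count_classes(sorted(test_set), cls_of),
    )


def _count_classes(ids: Sequence[str], cls_of: Mapping[str, str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for mid in ids:
        out[cls_of[mid]] = out.get(cls_of[mid], 0) + 1
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise QsarError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_active(self) -> int:
        return self.tp + self.fn

    @property
    def n_inactive(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """SE/SP/Q/MCC with explicit flags for undefined (zero-denominator) values."""

    se: float | None
    sp: float | None
    q: float
    mcc: float | None
    undefined: frozenset[str] = frozenset()

    def formatted(self, ndigits: int = 3) -> dict[str, str]:
        """Table-style rendering: undefined entries become '-'."""
        out = {}
        for key in ("se", "sp", "q", "mcc"):
            val = getattr(self, key)
            out[key] = "-" if val is None else f"{round(val, ndigits):.{ndigits}f}"
        return out


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    SE = TP/(TP+FN), SP = TN/(TN+FP), Q = (TP+TN)/n,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero denominator yields None for that metric plus an ``undefined`` flag.
    """
    if c.n == 0:
        raise QsarError("cannot compute metrics from all-zero counts")
    undefined: set[str] = set()
    se = c.tp / c.n_active if c.n_active else None
    sp = c.tn / c.n_inactive if c.n_inactive else None
    if se is None:
        undefined.add("se")
    if sp is None:
        undefined.add("sp")
    q = (c.tp + c.tn) / c.n
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = None
        undefined.add("mcc")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / float(np.sqrt(denom))
    return MetricsReport(se=se, sp=sp, q=q, mcc=mcc, undefined=frozenset(undefined))


def counts_from_rates(
    se: float,
    sp: float,
    n_active: int,
    n_inactive: int,
    tol: float = 5e-4,
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed SE/SP rates.

    TP is the unique integer in [0, n_active] with |TP/n_active - SE| < tol
    (TN analogously); raises if no integer or more than one matches. The
    default tolerance corresponds to 3-decimal rounding of the rates.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise QsarError("SE and SP must lie in [0, 1]")

    def invert(rate: float, n: int, what: str) -> int:
        hits = [k for k in range(n + 1) if abs(k / n - rate) < tol]
        if len(hits) != 1:
            raise QsarError(
                f"{what}: {len(hits)} integers in [0,{n}] match rate {rate} "
                f"at tolerance {tol}"
            )
        return hits[0]

    tp = invert(se, n_active, "TP")
    tn = invert(sp, n_inactive, "TN")
    return ConfusionCounts(tp=tp, tn=tn, fp=n_inactive - tn, fn=n_active - tp)


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> ConfusionCounts:
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((yt == ACTIVE) & (yp == ACTIVE))),
        tn=int(np.sum((yt == INACTIVE) & (yp == INACTIVE))),
        fp=int(np.sum((yt == INACTIVE) & (yp == ACTIVE))),
        fn=int(np.sum((yt == ACTIVE) & (yp == INACTIVE))),
    )


def clusterwise_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    clusters: Sequence[str],
) -> dict[str, tuple[ConfusionCounts, MetricsReport]]:
    """Per-structural-cluster confusion counts and metrics.

    Single-class clusters naturally yield undefined SE or SP (rendered '-');
    clusters with no members are absent from the report.
    """
    yt, yp, cl = np.asarray(y_true), np.asarray(y_pred), np.asarray(clusters)
    out: dict[str, tuple[ConfusionCounts, MetricsReport]] = {}
    for label in sorted(set(cl)):
        m = cl == label
        counts = confusion_from_predictions(yt[m], yp[m])
        out[label] = (counts, compute_metrics(counts))
    return out


# ---------------------------------------------------------------------------
# Balanced random forest
# ---------------------------------------------------------------------------

@dataclass
class RFConfig:
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    seed: int = 0
    #: per-class bootstrap size; None = minority-class count.
    sample_size: int | None = None


class BalancedRandomForest:
    """Random forest with per-class bootstraps of minority-class size.

    Every tree draws ``sample_size`` molecules *with replacement* from each
    class (so majority-class molecules are subsampled and minority-class
    molecules may recur), removing the majority-class preference that plain
    bootstrapping exhibits on imbalanced activity sets. OOB votes are kept
    per molecule; ``prob_active`` is the fraction of tree votes for the
    active class.
    """

    kind = "RF"

    def __init__(self, config: RFConfig | None = None) -> None:
        self.config = config or RFConfig()
        self.trees_: list[DecisionTreeClassifier] = []
        self.feature_names_: list[str] | None = None

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y: Sequence[str]) -> "BalancedRandomForest":
        X, names = _as_matrix(X)
        y = np.asarray(y)
        classes = sorted(set(y))
        if len(classes) < 2:
            raise QsarError("training labels contain a single class")
        if set(classes) != {ACTIVE, INACTIVE}:
            raise QsarError(f"labels must be {{'A','B'}}, got {classes}")
        self.feature_names_ = names
        self._X = np.ascontiguousarray(X, dtype=np.float32)
        self._y = y
        n = len(y)
        idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
        m = self.config.sample_size or min(len(v) for v in idx_by_class.values())
        self.per_class_sample_size_ = m
        rng = np.random.default_rng(self.config.seed)
        self.trees_ = []
        self._oob_votes_active = np.zeros(n)
        self._oob_votes_total = np.zeros(n)
        self._oob_masks: list[np.ndarray] = []
        for _ in range(self.config.n_trees):
            boot = np.concatenate(
                [rng.choice(idx_by_class[c], size=m, replace=True) for c in classes]
            )
            tree = DecisionTreeClassifier(
                max_features=self.config.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(self._X[boot], y[boot])
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            self._oob_masks.append(oob)
            if oob.any():
                pred = _tree_predict(tree, self._X[oob])
                self._oob_votes_active[oob] += pred == ACTIVE
                self._oob_votes_total[oob] += 1
            self.trees_.append(tree)
        return self

    # -- prediction --------------------------------------------------------
    def prob_active(self, X) -> np.ndarray:
        """Fraction of tree votes for the active class."""
        X, _ = _as_matrix(X, expect=self.feature_names_)
        Xf = np.ascontiguousarray(X, dtype=np.float32)
        votes = np.zeros(len(Xf))
        for tree in self.trees_:
            votes += _tree_predict(tree, Xf) == ACTIVE
        return votes / len(self.trees_)

    def predict_class(self, X) -> np.ndarray:
        p = self.prob_active(X)
        return np.where(p >= 0.5, ACTIVE, INACTIVE)

    # -- OOB internals -----------------------------------------------------
    def oob_prob_active(self) -> np.ndarray:
        """Per-training-molecule active-vote fraction over trees where it was OOB."""
        self._check_fitted()
        with np.errstate(invalid="ignore"):
            return np.where(
                self._oob_votes_total > 0,
                self._oob_votes_active / np.maximum(self._oob_votes_total, 1),
                np.nan,
            )

    def oob_predict(self) -> np.ndarray:
        p = self.oob_prob_active()
        return np.where(p >= 0.5, ACTIVE, INACTIVE)

    def oob_confusion(self) -> ConfusionCounts:
        return confusion_from_predictions(self._y, self.oob_predict())

    def oob_metrics(self) -> MetricsReport:
        return compute_metrics(self.oob_confusion())

    def importance(self) -> pd.Series:
        """Permutation mean decrease in accuracy, averaged over trees.

        For each tree: OOB accuracy, minus OOB accuracy after permuting one
        descriptor's values among the OOB molecules; the drop, averaged over
        all trees, is that descriptor's importance.
        """
        self._check_fitted()
        n_feat = self._X.shape[1]
        imp = np.zeros(n_feat)
        rng = np.random.default_rng(self.config.seed + 1)
        for tree, oob in zip(self.trees_, self._oob_masks):
            if not oob.any():
                continue
            Xo = np.ascontiguousarray(self._X[oob])
            yo = self._y[oob]
            base = np.mean(_tree_predict(tree, Xo) == yo)
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            perm = rng.permutation(len(yo))
            for j in used:
                saved = Xo[:, j].copy()
                Xo[:, j] = saved[perm]
                acc = np.mean(_tree_predict(tree, Xo) == yo)
                Xo[:, j] = saved
                imp[j] += base - acc
        imp /= len(self.trees_)
        names = self.feature_names_ or [f"x{j}" for j in range(n_feat)]
        return pd.Series(imp, index=names)

    def ranked_features(self) -> list[str]:
        """Descriptor names by decreasing importance (stable for ties)."""
        s = self.importance()
        order = np.argsort(-s.to_numpy(), kind="stable")
        return [s.index[i] for i in order]

    def _check_fitted(self) -> None:
        if not self.trees_:
            raise QsarError("model is not fitted")


def _tree_predict(tree: DecisionTreeClassifier, X32: np.ndarray) -> np.ndarray:
    """Fast label prediction bypassing sklearn input validation."""
    proba = tree.tree_.predict(X32)
    proba = proba.reshape(proba.shape[0], -1)
    return tree.classes_[np.argmax(proba, axis=1)]


def _as_matrix(X, expect: list[str] | None = None) -> tuple[np.ndarray, list[str] | None]:
    """Accept DescriptorMatrix / DataFrame / ndarray; align named columns."""
    if isinstance(X, DescriptorMatrix):
        X = X.values
    if isinstance(X, pd.DataFrame):
        if expect is not None:
            missing = [c for c in expect if c not in X.columns]
            if missing:
                raise QsarError(f"missing descriptor column: {missing[0]!r}")
            X = X[expect]
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if expect is not None and arr.shape[1] != len(expect):
        raise QsarError(
            f"expected {len(expect)} descriptor columns, got {arr.shape[1]}"
        )
    return arr, expect


def train_balanced_rf(X, y: Sequence[str], config: RFConfig | None = None) -> BalancedRandomForest:
    """Fit the balanced random forest (see :class:`BalancedRandomForest`)."""
    return BalancedRandomForest(config).fit(X, y)


# ---------------------------------------------------------------------------
# Descriptor selection sweep
# ---------------------------------------------------------------------------

DEFAULT_SELECTION_SIZES = (12, 25, 50, 100, 150, 200, 250)


@dataclass
class SelectionResult:
    ranking: list[str]
    per_k: dict[int, MetricsReport]
    chosen_k: int
    skipped: list[int] = field(default_factory=list)

    @property
    def chosen_features(self) -> list[str]:
        return self.ranking[: self.chosen_k]


def importance_selection_sweep(
    model: BalancedRandomForest,
    X,
    y: Sequence[str],
    k_list: Sequence[int] = DEFAULT_SELECTION_SIZES,
    config: RFConfig | None = None,
) -> SelectionResult:
    """Retrain on the top-k most important descriptors for each sweep size.

    Descriptors are ranked by the fitted model's permutation importance; for
    every feasible k a fresh balanced forest is trained on the top-k columns
    and its OOB metrics recorded. The chosen k maximizes OOB Q, with MCC as
    the tie-break. Sizes exceeding the descriptor count are skipped (logged).
    """
    ranking = model.ranked_features()
    frame = X.values if isinstance(X, DescriptorMatrix) else pd.DataFrame(
        X, columns=model.feature_names_
    ) if not isinstance(X, pd.DataFrame) else X
    cfg = config or model.config
    per_k: dict[int, MetricsReport] = {}
    skipped: list[int] = []
    for k in k_list:
        if k > len(ranking):
            skipped.append(k)
            continue
        sub = frame[ranking[:k]]
        rf = BalancedRandomForest(cfg).fit(sub, y)
        per_k[k] = rf.oob_metrics()
    if not per_k:
        raise QsarError("no feasible sweep size (all k exceed the descriptor count)")

    def score(k: int) -> tuple[float, float]:
        rep = per_k[k]
        return (rep.q, rep.mcc if rep.mcc is not None else -np.inf)

    chosen = max(per_k, key=score)
    return SelectionResult(
        ranking=ranking, per_k=per_k, chosen_k=chosen, skipped=skipped
    )


# ---------------------------------------------------------------------------
# SVM and MLP contracts
# ---------------------------------------------------------------------------

@dataclass
class SVMConfig:
    """RBF-kernel C-SVM defaults for the antifouling model.

    The cost and kernel-width values are the tuned settings of the published
    model (C = 1e7, gamma = 1e-8); class imbalance is handled by balanced
    class weights (equivalent to replicating the smaller class to parity).
    """

    C: float = 1e7
    gamma: float = 1e-8
    kernel: str = "rbf"
    scale: bool = True
    seed: int = 0


@dataclass
class MLPConfig:
    """Feed-forward network defaults: 2 hidden layers x 200 relu units, a
    2-unit output layer, batch size 36, 100 epochs, cross-entropy loss."""

    layer_sizes: tuple[int, ...] = (200, 200, 2)
    activation: str = "relu"
    batch_size: int = 36
    epochs: int = 100
    scale: bool = True
    seed: int = 0


class SklearnModel:
    """Uniform contract over scikit-learn classifiers (predict/prob_active)."""

    def __init__(self, kind: str, estimator, feature_names: list[str] | None):
        self.kind = kind
        self.estimator = estimator
        self.feature_names_ = feature_names

    def prob_active(self, X) -> np.ndarray:
        Xm, _ = _as_matrix(X, expect=self.feature_names_)
        proba = self.estimator.predict_proba(Xm)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(ACTIVE)]

    def predict_class(self, X) -> np.ndarray:
        Xm, _ = _as_matrix(X, expect=self.feature_names_)
        return self.estimator.predict(Xm)


def _check_two_class(y: np.ndarray) -> None:
    if len(set(y)) < 2:
        raise QsarError("training labels contain a single class")


def train_svm(X, y: Sequence[str], config: SVMConfig | None = None) -> SklearnModel:
    cfg = config or SVMConfig()
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    _check_two_class(y)
    steps = []
    if cfg.scale:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svm",
            SVC(
                C=cfg.C,
                gamma=cfg.gamma,
                kernel=cfg.kernel,
                class_weight="balanced",
                probability=True,
                random_state=cfg.seed,
            ),
        )
    )
    est = Pipeline(steps).fit(Xm, y)
    model = SklearnModel("SVM", est, names)
    model.config = cfg
    return model


def train_mlp(X, y: Sequence[str], config: MLPConfig | None = None) -> SklearnModel:
    cfg = config or MLPConfig()
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    _check_two_class(y)
    steps = []
    if cfg.scale:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "mlp",
            MLPClassifier(
                hidden_layer_sizes=cfg.layer_sizes[:-1],
                activation=cfg.activation,
                batch_size=min(cfg.batch_size, len(y)),
                max_iter=cfg.epochs,
                random_state=cfg.seed,
            ),
        )
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        est = Pipeline(steps).fit(Xm, y)
    model = SklearnModel("MLP", est, names)
    model.config = cfg
    return model


def consensus_predict(models: Sequence, X) -> np.ndarray:
    """Per-molecule majority vote over an odd number of fitted models."""
    if len(models) % 2 == 0:
        raise QsarError("consensus requires an odd number of models (tie-unsafe)")
    votes = np.stack([m.predict_class(X) for m in models])
    active = np.sum(votes == ACTIVE, axis=0)
    return np.where(active * 2 > len(models), ACTIVE, INACTIVE)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def save_model(model, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path):
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise QsarError(
            f"unsupported model format version: {blob.get('format_version')}"
        )
    return blob["model"]
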