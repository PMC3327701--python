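"""SVM classification of cohorts: grid-searched training, repeated stratified
k-fold evaluation, side-specific classifier combination, and permutation
significance testing.

Two schemes are supported:

* ``volumetric`` — an RBF-kernel SVM on the ICV-normalized volumes of the
  top-ranked structures;
* ``spectral`` — a linear SVM on the per-structure spectral embedding
  features (k eigenvectors per structure).

Hyperparameters (slack penalty C, RBF width gamma, and the number of
structures D) are chosen by an exhaustive grid search scored with
leave-one-out accuracy on the training split only. Structure ranking is
recomputed inside every training split and inside every permutation, so no
test label ever influences selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .selection import SeparabilityEngine, SeparabilityParams
from .spectral import nystrom_embedding, similarity_matrix, graph_laplacian, spectral_embed, zscore
from .volumetry import CohortTable

__all__ = [
    "ClassifierSpec",
    "GridChoice",
    "Metrics",
    "CVReport",
    "PermutationResult",
    "PosteriorModel",
    "train_with_grid",
    "evaluate_repeated_kfold",
    "combine_side_classifiers",
    "train_posterior_model",
    "permutation_test",
    "metrics_from_confusion",
    "infer_positive_label",
]


def _libsvm_c_grid() -> tuple[float, ...]:
    return tuple(2.0**e for e in range(-5, 16, 2))


def _libsvm_gamma_grid() -> tuple[float, ...]:
    return tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class ClassifierSpec:
    """Classification scheme and hyperparameter search space.

    The default grids follow the coarse log-spaced ranges customary for
    libsvm-style searches (C over 2^-5..2^15, gamma over 2^-15..2^3, both in
    steps of 2^2) with D searched over 1..20. :meth:`reduced` gives a small
    grid suitable for simulation studies where the effects are strong and an
    exhaustive search adds cost but no discrimination.
    """

    scheme: str = "volumetric"  # "volumetric" | "spectral"
    C_grid: tuple[float, ...] = field(default_factory=_libsvm_c_grid)
    gamma_grid: tuple[float, ...] = field(default_factory=_libsvm_gamma_grid)
    D_grid: tuple[int, ...] = tuple(range(1, 21))
    k: int = 2
    c: float = 2.0
    laplacian_variant: str = "unnormalized"
    embedding: str = "transductive"  # or "train_only"
    separability: SeparabilityParams = field(default_factory=SeparabilityParams)

    def __post_init__(self) -> None:
        if self.scheme not in ("volumetric", "spectral"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.embedding not in ("transductive", "train_only"):
            raise ValueError(f"unknown embedding mode {self.embedding!r}")
        for name, grid in (("C_grid", self.C_grid), ("gamma_grid", self.gamma_grid)):
            if not grid or any(v <= 0 for v in grid):
                raise ValueError(f"{name} must be nonempty and positive")
        if not self.D_grid or any(d < 1 for d in self.D_grid):
            raise ValueError("D_grid must be nonempty with D >= 1")

    @property
    def kernel(self) -> str:
        return "rbf" if self.scheme == "volumetric" else "linear"

    @classmethod
    def reduced(cls, scheme: str = "volumetric", **kw) -> "ClassifierSpec":
        return cls(
            scheme=scheme,
            C_grid=(1.0, 8.0, 64.0),
            gamma_grid=(0.125, 0.5, 2.0),
            D_grid=(1, 2, 4, 8),
            **kw,
        )


@dataclass(frozen=True)
class GridChoice:
    C: float
    gamma: float | None
    D: int
    loo_accuracy: float


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity, specificity as percentages.

    Metrics whose denominator is zero are NaN and listed in ``undefined``
    rather than silently reported as 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> Metrics:
    """Percent accuracy, sensitivity (= tp/(tp+fn)), specificity (= tn/(tn+fp))."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("confusion matrix is empty")
    undefined = []
    if tp + fn > 0:
        sens = 100.0 * tp / (tp + fn)
    else:
        sens, undefined = float("nan"), undefined + ["sensitivity"]
    if tn + fp > 0:
        spec = 100.0 * tn / (tn + fp)
    else:
        spec, undefined = float("nan"), undefined + ["specificity"]
    acc = 100.0 * (tp + tn) / total
    return Metrics(acc, sens, spec, tuple(undefined))


def infer_positive_label(classes) -> str:
    """Convention: patients (or the left-focus group in lateralization) are positive."""
    classes = sorted(str(c) for c in classes)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    non_control = [c for c in classes if "control" not in c.lower()]
    if len(non_control) == 1:
        return non_control[0]
    left = [c for c in classes if c.endswith("_L")]
    if len(left) == 1:
        return left[0]
    return classes[0]


# --- feature construction ---------------------------------------------------


class _FeatureBuilder:
    """Builds per-fold feature matrices ordered by a structure ranking.

    Volumetric features are the normalized volumes themselves; spectral
    features are per-structure embedding blocks. Transductive blocks depend
    only on the full cohort's volumes and are cached across folds; train-only
    blocks are recomputed per training split with Nystrom extension.
    """

    def __init__(self, cohort: CohortTable, spec: ClassifierSpec):
        self.spec = spec
        self.X = cohort.volume_matrix()
        self.names = cohort.structures
        self._cache: dict[int, np.ndarray] = {}

    @property
    def block_width(self) -> int:
        return 1 if self.spec.scheme == "volumetric" else self.spec.k

    def _transductive_block(self, s: int) -> np.ndarray:
        if s not in self._cache:
            z = zscore(self.X[:, s], name=self.names[s])
            W = similarity_matrix(z, self.spec.c)
            L = graph_laplacian(W, self.spec.laplacian_variant)
            self._cache[s] = spectral_embed(L, self.spec.k)
        return self._cache[s]

    def _train_only_block(self, s: int, train_idx: np.ndarray) -> np.ndarray:
        col = self.X[:, s]
        tr = col[train_idx]
        sd = tr.std()
        if sd == 0:
            raise ValueError(f"zero variance in training split for {self.names[s]}")
        z_all = (col - tr.mean()) / sd
        return nystrom_embedding(z_all[train_idx], z_all, self.spec.k, self.spec.c)

    def matrix(self, struct_indices, train_idx) -> np.ndarray:
        """Full-row (all subjects) feature matrix, standardized on train rows."""
        struct_indices = np.asarray(struct_indices)
        train_idx = np.asarray(train_idx)
        if self.spec.scheme == "volumetric":
            F = self.X[:, struct_indices].astype(float)
        elif self.spec.embedding == "transductive":
            F = np.hstack([self._transductive_block(int(s)) for s in struct_indices])
        else:
            F = np.hstack(
                [self._train_only_block(int(s), train_idx) for s in struct_indices]
            )
        mu = F[train_idx].mean(axis=0)
        sd = F[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        return (F - mu) / sd


def _make_svc(spec: ClassifierSpec, C: float, gamma: float | None) -> SVC:
    if spec.kernel == "rbf":
        return SVC(kernel="rbf", C=C, gamma=gamma)
    return SVC(kernel="linear", C=C)


def _loo_correct(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, C, gamma, best: int = -1
) -> int:
    """Number of correct leave-one-out predictions.

    Aborts (returning -1) as soon as the running count can no longer strictly
    exceed ``best`` — a pure optimization that leaves the grid-search argmax
    and its tie-breaking unchanged.
    """
    n = len(y)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        if correct + (n - i) <= best:
            return -1
        tr = idx != i
        if len(np.unique(y[tr])) < 2:
            return -1
        model = _make_svc(spec, C, gamma)
        model.fit(X[tr], y[tr])
        correct += int(model.predict(X[i : i + 1])[0] == y[i])
    return correct


def train_with_grid(features, labels, spec: ClassifierSpec):
    """Exhaustive (C, gamma, D) grid search scored by leave-one-out accuracy.

    ``features`` must be the training-split feature matrix with columns
    ordered by the structure ranking (one column per structure in the
    volumetric scheme, k columns per structure in the spectral scheme); the
    D axis of the grid keeps the leading D structure blocks. Ties are broken
    toward smaller D, then smaller C, then smaller gamma; the winning
    combination is refit on the whole training split.

    Returns ``(model, choice)`` with ``choice`` a :class:`GridChoice`.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 3:
        raise ValueError("training split needs two classes with >= 3 members each")
    width = 1 if spec.scheme == "volumetric" else spec.k
    max_d = X.shape[1] // width
    d_grid = [d for d in sorted(set(spec.D_grid)) if d <= max_d]
    if not d_grid:
        raise ValueError(
            f"no feasible D in grid {spec.D_grid} for {max_d} available structures"
        )
    gamma_grid = sorted(set(spec.gamma_grid)) if spec.kernel == "rbf" else [None]
    n = len(y)
    best: GridChoice | None = None
    best_correct = -1
    done = False
    for D in d_grid:  # ascending: ties keep the smallest D, then C, then gamma
        Xd = X[:, : D * width]
        for C in sorted(set(spec.C_grid)):
            for gamma in gamma_grid:
                correct = _loo_correct(Xd, y, spec, C, gamma, best=best_correct)
                if correct > best_correct:
                    best_correct = correct
                    best = GridChoice(C=C, gamma=gamma, D=D, loo_accuracy=correct / n)
                if best_correct == n:
                    done = True  # a perfect score cannot be strictly beaten
                    break
            if done:
                break
        if done:
            break
    if best is None:
        raise ValueError("all grid points degenerate (single-class LOO folds)")
    model = _make_svc(spec, best.C, best.gamma)
    model.fit(X[:, : best.D * width], y)
    return model, best


# --- repeated k-fold evaluation ---------------------------------------------


@dataclass
class CVReport:
    """Repeated stratified k-fold results for one scheme."""

    scheme: str
    folds: int
    repeats: int
    positive_label: str
    subject_ids: tuple[str, ...]
    accuracy: np.ndarray  # per repeat, %
    sensitivity: np.ndarray
    specificity: np.ndarray
    chosen: list[list[GridChoice]]  # [repeat][fold]
    fold_assignments: np.ndarray  # (repeats, N) fold index per subject
    predictions: np.ndarray  # (repeats, N) predicted labels

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.accuracy))

    @property
    def sensitivity_mean(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def specificity_mean(self) -> float:
        return float(np.nanmean(self.specificity))

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "folds": self.folds,
            "repeats": self.repeats,
            "positive_label": self.positive_label,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity_mean": self.sensitivity_mean,
            "sensitivity_sd": float(np.nanstd(self.sensitivity)),
            "specificity_mean": self.specificity_mean,
            "specificity_sd": float(np.nanstd(self.specificity)),
            "chosen_D_mode": int(
                np.bincount([c.D for r in self.chosen for c in r]).argmax()
            ),
        }

    def to_json(self) -> str:
        obj = self.summary()
        obj["accuracy_per_repeat"] = self.accuracy.tolist()
        obj["sensitivity_per_repeat"] = self.sensitivity.tolist()
        obj["specificity_per_repeat"] = self.specificity.tolist()
        obj["fold_assignments"] = self.fold_assignments.tolist()
        obj["predictions"] = self.predictions.tolist()
        obj["subject_ids"] = list(self.subject_ids)
        obj["chosen"] = [
            [{"C": c.C, "gamma": c.gamma, "D": c.D, "loo": c.loo_accuracy} for c in r]
            for r in self.chosen
        ]
        return json.dumps(obj, indent=1)


def _fold_seed(seed: int, repeat: int, attempt: int = 0) -> int:
    return int((seed * 100003 + repeat * 7919 + attempt * 104729) % (2**31 - 1))


def _stratified_splits(y: np.ndarray, folds: int, seed: int, repeat: int):
    """Seeded stratified splits, redrawn (bounded) if a training split is
    single-class.

    ``folds == n`` is the leave-one-out limit: every subject is its own test
    fold (stratification is vacuous for singleton test sets, and every
    training split keeps both classes as long as each class has >= 2
    members).
    """
    n = len(y)
    if folds == n:
        idx = np.arange(n)
        splits = [(idx[idx != i], np.array([i])) for i in range(n)]
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            return splits
        raise RuntimeError("leave-one-out needs >= 2 members per class")
    for attempt in range(100):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=_fold_seed(seed, repeat, attempt)
        )
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            return splits
    raise RuntimeError("could not draw non-degenerate stratified folds in 100 tries")


def evaluate_repeated_kfold(
    cohort: CohortTable,
    labels=None,
    spec: ClassifierSpec | None = None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    positive_label: str | None = None,
) -> CVReport:
    """Repeated, seeded, stratified k-fold evaluation of one scheme.

    Structure ranking (and, in train-only mode, the spectral embedding) is
    recomputed from the training split of every fold; the grid search sees
    training data only. Metrics are computed per repeat from the pooled fold
    predictions; means and SDs are taken over repeats.
    """
    spec = spec or ClassifierSpec()
    if not cohort.normalized:
        raise ValueError("cohort must be ICV-normalized")
    y = np.asarray(labels if labels is not None else cohort.labels())
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    pos = positive_label or infer_positive_label(classes)
    if pos not in classes:
        raise ValueError(f"positive label {pos!r} not among classes {list(classes)}")
    n = len(y)
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in 2..{n}")

    engine = SeparabilityEngine(cohort, spec.separability)
    builder = _FeatureBuilder(cohort, spec)
    max_d = max(spec.D_grid)

    acc = np.empty(repeats)
    sens = np.empty(repeats)
    specif = np.empty(repeats)
    fold_assign = np.full((repeats, n), -1, dtype=int)
    preds = np.empty((repeats, n), dtype=object)
    chosen_all: list[list[GridChoice]] = []

    for r in range(repeats):
        splits = _stratified_splits(y, folds, seed, r)
        chosen_r: list[GridChoice] = []
        for f, (train_idx, test_idx) in enumerate(splits):
            order = engine.rank(train_idx, y[train_idx])
            top = order[: min(max_d, len(order))]
            F = builder.matrix(top, train_idx)
            model, choice = train_with_grid(F[train_idx], y[train_idx], spec)
            width = builder.block_width
            yhat = model.predict(F[test_idx][:, : choice.D * width])
            preds[r, test_idx] = yhat
            fold_assign[r, test_idx] = f
            chosen_r.append(choice)
        chosen_all.append(chosen_r)
        is_pos = y == pos
        hit = preds[r] == y
        tp = int(np.sum(hit & is_pos))
        fn = int(np.sum(~hit & is_pos))
        tn = int(np.sum(hit & ~is_pos))
        fp = int(np.sum(~hit & ~is_pos))
        m = metrics_from_confusion(tp, fn, tn, fp)
        acc[r], sens[r], specif[r] = m.accuracy, m.sensitivity, m.specificity

    return CVReport(
        scheme=spec.scheme,
        folds=folds,
        repeats=repeats,
        positive_label=pos,
        subject_ids=tuple(cohort.data["subject_id"].astype(str)),
        accuracy=acc,
        sensitivity=sens,
        specificity=specif,
        chosen=chosen_all,
        fold_assignments=fold_assign,
        predictions=preds,
    )


# --- side-specific classifier combination -----------------------------------


@dataclass
class PosteriorModel:
    """A fitted SVM with Platt-style posteriors over named features."""

    estimator: object  # fitted classifier with predict_proba and classes_
    feature_names: tuple[str, ...]
    positive_label: str
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def patient_posterior(self, subject_features) -> float:
        try:
            x = np.array(
                [float(subject_features[n]) for n in self.feature_names]
            )
        except KeyError as exc:
            raise KeyError(f"subject features missing {exc.args[0]!r}") from exc
        x = (x - self.feature_means) / self.feature_sds
        proba = self.estimator.predict_proba(x[None, :])[0]
        pos_idx = list(self.estimator.classes_).index(self.positive_label)
        return float(proba[pos_idx])


def train_posterior_model(
    cohort: CohortTable,
    structures,
    patient_groups,
    control_group: str,
    spec: ClassifierSpec | None = None,
    C: float = 1.0,
    gamma: float = 0.5,
    seed: int = 0,
) -> PosteriorModel:
    """Fit one side-specific classifier with calibrated posteriors.

    The positive ("patient") class pools ``patient_groups``; features are the
    z-scored normalized volumes of the given structures.
    """
    spec = spec or ClassifierSpec()
    if not cohort.normalized:
        raise ValueError("cohort must be ICV-normalized")
    patient_groups = (
        [patient_groups] if isinstance(patient_groups, str) else list(patient_groups)
    )
    sub = cohort.select_groups(patient_groups + [control_group])
    y = np.where(np.isin(sub.labels(), patient_groups), "patient", "control")
    X = sub.data[list(structures)].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    # Platt-style sigmoid on SVM decision values, fit by internal CV
    est = CalibratedClassifierCV(
        _make_svc(spec, C, gamma), method="sigmoid", cv=3, ensemble=False
    )
    est.fit((X - mu) / sd, y)
    return PosteriorModel(
        estimator=est,
        feature_names=tuple(structures),
        positive_label="patient",
        feature_means=mu,
        feature_sds=sd,
    )


def combine_side_classifiers(
    model_L: PosteriorModel, model_R: PosteriorModel, subject_features
) -> tuple[str, float]:
    """Max rule over the two side-specific patient posteriors.

    The subject is labelled ``"patient"`` iff the larger of the two patient
    posteriors strictly exceeds 0.5; the reported posterior is that maximum.
    """
    p_l = model_L.patient_posterior(subject_features)
    p_r = model_R.patient_posterior(subject_features)
    p = max(p_l, p_r)
    return ("patient" if p > 0.5 else "control"), p


# --- permutation testing -----------------------------------------------------


@dataclass(frozen=True)
class PermutationResult:
    n_permutations: int
    null_accuracies: np.ndarray  # %
    observed_accuracy: float  # %
    p_value: float
    statistic: float  # standardized observed accuracy against the null

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_permutations": self.n_permutations,
                "observed_accuracy": self.observed_accuracy,
                "p_value": self.p_value,
                "statistic": self.statistic,
                "null_mean": float(self.null_accuracies.mean()),
                "null_sd": float(self.null_accuracies.std()),
            },
            indent=1,
        )


def _median_value(grid) -> float:
    vals = sorted(grid)
    return vals[len(vals) // 2]


def _loo_accuracy_full(
    y: np.ndarray,
    spec: ClassifierSpec,
    engine: SeparabilityEngine,
    builder: _FeatureBuilder,
    D: int,
    C: float,
    gamma: float | None,
) -> float:
    """Leave-one-out accuracy with ranking redone inside every training split.

    Rankings for all leave-one-out splits come from the engine's vectorized
    per-split criterion, which is exactly the training-labels-only ranking of
    each split (see SeparabilityEngine.criterion_values_loo).
    """
    n = len(y)
    idx = np.arange(n)
    width = builder.block_width
    J_loo = engine.criterion_values_loo(y)  # row i: criterion without subject i
    correct = 0
    for i in range(n):
        tr = idx[idx != i]
        top = np.argsort(-J_loo[i], kind="stable")[:D]
        F = builder.matrix(top, tr)
        model = _make_svc(spec, C, gamma)
        model.fit(F[tr], y[tr])
        correct += int(model.predict(F[i : i + 1, : D * width])[0] == y[i])
    return 100.0 * correct / n


def permutation_test(
    cohort: CohortTable,
    labels=None,
    spec: ClassifierSpec | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    D: int | None = None,
    C: float | None = None,
    gamma: float | None = None,
) -> PermutationResult:
    """Permutation test of the leave-one-out classification rate.

    For each permutation the class labels are shuffled and the full pipeline
    — structure ranking on each LOO training split, then classification of
    the held-out subject with a fixed-hyperparameter classifier on the top D
    structures — is re-run. The p-value is (1 + #{null >= observed}) /
    (1 + n_permutations); the statistic standardizes the observed accuracy
    against the null mean and SD.

    The classifier hyperparameters are fixed (defaults: grid medians) rather
    than re-searched per permutation, matching a fixed "classifier based on
    the top ranked structures".
    """
    spec = spec or ClassifierSpec()
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    if not cohort.normalized:
        raise ValueError("cohort must be ICV-normalized")
    y = np.asarray(labels if labels is not None else cohort.labels())
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 members each")
    D = D if D is not None else min(_median_value(spec.D_grid), len(cohort.structures))
    C = C if C is not None else _median_value(spec.C_grid)
    if gamma is None and spec.kernel == "rbf":
        gamma = _median_value(spec.gamma_grid)

    engine = SeparabilityEngine(cohort, spec.separability)
    builder = _FeatureBuilder(cohort, spec)
    observed = _loo_accuracy_full(y, spec, engine, builder, D, C, gamma)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        null[b] = _loo_accuracy_full(y_perm, spec, engine, builder, D, C, gamma)

    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    sd = null.std()
    stat = (observed - null.mean()) / sd if sd > 0 else float("inf")
    return PermutationResult(
        n_permutations=n_permutations,
        null_accuracies=null,
        observed_accuracy=observed,
        p_value=float(p),
        statistic=float(stat),
    )
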