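"""RBF-kernel SVM classification with two-level validation.

Outer level: repeated stratified 70/30 hold-out (default 50 repeats).
Inner level: k-fold cross-validated grid search over (C, gamma) on the
training part only.  Features are z-scored with training-fold statistics.
Class probabilities come from Platt scaling (pairwise coupling for three
classes), so each spectrum can be assigned to the class with the highest
probability.

The split unit defaults to ``subject``: all 15 replicate scans of a serum
sample stay on one side of the split, which is the leakage-free design.
``unit="spectrum"`` splits individual scans, letting replicates of one
subject appear in both train and test — optimistic, but provided because
splitting "the total data" at the spectrum level is how such studies often
report their numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluate_report import MetricsSummary, confusion_metrics, roc_auc
from .select_features import FeatureMask, apply_mask, stability_select
from .spectra_io import SpectrumSet

__all__ = [
    "ClassifierSpec",
    "SplitPlan",
    "SelectionSpec",
    "TrainedModel",
    "train_rbf_svm",
    "predict_spectra",
    "repeated_holdout",
    "positive_class",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """RBF-SVM hyperparameter search space."""

    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    inner_folds: int = 5
    probability_outputs: bool = True

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")


@dataclass(frozen=True)
class SplitPlan:
    """Outer hold-out design."""

    train_fraction: float = 0.7
    n_repeats: int = 50
    unit: str = "subject"  # or "spectrum"
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.unit not in ("subject", "spectrum"):
            raise ValueError("unit must be 'subject' or 'spectrum'")


@dataclass(frozen=True)
class SelectionSpec:
    """Stability-selection settings for per-repeat (in-fold) feature selection."""

    n_repeats: int = 100
    subsample_fraction: float = 0.7
    alpha: float = 0.05
    min_hits: int = 70
    unit: str = "spectrum"


@dataclass
class TrainedModel:
    """Fitted scaler + RBF-SVM with Platt-scaled probabilities."""

    pipeline: Pipeline
    classes: tuple[str, ...]
    best_params: dict[str, float]
    inner_cv_accuracy: float
    n_training_spectra: int

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return predict_spectra(self, x)

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(np.asarray(x, dtype=float))


def train_rbf_svm(
    x: np.ndarray, y: np.ndarray, spec: ClassifierSpec | None = None, seed: int = 0
) -> TrainedModel:
    """Grid-searched soft-margin RBF SVM on z-scored features.

    (C, gamma) are chosen by ``inner_folds``-fold cross-validated accuracy;
    the winning setting is refit on all training data.
    """
    spec = spec or ClassifierSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contain a single class")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    probability=spec.probability_outputs,
                    random_state=seed,
                ),
            ),
        ]
    )
    n_folds = min(spec.inner_folds, int(min(np.bincount(np.searchsorted(classes, y)))))
    n_folds = max(2, n_folds)
    if spec.probability_outputs:
        # accuracy picks (C, gamma); exact accuracy ties go to the setting
        # with the best cross-validated log-loss, so a degenerate Platt
        # calibration (flat 0.5 probabilities) never wins a tie
        scoring = {"acc": "accuracy", "nll": "neg_log_loss"}

        def refit(cv_results) -> int:
            acc = np.asarray(cv_results["mean_test_acc"], dtype=float)
            nll = np.asarray(cv_results["mean_test_nll"], dtype=float)
            tied = np.where(acc >= acc.max() - 1e-12)[0]
            return int(tied[np.argmax(nll[tied])])

        acc_key = "mean_test_acc"
    else:
        scoring, refit, acc_key = "accuracy", True, "mean_test_score"
    search = GridSearchCV(
        pipe,
        {"svm__C": list(spec.C_grid), "svm__gamma": list(spec.gamma_grid)},
        scoring=scoring,
        cv=StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=refit,
    )
    with warnings.catch_warnings():
        # Platt-scaled probabilities via SVC(probability=True) are the
        # intended interface here; silence the pending-rename notice
        warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")
        search.fit(x, y)
    return TrainedModel(
        pipeline=search.best_estimator_,
        classes=tuple(str(c) for c in search.best_estimator_.classes_),
        best_params={
            "C": float(search.best_params_["svm__C"]),
            "gamma": float(search.best_params_["svm__gamma"]),
        },
        inner_cv_accuracy=float(search.cv_results_[acc_key][search.best_index_]),
        n_training_spectra=int(x.shape[0]),
    )


def predict_spectra(model: TrainedModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-spectrum class probabilities and argmax classes.

    Probability rows sum to 1; exact ties go to the lexicographically first
    class (model classes are kept sorted).
    """
    x = np.asarray(x, dtype=float)
    expected = model.pipeline.named_steps["scale"].n_features_in_
    if x.ndim != 2 or x.shape[1] != expected:
        raise ValueError(f"feature matrix has {x.shape[-1] if x.ndim else 0} columns, model expects {expected}")
    probs = model.pipeline.predict_proba(x)
    # sklearn's classes_ are sorted, so argmax's first-maximum rule is the
    # lexicographic tie-break
    labels = np.array([model.classes[i] for i in np.argmax(probs, axis=1)], dtype=object)
    return probs, labels


def positive_class(groups: tuple[str, ...]) -> str:
    """Diseased class of a pairwise comparison (cancer over benign over healthy)."""
    for g in ("cancer", "benign"):
        if g in groups:
            return g
    return groups[0]


def _split_indices(
    sset: SpectrumSet, groups: tuple[str, ...], plan: SplitPlan, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    labels = sset.labels()
    if plan.unit == "subject":
        subject_of = sset.subject_ids()
        train_subjects: list[str] = []
        for g in groups:
            subs = sorted({sid for sid, gg in zip(subject_of, labels) if gg == g})
            subs = list(rng.permutation(subs))
            n_train = int(round(plan.train_fraction * len(subs)))
            n_train = min(max(n_train, 1), len(subs) - 1)
            train_subjects.extend(subs[:n_train])
        train_mask = np.isin(subject_of, train_subjects)
        in_groups = np.isin(labels, groups)
        return np.where(train_mask & in_groups)[0], np.where(~train_mask & in_groups)[0]
    # spectrum-level split, stratified by class
    train_idx: list[int] = []
    test_idx: list[int] = []
    for g in groups:
        idx = np.where(labels == g)[0]
        idx = rng.permutation(idx)
        n_train = int(round(plan.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def repeated_holdout(
    sset: SpectrumSet,
    spec: ClassifierSpec | None = None,
    plan: SplitPlan | None = None,
    mask: FeatureMask | None = None,
    selection: SelectionSpec | None = None,
    comparison: tuple[str, str] | None = None,
    positive: str | None = None,
    collect_scores: bool = False,
) -> MetricsSummary | tuple[MetricsSummary, np.ndarray, np.ndarray]:
    """Repeated stratified 70/30 hold-out evaluation of one pairwise contrast.

    Exactly one of ``mask`` (features fixed in advance) or ``selection``
    (stability selection recomputed inside each training fold — the
    leakage-free default of the pipeline) must be given.  Per repeat the
    model is trained with inner grid search and scored on the held-out part;
    sensitivity, specificity, accuracy and AUC are recorded and summarised
    as mean +/- SD.  A repeat whose test part lost a class is skipped and
    counted in ``skipped_repeats``.

    With ``collect_scores`` the held-out probability scores and truths of
    all repeats are returned too (for a pooled ROC overlay).
    """
    spec = spec or ClassifierSpec()
    plan = plan or SplitPlan()
    if (mask is None) == (selection is None):
        raise ValueError("provide exactly one of mask= or selection=")
    if comparison is None:
        if mask is not None and len(mask.comparison) == 2:
            comparison = tuple(mask.comparison)  # type: ignore[assignment]
        else:
            groups = [g for g in sset.groups_present() if g != "unknown"]
            if len(groups) != 2:
                raise ValueError("comparison groups ambiguous; pass comparison=")
            comparison = (groups[0], groups[1])
    pos = positive or positive_class(comparison)
    pair = sset.select_groups(comparison)
    if len(pair.groups_present()) < 2:
        raise ValueError("both comparison groups must be present")

    sens, specif, acc, auc = [], [], [], []
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    skipped = 0
    for r in range(plan.n_repeats):
        ss = np.random.SeedSequence(plan.seed, spawn_key=(r,))
        rng = np.random.default_rng(ss)
        rep_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        train_idx, test_idx = _split_indices(pair, comparison, plan, rng)
        train_set = pair.select_indices(train_idx)
        test_set = pair.select_indices(test_idx)
        if len(set(test_set.labels())) < 2 or len(set(train_set.labels())) < 2:
            skipped += 1
            continue
        if selection is not None:
            rep_mask = stability_select(
                train_set,
                comparison,
                n_repeats=selection.n_repeats,
                subsample_fraction=selection.subsample_fraction,
                alpha=selection.alpha,
                min_hits=selection.min_hits,
                seed=rep_seed,
                unit=selection.unit,
            )
            if rep_mask.n_selected == 0:
                skipped += 1
                continue
        else:
            rep_mask = mask  # type: ignore[assignment]
        x_train, y_train = apply_mask(train_set, rep_mask)
        x_test, y_test = apply_mask(test_set, rep_mask)
        model = train_rbf_svm(x_train, y_train, spec, seed=rep_seed)
        probs, y_pred = predict_spectra(model, x_test)
        pos_col = model.classes.index(pos)
        scores = probs[:, pos_col]
        se, sp, ac = confusion_metrics(y_test, y_pred, pos)
        _, _, a = roc_auc(scores, y_test == pos)
        sens.append(se)
        specif.append(sp)
        acc.append(ac)
        auc.append(a)
        if collect_scores:
            pooled_scores.append(scores)
            pooled_truth.append(y_test == pos)
    summary = MetricsSummary(
        comparison=f"{comparison[0]}_vs_{comparison[1]}",
        sensitivity=np.array(sens),
        specificity=np.array(specif),
        accuracy=np.array(acc),
        auc=np.array(auc),
        skipped_repeats=skipped,
    )
    if collect_scores:
        return (
            summary,
            np.concatenate(pooled_scores) if pooled_scores else np.array([]),
            np.concatenate(pooled_truth) if pooled_truth else np.array([]),
        )
    return summary


def train_holdout_ensemble(
    sset: SpectrumSet,
    mask: FeatureMask,
    spec: ClassifierSpec | None = None,
    n_models: int = 5,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> list[TrainedModel]:
    """Ensemble of multiclass models, each fit on a random subject-level 70% draw.

    Used for external validation: every spectrum of a blinded sample is
    predicted by every model, so a sample accumulates (spectra x models)
    votes, mirroring designs that report more votes per sample than it has
    scans.
    """
    spec = spec or ClassifierSpec()
    groups = tuple(g for g in sset.groups_present() if g != "unknown")
    plan = SplitPlan(train_fraction=train_fraction, n_repeats=n_models, unit="subject", seed=seed)
    models: list[TrainedModel] = []
    for r in range(n_models):
        ss = np.random.SeedSequence(seed, spawn_key=(r,))
        rng = np.random.default_rng(ss)
        rep_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        train_idx, _ = _split_indices(sset, groups, plan, rng)
        train_set = sset.select_indices(train_idx)
        x, y = apply_mask(train_set, mask)
        models.append(train_rbf_svm(x, y, spec, seed=rep_seed))
    return models
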