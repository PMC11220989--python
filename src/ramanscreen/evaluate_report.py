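"""Performance evaluation: confusion metrics, nonparametric ROC/AUC,
sample-level majority voting and report rendering.

The screening design predicts each replicate spectrum independently and
then assigns a serum sample to the class receiving the most spectrum-level
predictions (majority vote), so a handful of misclassified scans cannot
flip a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .select_features import FeatureMask, apply_mask
from .spectra_io import SpectrumSet

__all__ = [
    "MetricsSummary",
    "VoteRecord",
    "confusion_metrics",
    "roc_auc",
    "majority_vote",
    "external_validate",
    "render_report",
]


@dataclass
class MetricsSummary:
    """Per-repeat sensitivity/specificity/accuracy/AUC with mean +/- SD."""

    comparison: str
    sensitivity: np.ndarray = field(default_factory=lambda: np.array([]))
    specificity: np.ndarray = field(default_factory=lambda: np.array([]))
    accuracy: np.ndarray = field(default_factory=lambda: np.array([]))
    auc: np.ndarray = field(default_factory=lambda: np.array([]))
    skipped_repeats: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "accuracy", "auc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")
            setattr(self, name, arr)
        lengths = {
            self.sensitivity.size,
            self.specificity.size,
            self.accuracy.size,
            self.auc.size,
        }
        if len(lengths) != 1:
            raise ValueError("per-repeat metric vectors must have equal length")

    @property
    def n_repeats(self) -> int:
        return self.accuracy.size

    def mean(self, name: str) -> float:
        arr = getattr(self, name)
        return float(np.mean(arr)) if arr.size else float("nan")

    def sd(self, name: str) -> float:
        arr = getattr(self, name)
        return float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "comparison": self.comparison,
                "repeat": np.arange(1, self.n_repeats + 1),
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
                "auc": self.auc,
            }
        )

    def summary_row(self) -> dict[str, str]:
        row = {"comparison": self.comparison}
        for name in ("auc", "sensitivity", "specificity", "accuracy"):
            row[name] = f"{self.mean(name):.3f} ± {self.sd(name):.3f}"
        return row

    def __str__(self) -> str:
        parts = [
            f"{name}={self.mean(name):.3f}±{self.sd(name):.3f}"
            for name in ("auc", "sensitivity", "specificity", "accuracy")
        ]
        return f"{self.comparison}: " + ", ".join(parts) + f" ({self.n_repeats} repeats)"


@dataclass
class VoteRecord:
    """Per-sample spectrum-prediction counts and the majority-vote class."""

    sample_id: str
    counts: dict[str, int]
    predicted: str
    true_class: str = "unknown"
    tie: bool = False

    @property
    def correct(self) -> bool | None:
        if self.true_class == "unknown":
            return None
        return self.predicted == self.true_class


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str
) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy of binary predictions.

    ``sensitivity = TP/(TP+FN)``, ``specificity = TN/(TN+FP)``,
    ``accuracy = (TP+TN)/N`` with ``positive`` defining the diseased class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = y_true == positive
    if not pos.any():
        raise ValueError(f"positive class {positive!r} absent from y_true")
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    accuracy = (tp + tn) / y_true.size
    return sensitivity, specificity, accuracy


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC curve and trapezoidal AUC.

    ``labels`` are booleans (True = positive).  The AUC equals the
    Mann-Whitney probability that a random positive outscores a random
    negative, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(labels, scores)
    auc = float(skmetrics.roc_auc_score(labels, scores))
    return fpr, tpr, auc


def majority_vote(counts: dict[str, int]) -> tuple[str, bool]:
    """Class with the most spectrum-level predictions.

    Returns ``(predicted, tie)``; ties are broken lexicographically and
    flagged rather than silently resolved.
    """
    if not counts or sum(counts.values()) <= 0:
        raise ValueError("vote counts empty or all zero")
    if any(v < 0 for v in counts.values()):
        raise ValueError("vote counts must be non-negative")
    best = max(counts.values())
    winners = sorted(c for c, v in counts.items() if v == best)
    return winners[0], len(winners) > 1


def external_validate(
    models,
    external: SpectrumSet,
    mask: FeatureMask,
    truth: dict[str, str] | None = None,
) -> list[VoteRecord]:
    """Blinded external validation by spectrum-level prediction + majority vote.

    ``models`` is one trained model or a sequence of them (an ensemble of
    hold-out repeats); every model predicts every external spectrum, counts
    are accumulated per sample over (spectra x models), and each sample is
    assigned the majority class.  If ``truth`` maps subject ids to classes,
    correctness is attached after voting (unblinding).
    """
    if not hasattr(models, "__iter__"):
        models = [models]
    models = list(models)
    if not models:
        raise ValueError("need at least one trained model")
    x, _ = apply_mask(external, mask)
    subject_ids = external.subject_ids()
    classes = list(models[0].classes)
    counts: dict[str, dict[str, int]] = {
        sid: {c: 0 for c in classes} for sid in external.subjects()
    }
    for model in models:
        if list(model.classes) != classes:
            raise ValueError("ensemble models disagree on class sets")
        _, predicted = model.predict(x)
        for sid, cls in zip(subject_ids, predicted):
            counts[sid][cls] += 1
    records: list[VoteRecord] = []
    for sid in external.subjects():
        predicted, tie = majority_vote(counts[sid])
        true_class = (truth or {}).get(sid, "unknown")
        records.append(VoteRecord(sid, counts[sid], predicted, true_class, tie))
    return records


# -- report rendering -------------------------------------------------------


def votes_to_frame(votes: list[VoteRecord]) -> pd.DataFrame:
    classes = sorted({c for v in votes for c in v.counts})
    rows = []
    for v in votes:
        row: dict[str, object] = {"sample_id": v.sample_id}
        for c in classes:
            row[f"votes_{c}"] = v.counts.get(c, 0)
        row.update(predicted=v.predicted, true_class=v.true_class, tie=v.tie)
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    out_dir,
    metrics: list[MetricsSummary] | None = None,
    votes: list[VoteRecord] | None = None,
    preprocessed: SpectrumSet | None = None,
    masks: dict[str, FeatureMask] | None = None,
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray, float]] | None = None,
) -> dict[str, Path]:
    """Write metric/vote tables (3-decimal CSV) and the standard figures.

    Figures: per-group mean spectra +/- SD, pairwise difference spectra,
    ANOVA hit-count profiles, ROC overlay.  Only the artefacts whose inputs
    were supplied are produced; the returned dict maps artefact names to
    paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if metrics:
        per_repeat = pd.concat([m.to_frame() for m in metrics], ignore_index=True)
        path = out_dir / "metrics_per_repeat.csv"
        per_repeat.to_csv(path, index=False, float_format="%.6f")
        written["metrics_per_repeat"] = path
        summary = pd.DataFrame([m.summary_row() for m in metrics])
        path = out_dir / "metrics_summary.csv"
        summary.to_csv(path, index=False)
        written["metrics_summary"] = path

    if votes:
        path = out_dir / "votes.csv"
        votes_to_frame(votes).to_csv(path, index=False)
        written["votes"] = path

    if preprocessed is not None and len(preprocessed):
        fig, axes = plt.subplots(2, 1, figsize=(9, 7), sharex=True)
        wn = preprocessed.grid.values
        means: dict[str, np.ndarray] = {}
        for g in preprocessed.groups_present():
            m = preprocessed.select_groups([g]).intensity_matrix()
            mu, sd = m.mean(axis=0), m.std(axis=0)
            means[g] = mu
            axes[0].plot(wn, mu, label=g)
            axes[0].fill_between(wn, mu - sd, mu + sd, alpha=0.25)
        axes[0].set_ylabel("normalized intensity")
        axes[0].legend()
        axes[0].set_title("mean preprocessed spectra ± SD")
        names = list(means)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                axes[1].plot(wn, means[names[i]] - means[names[j]], label=f"{names[i]} - {names[j]}")
        axes[1].axhline(0.0, color="k", lw=0.5)
        axes[1].set_xlabel("Raman shift (cm$^{-1}$)")
        axes[1].set_ylabel("difference")
        axes[1].legend()
        path = out_dir / "mean_spectra.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["mean_spectra"] = path

    if masks:
        fig, ax = plt.subplots(figsize=(9, 4))
        for name, mask in masks.items():
            ax.plot(mask.grid.values, mask.hit_counts, label=name)
        first = next(iter(masks.values()))
        ax.axhline(first.min_hits, color="k", ls="--", lw=0.8, label=f"threshold > {first.min_hits}")
        ax.set_xlabel("Raman shift (cm$^{-1}$)")
        ax.set_ylabel(f"significant repeats / {first.n_repeats}")
        ax.legend()
        path = out_dir / "hit_count_profiles.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["hit_counts"] = path

    if roc_curves:
        fig, ax = plt.subplots(figsize=(6, 6))
        for name, (fpr, tpr, auc) in roc_curves.items():
            ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        path = out_dir / "roc_overlay.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["roc_overlay"] = path

    return written
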