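"""End-to-end orchestration: simulate -> preprocess -> select -> evaluate ->
external validation -> report, reproducible from one master seed.

Each stage derives its own seed substream from the master seed, so a rerun
with an identical configuration writes byte-identical metric tables.  A
manifest records the configuration hash, the derived stage seeds, the
decision flags in effect (split unit, selection placement, hit-threshold
boundary rule) and a checksum per CSV artefact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import classify, evaluate_report, preprocess, select_features, spectra_io, synthetic_cohort
from .spectra_io import default_grid, write_spectrum_set

__all__ = ["RunConfig", "run_all", "load_run_config"]

_STAGES = ("simulate", "background", "select", "evaluate", "external", "report")
_PAIRS = (("cancer", "healthy"), ("benign", "healthy"), ("cancer", "benign"))


@dataclass(frozen=True)
class RunConfig:
    """Single configuration for a full pipeline run."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 10, "benign": 10, "cancer": 10}
    )
    n_external_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 5, "benign": 5, "cancer": 5}
    )
    grid_start: float = 400.0
    grid_stop: float = 1800.0
    grid_step: float = 1.0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    preprocess: dict = field(default_factory=dict)  # PreprocessConfig overrides
    selection: dict = field(default_factory=dict)  # SelectionSpec overrides
    classifier: dict = field(default_factory=dict)  # ClassifierSpec overrides
    split: dict = field(default_factory=dict)  # SplitPlan overrides
    selection_in_fold: bool = True
    external_model_repeats: int = 5
    out_dir: str = "ramanscreen_run"
    seed: int = 0


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def build_cohort_config(config: RunConfig) -> synthetic_cohort.CohortConfig:
    base = synthetic_cohort.CohortConfig(
        n_per_group=dict(config.n_per_group), seed=_stage_seed(config.seed, "simulate")
    )
    return replace(base, **config.cohort) if config.cohort else base


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "config": asdict(config),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in _STAGES},
        "decision_flags": {
            "split_unit": config.split.get("unit", "subject"),
            "selection_in_fold": config.selection_in_fold,
            "hit_threshold_rule": "strict (hits > min_hits)",
        },
        "stages": {},
        "checksums": {},
    }

    def log(stage: str, **info) -> None:
        manifest["stages"][stage] = {"wall_s": round(time.time() - t0, 2), **info}
        print(f"[{stage}] " + ", ".join(f"{k}={v}" for k, v in info.items()))

    grid = default_grid(config.grid_start, config.grid_stop, config.grid_step)

    # 1. simulate
    cohort_cfg = build_cohort_config(config)
    cohort, truth = synthetic_cohort.generate_cohort(cohort_cfg, grid)
    # same generative parameters (and hence the same container background)
    # as the model-building cohort; the external subjects use disjoint
    # substreams, so sharing the seed introduces no overlap
    external, ext_truth = synthetic_cohort.generate_external_set(
        cohort_cfg, grid, dict(config.n_external_per_group)
    )
    write_spectrum_set(cohort, out / "cohort.csv")
    write_spectrum_set(external, out / "external.csv")
    import pandas as pd

    pd.DataFrame(
        sorted(truth.labels.items()), columns=["subject_id", "true_group"]
    ).to_csv(out / "cohort_truth.csv", index=False)
    pd.DataFrame(
        sorted(ext_truth.labels.items()), columns=["subject_id", "true_group"]
    ).to_csv(out / "external_truth.csv", index=False)
    log("simulate", n_spectra=len(cohort), n_subjects=len(cohort.subjects()),
        n_external=len(external))

    # 2. preprocess (shared container-background estimate)
    pp_cfg = preprocess.PreprocessConfig(**config.preprocess)
    bg_scans = synthetic_cohort.generate_background_scans(cohort_cfg, grid)
    bg_mean = preprocess.mean_background(bg_scans)
    cohort_pp = preprocess.preprocess_set(cohort, bg_mean, pp_cfg)
    external_pp = preprocess.preprocess_set(external, bg_mean, pp_cfg)
    log("preprocess", n_spectra=len(cohort_pp), normalization=pp_cfg.normalization)

    # 3. stability selection (full-cohort masks, used for reporting and the
    #    external-validation feature set; per-fold selection happens in stage 4)
    sel = classify.SelectionSpec(**config.selection)
    select_seed = _stage_seed(config.seed, "select")
    masks: dict[str, select_features.FeatureMask] = {}
    for pair in _PAIRS:
        mask = select_features.stability_select(
            cohort_pp,
            pair,
            n_repeats=sel.n_repeats,
            subsample_fraction=sel.subsample_fraction,
            alpha=sel.alpha,
            min_hits=sel.min_hits,
            seed=select_seed + _PAIRS.index(pair),
            unit=sel.unit,
        )
        name = f"{pair[0]}_vs_{pair[1]}"
        masks[name] = mask
        pd.DataFrame(
            {
                "wavenumber": grid.values,
                "hit_count": mask.hit_counts,
                "selected": mask.selected.astype(int),
            }
        ).to_csv(out / f"mask_{name}.csv", index=False)
    log("select", **{k: m.n_selected for k, m in masks.items()})

    # 4. pairwise repeated hold-out
    cls_spec = classify.ClassifierSpec(**config.classifier)
    plan = classify.SplitPlan(seed=_stage_seed(config.seed, "evaluate"), **config.split)
    metrics: list[evaluate_report.MetricsSummary] = []
    roc_curves: dict[str, tuple] = {}
    for pair in _PAIRS:
        name = f"{pair[0]}_vs_{pair[1]}"
        kwargs: dict = {"comparison": pair, "collect_scores": True}
        if config.selection_in_fold:
            kwargs["selection"] = sel
        else:
            kwargs["mask"] = masks[name]
        summary, scores, is_pos = classify.repeated_holdout(
            cohort_pp, cls_spec, replace(plan, seed=plan.seed + _PAIRS.index(pair)), **kwargs
        )
        metrics.append(summary)
        if scores.size:
            roc_curves[name] = evaluate_report.roc_auc(scores, is_pos)
        print("  " + str(summary))
    log("evaluate", comparisons=len(metrics))

    # 5. blinded external validation: union of pairwise masks feeds an
    #    ensemble of three-class models; votes accumulate over spectra x models
    union = select_features.FeatureMask(
        grid,
        np.max([m.hit_counts for m in masks.values()], axis=0),
        np.any([m.selected for m in masks.values()], axis=0),
        n_repeats=sel.n_repeats,
        min_hits=sel.min_hits,
        alpha=sel.alpha,
        comparison=("healthy", "benign", "cancer"),
    )
    models = classify.train_holdout_ensemble(
        cohort_pp,
        union,
        cls_spec,
        n_models=config.external_model_repeats,
        seed=_stage_seed(config.seed, "external"),
    )
    votes = evaluate_report.external_validate(models, external_pp, union, ext_truth.labels)
    n_correct = sum(1 for v in votes if v.correct)
    log("external", n_samples=len(votes), n_correct=n_correct,
        votes_per_sample=config.external_model_repeats * cohort_cfg.scans_per_subject)

    # 6. report
    artefacts = evaluate_report.render_report(
        out, metrics=metrics, votes=votes, preprocessed=cohort_pp,
        masks=masks, roc_curves=roc_curves,
    )
    log("report", files=len(artefacts))

    for p in sorted(out.glob("*.csv")):
        manifest["checksums"][p.name] = _file_checksum(p)
    manifest["wall_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
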