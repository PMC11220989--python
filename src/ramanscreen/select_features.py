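"""Per-wavenumber ANOVA stability feature selection.

At every grid point a one-way fixed-effects F test compares intensity
across the groups being contrasted.  Because a single pass is sensitive to
the particular spectra drawn, the test is repeated over random
subject-stratified subsamples (default 100 repeats at fraction 0.7) and a
wavenumber is retained only when it reaches significance in strictly more
than ``min_hits`` repeats (default > 70 of 100).  The surviving wavenumbers
form the input features of the downstream SVM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra_io import SpectrumSet, WavenumberGrid

__all__ = [
    "FeatureMask",
    "EmptySelectionError",
    "anova_f",
    "stability_select",
    "apply_mask",
]


class EmptySelectionError(ValueError):
    """No wavenumber survived the stability threshold."""


class UndefinedFError(ValueError):
    """ANOVA F is 0/0: no variance between or within groups."""


@dataclass
class FeatureMask:
    """Stability-selection outcome over one wavenumber grid."""

    grid: WavenumberGrid
    hit_counts: np.ndarray  # per grid point, 0..n_repeats
    selected: np.ndarray  # boolean
    n_repeats: int = 100
    min_hits: int = 70
    alpha: float = 0.05
    comparison: tuple[str, ...] = ()
    subsample_fraction: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        self.hit_counts = np.asarray(self.hit_counts, dtype=int)
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.hit_counts.size != len(self.grid) or self.selected.size != len(self.grid):
            raise ValueError("mask vectors must match the grid length")
        if (self.hit_counts > self.n_repeats).any() or (self.hit_counts < 0).any():
            raise ValueError("hit counts must lie in 0..n_repeats")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def selected_wavenumbers(self) -> np.ndarray:
        return self.grid.values[self.selected]

    def all_true(self) -> "FeatureMask":
        """Mask selecting every grid point (bypass selection)."""
        return FeatureMask(
            self.grid,
            np.full(len(self.grid), self.n_repeats),
            np.ones(len(self.grid), bool),
            self.n_repeats,
            self.min_hits,
            self.alpha,
            self.comparison,
        )


def anova_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA.

    Returns ``(F, p)`` with ``F = MS_between / MS_within`` on
    ``(k - 1, N - k)`` degrees of freedom and ``p`` from the upper tail of
    the F distribution.  For two groups F equals the squared pooled-variance
    t statistic.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    dfb = len(arrays) - 1
    dfw = int(ns.sum()) - len(arrays)
    if ssw == 0.0 and ssb == 0.0:
        raise UndefinedFError("no variance within or between groups; F undefined")
    if ssw == 0.0:
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return f, p


def _anova_p_columns(group_mats: list[np.ndarray]) -> np.ndarray:
    """Vectorised one-way ANOVA p-values across the columns of stacked groups."""
    ns = np.array([m.shape[0] for m in group_mats])
    n_total = int(ns.sum())
    k = len(group_mats)
    means = np.vstack([m.mean(axis=0) for m in group_mats])  # k x P
    grand = (ns[:, None] * means).sum(axis=0) / n_total
    ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = np.zeros_like(ssb)
    for m, mu in zip(group_mats, means):
        ssw += ((m - mu) ** 2).sum(axis=0)
    dfb, dfw = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    # zero within-group variance: F infinite when a between-group difference
    # exists (p -> 0), undefined when both are zero (treated as no evidence)
    both_zero = (ssw == 0) & (ssb == 0)
    p = np.where(np.isnan(p) & ~both_zero, 0.0, p)
    p = np.where(both_zero, 1.0, p)
    return p


def _subject_stratified_indices(
    sset: SpectrumSet, groups: tuple[str, ...], fraction: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per group: row indices, sampled per subject at rate ``fraction``."""
    by_group_subject: dict[str, dict[str, list[int]]] = {g: {} for g in groups}
    for i, s in enumerate(sset.spectra):
        if s.group in by_group_subject:
            by_group_subject[s.group].setdefault(s.subject_id, []).append(i)
    out: dict[str, np.ndarray] = {}
    for g in groups:
        rows: list[int] = []
        for subject in sorted(by_group_subject[g]):
            idx = np.array(by_group_subject[g][subject])
            if fraction >= 1.0:
                take = idx
            else:
                m = max(1, int(round(fraction * idx.size)))
                take = rng.choice(idx, size=m, replace=False)
            rows.extend(int(i) for i in take)
        out[g] = np.array(sorted(rows), dtype=int)
    return out


def stability_select(
    sset: SpectrumSet,
    comparison: tuple[str, ...],
    n_repeats: int = 100,
    subsample_fraction: float = 0.7,
    alpha: float = 0.05,
    min_hits: int = 70,
    seed: int = 0,
    unit: str = "spectrum",
) -> FeatureMask:
    """Repeated subject-stratified subsampling + per-wavenumber ANOVA.

    For each of ``n_repeats`` repeats a random fraction of every subject's
    spectra is drawn, a one-way ANOVA across ``comparison`` groups is run at
    every wavenumber, and points with ``p < alpha`` score a hit.  Points with
    strictly more than ``min_hits`` hits are selected.  Each repeat uses its
    own deterministic substream of ``seed``, so hit counts do not depend on
    repeat ordering.

    ``unit="subject_mean"`` averages each subject's subsampled spectra before
    testing, avoiding the significance inflation that within-subject
    correlation causes at the spectrum level.
    """
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if len(comparison) < 2:
        raise ValueError("comparison needs at least two groups")
    groups_by_subject = sset.subject_group()
    for g in comparison:
        n_subj = sum(1 for s, gg in groups_by_subject.items() if gg == g)
        if n_subj < 3:
            raise ValueError(f"group {g!r} has {n_subj} subjects; need >= 3")
    x = sset.intensity_matrix()
    hit_counts = np.zeros(len(sset.grid), dtype=int)
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        idx = _subject_stratified_indices(sset, tuple(comparison), subsample_fraction, rng)
        mats = []
        for g in comparison:
            m = x[idx[g]]
            if unit == "subject_mean":
                subj = np.array([sset.spectra[i].subject_id for i in idx[g]])
                m = np.vstack([m[subj == u].mean(axis=0) for u in np.unique(subj)])
            mats.append(m)
        p = _anova_p_columns(mats)
        hit_counts += p < alpha
    selected = hit_counts > min_hits
    return FeatureMask(
        grid=sset.grid,
        hit_counts=hit_counts,
        selected=selected,
        n_repeats=n_repeats,
        min_hits=min_hits,
        alpha=alpha,
        comparison=tuple(comparison),
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def apply_mask(sset: SpectrumSet, mask: FeatureMask) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (spectra x selected wavenumbers) plus the label vector.

    Columns follow increasing wavenumber order.
    """
    if mask.grid != sset.grid:
        raise ValueError("mask grid does not match the spectrum set grid")
    if mask.n_selected == 0:
        raise EmptySelectionError("feature mask selects no wavenumbers")
    x = sset.intensity_matrix()[:, mask.selected]
    y = sset.labels()
    return x, y
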