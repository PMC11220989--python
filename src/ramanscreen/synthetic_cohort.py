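"""Synthetic serum-Raman cohort generator.

Emulates the statistical structure of a three-class serum screening study
(healthy controls, benign lung lesions, lung cancer) so every downstream
stage can be exercised with known ground truth:

* Lorentzian serum bands on a shared wavenumber grid, with class-dependent
  multiplicative intensity shifts at planted bands — the disease signal;
* a multiplicative log-normal per-subject latent factor, which correlates
  the 15 replicate scans (3 sessions x 5 scans) of a serum sample;
* a smooth container-background contribution (the sample tube scatters too);
* random polynomial baseline drift per spectrum (fluorescence-like);
* additive Gaussian shot-like noise;
* single-pixel cosmic-ray spikes, Poisson-many per spectrum.

Every draw is reproducible from one master seed; each subject consumes an
independent substream keyed by (group, subject index), so enlarging the
cohort leaves previously generated subjects bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_io import GROUPS, Spectrum, SpectrumSet, WavenumberGrid

__all__ = [
    "PeakSpec",
    "CohortConfig",
    "GroundTruth",
    "default_peaks",
    "default_cohort_config",
    "lorentzian",
    "generate_background",
    "generate_background_scans",
    "generate_cohort",
    "generate_external_set",
]

_CLASS_GROUPS = ("healthy", "benign", "cancer")
# spawn-key namespaces so subject streams never collide with shared draws
_BACKGROUND_KEY = 10_000
_EXTERNAL_KEY = 20_000


class CohortConfigError(ValueError):
    """A cohort configuration violates its invariants."""


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian serum band.

    ``class_multipliers`` scale the band per class; a band whose multipliers
    differ across classes carries the planted disease signal.
    """

    center: float  # cm^-1
    width: float  # Lorentzian half-width at half-maximum, cm^-1
    base_amplitude: float
    class_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise CohortConfigError(f"peak width must be > 0 (center {self.center})")
        if self.base_amplitude < 0:
            raise CohortConfigError(f"negative amplitude (center {self.center})")
        for g, m in self.class_multipliers.items():
            if g not in GROUPS:
                raise CohortConfigError(f"unknown group {g!r} in multipliers")
            if m <= 0:
                raise CohortConfigError(f"non-positive multiplier for {g!r}")

    def multiplier(self, group: str) -> float:
        return float(self.class_multipliers.get(group, 1.0))

    @property
    def is_differential(self) -> bool:
        mults = [self.multiplier(g) for g in _CLASS_GROUPS]
        return max(mults) != min(mults)


def default_peaks() -> list[PeakSpec]:
    """Common serum Raman bands with moderate three-class effects.

    Positions follow well-known serum assignments (phenylalanine ~1004,
    carotenoid ~1157, amide III ~1250, CH2 deformation ~1450, amide I
    ~1655 cm^-1, among others).  Three bands carry class effects graded so
    that both disease groups separate well from healthy while cancer vs
    benign is the harder comparison, the qualitative pattern such screening
    studies report.
    """
    return [
        PeakSpec(621.0, 8.0, 180.0),
        PeakSpec(757.0, 9.0, 220.0),
        PeakSpec(852.0, 10.0, 300.0),
        PeakSpec(1004.0, 6.0, 1000.0, {"benign": 1.18, "cancer": 1.30}),
        PeakSpec(1157.0, 9.0, 450.0, {"benign": 1.15, "cancer": 1.08}),
        PeakSpec(1250.0, 14.0, 350.0),
        PeakSpec(1335.0, 12.0, 400.0),
        PeakSpec(1450.0, 11.0, 700.0, {"benign": 1.12, "cancer": 1.22}),
        PeakSpec(1655.0, 13.0, 800.0),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults mirror the study design: 3 acquisition sessions x 5 scans per
    serum sample, i.e. 15 spectra per subject.
    """

    n_per_group: dict[str, int]
    sessions: int = 3
    scans_per_session: int = 5
    peaks: tuple[PeakSpec, ...] = ()
    baseline_order: int = 3
    baseline_scale: float = 30.0
    background_amplitude: float = 150.0
    noise_sd: float = 8.0
    spike_rate: float = 0.3  # expected cosmic rays per spectrum
    spike_amplitude_sd: float = 600.0
    subject_effect_sd: float = 0.05  # sd of log latent scale
    seed: int = 0

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks) if self.peaks else tuple(default_peaks())
        object.__setattr__(self, "peaks", peaks)
        for g, n in self.n_per_group.items():
            if g not in _CLASS_GROUPS:
                raise CohortConfigError(f"unknown group {g!r} in n_per_group")
            if n < 0:
                raise CohortConfigError("subject counts must be >= 0")
        if self.sessions < 0 or self.scans_per_session < 0:
            raise CohortConfigError("replicate counts must be >= 0")
        if self.noise_sd < 0 or self.spike_rate < 0 or self.subject_effect_sd < 0:
            raise CohortConfigError("noise_sd, spike_rate, subject_effect_sd must be >= 0")

    @property
    def scans_per_subject(self) -> int:
        return self.sessions * self.scans_per_session


def default_cohort_config(seed: int = 0, n_per_group: dict[str, int] | None = None) -> CohortConfig:
    """Study-scale defaults: 45 subjects per class unless overridden."""
    if n_per_group is None:
        n_per_group = {"healthy": 45, "benign": 45, "cancer": 45}
    return CohortConfig(n_per_group=n_per_group, seed=seed)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    labels: dict[str, str]  # subject_id -> true group
    subject_scales: dict[str, float]  # latent multiplicative factor
    spike_positions: dict[tuple[str, int, int], np.ndarray]  # spectrum key -> grid indices
    differential_wavenumbers: tuple[float, ...]  # centers of planted bands
    differential_widths: tuple[float, ...]


def lorentzian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Lorentzian line shape with half-width ``width``."""
    return 1.0 / (1.0 + ((x - center) / width) ** 2)


def clean_class_spectrum(config: CohortConfig, grid: WavenumberGrid, group: str) -> np.ndarray:
    """Noise-free band sum for one class (closed form, unit subject factor)."""
    x = grid.values
    out = np.zeros_like(x)
    for p in config.peaks:
        out += p.base_amplitude * p.multiplier(group) * lorentzian(x, p.center, p.width)
    return out


def generate_background(config: CohortConfig, grid: WavenumberGrid) -> Spectrum:
    """Smooth broad container-background spectrum, deterministic given the seed.

    Shape: a gentle slope plus a few broad Gaussian humps at seed-determined
    positions, scaled linearly by ``background_amplitude`` (so amplitude 0
    gives an all-zero background and doubling the amplitude doubles it).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_BACKGROUND_KEY,)))
    x = grid.values
    t = (x - grid.min) / (grid.max - grid.min)
    shape = 0.4 + 0.3 * t
    for _ in range(3):
        center = rng.uniform(grid.min, grid.max)
        width = rng.uniform(0.1, 0.3) * (grid.max - grid.min)
        shape = shape + rng.uniform(0.2, 0.6) * np.exp(-0.5 * ((x - center) / width) ** 2)
    return Spectrum("background", "unknown", 1, 1, config.background_amplitude * shape)


def generate_background_scans(
    config: CohortConfig, grid: WavenumberGrid, n_scans: int = 10
) -> SpectrumSet:
    """Noisy replicate scans of the container background (acquisition emulation)."""
    base = generate_background(config, grid).intensities
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_BACKGROUND_KEY, 1))
    )
    spectra = [
        Spectrum("background", "unknown", 1, k + 1, base + rng.normal(0.0, config.noise_sd, len(grid)))
        for k in range(n_scans)
    ]
    return SpectrumSet(grid, spectra, provenance="synthetic container background scans")


def _check_peaks_in_grid(config: CohortConfig, grid: WavenumberGrid) -> None:
    for p in config.peaks:
        if not (grid.min <= p.center <= grid.max):
            raise CohortConfigError(
                f"peak center {p.center} outside grid [{grid.min}, {grid.max}]"
            )


def _subject_spectra(
    config: CohortConfig,
    grid: WavenumberGrid,
    subject_id: str,
    group: str,
    rng: np.random.Generator,
    background: np.ndarray,
    truth: GroundTruth,
) -> list[Spectrum]:
    x = grid.values
    n = len(grid)
    clean = clean_class_spectrum(config, grid, group)
    latent = float(np.exp(rng.normal(0.0, config.subject_effect_sd))) if config.subject_effect_sd > 0 else 1.0
    truth.subject_scales[subject_id] = latent
    t = np.linspace(-1.0, 1.0, n)  # scaled axis keeps the random polynomial bounded
    spectra: list[Spectrum] = []
    for session in range(1, config.sessions + 1):
        for scan in range(1, config.scans_per_session + 1):
            y = latent * clean + background
            if config.baseline_scale > 0 and config.baseline_order >= 0:
                coeffs = rng.normal(0.0, config.baseline_scale, config.baseline_order + 1)
                y = y + np.polynomial.polynomial.polyval(t, coeffs)
            if config.noise_sd > 0:
                y = y + rng.normal(0.0, config.noise_sd, n)
            n_spikes = rng.poisson(config.spike_rate) if config.spike_rate > 0 else 0
            if n_spikes > 0:
                pos = rng.integers(0, n, size=n_spikes)
                amps = np.abs(rng.normal(0.0, config.spike_amplitude_sd, n_spikes))
                y = y.copy()
                np.add.at(y, pos, amps)
                truth.spike_positions[(subject_id, session, scan)] = np.unique(pos)
            spectra.append(Spectrum(subject_id, group, session, scan, y))
    return spectra


def _empty_truth(config: CohortConfig) -> GroundTruth:
    diff = [p for p in config.peaks if p.is_differential]
    return GroundTruth(
        labels={},
        subject_scales={},
        spike_positions={},
        differential_wavenumbers=tuple(p.center for p in diff),
        differential_widths=tuple(p.width for p in diff),
    )


def generate_cohort(config: CohortConfig, grid: WavenumberGrid) -> tuple[SpectrumSet, GroundTruth]:
    """Generate the model-building cohort with labels attached.

    Emits ``n_per_group[g]`` subjects per class, each contributing
    ``sessions * scans_per_session`` spectra.
    """
    _check_peaks_in_grid(config, grid)
    truth = _empty_truth(config)
    background = generate_background(config, grid).intensities
    spectra: list[Spectrum] = []
    for gi, group in enumerate(_CLASS_GROUPS):
        for j in range(config.n_per_group.get(group, 0)):
            subject_id = f"{group}_{j + 1:03d}"
            rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(gi, j)))
            truth.labels[subject_id] = group
            spectra.extend(
                _subject_spectra(config, grid, subject_id, group, rng, background, truth)
            )
    sset = SpectrumSet(grid, spectra, provenance=f"synthetic cohort, seed={config.seed}")
    return sset, truth


def generate_external_set(
    config: CohortConfig, grid: WavenumberGrid, n_per_group: dict[str, int]
) -> tuple[SpectrumSet, GroundTruth]:
    """Generate a blinded external-validation set with fresh subjects.

    Same generative parameters as the reference cohort; emitted group labels
    are ``unknown`` (the truth is held in :class:`GroundTruth` and unblinded
    only after prediction, as in an external verification).
    """
    _check_peaks_in_grid(config, grid)
    truth = _empty_truth(config)
    background = generate_background(config, grid).intensities
    spectra: list[Spectrum] = []
    for gi, group in enumerate(_CLASS_GROUPS):
        for j in range(n_per_group.get(group, 0)):
            subject_id = f"ext_{group}_{j + 1:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(_EXTERNAL_KEY + gi, j))
            )
            truth.labels[subject_id] = group
            subj = _subject_spectra(config, grid, subject_id, group, rng, background, truth)
            spectra.extend(s.replace(group="unknown") for s in subj)
    sset = SpectrumSet(grid, spectra, provenance=f"synthetic blinded external set, seed={config.seed}")
    return sset, truth


def null_config(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with all class multipliers removed (no disease signal)."""
    peaks = tuple(replace(p, class_multipliers={}) for p in config.peaks)
    return replace(config, peaks=peaks)
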