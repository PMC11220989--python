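"""Chemometric preprocessing chain for serum Raman spectra.

Stages, applied per spectrum from most local to most global artefact:

1. cosmic-ray removal — single/few-pixel spikes flagged against a rolling
   median and bridged by linear interpolation;
2. container-background subtraction — pointwise subtraction of the mean
   tube spectrum;
3. automatic-weighted least-squares smoothing — a Whittaker smoother
   (squared-second-difference roughness penalty, strength ``lambda``) whose
   point weights are re-estimated iteratively to down-weight outliers;
4. baseline correction — iterative ("modified") polynomial fitting: fit an
   order-p polynomial, clip the working spectrum to the fit, refit until the
   baseline stabilises, then subtract it;
5. total-area normalization — divide by the trapezoidal integral over the
   wavenumber axis so every spectrum has unit area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import median_filter
from scipy.sparse.linalg import spsolve

from .spectra_io import Spectrum, SpectrumSet, SpectraValidationError

__all__ = [
    "PreprocessConfig",
    "PreprocessError",
    "remove_cosmic_rays",
    "subtract_background",
    "mean_background",
    "smooth_awls",
    "correct_baseline_poly",
    "normalize_total_area",
    "preprocess_set",
]


class PreprocessError(ValueError):
    """A preprocessing stage received degenerate input."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Tuning knobs of the preprocessing chain.

    ``smooth_lambda`` is the Whittaker roughness penalty on the working grid
    (default 1e3 at 1 cm^-1 spacing); ``baseline_order`` the polynomial
    degree of the fluorescence baseline model (default 5).  ``baseline_tol``
    is relative to the working spectrum's range.
    """

    spike_window: int = 5
    spike_z_threshold: float = 8.0
    smooth_lambda: float = 1e3
    smooth_max_iter: int = 10
    smooth_tol: float = 1e-3
    baseline_order: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    normalization: str = "total_area"  # or "sum" or "none"

    def __post_init__(self) -> None:
        if self.spike_window < 3 or self.spike_window % 2 == 0:
            raise ValueError("spike_window must be odd and >= 3")
        if self.smooth_lambda < 0:
            raise ValueError("smooth_lambda must be >= 0")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.normalization not in ("total_area", "sum", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


# -- cosmic rays ------------------------------------------------------------


def _despike(y: np.ndarray, window: int, z: float) -> np.ndarray:
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale == 0.0:
        # the rolling median reproduces most points exactly (noise-free
        # input): the robust z-score is degenerate, so flag nothing
        return y.copy()
    flagged = np.abs(resid) > z * scale
    if not flagged.any():
        return y.copy()
    if flagged.all():
        raise PreprocessError("every point flagged as a spike; input degenerate")
    idx = np.arange(y.size)
    out = y.copy()
    out[flagged] = np.interp(idx[flagged], idx[~flagged], y[~flagged])
    return out


def remove_cosmic_rays(s: Spectrum, window: int = 5, z: float = 8.0) -> Spectrum:
    """Replace rolling-median outliers (> ``z`` robust SDs) by linear interpolation.

    Runs of adjacent flagged points are bridged from the nearest unflagged
    neighbours on either side; unflagged points pass through untouched.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    return s.replace(intensities=_despike(s.intensities, window, z))


# -- background -------------------------------------------------------------


def mean_background(backgrounds: list[Spectrum] | SpectrumSet) -> Spectrum:
    """Pointwise arithmetic mean of replicate background scans."""
    spectra = list(backgrounds)
    if not spectra:
        raise SpectraValidationError("mean_background needs at least one spectrum")
    n = spectra[0].intensities.size
    for b in spectra:
        if b.intensities.size != n:
            raise SpectraValidationError("background scans on differing grids")
    mean = np.mean([b.intensities for b in spectra], axis=0)
    return spectra[0].replace(intensities=mean)


def subtract_background(s: Spectrum, background_mean: Spectrum) -> Spectrum:
    """Pointwise subtraction of the mean container spectrum."""
    if s.intensities.size != background_mean.intensities.size:
        raise SpectraValidationError("spectrum and background on differing grids")
    return s.replace(intensities=s.intensities - background_mean.intensities)


# -- Whittaker smoothing ----------------------------------------------------


def _second_difference_penalty(n: int) -> sparse.csc_matrix:
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return (d.T @ d).tocsc()


def _whittaker_solve(y: np.ndarray, w: np.ndarray, lam: float, dtd: sparse.csc_matrix) -> np.ndarray:
    a = sparse.diags(w) + lam * dtd
    return spsolve(a.tocsc(), w * y)


def smooth_awls(
    s: Spectrum,
    smooth_lambda: float = 1e3,
    max_iter: int = 10,
    tol: float = 1e-3,
) -> Spectrum:
    """Iteratively reweighted Whittaker smoothing.

    Minimises ``sum_i w_i (y_i - z_i)^2 + lambda * sum (Delta^2 z)^2`` for the
    smooth estimate ``z``.  Weights start at 1 and are re-estimated with a
    Cauchy influence function of the standardised residuals, so spike-like
    outliers pull the fit less on each pass; iteration stops when the maximum
    weight change drops below ``tol`` or after ``max_iter`` passes.

    ``lambda = 0`` imposes no roughness penalty and returns the input.
    """
    y = s.intensities
    if not np.all(np.isfinite(y)):
        raise SpectraValidationError("non-finite intensities passed to smoother")
    if smooth_lambda == 0:
        return s.replace(intensities=y.copy())
    n = y.size
    dtd = _second_difference_penalty(n)
    w = np.ones(n)
    z = y
    for _ in range(max(1, max_iter)):
        z = _whittaker_solve(y, w, smooth_lambda, dtd)
        r = y - z
        mad = np.median(np.abs(r - np.median(r)))
        scale = 1.4826 * mad if mad > 0 else float(np.std(r))
        if scale == 0.0:
            break  # perfect fit (e.g. constant input)
        w_new = 1.0 / (1.0 + (r / (2.385 * scale)) ** 2)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    z = _whittaker_solve(y, w, smooth_lambda, dtd)
    return s.replace(intensities=z)


# -- polynomial baseline ----------------------------------------------------


def estimate_baseline_poly(
    y: np.ndarray,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Modified-polyfit baseline estimate.

    Repeatedly fit an order-``order`` polynomial to the working spectrum and
    clip the working spectrum to the fit, which peels peaks off the estimate
    while the smooth underside is retained.  Returns ``(baseline, converged)``;
    the stopping rule compares the max change between successive fits against
    ``tol`` times the input range.
    """
    n = y.size
    if order >= n:
        raise ValueError("baseline order must be smaller than the grid length")
    t = np.linspace(-1.0, 1.0, n)
    vand = np.polynomial.polynomial.polyvander(t, order)
    # hat matrix of the least-squares fit; reused across iterations
    proj = vand @ np.linalg.pinv(vand)
    scale = float(np.ptp(y)) or 1.0
    work = y.astype(float).copy()
    fit = proj @ work
    converged = False
    for _ in range(max(1, max_iter)):
        work = np.minimum(work, fit)
        new_fit = proj @ work
        if np.max(np.abs(new_fit - fit)) < tol * scale:
            fit = new_fit
            converged = True
            break
        fit = new_fit
    return fit, converged


def correct_baseline_poly(
    s: Spectrum,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> Spectrum:
    """Subtract the modified-polyfit baseline estimate from the spectrum."""
    baseline, _ = estimate_baseline_poly(s.intensities, order, max_iter, tol)
    return s.replace(intensities=s.intensities - baseline)


# -- normalization ----------------------------------------------------------


def normalize_total_area(s: Spectrum, wavenumbers: np.ndarray, mode: str = "total_area") -> Spectrum:
    """Scale the spectrum to unit area over the wavenumber axis.

    ``total_area`` uses the trapezoidal integral (area per cm^-1); ``sum``
    divides by the plain intensity sum.  A non-positive area signals a failed
    baseline correction and raises.
    """
    y = s.intensities
    if mode == "sum":
        area = float(np.sum(y))
    else:
        area = float(np.trapezoid(y, wavenumbers))
    if not area > 0:
        raise PreprocessError(
            f"non-positive spectral area ({area:.4g}) for {s.key}; "
            "baseline correction likely failed"
        )
    return s.replace(intensities=y / area)


# -- full chain -------------------------------------------------------------


def preprocess_spectrum(
    s: Spectrum,
    background_mean: Spectrum | None,
    cfg: PreprocessConfig,
    wavenumbers: np.ndarray,
) -> Spectrum:
    out = remove_cosmic_rays(s, cfg.spike_window, cfg.spike_z_threshold)
    if background_mean is not None:
        out = subtract_background(out, background_mean)
    out = smooth_awls(out, cfg.smooth_lambda, cfg.smooth_max_iter, cfg.smooth_tol)
    out = correct_baseline_poly(out, cfg.baseline_order, cfg.baseline_max_iter, cfg.baseline_tol)
    if cfg.normalization != "none":
        out = normalize_total_area(out, wavenumbers, cfg.normalization)
    return out


def preprocess_set(
    sset: SpectrumSet,
    background_mean: Spectrum | None = None,
    cfg: PreprocessConfig | None = None,
) -> SpectrumSet:
    """Run the full chain on every spectrum; cardinality and metadata preserved.

    Order: despike -> background subtraction -> Whittaker smoothing ->
    polynomial baseline -> total-area normalization.  Per-spectrum failures
    are re-raised with the spectrum identity attached.
    """
    cfg = cfg or PreprocessConfig()
    wn = sset.grid.values
    out: list[Spectrum] = []
    for s in sset.spectra:
        try:
            out.append(preprocess_spectrum(s, background_mean, cfg, wn))
        except Exception as exc:
            raise PreprocessError(f"preprocessing failed for spectrum {s.key}: {exc}") from exc
    return SpectrumSet(sset.grid, out, provenance=(sset.provenance + " | preprocessed").strip(" |"))
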