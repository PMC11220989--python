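"""Spectral data model and I/O.

A Raman spectrum is a vector of scattered-light intensities on a shared
wavenumber (Raman shift) grid in cm^-1.  A :class:`SpectrumSet` is a cohort
of such spectra with the bookkeeping the screening analysis needs: subject
identity, class label (healthy / benign lung lesion / lung cancer), and the
acquisition replicate structure (session x scan; the study design collects
3 sessions x 5 scans = 15 spectra per serum sample).

Two plain-text dialects are supported:

* ``wide_csv`` (canonical): one row per spectrum, columns
  ``subject_id,group,session,scan,wn_<wavenumber>...``
* ``long_csv``: one row per (spectrum, wavenumber) pair with columns
  ``subject_id,group,session,scan,wavenumber,intensity``
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "WavenumberGrid",
    "Spectrum",
    "SpectrumSet",
    "SpectraFormatError",
    "SpectraValidationError",
    "default_grid",
    "read_spectrum_set",
    "write_spectrum_set",
    "resample_to_grid",
]

#: Admissible class labels.  ``unknown`` marks blinded samples.
GROUPS = ("healthy", "benign", "cancer", "unknown")

METADATA_COLUMNS = ["subject_id", "group", "session", "scan"]


class SpectraFormatError(ValueError):
    """A spectra file does not conform to the declared dialect."""


class SpectraValidationError(ValueError):
    """Spectral data violate a structural invariant."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise SpectraValidationError("grid needs at least 2 wavenumbers")
        if not np.all(np.isfinite(values)):
            raise SpectraValidationError("grid contains non-finite wavenumbers")
        if not np.all(np.diff(values) > 0):
            raise SpectraValidationError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @property
    def min(self) -> float:
        return float(self.values[0])

    @property
    def max(self) -> float:
        return float(self.values[-1])


def default_grid(start: float = 400.0, stop: float = 1800.0, step: float = 1.0) -> WavenumberGrid:
    """Canonical acquisition grid: 400-1800 cm^-1 at ``step`` cm^-1 (1401 points)."""
    n = int(round((stop - start) / step)) + 1
    return WavenumberGrid(np.linspace(start, stop, n))


@dataclass
class Spectrum:
    """One scan's intensities plus acquisition metadata.

    ``session`` and ``scan`` are 1-based replicate indices within a subject.
    """

    subject_id: str
    group: str
    session: int
    scan: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SpectraValidationError(
                f"group {self.group!r} not in {GROUPS} (spectrum {self.subject_id})"
            )
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1:
            raise SpectraValidationError("intensities must be a 1-D vector")
        if not np.all(np.isfinite(arr)):
            raise SpectraValidationError(
                f"non-finite intensity in spectrum ({self.subject_id}, "
                f"session {self.session}, scan {self.scan})"
            )
        self.intensities = arr

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, int(self.session), int(self.scan))

    def replace(self, **changes) -> "Spectrum":
        return dataclasses.replace(self, **changes)


@dataclass
class SpectrumSet:
    """Cohort of spectra on one shared grid."""

    grid: WavenumberGrid
    spectra: list[Spectrum] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        seen: set[tuple[str, int, int]] = set()
        n = len(self.grid)
        for s in self.spectra:
            if s.intensities.size != n:
                raise SpectraValidationError(
                    f"spectrum {s.key} has {s.intensities.size} points, grid has {n}"
                )
            if s.key in seen:
                raise SpectraValidationError(f"duplicate (subject, session, scan) {s.key}")
            seen.add(s.key)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    # -- cohort bookkeeping -------------------------------------------------

    def intensity_matrix(self) -> np.ndarray:
        """Spectra stacked as an (n_spectra, n_wavenumbers) array."""
        if not self.spectra:
            return np.empty((0, len(self.grid)))
        return np.vstack([s.intensities for s in self.spectra])

    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.spectra], dtype=object)

    def subject_ids(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.spectra], dtype=object)

    def subjects(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for s in self.spectra:
            if s.subject_id not in seen:
                seen.add(s.subject_id)
                out.append(s.subject_id)
        return out

    def groups_present(self) -> list[str]:
        present = {s.group for s in self.spectra}
        return [g for g in GROUPS if g in present]

    def subject_group(self) -> dict[str, str]:
        return {s.subject_id: s.group for s in self.spectra}

    def scans_per_subject(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.spectra:
            counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
        return counts

    def subset(self, predicate: Callable[[Spectrum], bool]) -> "SpectrumSet":
        return SpectrumSet(self.grid, [s for s in self.spectra if predicate(s)], self.provenance)

    def select_groups(self, groups: Iterable[str]) -> "SpectrumSet":
        wanted = set(groups)
        return self.subset(lambda s: s.group in wanted)

    def select_indices(self, indices: Sequence[int]) -> "SpectrumSet":
        return SpectrumSet(self.grid, [self.spectra[i] for i in indices], self.provenance)

    def map_intensities(self, fn: Callable[[Spectrum], np.ndarray]) -> "SpectrumSet":
        """Apply ``fn`` per spectrum, preserving metadata and cardinality."""
        return SpectrumSet(
            self.grid,
            [s.replace(intensities=fn(s)) for s in self.spectra],
            self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: metadata columns followed by one column per wavenumber."""
        meta = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.spectra],
                "group": [s.group for s in self.spectra],
                "session": [s.session for s in self.spectra],
                "scan": [s.scan for s in self.spectra],
            }
        )
        wn_cols = [f"wn_{_format_wavenumber(w)}" for w in self.grid.values]
        data = pd.DataFrame(self.intensity_matrix(), columns=wn_cols)
        return pd.concat([meta, data], axis=1)


def _format_wavenumber(w: float) -> str:
    return f"{w:.6g}"


# -- readers / writers ------------------------------------------------------


def write_spectrum_set(sset: SpectrumSet, path, dialect: str = "wide_csv") -> None:
    """Write a cohort to CSV; the result round-trips through :func:`read_spectrum_set`."""
    if dialect == "wide_csv":
        sset.to_frame().to_csv(path, index=False, float_format="%.9g")
    elif dialect == "long_csv":
        frames = []
        for s in sset.spectra:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "session": s.session,
                        "scan": s.scan,
                        "wavenumber": sset.grid.values,
                        "intensity": s.intensities,
                    }
                )
            )
        if frames:
            df = pd.concat(frames, ignore_index=True)
        else:
            df = pd.DataFrame(columns=METADATA_COLUMNS + ["wavenumber", "intensity"])
        df.to_csv(path, index=False, float_format="%.9g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_spectrum_set(path, dialect: str = "wide_csv", grid: WavenumberGrid | None = None) -> SpectrumSet:
    """Read a cohort CSV written in ``dialect``.

    Rejects missing metadata columns, ragged rows, missing intensities and
    non-increasing wavenumber axes.  If ``grid`` is given for an empty
    wide file lacking wavenumber columns, it supplies the axis.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows
        raise SpectraFormatError(f"malformed CSV {path}: {exc}") from exc

    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"missing metadata column(s) {missing} in {path}")

    if dialect == "wide_csv":
        wn_cols = [c for c in df.columns if c.startswith("wn_")]
        if not wn_cols:
            if grid is not None:
                return SpectrumSet(grid, [])
            raise SpectraFormatError(f"no wavenumber (wn_*) columns in {path}")
        try:
            axis = np.array([float(c[3:]) for c in wn_cols])
        except ValueError as exc:
            raise SpectraFormatError(f"unparseable wavenumber column in {path}") from exc
        file_grid = WavenumberGrid(axis)  # raises on non-monotone axis
        values = df[wn_cols].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise SpectraFormatError(f"missing intensity values in {path}")
        spectra = [
            Spectrum(
                subject_id=str(row.subject_id),
                group=str(row.group),
                session=int(row.session),
                scan=int(row.scan),
                intensities=values[i],
            )
            for i, row in enumerate(df.itertuples(index=False))
        ]
        return SpectrumSet(file_grid, spectra)

    if dialect == "long_csv":
        for col in ("wavenumber", "intensity"):
            if col not in df.columns:
                raise SpectraFormatError(f"missing column {col!r} in {path}")
        if df.empty:
            if grid is None:
                raise SpectraFormatError(f"empty long CSV without a grid: {path}")
            return SpectrumSet(grid, [])
        spectra = []
        file_grid: WavenumberGrid | None = None
        for key, sub in df.groupby(METADATA_COLUMNS, sort=False):
            axis = sub["wavenumber"].to_numpy(dtype=float)
            g = WavenumberGrid(axis)
            if file_grid is None:
                file_grid = g
            elif g != file_grid:
                raise SpectraFormatError(f"inconsistent wavenumber axes in {path}")
            vals = sub["intensity"].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise SpectraFormatError(f"missing intensity values in {path}")
            subject_id, group, session, scan = key
            spectra.append(
                Spectrum(str(subject_id), str(group), int(session), int(scan), vals)
            )
        assert file_grid is not None
        return SpectrumSet(file_grid, spectra)

    raise ValueError(f"unknown dialect {dialect!r}")


def resample_to_grid(sset: SpectrumSet, target: WavenumberGrid) -> SpectrumSet:
    """Linearly interpolate every spectrum onto ``target``; metadata preserved.

    The target range must lie within the source range (no extrapolation).
    """
    src = sset.grid
    if target.min < src.min or target.max > src.max:
        raise SpectraValidationError(
            f"target grid [{target.min}, {target.max}] extends beyond "
            f"source [{src.min}, {src.max}]"
        )
    if target == src:
        return SpectrumSet(src, [s.replace() for s in sset.spectra], sset.provenance)
    spectra = [
        s.replace(intensities=np.interp(target.values, src.values, s.intensities))
        for s in sset.spectra
    ]
    return SpectrumSet(target, spectra, sset.provenance)
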