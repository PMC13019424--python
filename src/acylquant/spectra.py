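"""Spectrum data model, CSV I/O and preprocessing.

The atom of all processing is a :class:`Spectrum`: an intensity vector on a
strictly increasing wavenumber grid (cm^-1).  Collections of spectra sharing
one grid live in a :class:`SpectrumSet`, which is what the chemometric layers
consume.  Preprocessing follows the fixed order used throughout the package:
background subtraction, iterative polynomial baseline correction, then
normalization to unit area of the ester C=O stretching band (1720-1770 cm^-1),
which acts as the internal intensity standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectrumSet",
    "WindowSet",
    "ESTER_BAND",
    "resample",
    "subtract_background",
    "correct_baseline",
    "band_area",
    "normalize_ester_band",
    "extract_windows",
    "load_spectra",
    "save_spectra",
    "preprocess",
]

#: Internal-standard integration window for the ester C=O stretch (cm^-1).
ESTER_BAND = (1720.0, 1770.0)


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing, finite wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least 2 points in a 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("grid contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    @staticmethod
    def default() -> "WavenumberGrid":
        """650-1800 cm^-1 at 1 cm^-1 spacing (1151 points)."""
        return WavenumberGrid(np.arange(650.0, 1801.0, 1.0))

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((len(self.values), float(self.values[0]), float(self.values[-1])))


@dataclass
class Spectrum:
    """One intensity vector on a wavenumber grid."""

    grid: WavenumberGrid
    intensity: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != self.grid.values.shape:
            raise ValueError(
                f"intensity length {y.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity contains non-finite values")
        self.intensity = y

    def copy(self, intensity: np.ndarray | None = None, id: str | None = None) -> "Spectrum":
        return Spectrum(
            self.grid,
            self.intensity.copy() if intensity is None else intensity,
            self.id if id is None else id,
        )


class SpectrumSet:
    """Ordered collection of spectra on one shared grid, with metadata.

    Metadata is a per-spectrum mapping (species, ester form, replicate,
    composition id ...) keyed by spectrum id.
    """

    def __init__(
        self,
        grid: WavenumberGrid,
        intensities: np.ndarray,
        ids: Sequence[str],
        metadata: Mapping[str, Mapping[str, object]] | None = None,
    ) -> None:
        M = np.atleast_2d(np.asarray(intensities, dtype=float))
        if M.shape[1] != len(grid):
            raise ValueError("intensity matrix width does not match grid length")
        if M.shape[0] != len(ids):
            raise ValueError("number of ids does not match number of rows")
        if len(set(ids)) != len(ids):
            raise ValueError("spectrum ids must be unique")
        self.grid = grid
        self.intensities = M
        self.ids = list(ids)
        self.metadata: dict[str, dict[str, object]] = {
            i: dict((metadata or {}).get(i, {})) for i in self.ids
        }

    @classmethod
    def from_spectra(
        cls,
        spectra: Iterable[Spectrum],
        metadata: Mapping[str, Mapping[str, object]] | None = None,
    ) -> "SpectrumSet":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("empty spectrum collection")
        grid = spectra[0].grid
        for s in spectra[1:]:
            if s.grid != grid:
                raise ValueError("all spectra must share an identical grid")
        return cls(
            grid,
            np.vstack([s.intensity for s in spectra]),
            [s.id for s in spectra],
            metadata,
        )

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        for i, sid in enumerate(self.ids):
            yield Spectrum(self.grid, self.intensities[i], sid)

    def __getitem__(self, sid: str) -> Spectrum:
        try:
            i = self.ids.index(sid)
        except ValueError:
            raise KeyError(sid) from None
        return Spectrum(self.grid, self.intensities[i], sid)

    def map(self, fn) -> "SpectrumSet":
        """Apply a Spectrum -> Spectrum function to every member."""
        out = [fn(s) for s in self]
        return SpectrumSet.from_spectra(out, self.metadata)

    def subset(self, ids: Sequence[str]) -> "SpectrumSet":
        idx = [self.ids.index(i) for i in ids]
        return SpectrumSet(
            self.grid, self.intensities[idx], list(ids),
            {i: self.metadata[i] for i in ids},
        )


@dataclass
class WindowSet:
    """Pairwise non-overlapping closed wavenumber intervals.

    Stored and rendered sorted descending by the upper edge, the convention
    spectroscopy tables use (e.g. ``1800-1700,1500-1380,...``).
    """

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(lo), float(hi)) for lo, hi in self.intervals]
        for lo, hi in ivs:
            if not lo < hi:
                raise ValueError(f"window [{lo}, {hi}] needs lo < hi")
        ivs.sort(key=lambda w: -w[1])
        for (lo1, _), (_, hi2) in zip(ivs, ivs[1:]):
            if hi2 > lo1:
                raise ValueError("windows overlap")
        self.intervals = ivs

    @classmethod
    def from_string(cls, text: str) -> "WindowSet":
        """Parse the ``hi-lo,hi-lo,...`` dialect, e.g. ``1800-1700,930-650``."""
        intervals = []
        for item in text.split(","):
            item = item.strip()
            if not item:
                continue
            try:
                hi_s, lo_s = item.split("-")
                hi, lo = float(hi_s), float(lo_s)
            except ValueError:
                raise ValueError(f"cannot parse window item {item!r}") from None
            if hi <= lo:
                raise ValueError(f"window item {item!r} must be hi-lo with hi > lo")
            intervals.append((lo, hi))
        if not intervals:
            raise ValueError("empty window string")
        return cls(intervals)

    def to_string(self) -> str:
        return ",".join(f"{_fmt(hi)}-{_fmt(lo)}" for lo, hi in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def resample(s: Spectrum, g: WavenumberGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid within its span."""
    lo, hi = s.grid.values[0], s.grid.values[-1]
    if g.values[0] < lo or g.values[-1] > hi:
        raise ValueError(
            f"target grid [{g.values[0]}, {g.values[-1]}] outside source span [{lo}, {hi}]"
        )
    if g == s.grid:
        return s.copy()
    y = np.interp(g.values, s.grid.values, s.intensity)
    return Spectrum(g, y, s.id)


def subtract_background(s: Spectrum, bg: Spectrum, scale: float = 1.0) -> Spectrum:
    """Subtract a scaled background spectrum (quartz, medium) channelwise."""
    if s.grid != bg.grid:
        raise ValueError("spectrum and background are on different grids")
    return s.copy(intensity=s.intensity - scale * bg.intensity)


def correct_baseline(
    s: Spectrum, order: int = 3, n_iter: int = 20
) -> tuple[Spectrum, Spectrum]:
    """Remove a slowly varying baseline by iterative polynomial fitting.

    Repeatedly fits a degree-``order`` polynomial and clips the working signal
    to the elementwise minimum of signal and fit, so peaks stop attracting the
    baseline (ModPoly scheme).  Returns ``(corrected, baseline)``.

    The procedure is exactly equivariant under addition of any polynomial of
    degree <= order, so correcting an already-corrected spectrum removes a
    (numerically) zero baseline.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if order >= len(s.grid):
        raise ValueError("polynomial order must be below the number of grid points")
    # map grid to [-1, 1] for conditioning
    x = s.grid.values
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(t, order)
    # precompute pseudo-inverse once; the fit is plain least squares
    pinv = np.linalg.pinv(V)
    work = s.intensity.copy()
    fit = V @ (pinv @ work)
    for _ in range(n_iter):
        work = np.minimum(work, fit)
        fit = V @ (pinv @ work)
    baseline = Spectrum(s.grid, fit, f"{s.id}.baseline" if s.id else "baseline")
    corrected = s.copy(intensity=s.intensity - fit)
    return corrected, baseline


def _window_mask(grid: WavenumberGrid, lo: float, hi: float) -> np.ndarray:
    return (grid.values >= lo) & (grid.values <= hi)


def band_area(s: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of intensity over grid points inside a closed window."""
    lo, hi = window
    m = _window_mask(s.grid, lo, hi)
    if m.sum() < 2:
        raise ValueError(f"window [{lo}, {hi}] contains fewer than 2 grid points")
    return float(np.trapezoid(s.intensity[m], s.grid.values[m]))


def normalize_ester_band(
    s: Spectrum, window: tuple[float, float] = ESTER_BAND
) -> Spectrum:
    """Divide by the area of the ester C=O band so it integrates to 1."""
    a = band_area(s, window)
    if a <= 0:
        raise ValueError(
            f"ester band area is {a:.4g}; spectrum lacks a positive C=O band"
        )
    return s.copy(intensity=s.intensity / a)


def extract_windows(
    spectra: SpectrumSet, windows: WindowSet
) -> tuple[np.ndarray, np.ndarray]:
    """Stack intensities restricted to a window set.

    Channels are the concatenation of grid points falling inside each closed
    interval, in the window set's (descending) presentation order.  Returns
    ``(matrix, channel_map)`` with one row per spectrum and the channel
    wavenumbers.
    """
    masks = []
    for lo, hi in windows.intervals:
        m = _window_mask(spectra.grid, lo, hi)
        if not m.any():
            raise ValueError(f"window [{lo}, {hi}] contains no grid points")
        masks.append(np.where(m)[0][::-1])  # descending within each window
    cols = np.concatenate(masks)
    return spectra.intensities[:, cols], spectra.grid.values[cols]


def load_spectra(path: str | Path) -> SpectrumSet:
    """Read a wide spectra CSV: ``wavenumber_cm1,<id1>,<id2>,...``."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectra CSV needs a wavenumber column and >= 1 spectrum")
    if df.isna().any().any():
        raise ValueError("spectra CSV has missing values (ragged columns?)")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wn) > 0):
        raise ValueError("wavenumber column is not strictly increasing")
    grid = WavenumberGrid(wn)
    ids = [str(c) for c in df.columns[1:]]
    return SpectrumSet(grid, df.iloc[:, 1:].to_numpy(dtype=float).T, ids)


def save_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    """Write the wide CSV form with >= 12 significant digits."""
    df = pd.DataFrame({"wavenumber_cm1": spectra.grid.values})
    for i, sid in enumerate(spectra.ids):
        df[sid] = spectra.intensities[i]
    df.to_csv(path, index=False, float_format="%.12g")


def preprocess(
    spectra: SpectrumSet,
    background: Spectrum | None = None,
    background_scale: float = 1.0,
    baseline_order: int = 3,
    baseline_iter: int = 20,
    norm_window: tuple[float, float] = ESTER_BAND,
) -> SpectrumSet:
    """Background subtraction -> baseline correction -> ester-band normalization.

    The order is fixed; it is the one the chemometric layers assume.
    """

    def _one(s: Spectrum) -> Spectrum:
        if background is not None:
            s = subtract_background(s, background, background_scale)
        s, _ = correct_baseline(s, baseline_order, baseline_iter)
        return normalize_ester_band(s, norm_window)

    return spectra.map(_one)
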