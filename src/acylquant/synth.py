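"""Synthetic FAME / TAG Raman spectrum generator.

Pure-component spectra are sums of pseudo-Voigt bands whose positions follow
the known lipid Raman assignments over 650-1800 cm^-1: the ester C=O stretch
near 1740 cm^-1 (the internal standard), CH2/CH3 bending at 1439 cm^-1 with
amplitude growing with chain length among the saturated species, C=C stretch
near 1650 and =C-H bend near 1260 cm^-1 present only for the unsaturated acyl
groups (OA, one double bond; LA, two), skeletal C-C modes at 1050-1130 cm^-1,
and ester-sensitive features at 800-930 cm^-1 that distinguish methyl esters
from glycerol esters.  TAG models differ from their FAME counterparts by a
blue-shifted, broadened C=O band, a shifted CH2/CH3-to-C=O amplitude ratio,
perturbed 1600-1700 bands (unsaturated species only) and replaced 838-890
ester-bond bands.

Mixture spectra are exactly linear in mole fraction before noise; noise is
i.i.d. Gaussian plus a slow polynomial baseline drift, fully reproducible from
an integer seed.  Band amplitudes and widths are package-invented (only the
positions and qualitative orderings are physically anchored) and live in
versioned JSON files under ``acylquant/data/bands``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet, WavenumberGrid

__all__ = [
    "SPECIES",
    "Band",
    "BandModel",
    "Composition",
    "NoiseParams",
    "MixtureDesign",
    "component_model",
    "render",
    "pure_component_spectra",
    "mix",
    "generate_design",
    "generate_dataset",
]

#: The five acyl groups, in fixed order: myristate (14:0), palmitate (16:0),
#: stearate (18:0), oleate (18:1), linoleate (18:2).
SPECIES = ("MA", "PA", "SA", "OA", "LA")
ESTER_FORMS = ("FAME", "TAG")


@dataclass(frozen=True)
class Band:
    """One pseudo-Voigt band: unit-height profile scaled by ``amplitude``.

    ``shape`` is the Lorentzian fraction eta in [0, 1].
    """

    center: float
    fwhm: float
    amplitude: float
    shape: float = 0.3

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.shape <= 1.0:
            raise ValueError("shape (Lorentzian fraction) must lie in [0, 1]")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        hw = self.fwhm / 2.0
        lor = hw * hw / (d * d + hw * hw)
        gau = np.exp(-4.0 * np.log(2.0) * (d / self.fwhm) ** 2)
        return self.amplitude * (self.shape * lor + (1.0 - self.shape) * gau)


@dataclass(frozen=True)
class BandModel:
    """Band table for one (species, ester form) pure component."""

    species: str
    ester_form: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        co = [b for b in self.bands if 1720.0 <= b.center <= 1770.0]
        if len(co) != 1:
            raise ValueError(
                f"{self.species}/{self.ester_form}: expected exactly one C=O band "
                f"in [1720, 1770], found {len(co)}"
            )
        unsat = any(1600.0 <= b.center <= 1700.0 for b in self.bands)
        if unsat != (self.species in ("OA", "LA")):
            raise ValueError(
                f"{self.species}/{self.ester_form}: 1600-1700 cm^-1 bands must be "
                "present iff the acyl group is unsaturated"
            )

    @property
    def co_band(self) -> Band:
        return next(b for b in self.bands if 1720.0 <= b.center <= 1770.0)


def component_model(species: str, ester_form: str) -> BandModel:
    """Load the built-in band table for one pure component."""
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; expected one of {SPECIES}")
    if ester_form not in ESTER_FORMS:
        raise KeyError(f"unknown ester form {ester_form!r}; expected FAME or TAG")
    ref = resources.files("acylquant.data").joinpath(f"bands/{species}_{ester_form}.json")
    payload = json.loads(ref.read_text())
    bands = tuple(
        Band(b["center"], b["fwhm"], b["amplitude"], b["shape"])
        for b in payload["bands"]
    )
    return BandModel(payload["species"], payload["ester_form"], bands)


def render(model: BandModel | Sequence[Band], grid: WavenumberGrid) -> Spectrum:
    """Sum the band profiles on a grid; no noise."""
    bands = model.bands if isinstance(model, BandModel) else tuple(model)
    y = np.zeros(len(grid))
    for b in bands:
        y += b.profile(grid.values)
    sid = (
        f"{model.species}_{model.ester_form}" if isinstance(model, BandModel) else ""
    )
    return Spectrum(grid, y, sid)


def pure_component_spectra(
    ester_form: str, grid: WavenumberGrid | None = None
) -> dict[str, Spectrum]:
    """Noiseless pure spectra of all five components of one ester form."""
    grid = grid or WavenumberGrid.default()
    return {sp: render(component_model(sp, ester_form), grid) for sp in SPECIES}


@dataclass(frozen=True)
class Composition:
    """Mole percentages of the five acyl groups; designs sum to 100."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        f = {sp: float(self.fractions.get(sp, 0.0)) for sp in SPECIES}
        for sp, v in f.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{sp} fraction {v} outside [0, 100] mole %")
        object.__setattr__(self, "fractions", f)

    def __getitem__(self, sp: str) -> float:
        return self.fractions[sp]

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[sp] for sp in SPECIES])


@dataclass(frozen=True)
class NoiseParams:
    """Gaussian channel noise and slow polynomial baseline drift.

    ``sigma_rel`` and ``drift_amp_rel`` are fractions of the maximum
    pure-component intensity, emulating shot noise and the slow fluorescence /
    stray-light undulation real spectra carry.
    """

    sigma_rel: float = 0.01
    drift_order: int = 2
    drift_amp_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or self.drift_amp_rel < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.drift_order < 0:
            raise ValueError("drift_order must be >= 0")

    @staticmethod
    def noiseless(seed: int = 0) -> "NoiseParams":
        return NoiseParams(sigma_rel=0.0, drift_order=0, drift_amp_rel=0.0, seed=seed)


@dataclass(frozen=True)
class MixtureDesign:
    """Training / test compositions over the 5-component simplex."""

    train: tuple[Composition, ...]
    test: tuple[Composition, ...]
    seed: int = 0


def mix(
    c: Composition,
    components: Mapping[str, Spectrum],
    noise: NoiseParams | None = None,
    id: str = "",
) -> Spectrum:
    """Mole-fraction-weighted sum of component spectra plus drift and noise."""
    grid = None
    for sp, frac in c.fractions.items():
        if frac > 0 and sp not in components:
            raise KeyError(f"no component spectrum for {sp} (fraction {frac}%)")
    for s in components.values():
        if grid is None:
            grid = s.grid
        elif s.grid != grid:
            raise ValueError("component spectra are on different grids")
    assert grid is not None
    y = np.zeros(len(grid))
    for sp, frac in c.fractions.items():
        if frac > 0:
            y = y + (frac / 100.0) * components[sp].intensity
    if noise is not None and (noise.sigma_rel > 0 or noise.drift_amp_rel > 0):
        ref = max(float(np.max(s.intensity)) for s in components.values())
        rng = np.random.default_rng(noise.seed)
        if noise.drift_amp_rel > 0:
            t = np.linspace(-1.0, 1.0, len(grid))
            coef = rng.uniform(-1.0, 1.0, noise.drift_order + 1)
            drift = np.polynomial.polynomial.polyval(t, coef)
            peak = float(np.max(np.abs(drift)))
            if peak > 0:
                y = y + noise.drift_amp_rel * ref * drift / peak
        if noise.sigma_rel > 0:
            y = y + rng.normal(0.0, noise.sigma_rel * ref, len(grid))
    return Spectrum(grid, y, id)


def generate_design(n_train: int = 165, n_test: int = 20, seed: int = 0) -> MixtureDesign:
    """Compose a simplex design: 165 training and 20 test mixtures by default.

    Training always contains the five pure vertices, the ten 50/50 binary
    midpoints and the centroid; the remainder (and the whole test set) is drawn
    from a flat Dirichlet over the 5-simplex, scaled to mole percent.
    """
    if n_train < 5:
        raise ValueError("n_train must be >= 5 (need the five pure vertices)")
    fixed: list[Composition] = []
    for sp in SPECIES:
        fixed.append(Composition({sp: 100.0}))
    for i, a in enumerate(SPECIES):
        for b in SPECIES[i + 1:]:
            fixed.append(Composition({a: 50.0, b: 50.0}))
    fixed.append(Composition({sp: 20.0 for sp in SPECIES}))
    fixed = fixed[:n_train]
    rng = np.random.default_rng(seed)

    def draw(n: int) -> list[Composition]:
        out = []
        for _ in range(n):
            f = rng.dirichlet(np.ones(len(SPECIES))) * 100.0
            f[-1] = 100.0 - f[:-1].sum()  # close the simplex exactly
            out.append(Composition(dict(zip(SPECIES, f))))
        return out

    train = tuple(fixed + draw(n_train - len(fixed)))
    test = tuple(draw(n_test))
    return MixtureDesign(train=train, test=test, seed=seed)


def generate_dataset(
    design: Sequence[Composition],
    ester_form: str,
    noise: NoiseParams,
    grid: WavenumberGrid | None = None,
    prefix: str = "mix",
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Render raw (un-preprocessed) mixture spectra for a list of compositions.

    Per-sample noise seeds are derived deterministically from ``noise.seed``
    and the sample index, so regeneration is bitwise reproducible.  Returns the
    spectra plus a composition table ``sample_id, MA, PA, SA, OA, LA``.
    """
    grid = grid or WavenumberGrid.default()
    components = pure_component_spectra(ester_form, grid)
    spectra, rows, meta = [], [], {}
    for i, c in enumerate(design):
        sid = f"{prefix}_{ester_form}_{i:03d}"
        per_sample = NoiseParams(
            sigma_rel=noise.sigma_rel,
            drift_order=noise.drift_order,
            drift_amp_rel=noise.drift_amp_rel,
            seed=int(np.random.SeedSequence([noise.seed, i]).generate_state(1)[0] % (2**31)),
        )
        spectra.append(mix(c, components, per_sample, id=sid))
        rows.append({"sample_id": sid, **{sp: c[sp] for sp in SPECIES}})
        meta[sid] = {"ester_form": ester_form, "composition": c}
    table = pd.DataFrame(rows, columns=["sample_id", *SPECIES])
    return SpectrumSet.from_spectra(spectra, meta), table
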