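"""FAME-to-TAG calibration transfer via two-class PCA difference spectra.

Pure-component calibration standards for triacylglycerols are often
unavailable (mixed-acyl TAGs cannot be bought; free fatty acids crystallise).
The transfer trick: measure each fatty acid as its methyl ester (FAME) and as
the corresponding mono-acid TAG, extract the FAME->TAG spectral difference for
each acyl group i with a two-class PCA,

    delta_i = (Sc_TAG,i - Sc_FAME,i) * L_PC1,i

where L_PC1 is the first principal loading of the pooled replicate spectra and
Sc are the class-mean PC1 scores, then synthesise a simulated TAG mixture
spectrum from any FAME mixture spectrum,

    S_TAG(x) = S_FAME(x) + sum_i delta_i * c_i

with c_i the mole fraction of acyl group i.  PC1 carries the systematic
FAME-vs-TAG difference while replicate noise is relegated to the higher
components, so the PCA route is a noise-suppressed, subjectivity-free
replacement for hand-scaled difference spectra.

All spectra entering here are expected to be preprocessed (baseline-corrected
and ester-band normalized); deltas are computed on the full grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .spectra import Spectrum, SpectrumSet, WavenumberGrid
from .synth import SPECIES, Composition

__all__ = ["DeltaSpectrum", "TransferSet", "compute_delta", "simulate_tag",
           "simulate_tag_dataset"]


@dataclass(frozen=True)
class DeltaSpectrum:
    """Per-acyl FAME->TAG spectral variance with its PC1 provenance."""

    species: str
    delta: np.ndarray
    pc1_loading: np.ndarray
    score_fame: float
    score_tag: float
    pc1_explained: float

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.pc1_loading))
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"PC1 loading norm {norm} != 1")
        if not 0.0 <= self.pc1_explained <= 1.0 + 1e-12:
            raise ValueError("pc1_explained must lie in [0, 1]")
        recon = (self.score_tag - self.score_fame) * self.pc1_loading
        if not np.allclose(self.delta, recon, rtol=0, atol=1e-12 * max(1.0, float(np.max(np.abs(self.delta))))):
            raise ValueError("delta does not equal (score_tag - score_fame) * pc1_loading")


@dataclass(frozen=True)
class TransferSet:
    """The five per-acyl delta spectra on one shared grid."""

    deltas: Mapping[str, DeltaSpectrum]
    grid: WavenumberGrid

    def __post_init__(self) -> None:
        missing = [sp for sp in SPECIES if sp not in self.deltas]
        if missing:
            raise ValueError(f"transfer set missing species {missing}")
        n = len(self.grid)
        for sp, d in self.deltas.items():
            if d.delta.shape != (n,):
                raise ValueError(f"delta for {sp} not on the shared grid")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid": self.grid.values.tolist(),
            "deltas": {
                sp: {
                    "delta": d.delta.tolist(),
                    "pc1_loading": d.pc1_loading.tolist(),
                    "score_fame": d.score_fame,
                    "score_tag": d.score_tag,
                    "pc1_explained": d.pc1_explained,
                }
                for sp, d in self.deltas.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransferSet":
        payload = json.loads(Path(path).read_text())
        grid = WavenumberGrid(np.array(payload["grid"]))
        deltas = {
            sp: DeltaSpectrum(
                species=sp,
                delta=np.array(d["delta"]),
                pc1_loading=np.array(d["pc1_loading"]),
                score_fame=float(d["score_fame"]),
                score_tag=float(d["score_tag"]),
                pc1_explained=float(d["pc1_explained"]),
            )
            for sp, d in payload["deltas"].items()
        }
        return cls(deltas=deltas, grid=grid)


def compute_delta(fame_reps: SpectrumSet, tag_reps: SpectrumSet,
                  species: str = "") -> DeltaSpectrum:
    """Two-class PCA of pooled FAME / TAG replicate spectra of one acyl group.

    The pooled replicate matrix is channel-mean-centered, the first right
    singular direction is the PC1 loading, scores are the projections, and the
    delta spectrum is the class-mean score gap times the loading.  The loading
    sign is arbitrary; the delta is invariant to it.
    """
    if fame_reps.grid != tag_reps.grid:
        raise ValueError("FAME and TAG replicate sets are on different grids")
    if len(fame_reps) == 0 or len(tag_reps) == 0:
        raise ValueError("both replicate sets must be nonempty")
    X = np.vstack([fame_reps.intensities, tag_reps.intensities])
    Xc = X - X.mean(axis=0)
    total_var = float(np.sum(Xc * Xc))
    scale = float(np.max(np.abs(X))) or 1.0
    if total_var <= (1e-12 * scale) ** 2 * X.size:
        raise ValueError("degenerate variance: all pooled spectra are identical")
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loading = Vt[0]
    scores = Xc @ loading
    n_f = len(fame_reps)
    score_fame = float(scores[:n_f].mean())
    score_tag = float(scores[n_f:].mean())
    return DeltaSpectrum(
        species=species,
        delta=(score_tag - score_fame) * loading,
        pc1_loading=loading,
        score_fame=score_fame,
        score_tag=score_tag,
        pc1_explained=float(s[0] ** 2 / np.sum(s ** 2)),
    )


def compute_transfer_set(
    fame_reps: Mapping[str, SpectrumSet], tag_reps: Mapping[str, SpectrumSet]
) -> TransferSet:
    """Compute all five per-acyl deltas from per-species replicate sets."""
    grid = next(iter(fame_reps.values())).grid
    deltas = {
        sp: compute_delta(fame_reps[sp], tag_reps[sp], species=sp) for sp in SPECIES
    }
    return TransferSet(deltas=deltas, grid=grid)


def simulate_tag(
    s_fame_mix: Spectrum, c: Composition, transfer: TransferSet
) -> Spectrum:
    """Synthesise the TAG-mixture spectrum matching a FAME-mixture spectrum.

    Adds each per-acyl delta weighted by the mole fraction (mole % / 100):
    at 100% of one acyl group the full delta is applied.
    """
    if s_fame_mix.grid != transfer.grid:
        raise ValueError("FAME spectrum and transfer set are on different grids")
    y = s_fame_mix.intensity.copy()
    for sp in SPECIES:
        frac = c[sp] / 100.0
        if frac != 0.0:
            y = y + frac * transfer.deltas[sp].delta
    return Spectrum(s_fame_mix.grid, y, s_fame_mix.id)


def simulate_tag_dataset(
    fame_set: SpectrumSet, transfer: TransferSet,
    compositions: Mapping[str, Composition] | None = None,
) -> SpectrumSet:
    """Apply :func:`simulate_tag` to every spectrum of a composition-tagged set.

    Compositions are taken from the set's per-spectrum metadata (key
    ``"composition"``) unless an explicit mapping is given; metadata is
    preserved on the output.
    """
    out = []
    for s in fame_set:
        if compositions is not None:
            c = compositions.get(s.id)
        else:
            c = fame_set.metadata.get(s.id, {}).get("composition")  # type: ignore[assignment]
        if c is None:
            raise ValueError(f"no composition attached to spectrum {s.id!r}")
        out.append(simulate_tag(s, c, transfer))
    if not out:
        return SpectrumSet(fame_set.grid, np.empty((0, len(fame_set.grid))), [])
    return SpectrumSet.from_spectra(out, fame_set.metadata)
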