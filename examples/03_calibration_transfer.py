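"""FAME-to-TAG calibration transfer via two-class PCA.

Computes the per-acyl delta spectra (PC1 score gap times PC1 loading) from
pure FAME/TAG pairs and shows that adding the full delta to a pure FAME
spectrum reconstructs the corresponding pure TAG spectrum.
"""

import numpy as np

from acylquant import (SPECIES, Composition, RunConfig, SpectrumSet,
                       preprocess, pure_component_spectra, simulate_tag)
from acylquant.pipeline import stage_transfer

transfer = stage_transfer(RunConfig())

fame = pure_component_spectra("FAME")
tag = pure_component_spectra("TAG")

print("species  PC1 explained   ||delta||    pure-TAG reconstruction error")
for sp in SPECIES:
    d = transfer.deltas[sp]
    f = list(preprocess(SpectrumSet.from_spectra([fame[sp]])))[0]
    t = list(preprocess(SpectrumSet.from_spectra([tag[sp]])))[0]
    sim = simulate_tag(f, Composition({sp: 100.0}), transfer)
    rel = np.linalg.norm(sim.intensity - t.intensity) / np.linalg.norm(t.intensity)
    print(f"{sp:7s}  {d.pc1_explained:12.3f}  {np.linalg.norm(d.delta):9.4f}    {rel:.2e}")

# With noiseless pure pairs PC1 carries all the variance (explained = 1) and
# the reconstruction error is at machine precision: the simulated TAG
# spectrum leaves no features in the residual.
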