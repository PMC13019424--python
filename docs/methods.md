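# Methods

## Scope and model

`acylquant` quantifies the mole percentages of five fatty acyl groups —
MA (14:0), PA (16:0), SA (18:0), OA (18:1), LA (18:2) — in TAG-dominated
samples from Raman spectra over 650–1800 cm⁻¹. The central assumption is
bilinearity: after normalization to the ester C=O internal standard, a
mixture spectrum is (to first order) the mole-fraction-weighted sum of
component spectra, and the FAME→TAG spectral change of a mixture is the
mole-fraction-weighted sum of per-acyl pure-component changes. The second
assumption is what the transfer step encodes: the systematic FAME-vs-TAG
difference of one acyl group is one-dimensional and is captured by the first
principal component of pooled replicate spectra, while replicate noise falls
into higher components. Acyl–acyl interaction effects inside mixed TAGs are
outside the model: the deltas are learned only from mono-acid TAGs, so
samples where acyl groups interact strongly will show degraded accuracy.

## Pipeline and parameters

Preprocessing order is fixed: background subtraction (scale default 1.0) →
baseline correction → ester-band normalization. Baseline correction is an
iterative polynomial fit (default degree 3, 20 iterations) in which the
working signal is clipped to the elementwise minimum of signal and current
fit, so peaks stop attracting the baseline. This scheme is exactly
equivariant under addition of any polynomial of degree ≤ order, which makes
the preprocessing chain idempotent to machine precision — a useful
diagnostic invariant. Normalization divides by the trapezoidal area of the
C=O band over the closed window 1720–1770 cm⁻¹ (no local baseline anchoring
inside the window); a nonpositive area is an error, since it signals a
missing ester band.

Transfer deltas are computed on the full preprocessed grid from pooled
two-class PCA (channel means over the pooled set; class-mean scores; loading
sign irrelevant by construction). In TAG-spectrum simulation the composition
enters as mole fraction (mole % / 100), so a pure FAME spectrum receives the
full delta.

PLS1 models are fitted by NIPALS (centering only, no scaling), one model per
acyl group, on channels extracted from per-species window sets. Window
intervals are closed, stored descending by upper edge, and written in the
`hi-lo,hi-lo` dialect. The built-in window sets are the published optimized
ones; alternatively a greedy forward search adds regions from the breakpoint
partition {650, 800, 930, 1110, 1200, 1280, 1380, 1500, 1700, 1800} while
the 10-fold RMSECV improves by more than 1e−6, breaking ties toward the
higher-wavenumber region. The latent-variable count is chosen as the global
RMSECV minimum (smallest count on ties) over 1..max_lv with seeded 10-fold
CV. The default cap is max_lv = 6: a closed five-component system has
chemical rank 5, and one extra factor absorbs residual preprocessing
structure. The cap matters because cross-validation cannot penalize factors
that model systematic preprocessing artifacts shared across folds — on very
low-noise data an uncapped search keeps adding such factors, which degrade
predictions on independently rendered spectra.

Predictions are reported raw (not clipped to [0, 100]) with an out-of-range
flag, and composition summaries never force the five means to close to
100 %: the remainder is reported as "unknown", negative if the predictions
over-sum. Dispersion conventions follow the field: RMSEC/RMSEP divide by n;
the replicate SD divides by n−1; the standard error is sd/√n.

Median-linkage (WPGMC) clustering runs on squared Euclidean distances with
the Lance–Williams update d²(k, ij) = d²(k,i)/2 + d²(k,j)/2 − d²(i,j)/4 and
reports square-root heights, which preserves the geometric-midpoint
interpretation. Ties are broken by lowest pair index. Median linkage can
produce height inversions; trees are therefore cut by repeatedly splitting
the highest-height current root rather than by a height threshold.

## The synthetic generator

Because no instrument spectra ship with the package, a generator emulates
the statistical structure the pipeline assumes. Pure components are sums of
pseudo-Voigt bands; band positions and qualitative orderings follow the
standard lipid assignments (1740 C=O; 1439 CH₂/CH₃ bend growing SA > PA > MA;
1650/1260 unsaturation bands present only for OA/LA with LA > OA; skeletal
1050–1130; ester-sensitive 800–930 with distinct FAME vs TAG bands; weak
718/760 low-frequency bands). Amplitudes and widths are package-invented
and live in versioned JSON files (`acylquant/data/bands/`); they were chosen
once so that the five FAME spectra are mutually distinguishable below
1100 cm⁻¹, the FAME-vs-TAG difference concentrates near 1740, in 1500–1400
and in 900–800 cm⁻¹, and triplicate-replicate two-class PCA puts 83–87 % of
pooled variance on PC1. TAG tables differ from FAME tables by: C=O center
+4 cm⁻¹ and width ×1.3; a 1500–1400 amplitude-ratio shift (×1.12 at 1439);
perturbed C=C bands (−3 cm⁻¹, ×1.08) for OA/LA only; and replaced 838–890
ester bands.

Mixture spectra are exactly linear in mole fraction before noise. Noise is
i.i.d. Gaussian per channel (default sd 1 % of the maximum pure-component
intensity) plus a random polynomial drift (default order 2, amplitude 2 %),
all reproducible from integer seeds. The default design is 165 training
mixtures (the five pure vertices, ten binary midpoints, the centroid, and a
flat-Dirichlet fill of the 5-simplex) and 20 Dirichlet test mixtures; the
actual laboratory concentration design behind the published tables is not
public, so design-dependent figures are analogs rather than reproductions.

What the generator does **not** emulate: Raman cross-section differences
between bands of one molecule, polarization and crystal-orientation effects,
fluorescence photobleaching kinetics, cosmic rays, wavenumber miscalibration,
and acyl–acyl interactions in mixed TAGs. Passing tests therefore show the
pipeline is correct and well-conditioned under its stated assumptions, not
that instrument data will reach the same error levels.

## Numerical choices and degenerate inputs

Grids are stored strictly ascending (reports render descending); intervals
are closed. Resampling is linear interpolation, and requesting points
outside the source span is an error rather than extrapolation. Two-class
PCA refuses all-identical pooled spectra (degenerate variance). PLS refuses
a zero-variance target, and NIPALS stops early if the response residual is
exhausted. CLS unmixing requires full column rank; NNLS (Lawson–Hanson) is
always feasible and is accepted by its KKT conditions. Spectra CSVs are
written with 12 significant digits so save/load round-trips at 1e−11
relative.

## Problem sizes

Default test-suite and acceptance runs use the study-scale design (165/20,
1151 channels) for the closed loop, 100 seeds for noise-suppression and
LV-selection simulations, 20 seeds for transfer-vs-direct comparisons at a
reduced 40/10 design, and 50-point clusterings — sizes chosen to make every
stochastic claim stable at fixed seeds while keeping a full run in minutes.

## Known limitations

* The transfer model is first-order: one PC per acyl group. Curved
  FAME→TAG responses or interaction effects are not representable.
* Window optimization is greedy over a fixed partition; it will not find
  windows that are only jointly (non-monotonically) informative.
* Published per-model figures obtained on instrument spectra with a
  commercial PLS implementation are not numerically reproducible here; the
  package targets the method's structure and its closed-loop error regime.
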