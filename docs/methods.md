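# Methods

This note records the models behind `rfradiomics`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical conventions — the things a maintainer or reviewer would ask
about first.

## RF signal model

A frame is a matrix of beamformed RF samples (rows = axial samples, cols =
scan lines) on a rectangular scan-line grid; sector display geometry is
deliberately out of scope because every computation in the pipeline runs in
scan-line space.  Defaults: 20 MHz sampling, 3 MHz pulse centre frequency,
0.6 fractional −6 dB bandwidth, 128 lines × 2048 samples (≈7.9 cm depth at
1540 m/s) — plausible desk-scale values for an abdominal curved array.

Each scan line is a train of resolvable point scatterers convolved with a
Gaussian-modulated sinusoid.  One scatterer occupies each resolution cell
(cell length = pulse support, ±4σ ≈ 35 samples at defaults), at an
integer-jittered position (±cell/8) with random polarity, and its amplitude
is drawn directly from the tissue's Nakagami(m, Ω) law (power ~
Γ(m, Ω/m)).  Imposing amplitudes this way guarantees the envelope
statistics the Ω estimator assumes, with no scatterer-count tuning; a
`scatterer_density` above 1 splits each cell's draw over diffuse
sub-scatterers, which (physically correctly) drifts the envelope toward
Rayleigh.  The scatterer lattice phase is drawn independently per scan
line: a shared lattice aliases against the sliding analysis windows and
leaves deterministic per-row energy-slope artifacts of tens of dB/cm.

Attenuation is single-band: the RF amplitude is multiplied by
10^(−f_c·∫α dz/20), with α piecewise (background vs lesion ellipse), so the
envelope log-power declines at α·f_c dB/cm locally.  Frequency-dependent
spectral drift of the pulse with depth is not modelled — the attenuation
parameter here is a single energy-decay rate, matching what the DEA map
estimates.  Local spectral heterogeneity is modelled instead by perturbing
each scatterer's pulse centre frequency (fractional SD
`spectral_jitter_sd`).

### The two lesion classes

| parameter | MVI+ | MVI− | background | between-lesion jitter |
|---|---|---|---|---|
| α (dB·cm⁻¹·MHz⁻¹) | 0.9 | 0.5 | 0.5 | ±0.05 (normal) |
| Nakagami m | 0.8 | 1.1 | 1.0 | ±0.25 (normal) |
| Nakagami Ω | 1.2 | 1.2 | 1.0 | ×lognormal(0.10) |
| spectral jitter SD | 0.08 | 0.03 | 0.03 | ×lognormal(0.40) |

The positive class attenuates more strongly, is more pre-Rayleigh, and is
spectrally noisier, so all three parametric maps carry class signal.  Ω is
equal across classes on purpose: the OND contrast then arises only through
differential attenuation of the arriving energy, consistent with treating
stronger attenuation as the positive group's defining physical property.  The lesion is an axis-aligned ellipse (~1.8 cm × ~37% of the
aperture at mid-depth), jittered per lesion in size (±10% lognormal) and
centre.  Between-lesion jitters are chosen to be clinically large: B-mode
speckle statistics overlap heavily between MVI groups in practice, which is
exactly why image-only prediction of MVI is hard.

### Display emulation

Clinical grayscale images pass through operator-controlled display
processing that the RF data bypass.  The simulator therefore attaches to
each frame a per-acquisition time-gain-compensation curve — compensation of
the background attenuation plus a smooth operator error (linear
interpolation of 6 depth knots drawn N(0, 2.5 dB)) — and only the
grayscale-image arm of the pipeline applies it before log compression.
The parametric maps always work on raw RF.  Without this, the displayed
image would carry the absolute depth-brightness information that real
scanners remove, and the grayscale model would be unrealistically strong.

### What a green test does not establish

The generator reproduces envelope statistics, single-band attenuation, and
spectral jitter; it does not simulate diffraction, beam focusing,
elevational effects, sector scan conversion, motion, or reverberation
artifacts.  Green property tests establish that the estimators recover the
generating parameters of *this* world and that the pipeline's ordering and
separation behaviours hold in it — not that any particular clinical
performance level would be reached on real data.  One consequence is documented as a known red acceptance property:
in a fully generative world the grayscale-image model can read every
envelope-statistics class channel at least as well as the coarse parametric
maps, so the strict model ordering "three-map ≥ DEA-only ≥ grayscale" holds
only partially (the three-map model dominates both single arms stably; the
DEA-only ≥ grayscale link does not).

## Parametric maps

Windows default to 128 samples × 8 lines with 50% overlap (≈0.49 cm ×
~3.7 resolution cells axially) — conventional quantitative-ultrasound
sizing; no standard fixes these window parameters.

- **DEA**: the window is split into 8 axial sub-windows; DEA is the
  least-squares slope of 10·log₁₀(mean squared RF per sub-window) against
  sub-window centre depth, in dB/cm.  Unbiased at α=0 (|mean| < 0.1 dB/cm
  over seeds) and recovers α·f_c within a few percent seed-averaged;
  individual windows are noisy (±5 dB/cm), which is intrinsic to
  log-energy regression over ~4 speckle cells.
- **SDSD**: per window, the magnitude spectrum of Hann-tapered lines
  (averaged over the window's lines), in dB, restricted to the pulse band —
  estimated from the data as frequencies within 20 dB of the ROI-mean
  spectrum's peak.  SDSD is the standard deviation over band frequencies of
  (window spectrum − reference spectrum), the reference being the mean
  spectrum of the shallowest window row.  A pure amplitude change shifts
  the dB spectrum uniformly and leaves SDSD at zero; only spectral-shape
  differences register.  The within-ROI reference keeps the map
  self-contained and machine-independent.
- **OND**: moment estimators on the envelope, Ω̂ = mean(R²) and
  m̂ = mean(R²)²/var(R²) (m̂ kept as a diagnostic only).  Moments rather
  than maximum likelihood: closed form, robust at 1024-sample windows, and
  accurate to ~1% at that size.

Windows with zero energy are recorded as missing and mean-imputed from the
rest of the map (count kept on the map object) before the min–max 8-bit
rendering; a constant map renders mid-gray (128) to avoid 0/0.

## Texture battery

Matrix families quantise to 32 equal-width levels (fixed, configurable);
the histogram family works on the raw 8-bit intensities.  GLCM and GLRLM
matrices are computed per direction (0°, 45°, 90°, 135°, distance 1),
normalised/symmetrised, and averaged *as matrices* before feature
computation.  GLSZM zones are 8-connected; NGTDM uses a 3×3 neighbourhood
with masked-neighbour averaging and a 10⁶ cap on coarseness for flat
regions.  Degenerate single-level regions: contrast 0, energy 1,
correlation 1, information measures 0.

The exact 70-feature list is frozen in code (`feature_names_70`) with
documented order; the per-family counts (16+23+13+13+5) are structural
invariants asserted at run time.  Two of the 23 GLCM features
(dissimilarity and difference average) coincide mathematically; both are
kept because the list is defined by enumeration, not numerical
independence.  The wavelet step is a one-level orthonormal 2-D Haar
transform implemented in-package (no wavelet library in the environment);
odd dimensions are edge-replicated, sub-band masks are downsampled by 2×2
majority with ties counting as inside, and sub-band coefficient images are
min–max rescaled to 8-bit before texture extraction.

## Selection and classification

The sparse-representation step is concretised as L1-penalised least squares
of the ±1 label vector on subset-standardized features (sklearn lasso
objective, 1/(2n)·RSS + λ‖w‖₁).  Defaults: 100 iterations, stratified 80%
subsamples, threshold Tal = 0.004 applied to the *averaged* coefficients,
ties in |coefficient| broken lexicographically by feature name.  λ, when
not given, is picked from {0.01, 0.03, 0.1, 0.3} by ranking stability
(mean pairwise Jaccard of top-20 nonzero sets over 8 subsamples); smaller
penalties win ties.

The default protocol ("paper" mode) selects features on all samples and
cross-validates only the classifier — this leaks test labels into the
ranking and is optimistic; it is kept as the default because it is the
protocol many clinical radiomics studies report, and a "nested" mode
(selection re-run inside every LOOCV training fold) is provided for honest
estimates.

The classifier is an RBF-SVM (C=1, gamma='scale'); features are
standardized per training fold.  Hard labels threshold the decision score
at 0; ROC/AUC use the continuous scores (trapezoidal, identical to the
normalised Mann–Whitney U); the AUC interval is DeLong's.  The best
feature count maximises accuracy, then AUC, then smallness of k.  Decision
curves need probabilities, obtained from a logistic link fitted on the
LOOCV decision scores (Platt-style; slightly optimistic since the link is
fitted on all scores, documented here rather than hidden).  Net benefit is
NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t).

Group statistics: one-way ANOVA per parameter between MVI groups on the
per-lesion mean map values, plus a Tukey HSD table among the three
parameters (z-scored, pooled over lesions) — the latter is retained for
completeness even though pairwise comparison of different physical
quantities is of limited scientific value.

## Reproducibility and numerics

Every stochastic step flows from one seeded `numpy` generator per entry
point (frame, cohort, selection, pipeline); identical config + seed gives
byte-identical CSV outputs.  The pipeline writes its resolved config, a
SHA-256 config hash, package version and stage timings into a run
manifest.  Frames serialise as float32 column-major binary or plain-text
matrices with a JSON sidecar; maps as 8-bit BMP plus a sidecar holding the
raw value range, making the rendering invertible up to quantisation.

## Known limitations

- No acoustic field simulation (beamforming, diffraction, focusing) and no
  sector scan conversion; markers are taken natively in scan-line space.
- The DEA/SDSD definitions, window sizes, SR objective and SVM kernel are
  conventional reconstructions; the originals are not publicly specified.
- OND class contrast is indirect (via attenuation), so its effect size is
  the smallest of the three maps.
- The paper-mode selection protocol is optimistic by construction; use
  nested mode for unbiased performance estimates.
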