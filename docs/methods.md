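# Methods

## The intensity model

All of `faintnmr` rests on one proportionality. For an isolated signal in
a 1D proton spectrum acquired with full inter-scan relaxation,

    I = IG · NS · g(RG) · n_H · c

- **I** — absolute integral of the signal's region, in intensity·ppm
  units on the spectrum's own scale;
- **NS** — number of co-added scans (signal adds linearly, noise as √NS);
- **g(RG)** — the receiver's true gain at nominal setting RG; for an
  ideal amplifier g(RG) = RG;
- **n_H** — protons contributing to the signal;
- **c** — analyte concentration (mM; "mmol per liter" throughout);
- **IG** — the Intensity-Gain factor, a constant of the spectrometer,
  probe, pulse calibration and processing chain: intensity per scan, per
  RG unit, per proton, per mM.

Calibration divides measured integrals by NS·RG·c·n_H ("normalized
increments") and takes their arithmetic mean as IG (a median option
exists for contaminated sets; the mean is the definition). The dispersion
reported alongside is the population standard deviation of the
increments. Quantification inverts the model:
c = I / (IG · NS · RG · n_H), pooling all (signal × experiment) estimates
of a sample into a mean and a sample (ddof = 1) standard deviation.
Pooling is flat by default — every estimate weighs equally — with a
per-signal-first alternative behind the `pooling` flag; the two differ
only when signals are measured unequally often.

Assumptions inherited from the model: D1 ≥ 5·T1(max) so magnetization
recovers between scans (the metadata validator warns below that);
isolated signals (overlap is the user's responsibility via region
choice, flagged as a warning); constant temperature across a set; SNR
comfortably above 200:1 so integral noise stays below ~1% per estimate.

## RG linearization

Receiver amplifiers deviate from nominal gain by a few percent, and the
deviation is step-dependent. Because the usable RG range depends on
sample strength (an automatic receiver-gain routine caps strong samples
at low RG), the deviation does not average out: it correlates with
concentration and tilts the calibration slope away from 1.

The linearizer estimates, for each distinct RG step in the calibration,
f(RG) = (mean normalized increment at that step) / IG, and tabulates
RG_lin = RG · f(RG). Only the *shape* of g(RG)/RG is identifiable — the
global level is absorbed into IG — so the table is meaningful up to a
common factor, and back-calculation with linearized RG values is
invariant to that factor. No smoothing is applied across steps: measured
step corrections are not monotone, and smoothing would re-introduce bias
at the steps that matter. Lookups at tabulated steps are exact; between
steps, linear interpolation; outside the table, an error unless
extrapolation by the nearest edge's correction factor is explicitly
allowed.

## Synthetic data

The generator realizes the model exactly, so every downstream stage has
ground truth:

- **Lineshape**: Lorentzian, built directly in the frequency domain with
  analytically known areas; multiplets as weight-1 component sums. The
  matching time-domain path (`simulate_fid`) writes decaying complex
  exponentials with R2 = π·linewidth, so the processing chain can be
  tested against the same areas.
- **Gain**: a per-step deviation table g(RG)/RG. The default nonlinear
  model reuses the bundled instrument ladder's linearized/original ratios
  (0.92–0.97) — a realistic amplifier; an identity model is one flag away.
- **Noise**: additive white Gaussian in the frequency domain with per-point
  std `noise_sigma · g(RG) · √NS`, matching per-scan co-addition. The
  measured study did not state its noise model; Gaussian is this
  package's assumption, not an inferred fact. `noise_sigma_for_snr`
  back-solves the σ that puts a set's weakest signal at a target SNR
  (200:1 for the default noisy conditions).
- **Default study design**: five samples at 5.29, 29.44, 48.19, 77.78 and
  108.35 mM (the bundled quinine preparations), four (NS, RG) settings
  each with NS ∈ {2, 8, 32, 64} and RG spanning the instrument ladder up
  to each sample's strength-limited maximum (161, 90.5, 90.5, 40.3, 36),
  in duplicate: 40 spectra per set. Default signals are five singlets,
  1 Hz wide at 400 MHz, spread 1.8 ppm apart over a 14 ppm window with
  16384 points; integration regions are ±0.6 ppm around each.

What the simulator does **not** emulate: relaxation beyond the lineshape
(no T1 saturation bias), J-coupling evolution, solvent signals,
temperature drift, phase/baseline artifacts other than those injected on
purpose. Passing tests therefore demonstrate correctness of the
*method's arithmetic and estimators* under its stated assumptions, not
robustness to every pathology of real spectra.

## Numerical choices

- **Quadrature**: trapezoid on the spectrum grid, bounds half-open (a
  point exactly on the lower ppm bound belongs to the region, one exactly
  on the upper does not). For Lorentzians sampled at ≥1.5 points per
  half-width the grid error is negligible (<0.01%); the dominant bias is
  the analytic tail mass outside the region — 0.13% for the default
  ±0.6 ppm regions on 1 Hz lines, 0.64% at ±50 linewidths. Because IG is
  calibrated and applied on the *same* regions, this bias cancels in
  back-calculated concentrations.
- **FT normalization**: DFT × dwell time with the first FID point halved
  — the discrete approximation of the continuous transform, making
  spectral integrals independent of zero-filling (factors 1, 2, 4).
- **Auto-phase**: minimize derivative-entropy plus a heavily weighted
  (10⁶) negative-intensity penalty over (ph0, ph1), coarse 10° grid then
  Nelder–Mead. For noiseless absorption signals the penalty's minimum
  sits exactly at the true phases; the entropy term only disambiguates
  the grid stage. First-order phase is linear across the stored
  (descending-ppm) array with the pivot at index 0. Manual phases are a
  config flag. Convergence failure raises, carrying the best phases found.
- **Baseline**: polynomial (degree ≤ 2) fit to signal-free points found
  by iterated MAD clipping; a smoothing-spline alternative behind the
  method flag; identity on an all-zero spectrum. No apodization anywhere:
  window functions conserve integrals only approximately, and
  quantification prefers untouched integrals.
- **SNR**: peak height in the region over twice the standard deviation of
  a user-named noise region — the common convention, stated explicitly
  because only the 200:1 outcome is usually reported.
- **Reporting**: concentrations are rounded to 0.01 mM in tabular output;
  full precision is kept internally and in the library API.

## Design notes

- Spectra are generated in the frequency domain rather than via inverse
  FT of simulated FIDs, so simulator correctness never depends on the
  processing module it is used to test; the FID path exists separately
  and is held to the same integral contract.
- `FaintCalibrator` follows the scikit-learn estimator API (fit/predict,
  `get_params`/`set_params`, trailing-underscore fitted attributes)
  because the method genuinely is a fit-then-predict calibration; IO,
  processing and integration are stateless transforms on domain objects
  and remain plain functions.
- The bundled study's back-calculation pooled 13 signals and duplicate
  experiments without stating the grouping behind its per-sample σ; this
  package defines σ as the sample standard deviation of the flat estimate
  pool and exposes the per-signal-first alternative, rather than claiming
  to reproduce an unstated convention.
- The internal `.fnmr` format is a YAML text header plus a raw
  little-endian float64 payload: bit-exact round trips without any binary
  container dependency. The Bruker-style reader covers exactly the
  parameter subset quantification needs (NS, RG, D1, TE, SW, TD, SFO1,
  O1P, BYTORDA, DTYPA ∈ {int32, float64}) and never defaults NS or RG —
  a missing key is an error, because silently assumed scan counts corrupt
  quantification invisibly.

## Problem sizes

Simulated calibration sets are 40 spectra of 16384 points (five
concentrations × four settings × duplicates); the bundled study tables
have five samples and a 17-step RG ladder. These sizes match the emulated
study conditions and keep the full test suite and the acceptance script
in the seconds range.

## Known limitations

- The IG factor and the global level of g(RG) are confounded by design;
  only products IG·g(RG) are observable. All quantification results are
  invariant to this, but the fitted `ig_` should not be compared across
  gain models.
- Auto-phasing is specified by an integral-accuracy contract, not by
  equivalence to any vendor algorithm; on very noisy spectra the
  first-order term is weakly determined (the per-peak phase error stays
  small, and symmetric regions make integrals first-order insensitive to
  it).
- No peak picking, lineshape fitting or deconvolution: regions are the
  user's statement of which signals are isolated. Overlap handling beyond
  a warning, 2D experiments, and internal/external-reference modes are
  out of scope.
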