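# Methods

## Spectral model

Each analyte is modelled as a Beer–Lambert absorber whose per-unit
absorptivity is a sum of Gaussian bands,

    ε(λ) = Σ_k ε_k · exp(−(λ − μ_k)² / (2 σ_k²)),

so a pure-component spectrum at concentration c (µg/mL) is exactly
c·ε(λ), and mixtures are exactly additive. The Gaussian-band form is the
standard smooth approximation for solution-phase UV bands; it makes
linearity and additivity hold to machine precision, which in turn makes
the zero-crossing identities exact in the noise-free limit.

Spectra live on a uniform wavelength grid, by default 200–350 nm at
0.1 nm — the coarsest step that still resolves working wavelengths quoted
to one decimal place. Wavelengths are stored ascending regardless of scan
direction.

### Preset analytes

Two presets model a buprenorphine-like major component (valid range
20–80 µg/mL) and a naloxone-like minor one (5–20 µg/mL). Each has a
dominant band near 248 / 261 nm plus aligned secondary systems (deep-UV
near 214 nm, shoulder near 290 nm). The geometry is deliberate:

- the ~13.5 nm separation of the main bands puts each analyte's
  third-derivative zero crossing close to the *other* analyte's
  derivative extremum, i.e. the crossings are intrinsically sensitive
  working wavelengths;
- the aligned secondary bands plus the main-band overlap give a
  zero-order **spectral overlap** of 0.74 over 230–300 nm, measured as
  the uncentered cosine similarity of the normalized spectra (the
  complement of the spectral contrast angle). Cosine similarity is used
  deliberately: it is the standard "how much do these band systems
  overlap" measure for non-negative spectra, where mean-centred Pearson
  correlation conflates overlap with peak-position agreement;
- band amplitudes put typical working solutions (50 and 20 µg/mL) at
  peak absorbances of 1.29 and 1.37 AU, inside the 0.1–1.5 AU window
  where photometric error is smallest, while keeping enough derivative
  signal that the lowest levels sit ~100× above the derivative noise
  floor.

The presets are a synthetic stand-in for the real molecular spectra: no
attempt is made to reproduce any instrument trace, and the selected
working wavelengths (247.1 / 262.2 nm for the default seed) are
properties of these presets, not of the real drugs.

### Noise model

Instrument noise is additive i.i.d. Gaussian photometric noise, default
SD 0.002 AU — a realistic figure for a bench double-beam instrument —
plus a random quadratic baseline drift of up to 0.005 AU emulating slow
lamp/blank drift. A quadratic drift is annihilated exactly by third and
fourth differences and nearly so by the second, mirroring why derivative
spectrophotometry is robust to broad background. Slit-function
(bandwidth) convolution is not modelled: the band widths are free
parameters anyway, so a fixed extra broadening would be unidentifiable.
Identical seeds reproduce identical spectra bit-for-bit.

What the generator does **not** emulate: stray light and photometric
non-linearity at high absorbance, wavelength-registration error between
scans, temperature/solvent effects on band shape, and correlated
(1/f-like) noise. Passing tests therefore demonstrate the correctness of
the algorithms under the stated statistical model, not instrument-grade
robustness.

## Derivative transform

The default backend is the iterated symmetric difference

    D¹(λ) = [A(λ + Δλ/2) − A(λ − Δλ/2)] / Δλ,

applied n times (n = 1…4). Δλ is interpreted as the *total offset per
difference step*; it must be an integer multiple of twice the grid step
so half-offsets land on grid points, making the transform exact (no
interpolation). The output grid is trimmed by n·Δλ/2 per end — values are
only reported where the stencil is fully supported (trim, never pad).
Large Δλ acts as a low-pass filter; no additional smoothing is applied.

A Savitzky–Golay backend (local polynomial of order max(3, n) over a
window of ≈ Δλ, widened to the smallest valid odd window when Δλ is
narrow) is provided because scanning spectrophotometers do not publish
their internal algorithm. Both backends are linear operators and both
reproduce the closed-form third derivative of a Gaussian band to better
than 10⁻³ relative error at the extrema (tested).

White-noise amplification of the difference backend is
√(Σ_k C(n,k)²)/Δλⁿ; this `noise_gain` is what the parameter optimiser
uses to convert amplitude sensitivity into signal-to-noise.

## Zero-crossing screening and selection

Crossings are located as sign changes of consecutive samples, positioned
by linear interpolation (exact on-grid zeros are reported at the grid
point). On a 0.1 nm grid, interpolation leaves sub-0.01 nm error near any
well-conditioned crossing, so higher-order root polishing is unnecessary.

For each candidate working wavelength of a target analyte (= a crossing
of the interferent's mean-normalized derivative):

- **sensitivity** — slope of the target's derivative amplitude vs. its
  concentration at the consensus crossing (mean position across
  interferent levels, matched within a 2 nm window);
- **crossing stability** — SD of the crossing position across
  interferent concentrations (exactly zero for ideal Beer–Lambert
  spectra; noise makes it positive);
- **residual interference** — |slope of the interferent's amplitude vs.
  its own concentration| at the consensus crossing, relative to the
  target sensitivity.

Feasibility thresholds default to residual ≤ 0.02 and stability ≤ 0.2 nm
(two grid steps). These quantify the conventional qualitative criteria
("acceptable sensitivity and reproducibility"); they are package
conventions, not published constants. Among feasible candidates the most
sensitive wins, ties broken by smaller residual, then lower wavelength.

The (order, Δλ) search loops the screen over orders 1–4 and a Δλ grid
(default 14, 28, 42 nm) and ranks feasible pairs by the smaller of the
two analytes' SNR at their lowest validated level, SNR = sensitivity ×
level / (noise SD × noise gain). Screening standards are scanned three
times and averaged (default), standard practice when locating crossings
on a noisy instrument. For the default presets the search selects order 2
at Δλ = 28 nm — second and third differences score nearly identically for
these band widths, and the ranking is an honest SNR argument, not a
fitted choice.

## Calibration and quantitation

Unweighted ordinary least squares of amplitude on concentration (no
weighting is justified when the amplitude noise is concentration-
independent, as here). Standard errors of slope and intercept come from
the residual variance; r is the signed Pearson correlation (derivative
amplitudes may be negative, so |r| is the linearity figure of merit; the
default study yields |r| > 0.9999 ≥ the 0.997 assay convention).
Degenerate designs: identical concentrations raise an error; a flat
response returns slope 0 with a `degenerate` flag. Inversion is
c = (Y − b)/m; out-of-range results are flagged, not raised (assay
practice: dilute and re-run).

## Validation statistics

- CV% = 100·SD/mean (sample SD, ddof = 1); Error% =
  100·(mean found − nominal)/nominal, negative meaning under-recovery.
- Within-day rows pool the replicates of one day per level (n = 3 by
  default); between-day rows pool all days (n = 9).
- Standard-addition recovery = 100·(found_spiked − found_base)/added per
  spike, reported with mean ± SD across spikes. Spikes (default +10/20/30
  µg/mL on the major, +2.5/5/7.5 on the minor analyte) keep the spiked
  solutions inside the validated ranges.
- Method comparison: paired t (df = n − 1) by default — the convention
  consistent with a critical value of 4.303 at n = 3 — with a pooled-
  variance two-sample mode (df = n₁ + n₂ − 2) also exposed. The F ratio
  defaults to reference-method variance in the numerator (`match_paper`
  convention). Equivalence requires both |t| ≤ t_crit and F ≤ F_crit at
  α = 0.05. Zero-variance degenerate groups yield t = 0 / F = 0 when the
  summaries agree and ±∞ flags when they do not.
- The simulated reference method reports truth ± 0.5 % relative error —
  a typical HPLC repeatability — and tablets carry a 1 % relative content
  variation so both methods see the same per-tablet truth.

## Study sizes and runtime

The default study — 7-level × 6-replicate calibrations for both analytes,
3 × 3 × 3 validation, triplicate tablet assay, 3-spike recovery — runs in
~0.1 s, so the acceptance sweep (20 independently seeded studies, 480
precision/accuracy cells) and the 60-study unbiasedness check run in
seconds. These sizes match the emulated assay design; nothing is scaled
down.

## Known limitations

- Gaussian bands and additive noise are idealisations; real spectra can
  violate additivity (association equilibria, pH shifts) in ways the
  generator cannot produce.
- The working wavelengths, slopes and intercepts are properties of the
  synthetic presets and are not comparable to any instrument's values;
  only the *structure* of the results (linearity, CV/Error bounds,
  recovery near 100 %, t/F inside critical values) is meaningful.
- The JCAMP-DX reader supports only fixed-point `(X++(Y..Y))` tables —
  enough to ingest a simple exported scan, nothing more.
- No LOD/LOQ estimation and no weighted or robust regression.
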