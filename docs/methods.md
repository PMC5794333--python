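# Methods

This note documents the models, default parameters, numerical choices and
known limitations behind each osmoquant module. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Quantitative ¹H-NMR

### Model

A 1-D spectrum is a descending, evenly spaced chemical-shift axis (ppm)
with one intensity per point. Quantification is ratio-based qNMR: the
molar concentration of solute *s* in the tube is

    c_s = (A_s / A_std) · (n_H,std / n_H,s) · c_std

where A is the integrated area of the designated quantification peak,
n_H the number of equivalent protons behind it, and the internal standard
is TMSP (9 equivalent protons at 0.0 ppm). The proton-count factor is
standard qNMR practice and is required for molar results; it is tested
explicitly. Because quantification is a ratio, it is exactly invariant to
rescaling the whole spectrum.

### Peak detection and assignment

Peaks are local maxima of a lightly Savitzky–Golay-smoothed trace
(11 points, quadratic; disable with `smooth_points=0`) above
`min_snr × σ_noise`, where σ_noise is the MAD-based standard deviation of
a signal-free region (default 9–10 ppm) of the same trace. The default
`min_snr = 3` favours sensitivity for weak single-proton resonances; on a
65k-point axis a 3σ threshold admits a few spurious noise maxima, which is
harmless for assignment because a genuine resonance is always the nearest
candidate to its reference shift. The residual-water (HOD) region
4.6–4.9 ppm is excluded by default.

Assignment matches each reference peak to the nearest detected peak within
a tolerance (default 0.03 ppm; ties resolve toward lower ppm; one detected
peak is never assigned twice within the same solute). A solute counts as
identified only when **all** of its reference peaks match — a deliberately
conservative rule that trades sensitivity for specificity.

### Integration and the window choice

Areas are trapezoidal integrals over `center ± window` after subtracting a
straight baseline through the window endpoints; each endpoint value is the
mean over a small flanking margin (25% of the window per side) because a
single-sample endpoint would make the baseline the dominant noise term.
Areas are floored at zero.

A finite window truncates a Lorentzian line; since every quantification
line shares the same linewidth, the truncation factor cancels exactly in
the area ratio, so narrow windows cost no accuracy on clean spectra. The
function default is ±0.05 ppm, but the shipped library contains a
near-degeneracy — ectoine's 3.29 ppm methylene lies 0.02 ppm from glycine
betaine's 3.27 ppm quantification singlet — so all round-trip benchmarks
and the pipeline demo use ±0.008 ppm, which separates the two at the
default 1.5 Hz linewidth. The window is a method parameter to be chosen
against the solute panel in use.

### Shipped reference library

GB (3.91 ppm CH₂ 2H; 3.27 ppm N⁺(CH₃)₃ 9H, quantification), Ect (4.01,
3.44, 3.29, 2.12 ppm plus the methyl quantification peak, default
2.25 ppm with 2.44 ppm selectable — both values circulate in the
literature and neither is privileged), Ch (4.05, 3.50; 3.19 ppm N⁺(CH₃)₃
9H, quantification), TMSP (0.0 ppm, 9H). The default standard
concentration is 500 mM as reported for the assay the library mirrors;
note this is far above the solutes' tube concentrations, so spectra
acquired that way are quantifiable only where noise is small relative to
the solute peaks themselves (see the benchmark design below).

### Labelled glycine betaine

1,2-¹³C₂-GB appears as satellite doublets split by the one-bond ¹J(¹³C–H)
coupling (default 144 Hz → ±0.18 ppm at 400 MHz). The labelled pool is
estimated as **twice the upfield satellite** (3.09 ppm): the doublet is
symmetric, and the downfield satellite (3.45 ppm) collides with ectoine's
3.44 ppm resonance whenever ectoine is present. The unlabelled pool keeps
the central singlet, ectoine its quantification peak; components below 2%
of the largest are reported as zero (below that level the integral is
indistinguishable from neighbouring-line tails and baseline ripple). If
`J/(2·frequency) ≤ 2·window` the satellites are not resolvable from the
central peak and the routine fails with a diagnostic rather than returning
a meaningless ratio.

### Intracellular scaling

`c_cell = c_tube · V_sample / (n_cells · V_cell)`, exactly bilinear in
the numerator quantities and inverse-linear in the denominator ones. The
cell volume comes from the cylinder-plus-two-cones model

    V_cyl = π (w/2)² L,   V_2cones = 2·(π (w/2)² L / 3),   V = V_cyl + V_2cones

implemented verbatim from its printed form, so the total is always exactly
5/3 of the cylinder term (asserted as a regression guard). Note the cone
term uses the full length as cone height and is *added* to the cylinder —
a generous hull rather than a spindle whose cones replace the cylinder
ends; volumes are therefore upper-bound-flavoured approximations, and
"dead space" (oil bodies, granules) is not modelled. Salinity converts as
`% w/v × 10 / 58.44 g mol⁻¹`; 21% → 3.59 mol/l, 19% → 3.25 mol/l, while
5% gives 0.856 mol/l (sources quoting 0.85 have rounded).

## Synthetic spectra

Lines are Lorentzian with 1.5 Hz FWHM by default (typical solution-state
¹H linewidth); multiplets are first-order with binomial intensities
(second-order effects out of scope); a peak's integrated area is
`concentration × proton count`, making area linearity exact by
construction. Noise is additive Gaussian. The axis default is −0.5 to
10.5 ppm; benchmarks use 2¹⁷ points so that integration noise (∝ √grid
spacing) stays well below the recovery tolerances. The generator does
**not** simulate time-domain acquisition, phase/baseline artefacts,
chemical-shift drift, or vendor formats — passing round trips show the
analysis chain is self-consistent and correctly calibrated, not that it is
robust to pathologies the generator does not produce.

### Round-trip benchmark design

The 50-mixture recovery benchmark draws GB, Ect and Ch tube concentrations
uniformly from 0.04–0.12 mol/l with the standard at 0.06 mol/l, i.e. all
species of comparable magnitude, and adds noise with sd equal to 1% of the
maximum peak height. With a 500 mM standard next to millimolar solutes,
"1% of max height" noise would exceed a minor solute's entire integral and
no integration scheme could recover it; the benchmark therefore probes the
method in the regime where relative quantification is meaningful.
Acceptance thresholds: noise-free recovery within 2% always; noisy
recovery within 10% for ≥95% of solute values.

## CRF ion imaging

Pixels are classified by two thresholds: background `I ≤ t_low`, cytoplasm
`t_low < I ≤ t_high`, vacuole `I > t_high`. When thresholds are omitted
they are chosen by two-threshold between-class-variance maximisation
(3-class Otsu); manual thresholds reproduce a human operator's choice. I_B
is the equal-weight mean of four rectangular background regions, default
corner squares of 1/16 image width. The corrected signal is

    CRF_C = I_C,total − A_C · I_B,      CRF_norm = CRF_C / A_C

with I_C,total the **summed** cytoplasm intensity (interpreting it as a
mean would make the A_C multiplication dimensionally inconsistent with the
per-area normalisation). Vacuole pixels are excluded from the integral and
reported separately. CRF_C may legitimately be negative and is reported as
computed. Exact properties: adding a constant to every pixel leaves CRF_C
unchanged; scaling the image scales CRF_C and CRF_norm linearly; on a
noise-free synthetic image CRF_norm equals the cytoplasm−background level
difference exactly. CRF values are relative — no dye calibration to
absolute ion molarity is attempted.

The synthetic micrograph is an axis-aligned elliptical cell with a disk
vacuole strictly inside it, three flat strata plus Gaussian noise clipped
at zero. Real micrographs have shading, point-spread blur and
out-of-focus light that the generator does not emulate.

## Enzyme kinetics

`fit_mm` minimises Σ(v_i − V_max·S_i/(K_m+S_i))² with positivity bounds,
started from the Hanes–Woolf linearisation (S/v regressed on S). Fits are
unweighted by default (no error model is assumed; 1/v weighting is a
documented alternative left to the caller via pre-scaling). Standard
errors come from the Jacobian-based covariance. Degenerate designs fail
loudly: fewer than 3 distinct substrate levels, non-convergence, or a
fitted K_m above 100× the largest substrate concentration (saturation
unconstrained). The fit is exactly invariant to row permutation and
unit-consistent: rescaling substrate units rescales K_m alone.

Absorbance-based rates use the NAD(P)H molar absorptivity 6,220 M⁻¹cm⁻¹ at
340 nm and a 1 cm path by default; the initial slope is a least-squares
fit over the first fifth of the trace (≥3 points), and a trace trending
against the configured direction (decrease for NADH oxidation, increase
for NADP⁺ reduction) warns but still reports the magnitude.

Derived metrics are plain ratios (specificity constant V_max/K_m, residual
activity, osmolyte performance); a reference compared against itself is
exactly 100%. Reported values keep full precision; display rounding is
left to output formatting. The shipped published parameter table stores
printed (rounded) K_m/V_max, so specificity constants recomputed from it
can differ in the last digit from values computed on unrounded fits;
comparisons in tests use explicit tolerances, never display rounding.
Substrate for ICDH is total DL-isocitrate. Allosteric and
substrate-inhibition models are out of scope.

Parameter-recovery conditions: 8 substrate levels geometrically spaced
over 0.2–20×K_m, 3 replicates, 2% multiplicative rate noise, 200 seeds per
parameter pair — the acceptance bound is a median relative error below 5%
for both parameters at every published parameter pair.

## Statistics

Welch's t statistic uses the unequal-variance form with
Welch–Satterthwaite fractional degrees of freedom; identical entry points
exist for raw samples and for (mean, sd, n) summaries so published tables
can be re-tested. Regression reports OLS slope/intercept, R² as the
squared Pearson correlation, and the slope p from
t = r√((n−2)/(1−r²)). ANOVA is the standard between/within decomposition;
Tukey HSD uses the pooled within-group mean square and the studentized
range distribution with `q = |Δmean| / √(MSW/2·(1/n_i+1/n_j))`. All tail
probabilities come from scipy's numerically integrated distributions; the
test suite checks them to 10⁻⁶ against direct density integration
(scipy.integrate) and against statsmodels' independent Tukey
implementation, and calibrates Welch's type-I error at α = 0.05 to lie in
[0.04, 0.06] over 10,000 null simulations. All tests are two-sided.
Normality/variance gatekeepers (Shapiro–Wilk, Bartlett) are not
reimplemented; use scipy directly if needed. Degenerate inputs (n = 1
groups, zero within-group variance with distinct means, constant x) raise
rather than returning NaN.

The salinity-gradient demo regresses **per-salinity mean** concentrations
on NaCl molarity up to 3.25 mol/l (the extreme 21% point breaks the linear
regime and is excluded from the fit, though it is simulated and reported);
generating means at salinities without a published value are linearly
interpolated from their neighbours. Replicate-level scatter is off by
default so the demo is a clean round trip of the quantification chain.

## Pipeline and reproducibility

Run configs are YAML validated by pydantic models before any stage
executes; every generator takes an explicit seed and the run record echoes
the config, package version and all outputs, so seeded runs are
bit-identical. Output directories are never overwritten (a numeric suffix
is appended). Problem sizes in the shipped benchmarks (50 mixtures,
2¹⁷-point axes, 200 seeds × 16 parameter pairs, 10,000 null simulations)
were chosen to make the Monte-Carlo noise on each acceptance quantity
small relative to its tolerance while keeping a full run in the
tens-of-seconds range on a single core.

## Known limitations

- The spectral model is frequency-domain and first-order only; crowded or
  strongly coupled regions are not realistic.
- Identification requires every reference peak to match; heavily
  overlapped minor resonances can therefore suppress a genuinely present
  solute (it reports 0 rather than a biased value).
- The cell-volume model is a geometric approximation; intracellular
  molarities inherit its bias directly (volume enters linearly).
- Image segmentation assumes three separable intensity strata; it will
  fail loudly, not degrade gracefully, on images without them.
- The label-ratio routine assumes the upfield satellite region is clean;
  a solute panel with a resonance near (GB shift − J/2f) would need a
  different satellite choice.
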