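# Methods

## Scope and model

`mirdose` implements image-based internal dosimetry in the MIRD schema. The
measured quantity is the fraction of administered activity in each source
organ at each scan time, a(t) = C(t)·V/A_inj, from VOI mean concentration C
(Bq/mL), VOI volume V (mL) and administered activity A_inj. All times are
hours internally. Concentrations carry an explicit per-row flag stating
whether they were decay-corrected to injection time; when set, the
quantifier multiplies by e^(−λ_phys·t) to restore the physical activity —
there is no silent guessing.

For washout organs the curve is summarised by a single exponential
a₀·e^(−λ_eff·t). The time-integrated activity coefficient (TIAC) is the
closed-form integral τ = a₀/λ_eff (hours); the biologic clearance is
λ_bio = λ_eff − λ_phys and may be negative for organs accumulating tracer.
Physical half-lives are configuration constants: 67.71 min for ⁶⁸Ga
(λ_phys = 0.6142 h⁻¹, so an activity fraction bounded by 1 can never
integrate past 1/λ_phys = 1.628 h) and 6.647 d for ¹⁷⁷Lu.

## Fitting

Fits are nonlinear least squares on the untransformed activities
(`scipy.optimize.curve_fit`, log-linear start values). The default residual
weighting is *relative* (σ_i ∝ a(t_i)): quantitative PET concentration
errors scale with the signal, and with only four timepoints over ~1.6 h this
weighting is what keeps the recovered λ_eff unbiased enough that the median
relative recovery error stays within 5% at 5% multiplicative noise
(unweighted least squares lets the high-activity early point dominate and
degrades the slope to ~6%). `weighting="equal"` remains available.
Goodness of fit is R² computed unweighted on the activity scale. Degenerate
inputs (all-zero curves, fewer than two positive points) raise rather than
return nonsense; fitted λ_eff ≤ 0 (uptake phase) triggers an automatic,
logged fallback to the trapezoid rule.

## Trapezoid + physical-decay tail

For uptake-phase organs the TIAC is the trapezoid over [0, t_last] with an
assumed a(0) = 0 first point (no organ holds activity at injection), plus an
analytic tail a(t_last)/λ_phys that assumes physical decay only. The tail is
deliberately conservative: any real biologic clearance of the organ content
(gallbladder emptying within hours) would only shorten the effective
half-life, so the rule upper-bounds the true TIAC of an uptake organ. Two
numerical caveats are worth recording. First, the conservatism is *with
respect to the true kinetics of an uptake organ*, not with respect to the
mono-exponential fit of a washout curve: under the assumed zero start the
first trapezoid panel loses about a(t₁)·t₁/2 of area, which for fast
clearance (λ_eff ≳ 3 h⁻¹) exceeds the physical-tail margin, so
"trapezoid ≥ closed-form fit" does not hold in general. Second, the rule is
only as good as the sampling density inside the window; the property tests
use the study's four-point schedule for the uptake case.

## Red marrow, colon, bladder

*Red marrow.* Marrow cannot be outlined as one region, so three sample VOIs
(humeral head, femoral heads, lumbar L3–L4) provide normalized activity
concentrations per gram (unit tissue density, no cellularity correction —
the simplest defensible reading of an image-based marrow method). Each site
curve is fitted and integrated like any organ; the mean TIAC-per-gram is
scaled by the reference red marrow mass (1170 g, adult male). Fewer than
three usable sites is accepted with a warning.

*Colon.* The colon is measured as one region and its TIAC partitioned to
right colon, left colon and rectum proportionally to reference segment
masses (150/150/70 g by default, editable CSV). The partition conserves the
total exactly.

*Urinary bladder.* Content between voids follows
B(t) = Σᵢ fᵢ·(e^(−λᵢt_k) − e^(−λᵢt))·e^(−λ_phys·t) for t in the cycle
starting at the last void t_k — everything excreted since the void,
physically decayed — with urinary components (fᵢ, λᵢ) describing flow from
the body. B resets to zero every T_v hours. The TIAC is accumulated
cycle by cycle on a fixed grid (default step 0.002 h; halving the step
changes the result by < 0.1%) until the inflow is negligible. τ(T_v) is
increasing in T_v and bounded by the no-voiding integral
Σᵢ fᵢλᵢ/((λᵢ+λ_phys)·λ_phys). Because the acquisition's own voiding cycle is
what the images actually measured, the measured bladder TIAC is used
directly at that interval; other intervals use the model rescaled so it
reproduces the measurement at the acquisition interval. The default
components ((f, λ_bio) = (0.7, 0.6 h⁻¹)) describe a tracer with substantial
renal excretion and were chosen so the synthetic bladder TIAC at a 30-min
cycle lands near 8E-02 h, the order observed for renally excreted ⁶⁸Ga
peptides.

## Dose engine

Absorbed doses are the MIRD sums D_T = Σ_s τ_s·S(T←s), linear in every
TIAC. S-value kernels are explicit CSV inputs (mGy/(MBq·h), `#` metadata
lines carrying phantom id and units); the package never runs radiation
transport. Organ labels are matched case-insensitively through an editable
alias table; a source organ missing from the kernel is an error.

Self-dose-dominated organ doses transfer between phantom generations by the
inverse-mass law D′ = D·m_from/m_to (the caller decides applicability; the
rescaling is logged). w_R = 1 is assumed for all shipped radionuclides
(photons/electrons/positrons), so equivalent dose equals absorbed dose
numerically.

Effective dose: per-sex ED weights that sex's tissue doses; gonads resolve
to testes or ovaries; the colon tissue is the mean of its segments; the
pooled remainder is by default the arithmetic mean of the remainder-tissue
doses (a mass-weighted variant is selectable). The older scheme ships with
the historical *most-exposed-remainder* split: when a remainder tissue
(here typically the pancreas) receives the highest dose of all tissues,
half the remainder weight (0.025) applies to it and half to the mean of the
rest — this is what makes ED under the older convention exceed the newer
one for a pancreas-avid tracer, and the plain mean (pancreas weight 0.005)
cannot reproduce that behaviour. Tissues absent from a report are imputed
by policy (`total_body` default, `zero`, `nearest_organ`), and every
imputation is logged at WARNING. The reference-person ED averages male and
female tissue doses organ by organ before weighting; sex-specific tissues
use the sex that has them. Commercial codes implement additional remainder
bookkeeping that is not fully documented; reference-person EDs computed
here can therefore differ from theirs by a few percent, and no attempt is
made to force agreement.

## Synthetic data

The generator emulates a first-in-human ⁶⁸Ga dosimetry protocol: five
patients, 113 ± 21 MBq, four scans at 15/45/70/100 min, 30-min voiding
cycle. Ground-truth amplitudes are set so noiseless TIACs land near the
residence times published for a ⁶⁸Ga GRPR antagonist (pancreas 8.13E-02 h,
kidneys 2.14E-02 h, …) — fixture inputs that make the cohort look like the
study, not claims about it. Noise is multiplicative lognormal with unit
mean; CV defaults to 5%, motivated by the quantitative accuracy achievable
with a well-calibrated ⁶⁸Ga PET system (within ~6%). Concentrations are
emitted decay-corrected (as PET reconstructions are), so the uptake-phase
gallbladder rises monotonically across the window. One seed governs all
randomness; fixed seed gives byte-identical tables.

The toy S-kernel follows an inverse-mass self-dose law S(T←T) = c/m_T
(c = 450 mGy·g/(MBq·h), sized to give tens–hundreds of μGy/MBq for
abdominal organs under a ⁶⁸Ga-like emitter), random-but-deterministic
exponential-distance cross terms, wall doses from luminal contents, and
modest self-term boosts for hollow organs whose residence time includes the
content. What the generator does *not* emulate: image-domain effects
(partial volume, spill-over, reconstruction bias), inter-organ kinetic
correlation, patient anatomy variation, and real S-value anisotropy.
Passing tests therefore demonstrate the correctness of the analysis
pipeline, not the accuracy of any specific kernel or the fidelity of organ
segmentation.

## Problem sizes and numerics

Tests run the five-patient default cohort with two voiding intervals and
both weighting schemes; the parameter-recovery property uses 500 four-point
curves. Closed-form TIACs agree with adaptive quadrature to 1E-6 relative;
dose linearity and ED normalization hold to 1E-12; the bladder stepping is
validated against an independent per-cycle analytic sum to 0.1%. Ties and
degenerate cases: zero curves yield zero TIACs, zero total colon mass and
non-positive voiding intervals raise, and whole-body curves are rejected if
the normalized activity exceeds 1.1.

## Known limitations

- Mono-exponential kinetics only; multi-compartment models are out of scope.
- The marrow model ignores cellularity and fat fraction differences between
  sites.
- The bladder inflow components are configured or calibrated, not fitted
  from the sawtooth bladder curve itself (four timepoints cannot constrain
  them).
- Shipped phantom masses are nominal reference values intended for the toy
  kernel and the worked examples, not a certified phantom definition.
- The therapeutic extrapolation keeps λ_bio fixed across radionuclides; for
  long-lived therapeutic nuclides the extrapolated TIACs inherit all of the
  diagnostic window's uncertainty about slow kinetics.
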