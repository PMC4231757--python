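# Methods

This note records the models behind `tethermech`, the estimator and
numerical choices that were genuinely open, and what the synthetic-data
generator does and does not emulate. Units are nm, pN and seconds
throughout; thermal energy defaults to k_B T = 4.1 pN·nm (room
temperature) and times are converted to minutes only at reporting
boundaries.

## Polymer mechanics

The tether is treated at two levels of approximation, matching how the
two assays are analysed in practice.

**Excursion relation.** TPM analysis models the DNA as a Gaussian chain
with mean-square end-to-end distance 2 L_C ξ and the bead as a hard
sphere excluded by the coverslip. The in-plane RMS of the bead center is

R_RMS² = (L_C ξ/3) · (2 + 4 N_R/(√π erf N_R)),  N_R = R/√(L_C ξ/3).

The N_R → 0 limit is handled analytically (the bracket tends to 4, two
in-plane axes of variance 2 L_C ξ/3 each) rather than as 0/0. The
inversion ξ(R_RMS) uses bracketed root-finding (Brent) on
ξ ∈ [0.1, 1000] nm to 10⁻⁴ nm; the map is strictly monotone so
convergence is guaranteed, and an RMS outside the reachable range raises
an error carrying the reachable bounds. A freely-jointed-chain
Monte-Carlo with Kuhn length 2ξ, a hemispheric bead vector and surface
rejection reproduces the formula to ~2% at the reference geometry
(5092 bp, 1 μm bead); the test suite asserts 5%.

**Force-extension.** The Marko–Siggia interpolation is used as printed
above; it is accurate to a few percent against the exact worm-like chain,
which is far below the force noise considered here. Its numeric inverse
(extension at force) is Brent bisection on [0, L_C), used only by the
generator. Extensible-WLC corrections (relevant above ~10 pN) are out of
scope.

Contour length from base pairs uses 0.34 nm/bp (canonical B-DNA rise),
configurable.

## TPM pipeline choices

* **Drift filter**: subtraction of a centered 20 s moving average per
  axis. "High-pass" is realized this way because it is transparent,
  parameter-light, and exactly removes constants and (in the interior)
  linear ramps; the window must exceed the 4 s RMS window so genuine
  tether motion (correlation time ~0.1 s) is untouched (<3% effect,
  tested).
* **Windowed RMS**: dense (stride 1 frame) 4 s windows,
  rms = √(mean((x−x̄)²+(y−ȳ)²)). By default the means are per-window,
  so any residual drift does not inflate the kinetics observable;
  `center="global"` is available.
* **Persistence estimation** uses globally-centered windows and the
  quadratic mean of the windowed values. Reason: per-window centering
  absorbs ≈2 τ_c/T_w of the variance (≈2.5% of a stationary RMS at
  τ_c = 0.1 s, T_w = 4 s), and the excursion relation amplifies RMS
  errors ~3x into ξ; the globally-centered quadratic mean is unbiased
  for a stationary, drift-filtered record. The estimate requires
  stationarity (first/second-half mean RMS within 10%) and propagates
  the RMS standard error — effective sample size = number of
  non-overlapping windows — through the local derivative of the
  excursion relation.
* **Circularity** is √(λ_minor/λ_major) from the 2×2 position covariance
  (rotation-invariant); a bead fails when 1 − circularity exceeds 10%.
  A fixed-axes σ_min/σ_max variant exists behind a flag. A 20% axis
  anisotropy gives circularity ≈ 0.83 and fails cleanly; zero-variance
  records fail with a diagnostic instead of raising.
* **Stuck-bead events** are persistent step drops: the median RMS over
  the 10 s before and after each sample must differ by ≥50% of the
  pre-level. Minutes-long exponential collapse changes the level by only
  ~2% per 10 s and is never flagged; flagged spans can be masked to NaN.

## Condensation kinetics

Collapse is quantified on the smoothed (60 s centered running mean,
shrunken endpoints) ensemble average of release-aligned windowed-RMS
traces, fitted by R(t) = R_∞ + (R₀−R_∞) e^(−t/τ) with τ reported in
minutes; a zero-plateau variant is selectable. Fitting the average (and
not averaging per-trace fits) matches how ensemble traces are normally
presented and keeps low-amplitude traces from destabilizing the fit;
per-trace fitting remains possible by passing a single-member ensemble.

The fit is parametrized on (amplitude, plateau, τ) so the decay amplitude
carries its own standard error. Because smoothed RMS residuals are
strongly autocorrelated, white-noise standard errors are inflated by the
AR(1) effective-sample-size factor √((1+ρ)/(1−ρ)) with ρ the lag-1
residual autocorrelation; without this, flat control traces acquire
"significant" percent-level decays. A fit is flagged unidentifiable when
τ's relative standard error exceeds 50%, τ exceeds 5× the record length,
the uncertainties cannot be estimated, or the amplitude is within 2
standard errors of zero. Unstretched control ensembles are then never
assigned a confident time constant (0/50 seeded ensembles in testing),
while genuine collapse ensembles always are.

Late-time state is summarized by a Gaussian fit (sample mean/SD, the
MLE) to RMS samples pooled across a condition's trajectories after
15 min, and by the compaction ratio R_∞/R₀. Persistence length versus
protein concentration is interpolated by a saturating exponential
ξ(c) = ξ_∞ − (ξ_∞−ξ₀)e^(−c/c₀) per condition; this is descriptive
interpolation only, not a binding model, and flat data flag c₀ as
unidentifiable.

## Force-extension fitting

Residuals are vertical (force): the piezo sets the extension and force is
the noisy reading. Fits are unweighted by default (homoscedastic noise),
with optional per-point weights. The fixed-L_C model is linear in the
inverse stiffness 1/ξ, so confidence intervals are built in that
parametrization and mapped back; at 0.2 pN noise on a sub-pN sweep the
relative error is ~14% and a symmetric interval in ξ under-covers
(~83% observed vs 95% nominal) while the 1/ξ interval holds nominal
coverage. The free-L_C objective has a spurious minimum with L_C pinned
at max(z); the optimizer is multi-started from {1.05, 1.2, 1.5}·max(z),
bounded below by 1.001·max(z), and boundary-pinned solutions are
flagged. Model comparison is the nested F-test on residual sums of
squares (1 extra parameter, α = 0.05 default) with AIC reported
alongside; measured type-I rate is ≈6% and power against a 30% contour
shrinkage ≈100% at 0.1 pN noise. Exact (zero-residual) fit pairs are
returned as a degenerate comparison preferring the simpler model.

## Synthetic data

Each in-plane axis of the simulated bead is a stationary AR(1)
(discretized Ornstein–Uhlenbeck) process with correlation time τ_c
(default 0.1 s, typical for a micron bead on a ~1.7 μm tether) and
instantaneous standard deviation R_RMS(t)/√2, with R_RMS from the
excursion relation. τ_c affects the effective number of independent
samples, not the stationary RMS. Condensation is an exponential
relaxation of R_RMS(t) to plateau_fraction·R_RMS — the observable the
kinetics analysis fits, deliberately not a mechanistic bridging model.
Stage drift (linear ramp or random walk), discrete stuck events
(amplitude drops to a residual fraction), per-axis anisotropy (the
multiple-tether signature) and additive white tracking noise are
superimposed on request. Default acquisition matches the experiments:
25 Hz, 4 s RMS windows, 30 min collapse records, 8 trajectories per
ensemble, 20 nm tracking noise.

Force-extension sweeps are the force law evaluated on 30 extension
fractions spanning 0.1–0.85 of the current contour length plus Gaussian
force noise; readings near zero tension may go negative, as additive
detector noise implies — clipping at zero would truncate the noise
distribution and measurably bias fits and the F-test. A shrink schedule
emits one timestamped sweep per scheduled contour length, and down–up
sweep ordering is encoded in per-point phase labels.

What the generator does **not** emulate: the non-Gaussian statistics of
real bead excursions near the wall (the excursion relation is itself a
Gaussian-chain approximation, so generator and analysis share this
assumption by construction — passing tests show self-consistency, not
wall-effect accuracy), camera exposure blur, hydrodynamic coupling to
the surface, and mechanistic nucleation/zipping kinetics of bridging
proteins. Parameter-recovery results on synthetic data therefore bound
estimator error under the model's own assumptions, not instrument
systematics.

The image-plane stage renders a symmetric 2-D Gaussian spot (real
bright-field bead images have ring structure; thresholded centroiding is
insensitive to this at the tested SNRs) at 100 nm/px default, and tracks
the intensity-weighted centroid of pixels above 50% of the frame
maximum, with the threshold subtracted from the weights to suppress
sub-pixel mask bias. Frames with no dominant spot are flagged missing
rather than guessed.

## Problem sizes and determinism

Validation workloads are sized for quick, repeatable runs: 10-minute
records for single-tether persistence recovery, 30-minute 8-trajectory
ensembles for kinetics (50 seeded replicates when measuring medians), 200
replicates for fit-calibration checks, and 10⁵ accepted configurations
for the Monte-Carlo chain check. Every stochastic component takes an
explicit integer seed, child seeds are derived through NumPy's
`SeedSequence`, and identical configurations produce identical outputs,
including the on-disk fixture suite.

## Known limitations

* The excursion relation assumes a Gaussian chain; for tethers much
  shorter than ~10 persistence lengths the approximation degrades.
* The drift filter attenuates true tether motion slower than the 20 s
  window; pathological tethers with seconds-long correlation times would
  need a longer window.
* Windowed RMS with per-window centering under-measures a stationary
  amplitude by ≈2 τ_c/T_w (kept as the kinetics observable for its drift
  robustness; the persistence estimator avoids it as described above).
* Single-sweep persistence estimates at 0.2 pN noise on a sub-pN sweep
  carry ~7 nm standard errors (the Cramér–Rao bound for that design);
  precision comparable to published multi-molecule values requires
  averaging many sweeps.
* Stuck-event detection assumes drops are large (≥50%) and persistent
  (≥10 s); brief or shallow sticking is left to the circularity and
  stationarity screens.
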