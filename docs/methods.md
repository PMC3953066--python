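# Methods

## The relaxation model

Transverse relaxation of a heterogeneous seed sample is modelled as a
discrete sum of exponentials,

    I(t) = Σᵢ Aᵢ exp(−t / T2ᵢ),   Aᵢ ≥ 0, T2ᵢ > 0,

one term per proton pool. Amplitudes are carried as percentages of the
extrapolated t→0 signal of the acquisition (a full component set sums to
100); absolute instrument units enter only in the water-partition step
through the distilled-water calibration. The t→0 value is always an
extrapolation: simulated and real time grids start at one dwell (FID) or
one echo (CPMG) interval, never at zero.

Assumptions, and what is deliberately out of scope:

* Each pool relaxes mono-exponentially. No diffusion attenuation,
  J-modulation, or T1 weighting is modelled (the long recycle delay of the
  emulated acquisitions makes T1 saturation negligible).
* The solid phase is modelled as an exponential with T2 ≈ 0.016 ms. Rigid
  solids often show Gaussian (Abragam-type) free-induction lineshapes; an
  exponential was kept because the analysis this package reproduces treats
  all components as exponential. If real FID data show systematic early-time
  residuals, a Gaussian solid term would be the first extension to try.
* Noise is additive, Gaussian, homoscedastic per point.

## Acquisitions and the synthetic generator

Defaults mirror a 20 MHz benchtop time-domain spectrometer: FID with
0.4 µs dwell and 150 points (window 0.0004–0.06 ms), CPMG with 0.2 ms echo
time and 8000 echoes (0.2–1600 ms), 16 scans. The FID is the only window
onto the solid phase (fully relaxed by the first CPMG echo); the CPMG train
carries the mobile pools. All fitting and inversion therefore pools both
curves with a single shared amplitude scale — this joint treatment is what
makes every component identifiable at once.

The generator produces decays from reference component sets (wild type and
the mucilage mutants *mum2-11* and *myb5-1*, dry and 24 h-imbibed, plus
wild type 1 h-imbibed without soluble mucilage) or from user-supplied sets.
Printed reference amplitudes sum only approximately to 100 per row; sets
are renormalized to exactly 100 on construction.

Default noise is sd = 0.2 amplitude-% per point. At this level the fitted
amplitude standard errors of the water components are of order 0.1–1
amplitude-points over the default acquisition, i.e. at or below the few-
percent precision reported for instrument time courses of this kind; it is
the generator's single noise knob and deliberately conservative.

An imbibition time course interpolates per-component amplitudes between a
start and end set, Aᵢ(t) = Aᵢ,end + (Aᵢ,start − Aᵢ,end)·e^(−t/τᵢ) (hours),
renormalized to 100, with T2 interpolated with the same mixing fraction on
a log scale; a compartment absent from one state is padded in with
amplitude 0.

What the generator does **not** emulate: scan-to-scan drift, temperature
effects, B1 inhomogeneity, receiver dead time, heteroscedastic or
correlated noise, Gaussian solid lineshapes, or distributions of T2 within
a pool. Passing tests therefore demonstrate the correctness of the
analysis chain under the stated model, not robustness to every instrument
artifact.

## Discrete fitting

`MultiExponentialModel.fit(k)` minimizes the pooled residual sum of squares
by variable projection: the outer nonlinear search (scipy
`least_squares`, trust-region reflective, tolerances 1e-14) runs over
log T2 only — which enforces T2 > 0 — and for each candidate T2 set the
amplitudes are the exact non-negative least-squares solution. This is
deterministic, never needs amplitude starting values, and recovers
noiseless generator parameters to optimizer precision (relative error
~1e-9, far inside the 0.5 % the package's acceptance tests require).

Starting T2 values come from a log-grid NNLS decomposition: the decay is
regressed onto a 64-point log-spaced exponential dictionary spanning
0.5·t_min to 3·t_max; contiguous runs of non-zero weight form clusters and
the k largest-area clusters (area-weighted geometric-mean T2) seed the
search. If the dictionary fit explains less than half the signal energy
(uncentered R² < 0.5 — pure noise), or yields fewer than k clusters, the
start falls back to geometric spacing over the sampled window and the fit
is flagged.

Standard errors are Gauss–Newton: the full (A, T2) Jacobian at the optimum
gives cov = s²(JᵀJ)⁻¹ with s² = RSS/(n − 2k); amplitude errors are reported
on the normalized (percent) scale.

Model selection (`fit_select`) grows k from 1 and accepts k+1 over k by the
extra-sum-of-squares F-test, F = ((RSS_k − RSS_{k+1})/2)/(RSS_{k+1}/dof),
at α = 0.01 by default (BIC available). Two numerical guards: a fit whose
residuals are at numerical zero (below 1e-7 of the signal scale, relative)
ends the search — further components could only chase rounding error — and
a zero-RSS denominator falls back to comparing RSS directly. On noiseless
dry-seed generators this selects k = 4; on noisy imbibed generators k = 5.

Post-fit diagnostics never silently alter the result: components whose T2
ratio is below 1.5 *and* whose ±1 SE intervals overlap are reported as
merge candidates; fitted T2 outside the sampled time window (below half
the first sample or above a third of the last) raises an identifiability
flag. Tie-breaking philosophy throughout: prefer fewer, distinguishable
components.

## T2-spectrum inversion

The model-free counterpart estimates a non-negative density f(ln T2) on a
log grid (128 points, 1e-3–1e4 ms — the full range of seed components with
margin) by minimizing ‖Kf − I‖² + λR(f). The kernel folds trapezoid
quadrature weights in ln T2 into its columns, so f is a density per unit
ln T2 and peak areas integrate to component amplitudes; FID and CPMG rows
are stacked exactly as in the discrete fit.

* **MEM** (default): R(f) = Σ w f log(f/m) against a uniform prior m
  carrying the t→0 amplitude; solved over u = log f with L-BFGS-B,
  positivity automatic.
* **Tikhonov**: R(f) = ‖f‖², solved exactly by NNLS on an augmented
  system.

λ is chosen by the discrepancy principle — the largest λ keeping
χ² = ‖Kf − I‖² at n·sd², with sd either supplied or estimated from first
differences of the curve tail — via bisection on log λ with warm-started
solves. Noiseless data fall back to a floor of λ = 1e-6 (of the rescaled
problem): small enough to resolve adjacent pools at T2 ratio ~4, large
enough that a component lying between grid points is not split into two
spikes.

Long echo trains are compressed before inversion: samples are averaged
into at most 400 log-spaced time bins and each bin row weighted by √n.
For a decay smooth across a bin this is statistically equivalent to the
raw problem (the bin mean has variance sd²/n) and makes the inversion
orders of magnitude faster with no loss of resolution; the discrepancy
target adjusts automatically to the number of bins.

Peak extraction segments the density at deep local minima (below 50 % of
the smaller adjacent apex; shallower valleys leave the maxima in one
region, annotated as partially resolved). Each region becomes a component
with area-integrated amplitude and area-weighted geometric-mean T2;
regions under 0.5 % of the total area are discarded as ripple. A flat
spectrum yields no components (the function returns `None` and flags the
spectrum). Each single-maximum peak is additionally compared against the
inversion's point-spread function — the width a lone T2 of the same area
would show under the identical kernel, λ and method — and annotated as
possibly merged when broader than 1.3× that reference. This is how a
generator pair at T2 ratio 1.2, which no inversion of these data can
split, comes back as one component *with a merge note*.

## Compartment analysis

Attribution is ordinal by T2 rank: solid, exchangeable, intracellular
water + oil, adherent-mucilage water + oil, and (imbibed, fifth component)
external water. Sanity windows (solid T2 < 0.1 ms; a fifth component only
in imbibed samples) produce warnings, never silent relabelling; counts
outside 3–6 are errors.

Dry-seed oil content is A(3)+A(4): in a dry seed (~8 % residual water, all
bound) the two long-T2 components are pure oil.

Water partitioning compares an imbibed acquisition against a dry reference
of the same seed mass. Solids and oil gain no protons on imbibition, so
their absolute signal is conserved between the two acquisitions; since the
oil signal is itself carried over from the dry seed, the scale anchor
reduces algebraically to conservation of the solid-phase signal,
S_imb·A1_imb = S_dry·A1_dry. The dry oil signal is split between imbibed
components 3 and 4 in the dry A3:A4 ratio. Water in component i is then
(absolute Aᵢ − allocated oilᵢ)/water_signal_per_mg, expressed as % of
total sample mass; component 1 carries no water, component 2 counts in
full (in both states — the exchangeable pool grows on imbibition and its
full amplitude is water-exchangeable signal). Computed water below zero
(over-allocated oil) is floored at 0 with a warning, matching the
convention of printing 0 for dry-seed oil components. When a gravimetric
(oven-drying) water content is recorded, the NMR total is checked against
it and the difference logged.

The share of water held outside the seed tissues is reported as
`external_fraction`. Which compartments count as "outside" is genuinely
ambiguous — published statements of roughly 40 % external water for the
wild type are not exactly derivable from any single ratio of the
tabulated water columns — so the numerator is configurable and defaults to
adherent mucilage + external water over all water.

Kinetics: each labelled component's amplitude time course is fitted with
the mono-exponential approach to plateau A(t) = A∞ + (A₀ − A∞)e^(−t/τ)
(τ in hours, log-parameterized for positivity); the initial transfer rate
is (A∞ − A₀)/τ. A flat series (range below 1e-9 relative) reports rate 0
with no τ. No functional form for these kinetics is established in the
literature this emulates; mono-exponential is the minimal saturating
model.

The `synthetic_seed_sample` builder constructs dry/imbibed pairs from
first principles (seed mass, bound-water mass, oil fraction, added water
per compartment) with exact bookkeeping, which is how the mass-balance,
oil-conservation and buoyancy-ordering properties are verified to 1 %.

## Problem sizes and runtime

The test suite and the acceptance script use the default acquisition sizes
(150 FID + 8000 CPMG points, 8150 pooled observations per fit), 20 noise
realizations for the component-number selection check, and 200 Monte-Carlo
replicates for the amplitude-precision check; the full suite runs in well
under a minute on one CPU. These sizes are the package's chosen study
conditions, matching the emulated instrument settings.

## Known limitations

* Printed per-sample water percentages of the reference tables are not
  reproduced exactly: they require unpublished per-sample masses and the
  instrument's distilled-water calibration. The package reproduces the
  *procedure* and verifies it on bookkept synthetic seeds instead.
* The MEM objective here (entropy against a uniform prior, discrepancy-
  principle λ) is a documented, standard variant; the historical
  implementation it stands in for did not publish its exact stopping rule.
* Component labels are positional; pathological samples whose pools
  reorder in T2 would need manual relabelling.
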