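# Methods

All concentrations are nM and times are seconds throughout the library;
any unit conversion belongs at the I/O boundary. Signals are arbitrary
units (a.u.).

## Two-species equilibrium with ligand depletion

For receptor R (total Rₜ), ligand L (total Lₜ) and dissociation
constant K_D, the complex concentration is the smaller root of

    C² − (Rₜ + Lₜ + K_D)·C + Rₜ·Lₜ = 0,

evaluated in the cancellation-free form 2RₜLₜ/(b + √(b² − 4RₜLₜ)),
b = Rₜ + Lₜ + K_D. The smaller root is always the physical one: the
larger root exceeds min(Rₜ, Lₜ), which mass balance forbids. The
implementation asserts 0 ≤ C ≤ min(Rₜ, Lₜ) and is cross-checked in the
tests against a bracketed iterative mass-balance solver to 1e-9
relative on 1000 random systems, against the stoichiometric limit
(K_D → 0) and against the weak-binding limit C → RₜLₜ/K_D.

## One-site binding fits (two-stage depletion correction)

Stage 1 fits the raw signal against *added* ligand,
y = C + R·[L]ₜ/(K_D + [L]ₜ), by unweighted nonlinear least squares
(lmfit/Levenberg–Marquardt; initialization C = min y,
R = max y − min y, K_D = ligand at half-range). Stage 2 converts each
point to fractional saturation F = (y − C)/R, computes bound = F·[S]ₜ
and [L]_free = [L]ₜ − bound, and refits F = [L]_free/(K_D + [L]_free)
with the amplitude fixed at 1.0. The stage-2 K_D is the reported
constant.

Because stage 1 itself is biased by depletion, the cycle is run twice
(the second pass refits against the free-ligand axis of the first);
an option iterates to a relative tolerance instead. On noiseless data
at the study design the estimate moves < 0.1% between the first and
second pass; later passes show a small damped oscillation before
settling, which is why the default reports after exactly two passes.

Design notes:

* F is clamped to [0, 1.05] with out-of-range points flagged; free
  ligand implied negative (beyond numerical noise) is an error in the
  standalone operation, because it means the (R, C) mapping is
  inconsistent with the mass balance.
* **Heavy depletion.** When [S]ₜ is comparable to or larger than K_D
  (e.g. 100 nM substrate, K_D = 10 nM), the hyperbola-in-added-ligand
  stage cannot represent the data; its (R, C) estimates imply
  bound > added at low points, and the iteration oscillates instead of
  converging. `OneSiteBindingModel.fit(method="auto")` detects the
  inconsistency and falls back to fitting the exact mass-balance model
  y = C + R·C_bound([S]ₜ, [L]ₜ, K_D)/[S]ₜ directly, after which the
  normalization is self-consistent and the fractional refit recovers
  the true K_D. The empirical two-stage procedure remains the default
  path whenever it is self-consistent, which includes all the study
  designs the generators emulate.
* **Uncertainty.** The reported K_D standard error is taken from the
  three-parameter raw-stage fit on the converged ligand axis. The
  amplitude-fixed fractional fit conditions on R and C and understates
  the seed-to-seed scatter by a factor of ~3.5; the raw-stage error
  matches the empirical standard deviation across simulated replicate
  experiments within ~10% (checked by a calibration test at 500
  seeds).
* Replicates are averaged point-wise before fitting, carrying the SD,
  matching how triplicate titrations are reduced in practice.
* Bound ligand per point is computed from the fitted F times [S]ₜ
  (empirical normalization), not re-solved from K_D.

FRET reductions are the identities E_dq = 1 − I_DA/I_D and the
acceptor/donor ratio I₆₇₀/I₅₇₀. Anisotropy-derived inputs are accepted
as already-converted fraction-bound or raw signal; no photophysical
conversion is attempted.

## Competition fits and the exact IC₅₀ → K_i conversion

Displacement data are fit to
y = Y_min + (Y_max − Y_min)/(1 + 10^(x − log₁₀IC₅₀)), x = log₁₀ of the
total competitor concentration in nM, with the Hill slope fixed at 1
(no option to float it). A zero-competitor point cannot sit on the log
axis: it anchors Y_max (fixed at the mean zero-point signal) and is
excluded from the regression; without a zero point Y_max floats. The
curve is then normalized to the fraction of complex remaining,
F = (y − Y_min)/(Y_max − Y_min); the normalization is affine, so a
constrained refit leaves the IC₅₀ unchanged. A monotone-increasing
signal raises an orientation error rather than fitting a mirrored
curve.

The inhibition constant uses the exact correction

    K_i = IC₅₀ / [1 + Lₜ(y₀+2)/(2·K_D·(y₀+1)) + y₀] − K_D·y₀/(y₀+2),

with y₀ = C/(Lₜ − C) from the two-species quadratic. Its standard
error is propagated from the IC₅₀ standard error by the delta method
(the map is affine, so the error divides by the same denominator).
In the y₀ → 0 limit the expression reduces to the Cheng–Prusoff form
IC₅₀/(1 + Lₜ/K_D) (verified to 0.1%).

**Species assignment.** Two conventions exist for which species plays
Lₜ, and they are not equivalent:

* *Labeled-ligand (tracer) assignment* — Lₜ = total labeled ligand of
  the pre-assembled complex, y₀ = that tracer's initial bound/free
  ratio. Under this assignment the formula inverts the exact
  three-species competitive equilibrium to machine precision: applying
  it to the true half-displacement concentration returns the true K_i
  (verified to ~1e-14 relative over random systems). Use
  `KiContext.from_labeled_ligand` for this; all simulation round trips
  in the test suite use it.
* *Target-species assignment* — Lₜ = total concentration of the
  species the competitor binds (the tracer's binding partner), y₀ =
  that species' bound/free ratio. This convention appears in published
  worked examples in this assay family (e.g. IC₅₀ = 308 nM with
  Lₜ = 200 nM, 20 nM labeled partner and K_D = 120 nM giving
  K_i = 111 nM) and is reproduced by the plain `KiContext`
  constructor. It is *not* the exact inversion of the ternary
  equilibrium: for the example above the exact inversion of
  IC₅₀ = 308 nM would give ≈ 62 nM, and the true half-displacement
  point for K_i = 111 nM lies at ≈ 439 nM. Curiously the two
  assignments share almost the same denominator; they differ mainly in
  the subtracted K_D·y₀/(y₀+2) term.

The package computes whichever convention the supplied context
encodes; choose deliberately and report the choice.

**Accuracy of the fitted IC₅₀.** Even with the exact assignment, the
pipeline's residual error comes from the unit-Hill logistic fit: when
the shared binding species is present at a concentration comparable to
the IC₅₀, competitor depletion flattens and skews the displacement
curve in log-total space, and the fitted midpoint can deviate
substantially from the true half-displacement point (this is a
property of the estimator, not of the correction formula). Over random
systems with all concentrations and constants log-uniform in
10–1000 nM and grids spanning 0.01–100× the transition, the median
K_i recovery error is ~2.5%, but the upper tail is large in
strong-depletion corners — titrations should keep the shared species
well below the expected IC₅₀ when that is experimentally feasible.

## Single-turnover processivity analysis

With a dideoxy-terminated trap enforcing one binding event per primer
(a property of the experiment, assumed rather than checked), the band
ladder B_j (concentration at insertion position j; j = 0 is the
unextended primer) yields

    P_i = Σ_{j≥i} B_j / Σ_{j≥i−1} B_j   over extended products j ≥ 1,

for i from 2 up to the largest observed position: of the molecules
that completed insertion i−1, the fraction that went on to insert
nucleotide i. This is the unique definition consistent with the
survival product y(i) = P₃·…·P_i (y(2) = 1 after normalizing the
TLS-complex population P₂ to 1). P₂ is reportable whenever any product
is extended, even if nothing ran past position 1 (then P₂ = 0).

* **Noise floor.** Steps whose denominator falls below 1% (default) of
  the total extended product are truncated rather than reported —
  ratios of trace bands are meaningless.
* **Pre-incubation background.** The background table (products formed
  before the reaction is started) is subtracted band-wise per
  position; only extension products (j ≥ 1) are subtracted — the
  pre-incubation lane's unextended-primer band is not a product.
  Negative differences are clamped to zero, counted, logged and
  surfaced in reports.
* **Amplitude.** The total extended fraction vs time is fit to a flat
  line over points with t > 10 s (default); a zero-slope least-squares
  constant is the mean, reported with the sample SD. Fold stimulation
  between conditions is the amplitude ratio with relative SDs combined
  in quadrature.
* **Holoenzyme survival.** For exchange titrations the readout is
  full-length (run-off) product over all extension products; feeding
  those fractions into the dose-response/K_i machinery closes the
  pipeline.
* **Processivity extrapolation.** n = ln(threshold)/ln(P) with
  threshold 0.010 by default, reported raw and rounded to two
  significant figures (so P = 0.999 reports 4600). The kinetic
  partition P = k_pol/(k_pol + k_off) converts a plateau P and an
  independently known k_pol into k_off; the identity is enforced to
  1e-12 on construction.
* P_i is evaluated at a designated time point (default: the last),
  i.e. at the single-turnover plateau rather than per time point.

## Synthetic data generators

Each generator is seeded (`numpy.random.default_rng`); identical
(seed, config) pairs are byte-identical through file round trips.
Defaults emulate the assay family the package targets:

| generator | defaults |
|---|---|
| titration | substrate 20 nM; 12 ligand levels log-spaced over 0.1–10× K_D; K_D 120 nM; R 1.0, C 0.05; 3 replicates |
| competition | shared species 200 nM, labeled partner 20 nM, K_D 120 nM, K_i 111 nM; competitor 0 plus 5–5000 nM log-spaced; signal C 0.2, R 0.8 |
| ladder | primer 10 nM; 1e5 molecules; P_i = {0.215, 0.30, 0.45, 0.30, 0.15} for i = 2..6; amplitude 0.40 approached as A(1 − e^(−0.6t)); times 2.5–60 s; misinsertion background 2%/0.5% of primer at positions 1/2 only |
| exchange | shared complex 10 nM, labeled polymerase 50 nM, complex K_D 7.1 nM, K_i 31.7 nM; run-off position 25; extended fraction 0.8 |

Noise models: additive Gaussian on fluorescence-type signals, default
SD 2% of the dynamic range, drawn per replicate and averaged
point-wise as an experimenter would; binomial engagement plus
multinomial band counts on ladders. `noise="none"` emits exact
expected values for round-trip tests. Backgrounds are added
deterministically (and subtracted exactly by the analysis), so
counting noise lives entirely in the reaction bands.

What the generators do *not* emulate — and hence what passing tests do
not establish about real data: spectral bleed-through and inner-filter
effects, anisotropy photophysics, gel smearing and lane-registration
error, correlated (non-Gaussian) replicate structure, pipetting error
in the concentration grids, and any kinetic (pre-steady-state)
structure beyond the single-exponential approach to the single-turnover
plateau.

## Numerical choices

* Quadratic root in the cancellation-free form; ternary equilibrium by
  monotone bracketing (brentq) of the free-receptor mass balance on
  [0, Rₜ] at near-machine tolerance — equivalent to the closed-form
  cubic but robust across 10 orders of magnitude of inputs.
* Fit initializations as above; K_D bounded below by 1e-12 nM to keep
  the optimizer off the boundary.
* Flat curves (range indistinguishable from zero at 1e-10 relative)
  raise a degenerate-fit error rather than returning noise.
* Ties in half-range initialization resolve to the first closest
  point; results do not depend on this beyond the optimizer's start.
* Survival curves validate non-increase to 1e-12; the 2-significant-
  figure rounding uses round-half-even on the scaled mantissa.

## Known limitations

* The dose-response stage assumes a unit Hill slope by design; real
  curves with cooperativity or partial competition are out of scope.
* The IC₅₀ estimator's depletion bias (above) is the dominant error
  source in K_i round trips; the conversion formula itself is exact
  under the tracer assignment.
* Anisotropy inputs are taken as provided; no intensity-weighted
  fraction-bound conversion is attempted.
* Gel image processing (densitometry, molecular-weight calibration) is
  upstream of this package; inputs are already-quantified band
  concentrations.
* Kinetic (time-resolved) association/dissociation modeling and
  multi-site binding are out of scope.
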