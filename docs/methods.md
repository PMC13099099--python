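# Methods

## The generative model

One analysed mount ("run") of a powdered carbonate mixture with weight
fractions π = (π₁, π₂, π₃), Σπ = 1, produces primary-peak heights

    I_l ~ Normal(λ_l, κ λ_l),   λ_l = Λ · k_l π_l / Σᵢ kᵢ πᵢ,   l = 1, 2, 3,

with the aragonite RIR pinned at k₁ = 1. Λ (counts) is the expected summed
peak intensity of that mount; it varies run to run with mount mass, packing
and orientation, so every run gets its own Λ_j. κ (counts) sets the
heteroskedastic noise: variance proportional to expected height, the usual
behaviour of counting statistics plus preparation effects. The model uses
peak heights, not integrated areas; any constant of proportionality between
height and integrated intensity is absorbed into the RIRs. Only the three
dominant peaks are quantified; the Aragonite‑2 shoulder and the halite
internal standard are carried as metadata (halite is used solely for 2θ
alignment during raw-scan extraction).

Minerals truly absent from a mixture (π_l = 0) contribute no likelihood
term — the stated variance κλ degenerates at λ = 0. A recorded height of 0
for a mineral with π_l > 0 is an observation; an explicit NA/absent flag
excludes the term. Both conventions are supported because recording practice
varies between laboratories.

## Calibration (component 1)

Given mixtures of known composition, the posterior over (k₂, k₃, κ, Λ₁…Λ_M)
is sampled by an adaptive random-walk Metropolis-within-Gibbs scheme,
vectorised across chains: log-scale walks for Λ_j and κ (with Jacobian
correction), natural-scale walks for k₂ and k₃, proposal scales adapted
toward 44% acceptance during burn-in only. Each sweep updates all Λ_j
jointly (they are conditionally independent given the globals). Ten percent
of Λ proposals are independence draws centred on the run's observed total
height, with full Metropolis–Hastings correction; these guarantee the
sampler can re-anchor Λ at the data scale from anywhere in the support.

Defaults: 4 chains, 500,000 total iterations (summed over chains), 50%
burn-in, thinning 10, mandatory seed. Point estimates are posterior means;
the (k₂, k₃) posterior covariance feeds the calibration-error term
downstream.

### Priors, and two load-bearing choices

* k₂, k₃ ~ Uniform(0.01, 100) — deliberately diffuse.
* Λ_j — **flat on the positive axis** (default). The BUGS-style vague
  Gamma(0.001, 0.001) prior is available as `lambda_prior="gamma"`, but its
  density spike at zero is designed for precisions, not mean-scale
  parameters: combined with a free noise scale it rewards collapsing every
  Λ_j toward zero while κ inflates to pass the signal off as noise. That
  degenerate ridge can dominate the well-fitting posterior mode — on
  misspecified data we measured κ̂ running to its bound with Λ̂ at a
  fraction of the observed totals. On well-specified data the two priors
  give practically identical (k₂, k₃, κ) posteriors (posterior means agree
  to ~0.005 in k), which is the sensitivity argument for the flat default.
* κ ~ Gamma(0.001, 0.001) truncated to (0.001, 10³), with a Uniform option
  on the same support. The upper bound is a weakly-informative physical
  backstop: κ = 10³ already means a noise SD equal to the height of a
  1000-count peak, far beyond a usable instrument, while the degenerate
  ridge needs κ of the order of the raw peak heights.

### Diagnostics

Convergence: classic Brooks–Gelman–Rubin potential scale reduction per
parameter (implemented in-package; two identical chains give R̂ ≈ 1 by
construction) plus bulk effective sample sizes via `arviz`. Fits with
R̂ above threshold (default 1.05) warn loudly and the CLI refuses to write
output unless overridden.

Goodness of fit: three posterior-predictive p-values, one per mineral, with
discrepancy T_l = Σ_j (I_lj − λ_lj)²/(κ λ_lj) over calibration runs. For
each retained draw, T_l is evaluated on the data and on a replicate dataset
simulated from that draw; p_l is the fraction of draws with
T_l(rep) ≥ T_l(data). On well-specified synthetic data the per-dataset mean
of the three p-values is 0.50 ± 0.01 (measured over repeated simulations).

**Power limitation.** These p-values are conservative against distortions
that the free parameters can absorb. A global multiplicative bias on any
one mineral is *exactly* mean-absorbed by rescaling (k₂, k₃, Λ_j); tenfold
single-mineral noise inflation and isolated count spikes are largely soaked
up by κ and the per-run Λ_j (p stays within ~[0.15, 0.8]). What the check
does catch decisively is structural violation of the relative-intensity
law — e.g. swapping the two calcite peak assignments drives both calcite
p-values to ≈0.01. Users should read mid-range p-values as "not grossly
misassigned", not as proof of the noise model.

## Estimation and uncertainty (component 2)

Point estimate: π̂_l = (I_l/k̂_l)/Σ(Iᵢ/k̂ᵢ) — scale-invariant in I, exact
for noise-free input, continuous at I = 0 (absent peaks give π̂ = 0
exactly). Two first-order error components are evaluated at the plug-in
point (observed I, estimated π̂):

* **Intrinsic** σ²_I,l = φ_l² [k_m k_n π̂_l(1−π̂_l)² + k̂_l π̂_l²(k_m π̂_n +
  k_n π̂_m)] / [k_m k_n (1−π̂_l)], with φ_l² = κ̂ π̂_l(1−π̂_l)/I_l — the
  delta-method variance of the estimator under Var(I) = κλ. It doubles in
  precision when all heights double (σ² ∝ 1/I), peaks for weight fractions
  near 50% and vanishes at the simplex boundary.
* **Calibration** σ²_C,l = g_lᵀ Σ_k g_l where Σ_k is the (k₂, k₃) posterior
  covariance and g_l the analytic gradient of π̂_l in (k₂, k₃) (verified
  against central finite differences to 10⁻⁶ relative). Estimated rather
  than true k̂ in the partials has negligible effect.
* Combined SE = √(σ²_I + σ²_C), typically a few percent above σ_I alone
  when the calibration is precise.

Boundary rule: at π̂_l ∈ {0, 1} both components are defined as 0 (the
analytic limits), and a flag records that the rule fired. Pure samples
therefore carry zero SE by construction — they are excluded from MAE-style
validation metrics.

**Validity envelope.** The closed forms agree with a parametric Monte-Carlo
oracle (10⁵ simulated measurements per setting) to within 5% relative
wherever every present peak's expected height is at least ~3.5 noise SDs
(λ ≳ 12 κ) — the same detectability condition the raw-scan extractor's
3σ prominence threshold imposes. Below ~3 SDs the first-order expansion
degrades (we measured 10–35% relative error in deep-noise corners); such
peaks would not be trusted as "present" in practice.

Replicate averaging: the pooled estimate is the arithmetic mean of the
replicate compositions (renormalised defensively). Intrinsic errors are
independent across mounts and pool as √(Σσ²_I)/n; calibration error is
*shared* by all replicates measured under one calibration and is carried
unreduced (replicate mean), with the choice recorded in the output flags.
Averaging can therefore not shrink the total SE below σ_C.

## Synthetic data

`trixrd.synthetic` draws from the same generative model the calibration
assumes, so parameter-recovery and coverage tests are exact by
construction. Defaults encode the study conditions: the 17-mixture
calibration design (compositions from pure end-members through 50/25/25 to
binary mixtures), per-mount Λ ~ Uniform(1500, 3500) counts (inside the
observed 452–3554 count per-peak range), κ of order 40 for
calibration-level noise. Negative draws from the untruncated normal —
possible only at very small λ — are redrawn with a warning.

The three-tier precision study emulates the repeatability experiment on a
50/25/25 mixture: the *instrument* tier re-draws measurement noise only
(κ = 1, giving ~1 wt% scatter — repeat scans without touching the mount are
much quieter than the calibration-level κ, which also absorbs
mount-to-mount variation); the *operator* tier adds a small log-normal Λ
multiplier (remounting mainly rescales the total intensity, to which the
estimator is invariant — operator ≈ instrument precision); the *sampling*
tier additionally jitters the composition with a Dirichlet draw
(concentration 70, ~6 wt% scatter for a 50% mineral — random assortment of
grains between subsamples dominates the error budget). The operator and
sampling settings are explicit emulation knobs reproducing observed
magnitudes, not fitted quantities.

What the generator does *not* emulate: peak-shape effects (crystallinity,
preferred orientation — absorbed into the RIRs on real data), amorphous
background humps, detector dead time, or compositional trends in κ. Passing
tests demonstrate the statistical machinery is correct under its own
assumptions; they do not certify any particular instrument, which is why
calibration must be re-run per machine and practice.

The hold-out validation scenario uses generative κ = 10, emulating the
error magnitude actually observed when predicting known mixtures (~2 wt%
mean absolute error, most errors within one reported SE). The
calibration-level κ̂ ≈ 43 is conservative for prediction — it also absorbs
between-mount variation — so a self-consistent κ = 40 world would put
hold-out R² near 0.97 rather than the observed >0.99.

## File formats and peak extraction

CSV (UTF-8, comma, "." decimal, mandatory header) for peak tables, design
tables and estimate tables; heights in counts, compositions in percent
(fractions are internal). JSON for calibration parameters with explicit
key/type validation. Raw scans are two-column ASCII xy (2θ, counts), "#"
comments.

Manual peak tables are the primary input path; the extractor for raw scans
is deliberately simple and fully configurable: per peak a search window and
a background range whose edges must sit on quiet baseline; background is
the line through the edge-point medians; height is the maximum
background-subtracted count; a peak is absent when below 3× the robust
(MAD-based) edge noise or when its maximum sits on the window boundary
(a neighbouring peak's tail, not a resolved apex). The LMC/HMC windows abut
at 29.55 °2θ — halfway between the nominal centres, which are only ~0.3°
apart — and share quiet-flank background ranges on either side of the
doublet. If the halite internal standard (31.7 °2θ) is found, its offset
from nominal realigns all windows first. Extraction is invariant to
constant background offsets and equivariant under uniform count scaling. A
completely flat trace is rejected with an explicit "no peaks detected"
error rather than returning an empty measurement.

## Numerical choices

* Simplex-closure tolerance 10⁻¹² (closed-form arithmetic only).
* Forward/inverse round trip exact to 10⁻¹⁰ over the simplex.
* MCMC initialisation from moment estimates (median pairwise intensity
  ratios for k; observed run totals for Λ; scaled median squared residual
  for κ), jittered per chain for overdispersed starts.
* Gelman–Rubin uses the classic pooled-variance PSRF; ESS via arviz.
* Monte-Carlo oracle and all generators are deterministic given a seed
  (numpy `default_rng` streams).
* Tests run at reduced MCMC length: recovery/coverage fits use 20–40k total
  iterations over 2 chains, the well-specified p-value and acceptance-script
  fits 100–120k over 4 chains; posterior summaries at these lengths are
  stable to well within the asserted tolerances (R̂ < 1.01 throughout).

## Known limitations

* Three minerals, single primary peak each; no full-pattern fitting or
  Rietveld refinement, no >3-phase systems.
* No limit-of-detection inference: "is this mineral truly present?" would
  need a background-noise term and is out of scope; absent means
  *qualitatively absent in the diffractogram*.
* The delta-method SEs are first-order and degrade for peaks within ~3 SDs
  of the noise floor (see validity envelope above).
* Posterior-predictive p-values have limited power against distortions
  absorbable by (k, κ, Λ); see the calibration section.
* The normal noise model is untruncated; at realistic intensities the
  negative-tail mass is negligible, and the simulator redraws the rare
  negative sample.
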