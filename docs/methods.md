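# Methods

## Data model and census conventions

A cohort is a set of same-aged individuals reared at one constant
temperature and inspected once per day.  The day grid is 0-based: an egg
laid at day 0 occupies the egg stage on day 0.  A stage duration of *d*
means the individual was observed in that stage on exactly *d* consecutive
census days, so every duration is an integer ≥ 1.  Durations are recorded
only for stages an individual completed; an individual that died in stage
*s* carries durations for the contiguous prefix of stages before *s* and no
duration for *s* itself (daily inspection does not resolve partial
occupancy of the death stage).  All per-stage statistics are computed over
the survivors of that stage, the standard life-table convention, so the
missing death-stage occupancy never enters any downstream number.

The day × stage occupancy matrix (stage-frequency representation) is
derived from individual histories by assigning stage 1 to days [0, d₁),
stage 2 to days [d₁, d₁+d₂), and so on.  The derivation is one-way:
individual histories determine the matrix, but the matrix aggregates away
each individual's trajectory.

## Extended life-table statistics

For a stage sample x₁…x_N (survivors only):

* mean μ_D; standard error SE = s/√N with the n−1 sample standard
  deviation s; the bridge σ_D = SE·√N then recovers s exactly, which is
  what makes published (mean, SE, n) rows convertible to Gaussian widths;
* median (mean of the central pair for even N); mode(s): every maximizer of
  the integer-day frequency table is reported, the smallest designated
  primary so single-number tables are deterministic;
* skewness s = m₃/m₂^{3/2} and kurtosis k = m₄/m₂², with central moments
  m_r = (1/N)Σ(xᵢ−μ_D)^r — population-style moments with no bias
  correction.  This is the *non-excess* kurtosis convention: a Gaussian has
  k = 3 and s = 0, and departures from (3, 0) measure tail weight and
  asymmetry.  (Some texts describe kurtosis sign-relative to a Gaussian,
  i.e. excess kurtosis k−3; this package reports the plain moment ratio.)
* Shapiro–Wilk (scipy's implementation) with the conventional p ≥ 0.05
  normality verdict, valid for 3 ≤ n ≤ 5000 and non-constant samples;
* normal Q–Q points at plotting positions (i − ½)/n — symmetric and
  standard — with the reference line through the first- and third-quartile
  points.

Fecundity schedules (ages x = 1…k, survival lₓ non-increasing, fecundity
mₓ ≥ 0) give the net reproduction rate R₀ = Σ lₓmₓ and the mean generation
time T_G = (1/R₀) Σ x·lₓmₓ; T_G is undefined at R₀ = 0 and always lies
within the reproductive age span.  The cohort generator does not simulate
reproduction; these closed forms operate on user-supplied schedules.

## Impulse-response population model

Placing N eggs in a chamber at day 0 is the Kronecker-impulse input
u(t) = N·δ(t); the daily counts of individuals emerging into the next stage
are the system's impulse response.  Each stage is modelled as a linear
time-invariant block, stored as

* a normalized kernel w(t) — the fraction of *stage survivors* taking
  exactly t days, identified directly from the duration sample with each
  individual's clock restarted at its own stage entry — and
* a survival fraction S = survivors/entrants.

The raw experimental sequence equals S·w(t); storing the two factors
separately prevents mortality from being double-counted when blocks are
chained.  Chaining is discrete convolution of kernels and multiplication of
survivals, performed entirely in the time domain with finite sequences —
mathematically identical to multiplying transfer functions in the Z domain,
with no symbolic machinery.  Composition is associative and, on kernels,
commutative; kernel first moments add; output mass always equals the
product of survivals times input mass.

A composed model is the distribution of a *sum of independent draws* from
the per-stage empirical distributions.  It does not condition on identity:
an individual fast as a larva is not remembered as fast at the pupal stage.
For a single stage the model response to N·δ(t) reproduces the stage's
duration histogram exactly; across stages it reproduces the brute-force
enumeration of all duration combinations exactly (the test suite checks
both), which differs from the histogram of matched per-individual totals
whenever durations are correlated within individuals.  This independence
assumption is intrinsic to composing marginal kernels — with or without a
Gaussian assumption — and is shared by the stage-structured models the
kernel model is compared against.

The Gaussian counterpart of a block is built from a (mean, SE, n) row via
σ_D = SE·√n by integrating the normal density over unit day bins
[t−½, t+½) for t = 0…horizon and renormalizing over the truncated support.
Bin integration (not point evaluation) preserves total mass and behaves
correctly for small σ_D; σ_D = 0 degenerates to a point mass at the nearest
integer day.  The discrete kernel's mean matches μ_D closely and its
variance carries the usual binning term (≈ σ_D² + 1/12), within 1 % of σ_D
once σ_D ≳ 2 days.

Model comparison normalizes both sequences to unit mass (removing the
mortality scaling), then reports: earliest-maximum peak days (ties broken
toward the earliest day — the conservative choice when peaks time control
actions), the peak shift (Gaussian minus empirical, days counted from egg
laying), the L1 distance (0 for identical, 2 for disjoint distributions),
and the first/last days with mass.

## Synthetic cohort generator

The generator emulates the standard rearing protocol: per individual and
stage, first a Bernoulli(survival) draw decides death-in-stage, then a
continuous duration is drawn and discretized.  Families: point (degenerate),
normal, gamma (right-skewed, the typical real shape), and
Gaussian mixtures (bimodal cohorts).  Defaults in the examples and checks
are anchored to published rice-moth rows (egg ≈ 4.8 d at 26 °C; larva mean
24.4 d, SE 0.4, n 136; bimodal larval waves at 21 and 33 days) with
cohort sizes of a few hundred, the scale of real rearing experiments;
simulation-heavy checks use 10³–10⁴ individuals, enough for 4-sigma
recovery bounds while keeping the whole suite inside a few seconds.

Numerical choices:

* **Discretization** is t ↦ max(1, ceil(t)): an individual is counted in a
  stage on every census day it occupies any part of, and durations are ≥ 1
  by construction.  Ceiling adds a bias of about +0.5 day to the continuous
  mean.  Recovery tests therefore compare the empirical mean against
  E[max(1, ceil T)] computed by brute-force integration of the rounding map
  over the integer grid (`discretized_mean`), never against the continuous
  mean with an assumed offset.
* **Truncation**: non-positive draws from normal/mixture specs are rejected
  and resampled.  The induced bias is negligible for the parameter ranges
  used (mean ≳ 4·sd); gamma draws are positive by construction.
* **Seeding**: one root seed; each (individual, stage) pair draws from its
  own substream derived via `SeedSequence(seed, spawn_key=(i, j))`, so
  growing a cohort appends individuals without reshuffling existing ones,
  and equal configurations give byte-identical CSV output.
* `truth_record` returns the exact continuous moments (mixtures via
  mean = Σwᵢμᵢ, var = Σwᵢ(σᵢ²+μᵢ²) − mean²) for parameter-recovery tests.

What the generator does *not* emulate: within-individual correlation of
stage durations, temperature as a covariate (it is a label only),
time-varying mortality within a stage, fecundity/oviposition, and
observation error.  Passing tests therefore demonstrate the correctness of
the statistics and of the convolution machinery under the stated protocol,
not that any particular real species meets the model's independence
assumptions.

## Design choices on genuinely open points

* The raw-data CSV dialect (one row per individual,
  `individual_id,temperature_C,<stage>_days…,death_stage`) is fixed by this
  package; adapters for other deposited layouts are thin, isolated readers.
* Peak days in dynamics outputs count from egg laying (day 0), not from
  stage entry; per-stage kernels, by contrast, always start at stage entry.
* Degenerate inputs fail loudly and early: empty samples, constant samples
  for Shapiro–Wilk, zero-mass sequences, R₀ = 0 generation times and
  invalid generator specs all raise typed errors before any output is
  written; an empty stage inside the report pipeline is skipped with a
  warning instead.

## Known limitations

* The independence of composed stage blocks (above) is a modelling
  assumption, not a property of insects.
* Survivors-only statistics condition on completing the stage; under heavy,
  duration-correlated mortality they describe the surviving subpopulation.
* The Shapiro–Wilk test on integer-day data sees tied values; with large n
  and coarse grids (small σ relative to 1 day) discreteness alone can
  reject normality.
* Mixture component counts and gamma shapes must be supplied; the package
  diagnoses non-normality but does not fit alternative distributions.
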