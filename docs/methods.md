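# Methods

This note documents the models, numerical choices and known limitations of
`blastovar`. Coordinates are percent egg length (%EL) on [0, 100] with 0 at
the anterior pole; dorso-ventral position is percent embryo height;
intensities are arbitrary units on a 0–255 scale; integration bins are
half-open intervals [b, b+1) %EL. Developmental stages are the time classes
c13 and t1–t8 of cleavage cycle 14A (~6–7 min each), mapped to indices
0–8.

## Synthetic cohorts

### Generative model

Each expression domain d of gene g is a Gaussian bump. For one embryo at
time class with index τ, the intensity of gene g at A–P position x is

    I_g(x) = Σ_d  A_d · exp( −(x − c_d)² / (2 σ_d²) )  +  bg(x)  +  ε(x)

over the domains of g that are present, clipped to [0, 255], where

- c_d = c_d⁰ − s_d·τ + z_d·j_d : the realised centre. c_d⁰ is the centre at
  c13, s_d the anterior shift per class step (%EL/class; shifts are linear
  in the class index, consistent with the near-linear time–space
  trajectories of late blastoderm domains), j_d the embryo-to-embryo jitter
  SD and z_d a standard normal drawn **once per embryo per domain** —
  variability is modelled at the embryo level, not the nuclear level,
  because embryo-to-embryo variance is the quantity under test. Domains may
  share one z via a named jitter group; the abdominal Kni domain and Eve
  stripe 6 share one, encoding Kni's role in positioning the stripe-6
  anterior boundary.
- A_d = A_d⁰ · f_partial · max(0, 1 + cv·z′): amplitude with a Gaussian
  coefficient of variation (cv = 0.15 by default; no distributional
  information exists for amplitude noise, so this is a modelling choice)
  and a partial-expression factor (below).
- presence: each domain carries a per-time-class presence probability and,
  conditional on presence, a partial probability. Partial expression scales
  the amplitude by `partial_amplitude_frac` (default 0.3) — a 1-D trace
  cannot represent incomplete dorso-ventral extent, so reduced height is
  its proxy (documented limitation).
- bg(x) = const + q·(x − 50)²: a smooth non-specific-staining baseline
  (defaults 8 + 0.001·(x−50)²), plus i.i.d. Gaussian noise ε with SD 3.

Because the domains are Gaussian, the ground truth is analytic: half-maximum
boundaries sit at c_d ± σ_d·√(2 ln 2) and the true width is 2σ_d√(2 ln 2).
Every generated cohort returns this ground-truth table.

### Nuclear geometry

Nuclei sit on a deterministic quasi-hexagonal lattice: ~100 A–P columns
(for the default 1000 nuclei), each spreading its nuclei evenly over the
D–V axis with a golden-ratio phase. Two consequences are intended. First,
any lateral strip samples **every** A–P column — seeded uniform placement
left multi-%EL gaps that swallowed whole stripes at realistic densities.
Second, nuclear packing is not a modelled noise source, so presets with all
stochastic components switched off generate bit-identical embryos under any
seed; the scientifically meaningful randomness (jitter, amplitude noise,
presence, measurement noise) is all seed-controlled, with per-embryo seeds
derived as `seed + embryo_index`.

### Genotype presets

The `wildtype` preset places the seven Eve stripes at ~33–80 %EL at t8
(stripe-1→stripe-7 peak range ≈ 47 %EL, about one nucleus per %EL), with
anterior shift rates increasing posteriorly — stripe 6 moves 2.62 %EL and
stripe 7 4.36 %EL between t3 and t8; the posterior Gt domain moves
4.34 %EL. All domains carry uniform 0.75 %EL jitter (late wild-type
precision). Gap domains: anterior/posterior Hb, central Kr, abdominal Kni,
anterior/posterior Gt and the two terminal Hkb domains.

The `tll` preset differs where the mutant phenotype differs: no posterior
Hb domain; the posterior Gt domain expanded (σ 6 vs 4), more posterior, and
shifting 5.92 %EL t3→t8 (delayed retraction from the pole); Eve stripes 4–6
displaced posteriorly — subtly for stripe 4, substantially for 5 and 6,
with stripe 6 forming near the wild-type stripe-7 position (t8 centre
79.5 %EL), several nuclei wider (σ 3.9), and shifting 4.16 %EL t3→t8, about
as much as wild-type stripe 7 (shifts track position, not stripe identity).
The six-stripe mutant pattern thus spans nearly the same region as the
seven wild-type stripes. Stripe 7 is absent through t6, then appears
stochastically: P(six/partial/full) = 0.55/0.33/0.12 at t7 and
0.08/0.47/0.45 at t8, at a more posterior position (90.5 %EL at t8, giving
the 57 %EL extent in full-seven embryos). Posterior stripes 5–6, abdominal
Kni and posterior Gt carry inflated jitter (2.0 and 1.75 %EL) — the
loss-of-canalisation signature; stripe 7 keeps moderate positional jitter
(1.0 %EL) because its increased variability is mainly temporal (the
presence/partial draws), not spatial.

## Profile processing

- **Strip extraction** keeps nuclei with |y − 50| ≤ 100·f/2 (default
  f = 0.10), sorted by x; duplicate positions are separated by a stable
  1 ns-scale increment to keep x strictly increasing.
- **Background removal**: in 10-%EL windows, samples at or below the
  per-window 0.1 intensity quantile are baseline candidates; one global
  polynomial (degree ≤ 2, default 2) is least-squares fitted to them,
  subtracted, and the result clamped at 0. The operation is invariant to
  adding a constant and approximately idempotent. On dense multi-stripe
  fields the candidates sit in inter-stripe troughs that contain stripe-tail
  signal, so boundaries are biased slightly inward (~5–10% of a stripe
  width); this cancels in position/width *comparisons* and is accepted.
- **Registration** estimates x′ = a·x + b per profile (a ∈ [0.9, 1.1],
  |b| ≤ 5 %EL) by minimising the mean squared difference between the
  profile's spline evaluation and the reference on a 1-%EL grid (Powell,
  bounded), two passes against the running cohort mean; the cohort-mean map
  is re-centred to the identity (geometric-mean a → 1, mean b → 0) so the
  cohort as a whole never moves. Non-converged profiles pass through
  unregistered and are flagged.
  **Placement**: the pipeline applies registration only when building
  integrated profiles. Expression-based affine registration of a
  single-gene profile against the cohort mean absorbs part of the
  embryo-to-embryo positional variance — all of it for a single-domain gene
  such as *kni*, about half for the large, high-leverage Eve stripe 6 —
  and that variance is precisely the quantity the statistics test. The
  generator models no mounting or egg-length artifacts (what registration
  corrects in real images), so positional features are measured on
  unregistered, background-removed profiles.
- **Integration** assigns each sample to bin ⌊x⌋ (x = 100 → bin 99) and
  averages over all samples of all embryos; empty bins are linearly
  interpolated from filled neighbours (ends held). Desk-scale cohorts make
  sporadic empty bins likely, hence interpolation rather than NaN.
- **Smoothing**: Gaussian filter, σ = 1 bin by default, reflective
  boundaries (σ = 0 is the identity; the total sum is preserved to < 0.5%).
- **Scaling**: the mutant profile is multiplied by the ratio of 95th-
  percentile bin values (reference/target); for *hkb* the direction is
  reversed (wild-type scaled to mutant), configurable per gene. Positional
  features are invariant under this scaling when the baseline is zero.

## Feature extraction

- **Spline model**: quadratic (k = 2) smoothing splines. The default path
  sets the FITPACK residual budget to s = n·σ̂², where σ̂ is a robust noise
  estimate: the scaled MAD of residuals against a pilot least-squares
  spline with ~2-%EL knots (raw second differences are unusable — at
  nuclear sampling density the stripes themselves dominate them; the pilot
  subtracts stripe-scale structure first). `smoothing=0` interpolates;
  `knot_spacing` selects a fixed-knot least-squares spline (knots thinned
  where the data cannot support them). No smoothing parameters are
  published for this analysis; the defaults are calibrated only in the
  sense that they recover known synthetic parameters (peak position error
  SD ≈ 0.1 %EL at 1000 nuclei/embryo).
- **Peaks**: within each search window the peak is the largest interior
  local maximum on a 0.01-%EL grid, refined by local quadratic
  interpolation (ties → most anterior). Window-edge maxima are reported
  absent — a monotone flank of a neighbouring domain entering the window is
  not a domain — as are peaks below 0.1 of the profile's global maximum.
  Absence is a value, not an error.
- **Search windows** assign domain identity (the original study used expert
  inspection and enhancer-reporter evidence, which cannot be automated from
  1-D data). Shipped windows derive from the preset's expected domain
  layout at each time class: ±max(3σ, 4 %EL) around the expected centre,
  clipped at midpoints between neighbouring domains of the same gene.
  Fully user-overridable.
- **Boundaries**: the half-maximum crossings nearest the peak on each
  flank, bracketed by 0.05-%EL marching and solved by Brent's method
  (xtol 10⁻⁶). A flank with no crossing inside the window (fused domains)
  is censored with reason `no-half-max-crossing`; censored values are
  excluded from statistics, never extrapolated, and counted in reports. The
  half-maximum level is relative to the zero baseline (post background
  removal), not to the local valley.
- **Shifts** are peak(t_a) − peak(t_b) for t_a earlier, positive =
  anterior movement; cohort-level shifts compare per-embryo peak means
  between time classes.
- **Stripe-7 classification**: with A7 = stripe-7 amplitude relative to
  stripe 6 and V = inter-stripe valley depth, the class is *six* if
  A7 < 0.15, *full_seven* if A7 ≥ 0.50 and V ≤ 0.50, else *partial_seven*.
  Both evidence values discount the stripe-6 posterior flank, which with a
  broad mutant stripe 6 otherwise dominates the stripe-7 window: A7 is the
  largest excess above the flank predicted from stripe 6's fitted Gaussian
  half-width (measured on its clean anterior side), evaluated where the
  predicted flank has decayed below 0.3 of the stripe-6 peak; V requires an
  interior minimum of the raw profile between the peaks (no interior dip =
  fused, V = 1) and is that minimum's flank-subtracted height over the
  stripe-7 amplitude. This detects unseparated partial stripes that appear
  as shoulders rather than distinct peaks. On labelled synthetic cohorts
  the classifier is ~94% accurate with unbiased class frequencies; a
  partial stripe merged so completely into stripe 6 that no shoulder
  remains is indistinguishable from a broadened stripe 6 in one dimension
  and is called *six* — the cost of replacing the dorso-ventral
  completeness criterion with an amplitude criterion.

## Statistics

- **Mean tests**: pooled-variance two-sample Student *t* (pooled, not
  Welch, matching the named test), one-sided in each direction;
  df = n_a + n_b − 2. Zero pooled variance: p = 0.5 for equal means, 0/1
  by sign otherwise.
- **Variance tests**: Brown–Forsythe — Levene's statistic on absolute
  deviations from the group *median*, robust for small samples and
  non-normal data. W is referred to F(1, N−2) two-sided; the directional p
  halves the two-sided p with an ordering check on the mean absolute
  deviations (the F test is one-tailed in W; direction must come from the
  group spreads). min(p_less, p_greater) = p_two-sided/2 by construction.
- **The grid**: the default family is 7 stripes × {peak, anterior,
  posterior} × t1–t8 = 168 cells; Bonferroni uses n = 168 (the two
  directions of one test count as one family member — one consistent
  reconstruction of the printed family size; the exact composition is not
  stated in the source analysis). Corrected p < 0.005 flags significance.
  Cells with fewer than 3 uncensored values in either cohort are skipped
  with a note; censored features are dropped cell-wise with n reported; no
  imputation.
- **Summaries**: sample SDs use the n−1 denominator (SD missing for
  n < 2); pattern-class fractions sum to 1 per group; the boundary
  correlation is Pearson's r on embryo-paired values (≥ 3 complete pairs;
  zero variance → undefined, flagged as NaN).

## Problem sizes

Synthetic experiments use 1000 nuclei per embryo (≈100 strip samples at
1 %EL spacing) and cohorts of 40 embryos per time class for the
canalisation grid, 200 embryos per condition for parameter-recovery checks,
and 10⁴/2000 replicates for type-I/power calibration — sizes at which the
sampling bounds asserted by the tests are meaningful and the full suite
runs on a laptop. The paper-scale dataset (hundreds of embryos across nine
time classes and eight genes) is processed by the same code paths.

## What the synthetic tests do and do not show

The generator reproduces the *statistical structure* the analysis targets:
domain layout and its genotype differences, embryo-level positional jitter
with regional structure, time-linear anterior shifts, stochastic stripe-7
timing, amplitude noise and smooth background. It does not emulate real
antibody-staining data in other respects: domains are exactly Gaussian
(real domains are asymmetric, with sharper posterior boundaries), noise is
homoscedastic and uncorrelated across nuclei, there is no dorso-ventral
patterning, no channel cross-talk, no egg-geometry or mounting variation,
and time classes are exact labels rather than morphology-derived estimates.
Passing tests therefore demonstrate that the estimators recover known
parameters under the modelled structure and that the statistical machinery
is calibrated — not that the defaults are optimal for any particular
microscope or staining protocol.

## Known limitations

- The affine registration model is a small surrogate for the original
  spline-registration software, whose cost function is not published.
- Boundary positions on crowded stripe fields carry a small inward bias
  from trough-level background estimation (cancels in comparisons).
- Peak estimates of crowded stripes carry a position-dependent bias of up
  to ~0.15 %EL from neighbouring-stripe overlap; shift-rate checks
  therefore use a well-separated domain.
- Wild-type and mutant features use the same quadratic-spline extractor
  (the original wild-type analysis used dyadic wavelets); single-method
  consistency is preferred here, at the cost of comparability to the
  original wild-type feature tables at the sub-%EL level.
- Stripe-7 classes rest on amplitude and separation only (no D–V
  information); fully merged partial stripes are undetectable in 1-D.
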