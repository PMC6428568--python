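# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions adopted where the underlying assay protocols
leave room.

## Courtship memory: SI and its permutation null

The courtship index CI of one male is 100 × (time courting)/(test
duration); the suppression index of a trained group against a naive group
is SI = 100·(1 − c(CI⁺)/c(CI⁻)) for a center c. The Methods-style center is
the **mean** and is the default; the median is available
(`center="median"`) because courtship data are often summarized that way,
and the choice is echoed in every result object so downstream readers can
tell which was used. SI ≤ 100 by construction, is negative when trained
flies court more, and is undefined when the naive center is 0
(`UndefinedSIError`).

**H₀: SI = 0.** All CIs are pooled and re-assorted into simulated trained
and naive groups of the original sizes; an SI is computed per permuted data
set. Under exchangeability this is exact. The default tail is one-sided
"greater" because suppression is directional (memory can only lower
courtship); a two-sided option exists. When the number of distinct label
assignments C(n, n_t) is ≤ 200,000 the test enumerates all of them and
reports the exact proportion (recorded as `seed="exhaustive"`); otherwise
it draws 100,000 random re-assortments (both numbers configurable) and
reports the add-one-corrected estimate p = (1 + #extreme)/(1 + N), the
standard device that keeps sampled permutation p-values positive and valid.

**H₀: SI = SI_c.** The statistic is ΔSI = SI_exp − SI_ctrl. The null
re-assorts flies between the experimental and control arms *within
condition* (trained with trained, naive with naive), preserving all four
group sizes — the natural exchangeability structure when the question is
whether two genotypes learn equally, and the scheme this package commits
to explicitly. Because the trained-arm and naive-arm re-assortments are
independent, exhaustive mode enumerates the cross product of the two
combination sets. The default tail is two-sided.

**Guards.** A fully degenerate pool (all CIs identical) returns SI = 0,
p = 1 with a `degenerate` flag instead of erroring. A permuted arm whose
naive center is 0 has no defined SI; such permutations are excluded and
counted (`n_excluded`), and if they exceed 1% of the null the test aborts —
real courtship tables essentially never trigger this, but the behavior must
be explicit rather than silent.

Properties verified by the test suite: exact agreement with an independent
brute-force enumerator on small tables; convergence of sampled to
exhaustive p within binomial error; scale invariance of SI and p;
invariance to record order; calibrated type-I error (empirically ≈ 5% at
α = 0.05 over 10,000 null experiments with n = 16/16).

## Sleep scoring

Sleep is any maximal run of zero activity counts lasting ≥ 5 consecutive
minutes (`min_bout_min` configurable); any positive count is wake — the
standard DAM beam-break convention. Conventions the assay leaves open and
this package fixes:

- minutes are half-open [m, m+1); windows in hours convert as
  [60·start, 60·end);
- a zero run touching the record boundary counts at its observed length
  (no censoring correction) and is flagged `censored` in the output;
- bouts straddling a profile-bin edge or an analysis window are split by
  overlap, so the 30-min profile sums exactly to total clipped sleep and
  "total sleep between 7–10 h" counts only in-window minutes.

Group comparisons use the equal-variance two-sample Student t-test on
per-fly windowed totals, reported with group means ± SEM. The
sleep-deprivation transform inserts a single count whenever an inactivity
run (tracked from its true start, including pre-window minutes) reaches
`max_quiet_min` (< 5) inside the deprivation window, and always perturbs
the window's final quiet minute; this guarantees no scoreable sleep
overlaps the window while leaving every minute outside it untouched. It
models the *effect* of intermittent mechanical perturbation on the
inactivity-run structure, not shaker mechanics.

## Luminescence normalization

Relative luminescence divides each well's reading by the center of the
control wells at the same timepoint. The control center is the arithmetic
**mean** (the plural "controls" implies aggregation but no aggregator;
median available). Control wells are normalized too, giving a QC series
≈ 1. Per-well division happens before any group averaging — the
alternative (normalizing group means) is not offered because it discards
per-well variance needed by the t-test. Missing readings are never
imputed; a well with any missing value inside the analysis window is
excluded and logged. Windowed totals sum relative values at timepoints with
start ≤ t < end (a 3-h window at 15-min sampling holds 12 points), and are
additive over disjoint windows.

## Calcium imaging

- **ΔF/F** uses F₀ = mean of the first 10 s of the session (before any
  stimulation); the connectivity baseline uses each epoch's 10-s
  pre-stimulation window of the ΔF/F trace. These are different windows
  with different roles and both are configurable independently.
- **Epoch alignment**: nominal pulse onsets map to the first sample at or
  after the onset time (sample i at time i/rate); each epoch spans the pre
  window through pulse offset, and the epoch mean is the columnwise mean.
  The protocol stores the inter-pulse interval as **offset-to-onset**
  (onsets are therefore (pulse + IPI) apart); the alternative onset-to-
  onset reading of "30 s inter-pulse interval" is not used, and protocols
  with other spacings can be expressed directly.
- **Connectivity**: per fly, baseline and stimulation means of the
  epoch-averaged trace; across flies the two samples are compared with the
  Wilcoxon rank sum test by default (exact two-sided p), with Student's t
  and a paired signed-rank test behind flags. The rank-sum default treats
  the samples as independent even though they are paired per fly — that is
  the common usage this package follows, and the paired alternative is one
  flag away. p < 0.05 declares connectivity; the direction is the sign of
  the median paired difference.
- **R² map**: each voxel trace is z-scored with the population
  (divide-by-T) sd — the convention cancels in the correlation ratio, which
  a test asserts — then fit (slope + intercept) to the LED drive V(t)
  sampled at the volume rate (1 during pulses, 0 otherwise). Since the fit
  is affine in V(t), r = cov(Z, Zp)/(σ_Z σ_Zp) equals the Pearson
  correlation of trace and drive up to sign, and R² = r² ∈ [0, 1] treats
  excitation and inhibition symmetrically. Maps are computed on z-scored
  raw traces, not ΔF/F (R² is invariant to that affine choice in the
  noiseless case anyway). Zero-variance voxels get R² = 0 by convention;
  any non-finite sample invalidates its voxel (R² = 0, counted and logged),
  never imputed. The display projection maps [0, 1] linearly to [0, 65535]
  with half-up rounding (0.5 → 32768), monotone and invertible to within
  1/65535.

## Synthetic data: what it emulates, what it does not

The real assays publish no distributional forms, so every generator
distribution is a modelling choice of this package, fixed once:

- **CIs**: beta on [0, 100] parameterized by mean and concentration
  (default 12) — bounded like a fraction-of-time measure; the trained mean
  is naive_mean · (1 − SI/100) with default naive mean 60 and true SI 40,
  matching the effect scale such experiments report. With concentration 12
  the per-fly sd is ≈ 14 CI points.
- **Activity**: alternating wake/sleep with geometric dwell times
  (memoryless at minute resolution; defaults 20 min wake / 15 min sleep);
  sleep minutes have zero counts. Wake minutes draw from a
  **zero-truncated** Poisson (default rate 2/min): a fly awake for a full
  minute essentially always breaks the beam at least once, and truncation
  makes the generated bouts exactly recoverable from the counts, which is
  what "ground truth" must mean for a scorer that sees only counts. A plain
  Poisson variant (`truncate_wake_zeros=False`) exists for studying the
  merge artifacts zero wake minutes cause.
- **Luminescence**: a slowly ramping baseline (1000 counts + 3%/h) with
  multiplicative mean-one log-normal noise at the stated CV (default 0.1,
  typical of plate-reader replicates); the experienced group is multiplied
  by 1 + elevation (default 0.5) inside hours 7–10.
- **Calcium**: responsive voxels follow baseline · (1 + amplitude · V(t))
  with iid Gaussian noise, clipped at 0 — a square-pulse response with no
  indicator kinetics, rise time, bleaching or motion. Defaults (baseline
  100, amplitude 0.5, noise sd 2) put the response ~25 noise sd above the
  floor, in line with the strong responses connectivity mapping targets.

Consequently, passing tests demonstrate the *computations* are correct and
calibrated under these idealized conditions; they do not show robustness to
features real recordings have and the generators omit: non-beta CI shapes,
circadian structure in activity, wake minutes without beam breaks, reporter
drift that differs between groups, GCaMP kinetics, photobleaching and
motion. Those belong to preprocessing and experimental design, not to this
pipeline.

## Problem sizes

The validation suite and `scripts/acceptance.py` use sizes chosen to make
Monte-Carlo error small relative to the properties checked while staying
desk-scale: 10,000 simulated null experiments × 999 permutations for the
type-I calibration (binomial SE ≈ 0.2 percentage points at α = 5%), 200
replicates for SI recovery and power at n = 25/25, 100 traces of 12 h for
sleep-bout recovery, 500 traces for the √6 epoch-averaging check, and
8×16×16×120 null movies for the R² noise floor (E[R²] = 1/(T−1) under
independence). Exhaustive permutation checks run on tables of ≤ 12 flies,
where full enumeration is trivially cheap.

## Known limitations

- The within-condition swap null for H₀: SI = SI_c is one defensible
  exchangeability structure; others (e.g. permuting condition labels within
  genotype) answer different questions and are not implemented.
- Bout-architecture statistics (bout number, latency) are emitted as raw
  bouts but not modelled; no circadian analysis beyond the binned profile.
- The DAM reader ingests the 42-column monitor dialect and the minimal CSV;
  channel-status flags in monitor files are ignored rather than used to
  drop dead channels.
- TIFF movies are read whole into memory; volumes at the real acquisition
  size (512 × 512 × 42 × hundreds of volumes) would need chunked reading
  that this package does not provide.
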