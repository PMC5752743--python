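# Methods

This note records the scientific and numerical choices behind phvkit: the
growth model and how age at peak height velocity (APHV) is extracted, the
prediction equations, what the synthetic cohorts do and do not emulate, and
the conventions used by the validation battery.

## Growth model and APHV extraction

Stature is modelled with the five-parameter Preece–Baines Model 1,

    h(t) = h1 − 2 (h1 − hθ) / [exp(s0 (t − θ)) + exp(s1 (t − θ))],

valid from late childhood onward. Parameter domains enforced throughout:
`h1 > hθ > 0`, `0 < s0 < s1`, `θ ∈ [8, 18]` years. Equal rate constants
collapse the curve to a single logistic with no adolescent spurt and are
rejected at the type level. More subtly, a spurt only exists when `s1`
sufficiently exceeds `s0` (empirically `s1/s0 ≳ 6` in the region we sample);
rate pairs whose velocity curve is monotone are rejected by the parameter
sampler and raise a bracket error in APHV extraction.

The velocity `dh/dt` is analytic:

    v(t) = 2 (h1 − hθ) (s0 e0 + s1 e1) / (e0 + e1)²,  eᵢ = exp(sᵢ (t − θ)).

Across `(−∞, ∞)` it declines through childhood, passes a pre-pubertal
minimum and rises to a single adolescent peak before decaying to zero. APHV
is found on the bracket `θ ± 4` y by a coarse 513-point scan that locates the
*interior local* maximum (the global maximum on the bracket can sit on the
childhood limb at the left edge when the spurt is weak), refined by bounded
Brent minimisation of `−v` to `xatol = 1e−8`. An exhaustive 0.001-y grid
search is kept in the test suite as an independent oracle; the two agree to
within 0.002 y across the sampled parameter space.

Because the model is translation-equivariant in `θ`, `APHV − θ` depends only
on `(s0, s1)`. The package exploits this twice: as a tested invariant, and in
the simulator, where a target APHV is converted to `θ` exactly by computing
the shift once at a reference `θ` and subtracting — no root finding needed.

## Fitting

Per-subject nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective) with an analytic Jacobian and box bounds
(`h1 ∈ [120, 230]`, `hθ ∈ [100, 215]`, `s0 ∈ [1e−3, 0.45]`,
`s1 ∈ [0.3, 5]`, `θ ∈ [8, 18]`). Initialisation is data-driven: `h1` = max
observed height + 2 cm; `θ` at the peak of the empirical first-difference
velocity; `hθ` = observed height nearest `θ`; `s0 = 0.1`, `s1 = 1.0`. Up to
five multiplicatively jittered restarts (sd 5%) run when an attempt fails or
lands on invalid parameters; the convergence flag is honest — a subject
whose best solution is invalid or unconverged is reported as such, never
silently patched. Tolerances: relative change in the residual sum of squares
below 1e−10, 500 function evaluations per attempt. Heights are fitted as
measured; no smoothing. At least 6 visits are required (5 parameters plus
one residual degree of freedom); the residual SE uses `n − 5` degrees of
freedom.

## Prediction equations

The five published equations are stored to full printed precision and are
never re-fitted. Moore-1 girls and Moore-2 boys use age × stature; Moore-1
boys uses age × sitting height; the Mirwald equations additionally use leg
length (stature − sitting height) and the mass-by-stature ratio, taken as
mass in kg over stature in cm × 100, matching the source equations' usage.
Predicted APHV is `CA − offset` exactly. The equations are applied at every
visit regardless of age; visits outside the 8–18-y calibration window are
flagged (`age_out_of_calibration`) rather than refused, since evaluating
such extrapolation is the point of a validation study. Dispatch is explicit
by equation identifier — the package never infers which equation to use from
the data silently (`predict_cohort` maps the boys' equations to rows marked
`M` and the girls' to `F`, and leaves the other columns NaN).

## Synthetic cohorts

The generator emulates the structure of a mid-20th-century urban growth
study: 193 boys measured annually at 8–18 y and 199 girls at 8–16 y
(defaults), decimal ages jittered around the whole year (sd 0.15 y), and a
ground-truth registry of every subject's parameters and APHV.

* **APHV targeting.** True APHV is drawn per sex from a truncated normal —
  boys mean 14.06, sd 1.11, range [11.45, 17.34]; girls mean 11.89, sd 1.00,
  range [9.03, 14.82] — and `θ` is set exactly as described above. With
  ±2.4–3σ truncation the realised sd is mildly shrunk (≈1.05 for boys),
  which the tests account for by checking the induced mean within 0.1 y and
  sd within 0.15 y of target.
* **Rate constants and size.** `s0 ~ N(0.11, 0.015)`, `s1 ~ N(1.2, 0.2)`
  (rejection bounds `s0 ∈ [0.02, 0.3]`, `s1 ∈ [s0 + 0.3, 3]` plus the
  spurt-existence check); adult stature `N(176, 6.5)` cm for boys,
  `N(164, 6)` cm for girls; `h1 − hθ ~ N(13, 2)` cm. These are the package's
  own calibration, chosen to give realistic peak velocities (6–10 cm/y) and
  adolescent gains; all constants live in `CohortConfig`.
* **Sitting height.** Modelled as a fraction of stature declining
  logistically from 0.535 in childhood toward 0.52 in adulthood, with a
  transient 0.005 dip centred 0.5 y before the subject's APHV — legs spurt
  before the trunk — plus measurement noise (sd 0.3 cm). This yields
  leg-length/sitting-height ratios in the realistic 75–95% band without
  claiming any published values.
* **Mass.** `BMI(t) × (stature/100)²` with BMI linear in age from 16 kg/m²
  at 8 y to 21 kg/m² at 18 y plus a subject-level intercept (sd 1.5) —
  deliberately simple and documented as invented; mass only feeds the
  Mirwald equations.
* **Missingness and duplicates.** Visits drop with per-visit probability
  scaled to average `missing_visit_rate` (default 5%) but weighted linearly
  toward the oldest ages (late-adolescent attrition). With probability
  `duplicate_visit_rate` (default 5%) a visit gains a second observation at
  a nearby age inside the same whole-year age class, re-measured with fresh
  noise.
* **Reproducibility.** One global seed; each subject consumes a
  deterministic substream keyed by `(seed, subject index)`, so cohorts are
  byte-identical on rerun and extensible without reshuffling earlier
  subjects.

What the generator does **not** emulate: secular trends, measurement-protocol
drift, correlated family structure, non-Gaussian measurement error,
informative dropout (attrition is independent of maturity timing), and any
demographically faithful reproduction of historical statures. Passing tests
therefore show that the pipeline's statistical machinery behaves correctly
under a realistic data-generating process with known truth — not that any
particular historical cohort's values are reproduced.

## Validation conventions

* **Binning.** CA group = `floor(age + 0.5)` (group 8 spans 7.50–8.49 y);
  years-from-PHV bin = `floor(age − APHV + 0.5)` clipped to the reporting
  window [−3, +3], values outside [−3.50, +3.49] excluded. The closed
  floor rule reproduces every two-decimal printed range endpoint; apparent
  gaps such as −0.50/−0.51 in such tables are renderings of midpoint
  rounding.
* **Maturity classes.** Early / average / late by sex mean observed APHV
  ± 1.0 y, computed from the analysed cohort itself (not hard-coded), with
  the band endpoints inclusive for "average". One-decimal cutoffs arise by
  rounding at reporting time, not by truncating the mean.
* **Duplicates.** Within each (subject, CA group) the visit nearest the
  group midpoint is kept; exact ties keep the earlier age.
* **Exclusions.** Subjects whose fit did not converge, or whose fitted APHV
  falls outside their own measurement span, are excluded from summaries and
  counted in the run log/manifest.
* **Fitting set vs analysis set.** The growth curve is fitted on all of a
  subject's visits (duplicates included — more data constrain the fit);
  deduplication applies to the analysis tables only.
* **Bland–Altman.** OLS of `d = pred − obs` on `m = (pred + obs)/2` via the
  closed two-variable form; limits of agreement `mean(d) ± 1.96 sd(d)` with
  the n−1 denominator. At least 3 pairs required. Note that under
  `pred = obs + ε` with independent ε the population slope is
  `(σ²_ε/2)/(σ²_obs + σ²_ε/4)` — strictly zero only as ε → 0; the tests use
  small ε and a symmetric two-noisy-measures construction for the null.
* **Inference.** No ANOVA/post-hoc testing; descriptive differences are the
  product, with optional bootstrap standard errors available via the
  pipeline configuration for users who need uncertainty statements.

## Directional checks and problem sizes

The headline qualitative findings — predicted APHV rising with CA while its
within-group SD is compressed relative to observed APHV; predictions running
late for early maturers and early for late maturers near PHV; negative
Bland–Altman slopes in every CA group — are asserted as *signs* on
across-seed means over 20 default-scale cohorts (193 boys/199 girls each),
restricted to CA groups 8–18 (boys) / 8–16 (girls) with at least 20 visits
per cell; age jitter occasionally creates an out-of-range group of one or
two visits whose slope estimate is meaningless. The parameter-recovery check
uses 400 subjects with 0.3 cm stature noise; replicate-fit checks use 50
replicates of an 11-visit subject. These sizes give Monte-Carlo error
comfortably below the asserted margins while keeping the default suite fast.

## Reporting

Tables are written at 2 decimals (internal computation is full precision)
with a fixed float format and LF endings, so reruns under the same seed are
byte-identical. The JSON manifest records seed, config hash, version,
subject counts by sex and maturity class, and exclusion counts; it also
carries a wall-clock timestamp and is therefore identical across reruns
except for that one field. Exit codes: 0 success, 2 configuration error, 3
data error.

## Known limitations

* PB1 describes the adolescent spurt but has no mid-childhood growth
  component; fits to ages well below 8 y or above 18 y are out of scope.
* The simulator's mass and sitting-height models are pragmatic inventions;
  absolute Mirwald-equation biases on synthetic girls/boys should not be
  read as estimates of the equations' biases on any real population — only
  the directional/structural behaviour is claimed.
* Goodness-of-fit comparability with historical software implementations of
  PB1 is not asserted; loss, convergence criteria and starting values in
  decades-old analyses are unknown.
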