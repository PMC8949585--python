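# Methods

`walkir` implements a fitness–fatigue (Banister) impulse-response analysis
of walking performance in peripheral artery disease (PAD) rehabilitation:
quantification of a structured home walking program as daily training
impulses, prediction and per-subject calibration of walking performance,
method-agreement statistics, and a synthetic cohort generator that stands
in for the (non-public) patient data.

## Training-impulse quantification

A test-in/train-out (TiTo) prescription is two daily 10-minute sessions of
intermittent walking: `r` walk bouts of `walk_unit_min` minutes at a
metronome-controlled cadence, separated by equal rest bouts (1:1
walk:rest). A session's training impulse (TRIMP, arbitrary units) is the
product of

- **intensity** = prescribed cadence / habitual cadence (steps/min each,
  dimensionless) — the habitual cadence is counted during the first minute
  of the baseline 6-minute walk test;
- **density** = walking time / total elapsed time. The final bout has no
  trailing rest, so `r` bouts span `r·walk + (r−1)·rest` minutes
  (10 × 1-min walks with 1-min rests → 10/19 ≈ 0.53);
- **volume** = cadence × minutes per bout × bouts performed (total steps).

The canonical worked example (cadence 60 vs habitual 100, 10 × 1-min
bouts) gives 0.60 × (10/19) × 600 = 189.47… a.u. at full precision. A
presentation mode rounds intensity and density to two decimals and the
product to the nearest unit, reproducing the printed arithmetic
0.60 × 0.53 × 600 = 191 a.u. bit-for-bit; the pipeline itself always uses
full precision.

The daily load `w(t)` sums the session TRIMPs of each calendar day (two
sessions/day under the standard prescription); skipped sessions contribute
0 rather than being imputed. Partial adherence is modelled as a fraction
of repetitions, matching diary granularity (sessions done/skipped).

## Impulse-response model

Each subject is a first-order linear system with input `w(t)` and output
predicted performance `p(t)` in metres (pain-free walking distance, PFWD,
or total 6-minute distance, 6MWD):

    p(t) = p0 + k1 Σ_{i<t} w(i) e^{−(t−i)/τ1} − k2 Σ_{i<t} w(i) e^{−(t−i)/τ2}

- `p0` (m): baseline performance, pinned to the T0 measurement.
- `k1`, `k2` (a.u.): fitness/fatigue magnitudes per unit TRIMP, ≥ 0 by the
  physiological sign convention (training raises both components).
- `τ1`, `τ2` (days): decay constants; after τ days a component retains
  e⁻¹ ≈ 37 % of its value. The impulse response is implemented with the
  negative exponent `k·e^{−t/τ}` — the 37 %-decay definition forces it.
- The sum runs over days *strictly before* `t`: a day's training does not
  affect performance measured that same day (standard daily
  discretisation; the convolution is evaluated with a recursive
  exponential filter and verified against an O(T²) double loop).
- Days beyond the diary carry `w = 0`, giving the detraining extension.

Because fatigue usually decays faster (τ2 < τ1), performance keeps rising
briefly after training stops and then decays asymptotically to baseline.
`decay_to_baseline` operationalises "return to baseline" as the first day
(reported in weeks from cessation) at which the residual gain `p(t) − p0`
falls to a threshold fraction (default 5 %) of the peak post-training
gain; an exact return never occurs for an exponential decay, so the
threshold is a genuine modelling choice and is configurable. With `k2 = 0`
and a single impulse this reduces to the closed form `−τ1 ln(threshold)`
(≈ 3·τ1 at 5 %). At the published mean PFWD parameters driving a standard
27-week TiTo series the estimate is ≈ 24.6 weeks from cessation — the
post-cessation rise lasts ≈ 5 weeks and the 5 % point sits ≈ 19 weeks
(≈ 3·τ1/7) beyond the peak.

## Per-subject calibration

Subjects are measured at T0 and about four follow-up visits (scheduled at
weeks 5, 12, 20 and 28 ± the stated jitter). With so few points:

- `p0` is fixed at the measured T0 value rather than fitted, freeing one
  degree of freedom.
- For fixed (τ1, τ2) the model is linear in (k1, k2), so the RSS is
  profiled: a deterministic coarse grid over τ1 ∈ [10, 80] d, τ2 ∈ [5, 60]
  d (published cohort means ± ≥2 SD) in 2.5-d steps, with the magnitudes
  solved per grid point by bounded least squares 0 ≤ k ≤ k_max, followed
  by Nelder–Mead refinement of the decay constants (xatol 0.01 d, bounded
  to the same box; if refinement does not improve the grid optimum the
  grid point is kept).
- k_max (default 5 a.u., ~80 SD above the published magnitudes) exists
  because the two response columns become collinear as τ1 → τ2 and
  unbounded nonnegative least squares then returns enormous
  mutually-cancelling magnitudes; the bound removes only that degenerate
  ray.
- Grid ties are broken toward the smallest τ2, then the smallest τ1, so
  the fit is deterministic given its configuration.

Goodness of fit: R² = 1 − RSS/TSS over the post-baseline visits (T0 is
structurally exact and would inflate R²), and an ANOVA-style F test with
model df = 2 (the two magnitudes; the decay constants are treated as
profiled) and residual df = n − 3 — both configurable, since no canonical
df exists for this profiled design. A fit is *acceptable* when R² > 0.30.
With 4 free parameters against 4 post-baseline points the parameters are
only weakly identified; the reliable guarantee is prediction-level
recovery (visit-day predictions within 0.1 m on noiseless data), with
parameter-level recovery holding at the grid/refinement resolution when
the data are generated by the model itself.

## Agreement statistics

Measured and model-estimated values are pooled over subjects and visits
(T1–T4; at T0 the estimate equals the measurement by construction).
Pooling ignores within-subject correlation — a documented limitation of
the procedure being replicated.

- **Passing–Bablok regression**, implemented from first principles: the
  slope is the shifted median of all C(n,2) pairwise slopes (slopes of
  exactly −1 excluded; offset K = #{slopes < −1}, making the estimator
  symmetric in the two methods), the intercept is median(y − b·x).
  Confidence intervals use the asymptotic rank formula (not bootstrap, for
  determinism); linearity is assessed by a cusum test over residual signs
  referred to the Kolmogorov distribution.
- **ICC(A,1)** — two-way random effects, absolute agreement, single
  measure, the standard form for method comparison — from the ANOVA
  mean-square decomposition, with the McGraw–Wong F-based confidence
  interval. The form choice is a package decision (none is canonical for
  this analysis); the implementation is cross-checked against an
  independent implementation (pingouin) in the tests.
- **Paired t-test** (two-sided) for baseline vs end-of-treatment
  performance; identical vectors return t = 0, p = 1 by convention, and a
  constant non-zero difference (infinite t) raises a degenerate-data
  error.

## Synthetic cohort generator

The generator emulates the study design so every stage is testable
without patient data. Defaults (all configurable, YAML-serialisable):

- n = 100 subjects, 75 % male; baseline 6MWD ~ N(287, 85) m truncated at
  50 m; PFWD = 6MWD × fraction ~ N(0.40, 0.12) truncated to [0.05, 0.90]
  (matching the published PFWD 114 ± 61 m and guaranteeing PFWD ≤ 6MWD);
  habitual cadence ~ N(95, 15) steps/min truncated at 40 — the cadence
  distribution is not published, so cohort-level TRIMP magnitudes (the
  reported 276 → 601 a.u. progression) are emulated qualitatively
  (nondecreasing weekly load), not numerically.
- Program: 2 × 10-min sessions/day, 10 × 1-min bouts, 1-min rests, for
  round(N(27, 3)) weeks in [21, 33]; cadence starts at 60 % of habitual
  speed and rises 3 %/week to a per-subject cap ~ U(0.90, 1.00), rounded
  to integer steps/min. Sessions are independently skipped with
  probability 0.08 (92 % adherence), remaining in the diary with
  `performed_fraction = 0`.
- True model parameters per outcome from the published means/SDs
  (PFWD: k1 0.03 ± 0.06, k2 0.03 ± 0.06, τ1 45 ± 13 d, τ2 25 ± 10 d;
  6MWD: k1 0.02 ± 0.03, k2 0.03 ± 0.03, τ1 37 ± 11 d, τ2 26 ± 9 d) as
  truncated normals: magnitudes at ≥ 0, decay constants within the
  calibrator's identifiable search range. Because the published SDs are
  2–3× the means and only marginals are known, *independent* draws
  frequently produce subjects whose true PFWD collapses through zero or
  overtakes their 6MWD — trajectories no real claudicant cohort shows —
  so the draws are jointly rejection-sampled until
  0 < PFWD(t) < 6MWD(t) over the whole follow-up horizon
  (`enforce_plausibility`; the marginal-distribution tests switch it
  off). Note the zero-truncation raises the realised mean of k above the
  nominal value (N(0.03, 0.06) truncated at 0 has mean ≈ 0.055); tests
  compare against the analytic truncated-normal mean.
- Visits at weeks {0, 5, 12, 20, 28} with uniform jitter of ±{0, 1, 2, 2,
  3} weeks (≥ 7 days apart). The T0 measurement *is* the baseline test
  (no noise); follow-ups are true-model predictions plus i.i.d. N(0, 15 m)
  noise, clipped at 0 and at PFWD ≤ 6MWD.

What passing tests on this generator do **not** show: real diaries contain
structured (not i.i.d.) adherence lapses, real performance does not follow
the two-exponential model exactly, and measurement error is not Gaussian
homoscedastic. In particular, because the synthetic data come from the
fitted model family itself and the calibration has four free parameters
against four post-baseline points, noisy synthetic fits interpolate the
noise (median R² ≈ 1 at any noise SD); the intermediate R² values seen in
real cohorts arise from model misspecification that this generator
deliberately does not contain.

## Pipeline

`run_pipeline` orchestrates diary → TRIMP → fit → agreement → report for
a cohort read from the CSV dialects or generated synthetically (the
generator's files are a drop-in data source). Visit days are used as
recorded (actual ± jitter), not idealised weeks. Subjects failing the
R² > 0.30 rule stay in the agreement pooling by default (matching the
replicated procedure) and can be excluded by flag. Outputs: per-subject
fit reports and trajectory CSVs (day, trimp, fitness, fatigue,
predicted), cohort parameter summaries overall and by sex, an
actual-vs-estimated visit table, agreement JSON/CSV, and a manifest
(package version, config hash excluding the output path, seed). The same
configuration and seed give byte-identical outputs. `compare_subgroups`
performs per-parameter Welch t-tests between groups (e.g. sexes).

Problem sizes used by the test suite — 100-subject cohorts for the
end-to-end checks, 2000 draws for the law-of-large-numbers check, 200-day
series for the convolution oracle — were chosen to exercise the study's
scale while keeping each check comfortably fast.

## Known limitations

- Pooled agreement ignores repeated measures per subject.
- The fit is exactly identified (4 parameters, 4 residuals): parameter
  estimates on noisy data are unstable even when predictions are good;
  only prediction-level statements are robust.
- The decay-to-baseline estimate depends on the 5 % threshold choice; no
  canonical definition exists.
- The generator's habitual-speed distribution and PFWD/6MWD coupling are
  package choices, not published quantities.
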