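# Methods

## Problem setting

Serum cortisol follows a strong 24 h rhythm; salivary cortisol tracks the
free fraction at roughly a twentieth of the concentration.  When several
biomarkers with different half-lives are collected in one study, their
sampling grids rarely align, and downstream time-dependent analyses
(state-space models, neural sequence models, joint structural models)
often require equal-length series.  The framework implemented here asks:
how sparsely can a 24 h cortisol profile be sampled so that a polynomial
model fit to the sparse data, plus stochastic interpolation along that
model, still reproduces the dense profile and its clinical summary — the
24 h total output — without bias?

The pipeline operates per subject x condition x specimen profile:

1. **Downsampling.**  The densest collected grids are hourly serum (Q60,
   25 samples over 06:00-06:00) and two-hourly saliva (Q120, 13 samples);
   these are the *ground truth*.  Alternative grids are Q120 through Q360
   (every 2-6 h) and two intermittent clinical schedules INT1
   {0,2,4,8,14,24} h and INT2 {0,2,6,16,24} h.  Each grid caps the
   polynomial degree at its available degrees of freedom
   (6,6,5,4,3,3,3 for Q60...INT2), always leaving at least one residual
   degree of freedom.
2. **Polynomial validation.**  Ordinary least squares across degrees
   1..cap, with time affinely mapped to [-1,1] (a degree-6 Vandermonde
   in raw minutes is numerically unusable).  Fits are scored on
   themselves (R², RMSE) and against the ground-truth data.
3. **Stochastic interpolation.**  Missing target-grid times are filled
   with the fit's prediction plus a zero-mean Gaussian error truncated at
   ±1.96 residual sigmas.  One draw is one *iteration*; 100 iterations
   (each with its own seed derived from a master seed) give R² and RMSE
   distributions against the ground-truth model of the same degree; each
   distribution is summarised by its kernel-density mode (Gaussian
   kernel, Silverman bandwidth, 512-point grid spanning the data ±3
   bandwidths, ties toward the smaller value).  The iteration nearest the
   joint (R² peak, RMSE peak) after per-axis standardisation is the
   *optimal* iteration; only its seed needs storing to regenerate it
   bit-for-bit.
4. **Output and equivalence.**  24 h output is the trapezoidal integral
   of concentration over [0, 1440] minutes (a 7.5 ug/dl mean level gives
   ~10,800 ug*min/dl, matching the magnitudes this quantity is usually
   reported at; per-hour and plain-sum rules are available via
   `total_output(rule=...)`).  Interpolated outputs (from the regenerated
   optimal iteration) are compared with the ground-truth observed outputs
   by paired TOST on the log scale with equivalence region ±0.25 and
   alpha 0.05, reporting the 90% CI (the 1-2*alpha TOST convention),
   both one-sided p-values and Cohen's d = |mean(d)/sd(d)|.  Mean output
   differences across specimen and condition are tested with a two-way
   fixed-effects ANOVA (statsmodels OLS + anova_lm; interaction optional).

## Degree selection

The qualitative judgement "fit plateaus around degree d" is codified in
`select_optimal_degree` as the smallest degree d such that

* (a) the mean R²-vs-ground-truth gain from d to d+1 is below a plateau
  threshold (default **0.02**) — gains are computed within each scheme
  that supports both degrees and then averaged, so schemes with different
  degree caps never distort the comparison; and
* (b) the mean ensemble interpolation RMSE at d, normalised per scheme by
  that scheme's own minimum across degrees, is within a tolerance
  (default **10%**) of 1.

If no degree satisfies both, the degree with the lowest mean normalised
RMSE is returned with a warning.  The 10% RMSE band was chosen to be
commensurate with the replicate-to-replicate spread of the ensemble-RMSE
surface at the study's sample size (n = 8): a tighter band sits inside
Monte-Carlo noise and makes the rule unstable.  Both thresholds are
exposed in `RunConfig`.

## Error injection: reading and estimator

"Gaussian error within the 95% confidence interval of the residuals" is
implemented as a zero-mean Gaussian with sd equal to the fit's residual
spread, rejection-sampled until within ±1.96 sd (a truncated Gaussian,
whose sd is 0.8712 of the untruncated sigma).  Two alternative readings
are available behind `error_model`: uniform on the ±1.96 sd interval, and
truncation at the empirical 2.5/97.5% residual quantiles.

The residual spread defaults to the **residual standard error**
sqrt(SSres/(n-p)).  The plain sample sd (ddof=1) is available via
`residual_scale="sample"`, but it shrinks mechanically as parameters are
added (E[SSres] = (n-p) sigma²), which builds a spurious high-degree
advantage into the interpolation-RMSE surface; the RSE removes that bias
and is what a standard regression implementation reports as sigma.

Ensemble metrics are computed over the full target grid by default
(`metric_points="interpolated"` restricts them to the filled points), and
against the ground-truth *model* of the same degree
(`reference="data"` switches to ground-truth data).

## Synthetic cohort generator

No public data accompany the design being emulated, so the generator is
the test bed.  Per subject, a log-normal effect (log-sd 0.2, matching a
~20% between-subject CV in 24 h output) scales a deterministic circadian
curve; samples add a smooth ultradian fluctuation and iid assay noise.

* **Serum circadian shape**: mesor 7.5 ug/dl + 4.0 cos(2pi(t-120)/1440)
  + 1.3 cos(2pi(t-30)/720) — morning peak at 08:00, evening nadir,
  awakening/evening secondary structure.  The 12 h harmonic's amplitude
  and phase are set so that its quartic Legendre content cancels that of
  the phase-shifted fundamental: the noiseless curve is *cubic-dominant*
  (R² 0.90/0.98/0.98 at degrees 2/3/4), which is the regime in which
  degree-3 fits are the right stopping point for serum.
* **Saliva**: 0.06 x the same circadian shape evaluated 120 min later,
  i.e. the salivary peak sits at the 06:00 awakening.  This phase advance
  makes the saliva curve even about mid-window and hence
  *quadratic-dominant* (R² 0.94 at degree 2, gains < 0.01 beyond),
  reflecting the smoother, less complex trends salivary profiles show.
  The exercise transient is attenuated x0.3 in saliva.  Because of the
  phase advance, saliva is an exact fixed fraction of serum only when the
  advance is set to 0 (tested as such).
* **Exercise condition**: a Gaussian transient of height 5 ug/dl, sd 45
  min, centred at the 10:00 bout (t = 240).  Its 24 h AUC contribution
  (~560 ug*min/dl, ~5%) is small enough that the condition factor in the
  ANOVA stays non-significant, as expected for 24 h output.
* **Ultradian fluctuation**: amplitude 1.4 ug/dl (serum scale; x0.06 for
  saliva), period 240 min, phase drawn uniformly per profile.  Cortisol
  secretion is pulsatile; a smooth low-degree polynomial can capture none
  of a 6-cycle/day oscillation, so this term creates the irreducible
  residual floor that real profiles have.  Without it, polynomial fits
  chase iid noise ever more closely with degree, the interpolation-RMSE
  surface never plateaus, and no finite degree is "optimal" — a
  qualitatively wrong test bed.  The term is zero-mean over 24 h, so it
  does not bias AUCs.
* **Assay noise**: iid Gaussian, sd 0.4 ug/dl serum (~5% CV) and 0.03
  ug/dl saliva (~6% CV), in the range of commercial cortisol ELISAs.
  All sampled values are floored at zero (noise is additive Gaussian
  rather than log-normal so the residual distributions the error model
  assumes are symmetric).

Defaults were calibrated once, jointly, so that (i) 24 h outputs land at
the magnitudes such studies report (serum ~10,000-11,500, saliva
~500-700 ug*min/dl), (ii) the specimen contrast is overwhelming and the
condition contrast null in the ANOVA, and (iii) serum profiles plateau at
degree 3 and saliva at degree 2 under the selection rule.  (iii) is a
designed-in property of the generator, not an empirical finding: passing
recovery tests show the pipeline detects the structure the generator
plants, not that real cortisol is cubic/quadratic.

What the generator does *not* emulate: genuinely pulsatile (episodic
secretion + clearance) kinetics, autocorrelated or fractal noise,
binding-protein dynamics linking serum and saliva, assay floor/ceiling
effects, missing or irregular clinical timestamps.  Conclusions from
synthetic runs transfer to real data only insofar as real profiles are
"smooth trend + bounded symmetric residual".

## Numerical and API choices

* Time is integer minutes from the 06:00 admission start; grids are
  matched exactly (no tolerance) — all schemes are whole-hour.
* R² against zero-variance reference data is defined as 0 (with a
  warning) rather than NaN; it arises in degenerate synthetic tests.
* Least squares uses numpy.polynomial's SVD-based solver; tests verify
  coefficients against an independent normal-equations solve at 1e-8.
* Per-iteration seeds come from `SeedSequence((master_seed, i))`; one
  integer reproduces an entire run.  Ensemble inputs are checksummed so
  an optimal iteration can only be regenerated against the inputs that
  produced it.
* TOST with zero paired-difference spread degenerates to 0/1 p-values by
  the sign of the mean difference; Cohen's d is undefined (NaN) there.
* The ANOVA with literally zero output variation returns F = 0, p = 1
  for both factors (the formal 0/0 is resolved to the null outcome).

## Problem sizes

The default study replica is 8 subjects x 2 conditions x 2 specimens,
100-iteration ensembles for every alternative scheme x degree (592
ensembles per run, ~8 s on one core).  The stability analyses and the
recovery checks use 20 independently seeded replicas of that
configuration.  Demonstration scripts use the same sizes except where
noted in their headers.

## Known limitations

* The degree-selection thresholds are an explicit operationalisation of
  a qualitative judgement; other defensible rules (AIC/BIC, nested-F)
  exist and were deliberately not used, since the framework under study
  selects via its R²/RMSE/peak-density surfaces.
* Whether ensemble RMSE should be scored on the full grid or only the
  interpolated points, and whether KDE peaks should be pooled across
  subjects, are under-determined by the framework's description; the
  defaults (full grid, per-profile peaks) are flags, not claims.
* Equivalence is tested per scheme x condition x degree without
  multiplicity correction, mirroring the framework being replicated.
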