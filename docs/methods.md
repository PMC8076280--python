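# Methods

## Study design being modeled

The package analyzes a paired two-session design: each subject is measured
once under natural conditions (baseline) and once after drinking to a breath
alcohol content of 0.40 mg/l (aAC), the legal driving limit in many
countries (BAC = 2 × BrAC, so 0.8 g/l).  The measurement battery comprises a
visual arm (visual acuity, far/near stereoacuity, phorias, fusional
reserves, vergence facility, AC/A ratios, Sheard/Percival criteria) and a
driving arm (per-section mean speed, speed SD, SDLP, lane-excursion
distances, brake reaction time, event counts) on a 12.5 km simulated
itinerary with three sections: a 4.5 km dual carriageway, a 6 km two-lane
mountain road and a 2 km inner-city circuit.

Impairment is always the signed difference aAC − baseline.  The quantity of
scientific interest is whether overall visual deterioration (OVDS) predicts
overall driving deterioration (ODPDS) across subjects.

## Clinical metrics

* **Sign conventions.** Esophoria positive, exophoria negative; right
  hyperphoria positive.  Reserve magnitudes are stored unsigned with the
  side carried by the field name (`nfv_`/`pfv_`/`vfv_`), which avoids
  double-negation mistakes when mirroring exams.
* **AC/A.** Calculated AC/A = (15 − distance phoria + near phoria)/2.5 in
  Δ/D.  The constant 15 Δ is the near convergence demand implied by a 6 cm
  interpupillary distance at 40 cm; the formula is applied as printed, with
  no per-subject PD adjustment.  Gradient AC/A is the absolute phoria change
  through a −1.00 D lens at near.
* **Sheard.** Value = |phoria| − opposing reserve/2; the opposing reserve is
  PFV for exophoria, NFV for esophoria, and (our choice, the conservative
  one — the convention for orthophoric subjects is not standardized) the
  smaller of the two reserves at exactly zero phoria.  The reserve point is
  the blur point when recorded, otherwise the break, which is standard
  clinical practice.  Sheard's prism-prescription form (2·|phoria| −
  reserve)/3 is available behind a flag; both forms are negative exactly
  when the comfort rule is met.
* **Percival.** Value = G/3 − 2L/3 with G/L the greater/lesser lateral
  reserve point; symmetric in the two reserves by construction.
* **Vergence facility.** The 10–15 cpm normal range is treated as a closed
  interval; printed boundary values therefore classify as normal.
* **Criterion boundary.** A criterion value of exactly 0 is reported as
  *not* compensated (strict negativity required).

## Driving metrics

Traces are uniform-in-time samples of (t, cumulative path distance, speed,
signed lateral offset, section label).  All SDs are sample SDs (n − 1),
matching standard SDLP practice.  Lane-excursion geometry models the
vehicle as a width interval around the lateral offset: a sample invades a
side when |offset| + vehicle half-width > lane half-width on that side
(defaults: 3.5 m lane, 1.8 m vehicle, 10 Hz sampling — the simulator's
actual values are not published, so these are config parameters).  Distance
accumulates by a piecewise-constant rule: an inter-sample interval counts
fully iff its *starting* sample is in the invasion state, with no
sub-sample interpolation.  The rule makes TDTOL = DTIS + DTIOL an exact
identity and lets the trace generator construct targets exactly.  Section
membership comes from the trace's labels, not from path-distance
thresholds, so metrics survive itinerary edits.

Reaction-time matching: each brake-light onset is matched to the first
unconsumed brake press falling after it and before the next onset; presses
are consumed (never answer two onsets), unmatched onsets are recorded as
missed and excluded from the mean, and presses preceding the first onset are
ignored with a warning.

## Composite scores

Each variable's impairment column is z-scored against the cohort (n − 1 SD),
multiplied by its worsening direction, and averaged with equal weights per
subject.  Directions: decreases are worse for visual acuity, fusional
reserves and vergence facility (−1); increases are worse for stereoacuity,
|phoria|, and all driving variables (+1).  Phorias enter through the change
in |phoria| (movement away from orthophoria is deterioration regardless of
side).  The default component sets are: OVDS — VA, far/near stereoacuity,
four phorias, four horizontal break points, two vertical break points,
vergence facility (14 variables); ODPDS — all 16 driving variables.  The
published variable list names groups rather than exact columns, so the
mapping (break points rather than blur/recovery; both distances for
stereoacuity and phoria) is this package's declared choice and is
config-visible rather than inferred.  Zero-variance columns are excluded
with a warning; subjects missing more than half the components are flagged;
cohort means of every aligned column and of the composite are zero by
construction (asserted to 1e−9).

## Statistical battery

Paired differences are gated by a Kolmogorov–Smirnov normality check with
estimated mean/SD.  Because estimating the parameters makes the plain KS
p-value anti-conservative, the Lilliefors-corrected variant (statsmodels) is
the default; a flag restores the plain KS.  Normal → two-sided paired t;
non-normal → Wilcoxon signed-rank (zeros dropped, exact null for n ≤ 25
without tied magnitudes, else normal approximation with continuity
correction).  The Z statistic of the approximation is reported for the
Wilcoxon branch alongside df = n − 1; df is design metadata for a paired
sample rather than a property of the rank test.  Holm–Bonferroni adjustment
is computed by the step-down running-maximum formula with strict rejection
(p_adj < α); the default family structure is one family per results-table
arm (visual, driving), with a global option — the published analysis does
not state its family definition, so this is a declared assumption.
α = 0.05 throughout.  The OVDS–ODPDS association uses Spearman's ρ
(average ranks for ties, two-sided p), with a sensitivity mechanism that
re-computes after excluding listed points (the pipeline maps an (ovds,
odpds) coordinate to the nearest subject).

## Synthetic cohort generator

The generator is the package's stand-in for the study's deposited data and
defines the conditions under which everything is tested.

* **Margins.** Every variable reproduces the reference group mean ± SD per
  condition.  Signed variables are plain normal.  Non-negative variables use
  a rectified normal max(N(µ*, σ*), 0) and counts a rounded rectified
  normal, where (µ*, σ*) are solved numerically so the *transformed* draw
  has exactly the target mean and SD.  Without this correction, rectifying
  e.g. collisions (4.3 ± 3.7) would inflate the group mean by ≈ 0.8 and the
  generator would not recover the published impairments.  Signaling
  mistakes at baseline (0.0 ± 0.0) are an exact constant.
* **Pairing.** Baseline and aAC standard-normal scores share a Gaussian
  copula with within-subject correlation r (default 0.6; the study reports
  no subject-level covariance, so r is a free design parameter, not an
  estimate).
* **Coupling.** One latent severity factor per domain (visual, driving),
  correlated by κ, enters each aAC score with loading weight w = 0.3 in the
  variable's worsening direction.  The aAC margin stays exactly standard
  normal for any (r, w, κ).  κ = 0.55 was calibrated once, by a
  200 000-subject simulation, so the population OVDS–ODPDS Spearman
  correlation is ≈ 0.4 — the association magnitude the pipeline is meant to
  detect.  κ = 0 gives exactly independent composites and is used for
  type-I-error calibration.
* **TDTOL** is generated as the per-subject sum DTIS + DTIOL, making the
  additivity identity hold subject-wise; its SD is consequently implied
  rather than matched.
* **Traces.** Lateral offset is a stationary AR(1) (autocorrelation 0.95 at
  10 Hz) clipped just inside the lane boundary and rescaled (Brent solve)
  so the section's sample SD equals the target SDLP exactly; excursion
  episodes are injected as fixed offsets beyond the boundary over interval
  windows whose path increments are trimmed so the piecewise-constant rule
  returns DTIS/DTIOL exactly; speed is target mean + AR(1) noise
  standardized to the target SD (clipped at zero with a warning for
  extreme targets); brake onsets are spaced through the mountain section
  with presses at onset + requested reaction time.  Infeasible targets
  (excursions exceeding the section, SDLP unreachable under the clip)
  raise rather than silently approximating.
* **Dosing.** Classic Widmark: grams = BAC · r · weight with r = 0.68 l/kg
  (male) / 0.55 (female), BAC from the 2:1 BAC/BrAC ratio.  No elimination
  term is included; refined variants can be layered on top.

What the generator does *not* emulate: learning effects across sessions,
pharmacokinetic BrAC time courses, non-Gaussian tails and floor/ceiling
effects of clinical tests, demographic structure beyond n, correlations
between specific variable pairs beyond the single latent factor, and the
actual simulator's vehicle dynamics.  Passing tests therefore demonstrate
that the analysis machinery is correct and calibrated under a faithful
moment-level emulation — not that the published subject-level data would
yield identical statistics.

Variables whose group statistics were published only graphically (phorias,
horizontal fusional reserves) use text-reported shifts where available and
otherwise clinically typical values (Morgan's norms) as defaults; they are
flagged `published=False` in `vergedrive.reference` and are never used as
reproduction targets.

## Numerical choices and problem sizes

* Margin solver: least-squares on (µ, log σ) to 1e−14 tolerances, cached;
  residuals above 1e−6 raise.
* SDLP rescaling: Brent root-finding to 1e−12 on the scale factor.
* Composite tolerance: cohort means asserted to 1e−9.
* Monte-Carlo problem sizes used by the test suite and acceptance script:
  2000 null cohorts for type-I calibration (rates checked within two
  binomial SEs of 5%), 500 cohorts for power and parameter recovery
  (recovery checked within 3 MC SEs per variable), 200 cohorts for the
  correlation distribution (median ρ), 200 000 subjects for the one-off
  coupling calibration.

## Known limitations

* The Wilcoxon "Z with df = n − 1" is reported metadata, not a claim that
  the rank test has those degrees of freedom.
* The Sheard/Percival reserve-point choice (blur when present, else break)
  and the composite sub-measure mapping are declared conventions; studies
  that used different conventions will differ at the margins.
* Count margins match two moments, not full distributions; rare-event tail
  behavior (e.g. collision bursts) is not modeled.
* The trace generator's mountain-road speed targets at the published SD
  (21.4 km/h at mean 55.5) imply occasional clipping at 0 km/h, slightly
  shrinking the realized speed SD; SDLP and excursion targets are exact.
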