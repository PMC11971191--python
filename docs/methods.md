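# Methods

`tauseed` re-implements, as a tested and reusable pipeline, the
quantitative core of a study design built around early tau multimers:
seed-amplification (RT-QuIC) kinetics, proximity-ligation-assay (tau-PLA)
and AT8-IHC particle quantification, confidence-interval-based cohort
stratification, biosensor inclusion scoring, GFAP burden, and the
group-comparison statistics.  Because no real measurement data are
distributed with the package, a first-class synthetic-data module
generates every input with known ground truth; this note records the
models, the defaults and the reasoning behind every genuinely open design
choice.

## RT-QuIC kinetics

Each well of a seeded-aggregation assay is a ThT fluorescence time series
read every 15 min (0.25 h).  Four parameters summarise a well, all
computed on the reads at or before the assay cut-off (`cutoff_h`, default
52 h, the reproducible endpoint before spontaneous aggregation of the
substrate in negative-control wells):

* **F_max** — the maximum fluorescence in the retained window.
* **Lag time** — the first read strictly exceeding
  `mean(baseline) + n_sd * SD(baseline)` with `n_sd = 5`.  The baseline is
  the first `baseline_n_reads` reads; the SD is the sample SD (n−1).  The
  reported lag is the read time itself — no sub-interval interpolation,
  because 15 min is the instrument's native granularity.
* **Time to F_max** — the time of *first* attainment of the maximum
  (deterministic tie-break; a plateau reports when it is reached).
* **V_max** — the maximum slope over sliding least-squares windows of
  `slope_window` consecutive reads.

Wells that never cross the threshold (or whose maximum sits at the end of
the window) are right-censored; the censored value is substituted by the
cut-off itself, exactly 52 h, and censored wells enter replicate means and
group statistics at that value.  A configuration flag per summary table
(`lag_censored`, `t_fmax_censored`) makes sensitivity analyses that
exclude censored wells straightforward.

Two numerical defaults deviate from the most naive choices, for reasons
worth recording:

* **Baseline window = 20 reads (5 h), not 10.**  The 5·SD threshold uses
  an *estimated* SD.  Monte Carlo on iid Gaussian read noise shows that
  with a 10-read baseline a perfectly flat well falsely crosses its own
  threshold about 4% of the time over a 52-h trace (the sample SD of 10
  draws has a heavy low tail); 20 reads reduce this to under 1%.  Five
  hours still precede the earliest seeded lag under all default study
  conditions.  This residual false-crossing rate is an irreducible
  property of an estimated-SD threshold on unbounded noise: the package
  reports the censored fraction of negative-control wells rather than
  promising it is exactly 100%.
* **Slope window = 5 reads (1 h), not 2.**  The raw pairwise finite
  difference amplifies read noise by 1/Δt: with noise SD 40 a.u. the
  maximum "slope" of a *flat* well would be ≈ 600 a.u./h, larger than the
  true maximum slope (k·A/4 ≈ 390 a.u./h) of a genuinely seeded well.  A
  five-read least-squares window cuts the slope noise about four-fold
  while a growth phase lasting several hours remains well resolved.  Both
  parameters are configurable (`AssayConfig`), and a window of 2
  reproduces the textbook finite-difference estimator exactly.

On noise-free logistic curves the extracted lag agrees with the
closed-form crossing time to within one read interval and V_max agrees
with k·A/4 to within 2% at dense sampling; the test suite and
`scripts/acceptance.py` recompute both.

## Synthetic data: what it emulates, and what it does not

**Curves.**  A 4-parameter logistic with additive iid Gaussian read noise,
`F(t) = f0 + A/(1+exp(−k(t−t_half))) + ε`, sampled on the 15-min grid to
60 h.  It is the simplest shape with distinct lag/growth/plateau phases
whose threshold crossing has a closed form — the analytic lag oracle
`t* = t_half − ln(A/(θ−f0) − 1)/k`.  Samples draw `t_half`, `k`, `A` once
from truncated-normal between-sample distributions; triplicate wells share
the sample draw and differ only in read noise, mimicking per-case
triplicates.  The model deliberately ignores substrate chemistry, shaking
cycles, dilution-dependent kinetics and spectral effects.

**Default study conditions** (6/5/5 cohort plus controls): the
Double-Negative group has `t_half ~ N(60, 6)` truncated at 50 h, so most
wells censor at 52 h and the rest cross late — slow residual seeding, not
a hard zero.  Intermediate (`t_half ~ N(14, 2)`) and Double-Positive
(`N(17, 2.5)`) seed within hours with a common rate `k ~ N(0.6, 0.08)` and
amplitudes ≈ N(2500, 400), so their F_max and V_max distributions overlap
heavily — by design, since the study found those two groups statistically
indistinguishable on V_max.  The negative control (half-rise 58–70 h,
centred at 63 h) aggregates only spontaneously, with its analytic crossing
always after the 52-h cut-off but usually inside the 60-h recording; the
positive control half-rises at ≈ 8 h — late enough not to contaminate its
own 5-h baseline window, yet the fastest condition on the plate.

**Histology fields.**  16-bit single-channel images, Gaussian background,
bright objects rasterised as *digital* disks (diffuse class, area uniform
in 1.5–3.5 µm²) and digital ellipses with axis ratio 1–2 (perikaryal
class, 12.5–100 µm²).  An object's pixel set is the exact `n` nearest grid
points to a subpixel centre in the (elliptical) metric, so the realised
pixel area equals the requested area to within one pixel-area and always
lies inside the class window.  Rejection-sampled placement keeps
foreground components from touching (centre distance ≥ sum of effective
radii + 2 px), so connected-component counting recovers the generating
counts *exactly* — which is what makes the recovery tests sharp.  Real
DAB/hematoxylin scans have overlapping lesions, uneven illumination and
chromogen bleed-through; passing these tests therefore demonstrates
correctness of the counting/classification logic, not robustness to real
stain variability.

**Biosensor fields.**  Two channels: cell bodies as well-separated disks
(radius 6–9 px) in channel 0; inclusion puncta as bright 3×3 squares
inside exactly `round(n_cells · fraction)` cells in channel 1.  Real
fields have confluent cells (merged components count as one — a
documented limitation), autofluorescence and out-of-focus puncta.

**Determinism.**  Every generator call takes one integer seed; derived
seeds come from `numpy` `SeedSequence` spawning.  Identical seeds give
byte-identical CSV/TSV/TIFF outputs.

## Particle quantification

Foreground is `intensity > threshold`; particles are 8-connected
components (the default behaviour of the common particle-analysis tools),
converted to µm² via the pixel size.  Size windows are *closed* intervals
— a particle of exactly 12.5 µm² is perikaryal — because the printed
ranges carry no open/closed notation and closure keeps both boundaries
attributable.  Particles outside both windows are tallied as `other` and
excluded from pathology counts.  Border-touching particles are kept.
Thresholding is a fixed intensity by default (the synthetic generator's
contrast is known); Otsu's method is offered for real scans and refuses
degenerate single-population images rather than guessing.  GFAP burden is
`100 · stained area / ROI area`, validated to stay in [0, 100].

## Stratification

Positivity cut-offs are upper limits of the two-sided 99% confidence
interval of reference (Braak 0) counts, `x̄ + t_{(1+c)/2, n−1} · s/√n`
with the sample SD; the AT8 cut-off is additionally rounded *up* to a
whole number, the tau-PLA cut-off is not.  The two-sided quantile is used
because the interval is written as `x̄ ± t(σ/√n)` — its upper limit is
what defines positivity.  Positivity is strict (`>`).  The label map is
(PLA−, AT8−) → Double-Negative, (+,−) → Intermediate, (+,+) →
Double-Positive; the (−,+) cell falls outside the scheme's intended design
and is labelled Atypical with a warning, never silently binned.  Under the
default generator conditions the derived AT8 cut-off is 1 particle in the
median cohort and stratification recovers the generating label for ≈ 98%
of samples; the residual errors are reference-group samples whose own
count sits above the derived cut-off (inevitable: the cut-off is only
≈ 1.65 reference SDs above the reference mean).

## Group statistics

One-way ANOVA omnibus plus either Dunnett's many-to-one comparisons
(against a designated control group) or Bonferroni-adjusted all-pairwise
equal-variance t tests (adjusted p = min(1, k·p)).  Dunnett p-values come
from `scipy`'s multivariate-t implementation, cross-checked in the test
suite against R `multcomp` on a frozen fixture; the randomised integration
stream is internally seeded so results are reproducible to ≈ 1e-4.  The
two-way design (groups × treatment conditions with a control condition)
reports the condition main effect from a two-factor ANOVA and then runs
Dunnett comparisons *within each group* against the control condition;
the reference implementation the study used does not state its error
term, and the within-group form keeps each family's error rate
interpretable.  No Welch correction anywhere, matching the equal-variance
conventions of the original analyses.  Under the null, the Dunnett
family-wise false-positive rate measures ≈ 0.05–0.06 over 1000
simulations (3 groups, n = 6).

## End-to-end cohort run

`run_cohort` chains plate simulation → histology simulation and
quantification (3 fields per sample and stain; tau-PLA fields carry both
object classes, AT8 fields only perikaryal lesions) → CI stratification →
kinetics with censoring → biosensor scoring → statistics, writing
`plate.csv`, `samples.tsv`, `groups.tsv`, `thresholds.json`,
`kinetics(.wells).tsv`, `fret.tsv`, `stats.tsv`, a plain-text report and a
provenance record (configuration, its hash, seed, library versions).
Every table carries the configuration hash in a `#` header line, and a
re-run with the same configuration is byte-identical.  Problem sizes per
run — 54 wells × 241 reads, 96 histology fields of 384² px, 16 biosensor
fields of 120 cells — keep a full run in a few seconds on one core.

## Known limitations

* The iid Gaussian read-noise model makes a ~1%-per-well false threshold
  crossing of flat wells unavoidable (see above); real plate-reader noise
  is temporally correlated and bounded, which the generator does not
  model.
* Cell detection merges confluent cells; inclusion scoring is
  threshold-based, not a FRET-ratio computation.
* The two Dunnett variants share scipy's integration accuracy (~1e-4);
  p-values that close to 0.05 should not be over-interpreted.
* Semi-quantitative visual scoring, Braak staging, and all wet-lab and
  sequencing analyses are out of scope.
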