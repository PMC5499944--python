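# Methods

This note documents the models, parameter choices and numerical
conventions behind `recortex`, in the spirit of the methods documentation
of simulation-backed analysis packages.

## Synthetic-data model

The package analyses a study design with no deposited raw data, so the
generators in `recortex.synthetic` emulate the statistical structure each
analysis assumes.  They are the study conditions, not tuning knobs: their
defaults encode the published design (group sizes, trial counts, stimulus
rates) and the published group statistics, and the test suite measures the
pipeline against them.

**Anesthetized tactile sessions.**  Background spiking is homogeneous
Poisson (default 5 Hz — a typical infragranular cortical rate under light
barbiturate anesthesia).  Stimuli are 100 taps at 0.5 Hz per skin site.  A
responsive neuron receives, per stimulus, `Poisson(magnitude)` extra spikes
placed uniformly in a boxcar window (default 8–38 ms post-stimulus).  The
boxcar was chosen because its integral *is* the spikes/stimulus magnitude,
which makes the magnitude estimator analytically checkable; real evoked
responses have sharper onsets and longer tails, so detector power measured
here need not transfer exactly to real data.  Trial-to-trial refractoriness
and adaptation are ignored (pure Poisson), matching the detector, which
does not model them either.

**Awake treadmill sessions.**  An inhomogeneous Poisson train with rate
`background × (1 + depth · k(t))`, simulated by thinning.  The kernel
`k` sums a Gaussian bump per footfall — FWHM = `modulation_width`
(default 100 ms), centered `modulation_latency` ms after the footfall —
and is capped at 1 so the rate never exceeds the thinning bound
`background × (1 + depth)`.  A Gaussian was chosen over a boxcar here
because peri-footfall modulation in cortex is smooth and the detector's
smoothed-PSTH peak estimate should be exercised on a smooth peak.
Footfalls are quasi-periodic (even grid ±20% jitter; default 300 footfalls
in a 600 s recording, i.e. a 0.5 Hz step cadence over a 10-minute session).

**Behavioral cohorts.**  Per-(group, week) values for %WSS, open-field BBB
score and normalized failure point are drawn from a normal distribution
*censored* (clipped) to the measure's hard bounds (%WSS and failure point
in [0, 100], BBB in [0, 21]), with the parent mean and SD solved
numerically so the censored distribution has exactly the configured
moments.  Censoring rather than renormalized truncation is deliberate:
group statistics of the week-4 %WSS kind (mean 1.6, SD 4.3) have a
coefficient of variation above 1, which no truncated normal near a bound
can attain, while a censored normal can — and censoring reproduces the
floor effect of real cohorts, where many animals score exactly 0.  The
moment solver (`scipy.optimize.root` on the closed-form censored moments,
residual tolerance 1e−8) raises a parameter error for infeasible
mean/SD/bounds combinations.

Group-week means default to the published group statistics where printed
(week-4 %WSS 1.6 ± 4.3 for all groups; week-12 %WSS 19.4 ± 17.8 /
12.3 ± 15.4 / 1.6 ± 2.9 for complete / partial / sham therapy; week-2 BBB
6.5 ± 1.3 / 5.7 ± 2.0 / 5.2 ± 2.4).  Cells not printed numerically
(week-8 %WSS, later BBB weeks, the failure-point trajectory, axon-count
rates, motor-map label probabilities) were fixed once at values consistent
with the described patterns — a roughly ten-fold %WSS rise from week 4 to 8
under therapy, failure points declining to 55–65% of the week-2 assisted
support by week 12 under therapy and staying near 95% under sham, a
T1 < T4 < T7 rostro-caudal axon gradient with naive < sham < complete
therapy ordering, and a trunk-representation probability rising from 0.12
(sham) to 0.38 (complete therapy) — and are not adjusted thereafter.

The design's missingness is reproduced exactly: 14 sham animals (one
death), two partial-therapy animals without week-8 treadmill data
(listwise-dropped from the %WSS mixed ANOVA, leaving n = 42),
failure-point data in a 12/12/15 subset (n = 39), and motor maps in a
10/12/14 subset (n = 36).  These sizes give the split-plot interaction df
pairs (4, 78), (6, 123), (4, 72) and (4, 66), and the week-2 one-way df
(2, 41), which the validation suite asserts.

The per-animal trunk-area covariate is coupled to week-12 %WSS by
regressing on the empirically standardized behavioral score plus
independent Gaussian noise, which makes the expected Pearson correlation
equal the configured value without attenuation from the bounded behavioral
scale (default r = 0.41, the study's reported map–%WSS correlation).

**BBB scale.**  Generated BBB values are continuous by default; a
`round_half` option snaps them to the 0.5-point rubric.  The continuous
default keeps the generator's moment calibration exact; strict half-point
validation (`validate_bbb_scale(..., strict=True)`) is intended for
externally supplied score tables.

## Detector conventions

**Binning.**  PSTH bins are left-closed, right-open, with time zero at the
event; a spike exactly at the event time falls in the first post-stimulus
bin.  Binning uses `floor((t − left)/binsize)`, so the convention is exact,
not subject to histogram edge rules.

**Sensory classifier.**  The background SD is the population SD (ddof 0)
across the 95 background bins of the trial-summed PSTH — a single
per-neuron background statistic.  The three-bins criterion counts *any*
three suprathreshold post-stimulus bins (no consecutiveness requirement;
the awake detector, by contrast, explicitly requires a consecutive run —
each section's rule is followed to the letter, and criterion (a) is
subsumed by (b) under this reading).  The t-test of criterion (c) compares
per-trial spike rates (spikes/ms) in the onset–offset window against
per-trial background-window rates: an unpaired two-sided test with 100
trials per side, significant at p < 0.001 with the response mean above the
background mean.  If both samples have zero variance the t-statistic is
undefined; the classifier then requires the response rate to strictly
exceed background in every trial.  A neuron with zero background mean and
SD has threshold 0, so any post-stimulus spike is suprathreshold and the
t-test (or its fallback) alone governs.  Response magnitudes are computed
for every neuron, significant or not; percent-responding counts
significance on ≥1 of the seven contralateral forelimb sites only.

**Locomotor detector.**  The "99% confidence interval above the mean
firing rate" is implemented as the Poisson upper bound
`μ + z·√(μ/n)` on the trial-averaged per-bin count, with z = 2.5758 (the
0.995 normal quantile, i.e. the upper limit of a two-sided 99% CI) and μ
derived from the whole-recording rate — the only confidence construction
available from a single rate estimate.  The threshold comparison runs on
the smoothed PSTH (switchable to unsmoothed via `use_smoothed=False`); the
peak is the maximal suprathreshold smoothed bin with ties broken to the
earliest bin (determinism); the extent is the maximal consecutive
suprathreshold run containing the peak; the response rate always comes
from the unsmoothed counts over that extent.  The zero-phase smoother is a
length-five moving average applied forward then backward with
replicate-padded edges (unit DC gain at the boundaries, no peak shift).

**Motor maps.**  Sites are snapped to the nearest 0.5 mm cell center with
a 0.25 mm out-of-bounds tolerance; exact midpoints break toward the
smaller (AP, then ML) index.  AP is stored posterior-positive, so −0.5
means 0.5 mm rostral to bregma (the study's two sign conventions are
reconciled this way once).  Multiple penetrations in one cell collapse to
a single dominant label — the responsive movement with the lowest
threshold — before areas are counted; heatmap cells average all responsive
penetration thresholds and are missing (never zero) where no penetration
evoked movement.

**Axon densities.**  Density is count per mm² of *sampled* gray matter by
default; `per_roi=True` refers counts to the full region of interest, of
which the stereological scheme samples 50%.  Both variants are exposed
because "counts per area per slice" is ambiguous between the two.

## Statistical layer

Mixed (split-plot) ANOVA is computed by pingouin with sphericity
correction off, reporting the classical uncorrected df that the split-plot
design implies (a Greenhouse–Geisser correction can be applied downstream).
Factorial ANOVA uses statsmodels OLS with Type II sums of squares —
appropriate for the unbalanced group sizes here absent any
interaction-priority convention; saturated designs (error df ≤ 0) are
reported with their df structure and flagged rather than fitted.  The
binomial-GLM interaction is a joint Wald χ² on the (a−1)(b−1) interaction
coefficients of a logit model with neurons as samples; complete separation
(non-convergence or coefficients beyond ±15 on the logit scale) triggers a
ridge-penalized Newton fit (λ = 1e−4) whose penalized covariance feeds the
Wald statistic, flagged `separation=True`.  The robust correlation line is
an IRLS Tukey-biweight fit (c = 4.685, tolerance 1e−8, ≤100 iterations)
alongside the Pearson r.  An optional square-root transform is applied to
the dependent variable before any ANOVA fit when normality or
homoscedasticity demands it; results equal a fit on the pre-transformed
values exactly.

A note on one published statistic: a three-way ANOVA on 44 step-quality
observations with 2×2×2 cells has error df 36 under any standard full
factorial, not the (1, 40) a report of that design might show; the module
implements the generic factorial and documents the discrepancy rather than
matching it silently.

## Problem sizes and runtime

The validation suite measures detector operating characteristics at 1,000
null neurons (false positives), 200 neurons (power and latency recovery),
5,000-replicate nulls for type-I calibration of each test, 1,000 replicate
cohorts for moment calibration and 500 for correlation recovery; the
default end-to-end pipeline run uses 200 neurons per therapy × week cell
and completes in well under a minute per experiment on one CPU.  These
sizes keep every standard error small relative to the asserted tolerances.

## Known limitations

* Poisson spiking without refractoriness, bursting or correlated noise;
  detector calibration on real recordings may differ.
* The locomotor generator's Gaussian modulation kernel is an idealization;
  multi-phasic peri-footfall responses are only represented through the
  two-subpopulation latency configuration used in testing.
* Behavioral measures are generated independently across weeks (no
  within-animal autocorrelation); the mixed-ANOVA df structure is
  unaffected, but variance components of real longitudinal data are not
  emulated.
* The step-log generator draws criterion flags independently per paw for
  unsupported cycles; real failure modes are correlated across criteria.
* Manual scoring processes (video annotation, axon counting) are modeled
  only through their output tables.
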