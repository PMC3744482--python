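# Methods

## Dynamic complexity

Daily process ratings are short, bounded, ordinal time series; classical
variance-based instability measures conflate level, trend and noise.
Dynamic complexity targets *critical instability*: it is high when a
signal both moves a lot (fast, large direction changes) and explores much
of its theoretically possible range.

For a window `x_1..x_m` on an item with declared range `R`:

**Fluctuation intensity.** The window is segmented into maximal monotone
runs delimited by strict direction reversals. Each run contributes its
amplitude divided by its duration (in steps), and

    F = Σ_k (a_k / d_k) / (R · (m − 1)).

The normaliser is the steepest realisable configuration (a full-range
reversal at every step), so `F ∈ [0, 1]`, `F = 0` iff the window is
constant, and `F = 1` for the full-range zig-zag. Plateaus (equal
consecutive values) extend the current run rather than ending it; a run
ends only at a strict reversal, with the turning point placed at the last
extremal value. This keeps `F` continuous in the data and zero for
constant signals. One consequence worth stating plainly: time-reversing a
window leaves `F` unchanged *except* when a plateau sits exactly at a
reversal, where the last-extremal convention is direction-sensitive; the
property test for reversal symmetry therefore draws tie-free windows.

**Distribution degree.** Sort the window ascending as `y_1..y_m`. Under
perfectly even coverage of the range, a span of `c` sorted steps would
cover `I_c = c·R/(m−1)`. Deviations are accumulated over *all* spans
(every width `c = 1..m−1`, every start), counting only shortfalls
(under-dispersion):

    D = 1 − Σ max(0, I_c − (y_{a+c} − y_a)) / Σ I_c.

This makes the two closed-form limits exact: `D = 1` for an evenly spread
full-range window and `D = 0` when all values coincide. An
adjacent-spans-only variant (`spans="adjacent"`, width-1 gaps only) is
available for sensitivity analyses; all defaults use the all-spans form.

**Composite.** `C = F·D ∈ [0, 1]`, computed per item on a right-aligned
7-day window and stamped on the window's last day, so a peak summarises
the week *ending* on that day and never uses future data — critical
fluctuations can then be read as preceding the change they announce. The
item-averaged curve uses an unweighted mean: `C` is already
range-normalised per item, which makes 7-point Likert and visual-analogue
items commensurable without rescaling.

Implementation is checked against an independent naive re-implementation
(explicit run segmentation; double loop over all sorted spans) to 1e-12 on
random windows, mixed continuous and grid-rounded.

## Transition detection and interval labels

The day of maximal item-averaged complexity is always a transition (ties
break to the earliest day: earlier instability is the theoretically
meaningful event). Additional local maxima are accepted, in decreasing
height, if they reach at least `secondary_fraction = 0.9` of the global
peak and lie at least `min_separation = 14` days from every accepted
transition. Both knobs are exposed: no principled criterion for "a second
maximum" exists in this literature, so the defaults are deliberate,
logged, and configurable.

Interval labelling uses the half-open convention: a transition at day `t`
labels interval `k` as OT when `scan_k < t ≤ scan_{k+1}`. Transitions
before the first or after the last scan snap to the nearest interval
(scans are scheduled *near* transitions, not exactly on them). Two
transitions in one interval collapse to a single OT with a warning.
Controls carry no diary, hence every control interval is ISI.

## ROI panel analysis

Activation enters as significant-voxel counts per subject × scan × ROI
over a fixed ordered set of eight regions (CC/SMA, DLPFC r/l, Insula r/l,
Parietal r/l, Cuneus). Two derived quantities:

- **Inter-scan change** is the absolute difference `|Δ|` between bounding
  scans. Magnitudes, not signed changes, are the quantity of interest:
  activation may rise or fall across a transition, and global decreases
  would otherwise cancel the contrast structure.
- **Weighted percentage** divides every cell by the subject's single
  largest ROI × scan count (× 100). The normaliser is per subject and
  global across areas and scans, so high-count regions carry more
  statistical weight and scanner-sensitivity differences (1.5 T vs 3 T
  thresholds) are offset. Invariant to rescaling a subject's counts.

Inter-ROI correlation is the mean of the 28 pairwise Pearson correlations
across subjects at a scan position; comparisons between positions are
paired t-tests over the 28 pairs (df = 27). Raw counts are the default
correlation input; weighted percentages are available via a switch.

## Inferential layer

All tests are two-sided. Within-patient contrasts (OT vs NOT) use the
paired t on per-patient label means — a patient with several OT intervals
contributes one OT mean — giving df = 8 with nine patients.
Patient-vs-control contrasts use Welch's t with Satterthwaite fractional
df. Wilcoxon tests validate each parametric result: exact null
distributions for small tie-free samples (signed-rank up to n = 25,
rank-sum up to min(n) = 15), tie-corrected normal approximation otherwise,
with the route recorded in the method label. Zero differences are dropped
before signed-ranking (Wilcoxon's original rule).

Point-biserial effect sizes are Pearson correlations between the pooled
per-subject means and a 0/1 label coding (lexicographically larger label
coded 1, so OT is 1 in every contrast here), with the conventional bands
small ≤ .20, medium .21–.35, large > .35. The group × transition-type
ANOVA interaction uses Type-III sums of squares with sum-to-zero coding
(statsmodels OLS), valid for unbalanced cells. BCa bootstrap intervals
(scipy, jackknife acceleration) default to 10,000 resamples. No
multiple-testing correction is applied across ROIs by default; a Holm
option exists.

Degenerate inputs are defined rather than crashed on: identical paired
samples give t = 0, p = 1; constant groups with equal means give p = 1 in
the contrast driver; constant groups with distinct means report p at the
machine floor with a note; zero-variance effect-size inputs return NaN
with a flag.

## Synthetic cohorts

The generator encodes the substantive model: destabilization precedes
discontinuous change. Per item, a latent AR(1) with coefficient φ = 0.6
around a baseline mean has its innovation SD (σ = 0.08·R) multiplied by
κ = 3 during the w = 10 days before the transition day τ, and its mean
shifted by ±0.25·R (sign per item) from τ onward; values are clipped to
the scale and rounded to the Likert grid. The cohort template is 9
patients — seven with 3 scans and one transition, two with 4 scans and two
transitions in distinct intervals — plus 9 controls scanned on the matched
patients' schedules, with 37–65 rating days per patient and 20 items on a
1–7 scale. Item baselines are drawn uniformly from the middle 40 % of the
scale so that shifts and fluctuations are only moderately censored by the
bounds.

ROI panels draw first-scan counts around 12,000 voxels with inter-ROI
correlation induced by a common latent subject factor (loading √ρ,
ρ_pre = 0.75). Each later scan moves every ROI by a label-dependent
magnitude — OT 7479, NOT 1904, ISI 697 voxels by default, i.e. the
reported group means, plus shared and ROI-level Gaussian noise
(SD 2000 / 1000) — in the direction of a structured target; after a
patient's first OT the target uses a fresh latent factor with
ρ_post = 0.30, eroding the initial correlation structure. Counts are
integers floored at zero, and with zero noise every interval change equals
its label mean exactly. These ROI defaults are convenience targets so the
synthetic contrast table lands near the reported magnitudes; they claim no
distributional fidelity.

What the generator does *not* emulate: correlated item content (items are
independent given the transition schedule), subscale structure, missing
diary days, therapy events, autocorrelated or heavy-tailed voxel-count
noise, and scanner-specific thresholds beyond metadata. Passing tests
therefore demonstrate the pipeline's internal correctness and its
sensitivity under the stated generative model, not clinical validity on
real diaries.

## Problem sizes and determinism

All randomness flows from a single root seed through per-subject
`SeedSequence` fan-out, so any subject is reproducible in isolation and
identical seeds give bit-identical cohorts, panels and CSV bundles
(timestamps appear only in provenance.json). The benchmark scripts use 200
simulated patients for recovery/null calibration, 5,000 null draws for
paired-t size, 1,000 samples (n = 50, B = 10,000) for BCa coverage, and
100 cohort replicates for the contrast-table analogue.

## Known limitations

- **Transition-recovery margin.** With a 7-day right-aligned window and a
  flat 10-day inflation band, fully-inflated windows are stamped on days
  τ−4…τ−1. The expected complexity curve peaks exactly at τ (the shift-day
  window), but only ~5 % above that near-flat shoulder, so with 20 items
  the detected peak lands at τ−4 or τ−5 in roughly a quarter of simulated
  patients: detection is never late and at most w−m+1 days early.
  Empirically ~72 % of 200 simulated patients are recovered within ±3 days
  at the defaults (see `analysis/04_recovery_benchmark.py`); a ±5-day
  tolerance, a crescendo-shaped inflation, or more/less autocorrelated
  items would all move this number substantially.
- The secondary-maximum rule is a pragmatic operationalisation; detected
  OT counts on simulated cohorts can fall below the injected count when a
  second transition's peak stays under 90 % of the global maximum.
- Exact Wilcoxon routes require tie-free data; heavily tied Likert-derived
  statistics silently use the tie-corrected approximation (the method
  label says so).
- The pipeline starts at ROI count tables; no voxel-level processing, ROI
  delineation or BOLD modelling is included or planned.
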