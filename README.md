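# ordertrans

Detecting discontinuous change in psychotherapy from daily self-report
time series, and contrasting brain-activation changes across the
resulting process phases.

## The problem

Psychotherapeutic change is often not gradual: self-organizing-systems
accounts predict *order transitions* — sudden qualitative shifts of a
patient's experiential/behavioral pattern — preceded by a period of
*critical fluctuations*. With daily process ratings (e.g. the Therapy
Process Questionnaire, 7-point Likert or visual-analogue items) these
destabilization phases can be located in time, and repeated fMRI
measurements can then be compared between inter-scan intervals that do or
do not contain a transition.

`ordertrans` implements that analysis chain for researchers working with
daily diary data and repeated imaging (or any repeated biomarker):

1. **Dynamic complexity.** For a moving window of `m = 7` days over each
   item `x(t)` on a scale of theoretical range `R`, compute

   - *fluctuation intensity* `F = Σ_k (a_k/d_k) / (R·(m−1))`, summing over
     maximal monotone runs with amplitude `a_k` and duration `d_k` (runs
     end at strict direction reversals; a constant window gives `F = 0`, a
     full-range zig-zag gives `F = 1`);
   - *distribution degree*
     `D = 1 − Σ max(0, I_c − (y_b − y_a)) / Σ I_c`, comparing every span of
     the sorted window values against the ideal span `I_c = c·R/(m−1)`
     under perfectly even coverage of the range;
   - *dynamic complexity* `C = F·D ∈ [0, 1]`, stamped on the window's last
     day and averaged (unweighted) over items.

2. **Transition detection.** The maximum of the item-averaged complexity
   curve marks the primary order transition; further local maxima qualify
   if they reach ≥ 90 % of the global peak and are ≥ 14 days away.

3. **Interval contrasts.** Inter-scan intervals are labelled OT
   (transition, patients), NOT (no transition, patients) or ISI (untreated
   controls). Absolute ROI voxel-count changes — raw and as per-subject
   *weighted percentages* (100 × count / the subject's largest ROI × scan
   count) — are contrasted OT vs NOT (paired *t* + exact Wilcoxon), OT vs
   ISI and NOT vs ISI (Welch *t* + rank-sum), with point-biserial effect
   sizes, a two-factor (group × transition-type) ANOVA interaction, BCa
   bootstrap CIs (10,000 resamples), and inter-ROI correlation structure
   over the 28 region pairs.

Because raw clinical data of this design are not publicly deposited, the
package ships a first-class synthetic generator: bounded AR(1) item
dynamics with innovation-variance inflation before an injected transition
day and a level shift at it, plus matched ROI count panels with
label-dependent change magnitudes and a latent-factor correlation
structure. Every stage is tested against this known ground truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_complexity_transitions.py
python analysis/03_roi_contrasts.py
python analysis/04_recovery_benchmark.py
```

which prints (seed 42):

```
cohort written to results/cohort/
  patients: 9, controls: 9
  daily ratings per patient: 39-64 days
  true transitions: 11
intervals: 20 patient (9 OT, 11 NOT), 20 control ISI
primary transition within ±3 days of an injected one: 8/9 patients
mean-of-all-areas contrasts:
  OT-NOT   diff_voxels   diff=  6914.92 t=  8.25 (df= 8.00) p=0.000 wilcoxon p=0.004 r=0.92
  OT-ISI   diff_voxels   diff=  6840.38 t=  8.72 (df=13.97) p=0.000 wilcoxon p=0.000 r=0.91
  NOT-ISI  diff_voxels   diff=   -74.54 t= -0.14 (df=14.95) p=0.894 wilcoxon p=0.796 r=-0.03
  OT-NOT   diff_weighted diff=    32.68 t=  7.88 (df= 8.00) p=0.000 wilcoxon p=0.004 r=0.92
  OT-ISI   diff_weighted diff=    29.31 t=  6.55 (df=16.00) p=0.000 wilcoxon p=0.000 r=0.85
  NOT-ISI  diff_weighted diff=    -3.38 t= -0.95 (df=11.98) p=0.362 wilcoxon p=0.546 r=-0.23
inter-ROI correlation: first scan r=0.75 (SD 0.12) -> last scan r=0.15 (SD 0.36); t(df=27)=8.08, p=1.1e-08
recovery within ±3 days: 72.0% of 200 patients
null interval counts [100.0, 100.0], chi-square uniformity p = 1.000
```

Reading this: the 9 simulated patients contribute 20 inter-scan intervals;
intervals containing a detected transition show much larger activation
changes than non-transition intervals (paired t(8) = 8.25) and than
control intervals, while NOT vs ISI does not differ — the signature the
design is built to detect. The inter-ROI correlation collapses from the
first to the last scan, reflecting the post-transition differentiation of
the regional activation pattern. The null benchmark confirms that without
an injected effect the detected peaks spread evenly over intervals.

A `click` CLI exposes the same steps
(`ordertrans simulate|complexity|detect|compare|run`); `ordertrans run
--config run.yaml` writes the full report bundle (complexity, transitions,
labels, change table, Table-style contrast report, intercorrelation
summary, figures and provenance) in one go.

## Layout

- `src/ordertrans/` — the library: `timeseries` (data model + I/O),
  `complexity` (F, D, C), `detection` (transitions + interval labels),
  `roi` (panels, weighted %, intercorrelation), `stats` (tests, effect
  sizes, ANOVA, BCa, contrast driver), `simulate` (synthetic cohorts),
  `pipeline`/`cli` (orchestration).
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
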