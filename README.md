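# tapmark

Quantitative finger-tapping, dopamine-transporter SPECT and resting-state
connectivity analysis for cohorts at risk of synucleinopathies — in
particular REM sleep behavior disorder (RBD), where subtle ("mild") motor
impairment predicts conversion to Parkinson's disease or dementia with
Lewy bodies.

`tapmark` is for movement-disorder and neuroimaging researchers who have
(or want to simulate) three kinds of subject-level data:

- **finger-tapping waveforms** — thumb–index distance vs time from a
  magnetic sensing device, one 15-s trace per hand;
- **striatal VOI count tables** from ¹²³I-FP-CIT SPECT (caudate,
  anterior/posterior putamen, cerebellar reference);
- **ROI time-series matrices** from resting-state fMRI of the
  sensorimotor network (30 cortical, striatal and cerebellar regions).

It implements the full analysis chain: cycle-level tapping kinematics, a
normative 2-SD classifier for mild motor impairment (MMI), specific
binding ratios and asymmetry indices, ROI-to-ROI functional connectivity
with covariate-adjusted group contrasts under FDR control, and the
group-comparison/correlation statistics that tie the three modalities
together. A first-class synthetic-cohort generator makes every stage
testable without any subject data.

## The core measurements

**Tapping kinematics.** Each recording is low-pass filtered (zero phase,
20 Hz default); tap cycles are delimited by the valleys of the distance
trace. Per cycle *k* the pipeline extracts amplitude $A_k$ (mm), peak
open speed and peak close speed (m/s); per recording it reports the means
over retained cycles and the OLS decrement slope of each parameter
against cycle index (bradykinesia's "sequence effect").

**MMI classification.** From healthy controls (HC), fitted per parameter
$p$ and side $s$:

$$c_{p,s} = \bar{x}^{HC}_{p,s} - 2\,\mathrm{SD}^{HC}_{p,s}$$

A patient is MMI if any of the six values (amplitude, open, close speed ×
both hands) is strictly below its cutoff; the same rule on the decrement
slopes defines "progressive decrement".

**SPECT quantification.** Specific binding ratio and asymmetry index:

$$\mathrm{SBR} = \frac{C_{striatal} - C_{cereb}}{C_{cereb}},\qquad
\mathrm{AI} = \frac{|R - L|}{R + L}$$

with group means, percent reductions vs HC, and ANOVA + Tukey comparisons.

**Functional connectivity.** Band-pass 0.008–0.09 Hz, bivariate Pearson
correlation per ROI pair, Fisher $z = \mathrm{atanh}(r)$, then per pair an
OLS model of $z$ on a two-group indicator plus age and sex, with
Benjamini–Hochberg FDR across the 435 pairs of each contrast.

## Worked example

```python
from tapmark import classify_cohort, generate_cohort, make_fixtures, summarize_cohort

cohort = generate_cohort(make_fixtures("paper-like", seed=1))   # 20 HC / 15 / 8
cycles, summaries = summarize_cohort(cohort.waveforms.values())
table, normative = classify_cohort(summaries, cohort.subjects)
print(normative.summary())
print(f"{int(table['is_mmi'].sum())} of {len(table)} patients classified RBD-MMI")
```

prints

```
Normative tapping model (HC reference)
n_hc = 20
parameter     side        mean        sd    cutoff  slope mean  slope sd  slope cutoff
amplitude     R         51.220     9.914    31.392     -0.3206    0.2898       -0.9001
amplitude     L         53.142     8.428    36.287     -0.1706    0.2446       -0.6598
open_speed    R          0.475     0.100     0.276     -0.0029    0.0027       -0.0082
open_speed    L          0.507     0.088     0.330     -0.0016    0.0024       -0.0063
close_speed   R          0.475     0.100     0.276     -0.0029    0.0027       -0.0082
close_speed   L          0.506     0.088     0.330     -0.0016    0.0024       -0.0064

12 of 23 patients classified RBD-MMI
```

Each row is one tapping parameter on one side: the HC mean and sample SD
(amplitude in mm, speeds in m/s), the resulting 2-SD cutoff a patient
must fall strictly below to be flagged, and the same statistics for the
per-cycle decrement slopes (units per cycle). With this seed, 12 of the
23 simulated patients cross at least one cutoff and are classified
RBD-MMI.

The same chain is available from the shell:

```bash
tapmark run --out runs/demo --seed 1 --scale paper-like
```

which executes simulate → kinematics → classify → spect → fc → report and
leaves tidy CSV tables plus hash-chained JSON manifests under `runs/demo/`.

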