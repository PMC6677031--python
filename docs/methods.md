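# Methods

This note documents the models, conventions and design choices behind
`tapmark`: what each stage computes, which knobs matter, what the
synthetic cohort does and does not emulate, and where the genuinely open
design decisions were made.

## Tapping waveform model

The generator emits a raised-cosine tap train: within cycle *k*
(period $T = 1/f$) the thumb–index distance is

$$d(t) = \tfrac{A_k}{2}\,\bigl(1 - \cos(2\pi t/T)\bigr),
\qquad A_k = \max(A + s\,k,\ A_{floor})$$

with amplitude $A$ (mm), per-cycle decrement slope $s$ (mm/cycle) and a
small positive floor (default 1 mm) so pathological decrements never
produce negative excursions. The raised cosine was chosen because it
matches the smooth open/close morphology of real magnetic-sensor traces
and gives closed-form oracles: per-cycle excursion is exactly $A_k$ and
peak open/close speed is exactly $A_k\pi f$ (m/s for $A$ in meters).

Open/close asymmetry $a$ time-warps each cycle: the opening phase
occupies $a/(1+a)$ of the period and the closing phase $1/(1+a)$, so
peak close speed is $a$ times peak open speed while the excursion is
unchanged. The cohort generator exposes this as per-group
open/close-speed scale factors $s_o, s_c$ (multipliers on $A\pi f$),
realized by the substitution $f' = 2 f s_o s_c/(s_o+s_c)$,
$a = s_c/s_o$. Additive Gaussian distance noise (default 0.5 mm) is
clipped so distance stays non-negative. Traces sample the closed
interval $[0, \mathrm{duration}]$, so a train of exactly
$\mathrm{duration}\times f$ cycles ends on a valley.

The device sampling rate is configurable with a 200 Hz default —
comfortably above the harmonics of 2–4 Hz tapping.

## Kinematic extraction

- **Smoothing:** 4th-order Butterworth low-pass, applied forward-backward
  (zero phase), default cutoff 20 Hz. Speed is the central-difference
  derivative of the smoothed distance, reported in m/s; if a device
  supplies a measured speed trace it is used directly and flagged.
- **Segmentation:** cycles span consecutive valleys, detected as local
  minima with prominence ≥ 20 % of the recording's global excursion and
  separation ≥ 100 ms (deterministic, scale-adaptive). A recording
  endpoint counts as a valley only when it already sits at valley level
  (within 10 % of the global excursion of the detected valley level);
  otherwise the partial first/last segments are discarded.
- **Retention:** cycles shorter than 100 ms or with excursion < 5 mm are
  dropped (sensor-jitter suppression); thresholds are arguments.
- **Per-cycle parameters:** amplitude = in-cycle maximum minus the mean
  of the two bounding valley values (robust to baseline drift — a
  convention of this implementation, since per-cycle amplitude can also
  be defined against the within-cycle minimum); peak open speed = largest
  positive speed between opening valley and in-cycle maximum; peak close
  speed = largest negative-speed magnitude between maximum and closing
  valley.
- **Summaries:** arithmetic means over retained cycles; decrement slopes
  by OLS of each parameter on 1-based cycle index, requiring ≥ 3 cycles.

On noiseless synthetic trains the extracted amplitude and peak speeds
agree with the closed forms to well under 1 % (the residual is
discretization plus the ~0.1 % attenuation of the 3 Hz component by the
20 Hz filter).

## Normative model and MMI rule

Fitted on HC subjects only, per parameter and per side (sides are kept
separate because of hand dominance): mean and sample SD (n−1), cutoff
mean − 2·SD. Classification uses **strict** inequality — a value exactly
at the cutoff is not flagged — and requires all six parameters; a subject
is MMI with ≥ 1 flag. The identical construction on decrement slopes
gives the progressive-decrement criterion (slopes are negative; "below"
means more steeply negative). The two criteria are independent. The
fitted model serializes to JSON so classification is reproducible without
refitting. A degenerate (zero-variance) normative parameter is an error,
not a silent cutoff.

Under the null (patients drawn from the HC distribution, independent
parameters, population-true cutoffs) the analytic flag rate is
$1-(1-\Phi(-2))^6 = 12.90\,\%$; the test suite verifies this on 100 000
simulated subjects. Real tapping parameters are correlated within
subject, which can only lower the realized rate.

## SPECT quantification

SBR = (striatal − cerebellar)/cerebellar VOI mean counts; asymmetry
index AI = |R − L|/(R + L), computed on SBR values (the alternative —
raw counts — changes nothing when both sides share the cerebellar
reference). Negative SBR values, possible under noise, are clipped to 0
before AI with a warning so AI stays in [0, 1]; AI is undefined (NaN)
when R + L = 0. Percent differences vs HC are computed from group
arithmetic means: 100·(HC − group)/HC. Group inference is one-way ANOVA
with Tukey–Kramer post-hoc per region/side and per AI.

The generator inverts the SBR definition exactly:
striatal count = cerebellar × (1 + SBR + ε), ε ~ N(0, noise_sd), so the
zero-noise round trip recovers configured SBR values to machine
precision. The package works from already-labeled VOI rows; how the
anterior/posterior putamen boundary was drawn in image space is upstream
of this artifact and out of scope.

## Functional connectivity

Per subject: each ROI column is band-pass filtered 0.008–0.09 Hz with a
second-order Butterworth applied forward-backward (zero phase; only the
band itself is externally specified, the filter family is this package's
choice); Pearson correlations for all unique pairs; Fisher
z = atanh(r), capped at atanh(1 − 1e−7) so degenerate |r| = 1 pairs stay
finite and visible. Matrices are made exactly symmetric; analysis uses
the strict upper triangle (435 pairs for the default 30-ROI sensorimotor
set: bilateral M1, PM, SMA, S1, SPL, IPL, caudate, anterior/posterior
putamen, cerebellar lobules II, III, IV–V, VI, VII, VIII).

Group contrasts are fitted per pair as separate two-group OLS models
z ~ intercept + group + age(centered) + sex(M=0, F=1), matching the
two-group rows such tables are usually reported in; signed T belongs to
the first-named group. FDR: Benjamini–Hochberg across all pairs within a
contrast ("analysis" scope, the stricter default); a "seed" scope is
available that adjusts within each seed ROI's family, a pair receiving
the smaller of its two seeds' adjusted values. The per-pair regressions
are solved vectorized (one shared design matrix per contrast), which
keeps 500-replicate null simulations cheap.

Head motion enters the pipeline only as a per-subject mean frame-wise
displacement column compared across groups by ANOVA; computing it from
realignment parameters is upstream preprocessing and out of scope, as is
confound regression of white-matter/CSF signals (synthetic ROI series are
generated clean).

## Group and correlation statistics

- One-way ANOVA with Tukey–Kramer post-hoc (handles the unequal 20/15/8
  group sizes). All observations identical → F = 0, p = 1.
- Two-sample t: pooled-variance (Student) by default — Welch is an
  option; zero pooled variance with equal means → p = 1, with unequal
  means → |t| = ∞, p = 0, flagged.
- Chi-square without continuity correction by default (correction is an
  option); a zero marginal is an error.
- Pearson p-values by the t-approximation; partial correlation by
  least-squares residualization on intercept + covariates, df = n−2−k.
- Hand-to-hemisphere pairing: tapping parameters correlate with
  **contralateral** striatal uptake (R hand ↔ L striatum).
- No multiple-testing correction is applied across the correlation
  tables (each entry tested at two-tailed p < 0.05); this mirrors common
  reporting practice and is a deliberate, documented caveat.

## Synthetic cohort

The generator emulates a three-group study (HC / RBD-N / RBD-MMI,
default 20/15/8 subjects) at published group-level statistics:

- demographics, clinical scores and polysomnography as truncated normals
  around per-group means/SDs; integer UPDRS-III items as Binomial(4,
  mean/4), totals by summation;
- tapping: per-subject amplitude ~ N(group mean, 8 mm), rate ~ N(3,
  0.3) Hz, amplitude decrement ~ N(group mean, group SD) with HC default
  −0.24 ± 0.30 mm/cycle; the MMI group taps smaller (38/36 mm vs 60/58)
  and slower, with close speed more affected than open speed (scales
  0.70 vs 0.85);
- SPECT: HC SBR levels 4.5/4.2/4.0 (caudate/anterior/posterior putamen —
  typical healthy-elderly magnitudes, chosen here since no absolute
  levels are published), patient groups reduced by the published percent
  differences, which encode both the posterior > anterior > caudate
  gradient and the right-worse asymmetry of the MMI group; between-subject
  SD 0.4, count noise SD 0.1;
- fMRI: zero-mean multivariate Gaussian ROI series (180 volumes,
  TR 2.5 s) from per-group target correlation matrices — a weak
  compound-symmetry background (r = 0.1) plus effect pairs at Δr = 0.3:
  striatum–SPL coupling reduced in both patient groups vs HC, cerebellar
  lobule VIII–S1/PM coupling elevated in RBD-MMI vs RBD-N.

Everything is a pure function of (config, seed); a single global seed
fans out to per-stage, per-subject streams via fixed spawn keys, so
toggling one stage never perturbs another.

**What the generator does not emulate:** real waveform morphology beyond
the raised-cosine family (tremor, hesitations, inter-tap variability),
hemodynamics, scanner noise, autocorrelated BOLD series, motion
artifacts, within-subject correlation between tapping, uptake and
connectivity (each modality is drawn independently given the group), and
item-level UPDRS covariance. Passing tests therefore demonstrate that the
measurement and inference chain is correct under known generating
conditions — not that the published group differences would replicate in
new subjects.

## Numerical conventions and degenerate inputs

- Zero-phase filtering throughout (no group delay); filter transients at
  trace edges are handled by scipy's default odd-extension padding.
- Valley ties broken by earliest sample (scipy `find_peaks` order);
  segmentation never yields more cycles than detected valleys − 1.
- Fisher-z cap atanh(1 − 1e−7); zero-variance ROI columns yield NaN pairs
  with a warning rather than an error.
- Rank-deficient contrast designs (e.g. single-sex subsets) raise with
  the offending columns named; pairs with zero residual variance are
  reported missing.
- CSV output uses `%.10g` formatting; manifests store relative paths and
  SHA-256 hashes and chain each stage to its predecessor, making reruns
  byte-comparable.

## Problem sizes used in the test suite

The suite runs the full pipeline on a "tiny" cohort (3 subjects/group,
5-s waveforms, 40 volumes) and determinism/integration checks on the
"paper-like" cohort (20/15/8, 15 s, 180 volumes). Monte-Carlo checks use
100 000 subjects for classifier specificity, 1000 replicates for Fisher-z
calibration, and 500/200 replicates for FDR control and power ordering —
sizes chosen so each check's Monte-Carlo error is several times smaller
than the tolerance it asserts.

## Known limitations

- The MMI rule is a fixed 2-SD normative cutoff; no ROC calibration or
  probabilistic classification is provided (deliberately out of scope).
- Small normative samples (n = 20) make the cutoffs themselves noisy;
  the specificity analysis above treats cutoffs as population-true.
- FC contrasts assume Gaussian residuals of z-values and ignore the
  dependence between overlapping ROI pairs; FDR control is therefore
  approximate under strong dependence.
- The correlation tables are exploratory (uncorrected).
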