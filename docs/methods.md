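# Methods

`bgconn` implements and validates *background connectivity* estimation for
slow event-related fMRI: functional connectivity computed from task runs
after statistically removing task-evoked activity, compared against
resting-state connectivity from the same subjects.

## Model and pipeline

The working assumption is linear superposition: the observed parcel signal
during a task is intrinsic (rest-like) activity plus a trial-locked evoked
response plus nuisance contamination and noise,

    y_p(t) = x_p(t) + a_p * h(t) + c(t)' w_p + e_p(t)

where `h(t)` is the evoked time course (the trial template convolved with
the onset train) and `a_p` the parcel's response amplitude.  If that holds,
removing the evoked term should recover connectivity close to what a rest
scan would give.  Two removal methods are implemented:

* **LPF** — zero-phase low-pass filter with a 16-s period cutoff.  Trials
  recur every 12 s, so all trial-locked power sits at and above 1/12 Hz;
  a cutoff at 1/16 Hz removes it with margin, at the cost of also
  discarding fast *intrinsic* fluctuations.
* **FIR** — a per-run GLM whose task part is a finite impulse response
  basis: one indicator column per TR of the 12-s post-onset window (6
  columns at TR 2 s).  This fits an arbitrary evoked shape on the TR grid
  without assuming a canonical hemodynamic response; the residuals keep
  the broadband intrinsic signal minus a 25-dimensional projection
  (6 FIR + 18 nuisance + intercept).

The per-run chain is: 100-s high-pass → (task runs) LPF or FIR removal →
scrubbing (FD > 0.5 mm or DVARS > 0.5% of the grand mean absolute signal;
FD/DVARS computed on the raw series and motion parameters so that the
percent scale is meaningful) → pairwise partial correlations controlling
the 18 Power nuisance regressors (6 motion, CSF, white matter, global
signal, and their backward-difference derivatives) → Fisher z → average
across task runs.  Partial correlation is realized as
residualize-each-parcel-on-nuisance, then Pearson; the conditioning set is
the nuisance block only, not the other parcels.  Nuisance regressors are
partialled in all three datasets, including FIR residuals where they were
already in the GLM, so the three methods share identical procedures.

Comparisons are rank-based throughout: per-subject fingerprint similarity
(Spearman rho over the 4950-entry strict upper triangle), mean
within-network minus between-network Fisher-z (network contrast), a
3 (method) × 2 (connection type) fully within-subject ANOVA, per-connection
across-subject stability, the 7×7 network-collapsed version (28 unique
entries), subject identification by maximal fingerprint similarity, and
Spearman associations between similarity scores and mean/max FD/DVARS.
Group means of rho are taken on the Fisher-z scale and back-transformed.

## Synthetic cohort

The generator emulates the target design: per subject, one 480-s rest run
and four task runs of 4 s fixation + 18 trials × 12 s = 220 s (3.67 min),
TR 2 s.  Components:

* **Intrinsic structure.** A 7-network block correlation matrix over 100
  parcels (`r_within = 0.5` inside blocks, `r_between = 0.1` elsewhere),
  perturbed per subject by symmetric Gaussian jitter
  (`subject_jitter_sd = 0.05`) — the ground-truth fingerprint — then
  projected to the nearest PSD correlation matrix (eigenvalue clipping at
  0, rescale to unit diagonal).  Network sizes (17, 16, 13, 12, 10, 13,
  19) approximate a 100-parcel/7-network cortical atlas.
* **Temporal process.** AR(1) with coefficient 0.4 and cross-parcel
  innovation covariance equal to the true matrix; the stationary
  cross-sectional covariance is exactly the ground truth, and the spectrum
  is red but broadband.  Broadbandness is what differentiates the two
  removal methods: the LPF discards the fast part of the intrinsic signal
  (fewer effective samples → noisier subject estimates), while FIR keeps
  it.
* **Evoked response.** A 6-sample double-gamma-like template
  `[0, .6, 1, .7, .3, .1]` placed at each onset, scaled by a per-parcel
  amplitude: 1.5 signal-sd units on Visual and Dorsal Attention parcels
  (30 of 100), 0 elsewhere.  The amplitude and extent of real
  passive-viewing responses are not constrained here; 1.5 sd in visual and
  attention regions is a plausible strong sensory response and makes raw
  task correlations visibly conflated.  Any 6-sample shape is inside the
  FIR model span by construction, so FIR removal is exact up to estimation
  noise.
* **Confounds and noise.** Nine confound signals (slow AR(1) motion
  drifts; AR(1) CSF/WM/global with sd 1) contaminate parcels through
  Gaussian loadings (sd 0.15); white noise sd 0.5; constant baseline 1000
  (so DVARS-as-percent behaves like raw BOLD units).
* **Motion spikes.** Per-volume probability 0.02; a spike is a sustained
  translation step summing to 1 mm of framewise displacement plus a
  one-volume corruption of the parcel signals.  The step form makes FD
  exceed threshold exactly at the spike volume; the signal corruption is
  transient and sits below the DVARS threshold at defaults, so scrubbing
  removes exactly the injected volumes and the retained series is
  artifact-free.
* **Seeding.** One master seed; subject streams are derived as
  `seed + subject_index`, with fixed sub-stream identifiers for
  covariance, loadings and each run.  Identical inputs give bit-identical
  output.

What the generator does **not** emulate: voxel-level structure, spatially
varying hemodynamics, physiological (cardiac/respiratory) noise,
distance-dependent noise correlations, or task-driven *changes* in
connectivity (the true matrix is identical across rest and task).  Passing
tests therefore show that the estimation machinery recovers what the
superposition model implies — not that real task data satisfy that model.

## Numerical choices

* Filters: 5th-order Butterworth applied forward-backward (zero-phase,
  squared magnitude response), even-reflect padding of one cutoff period.
  The single-pass gain at the 12-s task period is ~0.23, hence ~0.05 after
  two passes; DC is preserved exactly by filtering the demeaned signal and
  restoring the mean.  The 100-s high-pass substitutes a Butterworth for
  FSL-style Gaussian running-line detrending; at these cutoffs the
  difference is immaterial for correlation estimates.
* Onset-to-volume mapping rounds `onset / TR`; exact here because onsets
  are TR multiples.
* The FIR GLM always includes an intercept and is fitted per run by OLS
  (no autocorrelation correction); exactly collinear columns (e.g.
  derivatives of constant confounds) are pruned with a logged warning, and
  a model still rank-deficient afterwards is an error naming the columns.
* Fisher z clips |r| at 1 − 1e−7 so perfect correlations stay finite.
* Greenhouse–Geisser epsilon is estimated per effect from the covariance
  of orthonormalized (Helmert) condition contrasts, clipped to
  [1/df, 1]; p-values use the F distribution with fractional corrected df.
  Generalized eta-squared uses the within-design convention whose
  denominator includes the subject SS and every error SS.
* Scrubbing defaults: FD 0.5 mm, DVARS 0.5%, minimum retained fraction
  0.5 (runs below it are dropped; a subject's average then uses the
  remaining runs, and a subject with no usable rest or task data is
  excluded with a logged reason).
* DVARS is defined at the parcel level (RMS of the temporal difference
  across parcels, percent of grand mean absolute signal) — a documented
  stand-in for voxelwise DVARS, scale-invariant by construction, with the
  threshold exposed.

## Problem sizes and known limitations

Validation runs use a 20-subject cohort at the full design (100 parcels,
rest + 4 task runs) and a 500-replication null for ANOVA calibration;
both complete in seconds.  Identification accuracy, effect orderings and
calibration are stochastic properties checked under fixed seeds.

The recovery advantage of removal over raw task connectivity is large for
FIR but modest for LPF at these defaults: in raw task connectivity the
upward bias from shared evoked responses and the downward attenuation
from unfiltered noise partially cancel, while LPF trades evoked-bias
removal for correlation inflation from noise smoothing.  The *ordering*
of interest (FIR closest to rest; LPF sharpest apparent network
structure; the two background methods most similar to each other) is
stable across seeds; the raw-vs-LPF recovery margin is the quantity most
sensitive to the evoked-amplitude setting.

Follow-up pairwise tests are reported with uncorrected p-values (a Holm
option exists but defaults off).  Subject identification uses Spearman
similarity for consistency with the other analyses, a documented
divergence from the Pearson-based identification literature.
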