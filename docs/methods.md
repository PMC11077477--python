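# Methods

`rewardmap` reimplements the computational analyses used to show how drugs of
abuse engage nucleus-accumbens (NAc) reward ensembles: brain-wide FOS region
statistics, a gene–activity correlation screen (FOS-Seq), single-neuron
calcium-trace preprocessing with activation metrics, and population-level
ensemble dynamics including nonnegative tensor component analysis (TCA).
Everything runs on synthetic data with planted ground truth, so each stage's
sensitivity and calibration can be measured without animal data.

## Brain-wide FOS statistics (`fos_mapping`)

The input is a region × sample table of FOS+ cell counts projected onto Allen
atlas regions, with condition (saline / cocaine / morphine), processing batch,
and exposure phase labels per sample.

* **Batch z-scoring.** Counts are z-scored per (region, batch) across that
  batch's samples using the sample standard deviation (ddof=1; the paper-style
  small-n convention used throughout). A zero-variance cell maps to z=0 with a
  logged flag rather than NaN so downstream matrix operations stay total.
* **ANOVA screen + k-means.** A one-way ANOVA across conditions is run per
  region on the z-scores; regions with unadjusted p < 0.05 are kept.
  Multiplicity is deliberately not corrected at this step — the screen's
  cut-off convention is a fixed per-region p < 0.05. Retained regions'
  condition-mean profiles are clustered with seeded k-means (25 restarts);
  when k is not given it is chosen by silhouette score over k ∈ 2..10.
* **Drug contrasts.** Per drug, the contrast vector is mean z(drug) − mean
  z(saline) per region. Class labels use a per-region Welch two-sample t-test
  against saline at p < 0.05: significant under both drugs → "common", under
  exactly one → "<drug>-specific", else "none". Welch is a documented choice;
  the underlying test behind the published significance stars is not stated.
* **Phase similarity.** For one region, the (acute, withdrawal, chronic)
  saline-subtracted z-score triple per drug is compared across drugs by
  Euclidean distance.

## FOS-Seq (`fos_seq`)

A saline-subtracted FOS contrast vector is matched to a gene × region ISH
expression atlas on the lexicographically sorted intersection of region names
(a warning is raised below 10 shared regions). Both the FOS vector and every
gene vector are **sigmoid transformed**: standardized (ddof=1) and mapped
through the logistic function. The functional form is not prescribed by the
source method beyond "sigmoid"; the logistic on standard scores realizes its
purpose — damping outlier leverage — while preserving order exactly.

Per gene, the Pearson correlation r across regions is computed on the
transformed vectors, with the exact two-sided t-based p (n−2 df). p-values
are computed on the same transformed vectors used for r. A Gaussian null is
fitted to the screen-wide r distribution; the default fit is the sample-moment
MLE, with a `histogram` option (Freedman–Diaconis bins, least-squares) as an
alternative — on the null calibration dataset both agree to well within a
standard error. The classification threshold defaults to the fitted σ rounded
to two decimals (the published analysis reports μ = 0.0, σ = 0.15 and a fixed
±0.15 threshold, reproducible via `fixed_threshold=0.15`). Benjamini–Hochberg
FDR is applied over all genes in a call; a gene is positive if
r > +threshold with adjusted p < α, negative if r < −threshold with adjusted
p < α, else unclassified. Intersecting two conditions keeps genes significant
in both, keyed by sign quadrant and ranked by min(|r_a|, |r_b|).

For n matched regions the null sd of r is ≈ 1/√(n−1); with the default 100
regions the fitted σ lands near 0.10, and recovery of planted genes at a
pre-noise correlation of 0.6 is essentially complete (|r| ≈ 0.6 against a
≈0.10 null).

## Calcium-trace preprocessing (`calcium`)

Sessions are neurons × frames raw fluorescence at 4.82 Hz with a velocity
trace, labeled event times, and a baseline window. Sessions recorded on a
schedule (drug sessions: a 1-min baseline, then 1 min every 10 min post
injection) carry explicit per-frame acquisition times for the concatenated
trace. All windows are half-open [start, end); frames are 0-based.

* **Baseline z-scoring.** z = (Fraw − μ)/σ per neuron, μ and σ from the 30 s
  before presentation (ddof=1). Zero-σ neurons are flagged and excluded from
  σ-threshold calls.
* **Consumption preprocessing.** Each trace passes a second-order Butterworth
  low-pass with normalized cut-on 0.266 — interpreted as a fraction of the
  Nyquist frequency, the standard digital-filter convention — applied
  zero-phase (forward–backward) so no lag is introduced ahead of the
  lag-sensitive motor classification. μ and σ are then pooled over the
  baseline samples of the traces whose baseline mean lies strictly below the
  median of baseline means, and z = (F − μ)/σ is applied with those shared
  statistics.
* **Drug normalization.** Per 1-minute segment and neuron,
  Fcorr = (F − μ)/μ with μ the mean of the ⌈0.2·n⌉ smallest samples of the
  segment (ceiling, so the quintile set is never empty); segments are
  concatenated in time order. The transform is invariant to multiplicative
  gain.
* **Peak detection.** Local maxima above 3σ, pruned greedily highest-first
  (ties: earlier frame) so surviving peaks are ≥ round(1.3 s × frame rate)
  frames apart — 6 frames at 4.82 Hz, set by the GCaMP6s decay time.
* **Activation calling.** Consumption: a neuron is activated when its mean z
  from 10 s after consumption start to the window end (default: end of
  recording, configurable) exceeds 3. Drug: the trace is low-pass filtered
  like consumption traces, Fcorr-normalized, and re-centered on its
  pre-injection baseline mean; σ is the sd of the *unfiltered* Fcorr over the
  1-min pre-injection baseline (the measured-signal sd, matching the
  consumption formula's use of raw-trace σ); a neuron is activated when any
  supra-3σ peak falls in [20, 40) min post injection (cocaine) or [30, 50)
  min (morphine). Measuring height above the resting level matters: the
  lowest-quintile normalization leaves resting Fcorr ≈1.4 noise-sd above
  zero, and an absolute threshold would degenerate to ≈1.6σ.
* **Preference strength.** (Peak_drug − Peak_natural)/(Peak_drug +
  Peak_natural) ∈ [−1, 1]; undefined (NaN-flagged) when both peaks are zero.

## Ensemble dynamics (`ensemble`)

* **Motor classification.** Velocity is thresholded into a binary movement
  vector. Per neuron, the Pearson correlation with the movement vector is
  evaluated at signed lags ±1..10 frames (~2 s; positive lag = activity
  follows movement, the physiological indicator delay; negative = premotor).
  The symmetric search makes labels exactly invariant under joint time
  reversal of traces and movement, which a one-sided search cannot be. A
  neuron is motor-associated when |PCC| at its best lag exceeds a threshold
  selected from {0.20, 0.25, 0.30, 0.35, 0.40} as the smallest value at which
  the motor group's moving-vs-resting activity difference is significant
  (one-sided Wilcoxon signed-rank, α = 0.05) while the nonmotor group's is
  not. When no grid value qualifies — common when time-locked responses give
  the whole population a small shared moving-frame bias — the 0.30 midpoint
  is used and flagged.
* **Connectivity index.** Neuron pairs with activity correlation > 0.3 in a
  1-min segment are "synchronized"; each segment's pair count is divided by
  the pre-injection baseline segment's count. A zero baseline count errors
  unless a +1 pseudocount is explicitly enabled (logged).
* **Consumption states.** Seeded k-means over per-neuron consumption traces,
  with 2-D NMF and t-SNE coordinates for visualization (perplexity 30 capped
  at (n−1)/3, seeded; embeddings are visualization-only and deliberately kept
  out of quantitative checks — they are stochastic and non-identifiable).
* **Activation / variance contrasts.** Pre-vs-post activated fractions are
  compared with a two-sided Fisher exact test on the 2×2 table; the variance
  concentration statistic is the summed explained-variance ratio of the top 3
  principal components of the neuron × time matrix (neurons as observations).
* **TCA.** The trials × neurons × time tensor (nonnegative; negatives are
  clipped with a log message) is decomposed by nonnegative CP via HALS
  alternating updates, best of 10 seeded restarts by relative reconstruction
  error, up to 300 sweeps or an error plateau of 1e−10. Neuron and time
  factor columns are normalized to unit L2 norm with the scale absorbed into
  the trial factors; components are ordered by trial-factor energy. A
  dead component (zero Gram diagonal) is reinitialized with small random
  values. Trend statistics are OLS slopes of each trial factor on trial
  index; neurons contributing to state 1 over state 2 are those with a
  strictly positive loading difference, and their mean responses in the first
  and last sessions are compared with a paired two-sided Wilcoxon test.

## Synthetic data (`synthetic`)

The generators are pure functions of (spec, seed) — identical seeds give
byte-identical outputs — and return planted truth alongside the data.

* **FOS counts.** Poisson draws with log-linear per-batch multipliers
  (`batch_shift` scales a per-batch standard-normal log effect) and lognormal
  per-region base-rate heterogeneity around `base_rate` = 200 counts.
  A responsive region's mean is raised by effect_size·√λ counts so the
  planted shift is ~effect_size sd on the post-z-scoring scale (default 3).
  Groups default to saline/cocaine/morphine with 5 samples each over 2
  batches, with every batch containing all conditions (required for
  within-batch z-scoring across conditions).
* **ISH atlas.** On the standardized scale a positive gene is
  r·z(contrast) + √(1−r²)·ε so the pre-noise expected correlation equals
  `signal_r` (default 0.6); negative genes flip the sign; null genes are pure
  noise. The standardized value maps affinely into nonnegative expression
  energies with additive measurement noise (`noise_sd`, default 0.1 on an
  expression scale of 2).
* **Calcium sessions.** Traces are baseline level (50 a.u.) + Gaussian noise
  (σ = 1) + impulse trains convolved with a peak-normalized exponential decay
  kernel (τ = 1.3 s), so response amplitudes are expressed in baseline-σ
  units and 3σ thresholds are meaningful by construction. Reward neurons emit
  an impulse at each event plus a sustained ~1 Hz lick-like train while
  consumption lasts (a single 1.3-s transient could never satisfy a
  mean-over-minutes criterion); motor neurons fire inside velocity bouts with
  a per-neuron lag of 1–10 frames, exercising the lag search; silent neurons
  carry noise plus low-rate spontaneous transients (0.05 Hz, 2σ) — real
  neurons are never flat. Velocity alternates exponential rest periods with
  ~4 s bouts at 6 cm/s plus jitter. Drug-session specs take
  `record_windows` to reproduce the 1-min-per-10-min imaging schedule.
* **Trial tensors.** Two planted components: an amplifying subpopulation
  whose trial factor scales by `gain_per_session` across sessions, and a
  disjoint stationary subpopulation with a flat trial factor; distinct
  Gaussian-bump time courses; nonnegative noise on top (sd 0.05 against
  factor scales of order 1).

What the generators do **not** emulate: imaging physics, motion artifacts,
neuropil contamination, spike inference, nonstationary drift, and realistic
inter-animal variability (a between-animal variance knob is exposed rather
than a claim of realism). Passing tests therefore demonstrate correctness of
the formulas and calibration of the statistics under a clean generative
model, not performance on real recordings.

## Pipelines, seeds, determinism (`pipeline`, `cli`)

Both end-to-end chains (FOS: z-score → ANOVA/k-means → contrast → FOS-Seq →
shared genes; ensemble: Fcorr → peaks → activation → motor split →
connectivity → TCA) validate their stage list before any computation, remove
partial outputs on failure, and write `provenance.json` with the config
SHA-256, the global seed, and the package version. Outputs carry no
timestamps, so a rerun with the same config and seed is byte-identical. One
global seed fans out to per-stage child seeds via named `SeedSequence`
spawning, so any stage can be re-run independently yet reproducibly. The CLI
exposes `simulate`, `fosmap`, `fosseq`, `ensemble`, and `run` subcommands
with exit codes 0/1/2 (ok / usage / data error).

## Problem sizes

The shipped tests and the acceptance script use 80–200 regions, 300–2000
genes, 45–200 neurons, sessions of 5–62 min at 4.82 Hz, and 15-trial tensors
(5 sessions × 3 trials, 40 time bins) — sizes matched to the published
datasets' order of magnitude (e.g. ~100 tracked neurons per cell type) while
keeping a full run in a couple of minutes on one core.

## Known limitations

* The Gaussian-null σ is sensitive to the planted-gene fraction: with ≥10%
  non-null genes the fitted σ inflates and the 1σ threshold adapts upward;
  the fixed 0.15 option decouples classification from contamination.
* The drug-activation false-positive rate on noise-only neurons is ~7% per
  20-min window under the adopted σ convention; any fixed-σ peak criterion
  over a long window has a nonzero noise floor.
* The motor threshold grid search can be undecidable on strongly time-locked
  synthetic populations (see above); the fallback is logged.
* HALS is a local optimizer: recovery guarantees hold at the planted
  signal-to-noise ratios tested, not for arbitrary tensors.
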