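# Methods

This note documents the models and procedures implemented in
`wmgating`, the assumptions behind them, the parameter choices that
matter, and what the synthetic-data tests do and do not establish.

## Task model and behavior

A session is 16 blocks × 60 trials. The first trial of every block is a
reference (red-frame) trial requiring no response; among the remaining
trials, 25% are switch transitions. Switch flags are allocated by exact
count (`round(p_switch × n_eligible)`) and shuffled rather than drawn
i.i.d., so condition counts are stable at session scale — balanced
designs downstream depend on that. Frames follow deterministically from
the switch flags (a block always starts in the reference frame).

Behavioral generation: per response trial, RT ~
Normal(μ_condition + subject intercept + subject gating-cost shift, σ),
truncated below at 0; draws beyond the 1400 ms response deadline become
no-response trials (neither RT nor correctness recorded). Correctness is
Bernoulli per condition. Defaults (units ms unless noted):

| parameter | default | rationale |
|---|---|---|
| condition RT means | 700 / 722.80 / 650 / 724.16 | plants a 22.80 ms opening and 74.16 ms closing cost on plausible baselines |
| trial RT σ | 150 | typical speeded two-choice spread |
| subject intercept σ | 50 | between-subject general speed |
| subject cost σ (opening/closing) | 27 / 37 | reproduces the reported between-subject cost SDs (~32 / ~40) once trial noise is added |
| accuracy | .95/.9183/.95/.9561 | plants a −3.17 pp opening and +0.61 pp closing accuracy cost |

Accuracy costs get no extra subject-level heterogeneity; binomial trial
noise already approximates the reported spread, and bounded
probabilities make additive Gaussian heterogeneity awkward. Mean RT uses
correct trials only; accuracy is percent correct among *responded*
trials (no-response trials excluded from the denominator — the
alternative convention would conflate misses with errors).

Cohen's d for paired contrasts is d = t/√n. This convention is pinned
because it is the only standard one consistent with the reported
(t, d) pairs at n = 33; it equals mean(diff)/sd(diff).

## EEG forward model

Epochs are −2000…+2000 ms at 256 Hz (configurable). Each trial is
Σ_k topography_k × waveform_k(condition, t) plus spatially correlated
Gaussian noise: channel positions on a Fibonacci hemisphere, covariance
exp(−d²/2ℓ²) with a random length scale per session, unit channel
variance, scaled by `noise_sd`. Correlated noise is deliberate — white
noise makes ICA unrealistically easy. Sources are transient Gaussian
bumps whose amplitude differs between conditions inside a defined
window (the ground-truth "representational" interval). Epochs are
simulated independently; inter-trial bleed-through is not modeled.

What the generator does **not** emulate: ocular/muscle artifacts beyond
amplitude outliers, 1/f spectra, non-stationary noise, volume-conducted
deep sources beyond the synthetic lead field, or any dependence of the
EEG on behavior. Passing tests therefore demonstrate correctness of the
pipeline's algebra and statistics under its own assumptions, not
robustness to real-world artifacts.

## Signal conditioning

Band-pass: 8th-order Butterworth (48 dB/oct per edge) applied
forward–backward (zero phase). Resampling: polyphase with the rational
factor of the rate ratio. Average reference per sample. Automatic
artifact rejection keeps a trial iff, on every channel: peak-to-peak
< 200 µV in every sliding 200 ms window; all samples within ±200 µV;
peak-to-peak > 0.5 µV in every sliding 100 ms window ("activity" is read
as windowed peak-to-peak; windows advance sample by sample and are
evaluated where they fit entirely inside the epoch). Any-channel failure
rejects the whole trial; channel interpolation is out of scope. Baseline
−200…0 ms. Condition selection keeps artifact-free, correct trials with
RT ≤ 1500 ms; subjects with < 50 surviving trials in any condition are
flagged for exclusion.

## Group ICA

Single-level subject PCA (20 components, whitened; a warning if the
eigenvalue fraction drops below 98%), temporal concatenation, extended
Infomax on the aggregate (annealing learning rate, via MNE), and
back-reconstruction C_s = W Y_s. Degenerate (zero-variance) whitened
directions from rank-deficient data are excluded from the Infomax
update and carried as identity rows.

With subject-level PCA, channel topographies are subject-specific
(basis·√λ·A); the exact reconstruction identities (back-projection of
all components = PCA-retained data; ppaf algebra) hold per subject. The
*group* topography of a component is the sign-aligned mean of unit-norm
subject topographies, re-normalized, with the largest-|weight| channel
made positive — component sign and scale are intrinsically arbitrary.
ppaf = 100·(1 − ‖X − X̂_subset‖²/‖X‖²) on PCA-centered data, the
residual-power complement.

For decoding and source analysis, back-projected epochs restore the
subject's PCA channel mean and are then re-baselined per trial. The
re-baselining matters: a single component's back-projection is exactly
rank-1 across channels, so *any* constant offset between two condition
decompositions is noiselessly separable by a linear classifier;
per-trial baseline correction removes constant offsets. A residual
artifact remains by design faithfulness: the two conditions' estimated
component gains differ slightly (ICA scale is arbitrary and estimated
per condition), so a pair whose source is equally active in both
conditions can still decode above chance inside that source's activity
window. This mirrors the analysis design being reproduced (all of its
matched pairs decoded above chance); conclusions should rest on the
cluster-level inference, not on any single pair's AUC.

## ICASSO

Runs resample time points with replacement and restart Infomax from
fresh random initialisations; similarity is |Pearson r| between
component time courses evaluated on the *original* aggregate (well
defined across resamples; computed exactly from the aggregate
covariance). Average-linkage agglomeration on 1 − S; Iq per cluster
(singleton intra-similarity defined as 1); reliable clusters have
Iq ≥ 0.85. The R-index is R(L) = (1/L) Σ_l within_l / min_m between_l,m
with singleton within-dissimilarity 0; its minimum over L suggests the
cluster count, degenerate zero-separation partitions scoring +inf. The
base decomposition's components are prepended as run 0 so each inherits
the Iq of its cluster. Desk-scale runs may estimate each unmixing on a
uniform column subsample of the aggregate; back-reconstruction always
uses the full data.

## Component matching

Templates (condition A) and candidates (condition B) pair when their
topographies correlate at |r| ≥ 0.9; each template shortlists at most 3
candidates, and a greedy pass in descending similarity enforces
one-to-one pairs (overlapping cluster membership is explicitly avoided).
Pairs where either side fails the Iq screen are dropped before decoding.

## Decoding

Features are the channel vector of the back-projected pair at one time
sample, restricted to 0–1500 ms. Classes are balanced by uniform random
undersampling. The classifier is LDA with Ledoit–Wolf shrinkage of the
pooled within-class covariance toward the scaled identity — mandatory,
since rank-1 back-projections make the empirical covariance singular.
Cross-validation: stratified 5-fold, applied twice ("applied twice"
plus "repeated once" is read as 2 total repetitions), repeat r seeded
with seed + r; AUC is averaged over folds × repeats. The
temporal-generalization matrix trains at every time and tests at every
other time within the same folds, so its diagonal equals the
time-resolved curve exactly. The internal fit is vectorized over time
points (per-fold einsum covariance + batched solve); the public
`lda_train` exposes the same model for single time points.

## Cluster permutation inference

Pointwise one-sided Wilcoxon signed-rank tests of AUC − 0.5 > 0 across
subjects (zeros dropped; tie-corrected normal approximation, exact
enumeration via a generating-function DP when ≤ 16 nonzero subjects —
the two regimes agree where they overlap). Supra-threshold points
(p < 0.05) form clusters — contiguous runs in 1D, 4-connected regions
in 2D TG matrices (the conservative adjacency) — with mass = Σ z
(z rather than raw W so masses are comparable across points with
different ties). The null sign-flips each subject's whole map; because
|AUC − 0.5| is flip-invariant, the per-point ranks are fixed and each
draw's W⁺ statistics reduce to two matrix products, with the per-point
critical W⁺ precomputed from the same p machinery. Cluster
p = (1 + #{null max mass ≥ observed})/(n_perm + 1), never exactly zero.
One-sided by default (above-chance decoding); `alternative="less"`
flips the direction.

## Source analysis

The synthetic lead field places voxels quasi-uniformly in a sphere and
channels on the upper cap; gains are Gaussian in channel–voxel distance
and average-reference centered. Sources are fixed-orientation scalars
(the standardization and contrast logic are orientation-agnostic; 3D
dipole moments are out of scope). The inverse is T = Lᵀ(LLᵀ + αH)⁺ with
H the average-reference centering matrix and
α = 10⁻³·trace(LLᵀ)/n_channels by default; standardized power is
j_v²/R_vv with R = TL. Zero localization error for single noiseless
sources (α → 0) is asserted numerically. Window maps average the
standardized power of the trial-averaged, re-baselined back-projection
over a significant TG window (trial-averaged rather than single-trial
input: the stabler and cheaper choice where the procedure is
underspecified). Group contrasts use voxelwise paired t with a
sign-flip null and the 95th percentile of null max |t| as the corrected
threshold; a zero observed statistic is never declared significant even
when the null degenerates.

## Orchestration and problem sizes

`pipeline.run_all` executes the cascade in memory and writes each
stage's artifact (CSV/JSON) to the output directory, so stages are
inspectable and re-runnable from the library; a strict
files-only hand-off between stages was dropped as needless plumbing at
this scale. `PipelineConfig()` defaults are the full-scale analysis settings: 20 PCs,
50 ICASSO runs, Iq 0.85, |r| 0.9, max 3 per template, 5-fold × 2,
0–1500 ms, 1000 cluster / 2500 source permutations, baseline −200…0 ms,
0.5–40 Hz, 256 Hz, 50-trial subject screen, α = 0.05.

The bundled demo (`pipeline.demo_setup`) scales sizes, not thresholds:
12 subjects, 24 channels, 6 blocks, epochs −500…+1800 ms, 8 PCs, 10
ICASSO runs (estimated on ≤16k aggregate columns, Infomax minibatch
512), 200 permutations in both inference layers, 200 voxels, decoding
grid decimated by 2 (128 Hz). Its two planted sources are lead-field
columns of two well-separated voxels (source SNR ≈ 10 at the peak),
with condition effects in 300–500 ms (gate opening) and 400–750 ms
(gate closing). These sizes keep the full cascade comfortably inside a
desk-scale run while leaving every statistical decision identical to
the full-scale configuration.

## Numerical conventions and degenerate inputs

- Ties in centrotype selection break toward the lowest estimate index;
  candidate matching sorts by (similarity desc, indices asc).
- Zero-variance similarity rows are zeroed with a warning; all-zero
  signed-rank differences give p = 1; identical estimates give an
  infinite R-index with a warning; zero-power data make ppaf an error.
- Undersampling keeps an equal-sized class untouched (no resampling).
- All randomness flows through seeded `numpy` generators; identical
  seeds reproduce every artifact byte for byte.

## Known limitations

- The per-condition-ICA gain mismatch described under *Decoding* means
  single-pair AUC curves can exceed chance without a planted condition
  difference; this is a property of the reproduced design, documented
  rather than patched.
- The subject screen and PCA retention warnings are diagnostics; the
  pipeline does not adaptively re-fit with different component counts.
- The synthetic lead field is not a head model; localization claims are
  limited to the estimator's mathematical properties and
  planted-voxel recovery on its own geometry.
- Normality of behavioral costs is reported (Kolmogorov–Smirnov
  diagnostic) but never gates the paired tests.
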