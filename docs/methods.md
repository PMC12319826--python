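# Methods

## The model

`soundbrain` implements voxelwise/parcelwise *encoding models* that predict
BOLD fMRI time series directly from an audio waveform, together with the
machinery to *brain-align* (fine-tune) the audio network on individual brain
data and to quantify the resulting encoding gains.

The feature extractor is the SoundNet architecture: seven blocks of
(1-D convolution → batch normalisation → ReLU), with temporal max-pooling
after blocks 1, 2 and 5.  All convolutions have stride 2, so the cumulative
temporal downsampling at the conv7 output is 2⁷ · 8 · 8 · 4 = 32,768.  At a
22,050 Hz input rate conv7 therefore emits feature frames at
22050/32768 ≈ 0.673 Hz, which is essentially the fMRI sampling rate at
TR = 1.49 s (1/1.49 ≈ 0.671 Hz): one feature frame per brain volume.  The
backbone has 2,874,320 parameters (conv 2,870,256 + batch-norm affine 4,064).

The encoding head implements

    y_i = Σ_k  h_{i,k} ⋆ x_k + b_i

one temporal kernel h_{i,k} per (feature channel k, brain target i) pair,
summed over the N = 1,024 conv7 channels, with a per-target intercept.  With
kernel size 1 this is exactly a mass-univariate linear regression of features
onto BOLD; with kernel size K > 1 the kernel acts as a K-tap FIR filter that
absorbs the haemodynamic lag (and any residual temporal misalignment between
network features and BOLD).  Padding of K−1 zeros is applied on the left
(causal) so a W-frame input yields exactly W output frames.  For a whole-brain
model (210 parcels, K = 5) the head has 1,075,410 parameters; for an
STG-voxel model (556 voxels, K = 5), 2,847,276.

**Frame/TR harmonization.** The conv arithmetic (floor((L + 2p − k)/s) + 1
per convolution, floor(L/pool) per pool) makes a W-TR audio window come out
at W or W+1 conv7 frames (e.g. a 70-TR window of 2,299,815 samples yields 71
raw frames).  Trailing frames are cropped (or zeros right-padded) so the head
always sees exactly W frames.

**Batch normalisation is frozen-statistics.** BN layers normalise by their
*stored* mean/variance (from the weight archive, or the (0, 1)
initialisation) and never update them from data; only the affine (γ, β) is
trainable.  This makes every frozen prefix a pure function of the input —
required for a reproducible baseline and null model — and is the standard
treatment when fine-tuning with very small batches, where batch statistics
are noisy and switching between batch and running statistics moves the
feature distribution out from under the trained head.

**Fine-tuning depth.** Depth `convN` trains blocks N..7 plus the head;
`none` is the frozen-backbone baseline.  Activations below the first
trainable block are computed once per window and cached for all epochs.

## Training

Optimisation is AdamW (decoupled weight decay, applied to kernels but not to
biases or BN affines — the head then behaves like a Ridge regression) on the
MSE between predicted and observed windows, with a reduce-on-plateau
learning-rate schedule (factor 0.5, patience ⌈patience/2⌉) and early stopping
when the validation loss fails to improve by δ for `patience` epochs.  The
weights of the best validation epoch are returned; the *incoming* model
counts as the epoch-0 candidate, so warm-started fine-tuning never returns a
model that validates worse than its starting point.

Two numerical choices matter for linear-head fits at and beyond
interpolation (the noiseless recovery setting):

- **Adam eps.** Near zero residual both Adam moments vanish and the update
  m̂/(√v̂ + ε) becomes noise of order 1 in every coordinate, including the
  ~3,000 per-target coordinates the data do not constrain.  A raised
  ε (1e-2 … 3e-2) suppresses these junk updates; together with weight decay
  and a staged learning-rate anneal (3e-3 → 1e-4) the fit settles toward the
  minimum-norm interpolator.
- **Batch scaling.** Gradients within an optimiser step are scaled so a step
  always follows the batch-mean MSE regardless of batch size (relevant
  because a fixed ε breaks Adam's scale invariance).

Defaults: window 70 TR, kernel size 5, learning rate 1e-2, weight decay
1e-4, patience 10, batch size 1 window.  The grid-search utility trains the
frozen-backbone baseline for each grid point and selects by validation r²
(median over targets, mean over runs); group models use the field-wise
(lower) median of the five individual subjects' configurations and train on
the pooled runs of the five non-target subjects.

## Evaluation and statistics

Per run, predictions of consecutive non-overlapping windows are concatenated
and scored per target with r² = 1 − SS_res/SS_tot (SS_tot about the column
mean).  Negative values are kept; constant target columns yield NaN with a
warning.

Model comparisons are paired across runs: a two-sided Wilcoxon signed-rank
test per target on per-run r² differences (zero differences dropped), then
Benjamini–Yekutieli FDR correction across targets (valid under arbitrary
dependence), significant at q < 0.05.  The signed-rank null distribution is
computed exactly by dynamic programming for n ≤ 25 (midranks doubled to keep
integer weights, so ties are handled exactly); beyond that a tie-corrected
normal approximation is used.  The BY adjustment is delegated to statsmodels;
an independent closed-form step-up implementation
(q_(i) = monotone envelope of p_(i)·m·c(m)/i, c(m) = Σ 1/j) serves as the
test oracle.  The null reference is the same architecture with seeded random,
untrained weights.

Percent-difference maps report 100·(mean_aligned − mean_baseline)/mean_baseline
per target, masked where |mean aligned r²| < 0.05 or the paired difference is
not significant.  The cross-subject transfer matrix applies every subject's
model to every subject's runs and summarises each cell by the per-run
maximum-over-targets r².

## Synthetic data

The generator emulates the structure of a TV-series fMRI dataset: seasons ×
episodes × two runs (a/b) per episode, each run a mono 22,050 Hz soundtrack
(seeded mixture of tones and band-limited noise bursts over a low noise
floor, ~0.4 events/s, amplitude within [−1, 1]) paired with an
n_TR × n_targets BOLD matrix at TR = 1.49 s.  All subjects hear the same
audio per (season, episode, segment), as in the real study.

BOLD is generated by the same function class the head fits: a planted linear
FIR read-out of the (frozen, seeded-random) backbone's conv7 features, plus
i.i.d. Gaussian noise.  Specifics:

- **Identifiability of planted kernels.**  A dense random kernel over
  1,024 channels × K lags has most of its mass outside the row space spanned
  by a desk-scale dataset (≈10³ frames) and could never be recovered even
  from noiseless data.  Planted kernels are therefore drawn inside the
  top-`plant_rank` (default 64) principal directions of the realised lagged
  features, scaled to unit signal variance.  Noiseless recovery is then
  well-posed: the minimum-norm least-squares solution has cosine ≈ 1 with
  the planted kernels.
- **Planted intercept.**  The per-target intercept centres the noiseless
  signal over the dataset, as preprocessed (detrended, confound-regressed)
  BOLD is; an untrained model consequently scores r² ≈ 0 rather than being
  penalised for a spurious mean offset.
- **Noise level.**  Default σ = 1.5 against unit signal variance puts the
  best achievable r² near 1/(1+σ²) ≈ 0.3, matching the upper range of
  encoding accuracies reported for auditory cortex; σ = 0 is used for
  recovery, small σ for directional checks.
- **Subject structure.**  A shared mapping models group-like homogeneity;
  `shared_mapping=False` gives every subject an independent kernel draw
  (subject-specific functional organisation).  The `teacher_perturb_depth`
  option generates BOLD from a copy of the backbone whose conv weights at
  blocks ≥ depth are jittered by `perturb_scale` × their RMS: the frozen
  backbone is then mis-specified and fine-tuning those blocks has headroom.

What the generator does **not** emulate: acoustic realism of speech/music,
haemodynamic biophysics beyond the FIR convolution, spatial correlation
between targets, scanner drift/motion artefacts.  Passing tests on this data
demonstrate correctness of the machinery (shapes, arithmetic, optimisation,
statistics) and qualitative phenomena (subject specificity, fine-tuning
direction), not performance on real fMRI.

## Reference protocols and problem sizes

`soundbrain.protocols` fixes the study conditions used by the test suite and
`scripts/acceptance.py`, at sizes chosen for a single CPU:

- *Recovery*: σ = 0, 10 targets, 20 runs × 100 TR, K = 3, frozen backbone,
  15/5 run split; staged AdamW anneal (3e-3/1e-3/3e-4/1e-4 × 3000/2500/
  2000/1500 epochs, weight decay 0.01, ε = 3e-2) from zero kernels.
  Measures held-out r² and planted-kernel cosine.
- *Null model*: 50 targets, σ = 1.5; mean r² of an untrained model.
- *Transfer*: 3 subjects × 4 runs × 40 TR, subject-specific mappings,
  σ = 0.5; head-only models; row-wise diagonal dominance of the max-r²
  matrix.
- *Fine-tuning direction*: K = 1 head (capacity-limited read-out),
  20 runs × 100 TR, σ = 0.2, teacher perturbed at conv5 with scale 2.0;
  baseline (500 epochs) then conv4 model warm-started from the baseline
  head (120 epochs, lr 3e-4).  With an expressive head (K ≥ 3 × 1,024
  channels against ~10³ frames) a frozen-backbone probe can emulate almost
  any perturbed teacher, leaving no headroom — hence the deliberately
  narrow head in this protocol.

## Known limitations

- The backbone loader accepts an external named-tensor archive; without one,
  weights are seeded random — useful for nulls and synthetic work, but not a
  pretrained audio representation.
- Audio I/O is WAV-only (scipy); FLAC requires libsndfile bindings.
- The season-comparison analysis applies a plain 0.05 threshold per category
  pair with no correction across categories (by design, matching the
  reference analysis); interpret multiple categories accordingly.
- Exact signed-rank p-values switch to a normal approximation at n > 25;
  at n = 48 runs the approximation is accurate but not exact.
- Scene embeddings use unweighted time-mean pooling and timestamp embeddings
  tap the conv5 block output after its pool (hop 8,192 samples ≈ 0.37 s);
  a pre-pool tap (hop 2,048) is available via a flag.
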