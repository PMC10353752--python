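# Methods

This note documents the models, estimators and numerical choices behind
`arcsync`, and what the synthetic-data experiments do and do not show.

## Problem setting

A group of subjects watches the same narrative stimulus whose plot follows
the six-phase dramatic arc (exposition, rising action, crisis, climax,
falling action, denouement).  The package asks three questions of such
data: (1) does moment-to-moment neural similarity across subjects
(intersubject correlation) track the audience's engagement with the
narrative; (2) can continuous engagement be decoded from EEG-derived
features (amplitudes, within-subject connectivity, graph summaries,
spectral ISC bands); (3) do behavioral measures — phase-boundary
judgements and free recall — show the phase structure.

## Preprocessing chain

Raw scalp EEG is processed per subject in a fixed order: zero-phase
third-order Butterworth band-pass (1–40 Hz, applied forward–backward so
the effective attenuation doubles but no phase distortion is introduced —
important because every downstream statistic is a correlation); bad-channel
flagging (a channel is bad when its temporal SD lies outside the
cross-channel mean ± 3 SD; "activity" is operationalised as temporal SD);
an ICA component-rejection *hook* (`apply_component_rejection`) that
reconstructs data with user-supplied component indices removed — automated
artifact classification is deliberately out of scope, as component
selection is an expert judgement; spherical-spline interpolation of bad
channels from their six nearest good neighbours; average re-reference;
downsampling by averaging bins of five samples (1 kHz → 200 Hz; a bin mean,
not a polyphase resampler, so the operation is exactly reproducible);
spherical-spline surface Laplacian (CSD) with medium spline flexibility
m = 4, λ = 1e-5, 50 Legendre terms; per-channel z-normalisation over time
(population SD).

The CSD operator is precomputed once per montage: the regularised spline
system is solved with a mean-zero constraint and the reduced-order
(m − 1) Legendre series applied, giving a channels × channels matrix whose
rows sum to ~0 (constants are annihilated) and which scales a zonal
spherical harmonic of degree n by ≈ n(n+1) — verified on a dense synthetic
montage.  Duplicate electrode positions are rejected rather than
regularised away.

A `bin_stage` switch (`pre`/`post`/`both`) controls whether the 5-sample
binning happens before the CSD, after it, or twice; the default bins once
before CSD, treating a second downsampling of already-200 Hz data as a
no-op consistency statement.

## Dynamic intersubject correlation

The dISC window is a 15-sample rectangle convolved with a Gaussian
(σ = 3 samples), centrally cropped and normalised — at 200 Hz this spans
75 ms.  The taper enters as *weights* of a weighted-moment Pearson
correlation rather than multiplying the signal; this preserves the
correlation scale for constant signals and matches tapered-window usage in
the dynamic-connectivity literature (a `multiply` variant is trivial to
build from the same sliding-moment machinery).  The window slides in
1-sample steps.  Per window, channel and unordered subject pair, the
correlation is Fisher z-transformed with clipping at |r| ≤ 1 − 1e-12 (so
identical signals give a large finite z) and averaged over pairs in
z-space; reported correlations are mapped back with tanh.

Significance against an engagement trace uses phase-randomised surrogates
of the *engagement* series: the Fourier amplitudes are kept bin-wise
(DC and Nyquist untouched) and all other phases redrawn uniformly, which
preserves the amplitude spectrum — hence the autocorrelation — while
destroying phase alignment.  The p-value is
p = (1 + #{null ≥ empirical}) / (1 + n_perm), one- or two-tailed (on |r|),
with Benjamini–Hochberg FDR across channels.  On the common z-scale
R² = 1 − MSE, so both are reported from the same residual.  The default
permutation count is 1000; calibration tests confirm the type-I error at
α = 0.05 stays inside [0.03, 0.07] for independent white-noise inputs.

## Spectral ISC bands

Frequency-resolved ISC between two subjects at one channel is the
magnitude-squared coherence |Gxy|²/(Gxx·Gyy) from Welch estimates
(Hann-tapered, mean-detrended segments).  A 15-sample window cannot hold
two Welch segments nor resolve the delta band, so the spectral stream uses
its own sliding window: 4 s windows stepping by 0.5 s, 1 s segments with
50% overlap (7 segments, 1 Hz resolution).  This is the package's largest
departure from the correlation stream's window and is deliberately
configurable.  Single-segment estimates are refused outright because their
coherence is identically one.  Band summaries average the pair-averaged
coherence over half-open bins (1–4] δ, (4–7] θ, (8–13] α, (14–30] β; bins
in the 7–8 Hz gap belong to no band.  Welch small-sample bias
(~1/segments for independent signals) is acknowledged and tested, not
corrected: every comparison is within a fixed segment configuration.

## Connectivity and graph features

Within-subject dynamic functional connectivity uses the same tapered
window contract: all channel pairs, Fisher z, symmetric with zero
diagonal; 32 channels give 32·31/2 = 496 pair features.  Graph summaries
per windowed matrix:

* **Node degree** — signed strength, the literal row sum of weights.
* **Clustering coefficient** — Onnela form on the positive graph: weights
  rescaled by the maximum, triangle intensities averaged as geometric
  means, nodes with binary degree < 2 set to 0.
* **Betweenness centrality** — Brandes accumulation with edge lengths
  1/weight on the positive graph, fractional path counting, endpoints
  excluded, unreachable pairs contributing nothing.

Negative Fisher-z edges are zeroed for CC and BC (the definitions require
nonnegative weights); a `neg_mode="abs"` switch absolutises them instead.
Degree keeps the signed sum.  All three are verified against exhaustive
brute-force enumeration on small random graphs and against networkx.

## Engagement decoding

Leave-one-subject-out support vector regression: window-feature vectors of
all training subjects are pooled, engagement z-scored, an RBF SVR
(C = 1, ε = 0.1, γ = "scale" — the implementing library's defaults, since
only "nonlinear SVR" is specified) fit after per-fold standardisation on
training statistics, then applied to the held-out subject.  Fold
performance is the Fisher z of Pearson(prediction, observed); fold z's are
averaged and mapped back.  MSE is taken between predictions and the
z-scored target, so R² = 1 − MSE can be negative for a predictor worse
than the mean — exactly the regime a permutation test then adjudicates.

Feature selection (optional, default on) runs inside each fold on training
subjects only: per subject and feature, the window course is correlated
with engagement, Fisher z-transformed, and the z's tested against zero
(one-sample t, p < 0.01); the sign of the mean z is recorded.  An empty
selection falls back to all features (a `skip` mode exists).  A hash check
in the tests asserts the held-out subject's data is untouched during
selection.

The permutation null re-runs the *entire* procedure — selection included —
against phase-randomised engagement.  Because each iteration refits
n_subjects SVRs, a `fast_null_windows` option evaluates both the empirical
statistic and its null on an evenly spaced window subsample, keeping the
comparison internally consistent; recovery experiments use 80 windows and
199 permutations.

Proportion scores aggregate fold-wise selections into region blocks
(frontal/central/parietal/temporal/occipital, assigned by the first letter
of the 10–20 label): block score = mean over folds of selected/possible
features in the block.  The null redraws equal-size selection sets
uniformly per fold; one-tailed p, BH-FDR across blocks.  Per-phase
decoding slices the window grid by the arc segmentation, skips phases with
fewer than 10 windows or constant engagement, and BH-corrects across the
six phases within one feature source.

## Behavioral statistics

Ratings are sample-and-hold resampled onto the EEG clock (pre-first-event
samples take the scale midpoint 5), z-normalised, and summarised by all
pairwise correlations, Fisher-averaged, with per-pair correlation tests
and BH-FDR; constant (degenerate) raters are excluded with a warning.

The segmentation coincidence test counts, at candidate times on a uniform
0.25 s grid, the raters with any stamp within ± 3 s.  The null redraws
each rater's stamps uniformly over the stimulus (preserving per-rater
counts) and records the *maximum* grid count per shuffle, so the
acceptance threshold — the smallest count whose chance exceedance
probability is below α — controls false acceptance anywhere in the
stimulus.  Two choices here were settled by measurement: a ± 1.5 s window
and stamp-only candidates recover only 3–5 of 6 true boundaries under
19 raters with 5 s jitter, whereas the ± 3 s grid scan recovers 5–6 of 6
on every tested seed while accepting nothing from uniform raters
(`half_window=True` restores the narrow reading).  Under the default
conditions the computed threshold is 8 of 19 raters.

Recall similarity is count-based LSA: per phase, a term-document matrix
over the subjects' documents (small built-in stop-word list, frequency
floor 2), truncated SVD with k = 20 components (clamped to the matrix rank
with a warning — synthetic corpora often have rank < 20), cosine
similarity of the score vectors.  The last two (short) phases can be
merged via `merge_last_two`.  Across-phase dispersion is compared by a
one-way ANOVA on per-subject similarity SDs with Šidák-corrected pairwise
Welch t-tests.

## Synthetic-data generator

The generator is first-class code; its defaults are the recovery-test
conditions: 8 subjects, 8 channels, 200 Hz, 120 s, SNR 1, engagement
coupling at two channels (Cz, Pz).

* **Engagement**: a piecewise-constant six-level arc over the consensus
  boundaries (0, 151, 300, 345, 460, 482, 506 s; proportionally rescaled
  for shorter stimuli), smoothed by a 10 s moving average; levels
  (3, 5, 6.5, 9, 4, 2) peak in the climax.  Raters are the curve plus
  i.i.d. Gaussian noise clipped to the 1–9 slider; σ = 2.77 was calibrated
  once by bisection to give a mean pairwise rater correlation of ≈ 0.40
  for 20 raters.
* **EEG**: per channel one 1–40 Hz band-limited realization z_c shared by
  all subjects; subject s, channel c sees
  x = snr · g_c · a(t) · z_c + η, with a(t) the engagement curve rescaled
  to [0.2, 1] (the shared component never vanishes) and η per-subject 1/f
  noise (spectral exponent 1).  Channels with nonzero gain additionally
  share a common band-limited source with weight 0.8 — mimicking a single
  neural source seen by neighbouring electrodes — which is what makes
  *within-subject* connectivity between coupled channels rise and fall
  with a(t); without it dFC carries no engagement signal in this model.
  The shared-component RMS is linear in snr; `snr=inf` yields identical
  subjects.  Electrode positions come from the standard 32-channel cap
  montage normalised to the unit sphere.
* **Segmentation raters**: true boundaries + Gaussian jitter clipped to
  the stimulus, with a fraction `p_random` of uniform responders; stamps
  sorted within rater.
* **Recall corpus**: per phase a shared topic over the front half of a
  120-word vocabulary and per-subject topics over disjoint blocks;
  `topic_overlap` is the shared weight, making expected between-subject
  cosine similarity monotone in it.

What the generator does **not** emulate: volume-conducted artifact
topographies, eye/EMG artifacts, non-stationary noise, rater response
lags, or the lexical structure of real speech.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to real-data pathologies.

## Problem sizes and determinism

Recovery experiments use 120 s cohorts, a 25-sample connectivity hop, 199
permutations and 10–20 generator seeds; spectral experiments use 60 s,
4-subject cohorts.  These sizes were chosen so the estimators operate in
the regime where their asymptotics hold while each experiment completes in
seconds to minutes on one CPU.  All randomness flows through
`numpy.random.default_rng` seeds; every reported number is reproducible
bit-for-bit under a fixed seed.

## Known limitations

* No correlated-component (CCA-style) ISC and no intersubject functional
  connectivity — both are out of scope by design.
* The spectral stream's window necessarily differs from the correlation
  stream's 15-sample window; band ISC values are therefore not directly
  comparable across the two streams.
* The coincidence test's uniform-redraw null ignores rater-specific
  response biases.
* EDF/BrainVision files are read (via MNE) but cohorts are exported to
  HDF5/CSV only.
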