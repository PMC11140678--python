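# Methods

`cortrack` reconstructs features of spoken-word-like stimuli from
evoked MEG sensor responses and asks where in lag space two participant
groups differ. This note documents the models, the estimation and
evaluation procedures, the synthetic data the package ships with, and
the numerical and design choices a user should know about.

## Decoding models

**Convolution (kernel ridge) decoder.** Each time-varying feature
channel `s_f(t)` (an auditory-spectrogram band or the amplitude
envelope, sampled every 10 ms) is reconstructed from a lagged window of
the evoked response `r(t, x)` over sensors `x`:

    s_f(t) = Σ_x Σ_{τ=τ1..τ2} g_f(τ, x) · r(t + τ, x)

Lags `τ` are positive stimulus-to-response delays: neural activity
follows, never precedes, the stimulus sample it encodes, so
reconstructing `s(t)` uses the response from `t + τ1` to `t + τ2`
(overview window 20–420 ms; moving analysis in non-overlapping 20 ms
windows, 20–40 … 400–420 ms). Stacking the lagged response samples as
rows of a design matrix `R` (one row per stimulus × frame, columns
ordered lag-major over sensors), the ridge estimate per channel is

    Ĝ_f = (RᵀR + λ_f I)⁻¹ RᵀS_f        (primal)
        = Rᵀ (RRᵀ + λ_f I)⁻¹ S_f       (dual / Gram form)

The two forms are algebraically identical; the dual form is cheap when
training samples are far fewer than lag × sensor dimensions, the usual
evoked-response regime. The solver is chosen by shape (`solver="auto"`)
and the equivalence is asserted to 1e-8 in the test suite. Each feature
channel is fit independently, with its own penalty.

**Penalty selection.** `λ_f` is selected on a fixed grid (default
`10^k, k = −3 … 6`) by leave-one-out error within the training data.
The left-out unit is one *stimulus* — all of its time frames — because
frames within a stimulus are strongly dependent and row-level LOO would
be optimistic. The fold solutions are obtained by down-dating the
pooled normal equations `(RᵀR, RᵀS)` with the held-out stimulus blocks,
which is exact (tested against refitting from scratch). Two selection
modes exist: `per-split` reselects the penalty inside every
cross-validation fold; `once` selects it once per stimulus–response
pairing and reuses it across folds. The grid optimum is almost always
the same point across folds, so `once` is the practical default for
sweeps and permutations; the equivalence on clean data is part of the
test suite.

**Static ridge decoder.** Non-time-varying features (band power
spectrum, modulation power spectrum, semantic vectors) are decoded from
the flattened 0–1000 ms response with the same ridge machinery, one row
per stimulus, solved in the dual form and with ordinary
leave-one-stimulus-out penalty selection.

**Logistic phoneme decoder.** Each retained phoneme (≥ 10 instances in
the stimulus set) gets an independent binary logistic model on the
lagged design, trained by averaged stochastic gradient descent with an
L2 penalty (scikit-learn's `SGDClassifier`, ≤ 200 epochs, tolerance
1e-6, seeded). A phoneme is called active in a frame iff the predicted
probability is strictly greater than 0.5; single-class training labels
skip the phoneme with a warning.

## Standardization

Features and responses are standardized *across stimuli* before
decoding: spectrogram and band power spectrum per frequency band, MPS
per (scale, rate, band) cell, envelope and each semantic dimension
globally, and the evoked response per (sensor, 10 ms sample). The
z-score uses the population standard deviation (divide by n), so a
two-stimulus feature with values {1, 3} maps exactly to {−1, +1};
zero-variance features are centered at 0, flagged by a warning, and
carry `sd = 0` in the recorded standardization state. Standardizing
across *all* stimuli (training and test) reproduces the original
analysis; a strict mode that recomputes statistics on the training fold
only is available for leakage sensitivity checks (not the default).
Note that per-(sensor, time) response standardization is a
time-varying rescaling that breaks exact convolutional structure; on
noise-free synthetic data the exact-inversion regime is therefore the
unstandardized one, and the tests exercise it there.

## Evaluation

**Leave-two-out pairwise criterion.** Every unordered pair of stimuli
is held out once (C(n, 2) splits; 946 for 44 stimuli). The decoder is
trained on the remainder, both held-out stimuli are reconstructed, and
the pair scores correct when

    sim(s1, p1) + sim(s2, p2) > sim(s1, p2) + sim(s2, p1)

where `sim` is Pearson correlation over the flattened feature cells and
the two items are first truncated to the shorter one's length (from
onset). Exact ties score 0.5 — a probability-zero event for continuous
data that matters only for degenerate inputs. A zero-variance vector's
similarity is defined as 0 with a warning. Accuracy is percent correct
over all pairs, so its resolution is 100/C(n, 2).

**Leave-one-out reconstruction** (Pearson r per held-out stimulus) is
provided as the secondary metric and is used for the noise-free
parameter-recovery checks (r > 0.99 in the well-conditioned regime).

**SNR estimate.** Per stimulus and sensor, the response is z-scored
with its own 300 ms-baseline mean and sd; the reported SNR is the RMS
of the z-scored signal during stimulus presentation divided by the
baseline variance of the z-scored signal, averaged over sensors and
stimuli. Pure noise gives SNR ≈ 1 under this normalization; the text
this estimator derives from is ambiguous about the order of operations,
and this is one documented reading.

## Significance and group statistics

**Label-permutation nulls.** Stimulus labels of the evoked responses
are permuted (within stimulus class where classes exist) and the full
leave-two-out evaluation is re-run; 200 permutations for the
convolution models is the default. The per-participant p-value is the
fraction of null accuracies at or above the observed one (an optional
add-one convention, (count+1)/(n+1), is off by default to match the
plain counting formula). Two significance summaries are reported: the
interpolated 95th percentile of the null, and the operational
alpha = 0.05 *significance level* — the smallest accuracy value above
which the exceedance p-value drops below 0.05. On a fine accuracy grid
(44 items, 946 pairs) the two coincide (~62%); on a coarse grid
(8 items, 28 pairs, 3.57-point steps) only the exceedance construction
respects the grid (~75–79%). Permutations refit the penalty by default
(conservative); a fast mode reuses the observed penalty.

**Lag sweep.** Accuracy is computed per non-overlapping 20 ms lag
window, 20–40 … 400–420 ms (half-open `[start, stop)` windows so each
10 ms lag sample belongs to exactly one window; 20 windows, 2 lag
samples each at 100 Hz). The lagged design spanning all windows is
built once per participant and each window evaluates on its column
subset.

**Group comparison.** Independent-samples Student t (pooled variance,
df = n1 + n2 − 2, matching df = 32 for 17 + 17; Welch available),
Benjamini–Hochberg FDR at 0.05 across comparisons, and Cohen's d with
the pooled sd.

**Cluster permutation over lags.** Per window a pooled t compares the
group accuracy curves; contiguous same-sign windows whose |t| exceeds
the two-sided alpha = 0.05 threshold form clusters; cluster mass is the
sum of t values and the largest |mass| cluster is retained. The null is
built by randomly reassigning participants to two groups of the
original sizes and re-applying the same rule;
p = N(null mass > observed)/N. No observed cluster gives p = 1 with an
empty cluster. The observed t-map and cluster masses agree with
MNE-Python's cluster machinery on shared data (tested).

A consequence worth stating: the largest-cluster statistic makes the
null distribution of p-values *valid but not uniform*. Under
exchangeable groups roughly a third to a half of datasets produce no
supra-threshold cluster at all (20 windows at cluster-forming
alpha 0.05) and receive p = 1, so the p distribution has a point mass
at 1 and the test is conservative. The test suite asserts validity
(P(p ≤ α) ≤ α plus binomial slack); a Kolmogorov–Smirnov test against
U(0, 1) rejects for this structural reason, and the corresponding
uniformity check is expected to fail for any faithful implementation of
the largest-cluster rule.

## Synthetic data

The generator runs the forward model the decoder assumes. Defaults
emulate the study dimensions: two cohorts of 17 participants, 44
stimuli, 56 sensor channels (28 planar gradiometer pairs), evoked
responses at 100 Hz averaged over 20 trials, and stimulus durations
drawn from N(810, 180²) ms truncated to [400, 1400] ms.

**Stimuli.** Each synthetic spectrogram is a sum of 2–5 syllable-like
Hanning bursts (inter-syllable interval ≈ 310 ms, jittered) with
formant-like Gaussian spectral profiles, scaled so every stimulus has
the same RMS power, as the presented sound sets did. Envelopes are the
across-band mean.

**Response functions.** Per participant, an early component (Gabor lag
kernel centered at 100 ms, 40 ms wide, truncated at ±3 sd) and a late
component (broad Hanning kernel over 160–340 ms lag), each projected
onto its own random unit sensor topography, fixed per participant.
The DLD-like group's late gain is multiplied by `deficit_factor`
∈ [0, 1]; `deficit_factor = 1` makes the groups exchangeable and
`deficit_factor = 0` removes late-lag tracking entirely. Kernels are
L2-normalized and the noise-free signal is scaled to unit RMS at the
cohort level (one common scale for both groups, so gain ratios are
preserved).

**Noise.** White Gaussian noise is added after (simulated) 20-trial
averaging: i.i.d. N(0, noise_sd²/20) over the whole window including a
300 ms baseline. The default `noise_sd = 64` (single-trial sd in units
of signal RMS) was chosen so that desk-scale envelope decoding of a
44-item participant lands near 80%, the range reported for real
recordings; single-trial evoked fields sit far below the MEG noise
floor, so a single-trial amplitude SNR of order 10⁻² is the realistic
regime. The noise model deliberately omits 1/f spectra and
spatial correlation (pluggable); white noise averages out more
efficiently than real MEG noise, which is why a large single-trial sd
is needed to reach realistic accuracies. Passing tests on this
generator therefore demonstrate correctness of the estimation and
inference machinery, not performance on real recordings.

**Seeding.** A single master seed; stimuli, the normalization probe,
and every participant draw from deterministically spawned child
sequences, recorded in the participant table.

## Problem sizes used by tests and the acceptance script

Full-scale evaluation (56 sensors, 128 bands, 41 lags) is never needed
to verify the machinery, and the package's own checks run at desk
scale: 16 spectrogram bands, 4–8 sensors, envelope decoding (one
feature channel). Permutation thresholds use one 44-item participant
(200 permutations, fast penalty mode) and, for the 8-item case, the
null pooled over ten participants, because a single 28-pair threshold
estimate is quantized to 3.57-point steps and its upper tail sits near
the 5% boundary. Cluster-test calibration uses 100 null
cohorts of 8 + 8 participants with 8 stimuli; power uses 50 cohorts of
17 + 17 with 10 stimuli at `deficit_factor = 0.5`.

## Known limitations

- The auditory filterbank is a log-spaced Gaussian band filterbank with
  half-wave rectification and 16 ms/10 ms integration — a documented
  approximation of cochlear-model toolboxes, pluggable behind the same
  interface. The modulation filters are Gaussians in the 2-D modulation
  domain with a bandwidth floor (1.5 Hz, 0.5 cyc/oct); upward and
  downward modulations are combined.
- Semantic vectors are synthetic stand-ins; real norms are out of scope.
- The 8-item significance threshold is intrinsically coarse (28 pairs):
  reported levels move in 3.57-point steps, and estimates from 200
  permutations fluctuate by about one step around the population value.
- With only 10 ms sampling, each 20 ms lag window holds two lag
  samples; window-level accuracies are correlated between neighbouring
  windows through the stimulus autocorrelation, which the cluster test
  exploits by design.
- `per-split` penalty selection inside every permutation is the
  conservative default but is computationally heavy; the fast mode
  (reuse the observed penalty) is what the shipped scripts use.
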