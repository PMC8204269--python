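# Methods

This note documents the models, estimators and design choices behind
`brainstates`, what the synthetic generator does and does not emulate, and
the numerical conventions used throughout.

## 1. Data preparation (`prep`)

Input is one `[T × N]` matrix per subject (N parcels). Preparation applies,
per subject:

1. **Band-pass and resample.** Zero-phase (forward–backward) Butterworth of
   order 5 with the requested band (default 1–45 Hz), then polyphase
   resampling to `fs_out` (default 250 Hz). A filter stage whose normalized
   edge lies below 10⁻³ or above 0.99 of Nyquist is skipped: IIR designs
   there are numerically meaningless, and the wide-band limit then reduces
   exactly to the identity.
2. **Standardization.** Per-parcel z-scoring. Applied per subject *before*
   concatenation so between-subject amplitude differences cannot
   masquerade as states. A zero-variance parcel is an error naming the
   parcel.
3. **Symmetric orthogonalization.** The closest (Frobenius) set of mutually
   orthogonal parcel time series under the non-preferential scheme with
   per-column scaling, computed by alternating a polar decomposition with
   least-squares column lengths until the relative change falls below
   10⁻⁹ (cap 100 iterations). This removes zero-lag leakage between
   parcels; it also removes genuine zero-lag coherence, a known property of
   leakage correction. Columns are re-standardized afterwards.
4. **Concatenation** with exact per-subject boundary bookkeeping. The
   ordering standardize → orthogonalize is a package decision (the two
   operations do not commute; the difference is a per-column scale).

## 2. The TDE-HMM (`tdehmm`)

### Embedding and reduction

Each sample is replaced by the window of the signal across lags −7…+7
(L = 15; ±28 ms at 250 Hz), so column (n, l) at row t equals `x[t+l, n]`.
Rows needing out-of-segment samples are dropped — never padded, and never
wrapped across subject boundaries; an alignment array maps each embedded
row to its lag-0 original sample. The embedded data (dimension L·N) are
reduced to P = 4N dimensions by PCA fit on the pooled concatenated matrix
(per-subject PCA would give subjects different bases and break model
transfer); the basis, its mean and eigenvalues are stored for reuse on new
data.

### Model

K states, each a zero-mean Gaussian over the reduced space. The
observation mean is fixed at zero because the data are standardized and the
state contrast is meant to be carried by (auto)covariance alone. Priors are
conjugate:

- transition rows: Dirichlet(1 + 5·δ) — a weak diagonal stickiness, four
  orders of magnitude below the data counts at the default scale;
- initial distribution: Dirichlet(1);
- state precisions: Wishart with P + 2 degrees of freedom and scale chosen
  so the prior mean covariance equals the pooled empirical covariance.

### Inference

Variational Bayes EM. The E-step runs scaled forward–backward per subject
segment under the *expected* log parameters (digamma expressions for the
Dirichlets; the standard expected log-determinant and expected precision
for the Wisharts); the M-step adds expected counts to the priors. The free
energy `F = ΣKL − log Z̃` is evaluated after every E-step and is
non-increasing over full-batch cycles (property-tested); convergence is
declared when its relative change falls below `tolerance`. With
`point_estimate=True` all parameters are treated as fixed at their
posterior means and `F = −log p(y|θ̂)` — tested against a logsumexp
forward-recursion oracle. The Wishart KL term was verified against
numerical quadrature in the P = 1 (Gamma) special case.

**Initialization.** Each restart seeds a k-means clustering of
non-overlapping 25-sample windows described by their per-dimension log mean
square; the window's cluster is soft-assigned (0.9) to its samples. Because
states differ in local (auto)covariance, this lands the optimizer near the
correct basin. The uninformed alternative (`init='chunks'`, random
contiguous chunk assignment) is retained; purely i.i.d. soft starts were
found to converge to merge/split local optima on covariance-contrast data
and are not offered. Restarts (default 10) are ranked by final free energy;
`init_cycles` optionally screens all restarts for a few cycles and
continues only the best.

**Stochastic mode.** `batch_segments` switches to stochastic variational
inference: each iteration updates on a random batch of contiguous segments
(default intent: 15) and blends sufficient statistics with forgetting rate
`0.7·iter^(−0.7)`. Stochastic updates are not monotone in free energy;
full-batch is the default and the mode under test.

**Decoding and transfer.** Viterbi runs in the log domain on posterior-mean
parameters with ties broken toward the lower state index (tested against
exhaustive path enumeration). `apply_model` embeds new data with the
training lag set, projects with the training PCA basis, and runs
forward–backward with every parameter frozen — the mechanism for applying
an observation model trained on one cohort to another.

### Numerical conventions

Covariance scale matrices are symmetrized each M-step and ridge-regularized
by `1e-8·trace/P` only if an eigenvalue falls below 1e-10. Emission
quadratic forms use Cholesky triangular solves. Forward–backward and
Viterbi kernels are numba-compiled when numba is importable, with identical
pure-numpy fallbacks.

## 3. State characterization (`states`)

- **Temporal statistics** are computed on the Viterbi path (hard states):
  fractional occupancy per subject; life times as maximal constant runs;
  interval times as gaps between consecutive *complete* visits. Runs
  touching a subject boundary are censored (excluded), and a state with a
  single complete visit in a subject contributes no interval. Durations are
  reported in ms (`samples × 1000/fs`).
- **State-wise multitaper spectra**: 2 s windows, 50% overlap,
  time-bandwidth 4, 7 DPSS tapers, restricted to 1–30 Hz; windows never
  straddle subject boundaries. The state-k spectrum is the γ-weighted
  window average `Σ_w γ̄_wk S_w / Σ_w γ̄_wk`. When state visits are much
  shorter than the window the estimates mix across states — contrast
  survives (occupancies within a window are competitive) but is diluted;
  this is inherent to window weighting. A state with zero probability mass
  gets NaN spectra rather than an error.
- **NNMF spectral modes**: multiplicative (Frobenius) updates on the
  `[K·N × F]` stack, best of 5 seeded restarts by reconstruction error,
  modes rescaled to unit maximum and returned in descending peak-frequency
  order. Default M = 3 (two oscillatory bands plus a residual mode). The
  factorization is unique only up to the usual NMF indeterminacies; tests
  use generating profiles with anchor rows.
- **Power topographies**: trapezoidal band integrals of the psd per parcel.
  `match_topographies` computes the full (non-symmetric) pairwise Pearson
  matrix between two K-sets and the Hungarian assignment maximizing total
  matched correlation.

## 4. Electrode linkage (`linkage`)

- **Middle bipolar channel**: contacts 4−5 (8-contact shafts) or 8−9
  (16 contacts), 1-based along the shaft; other layouts are rejected. The
  electrode is summarized by this single channel and the midpoint of the
  two contacts.
- **Time-frequency power**: complex Morlet wavelets, 5 cycles, 1–45 Hz in
  0.5 Hz steps (the method is a package decision; any TFR with matched
  temporal resolution would do). The channel is polyphase-resampled to the
  γ rate first, and the embedding alignment selects rows matching γ.
- **Correlation spectra**: per frequency bin, Pearson r between a state's
  γ and the power time course, two-sided p from the t distribution with
  T−2 degrees of freedom (no autocorrelation correction — the plain
  estimator; treat p-values as descriptive). Zero-variance bins are
  flagged invalid and excluded from the peak.
- **FDR**: Benjamini–Hochberg step-up (statsmodels) over the pooled
  within-subject family of all (state, electrode, frequency) p-values;
  also returns the smallest surviving |r| for plotting thresholds.
- **Functional assignment**: the state with the largest peak r, provided
  its peak p < 0.05 (uncorrected); ties break toward the lower state index
  and are flagged.
- **Spatial assignment**: per state, threshold the voxel topography at its
  90th percentile (reading "threshold at 90%" as a percentile — always
  nonempty; 90%-of-maximum is available via `threshold_mode='max'`), take
  the largest 26-connected component on the 8 mm lattice (ties keep the
  component containing the global maximum), and assign the state with the
  smallest mean Euclidean distance from the electrode midpoint to the
  component's voxel centers. Invariant to adding a constant to the
  topography.
- **Agreement**: Pearson χ² test of independence (no Yates correction) on
  the functional × spatial crosstab over electrodes assigned by both
  routes; unassigned electrodes are excluded and counted separately; the
  agreement fraction is the diagonal mass of the full K × K table.

## 5. The synthetic world (`synth`)

The generator emulates the four inputs the pipeline consumes with exact
ground truth. Defaults (the stated world used by the acceptance suite):

| parameter | default | rationale |
| --- | --- | --- |
| states K | 5 | the regime the method is used in |
| sampling rate | 250 Hz | pipeline's working rate |
| parcels | 20 (3 per state + 5 undriven) | desk-scale |
| subjects × samples | 3 × 30,000 (2 min each) | desk-scale fitting |
| self-transition | 0.95 | mean life time 80 ms — the sub-second regime |
| state frequencies | 7, 11, 15, 20, 26 Hz | theta–beta; resolvable within the ±28 ms lag window (a 4 Hz cycle is not) |
| within-state parcel offsets | 0, ±1.25 Hz | incoherent band activity: phase-locked identical sinusoids would be rotated subject-specifically by leakage correction |
| burst amplitude / noise sd | 2.0 / 0.5 | 9:1 burst-to-noise variance contrast in driven parcels |
| envelope | Hann-smoothed occupancy (44 ms taper) | bursts wax and wane; rectangular gates create an artificial transition regime that a lag-embedded model prefers over the true states |
| electrodes | 5 per subject (one per state), 8/16 contacts, gain 2 | contact counts as in clinical sEEG shafts |
| geometry | 3×3×3-voxel parcel blobs on an 8 mm grid; a state's parcels clustered 40 mm apart, clusters 150 mm apart | states are spatially localized networks; electrodes implanted at their coupled state's cluster |

Oscillation phase is a function of absolute time (continuous across
visits). iEEG contacts carry the coupled oscillation with a Gaussian
amplitude profile along the shaft peaked at the first middle contact, so
the bipolar derivation retains it; envelope `1 + gain·env(t)`.

**What a green test does and does not establish.** The generator produces
white Gaussian noise (no 1/f background), stationary state spectra,
noise-free state dynamics exactly first-order Markov, and no artifacts,
bad segments, volume conduction beyond the modelled zero-lag mixing, or
inter-subject variability in state signatures. Green acceptance tests
establish that the implementation recovers a correctly specified world —
not that the method is robust to model misspecification on real
recordings. The Viterbi accuracy ceiling in this world is ≈ 0.94, set by
state visits (80 ms) shorter than the embedding window (60 ms), not by
noise.

## 6. Known limitations

- Window-weighted state spectra are diluted when life times are much
  shorter than the window (see §3); sample-resolution spectral estimators
  are not implemented.
- Correlation-spectrum p-values ignore autocorrelation; a circular-shift
  permutation alternative is a possible extension, not currently shipped.
- Stochastic inference is provided for completeness but is not the tested
  path; its batch construction treats subject segments as the unit.
- `spatial_assign` requires topographies with at least two distinct
  values; truly flat maps are rejected rather than assigned at random.
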