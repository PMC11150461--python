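# Methods

This note documents the models, algorithms and design choices behind
`emgsyn`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Envelope processing

Each raw channel is band-pass filtered 10–400 Hz with a 4th-order
Butterworth applied forward and backward (`sosfiltfilt`; zero phase,
effective order 8), demeaned, full-wave rectified and low-pass filtered at
6 Hz with another zero-lag 4th-order Butterworth.  Two numerical choices:

* Low-pass filtering a rectified signal can produce small negative
  excursions; the envelope is clipped at zero so the non-negativity the
  factorization requires holds exactly.
* At 1000 Hz the 400 Hz band edge sits at 0.8 x Nyquist, which is fine; a
  sampling rate at or below 800 Hz is an error, and below 850 Hz a warning
  is issued because the filter response near the edge is distorted.
* Demeaning is applied after the band-pass (which already removes DC), so
  it is near-idempotent; the order follows standard envelope practice.

The analyzed movement phase of each trial, given as a (start, end) sample
pair, is resampled to 100 uniformly spaced points by linear interpolation
with both endpoints included.  Linear interpolation is the
least-assumption scheme and has a known error bound (grid-spacing²/8 times
the maximum second derivative), which the tests verify.

Per participant, trials are concatenated per task (6 x 100 = 600 columns)
and each muscle row is divided by that muscle's maximum over all tasks of
that participant, so 1 marks the muscle's peak activation anywhere in the
session and a single task's matrix may peak below 1.  A muscle that is
all-zero across every task makes the normalization undefined and is
reported by name.

## Factorization

NMF minimizes the Frobenius reconstruction error by alternating
non-negative least squares: each half-update solves its subproblem exactly
with a block-principal-pivoting NNLS solver (`_nnls.nnls_multi`) that
batches the many right-hand sides by shared passive set; columns that
fail to converge (near-singular normal equations) fall back to scipy's
active-set NNLS.  Exact alternating updates make the residual
non-increasing, which is asserted in tests.  A multiplicative-update
solver is available behind `solver="mu"` as a fallback/benchmark.

* Initialization: entries uniform on (0, 1] from the restart's child seed,
  `SeedSequence([seed, restart])`, so runs are reproducible and restarts
  independent.
* Convergence: absolute change of the residual norm below `tol x ||E||_F`
  (default 1e-6) or `max_iter` (default 500); non-convergence returns the
  best iterate flagged `converged=False` rather than raising.
* A synergy that collapses to zero mid-run is reseeded with small random
  values; otherwise the alternating updates could never revive it.
* Each fit is repeated from `restarts` (default 50) random starts and the
  highest-tVAF solution is kept, then normalized so every W column has
  maximum 1 with the matching C row scaled inversely (the product is
  unchanged; tVAF is invariant, verified to 1e-9).

tVAF uses the uncentered total sum of squares, the convention of the
synergy literature: `100 (1 − SSE/SST)` with `SST = Σ E²`.  It is not
clamped, and a zero envelope matrix is an explicit error.

The tVAF curve runs k = 1..m−1 (configurable upper bound `k_max`).  The
selection criteria assume a non-decreasing curve, but a restart stuck in a
poor local minimum can violate that; a drop at k+1 triggers one re-run
with fresh restart seeds, and if the value is still lower it is replaced
by the value at k and the index recorded in `monotonicity_adjusted_k`.

## Synergy-number selection

NoS is the smallest k satisfying both criteria at once: tVAF(k) strictly
above 90 and, unless k is the last curve point, an increment to k+1 of at
most 1 percentage point.  The conjunctive reading is the only one that
yields a single well-defined count; thresholds are parameters.  If no k
qualifies, the last k is returned with a `fallback` flag rather than an
error.  NoSoA is the arithmetic mean of all NoS values rounded half-up
(the tie rule is recorded here because 0.5 means are possible with 21
values; the emulated study's 4.14 is insensitive to it).  The coefficient
of variation uses the sample (n−1) standard deviation over the mean;
summaries are reported at 2 decimals with full precision kept internally.

## Similarity and alignment

* CosSim, Pearson r: standard definitions; zero vectors and constant
  vectors are errors, not NaNs.
* The sharing threshold for synergy vectors is the two-tailed critical
  Pearson r at the muscle count: `r = t / sqrt(t² + df)` with
  `df = m − 2` from the inverse central t distribution — 0.623 for 16
  muscles at p = 0.01.  It is computed, not hard-coded, so other montages
  work.
* r_max is the maximum Pearson correlation between two activation
  waveforms over integer lags, computed on the overlapping region only.
  By default it operates on the concatenated 600-point rows with the lag
  window bounded to ±10% of one 100-point trial block, which prevents
  spurious cross-trial alignment; a trial-averaged mode is available by
  passing 100-point rows.  A positive lag means the second waveform is
  delayed.  Ties go to the smallest |lag|, negative first; zero-variance
  overlaps are skipped.
* Alignment across participants: greedy assignment that repeatedly accepts
  the globally most similar remaining (reference, other) synergy pair by
  CosSim, ties broken toward the lowest reference index.  W columns and C
  rows are permuted together.  Greedy is the documented method; an
  exhaustive assignment (k ≤ 8) exists as a test oracle.  On random
  unstructured weight pairs greedy occasionally lands a few percent below
  the exhaustive optimum (tests bound this); on structured synergy data
  the two agree.

## Reconstruction and randomized nulls

Fixing W and refitting C (or vice versa) is a set of independent exact
NNLS problems, one per envelope column, solved by the same
block-principal-pivoting solver.  Because the target's own decomposition
minimizes the same objective over both factors, tVAF_rec can never exceed
the target's own tVAF (up to solver tolerance) — an invariant the tests
assert.  Scaling a fixed W column by α scales the refit C row by 1/α.

The chance floor draws one uniform(0,1) random matrix per real source
(W-style matrices are column-max-normalized), preorders it against the
corresponding real source's factor by greedy CosSim matching, and refits.
Using as many random as real sources keeps tVAF_rand averages comparable
with tVAF_rec averages.  Uniform entries are the minimal-assumption
non-negative choice; everything is seed-controlled.

For cross-task reconstruction the fixed factor is preordered against the
target task first (synergies are only ordered within tasks): B's W is
permuted by matching B's coefficient rows onto A's before refitting A's
coefficients, and symmetrically B's C is permuted by weight-vector
similarity before refitting A's weights.

## Shared-synergy counting

All column pairs between two tasks are scored by Pearson r; pairs are
accepted greedily in descending r while above the critical value, each
synergy used at most once (one-to-one matching — the reported ranges
presuppose it, and it keeps `n_shared ≤ min(k₁, k₂)`).  The relative
count is `100 n / (k₁ + k₂ − n)`.  sharedOA compares every task at the
common rank NoSoA; sharedIND at each task's own NoS.  A synergy is shared
across all three tasks only when the three pairwise matchings agree
transitively (a in A matched to b in B and c in C, with (b, c) matched in
the B–C comparison); this makes the all-task claim well-defined.

## The synthetic-data generator

The generator emulates the study design the pipeline targets — 7
participants x 3 tasks x 6 trials, 16 muscles at 1000 Hz — with known
ground truth:

* **Weights.**  Per-task study-level templates: each synergy has 3–4
  dominant muscles (weights 0.6–1) over a weak floor (0–0.15), column max
  1.  Declared shared synergies reuse the identical template column across
  tasks; undeclared cross-task template pairs are redrawn until their
  correlation stays well below the sharing threshold, so the declared
  structure is the only structure present.  Every muscle is guaranteed a
  weight ≥ 0.3 in at least one task-specific synergy: a montage records
  movement-relevant muscles, and a near-silent channel would be
  carrier-noise-dominated and unrecoverable by construction.  Participants
  get multiplicative weight perturbations (SD `participant_variation`,
  default 0.25) with renormalization; the perturbed shared column is
  reused across that participant's tasks.
* **Activations.**  One Gaussian burst per synergy on the 100-point phase,
  tails truncated to exact zero below 2% of the burst amplitude.  The
  truncation matters: real bursts switch off between subtasks, and the
  resulting anchor windows (times where a single synergy is active) make
  the factorization identifiable — without them exact alternative
  factorizations exist and ground-truth recovery is ill-posed.  Shared
  synergies burst early (16–30% of the phase, the 'jump' role) with one
  burst profile reused across tasks; task-specific bursts are spread over
  45–88%.  Per-trial variation: center jitter (`timing_jitter_sd`, % of
  phase) and amplitude scaling (`trial_amplitude_sd`, default 0.1).
  Trial-to-trial envelope variability is not characterized by the emulated
  study, so it is a free parameter rather than a fitted value.
* **Raw signals.**  White noise band-passed 20–380 Hz (unit variance,
  zero mean) multiplied by the intended envelope upsampled onto the
  analyzed window, plus a small constant modulation floor
  (`baseline_level`, default 2% of the trial peak).  Trials are 1400
  samples with the analyzed phase at samples 200–1200: the margins exceed
  the zero-lag filters' warm-up, and the 1 s phase gives bursts realistic
  durations (30–60 ms) that the 6 Hz envelope low-pass can track — with a
  much shorter phase the smoothing smears the bursts and envelope fidelity
  degrades.  Envelope noise (`envelope_noise_sd`, fraction of the trial
  peak, default 0.05) is added to the intended envelope before modulation.
* **Determinism.**  Everything derives from one integer seed through
  `SeedSequence` children keyed by participant/task/trial; identical
  configurations and seeds reproduce signals bitwise.

What the generator does **not** emulate: volume conduction / crosstalk
between channels, electrode lift or motion artifacts, non-stationary
carrier spectra, force–EMG nonlinearity, and any biomechanics of the
movement itself (events are inputs, not detected).  Passing tests
therefore show that the pipeline recovers planted synergy structure
through a realistic signal chain — not that any particular real dataset
satisfies the synergy model.

Because the pipeline's amplitude normalization rescales muscle rows by
their cross-task maxima, recovered weights live on a rescaled axis;
`expected_weight_matrix` applies the same row scaling to the ground truth
(and re-imposes column max 1) so recovery is scored on the scale the
pipeline actually sees.

## Problem sizes used in tests and the acceptance script

NMF restarts and the k-range are robustness knobs, not study conditions;
the package default mirrors the emulated analysis (50 restarts, k up to
m−1), while tests and `scripts/acceptance.py` use 3–10 restarts and k up
to 8 — on the generated data the best-of-restarts solution is stable well
below 50 restarts, and NoS never approaches 8.  The acceptance script
runs the full 7 x 3 x 6 study; simulation-based tests use 1–3
participants and 4–6 trials per condition.  All seeds are fixed.

## Known limitations

* The alternating solver guarantees monotone residuals but only local
  optimality; the restart scheme mitigates, and the curve monotonicity
  repair handles the rare residual artifacts.
* Greedy matching is order-dependent on near-tied similarities; ties are
  broken deterministically but a different tie rule could change
  individual matchings (not the counts, in practice).
* The critical-r threshold treats muscle weights as paired observations,
  the convention of the sharing literature; weights are not actually
  i.i.d. samples, so the threshold is a calibrated convention, not a
  hypothesis test.
* r_max on concatenated rows with a bounded lag window slightly penalizes
  waveforms whose timing differs by more than the window; the
  trial-averaged mode trades that against cross-trial smearing.
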