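# Methods

## The model

`semigait` models a stream of inertial-sensor features with a triplet chain:
activity `X_n ∈ {1..r}`, gait/leg phase `U_n ∈ {1..τ}` (τ = 4), and a
minimum-remaining-sojourn counter `D_n ∈ {0..ℓ}`, observed through a
per-cell Gaussian mixture with latent component indicator `H_n ∈ {1..κ}`.
Only the full tuple is assumed Markov; none of the marginal processes needs
to be.  The joint transition factorizes as

    p(v', h', d', y' | v, d) = p(v' | v, d) · p(h' | v') · p(d' | v', d) · p(y' | v', h')

with

    p(v' | v, d) = δ_v(v')            if d > 0,    p*(v' | v)   if d = 0
    p(d' | v', d) = δ_{d-1}(d')       if d > 0,    p(d' | v')   if d = 0.

The counter freezes the regime for a *minimum* dwell and then releases it —
the chain may stay arbitrarily longer, it is simply free.  This differs from
explicit-duration HSMMs, which force an exit when the drawn sojourn elapses
and therefore need the duration support to cover the longest plausible
dwell; here `ℓ` only needs to cover the *shortest* guaranteed dwell, which
keeps the composite state count `r·τ·(ℓ+1)` small.

Phases follow a fixed structural graph: within an activity, self-loops and
the cycle `1→2→3→4→1`; across activities, only `(a, phase 1) → (b, phase 2)`.
Activity changes are thereby synchronized with stride boundaries.  The graph
is represented as a boolean mask; masked entries of `p*` are exact zeros and
every estimation step preserves them (estimates are renormalized on the
allowed support).

### Parameters

| parameter | shape | default | meaning |
|---|---|---|---|
| `r` | — | data-dependent | number of activities |
| `tau` | — | 4 | gait/leg phases per cycle |
| `ell` | — | 9 | largest minimum sojourn (samples); 0 disables the semi-Markov part |
| `kappa` | — | application-dependent (CLI default 6) | mixture components per cell |
| `w` | — | 12 | feature dimension (6 axes × mean/std) |
| `zeta` | `r·τ·(ℓ+1)` | factored `ζ_v · p(d\|v)` | initial law over composite states |
| `pstar` | `(rτ)²` | — | regime-switch matrix, used at `d = 0` only |
| `pdur` | `rτ × (ℓ+1)` | — | fresh-minimum-sojourn law per cell |
| `c, μ, Σ` | per cell × component | full covariances | mixture emission parameters |
| `reg_floor` | — | 1e-6 | lower bound on covariance eigenvalues |

How the *initial* counter is distributed is not identifiable from a single
sequence start; the default factors the initial law as `ζ_v · p(d|v)`, and a
fully joint distribution over `(v, d)` is accepted everywhere.

Transitions are stored factored (`pstar`, `pdur`) rather than as the dense
composite matrix: the countdown rows are deterministic, so the dense form
carries no extra information, and the factored estimate preserves the
semi-Markov structure under learning by construction.  `joint_transition`
materializes the dense matrix for inspection and cross-checks.

## Inference

Filtering, smoothing, pairwise posteriors, mixture responsibilities and the
log-likelihood come from a forward–backward recursion over the composite
chain, using the factored structure: a push-forward costs
`O(n_v² + n_v·ℓ)` per step instead of `O((n_v·ℓ)²)`.

The recursions run in **log domain** with per-entry log-sum-exp.  On sharply
separated gait data the per-state likelihood spread within a single step
routinely exceeds the ~745 log-units that double-precision probability
scaling can represent — at a hard activity boundary the smoothed posterior
can sit hundreds of log-units below the filtered mode, and probability-space
scaling (even with per-step renormalization) collapses those states to exact
zeros.  All exported posterior tables are ratio forms, so they are returned
in probability space; per-step scales cancel and the per-step log
normalizers accumulate into the sequence log-likelihood.

Decoding is MPM: the per-sample argmax of the smoothed (batch) or filtered
(on-line) activity and phase marginals.  Ties break to the lowest index.
Joint MAP (Viterbi) decoding is deliberately not provided.

Emission log-densities are computed through Cholesky factors, so any
strictly positive-definite covariance is usable regardless of conditioning;
an indefinite covariance raises an error naming the offending component.

## Batch learning

EM alternates exact smoothing with closed-form updates: the initial law
takes the first smoothed marginal; `pstar` and `pdur` renormalize the
accumulated pairwise posteriors restricted to transitions out of `d = 0`
(the only stochastic rows — a dense estimate would re-derive the countdown
entries exactly, so nothing is lost); weights, means and covariances are
responsibility-weighted moments with the biased `1/N` covariance (no Bessel
correction).

The same update is expressible through five per-sample expectation tables —
pairwise free transitions `S¹`, composite occupancies `S²`, cell/component
occupancies `S³`, weighted observation sums `S⁴` and outer-product sums
`S⁵` — and the two routes agree to floating-point precision
(`params_from_stats(complete_stats(post)) ≡ m_step(post)`); the test suite
pins this identity at 1e-12.  The statistics route is what the on-line
learner blends.

Numerical choices:

* **Covariance floor.** After each update, covariance eigenvalues are
  clipped from below at `reg_floor = 1e-6` *in the eigenbasis of the
  estimate*.  Eigenvalue clipping is the exact maximizer of the expected
  complete-data log-likelihood over the constrained covariance set, so EM
  remains monotone; an additive diagonal floor does not have this property
  (it perturbs healthy covariances every iteration and fights variance
  collapse with persistent small likelihood decreases).  A well-conditioned
  covariance passes through unchanged.
* **Starved rows/cells.** Transition rows or emission cells whose expected
  occupancy is below 1e-10 keep their previous value (or fall back to
  uniform over the allowed support when there is no previous value); a
  starved mixture component keeps its moments while its weight follows the
  vanishing occupancy.
* **Dead components.** A component whose weight reaches exactly zero can
  never recover.  `em_fit(..., rescue_dead=True)` re-seeds such a component
  once, at the observation farthest (Mahalanobis) from the cell's occupancy
  center.  Re-seeding necessarily breaks that iteration's monotonicity
  guarantee, so it is off by default.
* **Stopping.** `max_iter = 100` with relative log-likelihood tolerance
  `1e-6` by default.
* **Multiple sequences.** `em_fit` accepts a list of sequences (one per
  subject/recording); each gets its own forward–backward pass restarting
  from the initial law and the statistics pool length-weighted.
  Concatenating recordings instead would fabricate impossible transitions
  at the seams.

### Supervised initialization

Training recordings carry activity labels but no phase labels.  Phases are
pseudo-labelled by a documented heuristic: the smoothed gyroscope magnitude
is peak-picked per constant-activity segment (minimum cycle spacing 0.4 s),
each detected cycle is split into four phases by duration quartiles, and the
margins reuse the nearest cycle length.  Per-cell mixtures are then fitted
with k-means-seeded EM (scikit-learn), `pstar`/`pdur` come from pseudo-label
transition and run-length counts (a run of length `L` is a censored draw
`min(L−1, ℓ)` from the sojourn law), and everything is masked and
renormalized.  The heuristic only needs to be roughly phase-consistent —
batch EM refines all parameters afterwards — and it is swappable: true
phase labels can be passed in directly.

## On-line learning

Every `W_l` samples (default 1000, i.e. 10 s at 100 Hz) the buffered window
is smoothed under the current parameters, its expected statistics (averaged
per sample) are blended into the running ones,

    S ← (1 − ρ_m) S + ρ_m S_window,

and all parameters except the initial law are refreshed in closed form.
Decoding stays causal throughout: each sample is labelled from the filtering
distribution the moment it arrives, and a parameter refresh lags the data
that produced it by at most one window.

Design choices where the procedure is under-determined:

* **Stepsize indexing.** `ρ` is indexed per update (`ρ_m = 1/m`), not per
  sample — the statistics are blended once per window, and a per-sample
  `1/n` with windowed blending would shrink the steps `W_l`-fold too fast.
* **Warm start.** When the stream begins from a batch-trained model, the
  running statistics can be seeded with the training data's expectations
  (`FitReport.final_stats`) and `OnlineConfig.warmup` set to the number of
  window-equivalents they represent, making the schedule `1/(warmup + m)`.
  Stochastic approximation counts all absorbed data; restarting the count
  at deployment means the very first window (`ρ_1 = 1`) *replaces* the
  running statistics, so a window containing a single activity erases every
  other activity's transition and emission statistics — on confusable
  subjects this self-reinforces and can collapse recognition entirely.
  The bare `1/m` schedule remains the default.
* **Window prior.** The filtering distribution carried into the window
  start serves as the smoothing prior, so no backward pass ever crosses a
  window boundary and memory stays `O(W_l)`.  Windows are disjoint blocks.
* **Degenerate windows.** A window whose smoothing underflows (possible
  when the current model assigns the whole window essentially zero
  likelihood) is skipped with a warning rather than corrupting the
  statistics; a stream shorter than one window is decoded without updates.

With `ρ ≡ 0` the learner reduces exactly to batch filtering; a single
window spanning the whole sequence with `ρ = 1` reproduces one batch EM
iteration except for the initial law.  Both reductions are pinned by tests.

## Features

Per axis (3 acceleration + 3 angular rate): trailing mean and population
(`1/n`) standard deviation over a sliding window — 12 features per sample.
The window is causal so batch and on-line modes see identical features, and
it shrinks at the start of a recording so feature, label and sample indices
stay aligned.  Window length is 15 samples at 100 Hz and 5–8 at 25–50 Hz in
the studies here: roughly the shortest gait-phase duration, below which the
standard deviation estimate degrades and above which phase detail blurs.

## Synthetic data

Two generators, both seed-deterministic:

* `sample_model` simulates the generative process exactly (countdown
  dynamics, mixture emissions) for oracle tests, recovery studies and the
  dwell-guarantee check.
* `make_pseudo_imu` emits a 6-axis pseudo-IMU signal: per activity a
  phase-locked waveform (fundamental plus one harmonic) with
  activity-specific cycle frequency and per-axis amplitudes, plus white
  noise.  Phase labels are the cycle quarters; activity switches are
  synchronized with the cycle (a segment ends on a phase-1 sample and the
  next begins at phase 2), matching the transition graph.

Fixture realism is calibrated, not maximal: cycle frequencies are spread
geometrically so between-subject frequency variation cannot swap two
activities' identities; per-subject variability multiplies amplitudes and
frequencies by `1 ± U(0.6, 1.4)·jitter` (every subject deviates by a
comparable relative amount); an optional fixed sensor-frame rotation
(`placement_angle`, default 0.15 rad in the studies) emulates mounting
differences — the systematic, learnable mismatch an adaptive recognizer
actually faces; and the noise level (2× amplitude at feature level) is
chosen so cold-start held-out accuracy lands in the mid-90s% range reported
for real recordings rather than saturating.  What the generator does *not*
emulate: biomechanics (no ground-reaction transients, no double-support
asymmetry), sensor drift or bias instability, non-periodic or static
activities, and within-subject gait variability over time.  Passing tests
on this fixture therefore demonstrate correctness of inference, learning
and adaptation mechanics under realistic separability — not performance on
any real population.

The packaged studies (`loocv_run`, `run_two_section_study`) use scaled-down
problem sizes — 3–4 synthetic subjects, 12–25 s activity segments, two
protocol sections — chosen so the full pipeline (supervised init, ~8 EM
iterations, streaming with 10 s update windows) runs in a few minutes on a
single core.  The two-section study prepends a 10 s last-activity lead-in so
both sections are entered through the same activity switch, which keeps the
section comparison structurally fair.

## Evaluation

One-vs-rest per activity: sensitivity (equal to per-activity accuracy),
specificity, F1 and Matthews correlation, plus overall accuracy; undefined
ratios (empty denominators) report 0.  Totals are emitted both pooled
(sample-weighted over the joint confusion matrix) and macro-averaged, since
the two differ whenever folds are unbalanced.  A binned accuracy trace
(default 10 s bins) tracks on-line convergence.  The leave-one-subject-out
runner trains per fold on the remaining subjects and decodes the held-out
subject by smoothed MPM.

## Known limitations

* The gait-phase pseudo-labelling is a heuristic; its phase origin is only
  defined up to a rotation of the cycle, so phase agreement should be read
  modulo rotation.
* On-line adaptation is unsupervised self-training: with a badly wrong
  starting model it can reinforce its own errors (the warm-started schedule
  mitigates, but cannot eliminate, this).
* Static and non-periodic activities are outside the model's assumptions —
  every activity is assumed to drive a periodic four-phase cycle.
* Histogram (non-parametric) emission densities and automatic selection of
  `κ` are not implemented.
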