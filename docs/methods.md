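# Methods

## The classification problem

Atrial fibrillation (AFib) and atrial flutter with irregular ventricular
response (AFlu) can produce nearly indistinguishable RR-interval series on a
surface ECG, yet require different treatment. The package discriminates the
two from short RR series (nominally 22 intervals at 1 ms precision) by asking
a mechanistic question: *can a regular atrial rhythm, filtered through a
plausible multilevel atrioventricular (AV) block, reproduce the observed
intervals?* A good fit argues for AFlu (regular atrial activity, deterministic
blocking); a poor fit argues for AFib (chaotic atrial activity that no
deterministic block can explain).

## Forward model: multilevel AV block (MAVB)

Atrial activations form a perfectly regular train, `t_0j = t_s + j·Δa`, with
atrial cycle length `Δa`. Up to three blocking levels are stacked; the
conducted output of one level is the input of the next. Each level follows a
ratio pattern of `n+1 : n` blocks (`1:1` passthrough permitted), optionally
alternating between two ratios (e.g. `2:1 / 3:2`), starting at a phase offset
`o` inside the concatenated decision cycle. Levels are

* **Type II (Mobitz)** — fixed conduction delay `c`; every `(n+1)`-th signal
  is dropped abruptly; or
* **Type I (Wenckebach)** — the `k`-th conducted signal of a cycle is delayed
  by `c + (k−1)·δ`; the counter resets after the dropped beat.

The conducted times at the last level are the simulated ventricular
activations; their successive differences are the simulated RR intervals.
A single-level `n+1:n` Type I block has the closed-form RR pattern
`(n−1)` intervals of `Δa + δ` followed by `2Δa − (n−1)·δ`, which the event
simulator reproduces exactly and which serves as an independent check.

Two observations simplify the search space:

* `t_s` shifts every activation equally and cancels in RR differences, so it
  is fixed to 0; phase alignment is carried by the per-level offsets.
* The base delay `c` of each level also shifts *all* of that level's conducted
  times equally, so RR intervals are invariant to it. It is kept in the
  forward simulator's interface but excluded from the inverse search (fixed
  0): it is not identifiable from RR data.

### Blocktype presets

Five presets span the clinically reported configurations; they live in a
registry (serialisable to YAML/JSON), so changing them is configuration, not
code:

1. single Type I level, free ratio `n+1:n`, `n ∈ 1..5`;
2. single Type II level, free ratio, `n ∈ 1..5`;
3. fixed `2:1` Type II level feeding a free-ratio Type I level;
4. three Type II levels: alternating `2:1/3:2`, then twice alternating
   `1:1/2:1`;
5. two stacked free-ratio Type I levels, `n ∈ 1..3` per level.

The `n ≤ 3` cap in preset 5 keeps the default 1 ms grid enumerable on a single
CPU; all ratio ranges are registry entries and can be widened.

## Inverse simulation

The fit minimises the Euclidean deviation
`F(x) = ‖simulated RR − observed RR‖₂` (ms) over the feasible set `X`:
blocktype, `Δa` on a 1 ms grid within physiological bounds (175–400 ms,
narrowed per structure by `ρ·mean(RR)·(1 ± 0.25)` where `ρ` is the structure's
mean conducted fraction — the bounds are data- and blocktype-dependent by
design), per-level phase offsets, and delay increments `δ ∈ [0, 100]` ms on
the same grid. A candidate whose simulation deviates by more than 150 ms on
any single interval is *clipped* — discarded as infeasible rather than
penalised — which is what makes the objective landscape piecewise quadratic
with jump discontinuities. If every candidate is clipped the solver returns a
sentinel (infinite objective, no parameters) instead of raising; downstream
features saturate such samples at `sqrt(n)·150` ms, the largest value a
feasible candidate could attain.

The search is an exact enumeration, accelerated in three sound ways:

1. **Linearity.** With the discrete structure (blocktype, ratio choices,
   offsets) fixed, every simulated RR interval is linear in
   `θ = (Δa, δ₁, …, δ_L)`, because blocking decisions are pattern-based, not
   timing-based. Each structure's whole grid is evaluated as vectorised
   matrix products; monotonicity of conduction times reduces to linear
   constraints `Cθ > 0` checked on the surviving candidates.
2. **Clipping as interval arithmetic.** Each interval's clip condition
   confines `Δa` to an interval given the `δ` grid bounds; the intersection
   over intervals often empties the grid for irregular inputs, rejecting
   whole structures at once.
3. **Prefix-norm pruning** (optional, on by default). Squared residuals
   accumulate monotonically, so a candidate whose prefix norm exceeds the
   incumbent can be discarded. Candidates *equal* to the incumbent are kept
   so that tie-breaking is unaffected; toggling pruning never changes the
   result.

Ties are broken deterministically: lowest `Δa`, then lowest blocktype id,
then lexicographically smallest per-level parameter vector (ratio `n`,
offset, `δ` per level). Distinct parameter points can generate identical RR
sequences — most commonly, prepending a `2:1` level while halving `Δa`
changes nothing — so the reported blocktype can alias. Ordering `Δa` first
makes the smallest consistent atrial cycle the canonical representative,
which keeps noiseless parameter recovery exact; the objective value is
unaffected by the choice.

On integer inputs and grids (the 1 ms measurement grid), the vectorised path
and the scalar brute-force oracle (`brute_force_solve`, one forward event
simulation per candidate, no pruning) are bit-identical: residuals are
integers, so sums of squares are exact in double precision. The oracle is the
reference in the test suite; it is practical only on coarse grids
(tests use 5 ms grids, 12 intervals, and pairs of blocktypes per instance to
bound its runtime).

A one-interval sensitivity scan (perturb one interval by −400…+400 ms at
1 ms, re-solve each time) exposes the landscape: within each maximal segment
where the argmin parameters are constant, `F²` is *exactly* quadratic in the
offset (the perturbed interval contributes `(r − offset)²`), which the tests
verify via vanishing third differences; the jumps between segments are the
clipping discontinuities.

## Features

* `rawRR` — N-gram statistics of the raw series: means of all `n(n+1)/2`
  contiguous subsequences plus sample standard deviations (ddof 1) of the
  `n(n−1)/2` subsequences of length ≥ 2 — `n²` features, ordered by start
  index then length.
* `heatObjective` — the optimal deviation `F(x*)` alone.
* `heatSolution` — `[F(x*), Δa*, blocktype id, oc*₁..₄, RRvar, RRmean]`
  (9 features; the per-level parameter vector is zero-padded or truncated to
  length 4 — configurable via `OC_ENCODING_LENGTH`; multi-level presets carry
  more than 4 free values, so the fixed-length encoding necessarily truncates
  them).
* moving horizon — all stride-1 windows of length `n_sub ∈ {10..n_rr}`
  (`n_rr − n_sub + 1` windows; 6 at the study default `n_rr=22, n_sub=17`)
  are fitted independently, producing per-window series of the objective, the
  solution encoding, and a cross-window robustness term: window `k`'s optimal
  parameters evaluated on window `k+1` (the last window on its predecessor).
  That adjacent-window pairing is the minimal choice giving one
  generalisation measure per window.
* `heatSerAvg` / `heatSerAvgAge` — mean and sample sd of each of the 8
  component series (16 features; + age). The component count follows from the
  solution encoding length and is configurable.
* `heatSeries` — N-gram statistics of each component series, concatenated.

Standardisation (zero mean, unit sd per feature) is fitted on training data
only and applied unchanged at evaluation time; constant features get scale 1
with a warning. Sample (ddof 1) standard deviations are used for all
subsequence features so length-2 subsequences are well defined.

## Classifiers and validation

AFib is the positive class. Models:

* **Threshold** — the decision score *is* the (possibly sign-flipped)
  single feature; the cut maximising training accuracy is the threshold.
  Used for the one-dimensional `heatObjective` classifier.
* **SVM** — scikit-learn `SVC` behind a training-fold-fitted standardiser;
  kernel ∈ {rbf, poly}, `C` and `γ` (3 values each) and `n_sub` form the
  hyperparameter grid (2·3·3·13 = 234 configurations at the full window
  range).
* **CNN** — two convolutional blocks (two width-2 convolutions with 5
  filters and ReLU each, max-pool 2, dropout), a fully connected ReLU layer
  (12 units) and a sigmoid output unit; trained with Adam at default
  parameters (batch 32, up to 200 epochs, early stopping on a 10%
  validation split, patience 20). Implemented directly in numpy with fully
  seeded initialisation, shuffling and dropout, so training is exactly
  reproducible. Dropout ∈ {0.1, 0.2, 0.3} and `n_sub` are its grid. The
  network has a few hundred weights, sized to the small labelled sample.

Evaluation is repeated stratified 10-fold cross-validation; hyperparameters
are chosen by an inner stratified grid-search CV nested inside each outer
training fold (the leakage-free reading of grid-search tuning), with
first-in-grid tie-breaking. Accuracy and ROC area (trapezoidal rank method
on decision scores) are reported as mean ± sd over folds; sensitivity and
specificity pool held-out predictions over all folds.

## Synthetic benchmark

The clinical dataset is private, so a generator emulates its statistical
structure (380 samples, 190 per class, 22 intervals each):

* **AFlu** — the forward model itself: `Δa ~ N(240, 20)` ms rounded to the
  grid (constant within a sample, consistent with the sub-5 ms regularity of
  flutter), a uniformly drawn blocktype preset with random on-grid offsets
  and increments (`δ ≤ 40` ms), plus independent `N(0, 5 ms)` measurement
  jitter, rounded back to integers. Ground-truth parameters are stored for
  recovery scoring; with jitter 0 the solver recovers every sample exactly.
* **AFib** — a gamma renewal atrial process (mean cycle 182 ms, CV 0.25)
  filtered by concealed conduction: an impulse conducts only if the time
  since the last conducted beat exceeds a refractory period redrawn per beat,
  uniform on [250, 550] ms. This is our construction (the study describes
  its AFib data only statistically); it produces irregular RR with a
  controllable route to pseudo-regularisation.
* **Pseudo-regular AFib** (5% of the AFib class) — the same mechanism with a
  narrow refractory distribution [265, 290] ms, calibrated so the mean
  ventricular rate is ≈ 160 beats/min (mean RR ≈ 375 ms). RR variability
  collapses despite the chaotic atrial input, and the block model fits these
  samples markedly better than ordinary AFib — reproducing the documented
  failure mode.

What the generator does **not** emulate: real measurement artefacts,
premature beats (excluded from the clinical series by design), within-sample
atrial cycle drift, atrial cycle/refractory correlations, and the
patient-level clustering of the clinical data (each synthetic sample is its
own patient). Passing tests on this benchmark therefore demonstrate internal
consistency of the method and qualitative reproduction of the study's
separation finding — not clinical performance. In particular the
near-perfect ROC of the objective threshold on synthetic data reflects the
generator's idealised classes; the clinical figure is necessarily lower.

## Problem sizes and numerical choices

* Default grids: 1 ms for `Δa` and `δ`; clipping threshold 150 ms; `Δa`
  slack τ = 0.25. All configurable via `SolverConfig`.
* Oracle-equivalence checks run 20 instances of 12 intervals on 5 ms grids
  with rotating blocktype pairs; recovery checks run 10 draws per preset at
  22 intervals on the full 1 ms grid.
* The benchmark evaluation solves all 380 samples at full length on the
  default grid, runs the threshold classifier under 10×10-fold CV, and
  compares raw-N-gram vs model-feature SVMs under 10-fold CV with 2 repeats
  and the 18-configuration kernel grid at fixed `n_sub = 22` — sizes chosen
  to keep a complete run on one CPU in minutes while leaving the conclusions
  unchanged.
* Degenerate cases: series shorter than 2 intervals are rejected; windows
  shorter than 10 are rejected; a single-window moving-horizon series
  reports sd 0 with a warning; empty blocktype sets yield the sentinel
  solution.

## Known limitations

* The blocktype presets are provisional reconstructions of the clinically
  common configurations; the registry exists precisely so they can be
  corrected without code changes.
* Parameter aliasing means the reported blocktype — and occasionally even
  `Δa*` — is not unique: distinct grid points can generate bit-identical RR
  sequences (a constant series of `T` ms is explained by any cascade with
  `k` atrial beats per conducted beat and `Δa = T/k` in bounds, and richer
  multi-level constructions reproduce patterned sequences too). The
  canonicalisation and tie-break make the reported representative
  deterministic and usually the generating one; the objective value is
  always unique. How densely such aliases populate the space of RR series
  is an open mathematical question of the method.
* The heatSerAvg feature count (16) follows from this package's solution
  encoding; other encoding lengths give other counts, and the published
  dimension table is not internally reconcilable with a single encoding —
  the encoding length is therefore left configurable.
* The CNN baseline is deliberately tiny and CPU-bound; it exists as a
  comparison point, not as a tuned deep-learning contender.
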