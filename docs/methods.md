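# Methods

`s5m` mines short subsequences of labeled time series (*shapelets*) that are
simultaneously (i) statistically associated with a binary phenotype and
(ii) structurally representative of the candidate pool.  This note records
the model, the algorithmic choices, the simulation design and the known
limitations — including two places where the method, implemented faithfully,
does not deliver what one might hope for.

## Model and procedure

**Distance and prediction.**  For sequences `r` (shorter) and `s` (longer),
`dist(r, s)` is the minimum Euclidean norm of the pointwise difference over
all alignments of `r` slid along `s`.  A shapelet is a pair `(s, θ)`; it
predicts label 1 for a series `t` iff `dist(s, t) ≤ θ`.  Values are compared
raw — no z-normalization by default — because in the intended applications
(clinical severity scores, vital signs) the level carries meaning.  A
`znorm` flag exists for data where it does not.

**Candidate scoring.**  Candidates are all sliding windows of the requested
widths (identical value sequences deduplicated by default).  For each
candidate, all `n` series distances are computed and every observed distance
is tried as a threshold; each threshold yields a 2×2 table of prediction
against label, scored by the 1-df chi-squared independence test without
continuity correction (a config flag flips it on).  Tables with an empty
prediction margin carry no information and are defined to have p = 1.  The
candidate's score `p_min` is the minimum p over thresholds, ties broken
toward the smaller threshold.  Note this is the *observed* minimum over a
scan — see "Error control" below.

**Multiplicity corrections.**  Bonferroni divides the target family-wise
error rate α (default 0.05) by (number of candidates × number of thresholds
per candidate).  The Tarone-style threshold is the largest δ = α/k such that
at most k candidates have `p_min < δ`; candidates below δ are *testable*.

**Representative subset selection.**  Similarity is `sim = 1/(1 + dist)`.
A representative set R of a ground set S is scored by the mixture

    f(R) = λ_mix · f_fl(R) + (1 − λ_mix) · f_sr(R) + λ_size · |R|,

where `f_fl` (facility location) is the mean over S of the best similarity
to a representative and `f_sr` (sum redundancy) is the total ordered-pair
similarity over S minus the same total within R, both including diagonal
self-pairs.  Defaults λ_mix = 0.5, λ_size = 1.  With the diagonal
convention, each added representative already costs (1 − λ_mix) through the
redundancy term, so the positive size term acts as a per-item admission
budget: an item improves the mixture only while its similarity mass to the
current representatives is below λ_size − (1 − λ_mix) plus its coverage
gain.  Implementing the size term as a subtraction instead (the
`size_term_sign` flag) makes every admission gain ≤ λ_mix − (1 − λ_mix)
− λ_size < 0 at the defaults, i.e. no item is ever selected; the additive
form is therefore the default.

**Streaming selection.**  Items arrive one at a time; the state keeps the
growing representative set R̂ and the discard set B (initialized empty), a
lazily grown pairwise-similarity cache, per-item best-similarity-to-R̂/B
arrays and running pair-sum totals, so each arrival costs O(processed)
similarity evaluations (asserted by an operation counter in the tests).  For
a new item the gains of (a) promoting it to R̂ and (b) removing it again
from B are computed against the current processed ground set; the
facility-location normalizer is the processed count N for the promote side
and N − 1 for the discard side (removing the item shrinks the effective
ground set; the `max(·, 1)` guard makes the very first arrival
deterministic).  The item joins R̂ with probability a⁺/(a⁺ + b⁺) (negative
gains clipped); when both clipped gains are zero the probability falls back
to 0.5.  Two behavioral consequences worth knowing:

* *Coin-flip admissions at the head of the stream.*  While B is still
  empty, the discard-side gain is also non-positive, so redundant arrivals
  are admitted with probability 0.5 rather than rejected — the streaming
  optimizer systematically over-selects near-duplicates early.  This is
  inherent to the fallback rule, and it is why the optimizer tends to
  return more items than the greedy baseline on replicate benchmarks.
* *Saturation freeze.*  Once the similarity mass of R̂ to any new item
  exceeds the admission budget (≈ 0.5 at the defaults) the promote gain
  clips to exactly zero while the discard gain is positive, so the
  acceptance probability is exactly 0 for every later arrival.  Selection
  is therefore strongly arrival-order dependent: families of shapes that
  first appear after the freeze are never represented.

**Interleaved mining.**  Candidates are streamed in ascending `p_min` order
(stable in extraction order) through the streaming selector.  Discarded
candidates are excluded from the multiple-testing correction; after each
admission the significance threshold tightens to δ = min(δ, α/|R̂|) (never
raised again, starting from the α floor), and members with `p_min ≥ δ` are
evicted to B permanently, largest p first.  An arrival that is already
above the current δ is evicted before the threshold moves, which makes the
early exit — stopping at the first candidate with `p_min ≥ δ` — provably
equivalent to processing the full stream (tested).  The two-stage variants
run the same components in sequence instead: representatives-then-Tarone,
Bonferroni-then-representatives, Tarone-then-representatives, and the
interleaved loop with a similarity-cutoff representativeness rule whose
cutoff τ is drawn uniformly on (0, 1) once per run.

**Greedy baseline.**  `greedy_select` deliberately re-evaluates the
published objective from scratch (including the quadratic pair sums) at
every candidate step.  That is the cost profile the streaming optimizer is
designed to beat; the runtime-scaling study measures exactly this contrast.

## Simulation design

The generator builds two benchmark families from five fixed prototype
subsequences (ramp up, ramp down, peak, valley, step; length 7, amplitude
±2, user-replaceable): *replicate sets* (each sequence is a prototype plus
i.i.d. Uniform(−σ, σ) noise) for optimizer comparisons, and
*planted-shapelet classification sets* (case series of length m = 20 are
uniform noise with one noisy prototype overwriting a random window; controls
are pure uniform noise; the injection is recorded) for the mining study.
The benchmark grid is n ∈ {100, 200, 500} × σ ∈ {1, 2, 5} × 5 repetitions;
the scaled-down study run by the acceptance script and tests drops n = 500
and keeps the full σ grid, because the high-noise cells are where the
correction strategies separate.

The prototype amplitude is calibrated so the σ grid spans the regimes the
method comparison is about: at σ = 1 detection is comfortable for every
correction (hundreds of candidates clear even the Bonferroni bar); at σ = 2
the Bonferroni bar starts to miss; at σ = 5 no candidate clears Bonferroni
and only ~50 are Tarone-testable, so the multiplicity strategy alone decides
what is found.  Retrieval is scored by mapping each returned shapelet to its
most similar prototype: `k_d` is the number of distinct prototypes hit,
recall = k_d/|R|, precision = k_d/|R̂|, F1 their harmonic mean, and
`min_sim` the worst best-match similarity.  Per-repetition F1 values are
compared across pipelines with Welch's two-sided unequal-variance t-test,
pooled over the grid (per-cell tests can be had from the per-run table).

What the generator does *not* emulate: integer-valued clinical scores (and
hence heavy ties in the distance profiles), irregular sampling, missing
data, autocorrelated backgrounds, or case/control imbalance.  Passing tests
on this benchmark therefore says nothing about, e.g., the pruning
pathologies that discrete-valued data can trigger.

## Error control: a documented deficiency

The per-shapelet score `p_min` is a minimum over ~n dependent threshold
tests, and under the null its distribution is far from uniform: simulation
shows a median around 0.04 and P(p_min < 0.01) ≈ 0.14 for n = 100.  The
interleaved loop compares this scanned statistic against α/|R̂| with |R̂| a
handful, so on pure-noise data with shuffled labels essentially every run
yields discoveries: the measured null family-wise error rate of the mining
pipeline is ≈ 1 (reported honestly by the acceptance script as
`null_fwer_s5m`).  Controlling the FWER in this framework would require
counting testability by the minimum *attainable* p-value of each
(candidate, threshold) pair given its margins — the construction used by
the earlier per-hypothesis significant-pattern-mining framework — which is
deliberately out of scope here.  Treat returned "significant" sets as
ranked, diversity-pruned association candidates, not as FWER-controlled
discoveries.

## Equivalence of the interleaved and two-stage Tarone pipelines

Under common random numbers the interleaved pipeline and the
Tarone-then-representatives pipeline process the identical ascending-p
prefix of candidates with identical streaming decisions; the candidates
unique to the interleaved stream (p between the two-stage Tarone threshold
and α/|R̂|) arrive only after the saturation freeze, where the acceptance
probability is exactly zero.  In every cell of the benchmark grid the two
pipelines return bit-identical sets, so the expected power advantage of
interleaving does not materialize at the default mixture weights — the
Welch comparison between them is reported as computed (t = 0, p = 1).  The
advantage would require a regime in which the testable prefix is shorter
than the saturation point, which λ_mix = 0.5, λ_size = 1 and this
similarity scale do not produce.

## Numerical choices

* Thresholds are the exact observed distances; duplicate distances collapse
  to one split.  The all-inclusive threshold (every series predicted 1) is
  degenerate and scores p = 1.
* Chi-squared p-values come from the closed-form statistic
  n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) and the χ²₁ survival function.
* Candidate ordering ties break by extraction order (series, width, start),
  making every run reproducible; stochastic steps draw from one seeded
  generator per run, and pipeline variants compared under the same seed
  share their random numbers.
* Incremental caches are float64 running sums, verified against from-scratch
  recomputation to 1e-9 relative tolerance at every step of sampled runs;
  eviction rebuilds the best-similarity array (maxima cannot be
  decremented) in O(|R̂| · n).
* Exhaustive search refuses ground sets above 14 items; its ties break
  toward smaller, then lexicographically earlier subsets.

## Problem sizes used by the default study

Method comparison: 2 × 3 grid × 5 repetitions × 4–5 pipelines at m = 20,
window width 7.  Null calibration: 20 pure-noise runs at n = 100.  Recovery:
5 seeds at n = 200, σ = 0.5.  Runtime scaling: replicate sets of 50–400
items.  These sizes keep the full study in the minutes range on one core
while preserving each phenomenon measured.
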