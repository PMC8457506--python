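# Methods

## Signal model

A squiggle is modelled as a step-current series `x[0..L)` in pA, one value
per segmented translocation event. The gold standard model for a known
reference is the series of k-mer model means over the sequence's windows
(`|seq| − k + 1` events); for direct RNA the windows are enumerated from the
3' end, matching translocation order (`orientation="three_prime"`,
switchable). k is read from the model file (typical direct-RNA tables use
k = 5). Event indices are 0-based and intervals half-open throughout.

## DTW core

The alignment cost between two series is the minimum over monotone,
boundary-complete index paths (steps (1,0), (0,1), (1,1), unit weights) of
Σ|a_i − b_j|. This single cost function is used for every reported distance
so numbers from different stages are comparable. Design points:

* **No amplitude normalisation before alignment.** Reads of one ensemble
  share a pA scale; per-read z- or MAD-normalisation removes genuine
  similarity between them. Callers may normalise explicitly if comparing
  across devices.
* **No global band constraint by default.** The duplication structure we
  must detect is exactly what a tight Sakoe–Chiba band would suppress.
* **Deterministic traceback**: ties prefer the diagonal, then the move
  consuming side A. Co-optimal paths exist; every consumer only relies on
  path cost and stretch-run structure, and an exhaustive-enumeration oracle
  (`dtw_oracle`, feasible to length 8) pins the optimal distance in tests.
* The quadratic DP kernels are numba-compiled; a two-row variant computes
  distance-only queries in O(min(n,m)) memory.

## Cleaning cascade

Stages run in a fixed order, each computing its ensemble statistics once on
its own input (so the result does not depend on within-stage removal
order): length < 20% of mean → drop; leader strip; length re-check; global
3σ filter on per-read mean level, level σ and length (a statistic with zero
ensemble spread is skipped); sectional filter comparing each read's mean of
10 per-section σs against the ensemble at 2σ. Sample (n−1) standard
deviations are used everywhere. `SNR_LENGTH = mean(length)/sd(length)`
summarises length consistency before/after.

Leader detection: the trailing quarter of a read supplies reference
statistics; fixed windows (default 10 events) are scanned from the start,
and a window is leader-like iff |window mean − tail mean| > 3·tail σ or
window σ > 3·tail σ. The boundary is the end of the initial contiguous
leader-like run, capped at half the read. The cap means a read can never be
classified as pure leader; truly degraded reads are caught by the length
filters instead. Leaders statistically identical to the body are
undetectable by construction. Sectioning splits a read into 9 equal floors
plus a remainder-absorbing last section; reads shorter than the section
count are rejected with a recorded reason.

## Averaging

All three DTWA algorithms anchor the consensus length at a medoid (the read
minimising the sum of squared DTW distances to the rest; ties to the lowest
index) and track the Frechet function F(x) = Σ_n dtw(x, read_n)².

* **DBA** aligns every read to the current consensus and replaces each
  consensus position with the mean of all read values warped onto it.
  Because our reported DTW uses |·| local cost rather than the squared cost
  of classical barycentre analyses, monotone descent of F is not a theorem
  here; DBA therefore evaluates F after each update, discards an update
  that would increase it, and stops — the recorded history is non-increasing
  by construction and the returned consensus attains its last entry. In
  practice updates descend and convergence (relative change < `tol`,
  default 1e-4) takes well under 10 iterations. Reads are processed in
  read-id-sorted order internally so floating-point accumulation order is
  fixed: the result is bit-identical under input permutation.
* **MM** updates incrementally: after visiting read t, x ← ((t−1)x + y_t)/t
  where y_t is the read warped onto the consensus grid. The medoid fixes
  the length only (the first visit replaces its values). Order dependence
  is documented, not forbidden.
* **SSG** initialises from the medoid of a seeded random subsample (default
  size 16) and steps x ← x − η_t·2(x − y_t) with η_t = step0/√t
  (step0 = 0.25, keeping 2η_t ≤ 1 so each step is a damped move towards the
  warped read), shuffling the visit order each epoch. Fixed seed ⇒
  bit-reproducible.

## Voting

Aligning voter n to the consensus yields warp paths WP_CONSENSUS /
WP_SQUIGGLE-n. A maximal run where one voter index pairs with k ≥ 2
consecutive consensus positions means the voter was stretched — the
consensus is locally duplicated. Each voter casts one vote per position on
the run's all-but-first positions (deleting all-but-first makes a pure
duplication collapse exactly to its source; which run member is "the"
original is unidentifiable, so the convention only needs to be consistent).
The mirror case (consensus stretched against a voter) is tallied as
insertion evidence but never modifies the consensus: the correct value to
insert is not determined by the warp path, and a wrong insertion would bias
downstream modification analysis.

The sweep applies the *original* vote table at each threshold of a
descending grid (default 100% → 10% in 5% steps) as a single-pass deletion
(no re-averaging or re-voting), using ≥ so 100% agreement is attainable.
Voted length is therefore monotonically non-increasing along the sweep.
Selection takes the threshold minimising the mean DTW distance from the
voted consensus back to the voters — gold-free; ties break to the larger
threshold (fewer deletions). The voter set may be a superset of the
averaging set. Gold-based distances, when a gold model is supplied, are
recorded for evaluation only.

## Simulator

`simulate` generates the study conditions: i.i.d. uniform gold levels on
[65, 125] pA (the pore's working range, reproducing the high-entropy
character of a k-mer-model squiggle); per emitted event a duplication run
starts with probability 0.234, its extra-copy count drawn as
max(1, ⌈Gumbel(loc 2, scale 1)⌉) — extreme-value run lengths, ceiled and
floored at 1 since the discretisation of the underlying dwell process is
not observable; per-event deletion probability 0.02; Gaussian level noise
σ = 2 pA re-sampled per emitted event (duplicates are repeat measurements,
not bit-copies). The closed form
E[len ratio] = 1 + 0.234·E[max(1, ⌈G⌉)] − 0.02 = 1.70 fixes these defaults
at the ×1.7 inflation level observed across real ensembles; the Gumbel tail
sum is evaluated with scipy. Leaders: length ~ N(50, 15²) events (min 1),
levels ~ N(body mean + 90 pA, (2·body σ)²) — an open-pore-like amplitude
well above the 3σ detectability condition. Chimeras concatenate a full read
with a 20–80% prefix of a second read *including that molecule's leader*
(the unrecognised junction retains the adapter signal — this is what makes
chimeras detectable by the sectional filter, as in real data); short reads
keep 5–15% of their events; global outliers are shifted ±20 pA whole-read.
Default corrupt fractions are 5% each. Every draw flows from explicit
seeds; truth annotations (per-event source position, leader length,
corruption flags) ride along on each read.

What the simulator does **not** emulate: dwell-time distributions and raw
3000/4000 Hz current (we start from segmented events), homopolymer merges
as a distinct mechanism (subsumed under deletions), k-mer-dependent noise
heteroscedasticity, and systematic deviations of real pores from the OEM
k-mer table. Passing tests therefore demonstrate correct behaviour of the
pipeline under duplication/deletion/noise/leader/chimera distortion, not
calibration against any particular flow cell.

## Problem sizes in the test suite

Unit tests use toy series and 300-event golds with 16–32 reads. The
end-to-end recovery check runs twenty replicates of gold lengths drawn in
[800, 1300] with 64 reads (≈1.7× inflated), rotating DBA/MM/SSG across
replicates — one algorithm per replicate gives the same per-algorithm
coverage at a third of the alignment cost. DBA there runs with max_iter 4,
tol 1e-3: voting needs the consensus's duplication structure, which is
fixed by the medoid after the first few barycentre updates, not a fully
converged average.

## Known limitations

* Insertion voting is detection-only by design; a consensus derived from an
  ensemble with many deletions will stay short.
* The MM update is one reasonable reading of "incrementally updated
  consensus equivalent to DBA"; other published incremental variants weight
  visits differently and would give slightly different (still
  order-dependent) results.
* The global/sectional filters use plain means and σs and are therefore
  subject to masking under heavy contamination (>~30% corrupt reads).
* `dtw` materialises the full n×m cost matrix when a path is required
  (~32 MB at 2000×2000); distance-only queries avoid it.
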