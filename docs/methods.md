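# Methods

## The model

Convergent cross mapping treats a pair of observed time series X, Y as two
projections of one underlying deterministic (possibly chaotic) dynamical
system. Takens' delay-embedding theorem guarantees that, generically, the
lagged-coordinate map

    m_y(t) = (Y(t), Y(t−τ), …, Y(t−(E−1)τ))

is an embedding of the system attractor whenever E exceeds twice its box
dimension; the reconstructed point cloud ("shadow manifold" M_y) then
preserves neighborhood structure. If X causally drives Y, X's states are
dynamically imprinted on Y's history, so neighborhoods in M_y select time
indices at which X was in similar states — and X becomes predictable *from
the effect's record*. The asymmetry of this construction is what gives the
test its direction: predicting X from M_y ("Y xmap X") tests X → Y.

Assumptions worth keeping in mind: the series are equally spaced and
complete (non-finite values are rejected at load; interpolate upstream);
the dynamics are stationary over the record; coupling is strong enough to
imprint but not so strong that the driven variable fully synchronizes to
the driver, in which case both directions cross-map and the test loses its
asymmetry. Strong common forcing by a third variable can likewise induce
spurious convergence.

## The estimator, step by step

1. **Embedding.** Points ordered by time, tagged by the time index of the
   leading (most recent) coordinate; the first valid tag is (E−1)τ
   (0-based). Pairwise Euclidean distances are computed once per (E, τ)
   and reused across library sizes and τ_p values.
2. **Simplex projection.** For a held-out target m_y(t), the E+1 nearest
   library neighbors (the simplex of the embedding dimension), excluding
   the target itself and optionally a Theiler window of ±w time steps,
   give weights u_i = exp(−d_i/d_1) normalized to sum to one. If d_1 = 0
   the weights are uniform over all zero-distance neighbors. Distance ties
   are broken toward the earlier time index.
3. **The causal delay.** The point at time t predicts the opposing series
   at t − τ_p: positive τ_p means the cause precedes the effect. Manifold
   points whose shifted index would precede the record are clipped from
   the sweep up front, so every prediction is valid by construction.
4. **Skill.** ρ_ccm is the Pearson correlation between held-out and
   predicted values. A window in which either side has zero variance gets
   ρ = 0 (flagged and counted) rather than NaN so that parameter
   optimization remains total.
5. **Library sweep.** For each library size L, every window of L
   consecutive manifold points (stride 1) yields one leave-one-out ρ; the
   reported skill at L is the mean across windows. Averaging per-window
   correlations (rather than pooling all predictions into one Pearson)
   keeps each window's skill on its own scale; pooling is a plausible
   alternative and tends to agree at large L.
6. **Convergence verdict.** Δρ = ρ(L_max) − ρ(L_min) plus the relative
   difference Δρ / max(|ρ(L_max)|, 1e−6). The default causal verdict
   requires Δρ ≥ 0.1 and ρ(L_max) ≥ 0.2. Both thresholds are configurable;
   the criterion is inherently qualitative, and these defaults encode
   "visible rise, non-trivial terminal skill". A high flat curve is
   association, not causation, and does not converge.

## Parameter search

The objective for a cell (E, τ_p) is the **maximum over the library grid**
of the windowed mean ρ — the plateau of the convergence curve — not the
convergence delta; convergence remains a separate verdict evaluated at the
optimum. Defaults for a series of length N: E ∈ {2, …, min(10, ⌊√N⌋)},
τ_p ∈ {0, …, min(10, ⌊N/5⌋)}, and ~8 library sizes evenly spaced from
max(E+2, 10) to the usable point count. Records shorter than 25 points
draw a warning; shorter than 10, a refusal.

Cyclic coordinate descent alternates full line scans of the E and τ_p
axes, stops when a cycle leaves the position unchanged (or after 10
cycles), and breaks ties toward smaller E, then smaller τ_p. Two
refinements matter in practice, both discovered on synthetic fixtures with
known structure:

- **Diagonal ridges.** In a deterministic system, X(t−τ_p−1) is itself
  predictable from X(t−τ_p), so a larger embedding can trade off against a
  longer delay; the skill surface then carries a ridge along (E+k, τ_p+k)
  on which axis-aligned scans stall at a coordinate-wise local maximum.
  The search therefore probes the four diagonal neighbors whenever a cycle
  stalls, and runs from three deterministic corner starts (min/min E-scan
  first, max-E/min-τ_p τ_p-scan first, min-E/max-τ_p) taking the best
  terminal. On 5×5 grids over random forced-map fixtures this matches the
  exhaustive argmax on 10/10 fixtures (8/10 for a single start).
- **Audit path.** `full_surface` evaluates every cell exhaustively — the
  data behind the sensitivity heatmaps — and its argmax is the reference
  the descent is tested against. Infeasible cells (too few usable points
  for max(E+2, 10) library members after τ_p clipping) are reported as
  missing, never as zero.

Both causal directions are optimized independently: the asymmetry between
them is the method's point, and nothing forces the two manifolds to share
an optimal embedding.

## Synthetic systems

**Coupled logistic maps** (the canonical cross-mapping benchmark):

    X(t+1) = X(t)·(r_x − r_x·X(t) − β_yx·Y(t))
    Y(t+1) = Y(t)·(r_y − r_y·Y(t) − β_xy·X(t))

Defaults: n = 400 after a 100-step burn-in, r_x = 3.8, r_y = 3.9,
β_xy = 0.32 (X drives Y), β_yx = 0, observation noise off. The driven
map's growth rate is deliberately high: with a weakly chaotic driven map
(r_y ≲ 3.7) forcing of 0.32 induces partial synchronization and the
*non-causal* direction retains spurious skill of ρ ≈ 0.2–0.4 — a real and
instructive failure mode of the method, but not the regime a
direction-recovery benchmark should sit in. At r_y = 3.9 the driven map's
intrinsic chaos dominates its own dynamics, the false direction stays
near ρ ≈ 0, and the true direction still converges to ρ ≈ 0.85.

Note the forcing enters Y(t+1) through X(t): the causal delay of this
system is one step, and the tuned τ_p* recovers 1 (or 2 along the
E/τ_p ridge), not 0. Noise here is observational only (added after the
dynamics), so the ground-truth coupling stays exact. Trajectories that
escape (0,1) trigger a reseed with a warning; collapse to a fixed point
(variance < 1e−8) warns without rejecting.

**Predator–prey oscillator** emulating a two-species laboratory microcosm
sampled every 12 h for 30 days (n = 60, dt = 0.5 days): Lotka–Volterra
dynamics (prey growth α = 1.1 /day, attack rate 1.0, conversion
efficiency 0.5, predator mortality 1.0 /day) integrated by classical RK4
with 20 substeps per sample, giving a period of ≈ 6 days (12 samples).
The top-down coupling (attack) is stronger than the bottom-up coupling
(conversion), matching the asymmetry such systems show.

Two noise sources, both multiplicative log-normal so trajectories stay
strictly positive: per-step demographic *process* noise (sd 0.1) and
*observation* noise on the samples (sd 0.02). The process noise is a
deliberate deviation from the observational-only policy used for the
logistic maps, and it is load-bearing: a deterministic limit cycle is a
closed one-dimensional orbit that either variable's manifold reconstructs
perfectly, so cross-map skill is symmetric regardless of the coupling
strengths, and the expected top-down dominance cannot appear. Cycle-to-
cycle variability from demographic noise is precisely what lets the
asymmetric couplings express themselves (top-down ≥ bottom-up terminal
skill in ~18/20 seeds). Thinning this record from 60 to 20 samples
collapses the convergence verdict (from ~19–20/20 seeds to ~6/20),
reproducing the known breakdown of the method between 20 and 30 points.

What these generators do *not* emulate: secular trends, irregular
sampling, measurement floors/saturation, regime shifts, and external
common drivers. Passing tests on them shows the machinery is correct and
the method behaves as theory predicts in its intended regime — not that
any particular real record satisfies the assumptions.

## Numerical choices

- Neighbor search inside the windowed sweep uses `argpartition` on each
  window's distance submatrix followed by a lexicographic (distance, time
  index) sort of the selected k — identical to a full stable sort except
  when an exact distance tie straddles the k-th boundary, which has
  measure zero for continuous-valued data. The single-point API
  (`neighbor_rank`) uses the exact stable sort.
- Skill is computed by a direct centered dot product, clipped to [−1, 1]
  against rounding; it matches `scipy.stats.pearsonr` to 1e−12 in tests.
- Exponential weights underflow to zero for distance ratios beyond ~745;
  this is intended (those neighbors are irrelevant) and handled silently.
- All simulations take explicit integer seeds; repeated runs are
  bit-identical, and the pipeline itself contains no randomness.

## Problem sizes

The test suite and `scripts/acceptance.py` use n = 400 × 20 seeds for
direction recovery, n = 100 × 20 seeds for the white-noise null,
n = 60/20 × 20 seeds for the thinning breakdown, n ≤ 58 fixtures for
equivalence with the naive double-loop reference (tolerance 1e−10), and
ten n = 120 fixtures with 5×5 grids for the descent audit — sizes at
which each effect is comfortably resolved on a single CPU in about a
minute.

## Limitations

Pairwise tests only (no conditioning on further variables); no surrogate-
data significance calibration — the convergence verdict is a qualitative
criterion with configurable thresholds, not a p-value; no bootstrap
library resampling (sliding contiguous windows only), so strong secular
trends can inflate skill; sensitive to synchrony under very strong
forcing, as all cross-mapping variants are. The causal-delay convention
(manifold time t predicts the opposing series at t − τ_p) must be kept in
mind when comparing with tools using the opposite sign.
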