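# Methods

This note documents the models and procedures implemented in `shapemsm`,
the numerical conventions they follow, and what the synthetic-data
validation does and does not demonstrate.

## Shape featurization

**USR descriptor.** A structure of n atoms is reduced to 12 numbers.
Four reference points are located: the molecular centroid (ctd), the
atom closest to it (cst), the atom furthest from it (fct), and the atom
furthest from fct (ftf). For each reference point the distribution of
Euclidean distances from all n atoms is summarized by its first three
moments, concatenated in the order ctd, cst, fct, ftf.

Conventions, chosen to make the descriptor total and deterministic:

- *Population* (biased) moments throughout: variance is the second
  central moment, skewness the third standardized central moment
  μ₃/σ³.
- σ = 0 (all distances equal, e.g. coincident atoms) ⇒ skewness := 0,
  so degenerate frames featurize to a well-defined vector.
- Ties in locating cst/fct/ftf break to the lowest atom index, so the
  descriptor is stable under re-runs though (like USR generally) not
  guaranteed continuous at tie configurations.
- The descriptor is invariant under rigid motions and atom reordering.
  It is **not** invariant under mirror reflection in general — an
  enantiomer presents the same four distance distributions only in
  special geometries — and no chirality correction is applied.

By default all atoms enter the distance distributions; `heavy` and `ca`
selections are available because practice varies on whether hydrogens
are retained.

**CA-skip baseline.** The coarse Cartesian alternative concatenates the
(x, y, z) of alpha carbons at indices 0, skip+1, 2(skip+1), … — take
one, skip `skip`, default 4. Unlike USR it is not rotation-invariant, so
its distance is the minimum RMSD after Kabsch superposition (proper
rotations only; at least 3 points required).

## Basin decomposition

Conformation–energy samples become vertices of a k-nearest-neighbor
graph (default k = 10; the value is a modeling choice, not estimated
from data). The union symmetrization (keep an edge if either endpoint
lists the other) is used rather than mutual k-NN so no vertex is
isolated. Duplicate feature vectors are merged into a single vertex —
edge distances must be positive — with the merged vertex taking the
*minimum* energy of its duplicates (the basin-relevant depth) and the
original row indices recorded.

A vertex u is a **local minimum** when e(u) ≤ e(v) for every neighbor v
(non-strict). From every other vertex, descent repeatedly follows the
neighbor maximizing the descent ratio [e(u) − e(v)] / d(u, v) over
strictly-lower-energy neighbors; vertices draining to the same minimum
form one basin.

Tie and plateau rules: among equal best ratios the lower-energy neighbor
wins, then the lower vertex index. Because descent only ever moves to
strictly lower energy, every local minimum — including each member of an
equal-energy plateau — terminates descent at itself and anchors its own
basin. This keeps three properties exactly consistent: descent strictly
decreases energy (hence terminates in ≤ n steps), the number of basins
equals the number of local minima, and adjacent equal-energy minima
remain distinct. Plateaus have measure zero for continuous energies, so
the rule matters only for degenerate inputs.

Out-of-sample frames (those without energies) are labeled by the basin
of their nearest graph vertex — an extension used only when a basin
model must label all frames.

## k-medoids macrostates and knee selection

Alternating k-medoids under the squared-Euclidean cost: assign each
frame to its nearest medoid, then replace each cluster's medoid with the
member minimizing the within-cluster sum of squared distances (SSE).
Because the cost is squared Euclidean, the exact medoid update
decomposes as cost(m) = n_c·|x_m|² − 2·x_m·Σxᵢ + Σ|xᵢ|², i.e. O(n_c·d)
per cluster, so exact updates remain practical on 10⁵–10⁶ rows of 12-d
features with no distance matrix. Seeding is k-medoids++ (squared
-distance weighted sampling); defaults are 5 restarts (best SSE kept)
and a 300-iteration cap, with a caller-supplied seed making runs
reproducible. SSE is nonincreasing within a run because each half-step
cannot raise the cost. Emptied clusters keep their previous medoid.
Assignment ties go to the lower cluster label.

The number of states is the **knee** of the SSE-vs-k profile: the k
whose (k, SSE) point lies furthest below the chord joining the profile's
endpoints (perpendicular distance in the raw plane; ties to the smallest
k). The default scan range 2–25 comfortably covers the 10–15-state scale
typical of large-biomolecule MSMs.

## Transition-model estimation

Counts use a sliding window at lag τ frames: every within-trajectory
pair (t, t + τ) increments C[i,j]. Trajectories are never concatenated,
so no artificial cross-boundary transitions exist. Before normalizing,
counts are restricted to the largest strongly connected component of the
count graph (largest by state count, then by count mass) — this
guarantees positive row sums and a unique unit eigenvalue. The estimate
is the non-reversible maximum likelihood T = C / rowsum(C); a
symmetrized (C + Cᵀ)/2 reversible mode exists for comparison only.
The stationary distribution is the left eigenvector with eigenvalue
closest to 1, made nonnegative and normalized to sum 1. Lags are
expressed in frames everywhere; conversion to physical time happens only
at reporting, via the frame interval.

State summaries report stationary populations sorted descending, the
top-m states itemized (per-state self-transition and cumulative
out-of-state probability = 1 − self) and the remainder pooled as "S*".
Populations are probabilities renormalized over the active (connected)
set. A strided PCA embedding (mean-centered, full SVD) is provided for
visual inspection of the discretization.

## Validation tests

**Implied timescales.** For each lag τ on a grid (default 1, 2, 5, 10,
20, 50, 100, 200, 500, 1000, 1500 frames) a model is re-estimated and
t_i(τ) = −τ / ln |λ_i(τ)| computed for the non-unit eigenvalues, sorted
by magnitude. Magnitudes are used, not real parts, because the
non-reversible estimator can have a complex spectrum. |λ| within 1e-12
of 1 reports t = ∞; |λ| = 0 reports NaN (the process relaxes within one
lag and is unresolvable). A timescale counts as *converged* at the first
lag where its relative variation over a 3-point window is ≤ 0.10 and the
curve stays above the cutoff region t ≤ τ (curves inside that region
indicate a discretization too coarse to resolve the process, whatever
their flatness).

**Chapman–Kolmogorov.** The n_sets = 5 states with the highest
self-transition probability at lag τ are tracked. For k = 1..K (default
5), the propagated prediction [T(τ)]ᵏ is compared to an independently
re-estimated T(kτ) on the self-transition entries; at k = 1 the two
coincide by definition. Uncertainty is a trajectory-level bootstrap
(default 200 resamples, fixed seed): trajectories are resampled with
replacement and T(kτ) re-estimated, giving 2.5–97.5 percentile bands.
The model passes when every finite predicted point lies inside its band.
States that drop out of the connected set at long lags yield NaN points,
which are excluded rather than failed.

## Synthetic ground truth

The generator emulates the raw inputs of an MSM study: `n_traj`
independent trajectories (default 12) whose hidden state path follows a
known row-stochastic matrix (default: 6 states, self-transition 0.9,
uniform off-diagonal mass, started from the stationary distribution),
with frames emitted as template coordinates plus isotropic Gaussian
noise (default 0.4 Å), optionally rigidly rotated per frame, and frame
interval 4 ps. Energies are recorded only every `energy_stride` frames
(default 32), mirroring the practice of evaluating an expensive
implicit-solvent energy on a subsample.

Templates are anisotropic Gaussian point clouds (random axis scales,
0.3–2 × 5 Å) rejection-sampled to satisfy two floors: pairwise
superposed RMSD ≥ 2 Å, and pairwise USR-feature distance ≥ 5 × the sum
of the two states' RMS feature spreads under the emission noise. The
second floor is the operative one: equal-scale isotropic clouds are
nearly indistinguishable to a *shape* descriptor (their
distance-distribution moments concentrate), so separability must be
enforced in the space where clustering happens. The ratio 5 makes state
overlap negligible, which is what lets parameter-recovery experiments
attribute errors to the estimators rather than to ambiguous data. If a
run of 500 candidates is rejected, the accepted set is discarded and
sampling restarts (early accepts can crowd the shape space).

The energy is quadratic in the conformation-space displacement:
e = base_energy(state) + c·|f(frame) − f(template)|², with f the USR map
and c = 0.05. Defining the energy in the same space where neighbor-graph
distances are measured makes each template the floor of one basin, so
the basin decomposition has (essentially) one basin per state as its
known ground truth; an energy defined on the raw 3n-dimensional noise
would be statistically independent of feature-space position and would
fragment every state into spurious basins.

**What passing tests show — and what they do not.** The synthetic data
has genuinely metastable, geometrically separated states, Markovian
switching, stride-limited energies, and multiple independent
trajectories. It does *not* have temporal correlation within a state (no
inertial or diffusive motion — frames are conditionally i.i.d.), noise
along collective modes, rugged energy landscapes, or the slow
conformational gradients of real proteins. Recovery results therefore
validate the estimators and the pipeline plumbing, not the adequacy of
USR features for any particular real system. One structural consequence:
because within-state frames are i.i.d., *any* refinement of the true
states is exactly lumpable, so a fragmented discretization here stays
Markovian and fails only by statistical noise — real MD punishes
fragmentation harder.

## Validation problem sizes

Parameter recovery runs 12 × 10,000 frames from the default 6-state
chain through the full Setting-C pipeline at τ = 1 (knee scan 2–25);
it recovers k = 6 with ≤ 0.05 maximum row total-variation error and
≤ 0.05 stationary L1 error. The setting comparison uses 12 × 13,334
frames (≈160k structures, 5,000 energy-bearing samples at stride 32)
with self-transition 0.995, chosen so state lifetimes (≈200 frames) are
resolvable at the 32-frame energy stride — a basin MSM on strided
energies is otherwise not estimable at all. On this data the
basin-over-5,000-samples model (Setting B) shows clearly larger
Chapman–Kolmogorov deviations and rougher implied-timescale curves than
the all-frames k-medoids model (Setting C), reproducing the expected
quality ordering. The CK discrimination check uses a 4-state chain whose
two merged substates have self-transitions 0.85 and 0.99 with near-equal
stationary weight: the merged label's survival is a two-rate mixture
that a one-rate Markov model cannot fit, so the test must (and does)
flag it.

## Known limitations

- USR features can in principle collide for distinct shapes (the
  descriptor is not injective); nothing in the pipeline detects this.
- The non-reversible estimator gives no uncertainty on the transition
  matrix itself; only the CK test carries bootstrap bands.
- The `rmsd` neighbor-graph metric is quadratic in the number of
  vertices and intended for the ≤ ~5,000-sample basin settings only.
- Basin assignment of frames without energies (nearest labeled vertex)
  is a pragmatic extension with no energetic justification.
- Knee selection assumes the SSE profile has a single dominant corner;
  hierarchical state structure can produce ambiguous knees.
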