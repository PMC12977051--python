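# Methods

## Kinetic clocks and the conditional-activity statistic

Every retained residue contributes a point process: the times at which
its dihedral degree of freedom changes discrete state. For amino acids
the degree of freedom is the first side-chain torsion χ₁ (N–CA–CB–γ,
with the γ heavy atom CG/CG1/OG/OG1/SG depending on residue type;
glycine and alanine carry no χ₁ and are excluded). For DNA it is the
glycosidic base–sugar torsion, O4′–C1′–N9–C4 in purines and
O4′–C1′–N1–C2 in pyrimidines, whose two wells are the syn and anti base
orientations. Raw dihedrals in (−180°, 180°] are mapped to [0°, 360°)
by adding 360° to negative values, because the state boundaries are
defined on that range.

State boundaries are fixed constants placed in the minima of the
pooled angle densities: protein X/Y/Z at 0°/120°/240° (half-open
bins), DNA S = [0°, 140°) ∪ [330°, 360°) and A = [140°, 330°). They are
deliberately not learned from the data — identical boundaries for every
residue and system keep activities comparable — but `density_profile`
exists to check, on a new system, that the boundaries still sit in
density minima.

Given transition times T(X, 1) < … < T(X, N) over an observation time
τ (the full per-replica trajectory duration, shared by all residues),
the forward recurrence time W(X, t) is the wait from t until X's next
transition. The three derived quantities are

- τₚ[X] = (1/2τ) Σ W², the sum running over the N+1 waiting intervals
  that partition [0, τ];
- τₚ[X][Y] = (1/τ) Σᵢ₌₁^{N(Y)−1} W(X, T(Y, i+1)) · (T(Y, i+1) − T(Y, i));
- A[X][Y] = −ln(τₚ[X][Y] / τₚ[X]).

τₚ[X] is exactly the mean of W(X, t) over a uniformly random t in
[0, τ] (length-biased interval sampling); the test suite verifies this
equivalence against a Monte-Carlo average. A[X][Y] is directional: the
row is the affected residue X, the column the influencing residue Y,
and every output states this orientation. Natural logarithms
throughout.

### Boundary censoring

The sums above need values for the interval before the first transition
and after the last. Both boundary intervals are included in the
partition (so the interval lengths sum exactly to τ and the 1/2τ
prefactor yields exactly the random-start average), and W evaluated at
or after the last transition is censored at the trajectory end,
W = τ − t, which can contribute zero-valued terms to exchange sums. Any
other choice either loses the exact normalization or produces infinite
terms; the effect is O(1/N) and is negligible for records that pass the
transition filter. Two consequences are exercised in the tests: the
toy record (transitions 1, 3, 7; τ = 7) has τₚ = 1.5 and self-exchange
8/7 by hand, and a periodic clock of period c has memory
−ln(2(N−2)/N) → −ln 2.

### Limits that anchor the scale

- Poisson clock: memoryless, A[X][X] → 0 (and A between independent
  processes → 0, with spread ∝ 1/√N).
- Periodic clock: A[X][X] → −ln 2, the maximal anti-memory of a
  deterministic renewal.
- Bursty clock (two-exponential mixture, means m₁, m₂, weight w):
  A[X][X] → ln(E[W²] / 2E[W]²) > 0 — the large-N limit used to plant
  high-memory residues in synthetic systems.

## Filtering and replicas

Residues need at least 10 transitions to enter the analysis (default
`min_transitions = 10`); below that the waiting-time statistics are too
poorly sampled for the ratio estimator. The filter is applied per
replica — a residue may be retained in one replica and dropped in
another — because pooling counts across replicas would let two
half-sampled records impersonate one well-sampled one. Replicas are
never concatenated (a splice would fabricate a transition); activity
matrices are computed per replica and then averaged entrywise, with the
SEM over replicas attached per entry. Averaging after the −ln transform
(rather than averaging times first) matches the per-replica error bars
reported on the distance profiles. Missing entries (a residue dropped
in some replica, or a fully censored exchange sum) stay missing and are
averaged over the replicas where they exist.

Transition times are recorded at frame resolution: the time of the
first frame in the new state, i × frame_interval. Any consistent
convention shifts all times equally and leaves waiting times unchanged
to within one frame. No dwell-time debouncing is applied by default —
it materially changes N — but `detect_transitions(min_dwell_frames=k)`
provides it as an explicit choice. Frames whose dihedral is
geometrically undefined (NaN) inherit the previous frame's label so an
isolated numerical failure cannot fabricate two transitions.

## Dynamical memory, eigendomains, significance

The matrix diagonal A[X][X] is the dynamical memory; the grouped report
gives, per residue group, the percentage of retained residues with
memory above a threshold (default 4.0, an absolute constant on the
−ln scale). Domains are read from the principal eigenvector of
S = (M + Mᵀ)/2 with missing entries imputed as 0 — zero is the defined
independence value, so absence of evidence imputes no coupling. The
eigenvector is unit-norm with its global sign fixed so the
largest-magnitude component is positive; per-residue domain scores are
component magnitudes.

Significance of a coupling A[X][Y] is assessed against a circular-shift
null: Y's record is shifted by a uniformly random offset modulo τ
(preserving its single-residue waiting statistics except at the one
wrapped interval, destroying cross-timing with X), A is recomputed, and
the one-sided upper-tail p-value is (1 + #{A_null ≥ A_obs}) / (n + 1),
floored at 1/(n+1). Default n = 2000 permutations resolves p-values to
half-per-mille. p-values are reported raw; Benjamini–Hochberg
adjustment is available behind a flag for long pair tables. The null is
calibrated: under independent renewal processes the p-values are
uniform and the type-I error at 0.05 is nominal (both tested).

## Mutual information baseline

MI(X, Y) = H(X) + H(Y) − H(X, Y) in nats, plug-in frequencies over
simultaneous frames, 0 ln 0 = 0, no bias correction, same state
alphabets as the kinetic analysis so the comparison is like-for-like.
MI sees shared state occupancy; conditional activity sees shared
transition timing — the two can disagree, which is the point of
computing both.

## Spatial profiles

A residue's reference point is the center of geometry of its dihedral
quadruple's atoms on the time-averaged structure (first-frame positions
selectable); distances in nm. The distance profile reports, per 0.5 nm
bin out to 10 nm, the fraction of residue pairs with coupling at or
above the threshold (default 2.0 for activity — roughly 20% of the
largest inter-residue activity in well-sampled systems). The
distance-0 bin holds the self-pairs (diagonal) under the same
threshold. Activity counts ordered pairs (the matrix is directional);
MI counts unordered pairs once. The MI curve has no established
absolute threshold, so it reuses the fractional rule — 20% of the
maximum off-diagonal MI — which is a reconstruction, flagged in the
output metadata. Empty bins report a missing fraction, never 0.

## Synthetic data: what it emulates, what it does not

The generator produces renewal (semi-Markov) transition processes —
exponential (Poisson), fixed-period, and two-exponential-mixture
waiting laws — plus directional master→slave couplings (each master
transition triggers, with a configurable probability, one slave
response after a lag) and noisy angle emission around rotamer-state
centers (default centers 60°/180°/300°, Gaussian noise of 8°, ≈7σ from
the nearest state boundary).

Defaults of the packaged synthetic system: 6 residues, τ = 2000 time
units, mean waiting time 10 (≈200 transitions per residue, comfortably
past the ≥10 filter), frame interval = mean/40, trigger probability 1.
The response lag is fixed at three frame intervals: long enough to be
resolvable after frame discretization (a sub-frame lag lands master and
response in the same frame and erases the coupling — a real resolution
limit of the method, demonstrated in the tests), short enough against
the persistence time that the planted coupling dominates the matrix.
The planted high-memory residue uses a mixture clock (means 0.1·mean
and 4·mean, weight 0.8) whose analytic memory is ≈ +1.4.

These processes have no physical dynamics: no forces, no inertia, no
angular diffusion within a well, no correlated noise between residues.
Passing tests on them demonstrates that the estimators recover known
kinetic structure from transition timing at frame resolution — not that
any particular biomolecular system has such structure, nor that force
fields or sampling are adequate in a real study.

## Numerical choices and degenerate inputs

- Empty records (N = 0) yield NaN persistence; exchange needs
  N(Y) ≥ 2; a fully censored (all-zero) exchange sum yields NaN, never
  ±∞. NaN entries propagate as "missing", are excluded from pooling
  means, and are imputed as 0 only inside the eigendomain symmetrization.
- Coincident times when merging baseline and triggered slave
  transitions are perturbed by +τ·10⁻⁶ to preserve strict ordering.
- A circular shift landing exactly on 0 maps to τ (times live in
  (0, τ]).
- An all-zero symmetrized matrix has no domain structure and raises
  instead of returning an arbitrary eigenvector.
- All randomness flows from explicit integer seeds (specs carry their
  seed; table-level routines expand one root seed into per-pair seeds),
  so identical configuration and seed reproduce byte-identical outputs.

## Problem sizes used in the checks

The verification suite runs on synthetic records sized for tight
statistical bounds at interactive runtimes: renewal-limit checks use
τ = 10⁴ with unit mean waiting (N ≈ 10⁴) over 50–100 seeds;
directionality recovery uses 50 master–slave pairs at τ = 10³;
permutation calibration uses 100 independent pairs at τ = 200 with 99
permutations each; the end-to-end pipeline check uses the 6-residue
synthetic system above (8000 frames). At these sizes the full suite and
the reproduction script complete in seconds.

## Known limitations

- One degree of freedom per residue (χ₁ / glycosidic); χ₂₊, backbone
  and DNA backbone torsions are out of scope.
- Couplings faster than one frame interval are invisible (see the lag
  discussion above); choose the trajectory stride accordingly.
- The plug-in MI estimator is biased upward at small sample counts; no
  correction is applied.
- The ≥10-transition default is a floor, not a guarantee of
  convergence; slowly exchanging residues near the threshold carry
  large uncertainties, visible in the per-entry SEM under replication.
- Significance p-values are per-pair; tables over many pairs need the
  optional FDR pass.
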