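# condact

Time-resolved **kinetic correlation analysis** of molecular-dynamics
trajectories: which residues' motions *drive* which others, how far that
influence reaches, and which residues carry dynamical memory.

Classical correlation measures (covariance, mutual information) compare
*states*: they ask whether two residues tend to occupy related
conformations. They are blind to purely kinetic coupling, where a
transition in one residue reliably *triggers* a transition in another
without changing either one's state statistics. `condact` quantifies
that kinetic coupling — the **conditional activity** — from the timing
of dihedral-angle state transitions, for proteins, DNA, and protein–DNA
complexes such as the nucleosome.

## The method

Each residue contributes one kinetic clock: the side-chain torsion χ₁
(N–CA–CB–γ) for amino acids (Gly/Ala have none and are skipped), and
the glycosidic base–sugar torsion (O4′–C1′–N9–C4 for purines,
O4′–C1′–N1–C2 for pyrimidines) for DNA. Angles are wrapped to
[0°, 360°) and discretized: protein rotamers into three states
(X = [0°, 120°), Y = [120°, 240°), Z = [240°, 360°)), DNA into
syn/anti (S = [0°, 140°) ∪ [330°, 360°), A = [140°, 330°)). The frames
where the state changes are the transition times T(X, 1) < … < T(X, N)
over a trajectory of duration τ; residues with fewer than 10 transitions
are excluded as under-sampled.

With W(X, t) the forward recurrence time (wait from t until X's next
transition):

- persistence time τₚ[X] = (1/2τ) Σ W² over the waiting intervals that
  partition [0, τ] — the mean wait from a random start time until X's
  next transition;
- exchange time τₚ[X][Y] = (1/τ) Σᵢ W(X, T(Y, i+1)) · (T(Y, i+1) −
  T(Y, i)) — X's wait measured just after Y's transitions;
- **conditional activity** A[X][Y] = −ln(τₚ[X][Y] / τₚ[X]).

A[X][Y] > 0 means transitions of Y hasten the next transition of X;
A = 0 under independence; the matrix is directional (A[X][Y] ≠ A[Y][X]).
The diagonal A[X][X] is the **dynamical memory**: ≈ 0 for a memoryless
(Poisson) clock, −ln 2 for a strictly periodic one, positive for bursty,
history-dependent dynamics. The principal eigenvector of the symmetrized
matrix maps the dynamically connected domains; a circular-shift
permutation test attaches empirical p-values to couplings; and the
fraction of pairs with A ≥ 2, binned by spatial separation, profiles the
reach of kinetic communication — compared against the plug-in mutual
information MI(X, Y) = H(X) + H(Y) − H(X, Y) over the same state
alphabets as the entropic baseline.

## Worked example

Generate a synthetic system with a planted master→slave coupling and a
planted high-memory residue, then analyse it:

```python
import condact as c
from condact.testing import synthetic_system

series, truth = synthetic_system(seed=3)   # 6 residues, tau = 2000
model = c.ConditionalActivity.from_angles([series])
results = model.fit(compute_mi=True)
print(results.summary())
```

```
Conditional activity results
============================================================
residues retained        6
replicas                 1
min transitions filter   10

dynamical memory (top 5):  [A[X][X], -ln units]
  SYN:VAL:3                   1.509
  SYN:VAL:2                   0.032
  SYN:VAL:5                   0.021
  SYN:VAL:4                   0.021
  SYN:VAL:1                   0.012

strongest couplings (top 5):  [A[X][Y]]
  SYN:VAL:2          <- SYN:VAL:1             2.390
  SYN:VAL:5          <- SYN:VAL:4             0.108
  SYN:VAL:6          <- SYN:VAL:3             0.090
  SYN:VAL:2          <- SYN:VAL:6             0.082
  SYN:VAL:1          <- SYN:VAL:5             0.075

leading eigenvalue       1.522
top eigendomain residues SYN:VAL:3, SYN:VAL:4, SYN:VAL:1, SYN:VAL:5, SYN:VAL:6
```

The planted structure is read straight off the fit: residue 3 (a bursty
two-exponential clock) tops the dynamical memory, and the planted
coupling — residue 1 driving residue 2 — is the strongest off-diagonal
entry, A[2][1] ≈ 2.4, meaning transitions of residue 1 shorten residue
2's expected wait by a factor e^2.4 ≈ 11. `results.pvalues(...)` attaches
permutation p-values (the planted pair sits at the resolution floor
1/(n_permutations + 1)).

The same workflow runs from the shell on real trajectories:

```sh
condact extract topology.pdb traj.xtc --out angles.tsv
condact discretize angles.tsv --out transitions.tsv
condact activity transitions.tsv --out activity.tsv
condact significance transitions.tsv --out couplings.tsv
condact report transitions.tsv --groups examples/histone_groups.yaml
```

or end-to-end from a YAML config with `condact run --config run.yaml`,
which also writes the MI matrix, eigendomain scores, the
distance-resolved coupling profile, and a JSON manifest with content
hashes of every artifact.

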