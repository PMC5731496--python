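# Methods

This note records the models, conventions and numerical choices behind
`conftop`, in the order the pipeline applies them.

## Coarse-grained representation and kinematics

Proteins are ordered Cα traces: one coordinate triple per residue, paired
across structures by residue number (insertion codes unsupported;
alternate locations resolved to highest occupancy). Conformational moves
are rotations of pseudo-dihedral angles — the torsions defined by four
consecutive Cα atoms — about the central virtual Cα–Cα bond. The
C-terminal side of the bond moves, the N-terminal side is fixed; the sign
follows the IUPAC right-hand convention, so a planar trans chain has
torsion 180°. Because a move is a rigid rotation of one side, all virtual
bond lengths and bond angles are preserved exactly; the only degrees of
freedom explored are the N−3 torsions.

RMSD is always the minimal Cα RMSD over rigid superpositions (Kabsch
algorithm, proper rotations only), computed on the residue-number
intersection of the two traces. Conventions on whether reported RMSDs are
superposed vary across the literature; optimal superposition is the field
standard and is used everywhere here.

## Energy model

The search needs only a cheap plausibility filter, not a faithful force
field. The default Cα energy is

    E = Σ_bonds (d − 3.8)² + Σ_{|i−j|≥3, d<4} 10·(1 − d/4)²

in Å and arbitrary energy units: a harmonic restraint about the ideal
3.8 Å virtual bond plus a soft-sphere repulsion that activates below 4 Å
for residues three or more apart in sequence. It is rigid-motion invariant
and zero for an ideal clash-free chain. The energy is a pluggable callable
(`run_search(..., energy_fn=...)`); any coarse-grained potential with the
same signature can replace it. The acceptance threshold default (50 energy
units) is deliberately permissive: since dihedral moves preserve bonds
exactly, the bonded term only reflects the input geometry, and the
threshold mainly rejects steric collapse.

## Search parameters

- `max_iterations` 60,000 (production scale); desk-scale runs in the tests
  and scripts use 300–3,000 iterations on 10-residue toys, which finish in
  seconds while exhibiting the same qualitative behaviour.
- `rotation_limit` ±5°.
- Bond selection: probability ∝ angular difference to the goal wrapped to
  [0°, 180°]; differences below `skip_angle_tolerance` (1°) are skipped;
  when none remain the search reports convergence.
- Acceptance: downhill in RMSD-to-goal always; uphill iff
  ln r < −ΔRMSD/(a·RMSD_new) with r ~ U(0,1) and `scaling_factor_a` = 1.
  A proposal exactly at the goal (RMSD_new = 0) is accepted outright;
  RMSD_new = RMSD_parent falls through to the uphill test, which accepts
  for every r < 1.
- Parent selection: uniform over the pool by default; `goal_biased`
  (∝ 1/(RMSD+0.1)) and `greedy` policies are available. The uniform
  default is the least informative assumption and keeps early pool
  members alive for pathway coverage.
- `goal_rmsd_stop`: `SearchParams` defaults to 1.5 Å (a natural stop when
  only reaching the goal matters); the pipeline overrides it to 0 and runs
  the full budget, because cluster analysis wants an ensemble covering the
  whole pathway rather than the earliest goal hit.

All randomness flows through one `numpy` generator seeded from
`SearchParams.seed`; identical seeds give bit-identical trajectories.

## Dimensionality reduction

**Spherical PCA** rescales each data vector to unit norm and applies
standard PCA to the rescaled matrix. Normalization caps the leverage of
any single observation, which is what makes the variant robust to
outliers. The plain formulation — normalize the raw vectors — is the
default; pre-centering the rows before normalization is available as
`center_rows_first=True` for data whose mean offset should not influence
the spherical projection. With unit-norm input the method reduces exactly
to standard PCA, a property the tests pin down.

**Isomap** builds the K-nearest-neighbour graph with the minimal K whose
symmetrized graph (union rule: an edge survives if either endpoint lists
the other) is connected, weights edges by Euclidean distance, computes
exact Dijkstra geodesics between all pairs, and embeds them by classical
(Torgerson) MDS. Variance fractions are taken over positive eigenvalues
only; a warning is emitted when the most negative eigenvalue exceeds a
quarter of the leading one, which signals strongly non-Euclidean
geodesics rather than rounding noise. Embedding signs are fixed
deterministically (largest-magnitude coordinate positive per column) so
reruns are byte-identical.

Both methods keep d = 3 components by default, matching the observation
that three coordinates carry ≥ 90% of the ensemble variance for these
systems.

## Landmarks and filtration

Landmarks are chosen by the sequential maxmin scheme: first point uniform
under the seed, each next point maximizing its distance to the chosen set,
ties broken toward the lowest index (and duplicate coordinates masked so
the selection is always distinct). The coverage radius R is the maximum
distance of any cloud point to its nearest landmark.

The landmark *count* is selected by coverage stabilization: counts 10, 20,
30, … are tried until the relative drop in R between consecutive counts
falls below 5% (a vanishing R counts as converged, so clouds of duplicate
points stop at the first comparable count, 20); the stop count is averaged
over 5 sub-seeded repetitions and inflated by two population standard
deviations, capped at the cloud size.

The lazy witness filtration LW^ν is represented by its 1-skeleton: each
landmark pair (z₀, z₁) carries the appearance scale

    t_e = max(0, min_y (max(d(y,z₀), d(y,z₁)) − d(y)))

with witnesses y ranging over the whole cloud and d(y) = 0 for ν = 0 or
the nearest-landmark distance for ν = 1. The complex is a flag complex, so
the skeleton determines everything; appearance values are computed once
and every scale query is a thresholding. ν = 0 is the default for
clustering — it makes H₀ connectivity at scale t provably identical to
distance-threshold connectivity, hence the H₀ death scales equal
single-linkage merge heights exactly (an acceptance-tested identity).

H₀ barcodes come from union-find over edges sorted by appearance value:
all bars are born at 0, each merge kills one bar (elder rule, lower root
index survives), each final component contributes an infinite bar. H₁
barcodes use the standard boundary-matrix reduction over GF(2) with
columns stored as integer bitmasks; this is an oracle-scale routine guarded
at 2,000 simplices, used for validation fixtures rather than production
clouds. The homology field is GF(2); no orientation bookkeeping is needed
on flag complexes.

## Cluster decisions

Finite H₀ deaths sorted descending, d₁ ≥ d₂ ≥ …, drive two decisions:

- **Cluster count**: k = i + 1 for the largest i ≤ `max_levels` − 1 with
  d_i − d_{i+1} > 0.1 (the bar-gap threshold), else 1. This picks the
  finest level of the filtration preceded by a gap: merges separated by
  less than the gap are treated as simultaneous noise. The threshold is
  absolute in reduced-coordinate units and configurable, since embeddings
  are not normalized to a common scale.
- **Per-level partitions**: level i uses the midpoint of the scale plateau
  [d_i, d_{i−1}) on which exactly i components exist; simultaneous merges
  can make a level unachievable, in which case the nearest achievable
  partition is returned with a warning.

Because all levels come from the same filtration with the same landmark
set, level i+1 refines level i by construction, and the dendrogram
assembled from subset tests between consecutive levels is laminar; the
builder still verifies nesting and exact coverage and raises on violation.
Dendrogram heights are ordinal (by level), not metric.

Outliers are landmarks in blocks smaller than `min_size` (default 2) at
the selected level; they are dropped before reporting, and coarser levels
are restricted to the retained set.

Cluster reports use the population standard deviation of member RMSDs,
order clusters by increasing mean RMSD to the designated endpoint, and
pick as representative the member nearest the cluster's geometric centre
in the reduced space (a medoid, so the representative is always a real
sampled conformation).

## Synthetic data

Three generators make every stage testable without external files:

- `gaussian_blobs`: k isotropic components on a regular polygon with side
  `separation` (default 1.0 — ten times the bar-gap threshold) and spread
  `sigma` (default 0.05, twenty times smaller than the separation). This
  emulates the well-separated cluster regime the gap heuristic targets.
- `circle_cloud`: evenly spaced points with radial Gaussian noise, the
  analytic H₁ fixture.
- `toy_chain_pair`: a self-avoiding Cα chain with exact 3.8 Å bonds
  (persistent random walk, clash-free at ≥ 4 Å for residues 3+ apart) and
  a goal obtained by 20 random dihedral perturbations of up to 60°, each
  re-drawn until clash-free. The defaults put the endpoints 1.3–3 Å apart
  on 10 residues — far enough that the search has real work to do, close
  enough that 2,000 iterations show measurable progress.

What the toys do *not* emulate: realistic protein energetics, secondary
structure, the 100+-residue scale of real transitions, or multi-basin
energy landscapes. Passing tests therefore demonstrate the correctness of
the machinery (kinematics, filtration identities, decision rules) and the
qualitative behaviour of the search, not biological accuracy of any
specific clustering.

## Numerical choices and degenerate inputs

- Angles live in (−180°, 180°]; angular differences are wrapped to
  [0°, 180°] before use as selection weights.
- Kabsch uses SVD with a determinant correction so reflections are never
  returned; rank-deficient (planar/collinear) coordinate sets are handled
  by the same formula.
- Zero-norm rows are rejected by spherical PCA; clouds with no variance
  return an empty embedding.
- Identical points: maxmin masks chosen indices, coverage radius reaches
  exactly 0, and the landmark-count rule stops at the first comparable
  count.
- All stochastic stages accept integer seeds; the pipeline derives
  per-stage sub-seeds from the master seed by fixed offsets, so a stage
  can be re-run in isolation.

## Known limitations

- The search bias (toward goal torsions and downhill RMSD) concentrates
  sampling along one corridor; the ensemble is not a Boltzmann sample and
  cluster populations have no thermodynamic weight.
- The 0.1 bar-gap threshold is unit-dependent; embeddings with very
  different scales need a rescaled gap.
- H₁ is exact but deliberately size-guarded; production clouds get H₀
  only.
- PDB support covers standard ATOM records, one chain at a time; insertion
  codes are skipped and mmCIF is out of scope.
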