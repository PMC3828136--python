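# Methods

## Elastic network model

The capsid is modelled as a network of harmonic springs around the
deposited structure: for every coupled centroid pair the energy penalizes
the first-order change of the pair distance, giving the Hessian block
`k e eᵀ` with `e` the native unit separation.  This quadratic model assumes
the crystal structure is the free-energy minimum and that the low-energy
fluctuations of interest are collective and small-amplitude; it is built on
the empty protein shell, whose stability the quadratic form guarantees by
construction even where genome contacts stabilize the real particle.

Two backends share one code path:

* **Two-center (beta-Gaussian) network** — default for real structures.
  Each residue contributes its Cα and, when side-chain heavy atoms are
  present, their unweighted centroid (glycine contributes none).  Using the
  observed side-chain atoms avoids any geometric reconstruction rule.
  Side-chain coordinates are eliminated analytically: the effective
  main-chain matrix is the Schur complement
  `H_mm − H_ms H_ss⁻¹ H_sm`, so its size stays `3N` regardless of the
  side-chain count.  An isolated (uncoupled) side centroid makes `H_ss`
  singular and is reported as an error naming the residue.
* **Single-centroid network** — used by the synthetic toys and by the
  decimated mode (one centroid per two residues, cutoff rescaled to 15 Å),
  where only main-chain centroids exist.

Parameters (all configurable):

| parameter | default | rationale |
|---|---|---|
| cutoff | 7.5 Å | established two-center convention; 15 Å when decimated ×2 |
| spring strength | 1 (arbitrary) | every decision quantity (strain ratios, integrity, captured fraction) is scale-free, so thermal prefactors are absorbed into units |
| backbone bonus | 1 | consecutive main-chain pairs are always coupled; no extra strengthening by default |
| retained modes `M` | all capsid modes below the 5th nonzero mode of one isolated coat protein, floor 10 | keeps the collective inter-unit motions, discards intra-protein detail |
| reference protein | first protein of the structure | any conformer can be selected; conformers of one capsid give near-identical thresholds |

### Eigensolver

Small problems (≤ 1500 total degrees of freedom) are diagonalized densely.
Larger ones use shift-invert Lanczos (ARPACK) on the *generalized* sparse
problem `H z = λ B z`, where `H` is the full (main + side) Hessian and `B`
projects onto main-chain coordinates: its finite eigenpairs are exactly the
Schur-complement eigenpairs, so the effective matrix is never densified.
The shift is `−10⁻⁴ ×` the largest Hessian diagonal (making `H − σB`
positive definite for connected networks) and the start vector is fixed,
so results are deterministic; eigenvector signs are normalized by making
each mode's largest-magnitude component positive.  Both backends agree to
better than 1e-10 relative on every tested instance (the suite asserts
1e-8).

**Null modes.**  Eigenvalues below `1e-9 ×` the largest Hessian diagonal
are classified as rigid-body null modes.  The scale is the Hessian diagonal
rather than "the largest computed eigenvalue" because the latter is
backend-dependent (the sparse solver only computes a low window) and fails
on windows that are entirely degenerate; numerical nulls sit near 1e-12 of
the stiffness scale while the softest physical modes observed in realistic
networks sit many orders above it.  A connected network has exactly six
nulls; degenerate toys can legitimately have more (a single central-force
hinge spring leaves relative motions that do not stretch it at zero
energy), which the tolerance handles without special-casing.

## Strain minimization

The pair strain
`f_ij = Σ_l (1/λ_l) [ê_ij · (u_l,i − u_l,j)]²`
is precomputed for all pairs into an `N × N` matrix (blocked, contracted
over modes through per-residue 3×3 Gram matrices), which makes a greedy
move evaluation O(1) via the running table `S[r, d] = Σ_{j∈d} f_rj`.  An
optional pair cutoff truncates the pair set for very large capsids and is
flagged in reports as an approximation; by default all intra-domain pairs
count.

The minimizer at fixed `Q` starts from a uniform random labelling (with one
anchor residue per domain so all `Q` domains are nonempty), and repeatedly
proposes moving a random residue to a random other domain, accepting only
strict decreases — zero-change moves are rejected to avoid label drift —
and never emptying a domain.  The stochastic phase stops after `N`
consecutive rejections.  Because random proposals can reject `N` times in a
row while improving moves remain (observed directly on the ring toy, where
stopping there left the strain three orders of magnitude above the planted
optimum), a deterministic descent follows: a vectorized scan over all
(residue, domain) moves applies the best strictly improving move until none
exists.  The returned partition is therefore always a single-move local
optimum, and the accepted-move strain trace is strictly decreasing.

**Split/join refinement.**  If any domain's strain exceeds
`mean + k·SD` (`k = 2` by default) of the per-domain strains, the two
lowest-strain domains are merged, the highest-strain domain is split by the
plane through its centroid normal to its principal spatial axis (the
spatial bisection is this package's choice; degenerate splits fall back to
a median split along that axis), and the greedy pass is re-run — `Q` is
preserved throughout.  Iteration stops at homogeneity, non-improvement, or
10 rounds, and never returns a worse partition.  Note that a single outlier
among `Q` values has z-score at most `√(Q−1)`, so the default threshold
can only fire for `Q ≥ 6`; small-`Q` solutions are handled by restarts.

**Sweep.**  Each `Q` in the requested range (or an explicit grid) runs 5
independent greedy+refine chains by default, keeping the best; all chain
seeds derive from one master seed via `SeedSequence` spawning, so a sweep
is exactly reproducible and the report records seed and restart count.

## Rigid projection

Per-domain rigid bases stack 3 translations and 3 rotations linearized
about the unweighted domain centroid, orthonormalized by SVD with a 1e-10
rank tolerance (collinear domains lose the rotation about their line;
singletons keep translations only).  Centroid anchoring keeps translations
and rotations near-orthogonal; weights are uniform, consistent with the
uniform-mass network.  The captured-motion fraction weights each mode's
squared rigid projection by `1/λ_l`, the mode's share of the mean-square
fluctuation.  For any partition each normalized mode satisfies
‖rigid‖² + ‖internal‖² = 1; the fraction is 0 at `Q = 1` (nonzero modes
are orthogonal to global rigid motions) and 1 when every residue is its
own domain.

## Order parameters and selection

* Integrity averages, unweighted over proteins (or over user-supplied
  subdomains), the largest fraction of a group in one domain.
* Tile types single-link cluster domain sizes with a band of 3% of the
  mean domain size at that `Q` (the band is relative to the global mean,
  not per-pair — the configurable reading of "same size within ~3%").
* Interlocking clips its 20-residue terminal window to half the protein
  length for short chains (logged), and reports the larger of the N- and
  C-terminal averages.
* Selection returns *all* interior integrity peaks (plateau-aware) with at
  most 3 tile types, ranked by integrity then by larger `Q`; it is
  deliberately advisory — the report keeps every profile because the final
  call on a real capsid also involves visual inspection of the domain
  types.  Boundary values of the swept range are not peaks.

## Synthetic assemblies

The toys plant a known quasi-rigid organisation: all-pairs stiff springs
inside blocks (contrast 100× by default), a few soft springs between
adjacent blocks (the 9 closest cross pairs for ring contacts, 6 per
neighbour contact for the icosahedral toy — enough constraints to leave
exactly six null modes in generic geometry).  The hinge toy is the
deliberate exception: two stiff triangles and one soft spring, whose single
soft mode strains cross-hinge pairs but no intra-triangle pair.  The
icosahedral toy replicates one random cluster through the 60 proper
rotations of the icosahedral group (tilted 0.3 rad off a three-fold axis so
the three copies per face are distinct); the trimer-fused variant stiffens
cross-unit springs within each face triple, planting 20 super-blocks.  All
toys are bit-reproducible from their seed.

What the toys do *not* emulate: realistic protein geometry and packing
density, side chains, sequence connectivity along a backbone, conformer
heterogeneity (quasi-equivalence), and the soft-mode spectrum of a real
quasi-spherical shell.  Passing the planted-recovery suite shows the
machinery is correct and well-conditioned, not that any particular virus
will yield a clean decomposition; on real capsids the order-parameter
profiles are noisier and the selection is advisory.

Label agreement with the planted truth is scored by the optimal injective
label assignment (Hungarian algorithm), which is exact at any domain
count.

## Problem sizes

The test-suite and acceptance runs use desk-scale instances chosen so the
full pipeline (modes through selection) completes in seconds: ring toys of
32–240 points, icosahedral toys of 240 points with `Q` swept on a coarse
grid up to 60, and dense-oracle comparisons up to 300 residues.  Real
capsids run through the identical code path; the mode computation is the
dominant cost there (sparse shift-invert on `3N` up to ~2×10⁵ coordinates),
and the decimated single-centroid backend is the intended route for the
largest shells.

## Known limitations

* The all-pairs strain sum is O(N²) memory; beyond ~3×10⁴ residues use the
  documented pair-cutoff approximation or decimation.
* The two-center Schur complement is currently formed densely, so the
  two-center backend is practical to a few thousand residues; the
  single-centroid and decimated backends have no such limit.
* Domains are not constrained to be spatially compact or sequence
  contiguous (by design); at `Q` far above the innate value the strain
  landscape is nearly degenerate and recovered labels are arbitrary within
  blocks.
* No symmetry-adapted eigensolvers; icosahedral degeneracy is handled by
  the generic solver.
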