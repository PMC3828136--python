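# capsid-domains

Quasi-rigid domain decomposition of viral capsids from elastic-network
normal modes.

## The problem

Icosahedral virus shells are tiled by tens to hundreds of coat proteins,
but their mechanics and assembly are governed by a much smaller set of
multimeric units — dimers, trimers, pentamers/hexamers — that move as
nearly rigid bodies.  Identifying these basic mechanical units normally
requires nano-indentation experiments or heavy molecular-dynamics
simulation.  `capsid-domains` finds them from a single assembled structure
file: it characterises the capsid's equilibrium fluctuations with an
elastic network model and then partitions the residues into the groups
whose internal distance fluctuations are smallest, i.e. the groups that
behave most like rigid tiles.

It is aimed at structural virologists and biophysicists with a PDB/mmCIF
capsid structure (full assembly, or asymmetric unit plus biological
assembly transforms) who want candidate mechanical/assembly units and the
order parameters to judge them.

## Method

1. **Elastic network modes.**  The near-native free energy is the quadratic
   form `F(δ) = ½ δᵀ M δ` over the displacements `δ` of the `N` residue
   centroids.  The two-center (beta-Gaussian) network places a main-chain
   centroid (Cα) and a side-chain centroid (centroid of side-chain heavy
   atoms, none for glycine) per residue, couples every centroid pair within
   a cutoff (default 7.5 Å) with a Tirion spring, and eliminates side-chain
   coordinates analytically (Schur complement), so `M` stays `3N × 3N`.
   The lowest nonzero eigenpairs `(λ_l, u_l)` are computed by shift-invert
   Lanczos (ARPACK) on the sparse form, or dense diagonalization for small
   systems.  Modes up to the energy of the 5th nonzero mode of one isolated
   coat protein are retained (`M` modes).

2. **Strain-minimizing partition.**  The geometric strain of a residue pair
   `f_ij = Σ_l (1/λ_l) [ê_ij · (u_l,i − u_l,j)]²` is the mean-square
   fluctuation of the pair distance; it vanishes for pairs moving rigidly
   together.  A partition into `Q` domains is scored by the total
   intra-domain strain `F_Q = Σ_domains Σ_{i<j ∈ domain} f_ij`, minimized
   for each `Q` by a seeded stochastic greedy search (accept only strict
   decreases) with a deterministic final descent, plus a split/join
   refinement that rescues strongly asymmetric local minima.

3. **Order parameters and selection.**  Each swept `Q` is scored by protein
   *integrity* (mean largest fraction of a protein in one domain), number
   of *tile types* (domain-size classes within ~3% of the mean size),
   *interlocking* (terminal residues assigned away from the protein's
   dominant domain), and the *captured-motion fraction*
   `f = Σ_l λ_l⁻¹‖P u_l‖² / Σ_l λ_l⁻¹`, where `P` projects onto per-domain
   rigid translations/rotations.  Candidate optimal `Q` values are
   integrity maxima with few tile types, preferring the largest such `Q`.

## Worked example

Everything below runs in seconds and needs no downloads — the synthetic
module builds a 240-point icosahedral assembly (60 identical units on a
sphere, stiff springs inside each unit, soft springs between neighbours,
and extra stiff couplings fusing the units into 20 trimers):

```python
import numpy as np
import capsid_domains as cd

toy = cd.make_icosahedral_toy(4, contrast=100.0, seed=2, fuse_trimers=True)
capsid = cd.compute_modes(toy.network, 130)
unit = cd.subnetwork(toy.network, np.flatnonzero(toy.planted_labels == 0))
spectrum = capsid.truncate(cd.select_mode_count(capsid, cd.compute_modes(unit, 6)))

profile = cd.sweep(spectrum, toy.structure, 2, 2, restarts=5, seed=11,
                   q_values=[5, 10, 15, 20, 25, 30, 40, 60])
report = cd.build_report(profile, spectrum, toy.structure)
print(report.records[["Q", "integrity", "n_tile_types", "captured_fraction"]]
      .round(3).to_string(index=False))
print("top candidate:", report.candidates[0])
```

prints

```
 Q  integrity  n_tile_types  captured_fraction
 5      0.954             4              0.270
10      1.000             1              0.550
15      0.988             4              0.806
20      1.000             1              0.994
25      0.979             3              0.995
30      0.958             3              0.996
40      0.917             2              0.998
60      0.900             1              0.999
top candidate: {'Q': 20, 'integrity': 1.0, 'n_tile_types': 1,
 'interlocking': 0.0, 'captured_fraction': 0.994..., 'flags': []}
```

The selection ranks `Q = 20` first: integrity is perfect, all 20 domains
have one size (one tile type), and rigid motion of the 20 trimers accounts
for 99% of the shell's mean-square fluctuation — the planted trimeric
organisation, recovered without using the planted labels.  (`Q = 10` also
peaks at integrity 1 — pairs of trimers — but the rule prefers the
smallest units, i.e. the largest qualifying `Q`.)

The same pipeline runs from the shell on real structures:

```sh
capsid-domains modes --pdb capsid.pdb --n-modes 100 --save modes.npz
capsid-domains sweep --pdb capsid.pdb --modes modes.npz \
    --q-max 180 --seed 1234 --out report.json
capsid-domains decompose --pdb capsid.pdb --modes modes.npz --q 32 \
    --format pdb-bfactor --out domains.pdb   # color by B-factor to view
```

For very large shells, `--decimate 2` keeps one centroid per two residues
with the interaction cutoff rescaled to 15 Å.

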