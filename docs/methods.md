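# Methods

## Model

A protein structure is reduced to one node per residue at the Cα position.
Nodes within a cutoff distance are joined by harmonic springs with the
native pair distance as equilibrium length, giving the energy
E = Σ k_ij (d_ij − d⁰_ij)².  The native conformation is the energy minimum
by construction, so the 3N×3N Hessian at the native coordinates is
positive semi-definite, with an off-diagonal 3×3 block −2k_ij ûûᵀ per
spring (û the unit bond vector) and diagonal blocks fixed by translation
invariance.  Its six zero eigenvalues are rigid-body motion; the remaining
eigenpairs are the internal normal modes, of which the lowest-frequency
ones dominate collective, allosterically relevant motion.

Perturbations change spring constants only, never geometry:

* **Binding** to a site adds springs of stiffness α·k between the site's
  residue pairs.  By default pairs beyond the network cutoff are included
  (`site_pairs: all`): a bound ligand rigidly couples the whole pocket.
  The alternative (`within_cutoff`) only stiffens existing contacts.
* **Mutation** at residue m rescales every spring incident to m by θ:
  θ↑ > 1 for a stabilizing (bulkier) substitution, θ↓ ∈ (0, 1) for a
  destabilizing (Ala/Gly-like) one.  The factor multiplies the native
  constant k_mj rather than replacing it with a uniform value, so a
  mutation preserves the contact topology and relative stiffness pattern
  around m.

For each retained mode the coupling ε_μ,i = Σ_j |e_μ,i − e_μ,j|² sums the
squared relative displacement between residue i and its partners j.  The
sum runs over *network neighbors* of i by default: ε measures elastic work
transmitted through the springs attached to i.  A sum over all residues is
available (`coupling_neighbors_only: false`); it behaves similarly on compact
structures but mixes in spatially meaningless long-range terms.  Treating
mode amplitudes as a harmonic ensemble and integrating gives the
per-residue free energy g_i = ½ k_BT Σ_μ ln ε_μ,i up to an additive
constant that cancels in all reported differences.  The allosteric free
energy of a perturbation is Δg_i = ½ k_BT Σ_μ ln(ε⁽ᴾ⁾/ε⁽⁰⁾), and the
allosteric modulation Δh_i subtracts the mean of Δg over the analyzed
residues, isolating the residue-specific signal from the uniform
background.  Δh is exactly zero-mean by construction; per-chain centering
is available for multi-chain analyses where a global mean would let one
chain's background leak into another's signal.

## Parameters

| key | default | meaning |
|---|---|---|
| `cutoff_A` | 10 Å | spring cutoff; must exceed ~3.8 Å (consecutive Cα) |
| `k` | 1 k_BT/Å² | uniform spring constant; pure unit — Δg/Δh are invariant to it |
| `n_modes` | 10 | lowest-frequency non-rigid modes retained |
| `alpha` | 1.0 | binding-spring scale (doubles intra-site stiffness on contacts) |
| `theta_up` | 2.0 | stabilizing-mutation factor |
| `theta_down` | 0.01 | destabilizing factor; kept > 0 so the network stays connected |
| `probe_len` | 3 | probing-window length: the smallest site-like footprint |
| `rigid_tol` | 1e-9 | rigid-mode threshold relative to the largest eigenvalue |

The cutoff and spring form are conventions of the Cα elastic-network
family rather than fitted quantities; all outputs are ratios in k_BT, so k
cancels identically (asserted to 1e-8 in the tests).  θ↓ = 0.01 rather
than 0 keeps the perturbed Hessian connected and the log-ratio finite.

## Numerical choices

* Eigendecomposition is a full symmetric solve (`scipy.linalg.eigh`);
  structures at desk scale (≤ a few hundred residues) make iterative
  solvers unnecessary.  Modes with eigenvalue below `rigid_tol`·λ_max are
  classified rigid; a connected network in general position yields exactly
  six, and any other count is logged as a warning because it signals a
  floppy (under-coordinated) region whose near-zero modes would be
  silently dropped.
* Eigenvector sign is fixed (first significant component positive) and
  ties in altloc occupancy resolve to file order, so repeated runs are
  byte-identical.
* Unperturbed and perturbed modes are paired by frequency rank after
  rigid-mode removal.  An overlap-based pairing (greedy maximal
  |dot product|) is available (`mode_matching: overlap`) for cases where a
  perturbation reorders nearly degenerate modes.
* Couplings below 1e-12 are clamped before the logarithm (counted on the
  profile and logged): a residue moving rigidly with all its neighbors in
  some mode would otherwise produce ±∞.
* Exhaustive scans (ASM/APM) compute the unperturbed eigendecomposition
  once and re-diagonalize each perturbed system exactly; no perturbative
  eigenvalue approximation is used, so every map row is bit-identical to
  the corresponding stand-alone run (asserted in the tests).  A low-rank
  update scheme would be the natural acceleration hook for larger
  structures.
* ROC thresholds are quantile cuts of the strictly positive part of the
  Δh distribution at cumulative 5% steps; residues with Δh ≤ 0 are never
  predicted.  Comparison is strictly-greater, and the final (100%) bin
  uses a cut of 0 so that it predicts every positive residue.  The AUC is
  the trapezoidal area with anchors (0,0) and (1,1).  Functional-site
  residues are excluded from truth and background — they are driven, not
  responding.  Sites overlapping the functional site by ≥ 2% of their size
  are skipped as operationally orthosteric.
* Whether the perturbed residue itself enters the Δh mean is ambiguous in
  principle; it is included, which keeps the mean a fixed linear operator
  across a whole map scan.

## Synthetic structures

The generator produces deterministic Cα-only PDB text for four
architectures: an ideal α-helix (rise 1.5 Å, 100°/residue, radius 2.3 Å);
a two-lobe dumbbell (helical lobes joined by an extended, deliberately
non-collinear linker — a straight bead chain would be a floppy
central-force mechanism with spurious zero modes); an exactly two-fold
symmetric dimer (a jittered helix and its 180° image, preserving the
chain-swap isometry to PDB precision); and a compact self-avoiding random
coil (3.8 Å steps, centroid-biased so packing stays protein-like and every
bead keeps enough contacts for mechanical rigidity).

The annotated benchmark dumbbell plants a functional site at the outer end
of lobe A and designates as the allosteric pocket the five lobe-B residues
adjacent to the linker — the region through which the linker transmits
mechanical load when the functional site is stiffened.

These fixtures emulate the topology and connectivity of real proteins, not
their chemistry: no side chains, no sequence dependence, no solvent, and
binding is mimicked purely as local stiffening.  Tests passing on them
establish the internal correctness and calibration of the machinery — the
algebraic identities, invariances, symmetries, and the ability to recover
a mechanically planted signal — not predictive accuracy on experimental
allosteric annotations, which depends on real structures and all-atom
site definitions.

## Problem sizes

The shipped tests and the acceptance script run on 20–150-residue
synthetic structures: large enough to have well-separated rigid and
internal modes and meaningful permutation nulls, small enough that full
eigendecompositions keep the whole suite in seconds.  The library itself
has no size logic beyond a soft warning above 1800 residues / 26 chains.

## Known limitations

* Cα resolution: ligand and mutant identity enter only through α and θ;
  two chemically different ligands with the same footprint are identical
  to the model.
* Single conformation: multi-model files use the first model; no
  conformational averaging.
* The reported Δg is meaningful only relative to the unperturbed state of
  the same structure; profiles from different structures are not on a
  common scale.
* Probing windows never span chain breaks (gap in author numbering > 1 or
  consecutive Cα distance > 4.5 Å); inter-chain probes at interfaces are
  not generated.
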