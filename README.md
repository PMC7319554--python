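# allomap

Per-residue allosteric signaling from Cα elastic network models: response
profiles for ligand binding and mutations, exhaustive Allosteric Signaling
and Probing Maps, fragment-style probe design, and a reverse-perturbation
benchmark for allosteric-site prediction.

## Who it is for

Structural bioinformaticians and computational chemists who want a fast,
structure-only estimate of where a perturbation — a bound ligand, a
stabilizing or destabilizing substitution — is felt elsewhere in a protein,
at per-residue resolution, without running molecular dynamics.

## The model

The protein is a Cα harmonic (elastic) network: one unit-mass bead per
residue, springs of constant k between all bead pairs within a cutoff
(10 Å default), native distances as equilibrium lengths:

    E = Σ_<i,j> k_ij (d_ij − d⁰_ij)²

Perturbations act only on the spring constants.  Ligand binding to a site S
adds springs of stiffness α·k between the residue pairs of S (the bound
ligand rigidly couples the pocket); an UP mutation (bulkier residue) at m
multiplies every spring incident to m by θ↑ > 1, a DOWN mutation
(Ala/Gly-like) by θ↓ < 1.

From the lowest-frequency normal modes e_μ of the unperturbed (0) and
perturbed (P) networks (ten modes by default, rigid-body modes removed),
each residue gets a mode coupling measuring the elastic work the mode
exerts on it through its contacts,

    ε_μ,i = Σ_{j∈N(i)} |e_μ,i − e_μ,j|²

and a harmonic per-residue free energy g_i = ½ k_BT Σ_μ ln ε_μ,i.
Comparing states gives the **allosteric free energy**

    Δg_i = ½ k_BT Σ_μ ln( ε⁽ᴾ⁾_μ,i / ε⁽⁰⁾_μ,i )

and the background-free **allosteric modulation**
Δh_i = Δg_i − ⟨Δg⟩_chain.  Δh > 0: configurational work is exerted on the
residue (conformational change promoted); Δh < 0: the residue is
stabilized.  Values beyond ~1 k_BT indicate strong allosteric
communication.  Because Δg is a ratio of couplings, results are independent
of the absolute spring constant.

On top of the single-perturbation pipeline:

* **ASM** — the Allosteric Signaling Map: for every position m, the
  modulation range Δh_i^(m↓↑) = Δh_i^(m↑) − Δh_i^(m↓), the maximal signal a
  substitution at m can send to each residue i.
* **APM** — the Allosteric Probing Map: a small ligand-mimicking probe
  bound to each window of three consecutive residues (L−2 windows per
  L-residue chain), for fragment-based scanning of latent allosteric sites;
  probes can be extended residue by residue to tune the signal.
* **Reverse-perturbation benchmark** — bind the *functional* site,
  rank residues by Δh, and score known allosteric sites by ROC/AUC with
  thresholds at 5% quantile steps of the positive Δh range.

## Worked example

`examples/04_reverse_perturbation_benchmark.py` builds a synthetic
two-lobe (dumbbell) protein with a functional site in lobe A and a planted
allosteric pocket in lobe B, binds the functional site, and scores the
pocket:

```
benchmark summary:
           protein         site  n_truth   auc
synthetic_dumbbell pocket_lobeB        5 0.786

permutation null: mean AUC 0.491, 95th percentile 0.722
```

The pocket's AUC of 0.786 sits above the 95th percentile (0.722) of AUCs
obtained for random five-residue "pockets": binding at the functional site
specifically loads the planted distal pocket.  The other example scripts
print a single-perturbation Δg/Δh profile, a chain-swap-symmetric signaling
map of a dimer with its strongest senders to a target site, and a probe
scan that picks the best non-contacting (>11 Å) window and strengthens its
signal from +0.024 to +0.067 k_BT by extending it with two adjacent
residues.

## Command line

```bash
allomap fixture --kind dumbbell --n 60 --seed 0 --out dumbbell.pdb
allomap perturb dumbbell.pdb --up A.41 --bind A.3-5 --out-dir run/
allomap asm dumbbell.pdb --out-dir run/           # signaling map (TSV)
allomap apm dumbbell.pdb --out-dir run/           # probing map (TSV)
allomap signal-to-site run/apm.tsv --site sites.json --out-dir run/
allomap probe-extend dumbbell.pdb --base A.35-37 --add A.38 --add A.39
allomap benchmark --proteins annotated_dir/ --out-dir bench/
```

Every command writes a `provenance.json` (config, input hashes, version)
from which the run can be reproduced.

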