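"""Reverse-perturbation prediction of a planted allosteric pocket.

Simulates ligand binding at the functional site of an annotated two-lobe
structure and scores how well the resulting modulation profile ranks the
residues of the known (planted) allosteric pocket, via a quantile-binned
ROC curve.  A permutation null (random truth sets of the same size) shows
the AUC expected by chance.
"""

import numpy as np

from allomap import (
    RunConfig,
    make_annotated_dumbbell,
    reverse_perturb,
    roc_from_profile,
    run_benchmark,
)

protein = make_annotated_dumbbell(n_residues=60, seed=0)
config = RunConfig()

table, rocs = run_benchmark([protein], config)
print("benchmark summary:")
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

profile = reverse_perturb(protein, protein.functional_sites, config)
func = protein.functional_sites[0].members
candidates = [r for r in protein.structure.residue_ids if r not in func]
rng = np.random.default_rng(0)
null = [
    roc_from_profile(
        profile,
        {candidates[i] for i in rng.choice(len(candidates), 5, replace=False)},
        exclude=func,
    ).auc
    for _ in range(500)
]
print(f"\npermutation null: mean AUC {np.mean(null):.3f}, "
      f"95th percentile {np.quantile(null, 0.95):.3f}")
print("\nThe pocket's AUC well above the null's 95th percentile means binding at")
print("the functional site singles out the planted distal pocket, not chance.")
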