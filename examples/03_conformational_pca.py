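"""Pooled Cα PCA: do the two conditions occupy distinct conformations?

The generator displaces one helix rigidly by 5 Å in the agonist-like
condition.  PCA of the pooled, superposed Cα coordinates should place
that displacement on PC1, separate the conditions in projection space,
and concentrate the first eigenvector's per-residue magnitude on the
displaced helix.
"""

import numpy as np

from switchscan import ca_pca, ev_displacements
from switchscan.synth import (
    InteractionPlan,
    bundle_bw_map,
    default_demo_spec,
    make_condition_pair,
)

spec = default_demo_spec(seed=0)
planA = InteractionPlan(plants=[], helix_displacement=(6, (5.0, 0.0, 0.0)))
planB = InteractionPlan(plants=[])
trajA, trajB, truth, structure = make_condition_pair(
    spec, planA, planB, n_frames=300, seed=0,
    noise_sigma=0.5, backbone_noise_sigma=None)

bw = bundle_bw_map(spec)
sel_keys = [k for h in range(1, 8) for k in bw.helix_residues(h)]
selection = [structure.atom_index(c, s, "CA") for c, s in sel_keys]
pca = ca_pca([("agonist", trajA), ("antagonist", trajB)], selection, burn_in=0.1)

pc1 = pca.projections[:, 0]
lab = np.array(pca.frame_labels)
print(f"PC1 captures {100 * pca.eigenvalues[0] / pca.eigenvalues.sum():.1f}% "
      "of the pooled positional variance")
print(f"agonist    PC1 range: [{pc1[lab == 'agonist'].min():7.2f}, "
      f"{pc1[lab == 'agonist'].max():7.2f}] Å")
print(f"antagonist PC1 range: [{pc1[lab == 'antagonist'].min():7.2f}, "
      f"{pc1[lab == 'antagonist'].max():7.2f}] Å")

mags = ev_displacements(pca, 0)
top = np.argsort(mags)[::-1][:5]
print("\nlargest EV1 per-residue displacements:")
for i in top:
    chain, seq = sel_keys[i]
    print(f"  {bw.label_of(chain, seq)} ({chain}/{seq}): {mags[i]:.2f} Å")

print()
print("Disjoint PC1 ranges mean the two ligand states stabilise distinct")
print("global conformations; the EV1 ranking identifies which helix moves.")
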