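"""Backbone dihedral statistics and α/π secondary structure per condition.

The antagonist-like condition carries a π-helical (i→i+5 hydrogen-bonded)
segment on one helix; in the agonist-like condition the same segment is
ordinary α-helix.  Circular means of phi/psi and per-residue DSSP-style
label fractions make the transition visible.
"""

from switchscan import phi_psi, ss_fractions
from switchscan.synth import bundle_bw_map, default_demo_spec, make_condition_pair

spec = default_demo_spec(seed=0)
trajA, trajB, truth, structure = make_condition_pair(spec, n_frames=300, seed=0)
bw = bundle_bw_map(spec)

helix, j0, j1 = truth.pi_segment["antagonist"]
segment = [(spec.chain, helix * 100 + j) for j in range(j0 + 2, j1 - 1)]

print("phi/psi circular means (degrees) in the rebuilt segment:")
print(f"{'residue':>9} {'phi_agonist':>12} {'phi_antag':>10} "
      f"{'psi_agonist':>12} {'psi_antag':>10}")
for key in segment[:4]:
    stats = {("agonist", s.kind): s for s in phi_psi(trajA, [key], burn_in=0.1)}
    stats.update({("antagonist", s.kind): s
                  for s in phi_psi(trajB, [key], burn_in=0.1)})
    print(f"{str(bw.label_of(*key)):>9} "
          f"{stats[('agonist', 'phi')].circ_mean:12.1f} "
          f"{stats[('antagonist', 'phi')].circ_mean:10.1f} "
          f"{stats[('agonist', 'psi')].circ_mean:12.1f} "
          f"{stats[('antagonist', 'psi')].circ_mean:10.1f}")

print("\nπ-helix (label I) fraction in the segment:")
frA = ss_fractions(trajA, burn_in=0.1)
frB = ss_fractions(trajB, burn_in=0.1)
for key in segment[:4]:
    print(f"  {bw.label_of(*key)}: agonist {frA[key]['I']:.2f}, "
          f"antagonist {frB[key]['I']:.2f}")

print()
print("Under antagonist the segment's psi means shift toward the π-helical")
print("basin and its I-fraction approaches 1; under agonist it is pure α.")
print("This is the rigid-π-to-flexible-α transition associated with")
print("receptor activation.")
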