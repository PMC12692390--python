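"""Difference hydrogen-bond and hydrophobic contact networks between
conditions.

Occupancy (fraction of frames a pair interacts) is computed for every
candidate pair in both conditions; the difference matrix is what a
red/blue occupancy heatmap would display — positive deltas are contacts
gained in the first condition, negative deltas contacts lost.
"""

from switchscan import (
    InteractionCriterion,
    diff_occupancy,
    make_condition_pair,
    scan_contacts,
)
from switchscan.synth import default_demo_spec

spec = default_demo_spec(seed=0)
trajA, trajB, truth, structure = make_condition_pair(spec, n_frames=600, seed=0)

planted = {
    "hbond": tuple(sorted((spec.res_key(5, 10), spec.res_key(6, 10)))),
    "hydrophobic": tuple(sorted((spec.res_key(6, 5), spec.res_key(7, 5)))),
}

for kind in ("hbond", "hydrophobic"):
    crit = InteractionCriterion.default(kind)
    occA = scan_contacts(trajA, crit, burn_in=0.1, condition="agonist")
    occB = scan_contacts(trajB, crit, burn_in=0.1, condition="antagonist")
    dm = diff_occupancy(occA, occB)
    print(f"\n{kind}: {len(dm.pairs)} candidate pairs; largest occupancy shifts:")
    for pair, a, b, d in list(zip(dm.pairs, dm.occ_A, dm.occ_B, dm.delta))[:3]:
        print(f"  {pair[0][0]}/{pair[0][1]} – {pair[1][0]}/{pair[1][1]}: "
              f"{a:.2f} vs {b:.2f} (delta {d:+.2f})")
    by_pair = dict(zip(map(tuple, dm.pairs), zip(dm.occ_A, dm.occ_B, dm.delta)))
    a, b, d = by_pair[planted[kind]]
    p = planted[kind]
    print(f"  planted switching pair {p[0][0]}/{p[0][1]} – {p[1][0]}/{p[1][1]}: "
          f"{a:.2f} vs {b:.2f} (delta {d:+.2f})")

print()
print("The largest shifts are whole-interface contacts made or broken by the")
print("planted collective changes — the 5 Å displacement of helix 6 and the")
print("α→π transition on helix 7 — exactly how a real activation heatmap is")
print("dominated by the moving helix.  The planted single-pair switches show")
print("up with their designed occupancy contrast (~0.85 vs ~0.1).")
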