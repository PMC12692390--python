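# switchscan

State-dependent interaction-network and conformational analysis of GPCR
transmembrane-domain MD ensembles.

## The problem

Class C G-protein-coupled receptors such as the sweet-taste receptor
subunit TAS1R2 are activated through their seven-transmembrane domain
(7TMD): an agonist bound in the TMD pocket breaks the conserved *ionic
lock* — the salt bridge between R3.50 and an acidic residue on TM6
(Ballesteros–Weinstein numbering) — while an antagonist stabilises it.
Activation is accompanied by *partner switching*: other salt bridges
(e.g. D7.32–R3.32), hydrogen bonds and hydrophobic contacts form in one
functional state and vanish in the other, TM6 swings outward, and
π-helical (i→i+5 hydrogen-bonded) segments on TM7 relax to ordinary
α-helix.

Given two MD ensembles of the same receptor — one per ligand condition —
`switchscan` answers the question *which interactions are molecular
switches, and what conformational change do they accompany?*  It is a
library for computational structural biologists analysing their own
trajectories, with a thin CLI for config-driven batch runs.

## What it computes

For residue pair *(i, j)* and interaction kind *k* with geometric
criterion *C_k* (salt bridge: min N–O distance over the charged groups
≤ 4 Å; H-bond: donor–acceptor ≤ 3.5 Å with D–H–A ≥ 135° when hydrogens
exist; hydrophobic: side-chain C/S distance ≤ 5 Å), the **occupancy** in
condition *c* is

    occ_c(i,j) = (1/T) Σ_t  1[ C_k satisfied in frame t ],

computed after discarding a burn-in (default: the first 10 % of frames).
The **difference matrix** Δ(i,j) = occ_A − occ_B drives switch calls:
*formed_in_A* when occ_A ≥ 0.5 and occ_B ≤ 0.25 (symmetrically for B),
*absent* when both ≤ 0.25, *stable* otherwise.  `scan_saltbridge_network`
enumerates every basic × acidic pair and ranks calls by |Δ|.

Conformational analysis: Kabsch least-squares superposition; pooled Cα
PCA (covariance of superposed 3N coordinates, eigenvectors in descending
eigenvalue order, per-frame projections labelled by condition, and
per-residue eigenvector displacement magnitudes √λ_k ‖v_k(i)‖);
backbone φ/ψ with circular means; and Kabsch–Sander secondary structure
(H-bond energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol, bond when E < −0.5) with π > α > 3₁₀ priority so π segments
are not masked.

Because microsecond membrane-MD inputs are not shippable, the
`switchscan.synth` module generates toy seven-helix bundles whose
interaction dynamics are *planted* — per-frame Bernoulli or two-state
Markov formation of named pairs, a rigid one-helix displacement, a
π-helical segment — and records the ground truth, so every stage is
testable against known answers.

## Worked example

```python
from switchscan import make_condition_pair, scan_saltbridge_network
from switchscan.synth import default_demo_spec

spec = default_demo_spec(seed=0)
trajA, trajB, truth, structure = make_condition_pair(spec, n_frames=900, seed=0)
calls = scan_saltbridge_network(trajA, trajB, labels=("agonist", "antagonist"))
```

Printing the calls (`examples/01_switch_discovery.py`) gives:

```
          pair  occ_agonist  occ_antag   delta  call
     2.46-3.46        0.935      0.028  +0.906  formed_in_A
     3.50-4.50        0.162      0.956  -0.794  formed_in_B
     2.46-3.50        0.004      0.000  +0.004  absent
     ...
```

The top row is the planted anti-correlated salt bridge: present in 93.5 %
of agonist-like frames and 2.8 % of antagonist-like frames, the
signature of an activation switch.  The second row is the ionic-lock
analogue, formed in the inactive-like condition (95.6 %) and mostly
broken under agonist (16.2 %) — the planted probabilities were 0.95/0.02
and 0.15/0.95, so the scan recovers the ground truth to binomial
accuracy.  The remaining basic × acidic pairs are background and classify
as absent.

The other examples cover network differencing (`02`), pooled Cα PCA with
eigenvector displacement mapping (`03`), dihedral circular statistics and
the α/π transition (`04`), and static-structure distances plus the full
CSV report bundle (`05`).  The CLI wraps the same code:

```
switchscan demo --seed 0 --out demo_out
switchscan run --config run.yaml
switchscan distance --structure model.pdb --pair "3.50:6.35" --bw-map map.tsv
```

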