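# Methods

## Scope and model

`switchscan` compares two molecular-dynamics ensembles of a receptor
transmembrane domain — conventionally an agonist-bound ("condition A")
and an antagonist-bound ("condition B") system — and reports three layers
of state dependence:

1. **Interaction networks.** Per-frame geometric detection of salt
   bridges, hydrogen bonds and hydrophobic contacts; per-pair occupancy
   (fraction of analysed frames the criterion holds); condition
   differencing; and switch classification.
2. **Collective conformation.** Kabsch superposition, RMSD and radius of
   gyration series, and pooled Cα principal component analysis with
   per-residue eigenvector displacement magnitudes.
3. **Local backbone state.** φ/ψ dihedral circular statistics and
   Kabsch–Sander secondary-structure assignment with explicit π-helix
   handling.

Residues are addressed by `(chain, res_seq)` and, through a user-supplied
TSV map, by Ballesteros–Weinstein labels ("3.50" = most conserved residue
of helix 3).  The map is data, not inference: no alignment-based BW
numbering is attempted.

## Interaction criteria

All cutoffs are configurable; defaults below.

| kind          | criterion                                                | default |
|---------------|----------------------------------------------------------|---------|
| salt bridge   | min distance, basic N (Arg NH1/NH2/NE, Lys NZ) × acidic O (Asp OD1/OD2, Glu OE1/OE2) | ≤ 4.0 Å |
| hydrogen bond | donor–acceptor heavy-atom distance; plus D–H–A angle when hydrogens exist | ≤ 3.5 Å, ≥ 135° |
| hydrophobic   | min side-chain C/S distance between nonpolar residues    | ≤ 5.0 Å |
| ligand contact| min heavy-atom distance residue × ligand                 | ≤ 4.0 Å |

Histidine joins the basic set only when `protonated_his` is enabled
(default off, matching a pH 7.4 preparation); this avoids spurious
bridges from neutral His.  The hydrophobic residue set is
{ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, TYR, CYS}: broader than the
polarity partition because aromatic Tyr and thiol Cys pack
hydrophobically even though their chemistry is polar.  Side-chain-only
atoms are used for hydrophobic contacts (backbone proximity is not
packing); an all-heavy-atom mode exists.  Sequence-adjacent pairs
(|Δres_seq| ≤ 1, same chain) are excluded from all network scans —
they are trivially in contact and would dominate any heatmap.  For
hydrogen bonds without explicit hydrogens the angle term is dropped
rather than guessed; amide H positions are reconstructed only inside the
secondary-structure module, where the Kabsch–Sander energy requires them.

Occupancies are exact frame counts divided by the analysed frame number.
The default burn-in discards the first 10 % of frames, the usual
equilibration allowance when analysing the tail of a production run.  An
ionic-lock style formed/broken *state* series (for reporting, distinct
from occupancy) uses a 4.5 Å threshold with 10-frame hysteresis to
suppress chattering near the boundary.

## Switch discovery

`diff_occupancy` takes the union of the two pair universes (a pair never
seen in one condition has occupancy 0 there, keeping the difference
well-defined) and sorts by |Δ| descending.  `classify_switch` uses
formed ≥ 0.5 and broken ≤ 0.25: the interesting contrasts in receptor
activation studies (≈0.8 vs ≈0.1) sit far from both thresholds, so the
classification is insensitive to their exact placement; both are
configurable.  The salt-bridge scan enumerates every basic × acidic pair
on the shared topology and classifies each.  The scan is descriptive —
no multiple-testing correction is applied by default, because the output
is a ranked shortlist for structural inspection, not a hypothesis test;
a two-proportion z-screen with Benjamini–Hochberg control is available
(`two_proportion_screen`) for users who want one.

## Conformational analysis

Superposition is the closed-form Kabsch solution (SVD of the
cross-covariance, determinant-corrected to a proper rotation); collinear
selections are rejected rather than silently resolved.  PCA follows the
essential-dynamics convention: frames of *all* conditions are pooled,
aligned in two passes (to the first frame, then to the resulting mean),
and the covariance of the flattened 3N Cα coordinates is
eigendecomposed.  Pooling is the default because the question is whether
conditions separate in a *common* mode space; per-condition PCA is just
a call with one labelled trajectory.  Per-residue displacement
magnitudes of eigenvector *k* are scaled by √λ_k so they carry the
mode's amplitude in Å.

Dihedrals use the IUPAC sign convention (verified against MDAnalysis),
range [−180°, 180°).  All summaries are circular (vector mean,
variance = 1 − R): angle populations near ±180° make arithmetic means
meaningless, and activation-relevant ψ shifts (α ↔ π basins) are
precisely the cases where this matters.

Secondary structure is classic Kabsch–Sander: backbone H-bond energy
E = q₁q₂·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) with q₁q₂ = 0.084,
bond when E < −0.5 kcal/mol; an n-turn at residue i when the carbonyl of
i accepts from the amide of i+n; two consecutive n-turns define a
minimal helix.  Overlap resolution is π > α > 3₁₀ (the behaviour of
modern DSSP releases), chosen because the analysis of interest is
detecting π segments that α patterns would otherwise mask; classic
α-priority is available via `pi_priority=False`.  Amide hydrogens are
placed 1.01 Å from N opposite the C(i−1)–N–Cα bisector when absent.
Interior labels agree exactly with mdtraj's DSSP on ideal fixtures (the
test suite checks this); terminal-residue conventions differ between
DSSP implementations and are not part of the contract.

## Synthetic ensembles and what they do (not) show

The generator builds parallel ideal helix bundles (backbone from
internal coordinates via NeRF; φ/ψ = −57°/−47° for α, −57°/−70° for π;
side chains as coarse outward-pointing pseudo-atoms carrying the correct
PDB atom names) and emits frames in which:

* each planted pair's hidden state follows an independent Bernoulli or
  two-state Markov chain; the moved residue's side chain is rigidly
  shifted so the closest tip pair sits at the state's target distance
  (formed 3.5 Å — 2.9 Å for H-bonds, 4.3 Å for hydrophobic — broken
  10 Å, ± 0.08 Å jitter), reproducing the bimodal formed/broken distance
  regimes seen in real switch analyses;
* every atom receives isotropic Gaussian noise, default 0.5 Å for side
  chains and 0.12 Å for backbone atoms — folded backbones fluctuate much
  less than side chains, and the smaller backbone noise keeps the
  planted secondary structure detectable, as it is in real trajectories;
* optionally one helix is rigidly displaced per condition (the planted
  PCA mode) and one segment is rebuilt with π-helical dihedrals.

Tip placement happens after noise, so detection is deterministic given
the hidden state and recovery error is purely the sampling error of the
state sequence — which is what the statistical tests quantify.  Defaults
are 900 frames at 100 ps stride, a 10× scale-down of a 100–1000 ns
analysis window sampled every 100 ps.  The default demo plants an
ionic-lock-like bridge (formed 15 % / 95 % across conditions), an
anti-correlated switch bridge (95 % / 2 %), a Markov-switching hydrogen
bond (persistences 0.98/0.91, stationary occupancy ≈ 82 %, vs 8 %
independent in the other condition), a switching hydrophobic contact
(85 % / 10 %), a 5 Å displacement of helix 6 under agonist, and a
π segment on helix 7 under antagonist.

What passing on synthetic data does **not** show: the generator has no
force field, no membrane, no correlated side-chain rotamers, no
loops, and white positional noise instead of physical fluctuation
spectra.  Tests demonstrate that the estimators recover what was
planted at the stated statistical precision — not that an MD trajectory
of a given length suffices to resolve a given switch.

## Numerical choices and degenerate inputs

* Minimum distances are exhaustive over the criterion's atom sets; the
  whole-network scan (`scan_contacts`) vectorises over candidate atom
  pairs and frame chunks but is exact (no spatial pruning), and equals
  the per-frame detectors by construction and by test.
* Eigenvalues are clipped at 0 to absorb eigh round-off; eigenvector
  order is descending eigenvalue.
* Burn-in accepts a fraction (of frames, rounded) or an absolute count;
  discarding every frame is an error, not an empty result.
* Empty distance series, empty selections, chain-terminal dihedral
  requests, missing side-chain atoms, duplicate PDB serials and
  insertion codes all raise typed errors naming the offender.
* The pipeline computes every table before writing any file, so a
  failing stage leaves no partial report.

## Known limitations

* No binary trajectory formats (DCD/XTC/TRR); multi-model PDB and a
  tabular text dialect keep fixtures diffable.  Conversion via mdtraj or
  MDAnalysis upstream is straightforward.
* Hydrogen-bond detection with explicit hydrogens assumes H atoms are
  within 1.25 Å of their donor in the topology frame.
* The secondary-structure module implements helix classes only
  (H/I/G/C); sheets, bridges, turns and bends are out of scope.
* Figure rendering is intentionally absent: the CSV/JSON data layer is
  the contract, and plots belong to the user's notebook.
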