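"""Synthetic helix-bundle ensembles with planted, controlled dynamics.

Microsecond membrane-MD trajectories of a receptor are not reproducible at
desk scale, so every pipeline stage is exercised instead on toy
seven-helix bundles whose interaction dynamics are *planted*: named
residue pairs form and break with prescribed per-frame probabilities
(independent Bernoulli or two-state Markov), distances are bimodal
(formed ≈ 3–4 Å, broken ≈ 10 Å), one helix can carry a rigid displacement
that a Cα PCA must recover, and a designated backbone segment can be
rebuilt with i→i+5 (π-helical) instead of i→i+4 (α-helical) hydrogen-bond
geometry.  The generator records everything it planted
(:class:`GroundTruth`), so recovery tests have exact references.

Structures are coarse on purpose: full backbone (N, Cα, C, O) built from
ideal dihedrals, plus side-chain pseudo-atoms carrying the
chemistry-relevant PDB atom names (Arg NH1/NH2/NE, Asp OD1/OD2, ...) at
idealized outward-pointing geometry.  The detectors consume only named
atom positions, so rotameric realism is unnecessary.

Everything is deterministic given the seed: one global seed drives
per-purpose child streams (hidden states, noise, jitter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AtomRecord,
    BACKBONE_ATOMS,
    BWLabel,
    BWMap,
    Structure,
    SwitchscanError,
    Trajectory,
    acceptor_atoms,
    donor_atoms,
    hydrophobic_atoms,
    saltbridge_atoms,
)

__all__ = [
    "ALPHA_PHI_PSI",
    "PI_PHI_PSI",
    "BundleSpec",
    "PlantedInteraction",
    "InteractionPlan",
    "GroundTruth",
    "place_atom",
    "build_backbone",
    "build_bundle",
    "bundle_bw_map",
    "simulate_ensemble",
    "make_condition_pair",
    "default_demo_spec",
    "default_condition_plans",
]

ResKey = tuple[str, int]

#: Ideal helical backbone dihedrals (phi, psi), degrees.
ALPHA_PHI_PSI = (-57.0, -47.0)
PI_PHI_PSI = (-57.0, -70.0)

# Idealised backbone internal coordinates (Å / degrees, peptide geometry).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given A, B, C and internal coordinates (NeRF).

    ``bond`` = |C–D|, ``angle`` = B–C–D, ``dihedral`` = A–B–C–D.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.cos(tor) * np.sin(ang),
        bond * np.sin(tor) * np.sin(ang),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    M = np.column_stack([bc, m, n])
    return c + M @ d_local


def build_backbone(
    phis: Sequence[float],
    psis: Sequence[float],
    omega: float = 180.0,
) -> dict[str, np.ndarray]:
    """Cartesian backbone (N, CA, C, O per residue) from phi/psi lists.

    phi(i) sets the placement of C(i); psi(i) sets N(i+1); carbonyl O is
    placed anti to the next amide nitrogen (dihedral N–CA–C–O =
    psi + 180°).  phi of the first residue is undefined and ignored.
    """
    n = len(phis)
    if n != len(psis) or n < 2:
        raise SwitchscanError("need equal-length phi/psi lists with ≥ 2 residues")
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        if i > 0:
            C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phis[i])
        if i < n - 1:
            N[i + 1] = place_atom(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psis[i])
            CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, omega)
        O[i] = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psis[i] + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


# ---------------------------------------------------------------------------
# Bundle construction
# ---------------------------------------------------------------------------

#: Side-chain pseudo-atom templates: name → (outward Å, lateral Å, axial Å)
#: offsets from Cα along the residue's outward direction.
_SIDE_CHAIN_TEMPLATES: dict[str, list[tuple[str, float, float, float]]] = {
    "ALA": [("CB", 1.5, 0.0, 0.0)],
    "VAL": [("CB", 1.5, 0.0, 0.0), ("CG1", 2.6, 0.5, 0.0), ("CG2", 2.6, -0.5, 0.0)],
    "LEU": [("CB", 1.5, 0.0, 0.0), ("CG", 2.6, 0.0, 0.0),
            ("CD1", 3.7, 0.5, 0.0), ("CD2", 3.7, -0.5, 0.0)],
    "ILE": [("CB", 1.5, 0.0, 0.0), ("CG1", 2.6, 0.3, 0.0), ("CD1", 3.7, 0.3, 0.0)],
    "MET": [("CB", 1.5, 0.0, 0.0), ("CG", 2.6, 0.0, 0.0), ("SD", 3.8, 0.0, 0.0)],
    "PHE": [("CB", 1.5, 0.0, 0.0), ("CG", 2.7, 0.0, 0.0), ("CZ", 4.3, 0.0, 0.0)],
    "TRP": [("CB", 1.5, 0.0, 0.0), ("CG", 2.7, 0.0, 0.0), ("NE1", 3.9, 0.5, 0.0)],
    "PRO": [("CB", 1.5, 0.3, 0.0), ("CG", 2.3, 0.8, 0.0)],
    "GLY": [],
    "SER": [("CB", 1.5, 0.0, 0.0), ("OG", 2.6, 0.0, 0.0)],
    "THR": [("CB", 1.5, 0.0, 0.0), ("OG1", 2.6, 0.4, 0.0), ("CG2", 2.6, -0.6, 0.0)],
    "CYS": [("CB", 1.5, 0.0, 0.0), ("SG", 2.8, 0.0, 0.0)],
    "ASN": [("CB", 1.5, 0.0, 0.0), ("CG", 2.6, 0.0, 0.0),
            ("OD1", 3.6, 0.5, 0.0), ("ND2", 3.6, -0.5, 0.0)],
    "GLN": [("CB", 1.5, 0.0, 0.0), ("CD", 3.2, 0.0, 0.0),
            ("OE1", 4.2, 0.5, 0.0), ("NE2", 4.2, -0.5, 0.0)],
    "TYR": [("CB", 1.5, 0.0, 0.0), ("CG", 2.7, 0.0, 0.0), ("OH", 5.0, 0.0, 0.0)],
    "ASP": [("CB", 1.5, 0.0, 0.0), ("CG", 2.6, 0.0, 0.0),
            ("OD1", 3.6, 0.5, 0.0), ("OD2", 3.6, -0.5, 0.0)],
    "GLU": [("CB", 1.5, 0.0, 0.0), ("CD", 3.2, 0.0, 0.0),
            ("OE1", 4.2, 0.5, 0.0), ("OE2", 4.2, -0.5, 0.0)],
    "ARG": [("CB", 1.5, 0.0, 0.0), ("NE", 3.6, 0.0, 0.0),
            ("NH1", 4.6, 0.6, 0.0), ("NH2", 4.6, -0.6, 0.0)],
    "LYS": [("CB", 1.5, 0.0, 0.0), ("NZ", 4.0, 0.0, 0.0)],
    "HIS": [("CB", 1.5, 0.0, 0.0), ("ND1", 3.2, 0.5, 0.0), ("NE2", 3.6, -0.5, 0.0)],
}


def _element_of(name: str) -> str:
    for c in name:
        if c.isalpha():
            return c
    return "X"


@dataclass(frozen=True)
class BundleSpec:
    """Geometry and sequence of a toy transmembrane-like helix bundle.

    Helix ``h`` (1-based) occupies residue numbers ``h*100 + j`` for
    ``j = 1..n_res`` on a single chain; the numbering gap between helices
    marks them as topologically disconnected segments (loops are not
    modelled).  Rise and twist are the ideal α-helix parameters the
    backbone dihedrals reproduce; they are recorded for reference.
    """

    n_helices: int = 7
    n_res: int = 16
    sequences: tuple[tuple[str, ...], ...] | None = None
    rise_per_res: float = 1.5
    twist_per_res: float = 100.0
    radius: float = 10.5
    chain: str = "A"
    seed: int = 0

    def __post_init__(self):
        if self.n_helices < 1 or self.n_res < 4:
            raise SwitchscanError("bundle needs ≥ 1 helix of ≥ 4 residues")
        if self.sequences is not None:
            if len(self.sequences) != self.n_helices or any(
                len(s) != self.n_res for s in self.sequences
            ):
                raise SwitchscanError("sequences must be n_helices × n_res")
            for seq in self.sequences:
                for code in seq:
                    if code not in _SIDE_CHAIN_TEMPLATES:
                        raise SwitchscanError(f"unknown residue code {code!r}")
        if self.rise_per_res <= 0 or self.radius <= 0:
            raise SwitchscanError("geometry parameters must be positive")

    def helix_sequence(self, h: int) -> tuple[str, ...]:
        if self.sequences is not None:
            return self.sequences[h - 1]
        return tuple(
            "LEU" if j % 4 == 3 else "ALA" for j in range(1, self.n_res + 1)
        )

    def res_seq(self, helix: int, j: int) -> int:
        """Sequence number of residue j (1-based) of a helix."""
        if not (1 <= helix <= self.n_helices and 1 <= j <= self.n_res):
            raise SwitchscanError(f"helix {helix} residue {j} outside bundle")
        return helix * 100 + j

    def res_key(self, helix: int, j: int) -> ResKey:
        return (self.chain, self.res_seq(helix, j))


def _axis_to_z(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate a point cloud so the principal axis of `reference` maps to +z."""
    centered = reference - reference.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    axis = Vt[0]
    if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return coords @ R.T


def build_bundle(
    spec: BundleSpec,
    dihedral_overrides: dict[tuple[int, int], tuple[float, float]] | None = None,
) -> Structure:
    """Build an ideal parallel helix bundle on a circle of ``spec.radius``.

    ``dihedral_overrides`` maps (helix, residue_j) → (phi, psi), replacing
    the ideal α-helical values — the hook used to plant π-helical
    segments.  Deterministic: the same spec yields bit-identical
    coordinates.
    """
    overrides = dihedral_overrides or {}
    atoms: list[AtomRecord] = []
    serial = 1
    for h in range(1, spec.n_helices + 1):
        seq = spec.helix_sequence(h)
        phis = [overrides.get((h, j), ALPHA_PHI_PSI)[0] for j in range(1, spec.n_res + 1)]
        psis = [overrides.get((h, j), ALPHA_PHI_PSI)[1] for j in range(1, spec.n_res + 1)]
        bb = build_backbone(phis, psis)
        ca_ref = bb["CA"]
        stacked = np.vstack([bb["N"], bb["CA"], bb["C"], bb["O"]])
        stacked = _axis_to_z(stacked - ca_ref.mean(axis=0), ca_ref - ca_ref.mean(axis=0))
        theta = 2 * np.pi * (h - 1) / spec.n_helices
        offset = np.array([
            spec.radius * np.cos(theta), spec.radius * np.sin(theta), 0.0
        ])
        stacked = stacked + offset
        N, CA, C, O = np.split(stacked, 4)
        for j in range(1, spec.n_res + 1):
            res_name = seq[j - 1]
            res_seq = spec.res_seq(h, j)
            i = j - 1
            backbone = [("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])]
            # outward direction: horizontal, from the helix axis through Cα
            u = CA[i] - np.array([offset[0], offset[1], CA[i][2]])
            norm = np.linalg.norm(u)
            u = u / norm if norm > 1e-9 else np.array([np.cos(theta), np.sin(theta), 0.0])
            perp = np.cross([0.0, 0.0, 1.0], u)
            side = [
                (name, CA[i] + out * u + lat * perp + np.array([0.0, 0.0, ax]))
                for name, out, lat, ax in _SIDE_CHAIN_TEMPLATES[res_name]
            ]
            for name, pos in backbone + side:
                atoms.append(AtomRecord(
                    serial=serial, name=name, element=_element_of(name),
                    res_seq=res_seq, res_name=res_name, chain=spec.chain,
                    position=tuple(float(x) for x in pos),
                ))
                serial += 1
    return Structure(atoms)


def bundle_bw_map(spec: BundleSpec) -> BWMap:
    """Ballesteros–Weinstein map of a bundle: the middle residue of each
    helix is position 50."""
    mid = (spec.n_res + 1) // 2
    entries = {}
    for h in range(1, spec.n_helices + 1):
        for j in range(1, spec.n_res + 1):
            entries[spec.res_key(h, j)] = BWLabel(h, 50 + j - mid)
    return BWMap(entries)


# ---------------------------------------------------------------------------
# Interaction plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteraction:
    """One planted residue-pair dynamic.

    Exactly one of ``p_form`` (independent per-frame Bernoulli) or
    ``markov`` (stay-formed, stay-broken persistence probabilities) must
    be given.  The second residue of ``pair`` is the one whose side chain
    is repositioned to realise the state's target distance.
    """

    pair: tuple[ResKey, ResKey]
    kind: str  # saltbridge | hbond | hydrophobic
    formed_distance: float = 3.5
    broken_distance: float = 10.0
    p_form: float | None = None
    markov: tuple[float, float] | None = None

    def __post_init__(self):
        if (self.p_form is None) == (self.markov is None):
            raise SwitchscanError("give exactly one of p_form or markov")
        if self.p_form is not None and not 0 <= self.p_form <= 1:
            raise SwitchscanError("p_form must lie in [0, 1]")
        if self.markov is not None and not all(0 <= q <= 1 for q in self.markov):
            raise SwitchscanError("markov persistences must lie in [0, 1]")
        if not self.formed_distance < self.broken_distance:
            raise SwitchscanError("formed distance must be below broken distance")

    def stationary(self) -> float:
        """Long-run probability of the formed state."""
        if self.p_form is not None:
            return self.p_form
        qf, qb = self.markov
        a, b = 1 - qf, 1 - qb  # leave-formed, leave-broken rates
        if a + b == 0:
            return 0.5
        return b / (a + b)


@dataclass
class InteractionPlan:
    """Per-condition generative plan: planted pair dynamics plus optional
    collective features (one-helix rigid displacement, π-helical segment)."""

    plants: list[PlantedInteraction] = field(default_factory=list)
    helix_displacement: tuple[int, tuple[float, float, float]] | None = None
    pi_segment: tuple[int, int, int] | None = None  # (helix, j_start, j_end)

    def validate(self) -> None:
        moved = [p.pair[1] for p in self.plants]
        if len(set(moved)) != len(moved):
            raise SwitchscanError(
                "conflicting plants: a residue's side chain is moved by two plants"
            )
        anchors = {p.pair[0] for p in self.plants}
        clash = anchors & set(moved)
        if clash:
            raise SwitchscanError(
                f"conflicting plants share residues {sorted(clash)}"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests.

    ``states`` maps condition label → plant index → per-frame hidden
    formed/broken booleans; ``stationary`` holds the corresponding
    long-run occupancies.
    """

    seed: int
    n_frames: int
    plants: dict[str, list[PlantedInteraction]]
    states: dict[str, list[np.ndarray]]
    stationary: dict[str, list[float]]
    helix_displacement: dict[str, tuple[int, tuple[float, float, float]] | None]
    pi_segment: dict[str, tuple[int, int, int] | None]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "n_frames": self.n_frames,
            "conditions": {
                label: {
                    "plants": [
                        {
                            "pair": [list(p.pair[0]), list(p.pair[1])],
                            "kind": p.kind,
                            "formed_distance": p.formed_distance,
                            "broken_distance": p.broken_distance,
                            "p_form": p.p_form,
                            "markov": p.markov,
                            "stationary": self.stationary[label][k],
                            "states": [int(x) for x in self.states[label][k]],
                        }
                        for k, p in enumerate(self.plants[label])
                    ],
                    "helix_displacement": self.helix_displacement[label],
                    "pi_segment": self.pi_segment[label],
                }
                for label in self.plants
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Ensemble simulation
# ---------------------------------------------------------------------------

def _plant_atom_sets(structure: Structure, plant: PlantedInteraction):
    """(anchor atom indices, moved tip indices, all moved side-chain indices)."""
    rA = structure.residue(*plant.pair[0])
    rB = structure.residue(*plant.pair[1])
    if plant.kind == "saltbridge":
        _, atomsA = saltbridge_atoms(rA.res_name, protonated_his=True)
        _, atomsB = saltbridge_atoms(rB.res_name, protonated_his=True)
        idxA = structure.residue_atom_indices(rA, atomsA)
        idxB = structure.residue_atom_indices(rB, atomsB)
    elif plant.kind == "hbond":
        namesA = (donor_atoms(rA.res_name) | acceptor_atoms(rA.res_name)) - BACKBONE_ATOMS
        namesB = (donor_atoms(rB.res_name) | acceptor_atoms(rB.res_name)) - BACKBONE_ATOMS
        idxA = structure.residue_atom_indices(rA, namesA)
        idxB = structure.residue_atom_indices(rB, namesB)
    elif plant.kind == "hydrophobic":
        idxA = hydrophobic_atoms(structure, rA)
        idxB = hydrophobic_atoms(structure, rB)
    else:
        raise SwitchscanError(f"cannot plant interaction kind {plant.kind!r}")
    if not idxA or not idxB:
        raise SwitchscanError(
            f"plant {plant.pair} ({plant.kind}): residues lack the required atoms"
        )
    side_B = [
        i for i in structure.residue_atom_indices(rB)
        if structure.atoms[i].name not in BACKBONE_ATOMS
    ]
    return idxA, idxB, side_B


def _helix_atom_indices(structure: Structure, spec: BundleSpec, helix: int) -> np.ndarray:
    lo, hi = helix * 100 + 1, helix * 100 + spec.n_res
    return np.array([
        i for i, a in enumerate(structure.atoms)
        if a.chain == spec.chain and lo <= a.res_seq <= hi
    ])


def _sample_states(plant: PlantedInteraction, n_frames: int, rng) -> np.ndarray:
    if plant.p_form is not None:
        return rng.random(n_frames) < plant.p_form
    qf, qb = plant.markov
    states = np.empty(n_frames, dtype=bool)
    state = rng.random() < plant.stationary()
    for f in range(n_frames):
        u = rng.random()
        state = (u < qf) if state else (u >= qb)
        states[f] = state
    return states


def simulate_ensemble(
    structure: Structure,
    plan: InteractionPlan,
    n_frames: int = 900,
    noise_sigma: float = 0.5,
    seed: int = 0,
    backbone_noise_sigma: float | None = 0.12,
    jitter_sigma: float = 0.08,
    stride_ps: float = 100.0,
    base_coords: np.ndarray | None = None,
    spec: BundleSpec | None = None,
) -> tuple[Trajectory, list[np.ndarray]]:
    """Emit a trajectory realising a plan's hidden-state dynamics.

    Per frame: isotropic Gaussian noise is added to every atom (backbone
    atoms use the smaller ``backbone_noise_sigma``, emulating the stiffer
    backbone of a folded helix), each plant's hidden state is sampled, and
    the moved residue's side chain is rigidly shifted so the closest
    anchor–tip atom pair sits at the state's target distance ± jitter.
    Returns the trajectory and the per-plant hidden state arrays.
    """
    plan.validate()
    base = np.array(structure.coords if base_coords is None else base_coords, dtype=float)
    if plan.helix_displacement is not None:
        if spec is None:
            raise SwitchscanError("helix_displacement requires the BundleSpec")
        helix, vec = plan.helix_displacement
        base[_helix_atom_indices(structure, spec, helix)] += np.asarray(vec)

    rng_states = np.random.default_rng([seed, 1])
    rng_noise = np.random.default_rng([seed, 2])
    rng_jitter = np.random.default_rng([seed, 3])

    is_backbone = np.array([a.name in BACKBONE_ATOMS for a in structure.atoms])
    sigma = np.full(structure.n_atoms, noise_sigma)
    if backbone_noise_sigma is not None:
        sigma[is_backbone] = backbone_noise_sigma

    coords = base[None] + rng_noise.normal(size=(n_frames, structure.n_atoms, 3)) * sigma[None, :, None]

    all_states: list[np.ndarray] = []
    for plant in plan.plants:
        idxA, idxB, side_B = _plant_atom_sets(structure, plant)
        states = _sample_states(plant, n_frames, rng_states)
        all_states.append(states)
        targets = np.where(states, plant.formed_distance, plant.broken_distance)
        targets = targets + rng_jitter.normal(scale=jitter_sigma, size=n_frames)
        targets = np.clip(targets, 0.5, None)
        A = coords[:, idxA]  # (F, a, 3)
        B = coords[:, idxB]  # (F, b, 3)
        diff = B[:, None, :, :] - A[:, :, None, :]
        d = np.sqrt((diff * diff).sum(axis=-1))  # (F, a, b)
        flat = d.reshape(n_frames, -1)
        arg = flat.argmin(axis=1)
        a_i, b_i = np.unravel_index(arg, d.shape[1:])
        frames = np.arange(n_frames)
        vec = diff[frames, a_i, b_i]  # closest tip pair, A → B
        d0 = flat[frames, arg]
        unit = vec / d0[:, None]
        shift = (targets - d0)[:, None] * unit
        coords[:, side_B] += shift[:, None, :]

    times = np.arange(n_frames, dtype=float) * stride_ps
    return Trajectory(structure, coords, times), all_states


def _pi_overrides(pi_segment: tuple[int, int, int] | None):
    if pi_segment is None:
        return None
    helix, j0, j1 = pi_segment
    return {(helix, j): PI_PHI_PSI for j in range(j0, j1 + 1)}


def make_condition_pair(
    spec: BundleSpec,
    planA: InteractionPlan | None = None,
    planB: InteractionPlan | None = None,
    n_frames: int = 900,
    noise_sigma: float = 0.5,
    seed: int = 0,
    labels: tuple[str, str] = ("agonist", "antagonist"),
    **sim_kwargs,
) -> tuple[Trajectory, Trajectory, GroundTruth, Structure]:
    """Two labelled trajectories over a shared topology, plus ground truth.

    With no plans given, the default demo plants (on adjacent helices of a
    7×16 bundle): an ionic-lock-like salt bridge formed in condition B and
    mostly broken in A, an anti-correlated switch salt bridge formed in A,
    a Markov-switching hydrogen bond, a switching hydrophobic contact, a
    5 Å rigid displacement of one helix in condition A, and a π-helical
    segment in condition B only.
    """
    if (planA is None) != (planB is None):
        raise SwitchscanError("give both plans or neither")
    if planA is None:
        planA, planB = default_condition_plans(spec)
    structure = build_bundle(spec)
    baseA = structure.coords
    baseB = structure.coords
    if planA.pi_segment is not None:
        baseA = build_bundle(spec, _pi_overrides(planA.pi_segment)).coords
    if planB.pi_segment is not None:
        baseB = build_bundle(spec, _pi_overrides(planB.pi_segment)).coords
    trajA, statesA = simulate_ensemble(
        structure, planA, n_frames, noise_sigma, seed=(seed * 2 + 1) % (2**31),
        base_coords=baseA, spec=spec, **sim_kwargs,
    )
    trajB, statesB = simulate_ensemble(
        structure, planB, n_frames, noise_sigma, seed=(seed * 2 + 2) % (2**31),
        base_coords=baseB, spec=spec, **sim_kwargs,
    )
    la, lb = labels
    gt = GroundTruth(
        seed=seed,
        n_frames=n_frames,
        plants={la: planA.plants, lb: planB.plants},
        states={la: statesA, lb: statesB},
        stationary={
            la: [p.stationary() for p in planA.plants],
            lb: [p.stationary() for p in planB.plants],
        },
        helix_displacement={la: planA.helix_displacement, lb: planB.helix_displacement},
        pi_segment={la: planA.pi_segment, lb: planB.pi_segment},
    )
    return trajA, trajB, gt, structure


# ---------------------------------------------------------------------------
# Default demo conditions
# ---------------------------------------------------------------------------

def default_demo_spec(seed: int = 0) -> BundleSpec:
    """7 × 16 bundle whose sequence hosts the default planted pairs."""
    n_h, n_res = 7, 16
    seqs = []
    for h in range(1, n_h + 1):
        seq = ["LEU" if j % 4 == 3 else "ALA" for j in range(1, n_res + 1)]
        seqs.append(seq)
    # planted residues (helix, j, residue): see default_condition_plans
    placements = {
        (3, 8): "ARG", (4, 8): "GLU",   # ionic-lock-like pair
        (3, 4): "ARG", (2, 4): "ASP",   # switch salt bridge
        (5, 10): "SER", (6, 10): "ASP", # switching hydrogen bond
        (6, 5): "LEU", (7, 5): "ILE",   # switching hydrophobic contact
    }
    for (h, j), res in placements.items():
        seqs[h - 1][j - 1] = res
    return BundleSpec(
        n_helices=n_h, n_res=n_res,
        sequences=tuple(tuple(s) for s in seqs),
        seed=seed,
    )


def default_condition_plans(spec: BundleSpec) -> tuple[InteractionPlan, InteractionPlan]:
    """The demo's two-condition plan pair.

    Condition A emulates an agonist-bound ensemble: ionic lock mostly
    broken (15% formed), switch bridge formed (95%), the hydrogen bond
    present with ~82% stationary occupancy via a persistent Markov chain,
    the hydrophobic contact formed, one helix displaced 5 Å, all-α
    backbone.  Condition B emulates the antagonist-bound ensemble: lock
    formed (95%), switch broken (2%), hydrogen bond rare (8%),
    hydrophobic contact rare (10%), no displacement, and a π-helical
    segment on helix 7.
    """
    lock = (spec.res_key(3, 8), spec.res_key(4, 8))
    switch = (spec.res_key(3, 4), spec.res_key(2, 4))
    hb = (spec.res_key(5, 10), spec.res_key(6, 10))
    phob = (spec.res_key(6, 5), spec.res_key(7, 5))
    planA = InteractionPlan(
        plants=[
            PlantedInteraction(lock, "saltbridge", p_form=0.15),
            PlantedInteraction(switch, "saltbridge", p_form=0.95),
            PlantedInteraction(hb, "hbond", formed_distance=2.9,
                               markov=(0.98, 0.91)),  # stationary ≈ 0.818
            PlantedInteraction(phob, "hydrophobic", formed_distance=4.3,
                               p_form=0.85),
        ],
        helix_displacement=(6, (5.0, 0.0, 0.0)),
        pi_segment=None,
    )
    planB = InteractionPlan(
        plants=[
            PlantedInteraction(lock, "saltbridge", p_form=0.95),
            PlantedInteraction(switch, "saltbridge", p_form=0.02),
            PlantedInteraction(hb, "hbond", formed_distance=2.9, p_form=0.08),
            PlantedInteraction(phob, "hydrophobic", formed_distance=4.3,
                               p_form=0.10),
        ],
        helix_displacement=None,
        pi_segment=(7, 5, 12),
    )
    return planA, planB
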