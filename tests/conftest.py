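import numpy as np
import pytest

from switchscan.core import AtomRecord, Structure, Trajectory
from switchscan.synth import build_backbone


def make_atom(serial, name, res_seq, res_name, pos, chain="A", element=None):
    if element is None:
        element = next(c for c in name if c.isalpha())
    return AtomRecord(
        serial=serial, name=name, element=element, res_seq=res_seq,
        res_name=res_name, chain=chain, position=tuple(float(x) for x in pos),
    )


def helix_structure(phi, psi, n=12, res_name="ALA", chain="A"):
    """Backbone-only structure built from constant dihedrals."""
    bb = build_backbone([phi] * n, [psi] * n)
    atoms, serial = [], 1
    for i in range(n):
        for name in ("N", "CA", "C", "O"):
            atoms.append(make_atom(serial, name, i + 1, res_name, bb[name][i],
                                   chain=chain))
            serial += 1
    return Structure(atoms)


# Side-chain atom names used when building random toy residues.
_TOY_SIDECHAINS = {
    "ARG": ["CB", "NE", "NH1", "NH2"],
    "LYS": ["CB", "NZ"],
    "ASP": ["CB", "OD1", "OD2"],
    "GLU": ["CB", "OE1", "OE2"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1"],
    "TYR": ["CB", "CG", "OH"],
    "LEU": ["CB", "CG", "CD1"],
    "ILE": ["CB", "CG1", "CD1"],
    "VAL": ["CB", "CG1", "CG2"],
    "MET": ["CB", "CG", "SD"],
    "PHE": ["CB", "CG", "CZ"],
    "ALA": ["CB"],
    "GLY": [],
    "ASN": ["CB", "OD1", "ND2"],
    "GLN": ["CB", "OE1", "NE2"],
}


def random_toy_system(seed, n_res=12, n_frames=6, box=14.0, with_h=False):
    """Random compact toy Structure + Trajectory for oracle-equality tests.

    Residues are scattered in a box small enough that every interaction
    kind straddles its cutoff; atom positions are resampled per frame so
    the detectors see genuinely different geometries.
    """
    rng = np.random.default_rng(seed)
    names = list(_TOY_SIDECHAINS)
    atoms, serial = [], 1
    for r in range(n_res):
        res_name = names[rng.integers(len(names))]
        center = rng.uniform(0, box, 3)
        for name in ["N", "CA", "C", "O"] + _TOY_SIDECHAINS[res_name]:
            pos = center + rng.normal(scale=1.2, size=3)
            atoms.append(make_atom(serial, name, r + 1, res_name, pos))
            serial += 1
            if with_h and name in ("N", "OG", "OG1", "NZ", "NE", "NH1",
                                   "NH2", "OH", "ND2", "NE2"):
                hname = "H" if name == "N" else "H" + name[1:]
                hpos = pos + rng.normal(scale=0.4, size=3)
                hpos = pos + (hpos - pos) / np.linalg.norm(hpos - pos)
                atoms.append(make_atom(serial, hname, r + 1, res_name, hpos,
                                       element="H"))
                serial += 1
    structure = Structure(atoms)
    base = structure.coords
    coords = base[None] + rng.normal(scale=1.0, size=(n_frames, len(atoms), 3))
    times = np.arange(n_frames, dtype=float) * 100.0
    return structure, Trajectory(structure, coords, times)


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture
def toy_saltbridge_structure():
    """Arg and Asp with NH1–OD1 at exactly 3.5 Å; all other charged-group
    atoms ≥ 6 Å away."""
    atoms = [
        make_atom(1, "N", 1, "ARG", (0, 0, -8)),
        make_atom(2, "CA", 1, "ARG", (1.5, 0, -8)),
        make_atom(3, "C", 1, "ARG", (2.5, 1, -8)),
        make_atom(4, "O", 1, "ARG", (2.5, 2, -8)),
        make_atom(5, "NH1", 1, "ARG", (0, 0, 0)),
        make_atom(6, "NH2", 1, "ARG", (-6.5, 0, 0)),
        make_atom(7, "NE", 1, "ARG", (-7.5, 0, 0)),
        make_atom(8, "N", 3, "ASP", (0, 0, 9)),
        make_atom(9, "CA", 3, "ASP", (1.5, 0, 9)),
        make_atom(10, "C", 3, "ASP", (2.5, 1, 9)),
        make_atom(11, "O", 3, "ASP", (2.5, 2, 9)),
        make_atom(12, "OD1", 3, "ASP", (3.5, 0, 0)),
        make_atom(13, "OD2", 3, "ASP", (9.5, 0, 0)),
    ]
    return Structure(atoms)
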