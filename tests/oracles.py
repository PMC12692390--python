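"""Independent brute-force oracles for detector-equality tests.

Deliberately naive: scalar triple loops over every candidate atom pair or
triple, no vectorisation, no pruning, no shared code with the detectors
beyond the residue chemistry tables (which are definitions, not
algorithm).
"""

import math

from switchscan.core import (
    acceptor_atoms,
    donor_atoms,
    hydrophobic_atoms,
    saltbridge_atoms,
)

BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _pair_key(a, b):
    return (a, b) if a <= b else (b, a)


def _adjacent(resA, resB):
    return resA.chain == resB.chain and abs(resA.res_seq - resB.res_seq) <= 1


def brute_saltbridges(frame, structure, cutoff=4.0, protonated_his=False):
    out = set()
    residues = list(structure.iter_residues())
    for rA in residues:
        roleA, atomsA = saltbridge_atoms(rA.res_name, protonated_his)
        if roleA != "basic":
            continue
        for rB in residues:
            roleB, atomsB = saltbridge_atoms(rB.res_name, protonated_his)
            if roleB != "acidic" or _adjacent(rA, rB):
                continue
            found = False
            for i in range(rA.atom_start, rA.atom_stop):
                if structure.atoms[i].name not in atomsA:
                    continue
                for j in range(rB.atom_start, rB.atom_stop):
                    if structure.atoms[j].name not in atomsB:
                        continue
                    if _dist(frame[i], frame[j]) <= cutoff:
                        found = True
            if found:
                out.add(_pair_key(rA.key, rB.key))
    return out


def _hydrogens_on(structure, frame0, res, donor_idx):
    """Hydrogens within 1.25 Å of the donor in the topology coordinates."""
    out = []
    for i in range(res.atom_start, res.atom_stop):
        a = structure.atoms[i]
        if a.element.upper() == "H" and _dist(
            structure.coords[i], structure.coords[donor_idx]
        ) <= 1.25:
            out.append(i)
    return out


def brute_hbonds(frame, structure, cutoff=3.5, angle_cutoff=135.0):
    has_h = any(a.element.upper() == "H" for a in structure.atoms)
    out = set()
    residues = list(structure.iter_residues())
    for dres in residues:
        for ares in residues:
            if dres.key == ares.key:
                continue
            for di in range(dres.atom_start, dres.atom_stop):
                datom = structure.atoms[di]
                if datom.name not in donor_atoms(dres.res_name):
                    continue
                for ai in range(ares.atom_start, ares.atom_stop):
                    aatom = structure.atoms[ai]
                    if aatom.name not in acceptor_atoms(ares.res_name):
                        continue
                    if (_adjacent(dres, ares) and datom.name == "N"
                            and aatom.name in ("O", "OXT")):
                        continue
                    if _dist(frame[di], frame[ai]) > cutoff:
                        continue
                    if has_h:
                        hs = _hydrogens_on(structure, frame, dres, di)
                        if hs:
                            good = False
                            for hi in hs:
                                v1 = [frame[di][k] - frame[hi][k] for k in range(3)]
                                v2 = [frame[ai][k] - frame[hi][k] for k in range(3)]
                                dot = sum(x * y for x, y in zip(v1, v2))
                                n1 = math.sqrt(sum(x * x for x in v1))
                                n2 = math.sqrt(sum(x * x for x in v2))
                                ang = math.degrees(
                                    math.acos(max(-1.0, min(1.0, dot / (n1 * n2))))
                                )
                                if ang >= angle_cutoff:
                                    good = True
                            if not good:
                                continue
                    out.add(((dres.key, datom.name), (ares.key, aatom.name)))
    return out


def brute_hydrophobic(frame, structure, cutoff=5.0, nonpolar_set=None):
    from switchscan.core import DEFAULT_NONPOLAR_CONTACT_SET
    nonpolar = nonpolar_set or DEFAULT_NONPOLAR_CONTACT_SET
    out = set()
    residues = [r for r in structure.iter_residues() if r.res_name in nonpolar]
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            rA, rB = residues[a], residues[b]
            if _adjacent(rA, rB):
                continue
            idxA = hydrophobic_atoms(structure, rA)
            idxB = hydrophobic_atoms(structure, rB)
            found = False
            for i in idxA:
                for j in idxB:
                    if _dist(frame[i], frame[j]) <= cutoff:
                        found = True
            if found:
                out.add(_pair_key(rA.key, rB.key))
    return out


def brute_min_distance(frame, idxA, idxB):
    best = float("inf")
    for i in idxA:
        for j in idxB:
            best = min(best, _dist(frame[i], frame[j]))
    return best
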