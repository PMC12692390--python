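"""Domain types shared by the whole analysis stack.

The package analyses molecular-dynamics ensembles of G-protein-coupled
receptor transmembrane domains.  Everything downstream — interaction
detection, differential network analysis, PCA, secondary structure —
consumes the small set of containers defined here: atoms, structures,
trajectories, Ballesteros–Weinstein residue labels, and residue chemistry
classes.

Residues are identified throughout by ``(chain, res_seq)`` pairs, with
Ballesteros–Weinstein ("H.P") labels resolved through a user-supplied
:class:`BWMap`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SwitchscanError",
    "BWParseError",
    "BWLookupError",
    "ClassificationError",
    "MissingAtomsError",
    "AtomRecord",
    "Residue",
    "Structure",
    "Trajectory",
    "BWLabel",
    "BWMap",
    "ResidueClass",
    "parse_bw_label",
    "resolve_bw",
    "classify_residue",
    "STANDARD_AA",
    "DEFAULT_NONPOLAR_CONTACT_SET",
    "saltbridge_atoms",
    "donor_atoms",
    "acceptor_atoms",
    "hydrophobic_atoms",
    "BACKBONE_ATOMS",
]


class SwitchscanError(Exception):
    """Base class for all package errors."""


class BWParseError(SwitchscanError):
    """Malformed Ballesteros–Weinstein label text."""


class BWLookupError(SwitchscanError):
    """Label or residue absent from a BW map."""


class ClassificationError(SwitchscanError):
    """Residue code outside the standard amino-acid table."""


class MissingAtomsError(SwitchscanError):
    """A residue lacks atoms required by a distance metric."""


# ---------------------------------------------------------------------------
# Atomic containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, PDB-style.

    Positions are in Å.  ``serial`` must be unique within a
    :class:`Structure`; ``name`` follows PDB conventions ("CA", "NH1", ...).
    """

    serial: int
    name: str
    element: str
    res_seq: int
    res_name: str
    chain: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not all(np.isfinite(self.position)):
            raise ValueError(
                f"atom {self.serial} ({self.name}) has non-finite position"
            )


@dataclass(frozen=True)
class Residue:
    """A residue and the half-open atom index range it owns."""

    chain: str
    res_seq: int
    res_name: str
    atom_start: int
    atom_stop: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.res_seq)

    def __str__(self) -> str:  # e.g. "A/ARG652"
        return f"{self.chain}/{self.res_name}{self.res_seq}"


class Structure:
    """An ordered collection of atoms grouped into residues.

    Residue grouping follows file order: consecutive atoms sharing
    ``(chain, res_seq)`` form one residue.  Atom serials must be unique.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        seen: set[int] = set()
        for a in self.atoms:
            if a.serial in seen:
                raise ValueError(f"duplicate atom serial {a.serial}")
            seen.add(a.serial)
        self.residues: list[Residue] = []
        self._res_index: dict[tuple[str, int], int] = {}
        start = 0
        for i, a in enumerate(self.atoms):
            if i > 0 and (a.chain, a.res_seq) != (
                self.atoms[i - 1].chain,
                self.atoms[i - 1].res_seq,
            ):
                self._close_residue(start, i)
                start = i
        if self.atoms:
            self._close_residue(start, len(self.atoms))
        self._coords = np.array(
            [a.position for a in self.atoms], dtype=float
        ).reshape(len(self.atoms), 3)
        self._atom_lookup: dict[tuple[str, int, str], int] = {
            (a.chain, a.res_seq, a.name): i for i, a in enumerate(self.atoms)
        }

    def _close_residue(self, start: int, stop: int) -> None:
        a = self.atoms[start]
        res = Residue(a.chain, a.res_seq, a.res_name, start, stop)
        if res.key in self._res_index:
            raise ValueError(
                f"residue {res} appears in two non-contiguous blocks"
            )
        self._res_index[res.key] = len(self.residues)
        self.residues.append(res)

    # -- accessors ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Reference coordinates, shape (n_atoms, 3), Å."""
        return self._coords

    def residue(self, chain: str, res_seq: int) -> Residue:
        try:
            return self.residues[self._res_index[(chain, res_seq)]]
        except KeyError:
            raise BWLookupError(
                f"residue {chain}/{res_seq} not present in structure"
            ) from None

    def has_residue(self, chain: str, res_seq: int) -> bool:
        return (chain, res_seq) in self._res_index

    def atom_index(self, chain: str, res_seq: int, name: str) -> int:
        try:
            return self._atom_lookup[(chain, res_seq, name)]
        except KeyError:
            raise MissingAtomsError(
                f"residue {chain}/{res_seq} has no atom named {name!r}"
            ) from None

    def residue_atom_indices(
        self, res: Residue, names: Iterable[str] | None = None
    ) -> list[int]:
        """Indices of a residue's atoms, optionally restricted to names."""
        idx = range(res.atom_start, res.atom_stop)
        if names is None:
            return list(idx)
        wanted = set(names)
        return [i for i in idx if self.atoms[i].name in wanted]

    def iter_residues(self) -> Iterable[Residue]:
        return iter(self.residues)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.atoms == other.atoms

    def __repr__(self) -> str:
        return f"<Structure: {len(self.residues)} residues, {self.n_atoms} atoms>"


class Trajectory:
    """Frames × atoms × 3 coordinate array tied to a topology Structure.

    Coordinates in Å, times in ps, frames 0-indexed.
    """

    def __init__(
        self,
        structure: Structure,
        coords: np.ndarray,
        times: np.ndarray | Sequence[float],
    ):
        coords = np.asarray(coords, dtype=float)
        times = np.asarray(times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {coords.shape}")
        if coords.shape[1] != structure.n_atoms:
            raise ValueError(
                f"frame atom count {coords.shape[1]} != structure atom "
                f"count {structure.n_atoms}"
            )
        if times.shape != (coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.structure = structure
        self.coords = coords
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def slice_frames(self, start: int, stop: int | None = None) -> "Trajectory":
        return Trajectory(
            self.structure, self.coords[start:stop], self.times[start:stop]
        )

    def __repr__(self) -> str:
        return (
            f"<Trajectory: {self.n_frames} frames × "
            f"{self.structure.n_atoms} atoms>"
        )


# ---------------------------------------------------------------------------
# Ballesteros–Weinstein numbering
# ---------------------------------------------------------------------------

_BW_RE = re.compile(r"^(\d+)\.(\d+)$")


@dataclass(frozen=True, order=True)
class BWLabel:
    """Ballesteros–Weinstein position: helix 1–7, position relative to the
    helix's most conserved residue (numbered 50).  Renders as "H.P"."""

    helix: int
    position: int

    def __str__(self) -> str:
        return f"{self.helix}.{self.position}"

    render = __str__


def parse_bw_label(text: str) -> BWLabel:
    """Parse an "H.P" Ballesteros–Weinstein label, e.g. "3.50"."""
    m = _BW_RE.match(text.strip())
    if m is None:
        raise BWParseError(
            f"malformed Ballesteros–Weinstein label {text!r}: expected "
            "'<helix>.<position>' such as '3.50'"
        )
    return BWLabel(helix=int(m.group(1)), position=int(m.group(2)))


class BWMap:
    """Bidirectional (chain, res_seq) ↔ BW label mapping with helix extents."""

    def __init__(self, entries: dict[tuple[str, int], BWLabel]):
        self._fwd: dict[BWLabel, tuple[str, int]] = {}
        self._rev: dict[tuple[str, int], BWLabel] = dict(entries)
        for key, label in entries.items():
            if label in self._fwd:
                raise ValueError(
                    f"BW label {label} mapped to both {self._fwd[label]} and {key}"
                )
            self._fwd[label] = key
        self.helix_extents: dict[int, tuple[int, int]] = {}
        for (chain, seq), label in entries.items():
            lo, hi = self.helix_extents.get(label.helix, (seq, seq))
            self.helix_extents[label.helix] = (min(lo, seq), max(hi, seq))

    def __len__(self) -> int:
        return len(self._rev)

    def __contains__(self, label: BWLabel) -> bool:
        return label in self._fwd

    def resolve(self, label: BWLabel | str) -> tuple[str, int]:
        if isinstance(label, str):
            label = parse_bw_label(label)
        try:
            return self._fwd[label]
        except KeyError:
            near = sorted(
                (l for l in self._fwd if l.helix == label.helix),
                key=lambda l: abs(l.position - label.position),
            )[:3]
            hint = (
                f"; nearest mapped on helix {label.helix}: "
                + ", ".join(str(l) for l in near)
                if near
                else ""
            )
            raise BWLookupError(f"BW label {label} not in map{hint}") from None

    def label_of(self, chain: str, res_seq: int) -> BWLabel:
        try:
            return self._rev[(chain, res_seq)]
        except KeyError:
            raise BWLookupError(
                f"residue {chain}/{res_seq} has no BW label in map"
            ) from None

    def label_of_or_none(self, chain: str, res_seq: int) -> BWLabel | None:
        return self._rev.get((chain, res_seq))

    def helix_residues(self, helix: int) -> list[tuple[str, int]]:
        """Mapped residues of one helix, ordered by sequence number."""
        return sorted(
            (key for key, lab in self._rev.items() if lab.helix == helix),
            key=lambda k: (k[0], k[1]),
        )

    # -- TSV interchange: header `chain res_seq res_name bw` ---------------

    @classmethod
    def from_tsv(cls, path) -> "BWMap":
        entries: dict[tuple[str, int], BWLabel] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["chain", "res_seq", "res_name", "bw"]
            if header != expected:
                raise ValueError(
                    f"BW map header must be {expected}, got {header}"
                )
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                chain, seq, _res_name, bw = parts
                entries[(chain, int(seq))] = parse_bw_label(bw)
        return cls(entries)

    def to_tsv(self, path, structure: Structure | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tres_seq\tres_name\tbw\n")
            for (chain, seq), label in sorted(self._rev.items()):
                res_name = "UNK"
                if structure is not None and structure.has_residue(chain, seq):
                    res_name = structure.residue(chain, seq).res_name
                fh.write(f"{chain}\t{seq}\t{res_name}\t{label}\n")


def resolve_bw(bw_map: BWMap, label: BWLabel | str) -> tuple[str, int]:
    """Resolve a BW label to the (chain, res_seq) it maps to."""
    return bw_map.resolve(label)


# ---------------------------------------------------------------------------
# Residue chemistry
# ---------------------------------------------------------------------------

class ResidueClass(Enum):
    BASIC = "basic"
    ACIDIC = "acidic"
    POLAR = "polar"
    NONPOLAR = "nonpolar"
    SPECIAL = "special"


# Partition of the 20 standard residues. The hydrophobic-contact set used by
# the interaction engine is broader (see DEFAULT_NONPOLAR_CONTACT_SET) —
# aromatic TYR and the thiol CYS pack hydrophobically even though their
# chemistry is polar.
_CLASS_TABLE: dict[str, ResidueClass] = {
    "ARG": ResidueClass.BASIC,
    "LYS": ResidueClass.BASIC,
    "HIS": ResidueClass.BASIC,
    "ASP": ResidueClass.ACIDIC,
    "GLU": ResidueClass.ACIDIC,
    "SER": ResidueClass.POLAR,
    "THR": ResidueClass.POLAR,
    "ASN": ResidueClass.POLAR,
    "GLN": ResidueClass.POLAR,
    "TYR": ResidueClass.POLAR,
    "CYS": ResidueClass.POLAR,
    "ALA": ResidueClass.NONPOLAR,
    "VAL": ResidueClass.NONPOLAR,
    "LEU": ResidueClass.NONPOLAR,
    "ILE": ResidueClass.NONPOLAR,
    "MET": ResidueClass.NONPOLAR,
    "PHE": ResidueClass.NONPOLAR,
    "TRP": ResidueClass.NONPOLAR,
    "PRO": ResidueClass.NONPOLAR,
    "GLY": ResidueClass.SPECIAL,
}

STANDARD_AA = frozenset(_CLASS_TABLE)

#: Residues eligible for hydrophobic-contact detection (side-chain packing).
DEFAULT_NONPOLAR_CONTACT_SET = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR", "CYS"}
)


def classify_residue(res_name: str, strict: bool = True) -> ResidueClass:
    """Chemistry class of a standard residue.

    Unknown codes raise :class:`ClassificationError` when ``strict``;
    otherwise (hetero residues, ligands) they classify as SPECIAL.
    """
    try:
        return _CLASS_TABLE[res_name.upper()]
    except KeyError:
        if strict:
            raise ClassificationError(
                f"unknown residue code {res_name!r}; not a standard amino acid"
            ) from None
        return ResidueClass.SPECIAL


# Charged-group atoms entering salt-bridge minimum N–O distances.
_SB_BASIC_ATOMS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NH1", "NH2", "NE"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),  # only when protonated_his is enabled
}
_SB_ACIDIC_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

# Side-chain heavy-atom hydrogen-bond capability. Backbone N (donor, except
# proline) and backbone O (acceptor) are handled uniformly by callers.
_SC_DONORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "TRP": frozenset({"NE1"}),
}
_SC_ACCEPTORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


def saltbridge_atoms(res_name: str, protonated_his: bool = False) -> tuple[str, frozenset[str]]:
    """(role, atom names) of a residue's charged group for salt bridges.

    role is "basic", "acidic" or "none".  HIS participates only when
    ``protonated_his`` is set (default off at pH 7.4).
    """
    res_name = res_name.upper()
    if res_name in _SB_ACIDIC_ATOMS:
        return "acidic", _SB_ACIDIC_ATOMS[res_name]
    if res_name == "HIS" and not protonated_his:
        return "none", frozenset()
    if res_name in _SB_BASIC_ATOMS:
        return "basic", _SB_BASIC_ATOMS[res_name]
    return "none", frozenset()


def donor_atoms(res_name: str) -> frozenset[str]:
    """Heavy donor atoms of a residue: backbone N (except PRO) + side chain."""
    res_name = res_name.upper()
    side = _SC_DONORS.get(res_name, frozenset())
    if res_name == "PRO":
        return side
    return side | {"N"}


def acceptor_atoms(res_name: str) -> frozenset[str]:
    """Heavy acceptor atoms: backbone O + side-chain acceptors."""
    return _SC_ACCEPTORS.get(res_name.upper(), frozenset()) | {"O"}


def hydrophobic_atoms(structure: Structure, res: Residue) -> list[int]:
    """Indices of a residue's side-chain carbon/sulfur atoms (Cβ and beyond).

    Backbone atoms are excluded: the contacts of interest are side-chain
    packing, not chain proximity.
    """
    out = []
    for i in range(res.atom_start, res.atom_stop):
        a = structure.atoms[i]
        if a.name in BACKBONE_ATOMS:
            continue
        if a.element.upper() in ("C", "S"):
            out.append(i)
    return out
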