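"""Geometric interaction detection and occupancy statistics.

Detectors work on single frames; occupancy functions aggregate them over a
trajectory after discarding an equilibration burn-in (default: the first
10% of frames, mirroring the convention of analysing the tail of an MD run
once the system has relaxed).

Criteria (all configurable through :class:`InteractionCriterion`):

* **salt bridge** — minimum distance between basic side-chain nitrogens
  (Arg NH1/NH2/NE, Lys NZ, optionally protonated His) and acidic
  side-chain oxygens (Asp OD1/OD2, Glu OE1/OE2) ≤ 4.0 Å.
* **hydrogen bond** — donor–acceptor heavy-atom distance ≤ 3.5 Å and, when
  hydrogens are present, donor–H–acceptor angle ≥ 135°.
* **hydrophobic contact** — two nonpolar residues whose side-chain
  carbon/sulfur atoms come within 5.0 Å.
* **ligand contact** — any residue heavy atom within 4.0 Å of any ligand
  heavy atom.

Sequence-adjacent residue pairs (|Δres_seq| ≤ 1 on the same chain) are
excluded from network scans: they are trivially always in contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core import (
    DEFAULT_NONPOLAR_CONTACT_SET,
    MissingAtomsError,
    Residue,
    Structure,
    SwitchscanError,
    Trajectory,
    acceptor_atoms,
    donor_atoms,
    hydrophobic_atoms,
    saltbridge_atoms,
)

__all__ = [
    "InteractionCriterion",
    "DistanceSeries",
    "OccupancyMatrix",
    "pair_distance_series",
    "occupancy_from_distances",
    "lock_state_series",
    "detect_saltbridges",
    "detect_hbonds",
    "detect_hydrophobic",
    "ligand_contact_fraction",
    "occupancy_matrix",
    "resolve_burn_in",
]

ResKey = tuple[str, int]


@dataclass(frozen=True)
class InteractionCriterion:
    """Geometric definition of one interaction kind."""

    kind: str  # saltbridge | hbond | hydrophobic | ligand_contact
    distance_cutoff: float
    angle_cutoff: float | None = None  # degrees, hbond only
    protonated_his: bool = False
    nonpolar_set: frozenset[str] = DEFAULT_NONPOLAR_CONTACT_SET
    hydrophobic_all_heavy: bool = False
    exclude_adjacent: bool = True

    def __post_init__(self):
        if self.kind not in ("saltbridge", "hbond", "hydrophobic", "ligand_contact"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")

    @classmethod
    def default(cls, kind: str) -> "InteractionCriterion":
        cutoffs = {
            "saltbridge": 4.0,
            "hbond": 3.5,
            "hydrophobic": 5.0,
            "ligand_contact": 4.0,
        }
        angle = 135.0 if kind == "hbond" else None
        return cls(kind=kind, distance_cutoff=cutoffs[kind], angle_cutoff=angle)


@dataclass
class DistanceSeries:
    """Per-frame distance between one residue pair under a named metric."""

    pair: tuple[ResKey, ResKey, str]
    values: np.ndarray  # Å, one per analysed frame
    times: np.ndarray  # ps

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must align")
        if self.values.size and self.values.min() < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class OccupancyMatrix:
    """Fraction of analysed frames each residue pair interacts, one condition."""

    condition: str
    pairs: list[tuple[ResKey, ResKey]]
    occupancy: np.ndarray
    n_frames: int
    criterion: InteractionCriterion

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (len(self.pairs),):
            raise ValueError("one occupancy per pair required")
        if self.occupancy.size and not (
            (self.occupancy >= 0).all() and (self.occupancy <= 1).all()
        ):
            raise ValueError("occupancies must lie in [0, 1]")

    def as_dict(self) -> dict[tuple[ResKey, ResKey], float]:
        """Occupancy keyed by order-normalised pair."""
        return {
            _norm_pair(a, b): float(occ)
            for (a, b), occ in zip(self.pairs, self.occupancy)
        }


def _norm_pair(a: ResKey, b: ResKey) -> tuple[ResKey, ResKey]:
    return (a, b) if a <= b else (b, a)


def resolve_burn_in(n_frames: int, burn_in: float | int) -> int:
    """Number of leading frames to discard.

    A float in [0, 1) is a fraction of the trajectory; an int is a frame
    count.  At least one frame must survive.
    """
    if isinstance(burn_in, float) and 0 <= burn_in < 1:
        skip = int(round(burn_in * n_frames))
    elif isinstance(burn_in, (int, np.integer)) and burn_in >= 0:
        skip = int(burn_in)
    else:
        raise SwitchscanError(
            f"burn_in must be a fraction in [0,1) or a frame count, got {burn_in!r}"
        )
    if skip >= n_frames:
        raise SwitchscanError(
            f"burn-in of {skip} frames leaves no frames out of {n_frames}"
        )
    return skip


# ---------------------------------------------------------------------------
# Metric atom selection
# ---------------------------------------------------------------------------

def _metric_atoms(
    structure: Structure,
    resA: Residue,
    resB: Residue,
    metric: str,
    criterion: InteractionCriterion | None = None,
) -> tuple[list[int], list[int]]:
    """Atom index sets entering a min-distance metric for a residue pair.

    Metrics: ``saltbridge``, ``heavy``, ``hydrophobic``, ``ca``, or an
    explicit ``atoms:NAME1-NAME2`` pair.
    """
    if metric == "saltbridge":
        protonated = criterion.protonated_his if criterion else False
        roleA, atomsA = saltbridge_atoms(resA.res_name, protonated)
        roleB, atomsB = saltbridge_atoms(resB.res_name, protonated)
        if {roleA, roleB} != {"basic", "acidic"}:
            raise MissingAtomsError(
                f"salt-bridge metric needs one basic and one acidic residue, "
                f"got {resA} ({roleA}) and {resB} ({roleB})"
            )
        idxA = structure.residue_atom_indices(resA, atomsA)
        idxB = structure.residue_atom_indices(resB, atomsB)
        _require(idxA, resA, atomsA)
        _require(idxB, resB, atomsB)
        return idxA, idxB
    if metric == "heavy":
        idxA = [i for i in structure.residue_atom_indices(resA)
                if structure.atoms[i].element.upper() != "H"]
        idxB = [i for i in structure.residue_atom_indices(resB)
                if structure.atoms[i].element.upper() != "H"]
        return idxA, idxB
    if metric == "hydrophobic":
        idxA = hydrophobic_atoms(structure, resA)
        idxB = hydrophobic_atoms(structure, resB)
        _require(idxA, resA, {"side-chain C/S"})
        _require(idxB, resB, {"side-chain C/S"})
        return idxA, idxB
    if metric == "ca":
        return (
            [structure.atom_index(resA.chain, resA.res_seq, "CA")],
            [structure.atom_index(resB.chain, resB.res_seq, "CA")],
        )
    if metric.startswith("atoms:"):
        try:
            nameA, nameB = metric[len("atoms:"):].split("-")
        except ValueError:
            raise ValueError(
                f"explicit atom metric must look like 'atoms:CZ-CD', got {metric!r}"
            ) from None
        return (
            [structure.atom_index(resA.chain, resA.res_seq, nameA)],
            [structure.atom_index(resB.chain, resB.res_seq, nameB)],
        )
    raise ValueError(f"unknown distance metric {metric!r}")


def _require(indices: list[int], res: Residue, wanted: Iterable[str]) -> None:
    if not indices:
        raise MissingAtomsError(
            f"residue {res} lacks atoms required by metric: {sorted(wanted)}"
        )


def _min_dist_over_frames(coords: np.ndarray, idxA, idxB) -> np.ndarray:
    """Minimum pairwise distance per frame between two atom index sets."""
    A = coords[:, idxA]  # (F, a, 3)
    B = coords[:, idxB]  # (F, b, 3)
    diff = A[:, :, None, :] - B[:, None, :, :]
    d = np.sqrt((diff * diff).sum(axis=-1))
    return d.reshape(d.shape[0], -1).min(axis=1)


# ---------------------------------------------------------------------------
# Distance series and occupancy
# ---------------------------------------------------------------------------

def pair_distance_series(
    traj: Trajectory,
    resA: ResKey,
    resB: ResKey,
    metric: str = "saltbridge",
    burn_in: float | int = 0,
    criterion: InteractionCriterion | None = None,
) -> DistanceSeries:
    """Per-frame minimum distance between two residues under a metric.

    ``resA``/``resB`` are (chain, res_seq) keys.  The series is the
    exhaustive minimum over the metric's atom-pair set in every frame.
    """
    s = traj.structure
    rA, rB = s.residue(*resA), s.residue(*resB)
    idxA, idxB = _metric_atoms(s, rA, rB, metric, criterion)
    skip = resolve_burn_in(traj.n_frames, burn_in)
    values = _min_dist_over_frames(traj.coords[skip:], idxA, idxB)
    return DistanceSeries(
        pair=(resA, resB, metric), values=values, times=traj.times[skip:]
    )


def occupancy_from_distances(series: DistanceSeries, cutoff: float) -> float:
    """Fraction of frames with distance ≤ cutoff (exact count / n)."""
    n = series.values.size
    if n == 0:
        raise SwitchscanError("cannot compute occupancy of an empty distance series")
    return float(np.count_nonzero(series.values <= cutoff)) / n


def lock_state_series(
    series: DistanceSeries,
    cutoff: float = 4.5,
    hysteresis: int = 10,
) -> np.ndarray:
    """Formed/broken state labels for an ionic-lock-style distance series.

    The state flips only after ``hysteresis`` consecutive frames on the
    other side of the cutoff, suppressing chattering near the boundary.
    Returns a boolean array (True = formed).
    """
    below = series.values <= cutoff
    if below.size == 0:
        return np.zeros(0, dtype=bool)
    state = bool(below[0])
    run = 0
    out = np.empty(below.size, dtype=bool)
    for i, b in enumerate(below):
        if b != state:
            run += 1
            if run >= hysteresis:
                state = bool(b)
                run = 0
        else:
            run = 0
        out[i] = state
    return out


# ---------------------------------------------------------------------------
# Frame-level detectors
# ---------------------------------------------------------------------------

def _adjacent(resA: Residue, resB: Residue) -> bool:
    return resA.chain == resB.chain and abs(resA.res_seq - resB.res_seq) <= 1


def detect_saltbridges(
    frame: np.ndarray,
    structure: Structure,
    criterion: InteractionCriterion | None = None,
) -> set[tuple[ResKey, ResKey]]:
    """All basic–acidic residue pairs within the salt-bridge cutoff in one frame."""
    crit = criterion or InteractionCriterion.default("saltbridge")
    basic, acidic = [], []
    for res in structure.iter_residues():
        role, atoms = saltbridge_atoms(res.res_name, crit.protonated_his)
        idx = structure.residue_atom_indices(res, atoms)
        if role == "basic" and idx:
            basic.append((res, idx))
        elif role == "acidic" and idx:
            acidic.append((res, idx))
    out: set[tuple[ResKey, ResKey]] = set()
    for rA, idxA in basic:
        for rB, idxB in acidic:
            if crit.exclude_adjacent and _adjacent(rA, rB):
                continue
            d = np.linalg.norm(
                frame[idxA][:, None, :] - frame[idxB][None, :, :], axis=-1
            ).min()
            if d <= crit.distance_cutoff:
                out.add(_norm_pair(rA.key, rB.key))
    return out


def _attached_hydrogens(structure: Structure, res: Residue, donor_idx: int) -> list[int]:
    """Hydrogens covalently attached to a donor heavy atom (≤ 1.25 Å in the
    topology reference coordinates)."""
    out = []
    dpos = structure.coords[donor_idx]
    for i in range(res.atom_start, res.atom_stop):
        a = structure.atoms[i]
        if a.element.upper() != "H":
            continue
        if np.linalg.norm(structure.coords[i] - dpos) <= 1.25:
            out.append(i)
    return out


def _structure_has_hydrogens(structure: Structure) -> bool:
    return any(a.element.upper() == "H" for a in structure.atoms)


def detect_hbonds(
    frame: np.ndarray,
    structure: Structure,
    criterion: InteractionCriterion | None = None,
) -> set[tuple[tuple[ResKey, str], tuple[ResKey, str]]]:
    """Hydrogen bonds in one frame as (donor residue+atom, acceptor residue+atom).

    Donor–acceptor heavy-atom distance ≤ cutoff; when the structure carries
    hydrogens, additionally requires some donor-attached H with
    donor–H–acceptor angle ≥ the angle cutoff.  Intra-residue pairs and
    backbone–backbone bonds of sequence neighbours are excluded.
    """
    crit = criterion or InteractionCriterion.default("hbond")
    use_angle = crit.angle_cutoff is not None and _structure_has_hydrogens(structure)
    residues = list(structure.iter_residues())
    donors: list[tuple[Residue, int, list[int]]] = []
    acceptors: list[tuple[Residue, int]] = []
    for res in residues:
        for name in donor_atoms(res.res_name):
            for i in structure.residue_atom_indices(res, {name}):
                hs = _attached_hydrogens(structure, res, i) if use_angle else []
                donors.append((res, i, hs))
        for name in acceptor_atoms(res.res_name):
            for i in structure.residue_atom_indices(res, {name}):
                acceptors.append((res, i))
    out: set[tuple[tuple[ResKey, str], tuple[ResKey, str]]] = set()
    for dres, di, hs in donors:
        for ares, ai in acceptors:
            if dres.key == ares.key:
                continue
            dname = structure.atoms[di].name
            aname = structure.atoms[ai].name
            if (
                crit.exclude_adjacent
                and _adjacent(dres, ares)
                and dname == "N"
                and aname in ("O", "OXT")
            ):
                continue
            if np.linalg.norm(frame[di] - frame[ai]) > crit.distance_cutoff:
                continue
            if use_angle and hs:
                ok = False
                for hi in hs:
                    v1 = frame[di] - frame[hi]
                    v2 = frame[ai] - frame[hi]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if ang >= crit.angle_cutoff:
                        ok = True
                        break
                if not ok:
                    continue
            out.add(((dres.key, dname), (ares.key, aname)))
    return out


def detect_hydrophobic(
    frame: np.ndarray,
    structure: Structure,
    criterion: InteractionCriterion | None = None,
) -> set[tuple[ResKey, ResKey]]:
    """Nonpolar residue pairs whose side-chain C/S atoms come within cutoff."""
    crit = criterion or InteractionCriterion.default("hydrophobic")
    eligible = []
    for res in structure.iter_residues():
        if res.res_name not in crit.nonpolar_set:
            continue
        if crit.hydrophobic_all_heavy:
            idx = [i for i in structure.residue_atom_indices(res)
                   if structure.atoms[i].element.upper() != "H"]
        else:
            idx = hydrophobic_atoms(structure, res)
        if idx:
            eligible.append((res, idx))
    out: set[tuple[ResKey, ResKey]] = set()
    for k, (rA, idxA) in enumerate(eligible):
        for rB, idxB in eligible[k + 1:]:
            if crit.exclude_adjacent and _adjacent(rA, rB):
                continue
            d = np.linalg.norm(
                frame[idxA][:, None, :] - frame[idxB][None, :, :], axis=-1
            ).min()
            if d <= crit.distance_cutoff:
                out.add(_norm_pair(rA.key, rB.key))
    return out


# ---------------------------------------------------------------------------
# Trajectory-level statistics
# ---------------------------------------------------------------------------

def ligand_contact_fraction(
    traj: Trajectory,
    ligand: ResKey,
    residue: ResKey,
    cutoff: float = 4.0,
    burn_in: float | int = 0,
) -> float:
    """Fraction of frames a residue's heavy atoms touch the ligand's.

    The ligand is addressed as a hetero residue (chain, res_seq).
    """
    s = traj.structure
    if not s.has_residue(*ligand):
        raise SwitchscanError(f"ligand residue {ligand} absent from structure")
    lig = s.residue(*ligand)
    res = s.residue(*residue)
    lig_idx = [i for i in s.residue_atom_indices(lig)
               if s.atoms[i].element.upper() != "H"]
    res_idx = [i for i in s.residue_atom_indices(res)
               if s.atoms[i].element.upper() != "H"]
    skip = resolve_burn_in(traj.n_frames, burn_in)
    d = _min_dist_over_frames(traj.coords[skip:], res_idx, lig_idx)
    return float(np.count_nonzero(d <= cutoff)) / d.size


def _pair_interacting_series(
    traj: Trajectory,
    pair: tuple[ResKey, ResKey],
    criterion: InteractionCriterion,
    skip: int,
) -> np.ndarray:
    """Boolean per-frame interaction series for one residue pair."""
    s = traj.structure
    rA, rB = s.residue(*pair[0]), s.residue(*pair[1])
    coords = traj.coords[skip:]
    if criterion.kind == "saltbridge":
        idxA, idxB = _metric_atoms(s, rA, rB, "saltbridge", criterion)
        return _min_dist_over_frames(coords, idxA, idxB) <= criterion.distance_cutoff
    if criterion.kind == "hydrophobic":
        if criterion.hydrophobic_all_heavy:
            idxA = [i for i in s.residue_atom_indices(rA)
                    if s.atoms[i].element.upper() != "H"]
            idxB = [i for i in s.residue_atom_indices(rB)
                    if s.atoms[i].element.upper() != "H"]
        else:
            idxA = hydrophobic_atoms(s, rA)
            idxB = hydrophobic_atoms(s, rB)
        _require(idxA, rA, {"side-chain C/S"})
        _require(idxB, rB, {"side-chain C/S"})
        return _min_dist_over_frames(coords, idxA, idxB) <= criterion.distance_cutoff
    if criterion.kind == "hbond":
        return _hbond_pair_series(traj, rA, rB, criterion, skip)
    raise ValueError(f"occupancy not defined for kind {criterion.kind!r}")


def _hbond_pair_series(
    traj: Trajectory, rA: Residue, rB: Residue,
    criterion: InteractionCriterion, skip: int,
) -> np.ndarray:
    s = traj.structure
    use_angle = criterion.angle_cutoff is not None and _structure_has_hydrogens(s)
    coords = traj.coords[skip:]
    n = coords.shape[0]
    hit = np.zeros(n, dtype=bool)
    for dres, ares in ((rA, rB), (rB, rA)):
        dnames = donor_atoms(dres.res_name)
        anames = acceptor_atoms(ares.res_name)
        for di in s.residue_atom_indices(dres, dnames):
            hs = _attached_hydrogens(s, dres, di) if use_angle else []
            for ai in s.residue_atom_indices(ares, anames):
                d = np.linalg.norm(coords[:, di] - coords[:, ai], axis=-1)
                ok = d <= criterion.distance_cutoff
                if use_angle and hs:
                    ang_ok = np.zeros(n, dtype=bool)
                    for hi in hs:
                        v1 = coords[:, di] - coords[:, hi]
                        v2 = coords[:, ai] - coords[:, hi]
                        cosang = (v1 * v2).sum(axis=-1) / (
                            np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
                        )
                        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                        ang_ok |= ang >= criterion.angle_cutoff
                    ok &= ang_ok
                hit |= ok
    return hit


def scan_contacts(
    traj: Trajectory,
    criterion: InteractionCriterion,
    burn_in: float | int = 0.1,
    condition: str = "",
    chunk_frames: int = 100,
) -> OccupancyMatrix:
    """Occupancy of *every* candidate residue pair for a network kind.

    Vectorised whole-network version of :func:`occupancy_matrix` for the
    hbond and hydrophobic kinds: enumerates all candidate donor–acceptor
    (or nonpolar side-chain) atom pairs once, then streams frames in
    chunks.  Exact — no spatial pruning; a residue pair counts as
    interacting in a frame when any of its candidate atom pairs satisfies
    the criterion.  Pairs with zero occupancy are included, so condition
    differencing sees the full universe.
    """
    s = traj.structure
    use_angle = (
        criterion.kind == "hbond"
        and criterion.angle_cutoff is not None
        and _structure_has_hydrogens(s)
    )
    cand_i: list[int] = []
    cand_j: list[int] = []
    cand_h: list[list[int]] = []
    group_of: list[int] = []
    groups: dict[tuple[ResKey, ResKey], int] = {}

    def _group(a: Residue, b: Residue) -> int:
        key = _norm_pair(a.key, b.key)
        if key not in groups:
            groups[key] = len(groups)
        return groups[key]

    residues = list(s.iter_residues())
    if criterion.kind == "hbond":
        donors, acceptors = [], []
        for res in residues:
            for name in donor_atoms(res.res_name):
                for i in s.residue_atom_indices(res, {name}):
                    hs = _attached_hydrogens(s, res, i) if use_angle else []
                    donors.append((res, i, hs))
            for name in acceptor_atoms(res.res_name):
                for i in s.residue_atom_indices(res, {name}):
                    acceptors.append((res, i))
        for dres, di, hs in donors:
            for ares, ai in acceptors:
                if dres.key == ares.key:
                    continue
                if (
                    criterion.exclude_adjacent
                    and _adjacent(dres, ares)
                    and s.atoms[di].name == "N"
                    and s.atoms[ai].name in ("O", "OXT")
                ):
                    continue
                cand_i.append(di)
                cand_j.append(ai)
                cand_h.append(hs)
                group_of.append(_group(dres, ares))
    elif criterion.kind == "hydrophobic":
        eligible = []
        for res in residues:
            if res.res_name not in criterion.nonpolar_set:
                continue
            if criterion.hydrophobic_all_heavy:
                idx = [i for i in s.residue_atom_indices(res)
                       if s.atoms[i].element.upper() != "H"]
            else:
                idx = hydrophobic_atoms(s, res)
            if idx:
                eligible.append((res, idx))
        for k, (rA, idxA) in enumerate(eligible):
            for rB, idxB in eligible[k + 1:]:
                if criterion.exclude_adjacent and _adjacent(rA, rB):
                    continue
                g = _group(rA, rB)
                for i in idxA:
                    for j in idxB:
                        cand_i.append(i)
                        cand_j.append(j)
                        cand_h.append([])
                        group_of.append(g)
    else:
        raise ValueError(
            f"scan_contacts handles hbond/hydrophobic, not {criterion.kind!r}"
        )

    skip = resolve_burn_in(traj.n_frames, burn_in)
    coords = traj.coords[skip:]
    n_frames = coords.shape[0]
    n_groups = len(groups)
    if not cand_i:
        return OccupancyMatrix(condition, [], np.zeros(0), n_frames, criterion)

    order = np.argsort(np.asarray(group_of), kind="stable")
    ci = np.asarray(cand_i)[order]
    cj = np.asarray(cand_j)[order]
    ch = [cand_h[k] for k in order]
    gids = np.asarray(group_of)[order]
    starts = np.searchsorted(gids, np.arange(n_groups))

    counts = np.zeros(n_groups, dtype=float)
    for f0 in range(0, n_frames, chunk_frames):
        chunk = coords[f0:f0 + chunk_frames]
        diff = chunk[:, ci] - chunk[:, cj]
        hit = np.sqrt((diff * diff).sum(axis=-1)) <= criterion.distance_cutoff
        if use_angle:
            for k, hs in enumerate(ch):
                if not hs:
                    continue
                col = hit[:, k]
                if not col.any():
                    continue
                ok = np.zeros(chunk.shape[0], dtype=bool)
                for hi in hs:
                    v1 = chunk[:, ci[k]] - chunk[:, hi]
                    v2 = chunk[:, cj[k]] - chunk[:, hi]
                    cosang = (v1 * v2).sum(axis=-1) / (
                        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
                    )
                    ok |= np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= criterion.angle_cutoff
                hit[:, k] = col & ok
        group_hit = np.maximum.reduceat(hit.astype(np.uint8), starts, axis=1)
        counts += group_hit.sum(axis=0)

    pair_list = [None] * n_groups
    for pair, g in groups.items():
        pair_list[g] = pair
    return OccupancyMatrix(
        condition=condition,
        pairs=pair_list,
        occupancy=counts / n_frames,
        n_frames=n_frames,
        criterion=criterion,
    )


def occupancy_matrix(
    traj: Trajectory,
    pairs: Sequence[tuple[ResKey, ResKey]],
    criterion: InteractionCriterion,
    burn_in: float | int = 0.1,
    condition: str = "",
) -> OccupancyMatrix:
    """Per-pair interaction occupancy over the post-burn-in trajectory."""
    skip = resolve_burn_in(traj.n_frames, burn_in)
    occ = np.array([
        _pair_interacting_series(traj, pair, criterion, skip).mean()
        for pair in pairs
    ]) if pairs else np.zeros(0)
    return OccupancyMatrix(
        condition=condition,
        pairs=list(pairs),
        occupancy=occ,
        n_frames=traj.n_frames - skip,
        criterion=criterion,
    )
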