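"""Conformational analysis: superposition, PCA, dihedrals, secondary structure.

The activation signal this package looks for is conformational as well as
chemical: an agonist-bound ensemble occupies a different region of
collective-coordinate space than an antagonist-bound one, helices shift,
backbone dihedrals redistribute, and helical segments interconvert between
α (i→i+4 hydrogen bonding) and π (i→i+5) geometry.

Everything here is frame-based and exact:

* :func:`superpose` — Kabsch least-squares rigid-body fit (SVD).
* :func:`ca_pca` — positional covariance of superposed Cα coordinates over
  one or more labelled trajectories, pooled (combined-covariance) by
  default, eigendecomposed in descending order.
* :func:`phi_psi` — backbone dihedrals in the IUPAC sign convention with
  circular (vector-mean) statistics, since angle distributions near ±180°
  make arithmetic means meaningless.
* :func:`assign_ss` — Kabsch–Sander hydrogen-bond energies
  (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
  E < −0.5) with helix assignment from turn patterns.  π runs take
  priority over α so that π segments are not masked by overlapping α
  patterns (the behaviour of modern DSSP); classic α-priority is an
  option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    MissingAtomsError,
    Residue,
    Structure,
    SwitchscanError,
    Trajectory,
)
from .interactions import resolve_burn_in

__all__ = [
    "Superposition",
    "PCAResult",
    "DihedralStats",
    "SSAssignment",
    "superpose",
    "rmsd_series",
    "radius_of_gyration",
    "ca_pca",
    "ev_displacements",
    "dihedral",
    "phi_psi",
    "circular_mean_deg",
    "circular_variance",
    "assign_ss",
    "ss_fractions",
    "kabsch_sander_energy",
]

ResKey = tuple[str, int]


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    """Optimal rotation/translation mapping mobile onto reference.

    ``apply(x) = x @ rotation.T + translation``; det(rotation) = +1.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
) -> Superposition:
    """Kabsch least-squares superposition of mobile onto reference.

    The fit is computed on ``selection`` (all atoms when None); the
    returned transform applies to full coordinate arrays.  Degenerate
    (collinear or coincident) selections are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise SwitchscanError("superposition needs at least 3 selected atoms")
    P = mobile[sel]
    Q = reference[sel]
    if P.shape != Q.shape:
        raise SwitchscanError("selection sizes differ between mobile and reference")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear points leave the rotation about the line undetermined
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise SwitchscanError("degenerate (collinear) selection for superposition")
    C = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R_row = U @ D @ Vt  # row-vector convention: Pc @ R_row ≈ Qc
    rotation = R_row.T
    translation = Q.mean(axis=0) - P.mean(axis=0) @ R_row
    moved = Pc @ R_row
    rmsd = float(np.sqrt(((moved - Qc) ** 2).sum() / len(sel)))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame post-superposition RMSD (Å) against a reference frame.

    Defaults: reference = topology coordinates, selection = all atoms.
    """
    ref = traj.structure.coords if reference is None else np.asarray(reference)
    return np.array([
        superpose(traj.coords[f], ref, selection).rmsd
        for f in range(traj.n_frames)
    ])


def radius_of_gyration(
    frame: np.ndarray,
    selection: Sequence[int] | None = None,
    masses: Sequence[float] | None = None,
) -> float:
    """Radius of gyration (Å) of selected atoms.

    Mass-unweighted by default; pass per-selected-atom masses to weight.
    """
    frame = np.asarray(frame, dtype=float)
    if selection is not None and len(selection) == 0:
        raise SwitchscanError("radius of gyration of an empty selection")
    x = frame if selection is None else frame[np.asarray(selection)]
    if x.size == 0:
        raise SwitchscanError("radius of gyration of an empty selection")
    if masses is None:
        w = np.ones(len(x))
    else:
        w = np.asarray(masses, dtype=float)
    center = (x * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((x - center) ** 2).sum(axis=1)).sum() / w.sum()))


# ---------------------------------------------------------------------------
# Cα principal component analysis
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigendecomposition of the positional covariance of superposed
    selection coordinates, with per-frame projections and condition labels."""

    selection: np.ndarray  # atom indices into the topology
    mean_coords: np.ndarray  # (3N,) Å
    eigenvalues: np.ndarray  # descending, Å²
    eigenvectors: np.ndarray  # (3N, 3N), columns orthonormal
    projections: np.ndarray  # (frames, 3N)
    frame_labels: list[str]
    frame_times: np.ndarray


def ca_pca(
    trajs: Sequence[tuple[str, Trajectory]],
    selection: Sequence[int],
    burn_in: float | int = 0,
) -> PCAResult:
    """PCA of pooled selection coordinates over labelled trajectories.

    Frames of all conditions are stacked (pooled covariance), superposed
    in two passes — align to the first frame, compute the mean, re-align
    to the mean — and the covariance of the flattened 3N coordinates is
    eigendecomposed in descending eigenvalue order.
    """
    sel = np.asarray(selection, dtype=int)
    frames, labels, times = [], [], []
    for label, traj in trajs:
        skip = resolve_burn_in(traj.n_frames, burn_in)
        for f in range(skip, traj.n_frames):
            frames.append(traj.coords[f, sel])
            labels.append(label)
            times.append(traj.times[f])
    if len(frames) < 2:
        raise SwitchscanError("PCA needs at least 2 frames")
    X = np.stack(frames)  # (F, N, 3)

    def _align_all(target: np.ndarray) -> np.ndarray:
        return np.stack([superpose(x, target).apply(x) for x in X])

    aligned = _align_all(X[0])
    mean = aligned.mean(axis=0)
    aligned = _align_all(mean)
    mean = aligned.mean(axis=0)

    flat = aligned.reshape(len(aligned), -1)
    mu = mean.reshape(-1)
    centered = flat - mu
    cov = centered.T @ centered / len(flat)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = centered @ evecs
    return PCAResult(
        selection=sel,
        mean_coords=mu,
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=projections,
        frame_labels=labels,
        frame_times=np.asarray(times),
    )


def ev_displacements(pca: PCAResult, component: int = 0) -> np.ndarray:
    """Per-selected-atom displacement magnitude (Å) of one eigenvector.

    The Euclidean norm of each atom's 3-vector block of the component,
    scaled by sqrt(eigenvalue) so the magnitudes carry the mode's actual
    amplitude.  ``component`` is 0-based (0 = EV1).
    """
    if not 0 <= component < len(pca.eigenvalues):
        raise SwitchscanError(
            f"component {component} out of range (have {len(pca.eigenvalues)})"
        )
    v = pca.eigenvectors[:, component].reshape(-1, 3)
    return np.linalg.norm(v, axis=1) * np.sqrt(pca.eigenvalues[component])


# ---------------------------------------------------------------------------
# Backbone dihedrals and circular statistics
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention,
    range [−180°, 180°)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(-y, x))
    return -180.0 if ang >= 180.0 else float(ang)


def _dihedral_series(coords: np.ndarray, i0, i1, i2, i3) -> np.ndarray:
    """Vectorised dihedral over frames for four atom indices."""
    b1 = coords[:, i1] - coords[:, i0]
    b2 = coords[:, i2] - coords[:, i1]
    b3 = coords[:, i3] - coords[:, i2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = (n1 * n2).sum(axis=1)
    y = (m1 * n2).sum(axis=1)
    ang = np.degrees(np.arctan2(-y, x))
    ang[ang >= 180.0] = -180.0
    return ang


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean via vector averaging, in [−180°, 180°)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    mean = np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean()))
    return -180.0 if mean >= 180.0 else float(mean)


def circular_variance(angles_deg: np.ndarray) -> float:
    """Circular variance 1 − R, in [0, 1]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    R = np.hypot(np.sin(a).mean(), np.cos(a).mean())
    return float(1.0 - R)


@dataclass
class DihedralStats:
    """Per-frame phi or psi values of one residue with circular summaries."""

    residue: ResKey
    kind: str  # "phi" | "psi"
    values: np.ndarray  # degrees, [−180, 180)
    circ_mean: float
    circ_var: float


def _chain_neighbors(structure: Structure) -> dict[ResKey, tuple[Residue | None, Residue | None]]:
    """Previous/next residue along each chain (by file order + res_seq ± 1)."""
    out: dict[ResKey, tuple[Residue | None, Residue | None]] = {}
    residues = structure.residues
    for i, res in enumerate(residues):
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i < len(residues) - 1 else None
        if prev_res is not None and (
            prev_res.chain != res.chain or prev_res.res_seq != res.res_seq - 1
        ):
            prev_res = None
        if next_res is not None and (
            next_res.chain != res.chain or next_res.res_seq != res.res_seq + 1
        ):
            next_res = None
        out[res.key] = (prev_res, next_res)
    return out


def phi_psi(
    traj: Trajectory,
    residues: Sequence[ResKey],
    burn_in: float | int = 0,
) -> list[DihedralStats]:
    """Backbone phi/psi series with circular statistics for given residues.

    phi(i) = C(i−1)–N(i)–Cα(i)–C(i); psi(i) = N(i)–Cα(i)–C(i)–N(i+1).
    Chain-terminal residues (no neighbour on the needed side) are
    rejected by name.
    """
    s = traj.structure
    neighbors = _chain_neighbors(s)
    skip = resolve_burn_in(traj.n_frames, burn_in)
    coords = traj.coords[skip:]
    out: list[DihedralStats] = []
    for key in residues:
        res = s.residue(*key)
        prev_res, next_res = neighbors[res.key]
        if prev_res is None or next_res is None:
            raise SwitchscanError(
                f"residue {res} is chain-terminal; phi/psi undefined"
            )
        idx = {
            name: s.atom_index(res.chain, res.res_seq, name)
            for name in ("N", "CA", "C")
        }
        c_prev = s.atom_index(prev_res.chain, prev_res.res_seq, "C")
        n_next = s.atom_index(next_res.chain, next_res.res_seq, "N")
        phi = _dihedral_series(coords, c_prev, idx["N"], idx["CA"], idx["C"])
        psi = _dihedral_series(coords, idx["N"], idx["CA"], idx["C"], n_next)
        for kind, vals in (("phi", phi), ("psi", psi)):
            out.append(DihedralStats(
                residue=key, kind=kind, values=vals,
                circ_mean=circular_mean_deg(vals),
                circ_var=circular_variance(vals),
            ))
    return out


# ---------------------------------------------------------------------------
# Kabsch–Sander secondary structure
# ---------------------------------------------------------------------------

_KS_Q1Q2_F = 0.084 * 332.0  # (partial charges 0.42·0.20) × electrostatic factor
_KS_CUTOFF = -0.5  # kcal/mol
_NH_BOND = 1.01  # Å, amide H reconstruction distance


def kabsch_sander_energy(c, o, n, h) -> float:
    """Kabsch–Sander electrostatic H-bond energy (kcal/mol) for one
    carbonyl (C, O) / amide (N, H) pair."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    return float(_KS_Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn))


@dataclass
class SSAssignment:
    """Per-residue secondary-structure labels for one frame.

    Labels: H (α-helix), I (π-helix), G (3₁₀-helix), C (coil/other).
    """

    residues: list[ResKey]
    labels: list[str]

    def as_dict(self) -> dict[ResKey, str]:
        return dict(zip(self.residues, self.labels))


def _backbone_indices(structure: Structure) -> list[dict]:
    """Backbone atom indices per residue, chain-contiguous, with errors
    naming residues that lack N/CA/C/O."""
    out = []
    for res in structure.iter_residues():
        if res.res_name in ("HOH", "LIG"):
            continue
        entry = {"res": res}
        try:
            for name in ("N", "CA", "C", "O"):
                entry[name] = structure.atom_index(res.chain, res.res_seq, name)
        except MissingAtomsError:
            missing = [
                n for n in ("N", "CA", "C", "O")
                if not structure.residue_atom_indices(res, {n})
            ]
            raise MissingAtomsError(
                f"residue {res} lacks backbone atoms {missing} required for "
                "secondary-structure assignment"
            ) from None
        h_idx = structure.residue_atom_indices(res, {"H", "HN"})
        entry["H"] = h_idx[0] if h_idx else None
        out.append(entry)
    return out


def _amide_h(frame: np.ndarray, n_pos, ca_pos, c_prev_pos) -> np.ndarray:
    """Reconstruct the amide H: 1.01 Å from N, opposite the bisector of
    C(i−1)–N–Cα, in the peptide plane."""
    u1 = c_prev_pos - n_pos
    u1 /= np.linalg.norm(u1)
    u2 = ca_pos - n_pos
    u2 /= np.linalg.norm(u2)
    d = -(u1 + u2)
    d /= np.linalg.norm(d)
    return n_pos + _NH_BOND * d


def assign_ss(
    frame: np.ndarray,
    structure: Structure,
    pi_priority: bool = True,
) -> SSAssignment:
    """Kabsch–Sander helix assignment for one frame.

    Backbone hydrogen bonds are scored with the Kabsch–Sander energy
    (bond when E < −0.5 kcal/mol), amide hydrogens reconstructed from
    geometry when absent.  An n-turn at residue i means the carbonyl of i
    accepts from the amide of i+n; two consecutive n-turns define a
    minimal helix i..i+n−1.  With ``pi_priority`` (default) overlapping
    runs resolve π > α > 3₁₀; classic Kabsch–Sander α-priority otherwise.
    """
    bb = _backbone_indices(structure)
    n_res = len(bb)
    keys = [e["res"].key for e in bb]

    def same_chain_span(i: int, j: int) -> bool:
        ri, rj = bb[i]["res"], bb[j]["res"]
        return ri.chain == rj.chain and rj.res_seq - ri.res_seq == j - i

    # donor H position per residue (None for PRO / chain starts without C(i-1))
    h_pos: list[np.ndarray | None] = []
    for i, e in enumerate(bb):
        if e["res"].res_name == "PRO":
            h_pos.append(None)
            continue
        if e["H"] is not None:
            h_pos.append(frame[e["H"]])
            continue
        if i == 0 or not same_chain_span(i - 1, i):
            h_pos.append(None)
            continue
        h_pos.append(_amide_h(
            frame, frame[e["N"]], frame[e["CA"]], frame[bb[i - 1]["C"]]
        ))

    def hbond(acceptor: int, donor: int) -> bool:
        h = h_pos[donor]
        if h is None:
            return False
        e = kabsch_sander_energy(
            frame[bb[acceptor]["C"]], frame[bb[acceptor]["O"]],
            frame[bb[donor]["N"]], h,
        )
        return e < _KS_CUTOFF

    turns = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if same_chain_span(i, i + n) and hbond(i, i + n):
                turns[n][i] = True

    helix = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(1, n_res - n):
            if turns[n][i - 1] and turns[n][i]:
                helix[n][i:i + n] = True

    labels = []
    order = (5, 4, 3) if pi_priority else (4, 3, 5)
    name = {5: "I", 4: "H", 3: "G"}
    for i in range(n_res):
        lab = "C"
        for n in order:
            if helix[n][i]:
                lab = name[n]
                break
        labels.append(lab)
    return SSAssignment(residues=keys, labels=labels)


def ss_fractions(
    traj: Trajectory,
    burn_in: float | int = 0,
    pi_priority: bool = True,
) -> dict[ResKey, dict[str, float]]:
    """Per-residue label fractions over the post-burn-in trajectory."""
    skip = resolve_burn_in(traj.n_frames, burn_in)
    counts: dict[ResKey, dict[str, int]] = {}
    n = 0
    for f in range(skip, traj.n_frames):
        ss = assign_ss(traj.coords[f], traj.structure, pi_priority)
        for key, lab in zip(ss.residues, ss.labels):
            counts.setdefault(key, {"H": 0, "I": 0, "G": 0, "C": 0})[lab] += 1
        n += 1
    return {
        key: {lab: c / n for lab, c in labcounts.items()}
        for key, labcounts in counts.items()
    }
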