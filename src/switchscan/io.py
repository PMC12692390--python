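"""Readers and writers: PDB structures, trajectories, result tables.

Two trajectory dialects are supported:

* **multi-model PDB** (MODEL/ENDMDL blocks) — the canonical interchange
  format; frame times default to 100 ps × frame index when the file
  carries no time metadata.
* **tabular frames** — plain text, one row per atom per frame
  (``frame_index time_ps atom_serial x y z``), kept around because tiny
  hand-written fixtures stay diffable in it.

Coordinates are Å, times ps, frames 0-indexed.  PDB ``res_seq`` is taken
as-is from the file.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AtomRecord, Structure, SwitchscanError, Trajectory

__all__ = [
    "FormatError",
    "DEFAULT_STRIDE_PS",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "write_report",
    "file_digest",
]

#: Frame spacing assumed for multi-model PDB without time metadata (ps).
DEFAULT_STRIDE_PS = 100.0


class FormatError(SwitchscanError):
    """File-format violation, carrying the offending line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{path}:{lineno}: " if lineno is not None else f"{path}: "
        super().__init__(where + message)


# ---------------------------------------------------------------------------
# PDB parsing (ATOM/HETATM/MODEL/ENDMDL subset)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, path, lineno: int) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise FormatError(path, lineno, "ATOM/HETATM record too short for coordinates")
    altloc = line[16]
    if altloc not in (" ", "A"):
        raise FormatError(
            path, lineno, f"alternate location indicator {altloc!r} not supported"
        )
    icode = line[26]
    if icode != " ":
        raise FormatError(
            path, lineno, f"insertion code {icode!r} not supported"
        )
    try:
        serial = int(line[6:11])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        res_seq = int(line[22:26])
    except ValueError as exc:
        raise FormatError(path, lineno, f"unparseable numeric field: {exc}") from None
    name = line[12:16].strip()
    if not name:
        raise FormatError(path, lineno, "empty atom name")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the PDB atom-name convention: first alphabetic char
        element = next((c for c in name if c.isalpha()), "X")
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        res_seq=res_seq,
        res_name=line[17:20].strip(),
        chain=line[21],
        position=(x, y, z),
    )


def _read_pdb_models(path) -> list[list[tuple[int, AtomRecord]]]:
    """All models of a PDB file as lists of (lineno, atom)."""
    models: list[list[tuple[int, AtomRecord]]] = []
    current: list[tuple[int, AtomRecord]] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current and not in_model:
                    # atoms before the first MODEL card: treat as model 0
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append((lineno, _parse_atom_line(line, path, lineno)))
            # TER, REMARK, CRYST1 etc. are ignored
    if current:
        models.append(current)
    if not models or not models[0]:
        raise FormatError(path, None, "no ATOM/HETATM records found")
    return models


def read_structure(path) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only).

    Raises :class:`FormatError` with a line number for duplicate serials,
    insertion codes, or unparseable records.
    """
    model = _read_pdb_models(path)[0]
    seen: dict[int, int] = {}
    for lineno, atom in model:
        if atom.serial in seen:
            raise FormatError(
                path,
                lineno,
                f"duplicate atom serial {atom.serial} "
                f"(first seen at line {seen[atom.serial]})",
            )
        seen[atom.serial] = lineno
    return Structure([a for _, a in model])


_PDB_ATOM_FMT = (
    "{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
    "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {elem:>2s}\n"
)


def _format_atom(atom: AtomRecord, position) -> str:
    name = atom.name
    # PDB convention: 1–3 character names start in column 14
    if len(name) < 4:
        name = " " + name
    rec = "HETATM" if atom.res_name in ("HOH", "LIG") else "ATOM"
    x, y, z = position
    return _PDB_ATOM_FMT.format(
        rec=rec, serial=atom.serial, name=name, alt=" ", res=atom.res_name,
        chain=atom.chain, seq=atom.res_seq, icode=" ",
        x=x, y=y, z=z, occ=1.0, b=0.0, elem=atom.element,
    )


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as single-model PDB (1e-3 Å coordinate precision)."""
    with open(path, "w") as fh:
        for atom in structure.atoms:
            fh.write(_format_atom(atom, atom.position))
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(
    path,
    structure: Structure,
    dialect: str = "auto",
    stride_ps: float = DEFAULT_STRIDE_PS,
) -> Trajectory:
    """Read a trajectory in either dialect against a topology structure.

    Every frame must list exactly the structure's atoms (matched by serial
    for tabular, by order for multi-model PDB); a mismatch raises
    :class:`FormatError` naming the frame.
    """
    if dialect == "auto":
        with open(path) as fh:
            head = fh.read(6)
        dialect = "pdb" if head[:6] in ("MODEL ", "ATOM  ", "HETATM", "REMARK") else "tabular"
    if dialect == "pdb":
        return _read_traj_pdb(path, structure, stride_ps)
    if dialect == "tabular":
        return _read_traj_tabular(path, structure)
    raise ValueError(f"unknown trajectory dialect {dialect!r}")


def _read_traj_pdb(path, structure: Structure, stride_ps: float) -> Trajectory:
    models = _read_pdb_models(path)
    n = structure.n_atoms
    coords = np.empty((len(models), n, 3), dtype=float)
    for f, model in enumerate(models):
        if len(model) != n:
            raise FormatError(
                path, model[0][0] if model else None,
                f"frame {f} has {len(model)} atoms, topology has {n}",
            )
        for j, (lineno, atom) in enumerate(model):
            ref = structure.atoms[j]
            if atom.serial != ref.serial or atom.name != ref.name:
                raise FormatError(
                    path, lineno,
                    f"frame {f} atom {j} is {atom.serial}/{atom.name}, "
                    f"topology has {ref.serial}/{ref.name}",
                )
            coords[f, j] = atom.position
    times = np.arange(len(models), dtype=float) * stride_ps
    return Trajectory(structure, coords, times)


def _read_traj_tabular(path, structure: Structure) -> Trajectory:
    serial_to_idx = {a.serial: i for i, a in enumerate(structure.atoms)}
    n = structure.n_atoms
    frames: dict[int, np.ndarray] = {}
    frame_seen: dict[int, np.ndarray] = {}
    times: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(path, lineno, "expected 6 columns: frame time serial x y z")
            try:
                f = int(parts[0]); t = float(parts[1]); serial = int(parts[2])
                xyz = [float(p) for p in parts[3:6]]
            except ValueError as exc:
                raise FormatError(path, lineno, f"unparseable field: {exc}") from None
            if serial not in serial_to_idx:
                raise FormatError(path, lineno, f"atom serial {serial} not in topology")
            if f not in frames:
                frames[f] = np.empty((n, 3), dtype=float)
                frame_seen[f] = np.zeros(n, dtype=bool)
                times[f] = t
            j = serial_to_idx[serial]
            if frame_seen[f][j]:
                raise FormatError(path, lineno, f"frame {f} lists atom {serial} twice")
            frames[f][j] = xyz
            frame_seen[f][j] = True
    if not frames:
        raise FormatError(path, None, "no frame rows found")
    order = sorted(frames)
    if order != list(range(order[0], order[0] + len(order))):
        raise FormatError(path, None, f"frame indices not contiguous: {order[:5]}...")
    for f in order:
        if not frame_seen[f].all():
            missing = [structure.atoms[j].serial for j in np.flatnonzero(~frame_seen[f])]
            raise FormatError(
                path, None, f"frame {f} missing atoms with serials {missing[:5]}"
            )
    coords = np.stack([frames[f] for f in order])
    return Trajectory(structure, coords, np.array([times[f] for f in order]))


def write_trajectory(traj: Trajectory, path, dialect: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB or tabular frames."""
    if dialect == "pdb":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"MODEL {f + 1:>8d}\n")
                for j, atom in enumerate(traj.structure.atoms):
                    fh.write(_format_atom(atom, traj.coords[f, j]))
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif dialect == "tabular":
        with open(path, "w") as fh:
            fh.write("# frame_index time_ps atom_serial x y z\n")
            for f in range(traj.n_frames):
                t = traj.times[f]
                for j, atom in enumerate(traj.structure.atoms):
                    x, y, z = traj.coords[f, j]
                    fh.write(f"{f} {t:.3f} {atom.serial} {x:.4f} {y:.4f} {z:.4f}\n")
    else:
        raise ValueError(f"unknown trajectory dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Result tables and run manifest
# ---------------------------------------------------------------------------

#: Fixed column schemas of the report CSVs.
REPORT_SCHEMAS: dict[str, list[str]] = {
    "occupancy": ["condition", "pair", "bw_pair", "kind", "occupancy", "n_frames"],
    "switches": ["pair", "bw_pair", "kind", "occ_A", "occ_B", "delta", "call"],
    "pca_projections": ["condition", "frame", "time_ps", "pc1", "pc2"],
    "dihedrals": [
        "condition", "residue", "bw", "angle", "circ_mean_deg", "circ_variance",
    ],
    "ss_fractions": ["condition", "residue", "bw", "H", "I", "G", "C"],
    "distances": ["condition", "pair", "bw_pair", "metric", "time_ps", "distance"],
    "ligand_contacts": ["condition", "residue", "bw", "contact_fraction"],
}


def write_report(
    tables: Mapping[str, pd.DataFrame],
    path_prefix,
    manifest: Mapping | None = None,
) -> list[Path]:
    """Write named result tables as `<prefix>_<name>.csv` plus a JSON manifest.

    Known table names are checked against their documented column schema so
    downstream consumers can rely on the headers.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        if name in REPORT_SCHEMAS:
            expected = REPORT_SCHEMAS[name]
            if list(table.columns) != expected:
                raise ValueError(
                    f"table {name!r} columns {list(table.columns)} != schema {expected}"
                )
        out = prefix.parent / f"{prefix.name}_{name}.csv"
        table.to_csv(out, index=False)
        written.append(out)
    if manifest is not None:
        out = prefix.parent / f"{prefix.name}_manifest.json"
        with open(out, "w") as fh:
            json.dump(dict(manifest), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(out)
    return written


def file_digest(path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
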