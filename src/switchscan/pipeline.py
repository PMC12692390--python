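"""Config-driven end-to-end analysis of a two-condition trajectory pair.

:func:`run_compare` orchestrates the full battery the library exposes —
named-pair distance series, salt-bridge network scan with switch calls,
hydrogen-bond and hydrophobic occupancy differencing, pooled Cα PCA with
eigenvector displacement mapping, backbone dihedral circular statistics,
and α/π secondary-structure fractions — and writes the CSV/JSON report
bundle.  All tables are computed before anything is written, so a failing
stage leaves no partial outputs.

:func:`run_static_distance` measures a single pair distance on a static
structure, the way one compares an MD ensemble against an experimental
snapshot (e.g. an active-state receptor structure's ionic-lock distance).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .conformation import ca_pca, ev_displacements, phi_psi, ss_fractions
from .core import (
    BWMap,
    Structure,
    SwitchscanError,
    Trajectory,
    parse_bw_label,
)
from .diff import diff_occupancy, scan_saltbridge_network
from .interactions import (
    InteractionCriterion,
    ligand_contact_fraction,
    occupancy_from_distances,
    pair_distance_series,
    scan_contacts,
)

logger = logging.getLogger("switchscan")

__all__ = ["RunConfig", "run_compare", "run_static_distance", "analyze"]

ResKey = tuple[str, int]

CONFIG_VERSION = 1


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``).

    Residue tokens are either BW labels ("3.50", resolved through the BW
    map) or raw ``chain/res_seq`` references ("A/308").
    """

    structure: str
    conditions: list[tuple[str, str]]  # (label, trajectory path)
    bw_map: str | None = None
    burn_in: float = 0.1
    stride_ps: float = sio.DEFAULT_STRIDE_PS
    seed: int = 0
    criteria: dict[str, dict[str, Any]] = field(default_factory=dict)
    named_pairs: list[dict[str, str]] = field(default_factory=list)
    scans: dict[str, bool] = field(
        default_factory=lambda: {"saltbridge": True, "hbond": True, "hydrophobic": True}
    )
    ligand: dict[str, Any] | None = None
    pca_helices: list[int] = field(default_factory=list)
    dihedral_residues: list[str] = field(default_factory=list)
    output_prefix: str = "switchscan_run"
    version: int = CONFIG_VERSION

    def __post_init__(self):
        if not 0 <= self.burn_in < 1:
            raise SwitchscanError(f"burn_in must lie in [0, 1), got {self.burn_in}")
        labels = [lab for lab, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise SwitchscanError(f"condition labels must be distinct: {labels}")
        if len(self.conditions) != 2:
            raise SwitchscanError("run_compare analyses exactly two conditions")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        version = raw.pop("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise SwitchscanError(f"unsupported config version {version}")
        conditions = [(c["label"], c["trajectory"]) for c in raw.pop("conditions")]
        cfg = cls(conditions=conditions, version=version, **raw)
        base = Path(path).parent
        for p in [cfg.structure, cfg.bw_map, *(t for _, t in cfg.conditions)]:
            if p is not None and not (base / p).exists() and not Path(p).exists():
                raise SwitchscanError(f"configured input file not found: {p}")
        return cfg

    def criterion(self, kind: str) -> InteractionCriterion:
        params = self.criteria.get(kind, {})
        base = InteractionCriterion.default(kind)
        from dataclasses import replace
        if "nonpolar_set" in params:
            params = dict(params)
            params["nonpolar_set"] = frozenset(params["nonpolar_set"])
        return replace(base, **params)


def _resolve_token(token: str, bw_map: BWMap | None) -> ResKey:
    """Residue token → (chain, res_seq): "3.50" (BW) or "A/308" (raw)."""
    token = token.strip()
    if "/" in token:
        chain, seq = token.split("/")
        return (chain, int(seq))
    if bw_map is None:
        raise SwitchscanError(
            f"token {token!r} looks like a BW label but no BW map was given"
        )
    return bw_map.resolve(parse_bw_label(token))


def _bw_str(key: ResKey, bw_map: BWMap | None) -> str:
    if bw_map is None:
        return ""
    label = bw_map.label_of_or_none(*key)
    return str(label) if label is not None else ""


def _pair_str(pair: tuple[ResKey, ResKey]) -> str:
    return f"{pair[0][0]}/{pair[0][1]}:{pair[1][0]}/{pair[1][1]}"


def _bw_pair_str(pair, bw_map) -> str:
    a, b = _bw_str(pair[0], bw_map), _bw_str(pair[1], bw_map)
    return f"{a}:{b}" if a and b else ""


def analyze(
    structure: Structure,
    trajs: Sequence[tuple[str, Trajectory]],
    bw_map: BWMap | None,
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Compute the full analysis battery as named DataFrames (no I/O)."""
    tables: dict[str, pd.DataFrame] = {}
    (label_A, traj_A), (label_B, traj_B) = trajs
    burn = config.burn_in

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    # -- named-pair distance series + occupancy (ionic-lock style) --------
    stage("distances")
    dist_rows, occ_rows = [], []
    for spec_pair in config.named_pairs:
        a, b = spec_pair["pair"].split(":")
        keyA, keyB = _resolve_token(a, bw_map), _resolve_token(b, bw_map)
        metric = spec_pair.get("metric", "saltbridge")
        cutoff = float(spec_pair.get(
            "cutoff", config.criterion("saltbridge").distance_cutoff
        ))
        for label, traj in trajs:
            series = pair_distance_series(
                traj, keyA, keyB, metric, burn_in=burn,
                criterion=config.criterion("saltbridge"),
            )
            pair = (keyA, keyB)
            for t, d in zip(series.times, series.values):
                dist_rows.append((label, _pair_str(pair), _bw_pair_str(pair, bw_map),
                                  metric, t, d))
            occ_rows.append((label, _pair_str(pair), _bw_pair_str(pair, bw_map),
                             metric, occupancy_from_distances(series, cutoff),
                             series.values.size))
    tables["distances"] = pd.DataFrame(
        dist_rows, columns=sio.REPORT_SCHEMAS["distances"])

    # -- salt-bridge network scan + switch calls ---------------------------
    if config.scans.get("saltbridge", True):
        stage("saltbridge_scan")
        calls = scan_saltbridge_network(
            traj_A, traj_B, config.criterion("saltbridge"), burn_in=burn,
            labels=(label_A, label_B),
        )
        tables["switches"] = pd.DataFrame(
            [(_pair_str(c.pair), _bw_pair_str(c.pair, bw_map), "saltbridge",
              c.occ_A, c.occ_B, c.delta, c.call) for c in calls],
            columns=sio.REPORT_SCHEMAS["switches"],
        )

    # -- H-bond and hydrophobic network differencing -----------------------
    for kind in ("hbond", "hydrophobic"):
        if not config.scans.get(kind, True):
            continue
        stage(f"{kind}_scan")
        crit = config.criterion(kind)
        occA = scan_contacts(traj_A, crit, burn_in=burn, condition=label_A)
        occB = scan_contacts(traj_B, crit, burn_in=burn, condition=label_B)
        dm = diff_occupancy(occA, occB)
        tables[f"{kind}_diff"] = pd.DataFrame(
            [(_pair_str(p), _bw_pair_str(p, bw_map), a, b, d)
             for p, a, b, d in zip(dm.pairs, dm.occ_A, dm.occ_B, dm.delta)],
            columns=["pair", "bw_pair", "occ_A", "occ_B", "delta"],
        )
        for label, occ in ((label_A, occA), (label_B, occB)):
            occ_rows.extend(
                (label, _pair_str(p), _bw_pair_str(p, bw_map), kind,
                 float(o), occ.n_frames)
                for p, o in zip(occ.pairs, occ.occupancy) if o > 0
            )
    tables["occupancy"] = pd.DataFrame(
        occ_rows, columns=sio.REPORT_SCHEMAS["occupancy"])

    # -- ligand contact fractions ------------------------------------------
    if config.ligand is not None:
        stage("ligand_contacts")
        lig_key = (config.ligand["chain"], int(config.ligand["res_seq"]))
        cutoff = config.criterion("ligand_contact").distance_cutoff
        res_tokens = config.ligand.get("residues")
        if res_tokens:
            res_keys = [_resolve_token(t, bw_map) for t in res_tokens]
        else:
            res_keys = [r.key for r in structure.iter_residues()
                        if r.key != lig_key]
        rows = []
        for label, traj in trajs:
            for key in res_keys:
                frac = ligand_contact_fraction(traj, lig_key, key, cutoff, burn)
                rows.append((label, f"{key[0]}/{key[1]}",
                             _bw_str(key, bw_map), frac))
        tables["ligand_contacts"] = pd.DataFrame(
            rows, columns=sio.REPORT_SCHEMAS["ligand_contacts"])

    # -- pooled Cα PCA ------------------------------------------------------
    if config.pca_helices and bw_map is not None:
        stage("pca")
        sel_keys = [key for h in config.pca_helices for key in bw_map.helix_residues(h)]
        selection = [structure.atom_index(c, s, "CA") for c, s in sel_keys]
        pca = ca_pca(trajs, selection, burn_in=burn)
        tables["pca_projections"] = pd.DataFrame(
            {
                "condition": pca.frame_labels,
                "frame": np.arange(len(pca.frame_labels)),
                "time_ps": pca.frame_times,
                "pc1": pca.projections[:, 0],
                "pc2": pca.projections[:, 1],
            }
        )
        mags = ev_displacements(pca, 0)
        tables["ev1_displacements"] = pd.DataFrame(
            {
                "residue": [f"{c}/{s}" for c, s in sel_keys],
                "bw": [_bw_str(k, bw_map) for k in sel_keys],
                "magnitude": mags,
            }
        )

    # -- backbone dihedral circular statistics ------------------------------
    if config.dihedral_residues:
        stage("dihedrals")
        keys = [_resolve_token(t, bw_map) for t in config.dihedral_residues]
        rows = []
        for label, traj in trajs:
            for st in phi_psi(traj, keys, burn_in=burn):
                rows.append((label, f"{st.residue[0]}/{st.residue[1]}",
                             _bw_str(st.residue, bw_map), st.kind,
                             st.circ_mean, st.circ_var))
        tables["dihedrals"] = pd.DataFrame(
            rows, columns=sio.REPORT_SCHEMAS["dihedrals"])

    # -- α/π secondary-structure fractions ----------------------------------
    stage("secondary_structure")
    rows = []
    for label, traj in trajs:
        fractions = ss_fractions(traj, burn_in=burn)
        for key, frac in fractions.items():
            rows.append((label, f"{key[0]}/{key[1]}", _bw_str(key, bw_map),
                         frac["H"], frac["I"], frac["G"], frac["C"]))
    tables["ss_fractions"] = pd.DataFrame(
        rows, columns=sio.REPORT_SCHEMAS["ss_fractions"])
    return tables


def run_compare(config: RunConfig, config_dir: str | Path = ".") -> list[Path]:
    """End-to-end two-condition comparison from a run configuration.

    Reads the structure, trajectories and BW map, runs :func:`analyze`,
    and writes the CSV report bundle plus a JSON manifest echoing the
    config, the seed, and SHA-256 digests of every input.  Any stage
    failure aborts before a single output file is written.
    """
    base = Path(config_dir)

    def _path(p: str) -> Path:
        cand = base / p
        return cand if cand.exists() else Path(p)

    try:
        structure = sio.read_structure(_path(config.structure))
    except Exception as exc:
        raise SwitchscanError(f"stage read_structure failed: {exc}") from exc
    bw_map = None
    if config.bw_map is not None:
        bw_map = BWMap.from_tsv(_path(config.bw_map))
    trajs = []
    for label, traj_path in config.conditions:
        try:
            trajs.append((label, sio.read_trajectory(
                _path(traj_path), structure, stride_ps=config.stride_ps)))
        except Exception as exc:
            raise SwitchscanError(
                f"stage read_trajectory[{label}] failed: {exc}") from exc

    tables = analyze(structure, trajs, bw_map, config)

    manifest = {
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "criteria_resolved": {
            kind: {
                "distance_cutoff": config.criterion(kind).distance_cutoff,
                "angle_cutoff": config.criterion(kind).angle_cutoff,
            }
            for kind in ("saltbridge", "hbond", "hydrophobic", "ligand_contact")
        },
        "seed": config.seed,
        "inputs": {
            str(p): sio.file_digest(_path(p))
            for p in [config.structure, config.bw_map,
                      *(t for _, t in config.conditions)]
            if p is not None
        },
        "n_frames": {label: t.n_frames for label, t in trajs},
    }
    return sio.write_report(tables, config.output_prefix, manifest)


def demo_run(
    seed: int = 0,
    out_dir: str | Path = "switchscan_demo",
    n_frames: int = 900,
    write_trajectories: bool = False,
) -> dict[str, Path]:
    """Self-contained demo: synthetic two-condition bundle + full analysis.

    Builds the default 7×16 helix bundle, simulates the agonist-like and
    antagonist-like ensembles with their planted switches, runs the whole
    analysis battery, and writes the report bundle, the structure, the BW
    map, and the generator's ground truth into ``out_dir``.
    """
    from .synth import bundle_bw_map, default_demo_spec, make_condition_pair

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = default_demo_spec(seed)
    trajA, trajB, gt, structure = make_condition_pair(
        spec, n_frames=n_frames, seed=seed
    )
    bw_map = bundle_bw_map(spec)
    files: dict[str, Path] = {}
    sio.write_structure(structure, out / "bundle.pdb")
    bw_map.to_tsv(out / "bundle_bw.tsv", structure)
    gt.to_json(out / "ground_truth.json")
    files.update(structure=out / "bundle.pdb", bw_map=out / "bundle_bw.tsv",
                 ground_truth=out / "ground_truth.json")
    if write_trajectories:
        sio.write_trajectory(trajA, out / "traj_agonist.pdb")
        sio.write_trajectory(trajB, out / "traj_antagonist.pdb")

    mid = (spec.n_res + 1) // 2
    bw = lambda h, j: f"{h}.{50 + j - mid}"
    config = RunConfig(
        structure=str(out / "bundle.pdb"),
        conditions=[("agonist", ""), ("antagonist", "")],
        bw_map=str(out / "bundle_bw.tsv"),
        seed=seed,
        named_pairs=[
            {"pair": f"{bw(3, 8)}:{bw(4, 8)}", "metric": "saltbridge"},
            {"pair": f"{bw(3, 4)}:{bw(2, 4)}", "metric": "saltbridge"},
        ],
        pca_helices=[3, 5, 6, 7],
        dihedral_residues=[bw(7, j) for j in range(6, 12)],
        output_prefix=str(out / "report"),
    )
    tables = analyze(structure, [("agonist", trajA), ("antagonist", trajB)],
                     bw_map, config)
    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "seed": seed,
        "n_frames": n_frames,
        "generator": "default synthetic demo bundle",
    }
    for p in sio.write_report(tables, config.output_prefix, manifest):
        files[p.name] = p
    return files


def run_static_distance(
    structure_path,
    pair: str,
    metric: str = "saltbridge",
    bw_map_path=None,
) -> float:
    """Distance (Å) between one residue pair in a static structure.

    ``pair`` is "tokenA:tokenB" with tokens either BW labels (requires a
    map) or raw "chain/res_seq".  The metric follows the distance-series
    conventions: "saltbridge" (min N–O over the charged groups), "heavy",
    "ca", or an explicit "atoms:CZ-CD" atom pair.
    """
    structure = sio.read_structure(structure_path)
    bw_map = BWMap.from_tsv(bw_map_path) if bw_map_path else None
    a, b = pair.split(":")
    keyA, keyB = _resolve_token(a, bw_map), _resolve_token(b, bw_map)
    traj = Trajectory(structure, structure.coords[None], np.array([0.0]))
    series = pair_distance_series(traj, keyA, keyB, metric)
    return float(series.values[0])
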