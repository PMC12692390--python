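"""Two-condition differential network analysis and switch discovery.

A *molecular switch* is a residue-pair interaction whose occupancy differs
strongly and oppositely between two functional states — e.g. an ionic lock
formed in the antagonist-bound ensemble but broken under agonist, with a
second salt bridge doing the reverse.  This module takes per-condition
occupancy matrices, forms their difference, and classifies each pair.

Classification thresholds (configurable): a pair is *formed* in a
condition at occupancy ≥ 0.5 and *broken* at ≤ 0.25; a switch call
requires formed in one condition and broken in the other.  The scan is
descriptive — no multiple-testing correction by default, with an optional
two-proportion screen (Benjamini–Hochberg) for users who want one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SwitchscanError, Trajectory, saltbridge_atoms
from .interactions import (
    InteractionCriterion,
    OccupancyMatrix,
    occupancy_matrix,
)

__all__ = [
    "DiffMatrix",
    "SwitchCall",
    "diff_occupancy",
    "classify_switch",
    "scan_saltbridge_network",
    "two_proportion_screen",
]

ResKey = tuple[str, int]
Pair = tuple[ResKey, ResKey]


@dataclass
class DiffMatrix:
    """Occupancy difference (condition A − condition B) per residue pair,
    sorted by |delta| descending then lexicographic pair id."""

    condition_A: str
    condition_B: str
    pairs: list[Pair]
    occ_A: np.ndarray
    occ_B: np.ndarray
    delta: np.ndarray


@dataclass(frozen=True)
class SwitchCall:
    """One pair's state classification across two conditions."""

    pair: Pair
    occ_A: float
    occ_B: float
    delta: float
    call: str  # formed_in_A | formed_in_B | stable | absent


def diff_occupancy(A: OccupancyMatrix, B: OccupancyMatrix) -> DiffMatrix:
    """Per-pair occupancy difference A − B over the union pair universe.

    Pairs absent from one condition contribute occupancy 0 there.  The two
    matrices must have been computed under the same criterion.
    """
    if A.criterion != B.criterion:
        raise SwitchscanError(
            "occupancy matrices computed under different criteria cannot be "
            f"differenced: {A.criterion} vs {B.criterion}"
        )
    dA, dB = A.as_dict(), B.as_dict()
    pairs = sorted(set(dA) | set(dB))
    occ_A = np.array([dA.get(p, 0.0) for p in pairs])
    occ_B = np.array([dB.get(p, 0.0) for p in pairs])
    delta = occ_A - occ_B
    order = sorted(
        range(len(pairs)), key=lambda i: (-abs(delta[i]), pairs[i])
    )
    return DiffMatrix(
        condition_A=A.condition,
        condition_B=B.condition,
        pairs=[pairs[i] for i in order],
        occ_A=occ_A[order],
        occ_B=occ_B[order],
        delta=delta[order],
    )


def classify_switch(
    occ_A: float,
    occ_B: float,
    formed_threshold: float = 0.5,
    broken_threshold: float = 0.25,
) -> SwitchCall:
    """Classify one pair's two-condition occupancies.

    formed_in_A: occ_A ≥ formed_threshold and occ_B ≤ broken_threshold
    (symmetrically for formed_in_B); absent: both ≤ broken_threshold;
    stable otherwise.
    """
    if not (0 <= occ_A <= 1 and 0 <= occ_B <= 1):
        raise ValueError("occupancies must lie in [0, 1]")
    if occ_A >= formed_threshold and occ_B <= broken_threshold:
        call = "formed_in_A"
    elif occ_B >= formed_threshold and occ_A <= broken_threshold:
        call = "formed_in_B"
    elif occ_A <= broken_threshold and occ_B <= broken_threshold:
        call = "absent"
    else:
        call = "stable"
    return SwitchCall(
        pair=(("", 0), ("", 0)),
        occ_A=float(occ_A),
        occ_B=float(occ_B),
        delta=float(occ_A - occ_B),
        call=call,
    )


def scan_saltbridge_network(
    trajA: Trajectory,
    trajB: Trajectory,
    criterion: InteractionCriterion | None = None,
    burn_in: float | int = 0.1,
    labels: tuple[str, str] = ("A", "B"),
    formed_threshold: float = 0.5,
    broken_threshold: float = 0.25,
) -> list[SwitchCall]:
    """Scan every basic × acidic residue pair in two conditions.

    Enumerates all candidate salt bridges on the shared topology, computes
    per-condition occupancies, and returns switch calls sorted by |delta|
    descending — so a genuinely state-dependent bridge ranks first.
    """
    if trajA.structure.atoms != trajB.structure.atoms:
        raise SwitchscanError("the two trajectories must share a topology")
    crit = criterion or InteractionCriterion.default("saltbridge")
    s = trajA.structure
    basic, acidic = [], []
    for res in s.iter_residues():
        role, atoms = saltbridge_atoms(res.res_name, crit.protonated_his)
        if role == "basic" and s.residue_atom_indices(res, atoms):
            basic.append(res)
        elif role == "acidic" and s.residue_atom_indices(res, atoms):
            acidic.append(res)
    pairs: list[Pair] = []
    for rA in basic:
        for rB in acidic:
            if crit.exclude_adjacent and rA.chain == rB.chain and abs(
                rA.res_seq - rB.res_seq
            ) <= 1:
                continue
            pairs.append((rA.key, rB.key))
    occA = occupancy_matrix(trajA, pairs, crit, burn_in, condition=labels[0])
    occB = occupancy_matrix(trajB, pairs, crit, burn_in, condition=labels[1])
    diff = diff_occupancy(occA, occB)
    calls = []
    for pair, a, b, d in zip(diff.pairs, diff.occ_A, diff.occ_B, diff.delta):
        base = classify_switch(a, b, formed_threshold, broken_threshold)
        calls.append(SwitchCall(pair=pair, occ_A=base.occ_A, occ_B=base.occ_B,
                                delta=base.delta, call=base.call))
    return calls


def two_proportion_screen(
    diff: DiffMatrix, n_A: int, n_B: int, alpha: float = 0.05
) -> np.ndarray:
    """Optional statistical screen on a diff matrix.

    Two-proportion z-test per pair with Benjamini–Hochberg control;
    returns a boolean mask of pairs significant at ``alpha``.  The default
    pipeline does not apply this — the scan is descriptive.
    """
    from scipy.stats import norm
    from statsmodels.stats.multitest import multipletests

    kA = diff.occ_A * n_A
    kB = diff.occ_B * n_B
    p_pool = (kA + kB) / (n_A + n_B)
    se = np.sqrt(np.clip(p_pool * (1 - p_pool), 1e-300, None) * (1 / n_A + 1 / n_B))
    z = np.where(se > 0, (diff.occ_A - diff.occ_B) / se, 0.0)
    pvals = 2 * norm.sf(np.abs(z))
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject
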