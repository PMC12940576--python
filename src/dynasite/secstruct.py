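"""Backbone secondary-structure assignment over a reduced 5-state alphabet.

States: H (alpha-helix), G (3-10 helix), E (beta-sheet/bridge), T (turn),
C (coil).  Assignment follows the classic backbone hydrogen-bond energy
model: an electrostatic dipole-dipole energy is evaluated between each
carbonyl group and each amide group,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

and a hydrogen bond is assigned when E < -0.5 kcal/mol.  n-turns at offsets
3 and 4 define 3-10 and alpha helices via two consecutive turns; bridge
patterns define strands; isolated turns give T; everything else is coil.
Priority at conflicts is H > G > E > T > C.

Amide hydrogens absent from the file are inferred geometrically (1.01 A from
N along the direction opposing the bisector of the N-CA and N-C(prev)
bonds), so heavy-atom-only models are handled.
"""

from __future__ import annotations

import warnings

import numpy as np

from .structmodel import AMINO_ACIDS_3, Structure

__all__ = ["assign_secondary_structure", "ss_fractions", "SS_STATES"]

SS_STATES = ("H", "G", "E", "T", "C")

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q_FACTOR = 0.084 * 332.0
_NH_LENGTH = 1.01  # A


def _chain_residue_lists(structure: Structure):
    """Per-chain ordered lists of amino-acid residue keys."""
    chains: dict[str, list] = {}
    for key in structure.residues:
        if structure.residue_name(key) in AMINO_ACIDS_3:
            chains.setdefault(key[0], []).append(key)
    return chains


def _backbone(structure: Structure, key):
    idx = {structure.atoms[i].name: i for i in structure.residue_atoms(key)}
    out = {}
    for name in ("N", "CA", "C", "O", "H"):
        if name in idx:
            out[name] = np.array(structure.atoms[idx[name]].position)
    return out


def _infer_h(bb: dict, bb_prev: dict) -> np.ndarray | None:
    """Amide H along the direction opposing the bisector of N's two bonds."""
    if "N" not in bb or "CA" not in bb or bb_prev is None or "C" not in bb_prev:
        return None
    n = bb["N"]
    v1 = n - bb["CA"]
    v2 = n - bb_prev["C"]
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    d = v1 + v2
    nrm = np.linalg.norm(d)
    if nrm < 1e-6:
        return None
    return n + _NH_LENGTH * d / nrm


def hbond_energy(co: dict, nh: dict) -> float:
    """Dipole-model H-bond energy between a C=O group and an N-H group."""
    r_on = np.linalg.norm(co["O"] - nh["N"])
    r_ch = np.linalg.norm(co["C"] - nh["H"])
    r_oh = np.linalg.norm(co["O"] - nh["H"])
    r_cn = np.linalg.norm(co["C"] - nh["N"])
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # clashing groups: treat as (artificially) strong bond
    return _Q_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(frame: Structure) -> dict:
    """Per-residue 5-state label for every amino-acid residue in ``frame``.

    Residues missing backbone N/CA/C/O atoms are labeled C with a warning.
    Returns ``{residue_key: label}`` in residue order.
    """
    chains = _chain_residue_lists(frame)
    # flatten with per-chain sequence positions
    keys: list = []
    chain_of: list[int] = []
    for ci, (_, reslist) in enumerate(sorted(chains.items())):
        for key in reslist:
            keys.append(key)
            chain_of.append(ci)
    n = len(keys)
    labels = {k: "C" for k in keys}
    if n == 0:
        return labels

    bb = []
    complete = []
    for k in keys:
        b = _backbone(frame, k)
        bb.append(b)
        ok = all(name in b for name in ("N", "CA", "C", "O"))
        if not ok:
            warnings.warn(
                f"residue {k} missing backbone atoms; labeled coil",
                stacklevel=2,
            )
        complete.append(ok)

    # amide H: explicit when present, inferred otherwise; none for chain
    # starts and prolines (no amide H to donate)
    h_pos: list[np.ndarray | None] = []
    for i, k in enumerate(keys):
        if not complete[i] or frame.residue_name(k) == "PRO":
            h_pos.append(bb[i].get("H"))
            continue
        if "H" in bb[i]:
            h_pos.append(bb[i]["H"])
        elif i > 0 and chain_of[i - 1] == chain_of[i] and complete[i - 1]:
            h_pos.append(_infer_h(bb[i], bb[i - 1]))
        else:
            h_pos.append(None)

    # hb[i] = set of j such that CO(i) ... H-N(j) is a hydrogen bond
    hb: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        if not complete[i]:
            continue
        co = bb[i]
        for j in range(n):
            if j == i or h_pos[j] is None or not complete[j]:
                continue
            if chain_of[i] == chain_of[j] and abs(i - j) < 2:
                continue
            nh = {"N": bb[j]["N"], "H": h_pos[j]}
            if hbond_energy(co, nh) < HBOND_ENERGY_CUTOFF:
                hb[i].add(j)

    def turn(i: int, k: int) -> bool:
        j = i + k
        return (
            j < n
            and chain_of[i] == chain_of[j]
            and j in hb[i]
        )

    strength = {"C": 0, "T": 1, "E": 2, "G": 3, "H": 4}

    def promote(idx: int, lab: str) -> None:
        k = keys[idx]
        if strength[lab] > strength[labels[k]]:
            labels[k] = lab

    # helices: two consecutive n-turns; alpha (k=4) outranks 3-10 (k=3)
    for k_off, lab in ((4, "H"), (3, "G")):
        for i in range(n - 1):
            if turn(i, k_off) and turn(i + 1, k_off):
                for m in range(i + 1, i + k_off + 1):
                    promote(m, lab)

    # bridges (parallel / antiparallel), folded into one strand state E
    for i in range(1, n - 1):
        for j in range(i + 2, n - 1):
            para = (j in hb[i - 1] and i + 1 in hb[j]) or (
                i in hb[j - 1] and j + 1 in hb[i]
            )
            anti = (j in hb[i] and i in hb[j]) or (
                j + 1 in hb[i - 1] and i + 1 in hb[j - 1]
            )
            if para or anti:
                promote(i, "E")
                promote(j, "E")

    # isolated turns
    for k_off in (3, 4):
        for i in range(n):
            if turn(i, k_off):
                for m in range(i + 1, i + k_off):
                    promote(m, "T")

    return labels


def ss_fractions(ensemble, residue_key=None, analysis_stride_ns: float = 1.0):
    """Fraction of analysis frames in each secondary-structure state.

    With ``residue_key=None`` returns ``{residue_key: {state: fraction}}``
    over all amino-acid residues; otherwise the single residue's dict.
    Fractions sum to 1 per residue.
    """
    idxs = ensemble.analysis_frame_indices(analysis_stride_ns)
    tallies: dict = {}
    for fi in idxs:
        labels = assign_secondary_structure(ensemble.frame_structure(fi))
        for key, lab in labels.items():
            t = tallies.setdefault(key, {s: 0 for s in SS_STATES})
            t[lab] += 1
    nf = len(idxs)
    fractions = {
        key: {s: t[s] / nf for s in SS_STATES} for key, t in tallies.items()
    }
    if residue_key is not None:
        if residue_key not in fractions:
            raise KeyError(f"residue {residue_key} not found")
        return fractions[residue_key]
    return fractions
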