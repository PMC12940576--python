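"""Per-residue structural and dynamic descriptors over conformational ensembles.

Implements the metric battery used for dynamic active-site mapping: per-residue
RMSD sampled at fixed analysis ticks, RMSF, dynamic cross-correlation matrices
(DCCM), non-bonded heavy-atom contact counts, Shrake-Rupley solvent-accessible
surface area with side-chain exposure ratios, and ensemble secondary-structure
fractions.  Superposition conventions matter for the dynamic metrics: every
operation accepts a fit selection, and fitting on a rigid core is recommended
when flexible regions dominate (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .secstruct import SS_STATES, assign_secondary_structure, ss_fractions
from .structmodel import (
    CA_SPEC,
    AMINO_ACIDS_3,
    Ensemble,
    SelectionSpec,
    Structure,
    apply_transform,
    kabsch_superpose,
    select,
)

__all__ = [
    "read_metric_table",
    "write_metric_table",
    "DCCMatrix",
    "RadiusTableError",
    "VDW_RADII",
    "per_residue_rmsd",
    "per_residue_rmsf",
    "dccm",
    "dccm_residue_score",
    "contact_counts",
    "ensemble_contact_counts",
    "sasa",
    "exposure_ratio",
    "compute_metric_table",
    "METRIC_COLUMNS",
    "assign_secondary_structure",
    "ss_fractions",
]

#: Embedded van der Waals radii (A) for the elements handled here.
VDW_RADII = {
    "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "CU": 1.4,
    "H": 1.2, "D": 1.2, "P": 1.8, "SE": 1.9,
}

DEFAULT_PROBE_RADIUS = 1.4     # A, water probe
DEFAULT_QUADRATURE = 960       # golden-spiral sphere points
DEFAULT_CONTACT_CUTOFF = 5.0   # A, heavy-atom contact criterion

METRIC_COLUMNS = [
    "rmsd_mean", "rmsf", "contacts_mean", "sasa_mean",
    "exposure_ratio", "dccm_score",
] + [f"ss_{s}" for s in SS_STATES]


class RadiusTableError(KeyError):
    pass


def _vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise RadiusTableError(
            f"no van der Waals radius for element {element!r}"
        ) from None


# ---------------------------------------------------------------------------
# Superposition helpers
# ---------------------------------------------------------------------------

def superposed_frames(
    ensemble: Ensemble,
    fit_spec: SelectionSpec = CA_SPEC,
    reference: Structure | None = None,
) -> list[np.ndarray]:
    """Each frame rigidly fitted onto the reference over the fit selection."""
    ref = reference if reference is not None else ensemble.topology
    fit_idx = select(ensemble.topology, fit_spec)
    ref_coords = ref.coords
    out = []
    for fr in ensemble.frames:
        R, t, _ = kabsch_superpose(fr, ref_coords, fit_idx)
        out.append(apply_transform(fr, R, t))
    return out


def _amino_residues(structure: Structure):
    return [
        key for key in structure.residues
        if structure.residue_name(key) in AMINO_ACIDS_3
    ]


def _heavy_atom_indices(structure: Structure, key) -> list[int]:
    return [
        i for i in structure.residue_atoms(key)
        if not structure.atoms[i].is_hydrogen
    ]


# ---------------------------------------------------------------------------
# RMSD / RMSF / DCCM
# ---------------------------------------------------------------------------

def per_residue_rmsd(
    ensemble: Ensemble,
    reference: Structure | None = None,
    analysis_stride_ns: float = 1.0,
    fit_spec: SelectionSpec = CA_SPEC,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-residue heavy-atom RMSD to the reference at each analysis tick.

    Frames nearest each tick are globally superposed on the fit selection
    (Calpha by default), then each residue's heavy-atom RMSD to the reference
    is computed.  Returns ``(series, mean)`` where ``series`` has one row per
    residue and one column per tick time (ns) and ``mean`` is the time
    average per residue.
    """
    ref = reference if reference is not None else ensemble.topology
    if len(ref) != len(ensemble.topology):
        raise ValueError("reference not congruent with ensemble topology")
    tick_idx = ensemble.analysis_frame_indices(analysis_stride_ns)
    res_keys = _amino_residues(ensemble.topology)
    labels = [ensemble.topology.residue_label(k) for k in res_keys]
    heavy = {k: _heavy_atom_indices(ensemble.topology, k) for k in res_keys}
    fit_idx = select(ensemble.topology, fit_spec)
    ref_coords = ref.coords
    cols = {}
    for fi in tick_idx:
        t_ns = ensemble.times_ns[fi]
        R, t, _ = kabsch_superpose(ensemble.frames[fi], ref_coords, fit_idx)
        fitted = apply_transform(ensemble.frames[fi], R, t)
        vals = []
        for k in res_keys:
            idx = heavy[k]
            d = fitted[idx] - ref_coords[idx]
            vals.append(float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
        cols[t_ns] = vals
    series = pd.DataFrame(cols, index=labels)
    return series, series.mean(axis=1).rename("rmsd_mean")


def per_residue_rmsf(
    ensemble: Ensemble,
    selection: SelectionSpec = CA_SPEC,
    fit_spec: SelectionSpec = CA_SPEC,
    superpose: bool = True,
) -> pd.Series:
    """Root mean square fluctuation per residue (A).

    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames, computed on superposed
    frames and averaged over each residue's selected atoms.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    frames = (
        superposed_frames(ensemble, fit_spec) if superpose
        else [np.asarray(f) for f in ensemble.frames]
    )
    stack = np.stack(frames)                       # (F, N, 3)
    mean = stack.mean(axis=0)
    msf = np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0)  # per atom
    rmsf_atom = np.sqrt(msf)
    top = ensemble.topology
    sel = set(select(top, selection))
    out = {}
    for key in _amino_residues(top):
        idx = [i for i in top.residue_atoms(key) if i in sel]
        if idx:
            out[top.residue_label(key)] = float(np.mean(rmsf_atom[idx]))
    return pd.Series(out, name="rmsf")


@dataclass
class DCCMatrix:
    """Normalized dynamic cross-correlation matrix over selected residues."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("DCCM shape does not match id list")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite], atol=1e-9):
            raise ValueError("DCCM must be symmetric")
        if np.any(np.abs(m[finite]) > 1 + 1e-9):
            raise ValueError("DCCM entries must lie in [-1, 1]")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def dccm(
    ensemble: Ensemble,
    selection: SelectionSpec = CA_SPEC,
    fit_spec: SelectionSpec = CA_SPEC,
    superpose: bool = True,
) -> DCCMatrix:
    """Dynamic cross-correlation matrix over the selected atoms (one per
    residue; Calpha by default).

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>) with dr the deviation
    from the time-mean position after superposition.  Residues with zero
    positional variance yield NaN (undefined correlation), never a silent 0.
    """
    if ensemble.n_frames < 2:
        raise ValueError("DCCM undefined for a single frame")
    top = ensemble.topology
    frames = (
        superposed_frames(ensemble, fit_spec) if superpose
        else [np.asarray(f) for f in ensemble.frames]
    )
    sel = select(top, selection)
    ids = [top.residue_label(top.atoms[i].residue_key) for i in sel]
    stack = np.stack(frames)[:, sel, :]            # (F, n, 3)
    dev = stack - stack.mean(axis=0)
    # cross covariance of displacement vectors
    cov = np.einsum("fik,fjk->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov).copy()
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = cov / denom
    zero = var <= 1e-24
    mat[zero, :] = np.nan
    mat[:, zero] = np.nan
    np.clip(mat, -1.0, 1.0, out=mat)
    di = np.diag_indices(len(sel))
    diag = np.where(zero, np.nan, 1.0)
    mat[di] = diag
    return DCCMatrix(ids=ids, matrix=mat)


def dccm_residue_score(
    matrix: DCCMatrix, residue: str, partner_set: list[str]
) -> float:
    """Mean correlation of ``residue`` to the partner set (self excluded).

    This is the documented scalar reduction of a residue's row of the DCCM,
    used for active-site coupling scores against a fixed interaction set.
    """
    if residue not in matrix.ids:
        raise KeyError(f"residue {residue} not in DCCM")
    partners = [p for p in partner_set if p != residue]
    if not partners:
        raise ValueError("partner set empty after excluding self")
    missing = [p for p in partners if p not in matrix.ids]
    if missing:
        raise KeyError(f"partners not in DCCM: {missing}")
    i = matrix.ids.index(residue)
    vals = [matrix.matrix[i, matrix.ids.index(p)] for p in partners]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _bonded_exclusions(structure: Structure) -> set[frozenset[int]]:
    """Inter-residue covalent pairs to exclude: the peptide C(i)-N(i+1) link."""
    excl: set[frozenset[int]] = set()
    by_chain: dict[str, list] = {}
    for key in structure.residues:
        if structure.residue_name(key) in AMINO_ACIDS_3:
            by_chain.setdefault(key[0], []).append(key)
    for chain_keys in by_chain.values():
        for a_key, b_key in zip(chain_keys, chain_keys[1:]):
            if b_key[1] - a_key[1] != 1:
                continue
            c_idx = [i for i in structure.residue_atoms(a_key)
                     if structure.atoms[i].name == "C"]
            n_idx = [i for i in structure.residue_atoms(b_key)
                     if structure.atoms[i].name == "N"]
            if c_idx and n_idx:
                excl.add(frozenset((c_idx[0], n_idx[0])))
    return excl


def contact_counts(
    structure: Structure,
    residue_key,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    count_partners: bool = False,
) -> int:
    """Non-bonded heavy-atom contacts between a residue and the rest.

    Counts heavy-atom pairs (a in the residue, b outside it) with distance
    <= cutoff, excluding covalently linked pairs (the peptide bond to
    adjacent residues).  With ``count_partners=True`` the number of distinct
    partner residues is returned instead of the pair count.
    """
    if residue_key not in structure.residues:
        raise KeyError(f"residue {residue_key} not in structure")
    own = set(_heavy_atom_indices(structure, residue_key))
    if not own:
        return 0
    heavy = [
        i for i, a in enumerate(structure.atoms) if not a.is_hydrogen
    ]
    coords = structure.coords
    excl = _bonded_exclusions(structure)
    tree = cKDTree(coords[heavy])
    own_list = sorted(own)
    pairs = 0
    partners: set = set()
    for i in own_list:
        for jj in tree.query_ball_point(coords[i], cutoff):
            j = heavy[jj]
            if j in own:
                continue
            if frozenset((i, j)) in excl:
                continue
            pairs += 1
            partners.add(structure.atoms[j].residue_key)
    return len(partners) if count_partners else pairs


def ensemble_contact_counts(
    ensemble: Ensemble,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    analysis_stride_ns: float = 1.0,
    count_partners: bool = False,
) -> pd.Series:
    """Analysis-frame average of per-residue contact counts."""
    idxs = ensemble.analysis_frame_indices(analysis_stride_ns)
    top = ensemble.topology
    keys = _amino_residues(top)
    acc = np.zeros(len(keys))
    for fi in idxs:
        frame = ensemble.frame_structure(fi)
        for r, key in enumerate(keys):
            acc[r] += contact_counts(frame, key, cutoff, count_partners)
    labels = [top.residue_label(k) for k in keys]
    return pd.Series(acc / len(idxs), index=labels, name="contacts_mean")


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley, golden-spiral quadrature)
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def sasa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    quadrature_points: int = DEFAULT_QUADRATURE,
) -> tuple[np.ndarray, pd.Series]:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Each heavy atom is expanded by the probe radius; the fraction of sphere
    quadrature points not occluded by any neighboring expanded sphere gives
    that atom's accessible area.  Hydrogens get zero area and do not occlude.
    Returns ``(per_atom, per_residue)`` with per-residue sums keyed by
    residue label.
    """
    pts = _golden_spiral(quadrature_points)
    coords = structure.coords
    n = len(structure)
    radii = np.zeros(n)
    heavy_mask = np.zeros(n, dtype=bool)
    for i, a in enumerate(structure.atoms):
        if a.is_hydrogen:
            continue
        radii[i] = _vdw_radius(a.element) + probe_radius
        heavy_mask[i] = True
    heavy = np.flatnonzero(heavy_mask)
    per_atom = np.zeros(n)
    if len(heavy) == 0:
        return per_atom, pd.Series(dtype=float)
    hx = coords[heavy]
    hr = radii[heavy]
    tree = cKDTree(hx)
    rmax = hr.max()
    for hi, i in enumerate(heavy):
        ri = hr[hi]
        sphere = hx[hi] + ri * pts
        neigh = [
            j for j in tree.query_ball_point(hx[hi], ri + rmax) if j != hi
        ]
        if neigh:
            d = np.linalg.norm(
                sphere[:, None, :] - hx[neigh][None, :, :], axis=2
            )
            exposed = np.all(d >= hr[neigh][None, :], axis=1)
        else:
            exposed = np.ones(len(sphere), dtype=bool)
        per_atom[i] = exposed.mean() * 4.0 * np.pi * ri * ri
    per_res: dict[str, float] = {}
    for key, idxs in structure.residues.items():
        per_res[structure.residue_label(key)] = float(per_atom[idxs].sum())
    return per_atom, pd.Series(per_res, name="sasa")


#: Side-chain random-coil reference areas (A^2) for the exposure ratio.
#: SYNTHETIC reference: computed once with this module's Shrake-Rupley
#: routine (960 points, 1.4 A probe) on generator-built extended Gly-X-Gly
#: tripeptides in which the side chain is represented by its beta-carbon
#: (Calpha for glycine), then frozen here.  Under that proxy every non-Gly
#: residue shares one reference area.  See docs/methods.md for limitations.
_CB_PROXY_COIL_AREA = 56.10
_GLY_PROXY_COIL_AREA = 26.67
SIDECHAIN_COIL_REFERENCE: dict[str, float] = {
    aa: (_GLY_PROXY_COIL_AREA if aa == "GLY" else _CB_PROXY_COIL_AREA)
    for aa in AMINO_ACIDS_3
}


def _sidechain_indices(structure: Structure, key) -> list[int]:
    name = structure.residue_name(key)
    idxs = structure.residue_atoms(key)
    if name == "GLY":
        # glycine has no side chain: Calpha serves as its proxy
        return [i for i in idxs if structure.atoms[i].name == "CA"]
    side = [
        i for i in idxs
        if structure.atoms[i].name not in ("N", "CA", "C", "O", "OXT")
        and not structure.atoms[i].is_hydrogen
    ]
    return side


def exposure_ratio(
    structure: Structure,
    residue_key,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    quadrature_points: int = DEFAULT_QUADRATURE,
    clamp: bool = False,
) -> float:
    """Side-chain SASA as a percentage of its random-coil reference area.

    0% is fully buried; ~100% matches the isolated-tripeptide reference.
    Values can exceed 100 and are reported unclamped unless ``clamp=True``.
    """
    name = structure.residue_name(residue_key)
    if name not in AMINO_ACIDS_3:
        raise ValueError(f"unsupported residue type {name!r}")
    ref = SIDECHAIN_COIL_REFERENCE[name]
    per_atom, _ = sasa(structure, probe_radius, quadrature_points)
    side = _sidechain_indices(structure, residue_key)
    if not side:
        raise ValueError(f"residue {residue_key} has no side-chain atoms")
    pct = float(per_atom[side].sum() / ref * 100.0)
    return min(pct, 100.0) if clamp else pct


# ---------------------------------------------------------------------------
# Metric table assembly
# ---------------------------------------------------------------------------

def compute_metric_table(
    ensemble: Ensemble,
    reference: Structure | None = None,
    analysis_stride_ns: float = 1.0,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    quadrature_points: int = DEFAULT_QUADRATURE,
    dccm_partner_set: list[str] | None = None,
    fit_spec: SelectionSpec = CA_SPEC,
) -> pd.DataFrame:
    """Full per-residue metric table for one system.

    Columns: rmsd_mean, rmsf, contacts_mean, sasa_mean, exposure_ratio,
    dccm_score and the five ss_* state fractions.  ``dccm_partner_set``
    defaults to all residues (every residue scored against the rest).
    """
    top = ensemble.topology
    keys = _amino_residues(top)
    labels = [top.residue_label(k) for k in keys]
    _, rmsd_mean = per_residue_rmsd(
        ensemble, reference, analysis_stride_ns, fit_spec=fit_spec
    )
    rmsf = per_residue_rmsf(ensemble, fit_spec=fit_spec)
    contacts = ensemble_contact_counts(
        ensemble, contact_cutoff, analysis_stride_ns
    )
    tick_idx = ensemble.analysis_frame_indices(analysis_stride_ns)
    sasa_acc = None
    expo_acc: dict[str, float] = {lab: 0.0 for lab in labels}
    for fi in tick_idx:
        frame = ensemble.frame_structure(fi)
        per_atom, per_res = sasa(frame, probe_radius, quadrature_points)
        sasa_acc = per_res if sasa_acc is None else sasa_acc.add(per_res)
        for key, lab in zip(keys, labels):
            side = _sidechain_indices(frame, key)
            ref = SIDECHAIN_COIL_REFERENCE[frame.residue_name(key)]
            expo_acc[lab] += float(per_atom[side].sum()) / ref * 100.0
    sasa_mean = (sasa_acc / len(tick_idx)).reindex(labels)
    exposure = pd.Series(
        {lab: v / len(tick_idx) for lab, v in expo_acc.items()}
    )
    mat = dccm(ensemble, fit_spec=fit_spec)
    partners = dccm_partner_set if dccm_partner_set is not None else mat.ids
    dccm_scores = {}
    for lab in mat.ids:
        try:
            dccm_scores[lab] = dccm_residue_score(mat, lab, partners)
        except ValueError:
            dccm_scores[lab] = np.nan
    fracs = ss_fractions(ensemble, analysis_stride_ns=analysis_stride_ns)
    frac_rows = {
        top.residue_label(k): {f"ss_{s}": v[s] for s in SS_STATES}
        for k, v in fracs.items()
    }
    table = pd.DataFrame(index=labels)
    table["rmsd_mean"] = rmsd_mean.reindex(labels)
    table["rmsf"] = rmsf.reindex(labels)
    table["contacts_mean"] = contacts.reindex(labels)
    table["sasa_mean"] = sasa_mean
    table["exposure_ratio"] = exposure.reindex(labels)
    table["dccm_score"] = pd.Series(dccm_scores).reindex(labels)
    ss_df = pd.DataFrame.from_dict(frac_rows, orient="index")
    for col in [f"ss_{s}" for s in SS_STATES]:
        table[col] = ss_df[col].reindex(labels) if col in ss_df else 0.0
    return table


def write_metric_table(table: pd.DataFrame, path, parameters: dict | None = None) -> None:
    """Write a per-residue metric table as TSV with a parameter header.

    Header lines start with ``#`` and record the parameters used, so every
    output is regenerable from its own file.
    """
    with open(path, "w") as fh:
        for k, v in (parameters or {}).items():
            fh.write(f"# {k} = {v}\n")
        table.to_csv(fh, sep="\t", index_label="residue")


def read_metric_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a metric TSV written by :func:`write_metric_table`.

    Returns ``(table, parameters)``.
    """
    params: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                params[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t", index_col="residue")
    return table, params
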