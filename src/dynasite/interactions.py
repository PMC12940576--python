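"""Ligand-protein interaction detection, pose triage, and interaction-set algebra.

Detection is geometric: hydrogen bonds by donor-acceptor distance and
donor-H-acceptor angle, hydrophobic contacts by apolar heavy-atom proximity,
and pi-pi stacking by ring-centroid distance plus inter-plane angle.  Pose
triage enforces the dicopper-site rule for a catalytically plausible pose: a
hydroxyl or carbonyl oxygen within 4.0 A of either copper, oriented toward
the binuclear site.  Interaction-set algebra reduces per-substrate residue
sets to a universal core (engaged by every substrate), substrate-specific
positions, and shared subsets.

All printed cutoffs are inclusive boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .ligands import LIGAND_TEMPLATES
from .structmodel import (
    AMINO_ACIDS_3,
    CongruenceError,
    Ensemble,
    Structure,
)

__all__ = [
    "CopperSite",
    "LigandPose",
    "InteractionRecord",
    "InteractionMap",
    "BoundResult",
    "detect_hbonds",
    "detect_nonbonded_contacts",
    "detect_pi_stacking",
    "validate_pose",
    "cluster_poses",
    "classify_bound",
    "build_interaction_map",
    "classify_universal_specific",
    "copper_proximity_annotation",
]

# H-bond base criteria (relaxed by the printed tolerances at call time):
# donor-acceptor distance 3.0 A, donor-H-acceptor angle 140 degrees.
HBOND_BASE_DISTANCE = 3.0
HBOND_BASE_ANGLE = 140.0
DEFAULT_DISTANCE_TOLERANCE = 0.4
DEFAULT_ANGLE_TOLERANCE = 20.0

CONTACT_CUTOFF = 5.0
PI_CENTROID_CUTOFF = 5.0
PI_PARALLEL_MAX_ANGLE = 30.0
PI_TSHAPE_RANGE = (60.0, 120.0)
O_CU_MAX = 4.0
CLUSTER_RMSD = 5.0

INTERACTION_TYPES = ("hbond", "hydrophobic", "pi_stacking", "copper_adjacent")

#: Protein H-bond chemistry by (residue name, atom name).
PROTEIN_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
}
PROTEIN_DONORS = {
    ("*", "N"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("TRP", "NE1"),
}

#: Aromatic ring atom names for protein residues.
PROTEIN_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
}

APOLAR_ELEMENTS = {"C", "S"}


@dataclass
class CopperSite:
    """The binuclear copper center and its coordinating residues."""

    cu_a: np.ndarray
    cu_b: np.ndarray
    coordinating_residues: tuple = ()
    bridging_o2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cu_a = np.asarray(self.cu_a, dtype=float)
        self.cu_b = np.asarray(self.cu_b, dtype=float)
        if not (np.all(np.isfinite(self.cu_a)) and np.all(np.isfinite(self.cu_b))):
            raise ValueError("copper positions must be finite")
        if np.allclose(self.cu_a, self.cu_b):
            raise ValueError("CuA and CuB must be distinct positions")

    @property
    def midpoint(self) -> np.ndarray:
        return (self.cu_a + self.cu_b) / 2.0


@dataclass
class LigandPose:
    """One docked ligand pose with its upstream-reported binding energy."""

    ligand: Structure
    binding_energy: float
    pose_id: str
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.binding_energy):
            raise ValueError("binding energy must be finite")

    @property
    def code(self) -> str:
        return self.ligand.atoms[0].residue_name

    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.position for a in self.ligand.atoms if not a.is_hydrogen]
        )


@dataclass(frozen=True)
class InteractionRecord:
    residue: str
    substrate: str
    interaction_type: str
    frame_ns: float
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _ligand_atom_index(structure: Structure, ligand_indices) -> dict[str, int]:
    return {structure.atoms[i].name: i for i in ligand_indices}


def _ligand_code(structure: Structure, ligand_indices) -> str:
    return structure.atoms[ligand_indices[0]].residue_name


def _protein_residues(structure: Structure, exclude: set[int]):
    for key in structure.residues:
        if structure.residue_name(key) not in AMINO_ACIDS_3:
            continue
        idxs = [i for i in structure.residue_atoms(key) if i not in exclude]
        if idxs:
            yield key, idxs


def _angle_deg(a, b, c) -> float:
    v1 = np.asarray(a) - np.asarray(b)
    v2 = np.asarray(c) - np.asarray(b)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _attached_hydrogens(structure: Structure, donor_idx: int) -> list[int]:
    d = np.array(structure.atoms[donor_idx].position)
    key = structure.atoms[donor_idx].residue_key
    out = []
    for i in structure.residue_atoms(key):
        a = structure.atoms[i]
        if a.is_hydrogen and np.linalg.norm(np.array(a.position) - d) <= 1.25:
            out.append(i)
    return out


def _ring_plane(coords: np.ndarray):
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


# ---------------------------------------------------------------------------
# Detection operators
# ---------------------------------------------------------------------------

def detect_hbonds(
    frame: Structure,
    ligand_indices,
    substrate: str | None = None,
    frame_ns: float = 0.0,
    distance_tolerance: float = DEFAULT_DISTANCE_TOLERANCE,
    angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE,
) -> list[InteractionRecord]:
    """Ligand-protein hydrogen bonds under relaxed geometric criteria.

    A bond is reported when the donor-acceptor distance is <= base + tolerance
    (3.0 + 0.4 A) and the donor-H-acceptor angle is >= base - tolerance
    (140 - 20 deg).  When the donor carries no explicit hydrogen, the angle
    criterion is treated as satisfied (heavy-atom-only models).
    """
    ligand_indices = list(ligand_indices)
    code = _ligand_code(frame, ligand_indices)
    tmpl = LIGAND_TEMPLATES.get(code)
    lig_names = _ligand_atom_index(frame, ligand_indices)
    max_d = HBOND_BASE_DISTANCE + distance_tolerance
    min_a = HBOND_BASE_ANGLE - angle_tolerance
    coords = frame.coords

    lig_donors: list[tuple[int, int | None]] = []
    lig_acceptors: list[int] = []
    if tmpl is not None:
        for heavy, hyd in tmpl.donors:
            if heavy in lig_names:
                lig_donors.append(
                    (lig_names[heavy], lig_names.get(hyd) if hyd else None)
                )
        lig_acceptors = [lig_names[n] for n in tmpl.acceptors if n in lig_names]
    else:
        # untyped ligand: polar heavy atoms act as both donor and acceptor
        for i in ligand_indices:
            a = frame.atoms[i]
            if a.element.upper() in ("N", "O"):
                lig_donors.append((i, None))
                lig_acceptors.append(i)
    if not lig_donors and not lig_acceptors:
        return []

    def passes(d_idx: int, h_idx: int | None, a_idx: int) -> tuple[bool, float, float | None]:
        dist = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
        if dist > max_d:
            return False, dist, None
        hs = [h_idx] if h_idx is not None else _attached_hydrogens(frame, d_idx)
        if not hs:
            return True, dist, None
        best = max(
            _angle_deg(coords[d_idx], coords[h], coords[a_idx]) for h in hs
        )
        return best >= min_a, dist, best

    records = []
    lig_set = set(ligand_indices)
    for key, idxs in _protein_residues(frame, lig_set):
        resname = frame.residue_name(key)
        label = frame.residue_label(key)
        for i in idxs:
            at = frame.atoms[i]
            is_acc = ((resname, at.name) in PROTEIN_ACCEPTORS
                      or ("*", at.name) in PROTEIN_ACCEPTORS)
            is_don = ((resname, at.name) in PROTEIN_DONORS
                      or ("*", at.name) in PROTEIN_DONORS)
            hits: list[tuple[float, float | None]] = []
            if is_acc:
                for d_idx, h_idx in lig_donors:
                    ok, dist, ang = passes(d_idx, h_idx, i)
                    if ok:
                        hits.append((dist, ang))
            if is_don:
                for a_idx in lig_acceptors:
                    ok, dist, ang = passes(i, None, a_idx)
                    if ok:
                        hits.append((dist, ang))
            for dist, ang in hits:
                records.append(InteractionRecord(
                    residue=label, substrate=substrate or code,
                    interaction_type="hbond", frame_ns=frame_ns,
                    distance=dist, angle=ang,
                ))
    return records


def detect_nonbonded_contacts(
    frame: Structure,
    ligand_indices,
    substrate: str | None = None,
    frame_ns: float = 0.0,
    cutoff: float = CONTACT_CUTOFF,
) -> list[InteractionRecord]:
    """Hydrophobic (apolar-apolar) contacts within the distance cutoff.

    Each residue hosting at least one qualifying pair is reported once per
    frame with the minimum pair distance.
    """
    ligand_indices = list(ligand_indices)
    code = _ligand_code(frame, ligand_indices)
    coords = frame.coords
    lig_apolar = [
        i for i in ligand_indices
        if frame.atoms[i].element.upper() in APOLAR_ELEMENTS
    ]
    if not lig_apolar:
        return []
    records = []
    lig_set = set(ligand_indices)
    for key, idxs in _protein_residues(frame, lig_set):
        res_apolar = [
            i for i in idxs
            if frame.atoms[i].element.upper() in APOLAR_ELEMENTS
        ]
        if not res_apolar:
            continue
        d = cdist(coords[lig_apolar], coords[res_apolar])
        dmin = float(d.min())
        if dmin <= cutoff:
            records.append(InteractionRecord(
                residue=frame.residue_label(key),
                substrate=substrate or code,
                interaction_type="hydrophobic", frame_ns=frame_ns,
                distance=dmin,
            ))
    return records


def detect_pi_stacking(
    frame: Structure,
    ligand_indices,
    substrate: str | None = None,
    frame_ns: float = 0.0,
    centroid_cutoff: float = PI_CENTROID_CUTOFF,
) -> list[InteractionRecord]:
    """Pi-pi stacking between ligand rings and Phe/Tyr/Trp/His rings.

    Parallel stacking: centroid distance <= 5.0 A and inter-plane angle
    <= 30 deg; T-shaped: angle in [60, 120] deg (i.e. 60-90 after folding).
    """
    ligand_indices = list(ligand_indices)
    code = _ligand_code(frame, ligand_indices)
    tmpl = LIGAND_TEMPLATES.get(code)
    if tmpl is None:
        return []
    lig_names = _ligand_atom_index(frame, ligand_indices)
    coords = frame.coords
    lig_rings = []
    for ring in tmpl.rings:
        if all(n in lig_names for n in ring):
            lig_rings.append(coords[[lig_names[n] for n in ring]])
    records = []
    lig_set = set(ligand_indices)
    for key, idxs in _protein_residues(frame, lig_set):
        resname = frame.residue_name(key)
        if resname not in PROTEIN_RINGS:
            continue
        names = {frame.atoms[i].name: i for i in idxs}
        for ring_names in PROTEIN_RINGS[resname]:
            if not all(n in names for n in ring_names):
                warnings.warn(
                    f"{frame.residue_label(key)} lacks ring atoms; skipped",
                    stacklevel=2,
                )
                continue
            pc, pn = _ring_plane(coords[[names[n] for n in ring_names]])
            for lring in lig_rings:
                lc, ln = _ring_plane(lring)
                dist = float(np.linalg.norm(pc - lc))
                if dist > centroid_cutoff:
                    continue
                ang = np.degrees(np.arccos(np.clip(abs(np.dot(pn, ln)), 0, 1)))
                geometry = None
                if ang <= PI_PARALLEL_MAX_ANGLE:
                    geometry = ang
                elif PI_TSHAPE_RANGE[0] <= ang <= 90.0:
                    geometry = ang
                if geometry is not None:
                    records.append(InteractionRecord(
                        residue=frame.residue_label(key),
                        substrate=substrate or code,
                        interaction_type="pi_stacking", frame_ns=frame_ns,
                        distance=dist, angle=float(ang),
                    ))
    return records


def detect_all(
    frame: Structure,
    ligand_indices,
    substrate: str | None = None,
    frame_ns: float = 0.0,
) -> list[InteractionRecord]:
    """All interaction records for one frame (hbond, hydrophobic, stacking)."""
    return (
        detect_hbonds(frame, ligand_indices, substrate, frame_ns)
        + detect_nonbonded_contacts(frame, ligand_indices, substrate, frame_ns)
        + detect_pi_stacking(frame, ligand_indices, substrate, frame_ns)
    )


# ---------------------------------------------------------------------------
# Pose triage
# ---------------------------------------------------------------------------

def _qualifying_oxygen_indices(ligand: Structure) -> list[int]:
    code = ligand.atoms[0].residue_name
    tmpl = LIGAND_TEMPLATES.get(code)
    if tmpl is None:
        return [
            i for i, a in enumerate(ligand.atoms) if a.element.upper() == "O"
        ]
    names = {a.name: i for i, a in enumerate(ligand.atoms)}
    return [names[n] for n in tmpl.qualifying_oxygens if n in names]


def _ring_centroid(ligand: Structure) -> np.ndarray:
    code = ligand.atoms[0].residue_name
    tmpl = LIGAND_TEMPLATES.get(code)
    coords = ligand.coords
    if tmpl is None:
        return coords.mean(axis=0)
    names = {a.name: i for i, a in enumerate(ligand.atoms)}
    ring_idx = sorted({
        names[n] for ring in tmpl.rings for n in ring if n in names
    })
    if not ring_idx:
        return coords.mean(axis=0)
    return coords[ring_idx].mean(axis=0)


def validate_pose(
    pose: LigandPose,
    site: CopperSite,
    max_o_cu: float = O_CU_MAX,
) -> tuple[bool, str]:
    """Dicopper-site validity test for a docked pose.

    Valid iff (a) some hydroxyl/carbonyl oxygen is within ``max_o_cu`` of
    CuA or CuB (inclusive) and (b) that oxygen points toward the site: the
    ring-centroid-to-oxygen vector has positive projection onto the
    centroid-to-copper-midpoint vector.
    """
    ox = _qualifying_oxygen_indices(pose.ligand)
    if not ox:
        return False, "no_candidate_oxygen"
    coords = pose.ligand.coords
    d_a = np.linalg.norm(coords[ox] - site.cu_a, axis=1)
    d_b = np.linalg.norm(coords[ox] - site.cu_b, axis=1)
    dmin = np.minimum(d_a, d_b)
    best = int(np.argmin(dmin))
    if dmin[best] > max_o_cu:
        return False, f"distance ({dmin[best]:.2f} A > {max_o_cu} A)"
    centroid = _ring_centroid(pose.ligand)
    to_oxygen = coords[ox[best]] - centroid
    to_site = site.midpoint - centroid
    if float(np.dot(to_oxygen, to_site)) <= 0:
        return False, "orientation (oxygen points away from the copper site)"
    return True, "ok"


def cluster_poses(
    poses: list[LigandPose],
    rmsd_threshold: float = CLUSTER_RMSD,
) -> list[list[LigandPose]]:
    """Greedy energy-ranked clustering of poses by heavy-atom RMSD.

    The best-energy unassigned pose seeds a cluster; all unassigned poses
    within the RMSD threshold of the seed join it; repeat.  Pose RMSD uses
    ligand heavy atoms without re-superposition (common receptor frame).
    Mutates each pose's ``cluster_id`` and returns clusters in seed-energy
    order.
    """
    if not poses:
        return []
    n0 = len(poses[0].heavy_coords())
    for p in poses:
        if len(p.heavy_coords()) != n0:
            raise CongruenceError(
                f"pose {p.pose_id} has inconsistent ligand atom count"
            )
    order = sorted(range(len(poses)), key=lambda i: poses[i].binding_energy)
    unassigned = set(order)
    clusters: list[list[LigandPose]] = []
    cid = 0
    for i in order:
        if i not in unassigned:
            continue
        seed = poses[i]
        seed_xyz = seed.heavy_coords()
        members = []
        for j in order:
            if j not in unassigned:
                continue
            d = poses[j].heavy_coords() - seed_xyz
            rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
            if rmsd <= rmsd_threshold:
                members.append(j)
        for j in members:
            unassigned.discard(j)
            poses[j].cluster_id = cid
        clusters.append([poses[j] for j in members])
        cid += 1
    return clusters


@dataclass
class BoundResult:
    bound: bool
    frame_flags: list[bool]
    frame_times_ns: list[float]
    first_failure_index: int | None
    criterion: str


def classify_bound(
    ensemble: Ensemble,
    ligand_indices,
    site: CopperSite,
    analysis_stride_ns: float = 1.0,
    max_dev: float = O_CU_MAX,
    criterion: str = "o_cu_distance",
) -> BoundResult:
    """Bound/unbound call over an ensemble.

    Bound iff the criterion holds at every analysis frame (inclusive
    boundary).  Default criterion: minimum qualifying-oxygen-to-copper
    distance <= ``max_dev``.  Alternative ``"positional_deviation"``:
    ligand-centroid displacement from the reference pose <= ``max_dev``.
    """
    if criterion not in ("o_cu_distance", "positional_deviation"):
        raise ValueError(f"unknown criterion {criterion!r}")
    ligand_indices = list(ligand_indices)
    top = ensemble.topology
    lig_ref = Structure([top.atoms[i] for i in ligand_indices])
    ox_local = _qualifying_oxygen_indices(lig_ref)
    ox_global = [ligand_indices[i] for i in ox_local]
    ref_centroid = top.coords[ligand_indices].mean(axis=0)
    idxs = ensemble.analysis_frame_indices(analysis_stride_ns)
    flags, times = [], []
    for fi in idxs:
        fr = ensemble.frames[fi]
        if criterion == "o_cu_distance":
            if not ox_global:
                flags.append(False)
            else:
                d_a = np.linalg.norm(fr[ox_global] - site.cu_a, axis=1)
                d_b = np.linalg.norm(fr[ox_global] - site.cu_b, axis=1)
                flags.append(bool(np.minimum(d_a, d_b).min() <= max_dev))
        else:
            dev = np.linalg.norm(fr[ligand_indices].mean(axis=0) - ref_centroid)
            flags.append(bool(dev <= max_dev))
        times.append(float(ensemble.times_ns[fi]))
    first_fail = next((k for k, ok in enumerate(flags) if not ok), None)
    return BoundResult(
        bound=all(flags),
        frame_flags=flags,
        frame_times_ns=times,
        first_failure_index=first_fail,
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# Interaction-set algebra
# ---------------------------------------------------------------------------

@dataclass
class InteractionMap:
    """Per-substrate residue sets with persistence fractions."""

    substrate_sets: dict
    persistence: dict          # (substrate, residue) -> fraction in [0, 1]
    forced: set = field(default_factory=set)

    @property
    def substrates(self) -> list[str]:
        return list(self.substrate_sets)

    @property
    def residue_union(self) -> set:
        out: set = set()
        for s in self.substrate_sets.values():
            out |= s
        return out


def build_interaction_map(
    records_by_substrate: dict,
    n_analysis_frames: int | dict,
    min_persistence: float = 0.0,
    force_include: dict | None = None,
) -> InteractionMap:
    """Reduce per-substrate interaction records to residue sets.

    A residue enters a substrate's set when it has qualifying records in
    more than ``min_persistence`` of the analysis frames (default 0: any
    frame suffices).  ``force_include`` maps substrate -> residues added
    regardless of records (e.g. copper-coordinating histidines that frame
    the site without touching the ligand).
    """
    if not records_by_substrate:
        raise ValueError("at least one substrate required")
    sets: dict = {}
    persistence: dict = {}
    forced: set = set()
    for substrate, records in records_by_substrate.items():
        nf = (n_analysis_frames[substrate]
              if isinstance(n_analysis_frames, dict) else n_analysis_frames)
        frames_per_res: dict = {}
        for r in records:
            frames_per_res.setdefault(r.residue, set()).add(r.frame_ns)
        members = set()
        for res, frames in frames_per_res.items():
            frac = len(frames) / nf
            persistence[(substrate, res)] = frac
            if frac > min_persistence:
                members.add(res)
        if force_include:
            for res in force_include.get(substrate, ()):
                if res not in members:
                    members.add(res)
                    persistence.setdefault((substrate, res), 0.0)
                    forced.add((substrate, res))
        sets[substrate] = members
    return InteractionMap(substrate_sets=sets, persistence=persistence,
                          forced=forced)


@dataclass
class UniversalSpecific:
    universal: set
    specific: dict     # substrate -> residues engaged by that substrate only
    shared: dict       # frozenset of substrates (2 <= k < all) -> residues


def classify_universal_specific(imap: InteractionMap) -> UniversalSpecific:
    """Partition the residue union into universal / specific / shared groups.

    universal: residues in every substrate's set; specific: in exactly one;
    shared: everything else, keyed by its substrate-combination signature.
    The three groups partition the union exactly.
    """
    subs = imap.substrates
    if len(subs) < 2:
        raise ValueError("universal/specific classification needs >= 2 substrates")
    universal = set.intersection(*(imap.substrate_sets[s] for s in subs))
    specific = {s: set() for s in subs}
    shared: dict = {}
    for res in imap.residue_union:
        signature = frozenset(
            s for s in subs if res in imap.substrate_sets[s]
        )
        if len(signature) == len(subs):
            continue
        if len(signature) == 1:
            specific[next(iter(signature))].add(res)
        else:
            shared.setdefault(signature, set()).add(res)
    return UniversalSpecific(universal=universal, specific=specific,
                             shared=shared)


def copper_proximity_annotation(
    residues,
    site: CopperSite,
    structure: Structure,
    both_margin: float = 1.0,
) -> dict:
    """Label each residue by its nearer copper (minimum heavy-atom distance).

    Residues whose CuA and CuB distances differ by no more than
    ``both_margin`` are labeled ``"both"``; residues not resolvable in the
    structure are ``"unassigned"``.
    """
    label_to_key = {
        structure.residue_label(k): k for k in structure.residues
    }
    out = {}
    for res in residues:
        key = label_to_key.get(res)
        if key is None:
            out[res] = "unassigned"
            continue
        idxs = [
            i for i in structure.residue_atoms(key)
            if not structure.atoms[i].is_hydrogen
        ]
        coords = structure.coords[idxs]
        d_a = float(np.linalg.norm(coords - site.cu_a, axis=1).min())
        d_b = float(np.linalg.norm(coords - site.cu_b, axis=1).min())
        if abs(d_a - d_b) <= both_margin:
            out[res] = "both"
        else:
            out[res] = "CuA" if d_a < d_b else "CuB"
    return out


def records_to_table(records: list[InteractionRecord]):
    """Long-format table of interaction records (one row per record)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "residue": r.residue, "substrate": r.substrate,
            "type": r.interaction_type, "frame_ns": r.frame_ns,
            "distance": r.distance, "angle": r.angle,
        }
        for r in records
    ])


def interaction_map_to_dict(imap: InteractionMap) -> dict:
    """JSON-ready form of a map with its universal/specific/shared groups."""
    out = {
        "substrates": {
            s: sorted(v) for s, v in imap.substrate_sets.items()
        },
        "persistence": {
            f"{s}:{r}": p for (s, r), p in sorted(imap.persistence.items())
        },
        "forced": sorted(f"{s}:{r}" for s, r in imap.forced),
        "residue_union": sorted(imap.residue_union),
    }
    if len(imap.substrates) >= 2:
        cls = classify_universal_specific(imap)
        out["universal"] = sorted(cls.universal)
        out["specific"] = {s: sorted(v) for s, v in cls.specific.items()}
        out["shared"] = {
            "+".join(sorted(sig)): sorted(v) for sig, v in cls.shared.items()
        }
    return out
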