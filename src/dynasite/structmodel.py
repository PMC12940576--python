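"""Coordinate data model, PDB I/O, atom selection and rigid-body superposition.

The package models a protein (or protein-ligand complex) as an ordered list of
atoms grouped into residues, and a conformational ensemble as a topology plus a
stack of coordinate frames sharing the topology's atom order.  All coordinates
are in Angstrom; residue identity follows author numbering so that reported
labels match the literature convention (e.g. H180 ... H390 for the tyrosinase
active site).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "SelectionSpec",
    "FormatError",
    "CongruenceError",
    "DegeneracyError",
    "read_pdb",
    "write_pdb",
    "select",
    "kabsch_superpose",
    "apply_transform",
    "CA_SPEC",
    "HEAVY_SPEC",
]

DEFAULT_STRIDE_NS = 0.25

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class FormatError(ValueError):
    """Raised for unparseable coordinate records; message names the line."""


class CongruenceError(ValueError):
    """Raised when models/frames disagree in atom count or ordering."""


class DegeneracyError(ValueError):
    """Raised when a superposition problem is under-determined."""


@dataclass(frozen=True)
class Atom:
    """One atom with author-numbered residue identity and Angstrom position."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    position: tuple[float, float, float]
    insertion_code: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} has empty element")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} has non-finite position")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


class Structure:
    """Ordered atom list with derived residue grouping.

    Residues are keyed by ``(chain, author residue number, insertion code)``
    and appear in atom order.  ``coords`` is an ``(n_atoms, 3)`` float array.
    """

    def __init__(self, atoms: Sequence[Atom], metadata: dict | None = None):
        atoms = list(atoms)
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in Structure")
        self.atoms = atoms
        self.metadata = dict(metadata or {})
        self._residues: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(atoms):
            self._residues.setdefault(a.residue_key, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Residue key -> atom indices, in atom order."""
        return self._residues

    def residue_atoms(self, key: tuple[str, int, str]) -> list[int]:
        if key not in self._residues:
            raise KeyError(f"residue {key} not in structure")
        return self._residues[key]

    def residue_name(self, key: tuple[str, int, str]) -> str:
        return self.atoms[self._residues[key][0]].residue_name

    def residue_label(self, key: tuple[str, int, str]) -> str:
        """Compact author-numbered label, e.g. ``H367`` for His 367."""
        name = self.residue_name(key)
        one = THREE_TO_ONE.get(name, "X")
        return f"{one}{key[1]}{key[2]}"

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise CongruenceError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            dataclasses.replace(a, position=tuple(xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, metadata=dict(self.metadata))


@dataclass
class Ensemble:
    """A topology plus congruent coordinate frames at strictly increasing times."""

    topology: Structure
    frames: list[np.ndarray]
    times_ns: list[float]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("ensemble needs at least one frame")
        if len(self.frames) != len(self.times_ns):
            raise ValueError("frames and times differ in length")
        n = len(self.topology)
        for k, fr in enumerate(self.frames):
            fr = np.asarray(fr, dtype=float)
            if fr.shape != (n, 3):
                raise CongruenceError(
                    f"frame {k} has shape {fr.shape}, expected ({n}, 3)"
                )
            self.frames[k] = fr
        t = np.asarray(self.times_ns, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def span_ns(self) -> float:
        return float(self.times_ns[-1])

    def frame_structure(self, k: int) -> Structure:
        return self.topology.with_coords(self.frames[k])

    def analysis_frame_indices(self, analysis_stride_ns: float = 1.0) -> list[int]:
        """Frames nearest each analysis tick (stride, 2*stride, ...).

        Ties round toward the earlier frame.  Raises if the stride exceeds the
        trajectory span (no tick falls inside the trajectory).
        """
        if analysis_stride_ns <= 0:
            raise ValueError("analysis stride must be positive")
        times = np.asarray(self.times_ns)
        n_ticks = int(np.floor(self.span_ns / analysis_stride_ns + 1e-9))
        if n_ticks < 1:
            raise ValueError(
                f"analysis stride {analysis_stride_ns} ns exceeds trajectory "
                f"span {self.span_ns} ns"
            )
        out = []
        for j in range(1, n_ticks + 1):
            tick = j * analysis_stride_ns
            d = np.abs(times - tick)
            # ties toward earlier frame: np.argmin returns the first minimum
            out.append(int(np.argmin(d)))
        return out


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection; empty filters match everything."""

    chains: frozenset[str] | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = False
    side_chain_only: bool = False
    include_hetero: bool = True

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_seq <= hi):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.heavy_only and atom.is_hydrogen:
            return False
        if self.side_chain_only and (
            atom.name in BACKBONE_NAMES or atom.is_hydrogen
        ):
            return False
        if not self.include_hetero and atom.is_hetero:
            return False
        return True

    @classmethod
    def parse(cls, text: str) -> "SelectionSpec":
        """Parse a CLI-style selection, e.g. ``chain=A,resi=180-390,atoms=CA``."""
        kwargs: dict = {}
        for part in filter(None, (p.strip() for p in text.split(","))):
            key, _, val = part.partition("=")
            key = key.strip().lower()
            val = val.strip()
            if key == "chain":
                kwargs["chains"] = frozenset(val.split("+"))
            elif key == "resi":
                lo, _, hi = val.partition("-")
                kwargs["residue_range"] = (int(lo), int(hi or lo))
            elif key == "atoms":
                kwargs["atom_names"] = frozenset(val.split("+"))
            elif key == "heavy":
                kwargs["heavy_only"] = val.lower() in ("1", "true", "yes")
            elif key == "hetero":
                kwargs["include_hetero"] = val.lower() in ("1", "true", "yes")
            else:
                raise ValueError(f"unknown selection key {key!r}")
        return cls(**kwargs)


CA_SPEC = SelectionSpec(atom_names=frozenset({"CA"}), include_hetero=False)
HEAVY_SPEC = SelectionSpec(heavy_only=True)


def select(structure: Structure, spec: SelectionSpec) -> list[int]:
    """Indices (topology order) of atoms matched by ``spec``.

    The Cα spec yields one index per amino-acid residue that has a CA atom;
    an empty result is valid.
    """
    out = []
    for i, a in enumerate(structure.atoms):
        if spec.matches(a):
            if spec.atom_names == frozenset({"CA"}) and a.residue_name not in AMINO_ACIDS_3:
                continue  # calcium ions etc. share the CA name
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _prescan_coordinates(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for col in (30, 38, 46):
                fieldtxt = line[col:col + 8].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise FormatError(
                        f"unparseable coordinate field {fieldtxt!r} "
                        f"on line {lineno}"
                    ) from None


def _structure_from_gemmi_model(model: gemmi.Model, metadata: dict) -> Structure:
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            # altloc policy: keep highest occupancy, ties by altloc letter
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                else:
                    key_new = (-at.occ, at.altloc or "~")
                    key_old = (-prev.occ, prev.altloc or "~")
                    if key_new < key_old:
                        by_name[at.name] = at
            for at in res:
                if by_name.get(at.name) is not at:
                    continue
                serial += 1
                atoms.append(Atom(
                    serial=serial,
                    name=at.name,
                    element=at.element.name or "X",
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    chain=chain.name,
                    position=(at.pos.x, at.pos.y, at.pos.z),
                    is_hetero=res.het_flag == "H",
                ))
    return Structure(atoms, metadata=metadata)


def read_pdb(path: str | Path, stride_ns: float = DEFAULT_STRIDE_NS):
    """Read a PDB file into a :class:`Structure` (single MODEL) or
    :class:`Ensemble` (multi-MODEL).

    Multi-MODEL files become ensembles whose frame times follow the saved-
    snapshot convention: the first MODEL is the frame at ``t = stride_ns``
    (t=0 is the reference topology, not a saved frame), so a 20 ns run saved
    every 0.25 ns carries 80 MODELs.
    """
    path = Path(path)
    text = path.read_text()
    _prescan_coordinates(text)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    metadata = {"source": str(path)}
    if len(st) == 0:
        raise FormatError(f"{path}: no coordinate models found")
    if len(st) == 1:
        return _structure_from_gemmi_model(st[0], metadata)
    structures = [_structure_from_gemmi_model(m, metadata) for m in st]
    top = structures[0]
    frames = []
    for k, s in enumerate(structures):
        if len(s) != len(top):
            raise CongruenceError(
                f"{path}: MODEL {k + 1} has {len(s)} atoms, "
                f"MODEL 1 has {len(top)}"
            )
        frames.append(s.coords)
    times = [stride_ns * (k + 1) for k in range(len(frames))]
    return Ensemble(topology=top, frames=frames, times_ns=times)


def _gemmi_from_structure(structure: Structure) -> gemmi.Model:
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    last_res_key = None
    res = None
    for a in structure.atoms:
        ch = chain_map.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chain_map[a.chain] = ch
        if a.residue_key != last_res_key:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_seq, a.insertion_code or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
            last_res_key = a.residue_key
        at = gemmi.Atom()
        at.name = a.name
        at.serial = a.serial
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = 1.0
        res.add_atom(at)
    return model


def write_pdb(obj, path: str | Path) -> None:
    """Write a Structure (single MODEL) or Ensemble (multi-MODEL) as PDB."""
    st = gemmi.Structure()
    st.name = "dynasite"
    if isinstance(obj, Structure):
        st.add_model(_gemmi_from_structure(obj))
    elif isinstance(obj, Ensemble):
        for k in range(obj.n_frames):
            model = _gemmi_from_structure(obj.frame_structure(k))
            model.num = k + 1
            st.add_model(model)
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    st.setup_entities()
    doc_text = st.make_pdb_string()
    Path(path).write_text(doc_text)


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fit_rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the fit
    points.  The rotation is proper (det +1).  Requires at least three
    non-collinear fit points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(len(mobile))
    fit_indices = np.asarray(fit_indices, dtype=int)
    m = mobile[fit_indices]
    r = reference[fit_indices]
    if m.shape != r.shape:
        raise CongruenceError("fit point sets differ in shape")
    if len(m) < 3:
        raise DegeneracyError("superposition needs at least 3 fit points")
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    m0 = m - mc
    r0 = r - rc
    # collinearity check: rank of the centred point cloud
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise DegeneracyError("fit points are collinear")
    H = m0.T @ r0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = m @ R.T + t
    fit_rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return R, t, fit_rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation
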