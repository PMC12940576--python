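"""Idealized templates for the four melanogenic substrates.

Each template carries annotated chemistry for geometric interaction
detection: aromatic ring memberships, hydroxyl/carbonyl oxygens (the atoms
whose copper approach defines a catalytically plausible pose), hydrogen-bond
donors/acceptors, and apolar atoms.  Coordinates are idealized planar
geometries (bond lengths ~1.39 A aromatic, ~1.36 A C-O), not force-field
minimized structures; they serve pose construction and synthetic ensembles,
not energetics.

Codes (PDB residue-name field is three characters):
  TYS  L-tyrosine      monophenol, amino-acid side chain
  LDO  L-DOPA          catechol, amino-acid side chain
  DHC  DHICA           5,6-dihydroxyindole-2-carboxylic acid
  DHI  DHI             5,6-dihydroxyindole
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LigandTemplate", "LIGAND_TEMPLATES", "template_atoms"]

_RING = 1.39    # aromatic C-C, A
_CO = 1.36      # aromatic C-OH, A
_OH = 0.97      # O-H, A


@dataclass(frozen=True)
class LigandTemplate:
    code: str
    atoms: tuple  # (name, element, (x, y, z))
    rings: tuple  # tuples of atom names, one per aromatic cycle
    hydroxyl_oxygens: tuple
    carbonyl_oxygens: tuple = ()
    donors: tuple = ()      # (heavy atom, attached hydrogen or None)
    acceptors: tuple = ()

    @property
    def qualifying_oxygens(self) -> tuple:
        """Hydroxyl plus carbonyl oxygens used in pose validity tests."""
        return self.hydroxyl_oxygens + self.carbonyl_oxygens

    def coords(self, names=None) -> np.ndarray:
        wanted = names if names is not None else [a[0] for a in self.atoms]
        lookup = {a[0]: a[2] for a in self.atoms}
        return np.array([lookup[n] for n in wanted], dtype=float)


def _hexagon(center=(0.0, 0.0), start_deg=0.0):
    """Six ring-carbon positions in the z=0 plane."""
    out = []
    for k in range(6):
        ang = np.deg2rad(start_deg + 60.0 * k)
        out.append((center[0] + _RING * np.cos(ang),
                    center[1] + _RING * np.sin(ang), 0.0))
    return out


def _substituent(ring_pos, center=(0.0, 0.0), bond=_CO):
    """Position extended radially outward from a ring carbon."""
    v = np.array(ring_pos[:2]) - np.array(center)
    v = v / np.linalg.norm(v)
    p = np.array(ring_pos[:2]) + bond * v
    return (p[0], p[1], 0.0)


def _build_phenyl(code: str, second_oh: bool):
    ring = _hexagon()
    names = ["C1", "C2", "C3", "C4", "C5", "C6"]
    atoms = [(n, "C", xyz) for n, xyz in zip(names, ring)]
    # para hydroxyl on C4 (position index 3)
    o1 = _substituent(ring[3])
    atoms.append(("O1", "O", o1))
    atoms.append(("HO1", "H", _substituent(ring[3], bond=_CO + _OH)))
    hydroxyls = ["O1"]
    donors = [("O1", "HO1")]
    if second_oh:
        o2 = _substituent(ring[2])
        atoms.append(("O2", "O", o2))
        atoms.append(("HO2", "H", _substituent(ring[2], bond=_CO + _OH)))
        hydroxyls.append("O2")
        donors.append(("O2", "HO2"))
    # alanyl side chain off C1, bent out of plane
    c1 = np.array(ring[0])
    cb = c1 + np.array([1.2, 0.0, 0.9])
    ca = cb + np.array([1.2, 0.0, 0.9])
    n = ca + np.array([0.4, 1.3, 0.4])
    c = ca + np.array([1.4, -0.6, 0.2])
    o = c + np.array([0.6, -1.0, 0.3])
    oxt = c + np.array([1.1, 0.6, 0.3])
    atoms += [
        ("CB", "C", tuple(cb)), ("CA", "C", tuple(ca)),
        ("N1", "N", tuple(n)), ("C7", "C", tuple(c)),
        ("O3", "O", tuple(o)), ("O4", "O", tuple(oxt)),
    ]
    donors.append(("N1", None))
    acceptors = hydroxyls + ["O3", "O4"]
    return LigandTemplate(
        code=code,
        atoms=tuple(atoms),
        rings=(tuple(names),),
        hydroxyl_oxygens=tuple(hydroxyls),
        carbonyl_oxygens=("O3",),
        donors=tuple(donors),
        acceptors=tuple(acceptors),
    )


def _build_indole(code: str, carboxyl: bool):
    # six-membered ring carrying the 5,6-dihydroxy pattern
    ring6 = _hexagon()
    names6 = ["C1", "C2", "C3", "C4", "C5", "C6"]
    atoms = [(n, "C", xyz) for n, xyz in zip(names6, ring6)]
    # fused five-membered ring sharing the C1-C2 bond
    c1 = np.array(ring6[0])
    c2 = np.array(ring6[1])
    mid = (c1 + c2) / 2.0
    out_dir = mid[:2] / np.linalg.norm(mid[:2])
    bond_dir = (c2 - c1)[:2]
    bond_dir = bond_dir / np.linalg.norm(bond_dir)
    c8 = mid[:2] + 1.9 * out_dir + 0.55 * bond_dir
    n2 = mid[:2] + 1.9 * out_dir - 0.55 * bond_dir
    c9 = mid[:2] + 1.15 * out_dir + 1.15 * bond_dir  # bridge toward C2 side
    atoms.append(("C8", "C", (c8[0], c8[1], 0.0)))
    atoms.append(("N2", "N", (n2[0], n2[1], 0.0)))
    ring5 = ("C1", "C2", "C8", "N2")  # shared edge + apex atoms
    # 5,6-dihydroxy on C4, C5 (para side of the six-ring)
    atoms.append(("O1", "O", _substituent(ring6[3])))
    atoms.append(("HO1", "H", _substituent(ring6[3], bond=_CO + _OH)))
    atoms.append(("O2", "O", _substituent(ring6[4])))
    atoms.append(("HO2", "H", _substituent(ring6[4], bond=_CO + _OH)))
    hydroxyls = ("O1", "O2")
    donors = [("O1", "HO1"), ("O2", "HO2"), ("N2", None)]
    acceptors = ["O1", "O2"]
    carbonyls = ()
    if carboxyl:
        base = np.array(atoms[6][2][:2])  # C8 position: 2-carboxyl
        cdir = base / np.linalg.norm(base)
        c7 = base + 1.5 * cdir
        atoms.append(("C7", "C", (c7[0], c7[1], 0.0)))
        atoms.append(("O3", "O", (c7[0] + 0.7, c7[1] + 1.0, 0.0)))
        atoms.append(("O4", "O", (c7[0] + 0.7, c7[1] - 1.0, 0.0)))
        carbonyls = ("O3",)
        acceptors += ["O3", "O4"]
    return LigandTemplate(
        code=code,
        atoms=tuple(atoms),
        rings=(tuple(names6), ring5),
        hydroxyl_oxygens=hydroxyls,
        carbonyl_oxygens=carbonyls,
        donors=tuple(donors),
        acceptors=tuple(acceptors),
    )


LIGAND_TEMPLATES: dict[str, LigandTemplate] = {
    "TYS": _build_phenyl("TYS", second_oh=False),
    "LDO": _build_phenyl("LDO", second_oh=True),
    "DHC": _build_indole("DHC", carboxyl=True),
    "DHI": _build_indole("DHI", carboxyl=False),
}

#: Human-readable substrate names for the template codes.
SUBSTRATE_NAMES = {
    "TYS": "L-tyrosine",
    "LDO": "L-DOPA",
    "DHC": "DHICA",
    "DHI": "DHI",
}


def template_atoms(code: str):
    """(name, element, xyz) tuples for a substrate template."""
    try:
        return LIGAND_TEMPLATES[code].atoms
    except KeyError:
        raise KeyError(
            f"unknown ligand code {code!r}; known: {sorted(LIGAND_TEMPLATES)}"
        ) from None
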