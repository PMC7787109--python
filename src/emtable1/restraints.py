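"""Bond/angle restraint dictionary for the 20 standard amino acids.

Ideal values come from two sources: backbone and C-beta items use fixed
Engh-Huber-style constants (shared with the ideal C-beta construction, so
the two are self-consistent), while side-chain bonds and angles are measured
once, at first use, from the idealized residue coordinates of the Chemical
Component Dictionary bundled with biotite. Sigmas are class-based. Peptide
and disulfide links are handled by dedicated records matched on atom names.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

import biotite.structure.info as ccd_info

AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL"
).split()

# Engh-Huber-style backbone ideals (Angstrom / degrees); the C-beta entries
# are identical to the constants used by the ideal C-beta reconstruction.
BACKBONE_BONDS: dict[tuple[str, str], tuple[float, float]] = {
    ("CA", "N"): (1.458, 0.019),
    ("C", "CA"): (1.525, 0.021),
    ("C", "O"): (1.231, 0.020),
    ("C", "OXT"): (1.249, 0.019),
    ("CA", "CB"): (1.536, 0.033),
}
BACKBONE_ANGLES: dict[tuple[str, str, str], tuple[float, float]] = {
    ("C", "CA", "N"): (111.0, 2.8),
    ("CA", "C", "O"): (120.8, 1.7),
    ("CB", "CA", "N"): (110.5, 1.5),
    ("C", "CA", "CB"): (110.1, 1.5),
    ("CA", "C", "OXT"): (117.0, 2.0),
    ("O", "C", "OXT"): (122.2, 2.0),
}

PEPTIDE_BOND = (1.329, 0.014)  # C(i) - N(i+1)
PEPTIDE_ANGLES: dict[tuple[str, str, str], tuple[float, float]] = {
    # keyed (prev-atom(s), link atom order): see link_angle()
    ("CA", "C", "N"): (116.2, 2.0),
    ("O", "C", "N"): (123.0, 1.6),
    ("C", "N", "CA"): (121.7, 1.8),
}
DISULFIDE_BOND = (2.033, 0.08)  # SG - SG

SIDECHAIN_BOND_SIGMA = 0.02
SIDECHAIN_ANGLE_SIGMA = 2.0


@dataclass(frozen=True)
class BondRecord:
    atoms: tuple[str, str]
    ideal: float  # Angstrom
    sigma: float


@dataclass(frozen=True)
class AngleRecord:
    atoms: tuple[str, str, str]  # central atom second
    ideal: float  # degrees
    sigma: float


def _bond_key(a1: str, a2: str) -> tuple[str, str]:
    return (a1, a2) if a1 <= a2 else (a2, a1)


def _angle_key(a1: str, center: str, a3: str) -> tuple[str, str, str]:
    lo, hi = (a1, a3) if a1 <= a3 else (a3, a1)
    return (lo, center, hi)


def _angle_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    u = p1 - p2
    v = p3 - p2
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@lru_cache(maxsize=None)
def _ccd_geometry(resname: str):
    """Heavy-atom bond list and measured ideal bonds/angles for one residue."""
    try:
        atoms = ccd_info.residue(resname)
        bond_dict = ccd_info.bonds_in_residue(resname)
    except KeyError:
        return None
    coords = {}
    heavy = set()
    for i in range(atoms.array_length()):
        name = atoms.atom_name[i]
        coords[name] = np.asarray(atoms.coord[i], dtype=float)
        if atoms.element[i] not in ("H", "D"):
            heavy.add(name)

    bonds: list[tuple[str, str]] = []
    neighbors: dict[str, set[str]] = {a: set() for a in heavy}
    for (a1, a2) in bond_dict:
        if a1 in heavy and a2 in heavy:
            bonds.append(_bond_key(a1, a2))
            neighbors[a1].add(a2)
            neighbors[a2].add(a1)

    bond_ideals: dict[tuple[str, str], float] = {
        key: float(np.linalg.norm(coords[key[0]] - coords[key[1]])) for key in bonds
    }
    angle_ideals: dict[tuple[str, str, str], float] = {}
    for center, nbrs in neighbors.items():
        nbrs = sorted(nbrs)
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                key = _angle_key(nbrs[i], center, nbrs[j])
                angle_ideals[key] = _angle_deg(
                    coords[nbrs[i]], coords[center], coords[nbrs[j]]
                )
    return bonds, bond_ideals, angle_ideals


class RestraintDictionary:
    """Lookup of ideal bond lengths and bond angles per residue name."""

    def __init__(self) -> None:
        self._cache: dict[str, tuple | None] = {}

    def _entry(self, resname: str):
        resname = resname.upper()
        if resname not in self._cache:
            self._cache[resname] = _ccd_geometry(resname)
        return self._cache[resname]

    def covers(self, resname: str) -> bool:
        return self._entry(resname) is not None

    def residue_bonds(self, resname: str) -> list[tuple[str, str]]:
        """Heavy-atom template bonds (empty for unknown residues)."""
        entry = self._entry(resname)
        return list(entry[0]) if entry else []

    def bond(self, resname: str, a1: str, a2: str) -> BondRecord | None:
        key = _bond_key(a1, a2)
        if key in BACKBONE_BONDS and resname.upper() in AMINO_ACIDS:
            ideal, sigma = BACKBONE_BONDS[key]
            return BondRecord(key, ideal, sigma)
        entry = self._entry(resname)
        if entry and key in entry[1]:
            return BondRecord(key, entry[1][key], SIDECHAIN_BOND_SIGMA)
        return None

    def angle(self, resname: str, a1: str, center: str, a3: str) -> AngleRecord | None:
        key = _angle_key(a1, center, a3)
        if key in BACKBONE_ANGLES and resname.upper() in AMINO_ACIDS:
            ideal, sigma = BACKBONE_ANGLES[key]
            return AngleRecord(key, ideal, sigma)
        entry = self._entry(resname)
        if entry and key in entry[2]:
            return AngleRecord(key, entry[2][key], SIDECHAIN_ANGLE_SIGMA)
        return None

    @staticmethod
    def peptide_bond() -> BondRecord:
        return BondRecord(("C", "N"), *PEPTIDE_BOND)

    @staticmethod
    def disulfide_bond() -> BondRecord:
        return BondRecord(("SG", "SG"), *DISULFIDE_BOND)

    @staticmethod
    def link_angle(a1: str, center: str, a3: str) -> AngleRecord | None:
        """Peptide-link angle spanning two residues, matched on atom names."""
        for key, (ideal, sigma) in PEPTIDE_ANGLES.items():
            if (a1, center, a3) == key or (a3, center, a1) == key:
                return AngleRecord(key, ideal, sigma)
        return None


@lru_cache(maxsize=1)
def default_dictionary() -> RestraintDictionary:
    return RestraintDictionary()
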