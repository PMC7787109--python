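"""Atomic model I/O: PDB/mmCIF reading, PDB writing, assembly expansion,
and model-composition summaries.

The in-memory model is a plain chains -> residues -> atoms hierarchy carrying
exactly the information the validation metrics need (coordinates, occupancy,
B factors, element) plus the file-level metadata that curation inspects
(unit cell, number of coordinate sets, every resolution value found in the
metadata, assembly operators). Parsing is delegated to gemmi.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

import gemmi

from .errors import InvalidOperatorError, ParseFailureError

#: Three-letter codes treated as protein residues.
PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
       TRP TYR VAL MSE""".split()
)

#: Residue names recognized as water.
WATER_RESIDUES = frozenset({"HOH", "WAT"})


@dataclass
class Atom:
    """A single atom site (one conformer)."""

    name: str
    element: str
    coord: np.ndarray  # orthogonal Angstrom coordinates, shape (3,)
    occupancy: float = 1.0
    b_iso: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    name: str
    seqid: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name.upper() in WATER_RESIDUES

    @property
    def is_protein(self) -> bool:
        return self.name.upper() in PROTEIN_RESIDUES

    @property
    def is_ligand(self) -> bool:
        return not (self.is_protein or self.is_water)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class AssemblyOperator:
    """Rigid transform from the file header (BIOMT / _pdbx_struct_oper_list)."""

    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=1e-9) and np.allclose(
            self.translation, 0.0, atol=1e-9
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


IDENTITY_OPERATOR = AssemblyOperator(np.eye(3), np.zeros(3))


@dataclass
class StructureModel:
    """Hierarchical atom container plus curation-relevant metadata."""

    chains: list[Chain] = field(default_factory=list)
    n_models: int = 1
    cell: tuple[float, float, float, float, float, float] | None = None
    model_resolutions: list[float] = field(default_factory=list)
    assembly_operators: list[AssemblyOperator] = field(default_factory=list)
    label: str = ""

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain, res in self.iter_residues():
            for atom in res.atoms:
                yield chain, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        """All atom coordinates as an (n, 3) array, in hierarchy order."""
        pts = [
            a.coord
            for _, _, a in self.iter_atoms()
            if not (heavy_only and a.is_hydrogen)
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def copy(self) -> "StructureModel":
        chains = [
            Chain(
                c.id,
                [
                    Residue(r.name, r.seqid, r.icode, [replace(a, coord=a.coord.copy()) for a in r.atoms])
                    for r in c.residues
                ],
            )
            for c in self.chains
        ]
        return StructureModel(
            chains=chains,
            n_models=self.n_models,
            cell=self.cell,
            model_resolutions=list(self.model_resolutions),
            assembly_operators=[
                AssemblyOperator(op.rotation.copy(), op.translation.copy())
                for op in self.assembly_operators
            ],
            label=self.label,
        )

    def translate(self, shift: np.ndarray) -> "StructureModel":
        out = self.copy()
        shift = np.asarray(shift, dtype=float)
        for _, _, atom in out.iter_atoms():
            atom.coord += shift
        return out


@dataclass
class CompositionSummary:
    n_chains: int
    n_residues: int
    n_protein_residues: int
    n_ligands: int
    n_waters: int
    n_atoms: int
    single_atom_residue_fraction: float
    b_stats: tuple[float, float, float]  # min, max, mean
    occ_stats: tuple[float, float, float]


# -- resolution metadata ----------------------------------------------------

_PDB_RES_PATTERNS = (
    re.compile(r"RESOLUTION\.\s+(\d+\.?\d*)\s+ANGSTROM"),
    re.compile(r"RESOLUTION RANGE HIGH \(ANGSTROMS\)\s*:\s*(\d+\.?\d*)"),
    re.compile(r"RESOLUTION\s+\(ANGSTROMS?\)\s*:\s*(\d+\.?\d*)"),
)

_CIF_RES_ITEMS = (
    "_em_3d_reconstruction.resolution",
    "_reflns.d_resolution_high",
    "_refine.ls_d_res_high",
)


def _dedupe_resolutions(values: list[float]) -> list[float]:
    """Distinct resolution values (0.01 A agreement collapses duplicates)."""
    out: list[float] = []
    for v in values:
        if v > 0 and not any(abs(v - u) <= 0.01 for u in out):
            out.append(round(v, 4))
    return out


def _resolutions_from_pdb_remarks(remarks: list[str]) -> list[float]:
    found = []
    for line in remarks:
        for pat in _PDB_RES_PATTERNS:
            m = pat.search(line)
            if m:
                found.append(float(m.group(1)))
    return found


def _resolutions_from_cif(path: Path) -> list[float]:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    found = []
    for item in _CIF_RES_ITEMS:
        for raw in block.find_values(item):
            val = gemmi.cif.as_number(raw)
            if val == val:  # not NaN
                found.append(float(val))
    return found


# -- reading ----------------------------------------------------------------


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_model(path: str | Path, format: str = "auto") -> StructureModel:
    """Read an atomic model from a PDB or mmCIF file.

    All distinct resolution values found in the file metadata are collected
    into ``model_resolutions`` (mmCIF reconstruction/refinement items, or
    REMARK 2/3 records for PDB). The first model provides the hierarchy;
    ``n_models`` counts all coordinate sets. For atoms with alternate
    locations only the first-listed conformer per atom name is kept.

    Raises :class:`ParseFailureError` on unreadable input.
    """
    path = Path(path)
    if not path.exists():
        raise ParseFailureError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        coor_format = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
        st = gemmi.read_structure(str(path), format=coor_format)
    except (RuntimeError, ValueError) as exc:
        raise ParseFailureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseFailureError(f"{path}: no coordinate sets found")

    resolutions = [st.resolution] if st.resolution else []
    if fmt == "pdb":
        resolutions += _resolutions_from_pdb_remarks(list(st.raw_remarks))
    else:
        try:
            resolutions += _resolutions_from_cif(path)
        except (RuntimeError, ValueError):
            pass

    cell = None
    if st.cell.is_crystal():
        c = st.cell
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)

    operators = []
    for assembly in st.assemblies:
        for gen in assembly.generators:
            for op in gen.operators:
                operators.append(
                    AssemblyOperator(
                        np.array(op.transform.mat.tolist()),
                        np.array(op.transform.vec.tolist()),
                    )
                )
        break  # first assembly only

    chains = []
    for gchain in st[0]:
        chain = Chain(gchain.name)
        for gres in gchain:
            res = Residue(gres.name, gres.seqid.num, gres.seqid.icode.strip())
            seen: set[str] = set()
            for ga in gres:
                if ga.name in seen:
                    continue  # later-listed alternate conformer
                seen.add(ga.name)
                res.atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        b_iso=ga.b_iso,
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                    )
                )
            chain.residues.append(res)
        chains.append(chain)

    return StructureModel(
        chains=chains,
        n_models=len(st),
        cell=cell,
        model_resolutions=_dedupe_resolutions(resolutions),
        assembly_operators=operators,
        label=path.stem,
    )


# -- writing ----------------------------------------------------------------


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
        st.spacegroup_hm = "P 1"
    if model.model_resolutions:
        st.resolution = model.model_resolutions[0]
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.seqid, res.icode or " ")
            gr.het_flag = "A" if res.is_protein else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                if atom.altloc:
                    ga.altloc = atom.altloc
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: StructureModel, path: str | Path) -> None:
    """Write a model to fixed-column PDB format.

    Coordinates keep PDB precision (1e-3 A). The first model resolution, if
    any, is written as a REMARK 2 record; the cell goes into CRYST1.
    """
    st = _to_gemmi(model)
    st.write_pdb(str(path))


# -- assembly expansion ------------------------------------------------------


def expand_assembly(model: StructureModel) -> StructureModel:
    """Generate the biological assembly from the header operators.

    Each operator produces one copy of every chain; copies are disambiguated
    by appending ``_<operator index>`` to the chain id. A single identity
    operator (or no operators) returns an unchanged copy.
    """
    ops = model.assembly_operators or [IDENTITY_OPERATOR]
    for i, op in enumerate(ops):
        if abs(np.linalg.det(op.rotation)) < 1e-9:
            raise InvalidOperatorError(f"assembly operator {i} is singular")
    if len(ops) == 1 and ops[0].is_identity:
        return model.copy()

    out = model.copy()
    out.chains = []
    for k, op in enumerate(ops):
        for chain in model.chains:
            new_chain = Chain(f"{chain.id}_{k}")
            for res in chain.residues:
                new_res = Residue(res.name, res.seqid, res.icode)
                for atom in res.atoms:
                    new_res.atoms.append(replace(atom, coord=op.apply(atom.coord)))
                new_chain.residues.append(new_res)
            out.chains.append(new_chain)
    out.assembly_operators = [IDENTITY_OPERATOR]
    return out


# -- composition -------------------------------------------------------------


def model_composition(model: StructureModel) -> CompositionSummary:
    """Chain/residue/atom counts, ADP and occupancy statistics.

    Waters are residues named HOH/WAT; ligands are non-polymer, non-water
    residues. The single-atom-residue fraction feeds curation filter
    screening of C-alpha-only (or P-only) models.
    """
    n_residues = n_protein = n_ligand = n_water = n_single = 0
    b_vals: list[float] = []
    occ_vals: list[float] = []
    for _, res in model.iter_residues():
        n_residues += 1
        if res.is_water:
            n_water += 1
        elif res.is_protein:
            n_protein += 1
        else:
            n_ligand += 1
        if len(res.atoms) == 1:
            n_single += 1
        for atom in res.atoms:
            b_vals.append(atom.b_iso)
            occ_vals.append(atom.occupancy)

    def stats(vals: list[float]) -> tuple[float, float, float]:
        if not vals:
            return (0.0, 0.0, 0.0)
        arr = np.asarray(vals)
        return (float(arr.min()), float(arr.max()), float(arr.mean()))

    return CompositionSummary(
        n_chains=len(model.chains),
        n_residues=n_residues,
        n_protein_residues=n_protein,
        n_ligands=n_ligand,
        n_waters=n_water,
        n_atoms=len(b_vals),
        single_atom_residue_fraction=(n_single / n_residues) if n_residues else 0.0,
        b_stats=stats(b_vals),
        occ_stats=stats(occ_vals),
    )
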