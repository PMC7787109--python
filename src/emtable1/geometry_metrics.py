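"""Model-quality (geometry) indicators.

Connectivity is inferred from residue templates plus distance-based peptide
and disulfide links; on top of the bond graph the module computes bond/angle
RMSD and RMSZ against the restraint dictionary, C-beta deviations,
the MolProbity-style clashscore, and the minimum nonbonded distance.
Ramachandran statistics live in :mod:`emtable1.rama`.

Clashscore caveat: the canonical MolProbity clashscore adds hydrogens with
Reduce before scoring, whereas here atoms are scored as given; reports carry
an ``h_present`` flag so the two regimes can be told apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import UndefinedStatisticError
from .restraints import RestraintDictionary, default_dictionary
from .scattering import vdw_radius
from .structure_io import Atom, Chain, Residue, StructureModel

CLASH_OVERLAP_THRESHOLD = 0.4  # Angstrom of vdW sphere overlap
CLASH_MIN_BOND_SEPARATION = 4  # pairs < this many bonds apart never clash
NONBONDED_MIN_BOND_SEPARATION = 3  # 1-2 and 1-3 pairs excluded
CBETA_DEVIATION_THRESHOLD = 0.25  # Angstrom
PEPTIDE_BOND_CUTOFF = 1.8  # C(i)-N(i+1) distance
DISULFIDE_CUTOFF = 2.5  # SG-SG distance

# C-beta ideal construction constants (match the restraint dictionary).
CBETA_BOND = 1.536
CBETA_ANGLE_N = 110.5  # N-CA-CB
CBETA_ANGLE_C = 110.1  # C-CA-CB


# -- small vector helpers ----------------------------------------------------


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
    bond: float, angle_deg: float, dihedral: float,
) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of an atom X bonded to p3.

    X satisfies |X-p3| = bond, angle(X, p3, p2) = angle_deg and
    dihedral(X, p3, p2, p1) = dihedral (degrees).
    """
    ang = np.radians(angle_deg)
    tor = -np.radians(dihedral)  # sign matches dihedral_deg's convention
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def ideal_cbeta_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta inferred from the backbone N, CA, C atoms.

    Solves the two-cone intersection for the direction making the ideal
    N-CA-CB and C-CA-CB angles, taking the L-configuration branch.
    """
    a = n - ca
    a /= np.linalg.norm(a)
    b = c - ca
    b /= np.linalg.norm(b)
    ab = float(np.dot(a, b))
    c1 = np.cos(np.radians(CBETA_ANGLE_N))
    c2 = np.cos(np.radians(CBETA_ANGLE_C))
    det = 1.0 - ab * ab
    alpha = (c1 - ab * c2) / det
    beta = (c2 - ab * c1) / det
    norm2 = alpha**2 + beta**2 + 2 * alpha * beta * ab
    gamma2 = max(1.0 - norm2, 0.0)
    normal = np.cross(a, b)
    normal /= np.linalg.norm(normal)
    direction = alpha * a + beta * b + np.sqrt(gamma2) * normal  # +normal => L
    return ca + CBETA_BOND * direction


# -- flat atom table and bond graph ------------------------------------------


@dataclass
class FlatAtoms:
    """Per-atom flat view of a model, shared by the pairwise metrics."""

    atoms: list[Atom]
    residues: list[Residue]  # parallel: owning residue of each atom
    chains: list[Chain]
    residue_index: list[int]  # global residue ordinal per atom
    coords: np.ndarray

    @classmethod
    def from_model(cls, model: StructureModel) -> "FlatAtoms":
        atoms, residues, chains, res_idx = [], [], [], []
        ordinal = -1
        for chain in model.chains:
            for res in chain.residues:
                ordinal += 1
                for atom in res.atoms:
                    atoms.append(atom)
                    residues.append(res)
                    chains.append(chain)
                    res_idx.append(ordinal)
        coords = np.array([a.coord for a in atoms], dtype=float).reshape(-1, 3)
        return cls(atoms, residues, chains, res_idx, coords)

    def label(self, i: int) -> str:
        return (
            f"{self.chains[i].id}/{self.residues[i].name}"
            f"{self.residues[i].seqid}/{self.atoms[i].name}"
        )


@dataclass
class BondGraph:
    flat: FlatAtoms
    adjacency: list[set[int]]
    #: (i, j, kind) with kind in {template, peptide, disulfide}
    bonds: list[tuple[int, int, str]] = field(default_factory=list)

    def within_bonds(self, max_bonds: int) -> set[tuple[int, int]]:
        """All atom pairs connected by a path of at most ``max_bonds`` bonds."""
        pairs: set[tuple[int, int]] = set()
        for start in range(len(self.adjacency)):
            frontier = {start}
            seen = {start}
            for _ in range(max_bonds):
                nxt = set()
                for u in frontier:
                    nxt |= self.adjacency[u]
                nxt -= seen
                seen |= nxt
                frontier = nxt
            for v in seen:
                if v > start:
                    pairs.add((start, v))
        return pairs


def infer_connectivity(
    model: StructureModel, dictionary: RestraintDictionary | None = None
) -> BondGraph:
    """Build the covalent bond graph.

    Intra-residue bonds come from the residue template; hydrogens (when
    present) attach to the nearest heavy atom of their residue within 1.3 A.
    Consecutive residues in a chain are linked when C(i)-N(i+1) is shorter
    than 1.8 A; cysteine pairs with SG-SG below 2.5 A get a disulfide bond.
    Unknown residues keep their atoms with no template bonds.
    """
    dictionary = dictionary or default_dictionary()
    flat = FlatAtoms.from_model(model)
    n = len(flat.atoms)
    adjacency: list[set[int]] = [set() for _ in range(n)]
    bonds: list[tuple[int, int, str]] = []

    def add_bond(i: int, j: int, kind: str) -> None:
        if j not in adjacency[i]:
            adjacency[i].add(j)
            adjacency[j].add(i)
            bonds.append((min(i, j), max(i, j), kind))

    # intra-residue template bonds
    offset = 0
    residue_slices: list[tuple[Residue, int, int]] = []
    for chain in model.chains:
        for res in chain.residues:
            residue_slices.append((res, offset, offset + len(res.atoms)))
            offset += len(res.atoms)
    for res, lo, hi in residue_slices:
        index_of = {flat.atoms[i].name: i for i in range(lo, hi)}
        for a1, a2 in dictionary.residue_bonds(res.name):
            if a1 in index_of and a2 in index_of:
                add_bond(index_of[a1], index_of[a2], "template")
        # hydrogens by distance (templates above are heavy-atom only)
        for i in range(lo, hi):
            if not flat.atoms[i].is_hydrogen:
                continue
            best, best_d = None, 1.3
            for j in range(lo, hi):
                if flat.atoms[j].is_hydrogen:
                    continue
                d = float(np.linalg.norm(flat.coords[i] - flat.coords[j]))
                if d < best_d:
                    best, best_d = j, d
            if best is not None:
                add_bond(i, best, "template")

    # peptide links between consecutive residues of each chain
    slice_by_ordinal = {k: sl for k, sl in enumerate(residue_slices)}
    ordinal = 0
    for chain in model.chains:
        for r in range(len(chain.residues) - 1):
            res_a, lo_a, hi_a = slice_by_ordinal[ordinal + r]
            res_b, lo_b, hi_b = slice_by_ordinal[ordinal + r + 1]
            c_idx = next((i for i in range(lo_a, hi_a) if flat.atoms[i].name == "C"), None)
            n_idx = next((i for i in range(lo_b, hi_b) if flat.atoms[i].name == "N"), None)
            if c_idx is not None and n_idx is not None:
                if np.linalg.norm(flat.coords[c_idx] - flat.coords[n_idx]) < PEPTIDE_BOND_CUTOFF:
                    add_bond(c_idx, n_idx, "peptide")
        ordinal += len(chain.residues)

    # disulfides
    sg = [i for i in range(n) if flat.atoms[i].name == "SG" and flat.residues[i].name == "CYS"]
    for ii in range(len(sg)):
        for jj in range(ii + 1, len(sg)):
            i, j = sg[ii], sg[jj]
            if np.linalg.norm(flat.coords[i] - flat.coords[j]) < DISULFIDE_CUTOFF:
                add_bond(i, j, "disulfide")

    return BondGraph(flat, adjacency, bonds)


# -- bond/angle RMSD and RMSZ ------------------------------------------------


@dataclass
class RmsStats:
    rmsd_bonds: float
    rmsd_angles: float
    rmsz_bonds: float
    rmsz_angles: float
    n_bonds: int
    n_angles: int
    n_unmatched_bonds: int
    n_unmatched_angles: int


def geometry_rmsd_rmsz(
    model: StructureModel, dictionary: RestraintDictionary | None = None,
    graph: BondGraph | None = None,
) -> RmsStats:
    """RMS deviation and RMS Z-score of bonds and angles vs dictionary ideals.

    Bonds and angles without a dictionary record (ligands, hydrogens,
    link geometry not covered by the peptide records) are skipped and
    reported in the unmatched counts.
    """
    dictionary = dictionary or default_dictionary()
    graph = graph or infer_connectivity(model, dictionary)
    flat = graph.flat

    bond_devs, bond_z = [], []
    unmatched_bonds = 0
    for i, j, kind in graph.bonds:
        if flat.atoms[i].is_hydrogen or flat.atoms[j].is_hydrogen:
            unmatched_bonds += 1
            continue
        if kind == "peptide":
            rec = dictionary.peptide_bond()
        elif kind == "disulfide":
            rec = dictionary.disulfide_bond()
        else:
            rec = dictionary.bond(flat.residues[i].name, flat.atoms[i].name, flat.atoms[j].name)
        if rec is None:
            unmatched_bonds += 1
            continue
        obs = float(np.linalg.norm(flat.coords[i] - flat.coords[j]))
        bond_devs.append(obs - rec.ideal)
        bond_z.append((obs - rec.ideal) / rec.sigma)

    angle_devs, angle_z = [], []
    unmatched_angles = 0
    for center in range(len(flat.atoms)):
        nbrs = sorted(graph.adjacency[center])
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                if any(flat.atoms[t].is_hydrogen for t in (i, center, k)):
                    continue
                same_res = flat.residue_index[i] == flat.residue_index[center] == flat.residue_index[k]
                if same_res:
                    rec = dictionary.angle(
                        flat.residues[center].name,
                        flat.atoms[i].name, flat.atoms[center].name, flat.atoms[k].name,
                    )
                else:
                    rec = dictionary.link_angle(
                        flat.atoms[i].name, flat.atoms[center].name, flat.atoms[k].name
                    )
                if rec is None:
                    unmatched_angles += 1
                    continue
                u = flat.coords[i] - flat.coords[center]
                v = flat.coords[k] - flat.coords[center]
                obs = float(np.degrees(np.arccos(np.clip(
                    np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0))))
                angle_devs.append(obs - rec.ideal)
                angle_z.append((obs - rec.ideal) / rec.sigma)

    if not bond_devs and not angle_devs:
        raise UndefinedStatisticError("no matchable bond or angle restraints")

    def rms(vals: list[float]) -> float:
        return float(np.sqrt(np.mean(np.square(vals)))) if vals else 0.0

    return RmsStats(
        rmsd_bonds=rms(bond_devs), rmsd_angles=rms(angle_devs),
        rmsz_bonds=rms(bond_z), rmsz_angles=rms(angle_z),
        n_bonds=len(bond_devs), n_angles=len(angle_devs),
        n_unmatched_bonds=unmatched_bonds, n_unmatched_angles=unmatched_angles,
    )


# -- C-beta deviations -------------------------------------------------------


@dataclass
class CbetaResult:
    count: int
    deviations: list[tuple[str, int, float]]  # (chain, seqid, deviation)
    n_skipped: int  # residues missing a backbone atom


def cbeta_deviations(model: StructureModel) -> CbetaResult:
    """Distance of each observed C-beta from its backbone-implied ideal spot.

    Residues whose deviation exceeds 0.25 A are counted; residues missing
    any of N, CA, C, CB are skipped and reported.
    """
    deviations = []
    skipped = 0
    for chain, res in model.iter_residues():
        if not res.is_protein or res.name == "GLY":
            continue
        needed = {name: res.atom(name) for name in ("N", "CA", "C", "CB")}
        if any(a is None for a in needed.values()):
            skipped += 1
            continue
        ideal = ideal_cbeta_position(
            needed["N"].coord, needed["CA"].coord, needed["C"].coord
        )
        dev = float(np.linalg.norm(needed["CB"].coord - ideal))
        deviations.append((chain.id, res.seqid, dev))
    count = sum(1 for _, _, d in deviations if d > CBETA_DEVIATION_THRESHOLD)
    return CbetaResult(count=count, deviations=deviations, n_skipped=skipped)


# -- clashscore and minimum nonbonded distance -------------------------------


@dataclass
class ClashResult:
    clashscore: float  # clashes per 1000 atoms
    clashes: list[tuple[str, str, float]]  # (atom label, atom label, overlap)
    n_atoms: int
    h_present: bool


def clashscore(model: StructureModel, graph: BondGraph | None = None) -> ClashResult:
    """Pairs of vdW spheres overlapping by more than 0.4 A, per 1000 atoms.

    Pairs fewer than four bonds apart in the connectivity graph are exempt.
    All atoms present (hydrogens included, when deposited) enter both the
    pair scan and the per-1000-atom normalization.
    """
    graph = graph or infer_connectivity(model)
    flat = graph.flat
    n = len(flat.atoms)
    if n == 0:
        raise UndefinedStatisticError("clashscore undefined for an empty model")
    excluded = graph.within_bonds(CLASH_MIN_BOND_SEPARATION - 1)

    radii = np.array([vdw_radius(a.element) for a in flat.atoms])
    cutoff = 2.0 * radii.max() - CLASH_OVERLAP_THRESHOLD
    tree = cKDTree(flat.coords)
    clashes = []
    for i, j in tree.query_pairs(r=cutoff):
        i, j = (i, j) if i < j else (j, i)
        if (i, j) in excluded:
            continue
        overlap = radii[i] + radii[j] - float(np.linalg.norm(flat.coords[i] - flat.coords[j]))
        if overlap > CLASH_OVERLAP_THRESHOLD:
            clashes.append((flat.label(i), flat.label(j), overlap))
    return ClashResult(
        clashscore=1000.0 * len(clashes) / n,
        clashes=sorted(clashes, key=lambda c: -c[2]),
        n_atoms=n,
        h_present=any(a.is_hydrogen for a in flat.atoms),
    )


@dataclass
class NonbondedResult:
    distance: float
    pair: tuple[str, str]


def min_nonbonded_distance(
    model: StructureModel, graph: BondGraph | None = None
) -> NonbondedResult:
    """Shortest distance between atoms not connected by a 1-2 or 1-3 path."""
    graph = graph or infer_connectivity(model)
    flat = graph.flat
    n = len(flat.atoms)
    if n < 2:
        raise UndefinedStatisticError("minimum nonbonded distance needs >= 2 atoms")
    excluded = graph.within_bonds(NONBONDED_MIN_BOND_SEPARATION - 1)

    tree = cKDTree(flat.coords)
    span = float(np.linalg.norm(flat.coords.max(axis=0) - flat.coords.min(axis=0)))
    radius = 4.0
    best: tuple[float, int, int] | None = None
    while best is None:
        for i, j in tree.query_pairs(r=radius):
            i, j = (i, j) if i < j else (j, i)
            if (i, j) in excluded:
                continue
            d = float(np.linalg.norm(flat.coords[i] - flat.coords[j]))
            if best is None or d < best[0]:
                best = (d, i, j)
        if radius > span:
            break
        radius *= 2.0
    if best is None:
        raise UndefinedStatisticError("no nonbonded atom pair exists")
    return NonbondedResult(distance=best[0], pair=(flat.label(best[1]), flat.label(best[2])))


# -- assembled summary -------------------------------------------------------


@dataclass
class GeometrySummary:
    clashscore: float
    rmsd_bonds: float
    rmsd_angles: float
    rmsz_bonds: float
    rmsz_angles: float
    n_cbeta_dev: int
    min_nonbonded: float
    min_nonbonded_pair: tuple[str, str]
    rama_favored: float
    rama_allowed: float
    rama_outliers: float
    rama_z: float | None
    rama_z_band: str
    h_present: bool
    detail: dict = field(default_factory=dict)


def geometry_summary(
    model: StructureModel,
    dictionary: RestraintDictionary | None = None,
    rama_z_samples: int = 500,
    rama_z_seed: int = 0,
) -> GeometrySummary:
    """Compute the full model-quality block of Table 1."""
    from .rama import RamaReference, rama_z, ramachandran_classify

    dictionary = dictionary or default_dictionary()
    graph = infer_connectivity(model, dictionary)
    rms = geometry_rmsd_rmsz(model, dictionary, graph)
    cbeta = cbeta_deviations(model)
    clash = clashscore(model, graph)
    nonbonded = min_nonbonded_distance(model, graph)
    ref = RamaReference.default()
    rama = ramachandran_classify(model, ref)
    z = rama_z(model, ref, n_samples=rama_z_samples, seed=rama_z_seed)
    return GeometrySummary(
        clashscore=clash.clashscore,
        rmsd_bonds=rms.rmsd_bonds,
        rmsd_angles=rms.rmsd_angles,
        rmsz_bonds=rms.rmsz_bonds,
        rmsz_angles=rms.rmsz_angles,
        n_cbeta_dev=cbeta.count,
        min_nonbonded=nonbonded.distance,
        min_nonbonded_pair=nonbonded.pair,
        rama_favored=rama.favored_pct,
        rama_allowed=rama.allowed_pct,
        rama_outliers=rama.outlier_pct,
        rama_z=z.z if z is not None else None,
        rama_z_band=z.band if z is not None else "not_enough_residues",
        h_present=clash.h_present,
        detail={
            "rms": rms,
            "cbeta": cbeta,
            "clashes": clash.clashes,
            "rama_per_residue": rama.per_residue,
        },
    )
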