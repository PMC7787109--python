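"""Synthetic map/model generator.

Every metric in the toolkit gets a ground-truth target with no downloads:
an ideal poly-alanine helix built from the restraint dictionary's own
ideals, a band-limited Gaussian-atom density map, and two half-maps whose
per-shell noise is calibrated so their FSC crosses 0.143 at a planned
resolution. Defect injection (clashes, C-beta shifts, bond stretches, rigid
shifts, side-chain flips) perturbs exactly one thing at a time, emulating
the pathologies real deposited models exhibit (misplaced side chains,
models shifted relative to their map, steric overlaps).

Fixtures target metric testability, not reconstruction realism: there is no
CTF, no detector physics, no solvent, and noise is injected per Fourier
shell to match the FSC model exactly (Gaussian real-space noise is offered
as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curation import EntryBundle, RejectionCode
from .errors import EmTable1Error, InvalidSpecError
from .geometry_metrics import ideal_cbeta_position, place_atom
from .map_io import DensityMap, MapMetadata, write_map, write_sidecar
from .map_metrics import FSC_THRESHOLD_HALFMAP, _freq_magnitude, lowpass, model_to_map
from .restraints import default_dictionary
from .scattering import ScatteringTable, vdw_radius
from .structure_io import Atom, Chain, Residue, StructureModel, write_model

HELIX_PHI = -57.0
HELIX_PSI = -47.0
HELIX_OMEGA = 180.0
DEFAULT_B = 30.0


def build_polyala(
    n_residues: int,
    phi: float | np.ndarray = HELIX_PHI,
    psi: float | np.ndarray = HELIX_PSI,
) -> StructureModel:
    """Poly-alanine chain with prescribed backbone torsions.

    ``phi``/``psi`` may be scalars or per-residue arrays (phi[i] shapes the
    placement of C(i) relative to residue i-1's carbonyl, psi[i] the next
    amide nitrogen). Bond lengths and angles are the restraint dictionary's
    ideals and every C-beta sits exactly at its ideal reconstructed
    position, so the chain scores zero on all deviation-from-ideal metrics
    by construction. B = 30 A^2 and unit occupancy throughout.
    """
    if n_residues < 3:
        raise ValueError("chain needs at least 3 residues")
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (n_residues,))
    psi_arr = np.broadcast_to(np.asarray(psi, dtype=float), (n_residues,))
    d = default_dictionary()
    b_nca = d.bond("ALA", "N", "CA").ideal
    b_cac = d.bond("ALA", "CA", "C").ideal
    b_co = d.bond("ALA", "C", "O").ideal
    b_cn = d.peptide_bond().ideal
    a_ncac = d.angle("ALA", "N", "CA", "C").ideal
    a_caco = d.angle("ALA", "CA", "C", "O").ideal
    a_cacn = d.link_angle("CA", "C", "N").ideal
    a_cnca = d.link_angle("C", "N", "CA").ideal

    # backbone by internal coordinates
    n0 = np.zeros(3)
    ca0 = np.array([b_nca, 0.0, 0.0])
    ang = np.radians(a_ncac)
    c0 = ca0 + b_cac * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [(n0, ca0, c0)]
    for i in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_new = place_atom(n_prev, ca_prev, c_prev, b_cn, a_cacn, psi_arr[i - 1])
        ca_new = place_atom(ca_prev, c_prev, n_new, b_nca, a_cnca, HELIX_OMEGA)
        c_new = place_atom(c_prev, n_new, ca_new, b_cac, a_ncac, phi_arr[i])
        backbone.append((n_new, ca_new, c_new))

    chain = Chain("A")
    for i, (n, ca, c) in enumerate(backbone):
        # carbonyl O anti to the next amide N (planar peptide): the psi+180
        # dihedral makes O-C-N(i+1) equal 360 - (CA-C-O) - (CA-C-N) = 123.0
        o = place_atom(n, ca, c, b_co, a_caco, psi_arr[i] + 180.0)
        cb = ideal_cbeta_position(n, ca, c)
        res = Residue("ALA", i + 1)
        for name, elem, xyz in (
            ("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o), ("CB", "C", cb),
        ):
            res.atoms.append(Atom(name, elem, xyz.copy(), 1.0, DEFAULT_B))
        chain.residues.append(res)
    return StructureModel(chains=[chain])


def build_helix(n_residues: int) -> StructureModel:
    """Ideal poly-alanine alpha-helix (phi=-57, psi=-47, omega=180)."""
    return build_polyala(n_residues, HELIX_PHI, HELIX_PSI)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic entry."""

    n_residues: int = 20
    box: float = 40.0  # cubic box edge, Angstrom
    voxel: float = 1.0  # Angstrom
    target_d: float | None = 4.0  # planned FSC 0.143 crossing; None = no noise
    noise_seed: int = 0
    defects: list[tuple[str, dict]] = field(default_factory=list)
    noise_mode: str = "shell"  # "shell" (Fourier, matches FSC model) or "real"
    fsc_slope: float = 8.0  # sharpness of the planned SNR fall-off

    def validate(self) -> None:
        if self.target_d is not None and self.voxel > self.target_d / 2.0:
            raise InvalidSpecError(
                f"voxel {self.voxel} A violates Nyquist for target_d {self.target_d} A"
            )
        if self.box < 4 * self.voxel:
            raise InvalidSpecError("box too small for its voxel size")


def _shell_noise(
    shape: tuple[int, int, int],
    cell,
    signal: np.ndarray,
    target_d: float,
    slope: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Real-space noise whose per-shell power makes the expected half-map
    FSC equal lambda/(lambda+1) with lambda crossing 0.143/(1-0.143) at
    s* = 1/target_d."""
    s = _freq_magnitude(shape, cell)
    F_sig = np.fft.fftn(signal)
    power = np.abs(F_sig) ** 2
    power.flat[0] = 0.0  # DC is the mean, not signal contrast

    n_shells = max(shape) // 2
    s_max = float(s.max())
    edges = np.linspace(0.0, s_max * (1 + 1e-9), n_shells + 1)
    idx = np.clip(np.digitize(s.ravel(), edges) - 1, 0, n_shells - 1)
    shell_power = np.bincount(idx, weights=power.ravel(), minlength=n_shells)
    shell_count = np.bincount(idx, minlength=n_shells)
    mean_power = np.divide(
        shell_power, shell_count, out=np.zeros(n_shells), where=shell_count > 0
    )

    s_star = 1.0 / target_d
    lam_star = FSC_THRESHOLD_HALFMAP / (1.0 - FSC_THRESHOLD_HALFMAP)
    centers = (edges[:-1] + edges[1:]) / 2.0
    lam = lam_star * np.exp(slope * (s_star - centers) / s_star)
    noise_power = np.divide(mean_power, lam, out=np.zeros(n_shells), where=lam > 0)

    white = np.fft.fftn(rng.standard_normal(shape))
    scale = np.sqrt(noise_power / np.prod(shape))[idx].reshape(shape)
    scale.flat[0] = 0.0
    return np.fft.ifftn(white * scale).real


def synthesize_entry(model: StructureModel, spec: FixtureSpec) -> EntryBundle:
    """Build a complete synthetic entry: model + full map + half-maps + metadata.

    The model is centered in a cubic box and a Gaussian-atom density is
    computed from it; the two half-maps add independent noise draws whose
    per-shell amplitude plants the FSC 0.143 crossing at ``spec.target_d``;
    the deposited full map is the half-map average. Metadata (model and map
    side) reports the planned resolution, so the clean fixture passes
    curation. Deterministic given ``spec.noise_seed``.
    """
    spec.validate()
    n = int(round(spec.box / spec.voxel))
    cell = (spec.box, spec.box, spec.box, 90.0, 90.0, 90.0)
    template = DensityMap(np.zeros((n, n, n), dtype=np.float32), cell)

    model = model.copy()
    for kind, params in spec.defects:
        model = plant_defect(model, kind, **params)
    centroid = model.coords().mean(axis=0)
    model = model.translate(np.array([spec.box / 2] * 3) - centroid)
    model.cell = cell
    reported = spec.target_d if spec.target_d is not None else 4.0
    model.model_resolutions = [reported]

    table = ScatteringTable()
    signal = model_to_map(model, template, d_min=None, table=table)

    if spec.target_d is None:
        half1 = signal.copy()
        half2 = signal.copy()
    else:
        rng = np.random.default_rng(spec.noise_seed)
        if spec.noise_mode == "shell":
            noise1 = _shell_noise(signal.grid.shape, cell, signal.grid.astype(float),
                                  spec.target_d, spec.fsc_slope, rng)
            noise2 = _shell_noise(signal.grid.shape, cell, signal.grid.astype(float),
                                  spec.target_d, spec.fsc_slope, rng)
        elif spec.noise_mode == "real":
            sd = signal.grid.std()
            noise1 = sd * rng.standard_normal(signal.grid.shape)
            noise2 = sd * rng.standard_normal(signal.grid.shape)
        else:
            raise InvalidSpecError(f"unknown noise_mode {spec.noise_mode!r}")
        half1 = signal.copy()
        half1.grid = (signal.grid + noise1).astype(np.float32)
        half2 = signal.copy()
        half2.grid = (signal.grid + noise2).astype(np.float32)

    # the deposited map is the half-map average, low-passed at the nominal
    # resolution as reconstruction packages do before deposition
    full = signal.copy()
    full.grid = ((half1.grid + half2.grid) / 2.0).astype(np.float32)
    if spec.target_d is not None:
        full = lowpass(full, spec.target_d)

    return EntryBundle(
        model=model,
        map=full,
        map_metadata=MapMetadata([reported], source="fixture"),
        half_maps=(half1, half2),
        labels=f"fixture-{spec.n_residues}res-{spec.target_d}A-seed{spec.noise_seed}",
    )


def make_entry(spec: FixtureSpec) -> EntryBundle:
    """Convenience: helix of ``spec.n_residues`` fed through synthesize_entry."""
    return synthesize_entry(build_helix(spec.n_residues), spec)


# -- defect injection --------------------------------------------------------


def plant_defect(model: StructureModel, kind: str, **params) -> StructureModel:
    """Apply exactly one perturbation; all other atoms stay bit-identical.

    Kinds: ``clash`` (plant a single steric overlap of ``overlap`` A),
    ``cbeta_shift`` (move one C-beta by ``distance`` A), ``bond_stretch``
    (lengthen one carbonyl C-O bond by ``delta`` A), ``rigid_shift``
    (translate the whole model), ``sidechain_flip`` (rotate one C-beta
    about the N-CA axis by ``angle`` degrees).
    """
    out = model.copy()
    handlers = {
        "clash": _defect_clash,
        "cbeta_shift": _defect_cbeta_shift,
        "bond_stretch": _defect_bond_stretch,
        "rigid_shift": _defect_rigid_shift,
        "sidechain_flip": _defect_sidechain_flip,
    }
    if kind not in handlers:
        raise ValueError(f"unknown defect kind {kind!r}")
    handlers[kind](out, **params)
    return out


def _find_residue(model: StructureModel, res_index: int) -> Residue:
    count = 0
    for _, res in model.iter_residues():
        if count == res_index:
            return res
        count += 1
    raise EmTable1Error(f"residue index {res_index} not found")


def _defect_clash(model: StructureModel, res_index: int = 0, overlap: float = 0.5) -> None:
    """Add a lone oxygen overlapping one CB by exactly ``overlap`` A."""
    res = _find_residue(model, res_index)
    target = res.atom("CB") or res.atoms[-1]
    anchor = res.atom("CA")
    if anchor is not None and anchor is not target:
        direction = target.coord - anchor.coord  # outward along CA->CB
    else:
        direction = target.coord - model.coords().mean(axis=0)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    dist = vdw_radius("O") + vdw_radius(target.element) - overlap
    pos = target.coord + dist * direction
    model.chains.append(
        Chain("Z", [Residue("HOH", 1, atoms=[Atom("O", "O", pos, 1.0, DEFAULT_B)])])
    )


def _defect_cbeta_shift(model: StructureModel, res_index: int = 0, distance: float = 0.3) -> None:
    res = _find_residue(model, res_index)
    cb = res.atom("CB")
    ca = res.atom("CA")
    if cb is None or ca is None:
        raise EmTable1Error(f"residue {res_index} lacks CA/CB")
    direction = cb.coord - ca.coord
    cb.coord = cb.coord + distance * direction / np.linalg.norm(direction)


def _defect_bond_stretch(model: StructureModel, res_index: int = 0, delta: float = 0.02) -> None:
    """Move the carbonyl O radially along C->O (bond length changes; the O
    direction, hence the angles at C, does not)."""
    res = _find_residue(model, res_index)
    o = res.atom("O")
    c = res.atom("C")
    if o is None or c is None:
        raise EmTable1Error(f"residue {res_index} lacks C/O")
    direction = o.coord - c.coord
    o.coord = o.coord + delta * direction / np.linalg.norm(direction)


def _defect_rigid_shift(model: StructureModel, shift: float = 2.0, axis=(1.0, 0.0, 0.0)) -> None:
    vec = shift * np.asarray(axis, dtype=float) / np.linalg.norm(axis)
    for _, _, atom in model.iter_atoms():
        atom.coord += vec


def _defect_sidechain_flip(model: StructureModel, res_index: int = 0, angle: float = 120.0) -> None:
    """Rotate CB about the N-CA axis, swinging it out of its own density."""
    res = _find_residue(model, res_index)
    n, ca, cb = res.atom("N"), res.atom("CA"), res.atom("CB")
    if n is None or ca is None or cb is None:
        raise EmTable1Error(f"residue {res_index} lacks N/CA/CB")
    axis = n.coord - ca.coord
    axis /= np.linalg.norm(axis)
    theta = np.radians(angle)
    v = cb.coord - ca.coord
    # Rodrigues rotation
    rotated = (
        v * np.cos(theta)
        + np.cross(axis, v) * np.sin(theta)
        + axis * np.dot(axis, v) * (1 - np.cos(theta))
    )
    cb.coord = ca.coord + rotated


# -- curation presets --------------------------------------------------------

CURATION_PRESETS = (
    "clean",
    "NO_MODEL",
    "RESOLUTION_MISMATCH",
    "HALFMAP_GRID_MISMATCH",
    "BOX_MISMATCH",
    "PROCESS_FAILURE",
    "ENSEMBLE_MODEL",
    "SINGLE_ATOM_FRACTION",
    "RESOLUTION_TOO_LOW",
)


def curation_preset(name: str, seed: int = 0) -> EntryBundle:
    """A small bundle violating exactly the named admission filter.

    ``clean`` yields a bundle that passes every filter.
    """
    if name not in CURATION_PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {CURATION_PRESETS}")
    spec = FixtureSpec(n_residues=8, box=24.0, voxel=1.5, target_d=4.0, noise_seed=seed)
    bundle = make_entry(spec)

    if name == "clean":
        return bundle
    if name == "NO_MODEL":
        bundle.model = None
    elif name == "RESOLUTION_MISMATCH":
        # the 4 vs 6 A situation: map metadata and model metadata disagree
        bundle.model.model_resolutions = [6.0]
        bundle.map_metadata = MapMetadata([4.0], source="fixture")
    elif name == "HALFMAP_GRID_MISMATCH":
        h1, h2 = bundle.half_maps
        shrunk = DensityMap(h2.grid[:-2, :-2, :-2].copy(), h2.cell)
        bundle.half_maps = (h1, shrunk)
    elif name == "BOX_MISMATCH":
        # degenerate 1 A model cell against a real map box
        bundle.model.cell = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    elif name == "PROCESS_FAILURE":
        bundle.load_errors.append("synthetic parse failure")
    elif name == "ENSEMBLE_MODEL":
        bundle.model.n_models = 2
    elif name == "SINGLE_ATOM_FRACTION":
        # strip 30% of residues down to a lone C-alpha
        chain = bundle.model.chains[0]
        n_strip = int(np.ceil(0.30 * len(chain.residues)))
        for res in chain.residues[:n_strip]:
            res.atoms = [a for a in res.atoms if a.name == "CA"]
    elif name == "RESOLUTION_TOO_LOW":
        bundle.model.model_resolutions = [5.2]
        bundle.map_metadata = MapMetadata([5.2], source="fixture")
    return bundle


PRESET_EXPECTED: dict[str, RejectionCode | None] = {
    "clean": None,
    **{name: RejectionCode[name] for name in CURATION_PRESETS if name != "clean"},
}


# -- bundle export -----------------------------------------------------------


def write_bundle(bundle: EntryBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle to disk as PDB + three MRC maps + sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    if bundle.model is not None:
        paths["model"] = directory / "model.pdb"
        write_model(bundle.model, paths["model"])
    paths["map"] = directory / "map.mrc"
    write_map(bundle.map, paths["map"])
    if bundle.half_maps is not None:
        for i, half in enumerate(bundle.half_maps):
            paths[f"half{i + 1}"] = directory / f"half{i + 1}.mrc"
            write_map(half, paths[f"half{i + 1}"])
    paths["sidecar"] = directory / "sidecar.json"
    write_sidecar(bundle.map_metadata, paths["sidecar"])
    return paths
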