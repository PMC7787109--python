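"""Geometry indicators: connectivity, RMSD/RMSZ, C-beta, clashes, Ramachandran."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from emtable1.errors import UndefinedStatisticError
from emtable1.fixtures import build_helix, build_polyala, plant_defect
from emtable1.geometry_metrics import (
    CLASH_OVERLAP_THRESHOLD,
    cbeta_deviations,
    clashscore,
    geometry_rmsd_rmsz,
    infer_connectivity,
    min_nonbonded_distance,
)
from emtable1.rama import RamaReference, backbone_dihedrals, rama_z, ramachandran_classify
from emtable1.scattering import vdw_radius
from emtable1.structure_io import Atom, Chain, Residue, StructureModel


def _single_ala(offset=np.zeros(3)):
    helix = build_helix(3)
    res = helix.chains[0].residues[0]
    atoms = [Atom(a.name, a.element, a.coord + offset, 1.0, 30.0) for a in res.atoms]
    return Residue("ALA", 1, atoms=atoms)


def _random_rigid_copy(model, seed=5):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
    shift = rng.normal(scale=15.0, size=3)
    out = model.copy()
    for _, _, atom in out.iter_atoms():
        atom.coord = rot @ atom.coord + shift
    return out


class TestConnectivity:
    def test_single_ala_template_bonds(self):
        model = StructureModel(chains=[Chain("A", [_single_ala()])])
        graph = infer_connectivity(model)
        assert len(graph.bonds) == 4  # N-CA, CA-C, C-O, CA-CB

    def test_dipeptide_has_peptide_link(self):
        model = build_helix(3)
        model.chains[0].residues = model.chains[0].residues[:2]
        graph = infer_connectivity(model)
        kinds = [k for _, _, k in graph.bonds]
        assert len(graph.bonds) == 9
        assert kinds.count("peptide") == 1

    def test_distant_residues_not_linked(self):
        res1 = _single_ala()
        res2 = _single_ala(offset=np.array([10.0, 0.0, 0.0]))
        res2.seqid = 2
        model = StructureModel(chains=[Chain("A", [res1, res2])])
        graph = infer_connectivity(model)
        assert all(k == "template" for _, _, k in graph.bonds)


class TestRmsdRmsz:
    def test_ideal_helix_scores_zero(self, helix10):
        rms = geometry_rmsd_rmsz(helix10)
        assert rms.rmsd_bonds < 1e-9
        assert rms.rmsd_angles < 1e-9
        assert rms.rmsz_bonds < 1e-9
        assert rms.n_unmatched_bonds == 0

    def test_single_stretched_bond_arithmetic(self, helix10):
        delta = 0.02
        stretched = plant_defect(helix10, "bond_stretch", res_index=4, delta=delta)
        rms = geometry_rmsd_rmsz(stretched)
        assert rms.rmsd_bonds == pytest.approx(delta / np.sqrt(rms.n_bonds), rel=1e-6)
        # moving O radially leaves every bonded direction unchanged
        assert rms.rmsd_angles < 1e-9

    def test_rmsz_approaches_one_under_sigma_noise(self):
        """Perturbing every carbonyl O radially by N(0, sigma_CO) drives the
        C-O z-scores to unit RMS; the remaining bonds stay ideal, so
        rmsz_bonds -> sqrt(n_CO / n_bonds)."""
        model = build_polyala(120)
        d_sigma = 0.020  # sigma of the C-O record
        rng = np.random.default_rng(11)
        for _, res in model.iter_residues():
            c, o = res.atom("C"), res.atom("O")
            direction = (o.coord - c.coord) / np.linalg.norm(o.coord - c.coord)
            o.coord = o.coord + rng.normal(0.0, d_sigma) * direction
        rms = geometry_rmsd_rmsz(model)
        n_co = 120
        expected = np.sqrt(n_co / rms.n_bonds)
        assert rms.rmsz_bonds == pytest.approx(expected, rel=0.15)
        assert rms.rmsz_angles < 1e-9

    def test_no_restraints_raises(self):
        model = StructureModel(chains=[Chain("A", [
            Residue("UNK", 1, atoms=[Atom("X1", "C", np.zeros(3)),
                                     Atom("X2", "C", np.array([1.5, 0, 0]))])
        ])])
        with pytest.raises(UndefinedStatisticError):
            geometry_rmsd_rmsz(model)


class TestCbeta:
    def test_ideal_helix_all_below_hundredth(self, helix10):
        result = cbeta_deviations(helix10)
        assert result.count == 0
        assert all(d < 0.01 for _, _, d in result.deviations)

    def test_displaced_cbeta_counted(self, helix10):
        shifted = plant_defect(helix10, "cbeta_shift", res_index=3, distance=0.30)
        result = cbeta_deviations(shifted)
        assert result.count == 1
        devs = {seq: d for _, seq, d in result.deviations}
        assert devs[4] == pytest.approx(0.30, abs=1e-6)

    def test_below_threshold_not_counted(self, helix10):
        shifted = plant_defect(helix10, "cbeta_shift", res_index=3, distance=0.20)
        assert cbeta_deviations(shifted).count == 0

    def test_missing_backbone_atom_skipped(self, helix10):
        model = helix10.copy()
        model.chains[0].residues[0].atoms = [
            a for a in model.chains[0].residues[0].atoms if a.name != "N"
        ]
        result = cbeta_deviations(model)
        assert result.n_skipped == 1
        assert len(result.deviations) == 9


class TestClashscore:
    def test_separated_residues_score_zero(self):
        res1 = _single_ala()
        res2 = _single_ala(offset=np.array([15.0, 0.0, 0.0]))
        res2.seqid = 2
        model = StructureModel(chains=[Chain("A", [res1, res2])])
        assert clashscore(model).clashscore == 0.0

    def test_planted_overlap_arithmetic(self, helix10):
        """One planted 0.5 A overlap among n atoms scores 1000/n."""
        clashed = plant_defect(helix10, "clash", res_index=5, overlap=0.5)
        result = clashscore(clashed)
        assert len(result.clashes) == 1
        assert result.clashscore == pytest.approx(1000.0 / clashed.n_atoms)
        assert result.clashes[0][2] == pytest.approx(0.5, abs=1e-9)

    def test_overlap_below_threshold_ignored(self, helix10):
        touched = plant_defect(helix10, "clash", res_index=5, overlap=0.35)
        assert clashscore(touched).clashscore == 0.0

    def test_linearity_matches_brute_force(self, helix20):
        """k disjoint planted clashes score 1000k/n, and the clash pair list
        equals an O(n^2) scan."""
        model = helix20
        for k, res_index in enumerate((2, 8, 14)):
            model = plant_defect(model, "clash", res_index=res_index, overlap=0.6)
        result = clashscore(model)
        assert len(result.clashes) == 3
        assert result.clashscore == pytest.approx(3000.0 / model.n_atoms)
        assert sorted(result.clashes) == sorted(_brute_force_clashes(model))


def _brute_force_clashes(model):
    graph = infer_connectivity(model)
    flat = graph.flat
    excluded = graph.within_bonds(3)
    out = []
    n = len(flat.atoms)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            d = float(np.linalg.norm(flat.coords[i] - flat.coords[j]))
            overlap = vdw_radius(flat.atoms[i].element) + vdw_radius(flat.atoms[j].element) - d
            if overlap > CLASH_OVERLAP_THRESHOLD:
                out.append((flat.label(i), flat.label(j), overlap))
    return out


class TestMinNonbonded:
    def test_hand_enumerated_three_atoms(self):
        # A-B covalently bonded (1.5 A), C 4.0 A from B: eligible pairs are
        # A-C (5.5) and B-C (4.0); the bonded A-B pair is excluded
        res = Residue("LIG", 1, atoms=[
            Atom("C1", "C", np.array([0.0, 0.0, 0.0])),
            Atom("C2", "C", np.array([1.5, 0.0, 0.0])),
            Atom("C3", "C", np.array([5.5, 0.0, 0.0])),
        ])
        model = StructureModel(chains=[Chain("A", [res])])
        graph = infer_connectivity(model)
        graph.adjacency[0].add(1)
        graph.adjacency[1].add(0)
        graph.bonds.append((0, 1, "template"))
        result = min_nonbonded_distance(model, graph)
        assert result.distance == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_points_equal_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 30, size=(100, 3))
        res = Residue("LIG", 1, atoms=[
            Atom(f"C{i}", "C", c) for i, c in enumerate(coords)
        ])
        model = StructureModel(chains=[Chain("A", [res])])
        result = min_nonbonded_distance(model)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert result.distance == pytest.approx(d.min(), abs=1e-12)

    def test_single_atom_rejected(self):
        model = StructureModel(chains=[Chain("A", [
            Residue("LIG", 1, atoms=[Atom("C1", "C", np.zeros(3))])
        ])])
        with pytest.raises(UndefinedStatisticError):
            min_nonbonded_distance(model)


class TestRamachandran:
    def test_ideal_helix_fully_favored(self, helix10):
        result = ramachandran_classify(helix10)
        assert result.favored_pct == 100.0
        assert result.n_scored == 8  # termini have no phi or no psi

    def test_rare_region_is_outlier(self):
        model = build_polyala(12, 80.0, 80.0)
        result = ramachandran_classify(model)
        assert result.outlier_pct == 100.0

    def test_categories_partition(self):
        rng = np.random.default_rng(4)
        ref = RamaReference.default()
        pairs = ref.sample("general", 60, rng)
        model = build_polyala(60, pairs[:, 0], pairs[:, 1])
        result = ramachandran_classify(model)
        assert result.favored_pct + result.allowed_pct + result.outlier_pct == pytest.approx(100.0)

    def test_no_scorable_residue_raises(self):
        model = StructureModel(chains=[Chain("A", [_single_ala()])])
        with pytest.raises(UndefinedStatisticError):
            ramachandran_classify(model)


class TestRamaZ:
    def test_reference_drawn_model_is_ordinary(self):
        rng = np.random.default_rng(8)
        ref = RamaReference.default()
        pairs = ref.sample("general", 50, rng)
        model = build_polyala(50, pairs[:, 0], pairs[:, 1])
        result = rama_z(model, n_samples=300, seed=1)
        assert abs(result.z) < 3.0
        assert result.n_residues == 48

    def test_concentrated_rare_point_strongly_negative(self):
        model = build_polyala(20, 80.0, 80.0)
        result = rama_z(model, n_samples=300, seed=1)
        assert result.z < -3.0
        assert result.band == "poor"

    def test_too_few_residues_returns_absent(self):
        model = build_polyala(5)
        assert rama_z(model) is None


class TestRigidInvariance:
    def test_metrics_unchanged_under_rigid_motion(self, helix10):
        moved = _random_rigid_copy(helix10)
        rms_a, rms_b = geometry_rmsd_rmsz(helix10), geometry_rmsd_rmsz(moved)
        assert rms_b.rmsd_bonds == pytest.approx(rms_a.rmsd_bonds, abs=1e-6)
        assert rms_b.rmsd_angles == pytest.approx(rms_a.rmsd_angles, abs=1e-6)
        assert clashscore(moved).clashscore == clashscore(helix10).clashscore
        assert min_nonbonded_distance(moved).distance == pytest.approx(
            min_nonbonded_distance(helix10).distance, abs=1e-6
        )
        assert cbeta_deviations(moved).count == cbeta_deviations(helix10).count
        rama_a, rama_b = ramachandran_classify(helix10), ramachandran_classify(moved)
        assert rama_b.favored_pct == rama_a.favored_pct
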