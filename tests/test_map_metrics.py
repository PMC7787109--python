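"""Fourier and real-space metrics: FSC, d_FSC, synthesis, CC, d_99, d_model."""

import numpy as np
import pytest

from emtable1.errors import EmptyEnvelopeError, UndefinedCorrelationError
from emtable1.fixtures import FixtureSpec, build_helix, make_entry, plant_defect
from emtable1.map_io import DensityMap
from emtable1.map_metrics import (
    FSCCurve,
    atom_mask,
    cc_box,
    cc_mask,
    cc_per_residue,
    d99,
    d_fsc,
    d_model,
    fsc_curve,
    lowpass,
    model_to_map,
    nyquist_resolution,
)
from emtable1.scattering import ScatteringTable
from emtable1.structure_io import Atom, Chain, Residue, StructureModel

CUBE = (24.0, 24.0, 24.0, 90.0, 90.0, 90.0)


def _noise_map(rng, n=24, cell=CUBE):
    return DensityMap(rng.normal(size=(n, n, n)).astype(np.float32), cell)


def _point_model(coords, element="C", b=20.0):
    res = Residue("LIG", 1, atoms=[
        Atom(f"{element}{i + 1}", element, np.asarray(c, dtype=float), 1.0, b)
        for i, c in enumerate(coords)
    ])
    return StructureModel(chains=[Chain("A", [res])])


class TestFSC:
    def test_self_correlation_is_one(self, rng):
        m = _noise_map(rng)
        curve = fsc_curve(m, m)
        assert np.all(np.isclose(curve.fsc[curve.shell_counts > 0], 1.0))

    def test_symmetric_in_arguments(self, rng):
        m1, m2 = _noise_map(rng), _noise_map(rng)
        c12 = fsc_curve(m1, m2)
        c21 = fsc_curve(m2, m1)
        assert np.allclose(c12.fsc, c21.fsc, equal_nan=True)

    def test_independent_noise_fsc_near_zero(self):
        """|FSC_k| < 3/sqrt(n_k) in >= 95% of shells across seeds."""
        hits = total = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            curve = fsc_curve(_noise_map(r), _noise_map(r))
            ok = curve.shell_counts > 0
            bound = 3.0 / np.sqrt(curve.shell_counts[ok])
            hits += int(np.sum(np.abs(curve.fsc[ok]) < bound))
            total += int(np.sum(ok))
        assert hits / total >= 0.95

    def test_snr_to_fsc_relation(self, rng):
        """Half-maps with per-shell SNR lambda give FSC ~ lambda/(lambda+1)."""
        n = 32
        cell = (32.0,) * 3 + (90.0,) * 3
        signal = rng.normal(size=(n, n, n))
        lam = 1.0  # equal signal and noise power, everywhere
        sd = 1.0 / np.sqrt(lam)
        h1 = DensityMap((signal + sd * rng.normal(size=signal.shape)).astype(np.float32), cell)
        h2 = DensityMap((signal + sd * rng.normal(size=signal.shape)).astype(np.float32), cell)
        curve = fsc_curve(h1, h2)
        ok = curve.shell_counts > 200
        expected = lam / (lam + 1.0)
        sampling_err = 3.0 / np.sqrt(curve.shell_counts[ok])
        assert np.all(np.abs(curve.fsc[ok] - expected) < 0.1 + sampling_err)

    def test_constant_map_rejected(self):
        flat = DensityMap(np.ones((8, 8, 8)), CUBE)
        with pytest.raises(UndefinedCorrelationError):
            fsc_curve(flat, flat)


class TestDFsc:
    def test_hand_interpolated_crossing(self):
        curve = FSCCurve(
            shell_center_freq=np.array([0.1, 0.2, 0.3]),
            fsc=np.array([1.0, 0.9, 0.05]),
            shell_counts=np.array([10, 10, 10]),
            s_max=0.35, voxel_size=1.0,
        )
        s_star = 0.2 + 0.1 * (0.9 - 0.143) / (0.9 - 0.05)
        assert d_fsc(curve, 0.143) == pytest.approx(1.0 / s_star)

    def test_never_crossing_returns_nyquist(self):
        curve = FSCCurve(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                         np.array([5, 5]), 0.25, voxel_size=1.25)
        assert d_fsc(curve) == pytest.approx(2.5)

    def test_decreasing_in_threshold(self, entry4):
        curve = fsc_curve(*entry4.half_maps)
        d_loose = d_fsc(curve, 0.143)
        d_strict = d_fsc(curve, 0.5)
        assert d_strict >= d_loose


class TestModelToMap:
    def test_single_atom_peaks_at_center(self):
        template = DensityMap(np.zeros((24, 24, 24)), CUBE)
        model = _point_model([[12.0, 12.0, 12.0]])
        rho = model_to_map(model, template, d_min=None)
        assert np.unravel_index(np.argmax(rho.grid), rho.grid.shape) == (12, 12, 12)

    def test_superposition_linearity(self):
        template = DensityMap(np.zeros((24, 24, 24)), CUBE)
        a = _point_model([[8.0, 12.0, 12.0]])
        b = _point_model([[16.0, 12.0, 12.0]])
        both = _point_model([[8.0, 12.0, 12.0], [16.0, 12.0, 12.0]])
        rho_sum = model_to_map(a, template, None).grid + model_to_map(b, template, None).grid
        rho_both = model_to_map(both, template, None).grid
        assert np.allclose(rho_both, rho_sum, atol=1e-10)

    def test_integral_equals_form_factor_sum(self):
        """Non-band-limited atom integrates to f(0) = sum of Gaussian amplitudes.

        A modest B keeps the narrowest Gaussian term resolvable on the grid;
        blurring does not change the integral.
        """
        n, edge = 40, 12.0
        template = DensityMap(np.zeros((n, n, n)), (edge,) * 3 + (90.0,) * 3)
        model = _point_model([[6.0, 6.0, 6.0]], b=20.0)
        rho = model_to_map(model, template, d_min=None)
        integral = float(rho.grid.sum()) * (edge / n) ** 3
        a, _ = ScatteringTable().gaussians("C")
        assert integral == pytest.approx(a.sum(), rel=0.01)

    def test_occupancy_scales_density(self):
        template = DensityMap(np.zeros((24, 24, 24)), CUBE)
        model = _point_model([[12.0, 12.0, 12.0]])
        half = _point_model([[12.0, 12.0, 12.0]])
        half.chains[0].residues[0].atoms[0].occupancy = 0.5
        assert np.allclose(model_to_map(half, template, None).grid,
                           0.5 * model_to_map(model, template, None).grid, atol=1e-12)


class TestCCBox:
    def test_self_and_anticorrelation(self, rng):
        m = _noise_map(rng)
        neg = m.copy()
        neg.grid = -m.grid
        assert cc_box(m, m) == pytest.approx(1.0)
        assert cc_box(m, neg) == pytest.approx(-1.0)

    def test_noise_attenuation_closed_form(self):
        """cc(m, m + eps*noise) ~ 1/sqrt(1 + eps^2 var_n/var_m)."""
        eps = 0.7
        ccs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            m = _noise_map(r, n=32, cell=(32.0,) * 3 + (90.0,) * 3)
            noisy = m.copy()
            noise = r.normal(size=m.grid.shape)
            noisy.grid = (m.grid + eps * noise).astype(np.float32)
            ccs.append(cc_box(m, noisy))
        expected = 1.0 / np.sqrt(1.0 + eps**2)
        assert np.mean(ccs) == pytest.approx(expected, rel=0.02)

    def test_affine_rescaling_invariance(self, rng):
        m1, m2 = _noise_map(rng), _noise_map(rng)
        scaled = m1.copy()
        scaled.grid = (3.5 * m1.grid + 11.0).astype(np.float32)
        assert cc_box(scaled, m2) == pytest.approx(cc_box(m1, m2), abs=1e-5)

    def test_constant_input_rejected(self, rng):
        flat = DensityMap(np.ones((8, 8, 8)), CUBE)
        with pytest.raises(UndefinedCorrelationError):
            cc_box(flat, _noise_map(rng, n=8))


class TestCCMask:
    def test_mask_matches_brute_force_on_toy_grid(self):
        """Sphere-union membership equals a per-voxel nearest-atom scan."""
        cell = (8.0,) * 3 + (90.0,) * 3
        template = DensityMap(np.zeros((8, 8, 8)), cell)
        coords = np.array([[2.31, 4.13, 3.71], [5.87, 2.23, 6.01]])
        model = _point_model(coords)
        radius = 2.5
        mask = atom_mask(model, template, radius)
        brute = np.zeros((8, 8, 8), dtype=bool)
        for ix in range(8):
            for iy in range(8):
                for iz in range(8):
                    node = np.array([ix, iy, iz], dtype=float)  # voxel = 1 A
                    delta = coords - node
                    delta -= 8.0 * np.round(delta / 8.0)  # periodic box
                    d = np.linalg.norm(delta, axis=1).min()
                    brute[ix, iy, iz] = d <= radius
        assert np.array_equal(mask, brute)

    def test_self_synthesized_map_scores_one(self, entry4):
        calc = model_to_map(entry4.model, entry4.map, d_min=4.0)
        assert cc_mask(calc, calc, entry4.model) == pytest.approx(1.0)

    def test_half_box_translation_destroys_fit(self, entry4):
        shifted = entry4.model.translate(np.array([20.0, 0.0, 0.0]))
        calc = model_to_map(shifted, entry4.map, d_min=4.0)
        assert cc_mask(entry4.map, calc, shifted) < 0.2

    def test_empty_envelope_rejected(self, rng):
        m = _noise_map(rng, n=8)
        with pytest.raises((EmptyEnvelopeError, ValueError)):
            cc_mask(m, m, StructureModel(), radius=2.5)


class TestCCPerResidue:
    def test_homogeneous_entry_all_high(self, entry4):
        calc = model_to_map(entry4.model, entry4.map, d_min=4.0)
        detail = cc_per_residue(entry4.map, calc, entry4.model)
        values = [cc for _, _, cc in detail.per_residue["A"]]
        assert all(cc is not None and cc > 0.95 for cc in values)

    def test_flipped_side_chain_is_chain_minimum(self, entry4):
        flipped = plant_defect(entry4.model, "sidechain_flip", res_index=10, angle=120.0)
        calc = model_to_map(flipped, entry4.map, d_min=4.0)
        detail = cc_per_residue(entry4.map, calc, flipped)
        rows = detail.per_residue["A"]
        worst = min(rows, key=lambda r: r[2])
        assert worst[1] == 11  # seqid of the flipped residue

    def test_chain_cc_is_union_not_mean(self, entry4):
        """Per-chain CC comes from the concatenated residue masks."""
        model = entry4.model.copy()
        model.chains[0].residues = model.chains[0].residues[:3]
        calc = model_to_map(model, entry4.map, d_min=4.0)
        detail = cc_per_residue(entry4.map, calc, model)
        union = np.zeros(entry4.map.grid.shape, dtype=bool)
        for res in model.chains[0].residues:
            coords = np.array([a.coord for a in res.atoms])
            union |= atom_mask(model, entry4.map, 2.5, coords=coords)
        exp = entry4.map.grid[union].astype(float)
        cal = calc.grid[union].astype(float)
        direct = np.corrcoef(exp - exp.mean(), cal - cal.mean())[0, 1]
        assert detail.per_chain["A"]["protein"] == pytest.approx(direct, abs=1e-6)
        mean_of_residues = np.mean([cc for _, _, cc in detail.per_residue["A"]])
        assert detail.per_chain["A"]["protein"] != pytest.approx(mean_of_residues, abs=1e-12)


class TestD99:
    def test_band_limited_map_recovers_limit(self, entry4):
        limited = model_to_map(entry4.model, entry4.map, d_min=3.0)
        d = d99(limited)
        assert abs(1.0 / d - 1.0 / 3.0) <= 0.05 + 1e-9

    def test_white_noise_map_near_nyquist(self, rng):
        m = _noise_map(rng, n=32, cell=(32.0,) * 3 + (90.0,) * 3)
        d = d99(m)
        assert abs(1.0 / d - 1.0 / nyquist_resolution(m)) <= 2 * 0.05 + 1e-9

    @pytest.mark.parametrize("d_cut", [3.0, 4.0, 5.0])
    def test_lowpass_then_d99_never_finer(self, entry4, d_cut):
        limited = lowpass(entry4.map, d_cut)
        assert 1.0 / d99(limited) <= 1.0 / d_cut + 0.05 + 1e-9

    def test_matches_real_space_definition(self, rng):
        """The Parseval shortcut agrees with literal cc_box(map, lowpass(map, d))."""
        raw = _noise_map(rng, n=16, cell=(16.0,) * 3 + (90.0,) * 3)
        m = lowpass(raw, 2.5)
        d = d99(m)
        assert cc_box(m, lowpass(m, d)) >= 0.99
        one_coarser = 1.0 / (1.0 / d - 0.05)
        assert cc_box(m, lowpass(m, one_coarser)) < 0.99


class TestDModel:
    def test_self_consistency_at_four_angstrom(self, entry4):
        synthetic = model_to_map(entry4.model, entry4.map, d_min=4.0)
        result = d_model(synthetic, entry4.model)
        assert result.d_model == pytest.approx(4.0, abs=0.2)
        assert result.reliable

    def test_noise_degrades_estimate(self, entry4, rng):
        clean = model_to_map(entry4.model, entry4.map, d_min=4.0)
        noisy = clean.copy()
        noisy.grid = (clean.grid + 2.0 * clean.grid.std()
                      * rng.normal(size=clean.grid.shape)).astype(np.float32)
        d_clean = d_model(clean, entry4.model).d_model
        d_noisy = d_model(noisy, entry4.model).d_model
        assert d_noisy >= d_clean - 0.1

    def test_misplaced_model_flagged_unreliable(self, entry4):
        shifted = entry4.model.translate(np.array([20.0, 0.0, 0.0]))
        result = d_model(entry4.map, shifted)
        assert not result.reliable
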