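"""Fourier- and real-space map metrics.

Data quality: half-map Fourier shell correlation (FSC) and the resolution
estimates derived from it (d_FSC at 0.143/0.5), the map-detail estimate d_99
and the model-based estimate d_model. Model-versus-data fit: CC_box over the
whole box and CC_mask over a sphere-union envelope around the atoms, with
per-chain and per-residue breakdowns. Gaussian-atom density synthesis
(``model_to_map``) provides the model-side map for all model-based metrics.

All Fourier work assumes orthogonal cells (the universal case for cryo-EM
boxes); spatial frequency s = 1/d is measured in 1/Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyEnvelopeError, UndefinedCorrelationError
from .map_io import Cell, DensityMap
from .scattering import ScatteringTable
from .structure_io import StructureModel

FSC_THRESHOLD_HALFMAP = 0.143
FSC_THRESHOLD_STRICT = 0.5
DEFAULT_MASK_RADIUS = 2.5  # Angstrom
D99_CC_THRESHOLD = 0.99
D99_SCAN_STEP = 0.05  # in 1/d


# -- frequency bookkeeping ---------------------------------------------------


def _freq_magnitude(shape: tuple[int, int, int], cell: Cell) -> np.ndarray:
    """|s| in 1/Angstrom on the full FFT grid."""
    axes = [np.fft.fftfreq(n, d=cell[i] / n) for i, n in enumerate(shape)]
    return np.sqrt(
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )


def nyquist_frequency(dmap: DensityMap) -> float:
    """Smallest per-axis Nyquist frequency (1/Angstrom)."""
    return float(min(0.5 / v for v in dmap.voxel_size))


def nyquist_resolution(dmap: DensityMap) -> float:
    """Resolution limit of the sampling: twice the (largest) voxel size."""
    return float(2.0 * max(dmap.voxel_size))


def lowpass(dmap: DensityMap, d: float) -> DensityMap:
    """Sharp Fourier cutoff: zero all coefficients with |s| > 1/d."""
    F = np.fft.fftn(dmap.grid.astype(float))
    s = _freq_magnitude(dmap.grid.shape, dmap.cell)
    F[s > 1.0 / d] = 0.0
    out = dmap.copy()
    out.grid = np.fft.ifftn(F).real.astype(np.float32)
    return out


# -- FSC ---------------------------------------------------------------------


@dataclass
class FSCCurve:
    """Per-shell Fourier correlation between two maps."""

    shell_center_freq: np.ndarray  # 1/Angstrom, strictly increasing
    fsc: np.ndarray
    shell_counts: np.ndarray
    s_max: float  # Nyquist bound of the binning
    voxel_size: float  # largest voxel edge, for the no-crossing fallback

    @property
    def shell_width(self) -> float:
        return float(self.shell_center_freq[1] - self.shell_center_freq[0])


def fsc_curve(map1: DensityMap, map2: DensityMap, n_shells: int | None = None) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid.

    FSC_k = Re(sum F1 conj(F2)) / sqrt(sum|F1|^2 sum|F2|^2) over coefficients
    whose |s| falls in shell k; the DC term is excluded. Shells are of equal
    frequency width from 0 to the smallest per-axis Nyquist; by default there
    are N/2 shells for the largest grid dimension N.
    """
    if not map1.same_geometry(map2):
        raise ValueError("FSC requires identical grid sampling and cell")
    g1 = map1.grid.astype(float)
    g2 = map2.grid.astype(float)
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise UndefinedCorrelationError("FSC undefined for a constant map")
    if n_shells is None:
        n_shells = max(map1.grid.shape) // 2

    F1 = np.fft.fftn(g1)
    F2 = np.fft.fftn(g2)
    s = _freq_magnitude(map1.grid.shape, map1.cell)
    s_max = nyquist_frequency(map1)

    edges = np.linspace(0.0, s_max, n_shells + 1)
    idx = np.digitize(s.ravel(), edges) - 1  # shell index; <0 or >=n_shells dropped
    valid = (idx >= 0) & (idx < n_shells) & (s.ravel() > 0)
    idx = idx[valid]
    f1 = F1.ravel()[valid]
    f2 = F2.ravel()[valid]

    num = np.bincount(idx, weights=(f1 * np.conj(f2)).real, minlength=n_shells)
    p1 = np.bincount(idx, weights=np.abs(f1) ** 2, minlength=n_shells)
    p2 = np.bincount(idx, weights=np.abs(f2) ** 2, minlength=n_shells)
    counts = np.bincount(idx, minlength=n_shells)

    fsc = np.full(n_shells, np.nan)
    ok = (counts > 0) & (p1 > 0) & (p2 > 0)
    fsc[ok] = num[ok] / np.sqrt(p1[ok] * p2[ok])

    return FSCCurve(
        shell_center_freq=(edges[:-1] + edges[1:]) / 2.0,
        fsc=fsc,
        shell_counts=counts,
        s_max=float(s_max),
        voxel_size=float(max(map1.voxel_size)),
    )


def d_fsc(curve: FSCCurve, threshold: float = FSC_THRESHOLD_HALFMAP) -> float:
    """Resolution at the first FSC crossing below ``threshold``.

    The crossing frequency is linearly interpolated between shell centers;
    a curve that never drops below the threshold reports the Nyquist
    resolution (twice the voxel size).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    s = curve.shell_center_freq
    f = curve.fsc
    prev_s, prev_f = None, None
    for k in range(len(f)):
        if curve.shell_counts[k] == 0 or np.isnan(f[k]):
            continue
        if f[k] < threshold:
            if prev_s is None:
                return float(1.0 / s[k])
            s_star = prev_s + (s[k] - prev_s) * (prev_f - threshold) / (prev_f - f[k])
            return float(1.0 / s_star)
        prev_s, prev_f = s[k], f[k]
    return 2.0 * curve.voxel_size


# -- density synthesis -------------------------------------------------------

_EXP_CUTOFF = 30.0  # truncate atom footprints where 4 pi^2 r^2 / w > this


def _require_orthogonal(cell: Cell) -> None:
    if any(abs(a - 90.0) > 1e-6 for a in cell[3:]):
        raise ValueError("density synthesis supports orthogonal cells only")


def model_to_map(
    model: StructureModel,
    template: DensityMap,
    d_min: float | None,
    table: ScatteringTable | None = None,
) -> DensityMap:
    """Synthesize a model-based density map on the template's grid.

    Each atom contributes an occupancy-weighted sum of five isotropic
    Gaussians whose widths combine the electron form-factor widths with the
    atom's B factor; footprints wrap periodically. When ``d_min`` is given
    the result is band-limited by a sharp Fourier cutoff at s = 1/d_min.
    """
    _require_orthogonal(template.cell)
    table = table or ScatteringTable()
    shape = template.grid.shape
    voxel = template.voxel_size
    if d_min is not None and d_min < 2.0 * max(voxel):
        raise ValueError(f"d_min {d_min} below Nyquist limit {2 * max(voxel):.2f}")
    rho = np.zeros(shape, dtype=float)

    for _, _, atom in model.iter_atoms():
        if atom.occupancy == 0.0:
            continue
        a, b = table.gaussians(atom.element)
        w = b + max(atom.b_iso, 0.0)  # Angstrom^2
        amp = atom.occupancy * a * (4.0 * np.pi / w) ** 1.5
        decay = 4.0 * np.pi**2 / w
        r_cut = np.sqrt(_EXP_CUTOFF * w.max()) / (2.0 * np.pi)

        frac = (atom.coord - template.origin) / voxel
        center = np.rint(frac).astype(int)
        half = np.minimum(np.ceil(r_cut / voxel).astype(int), np.array(shape) - 1)
        offsets = [np.arange(c - h, c + h + 1) for c, h in zip(center, half)]
        d2 = [((off - frac[i]) * voxel[i]) ** 2 for i, off in enumerate(offsets)]
        r2 = d2[0][:, None, None] + d2[1][None, :, None] + d2[2][None, None, :]
        block = np.zeros_like(r2)
        for ai, ci in zip(amp, decay):
            block += ai * np.exp(-np.minimum(ci * r2, 700.0))
        wrapped = [off % n for off, n in zip(offsets, shape)]
        rho[np.ix_(*wrapped)] += block

    out = template.copy()
    out.grid = rho.astype(np.float32)
    if d_min is not None:
        out = lowpass(out, d_min)
    return out


# -- correlations ------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x.astype(float).ravel()
    y = y.astype(float).ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float((xc * yc).sum() / denom)


def cc_box(map1: DensityMap, map2: DensityMap) -> float:
    """Pearson correlation over every voxel of the box."""
    if not map1.same_geometry(map2):
        raise ValueError("cc_box requires identical grids")
    return _pearson(map1.grid, map2.grid)


def atom_mask(
    model: StructureModel,
    template: DensityMap,
    radius: float = DEFAULT_MASK_RADIUS,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean grid marking voxels within ``radius`` of any non-H atom.

    The mask is a hard union of spheres evaluated at grid nodes
    (origin + index * voxel), with periodic wrapping.
    """
    if radius <= 0:
        raise ValueError("mask radius must be positive")
    shape = template.grid.shape
    voxel = template.voxel_size
    mask = np.zeros(shape, dtype=bool)
    if coords is None:
        coords = model.coords(heavy_only=True)
    r2max = radius * radius
    for xyz in coords:
        frac = (xyz - template.origin) / voxel
        center = np.rint(frac).astype(int)
        half = np.minimum(np.ceil(radius / voxel).astype(int), np.array(shape) - 1)
        offsets = [np.arange(c - h, c + h + 1) for c, h in zip(center, half)]
        d2 = [((off - frac[i]) * voxel[i]) ** 2 for i, off in enumerate(offsets)]
        r2 = d2[0][:, None, None] + d2[1][None, :, None] + d2[2][None, None, :]
        wrapped = [off % n for off, n in zip(offsets, shape)]
        sub = mask[np.ix_(*wrapped)]
        mask[np.ix_(*wrapped)] = sub | (r2 <= r2max)
    return mask


def cc_mask(
    map_exp: DensityMap,
    map_calc: DensityMap,
    model: StructureModel,
    radius: float = DEFAULT_MASK_RADIUS,
) -> float:
    """Pearson correlation restricted to the atom envelope."""
    if not map_exp.same_geometry(map_calc):
        raise ValueError("cc_mask requires identical grids")
    mask = atom_mask(model, map_exp, radius)
    if not mask.any():
        raise EmptyEnvelopeError("atom mask selects no voxels")
    return _pearson(map_exp.grid[mask], map_calc.grid[mask])


@dataclass
class MapModelCC:
    """Whole-box, masked, per-chain and per-residue map-model correlations.

    ``per_chain`` maps chain id to a dict with ``protein`` and ``other``
    (ligand/water) entries; a residue whose mask is empty gets ``None``.
    """

    cc_box: float
    cc_mask: float
    per_chain: dict[str, dict[str, float | None]] = field(default_factory=dict)
    per_residue: dict[str, list[tuple[str, int, float | None]]] = field(default_factory=dict)


def cc_per_residue(
    map_exp: DensityMap,
    map_calc: DensityMap,
    model: StructureModel,
    radius: float = DEFAULT_MASK_RADIUS,
) -> MapModelCC:
    """Per-residue and per-chain map-model correlation breakdown.

    Each residue is scored over its own sphere-union mask; a chain's CC is
    computed over the union of its residues' masks (not the mean of the
    per-residue values), split into protein and ligand/water residues.
    """
    if not map_exp.same_geometry(map_calc):
        raise ValueError("cc_per_residue requires identical grids")
    per_residue: dict[str, list[tuple[str, int, float | None]]] = {}
    per_chain: dict[str, dict[str, float | None]] = {}
    for chain in model.chains:
        entries = []
        chain_masks = {"protein": np.zeros(map_exp.grid.shape, bool),
                       "other": np.zeros(map_exp.grid.shape, bool)}
        for res in chain.residues:
            coords = np.array(
                [a.coord for a in res.atoms if not a.is_hydrogen], dtype=float
            ).reshape(-1, 3)
            mask = atom_mask(model, map_exp, radius, coords=coords)
            group = "protein" if res.is_protein else "other"
            chain_masks[group] |= mask
            if mask.any():
                try:
                    cc = _pearson(map_exp.grid[mask], map_calc.grid[mask])
                except UndefinedCorrelationError:
                    cc = None
            else:
                cc = None
            entries.append((res.name, res.seqid, cc))
        per_residue[chain.id] = entries
        per_chain[chain.id] = {}
        for group, mask in chain_masks.items():
            if mask.any():
                try:
                    per_chain[chain.id][group] = _pearson(
                        map_exp.grid[mask], map_calc.grid[mask]
                    )
                except UndefinedCorrelationError:
                    per_chain[chain.id][group] = None
            else:
                per_chain[chain.id][group] = None
    return MapModelCC(
        cc_box=cc_box(map_exp, map_calc),
        cc_mask=cc_mask(map_exp, map_calc, model, radius),
        per_chain=per_chain,
        per_residue=per_residue,
    )


# -- resolution estimates ----------------------------------------------------


def d99(dmap: DensityMap, scan_step: float = D99_SCAN_STEP) -> float:
    """Coarsest low-pass cutoff that leaves the map essentially unchanged.

    Scans cutoffs from Nyquist towards coarse in steps of ``scan_step`` in
    1/d and returns the coarsest d with cc_box(map, lowpass(map, d)) >= 0.99.
    Because the low-passed map shares the retained Fourier coefficients with
    the original, that correlation equals sqrt(P_in / P_total) by Parseval's
    theorem (DC excluded), which is how it is evaluated here.
    """
    g = dmap.grid.astype(float)
    if np.ptp(g) == 0:
        raise UndefinedCorrelationError("d99 undefined for a constant map")
    F = np.fft.fftn(g)
    s = _freq_magnitude(g.shape, dmap.cell)
    power = np.abs(F) ** 2
    power.flat[0] = 0.0  # DC = mean term
    p_tot = power.sum()

    s_flat = np.sort(s.ravel())
    p_sorted = power.ravel()[np.argsort(s.ravel(), kind="stable")]
    p_cum = np.cumsum(p_sorted)

    s_nyq = nyquist_frequency(dmap)
    last_ok = s_nyq
    s_cut = s_nyq
    while s_cut > scan_step:
        k = np.searchsorted(s_flat, s_cut, side="right")
        p_in = p_cum[k - 1] if k > 0 else 0.0
        cc = np.sqrt(p_in / p_tot) if p_tot > 0 else 0.0
        if cc >= D99_CC_THRESHOLD:
            last_ok = s_cut
        else:
            break
        s_cut -= scan_step
    return float(1.0 / last_ok)


@dataclass
class DModelResult:
    d_model: float
    cc_at_optimum: float
    reliable: bool  # False when the optimum CC_mask is in the misfit regime (< 0.2)


def d_model(
    dmap: DensityMap,
    model: StructureModel,
    table: ScatteringTable | None = None,
    radius: float = DEFAULT_MASK_RADIUS,
    d_max: float = 10.0,
    step: float = 0.1,
) -> DModelResult:
    """Resolution cutoff at which the model map best matches the experimental map.

    A model map is synthesized once from the deposited B factors; a grid
    search over cutoffs d in [max(1.0, 2 * voxel), d_max] (step ``step``)
    low-passes it and scores CC_mask against the experimental map. Ties break
    toward finer d. When the optimum CC_mask is below 0.2 the estimate is
    flagged unreliable (the model probably does not sit in its density).
    """
    table = table or ScatteringTable()
    base = model_to_map(model, dmap, d_min=None, table=table)
    mask = atom_mask(model, dmap, radius)
    if not mask.any():
        raise EmptyEnvelopeError("atom mask selects no voxels")
    exp_vals = dmap.grid[mask]

    F = np.fft.fftn(base.grid.astype(float))
    s = _freq_magnitude(base.grid.shape, dmap.cell)

    d_lo = max(1.0, 2.0 * float(max(dmap.voxel_size)))
    candidates = np.arange(d_lo, d_max + 1e-9, step)
    best_d, best_cc = None, -np.inf
    for d in candidates:
        Fc = np.where(s > 1.0 / d, 0.0, F)
        calc = np.fft.ifftn(Fc).real
        try:
            cc = _pearson(exp_vals, calc[mask])
        except UndefinedCorrelationError:
            continue
        if cc > best_cc + 1e-12:  # strict improvement; earlier (finer) d wins ties
            best_cc, best_d = cc, float(d)
    if best_d is None:
        raise UndefinedCorrelationError("no cutoff produced a defined correlation")
    return DModelResult(d_model=round(best_d, 10), cc_at_optimum=best_cc, reliable=best_cc >= 0.2)


@dataclass
class ResolutionEstimates:
    """The Table 1 data-quality block."""

    d_model: float
    d_99: float
    consensus: float | None = None
    d_fsc: float | None = None
    d_fsc_05: float | None = None
    d_model_reliable: bool = True

    def __post_init__(self) -> None:
        for name in ("d_model", "d_99", "consensus", "d_fsc", "d_fsc_05"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
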