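"""Ramachandran classification and the Rama-Z score.

The reference is a smooth probability table on the (phi, psi) torus for
three residue classes (general, glycine, proline), materialized on a 2x2
degree grid from a fixed analytic mixture of wrapped Gaussians centered on
the classical basins (alpha, beta/extended, polyproline-II, left-handed
alpha). It is deliberately coarse compared to the Top8000-derived MolProbity
tables — class granularity and contour shapes are approximations — but the
favored/allowed/outlier machinery, the contour-mass definitions (0.98 and
0.9995) and the file-free droppability of a higher-fidelity table are the
same. ``RamaReference.from_tables`` accepts any replacement tables.

Rama-Z compares the mean per-residue log-probability of a model's backbone
dihedrals with its Monte Carlo null distribution under the reference itself,
so |Z| < 2 is ordinary, 2-3 suspicious and > 3 improbable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, UndefinedStatisticError
from .geometry_metrics import PEPTIDE_BOND_CUTOFF, dihedral_deg
from .structure_io import StructureModel

GRID_STEP = 2.0  # degrees
N_BINS = int(360 / GRID_STEP)
FAVORED_MASS = 0.98
ALLOWED_MASS = 0.9995

# (phi center, psi center, phi sd, psi sd, weight) per class
_MIXTURES: dict[str, list[tuple[float, float, float, float, float]]] = {
    "general": [
        (-63.0, -43.0, 12.0, 12.0, 0.45),   # right-handed alpha
        (-120.0, 130.0, 25.0, 20.0, 0.25),  # beta / extended
        (-65.0, 145.0, 15.0, 15.0, 0.17),   # polyproline II
        (57.0, 40.0, 10.0, 10.0, 0.06),     # left-handed alpha
        (-63.0, -43.0, 30.0, 30.0, 0.04),   # diffuse alpha shoulder
        (-110.0, 140.0, 45.0, 45.0, 0.03),  # diffuse beta shoulder
    ],
    "glycine": [
        (-63.0, -41.0, 13.0, 13.0, 0.30),
        (63.0, 41.0, 13.0, 13.0, 0.20),
        (-80.0, 170.0, 25.0, 25.0, 0.20),
        (80.0, -170.0, 25.0, 25.0, 0.15),
        (-63.0, -41.0, 35.0, 35.0, 0.08),
        (63.0, 41.0, 35.0, 35.0, 0.07),
    ],
    "proline": [
        (-63.0, -35.0, 8.0, 12.0, 0.50),
        (-63.0, 145.0, 8.0, 15.0, 0.40),
        (-63.0, 60.0, 15.0, 60.0, 0.10),
    ],
}


def _wrap(delta: np.ndarray) -> np.ndarray:
    return (delta + 180.0) % 360.0 - 180.0


def _mixture_table(components) -> np.ndarray:
    centers = np.arange(-180.0 + GRID_STEP / 2, 180.0, GRID_STEP)
    phi = centers[:, None]
    psi = centers[None, :]
    table = np.zeros((N_BINS, N_BINS))
    for (mphi, mpsi, sphi, spsi, w) in components:
        dphi = _wrap(phi - mphi) / sphi
        dpsi = _wrap(psi - mpsi) / spsi
        table += w * np.exp(-0.5 * (dphi**2 + dpsi**2)) / (2 * np.pi * sphi * spsi)
    return table / table.sum()


def _contour_level(table: np.ndarray, mass: float) -> float:
    flat = np.sort(table.ravel())[::-1]
    cum = np.cumsum(flat)
    idx = int(np.searchsorted(cum, mass))
    return float(flat[min(idx, flat.size - 1)])


@dataclass
class RamaReference:
    """Per-class (phi, psi) probability tables with favored/allowed contours."""

    tables: dict[str, np.ndarray]
    favored_level: dict[str, float]
    allowed_level: dict[str, float]

    _default: "RamaReference | None" = None

    @classmethod
    def from_tables(cls, tables: dict[str, np.ndarray]) -> "RamaReference":
        tables = {k: np.asarray(t, dtype=float) / np.asarray(t, dtype=float).sum()
                  for k, t in tables.items()}
        for name, t in tables.items():
            if t.shape != (N_BINS, N_BINS):
                raise ValueError(f"table {name!r} must be {N_BINS}x{N_BINS}")
        return cls(
            tables=tables,
            favored_level={k: _contour_level(t, FAVORED_MASS) for k, t in tables.items()},
            allowed_level={k: _contour_level(t, ALLOWED_MASS) for k, t in tables.items()},
        )

    @classmethod
    def default(cls) -> "RamaReference":
        if cls._default is None:
            cls._default = cls.from_tables({k: _mixture_table(v) for k, v in _MIXTURES.items()})
        return cls._default

    @staticmethod
    def residue_class(resname: str) -> str:
        if resname == "GLY":
            return "glycine"
        if resname == "PRO":
            return "proline"
        return "general"

    def probability(self, cls_name: str, phi: float, psi: float) -> float:
        """Bilinear interpolation of the cell-mass table on the torus."""
        table = self.tables[cls_name]
        fi = (phi + 180.0) / GRID_STEP - 0.5
        fj = (psi + 180.0) / GRID_STEP - 0.5
        i0 = int(np.floor(fi)) % N_BINS
        j0 = int(np.floor(fj)) % N_BINS
        ti = fi - np.floor(fi)
        tj = fj - np.floor(fj)
        i1 = (i0 + 1) % N_BINS
        j1 = (j0 + 1) % N_BINS
        return float(
            table[i0, j0] * (1 - ti) * (1 - tj)
            + table[i1, j0] * ti * (1 - tj)
            + table[i0, j1] * (1 - ti) * tj
            + table[i1, j1] * ti * tj
        )

    def classify(self, cls_name: str, phi: float, psi: float) -> str:
        p = self.probability(cls_name, phi, psi)
        if p >= self.favored_level[cls_name]:
            return "favored"
        if p >= self.allowed_level[cls_name]:
            return "allowed"
        return "outlier"

    def log_score(self, cls_name: str, phi: float, psi: float) -> float:
        return float(np.log(self.probability(cls_name, phi, psi) + 1e-300))

    def sample(self, cls_name: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n (phi, psi) pairs from the class table (jittered in-cell)."""
        table = self.tables[cls_name]
        flat_idx = rng.choice(table.size, size=n, p=table.ravel())
        i, j = np.unravel_index(flat_idx, table.shape)
        phi = -180.0 + (i + rng.uniform(0, 1, n)) * GRID_STEP
        psi = -180.0 + (j + rng.uniform(0, 1, n)) * GRID_STEP
        return np.column_stack([_wrap(phi), _wrap(psi)])


# -- phi/psi extraction ------------------------------------------------------


def backbone_dihedrals(model: StructureModel) -> list[tuple[str, int, str, float, float]]:
    """(chain id, seqid, class, phi, psi) for every scorable interior residue.

    A residue is scorable when its own N/CA/C are present and it is peptide
    bonded to both neighbors (chain termini have no phi or no psi).
    """
    out = []
    for chain in model.chains:
        residues = chain.residues
        for i in range(1, len(residues) - 1):
            prev, res, nxt = residues[i - 1], residues[i], residues[i + 1]
            if not res.is_protein:
                continue
            atoms = {}
            for key, r, name in (
                ("c_prev", prev, "C"), ("n", res, "N"), ("ca", res, "CA"),
                ("c", res, "C"), ("n_next", nxt, "N"),
            ):
                atoms[key] = r.atom(name)
            if any(a is None for a in atoms.values()):
                continue
            if (
                np.linalg.norm(atoms["c_prev"].coord - atoms["n"].coord) > PEPTIDE_BOND_CUTOFF
                or np.linalg.norm(atoms["c"].coord - atoms["n_next"].coord) > PEPTIDE_BOND_CUTOFF
            ):
                continue
            phi = dihedral_deg(atoms["c_prev"].coord, atoms["n"].coord,
                               atoms["ca"].coord, atoms["c"].coord)
            psi = dihedral_deg(atoms["n"].coord, atoms["ca"].coord,
                               atoms["c"].coord, atoms["n_next"].coord)
            out.append((chain.id, res.seqid, RamaReference.residue_class(res.name), phi, psi))
    return out


@dataclass
class RamaResult:
    favored_pct: float
    allowed_pct: float
    outlier_pct: float
    n_scored: int
    per_residue: list[tuple[str, int, str, str]]  # (chain, seqid, class, category)


def ramachandran_classify(model: StructureModel, ref: RamaReference | None = None) -> RamaResult:
    """Favored/allowed/outlier percentages over scorable residues."""
    ref = ref or RamaReference.default()
    scored = backbone_dihedrals(model)
    if not scored:
        raise UndefinedStatisticError("no residue with defined phi and psi")
    per_residue = []
    tally = {"favored": 0, "allowed": 0, "outlier": 0}
    for chain_id, seqid, cls_name, phi, psi in scored:
        cat = ref.classify(cls_name, phi, psi)
        tally[cat] += 1
        per_residue.append((chain_id, seqid, cls_name, cat))
    n = len(scored)
    return RamaResult(
        favored_pct=100.0 * tally["favored"] / n,
        allowed_pct=100.0 * tally["allowed"] / n,
        outlier_pct=100.0 * tally["outlier"] / n,
        n_scored=n,
        per_residue=per_residue,
    )


# -- Rama-Z ------------------------------------------------------------------

MIN_RAMA_Z_RESIDUES = 10


@dataclass
class RamaZResult:
    z: float
    band: str  # good (|Z|<2), suspicious (2-3), poor (>3)
    n_residues: int
    null_mean: float
    null_sd: float


def rama_z_band(z: float) -> str:
    if abs(z) < 2.0:
        return "good"
    if abs(z) <= 3.0:
        return "suspicious"
    return "poor"


_calibration_cache: dict[tuple, tuple[float, float]] = {}


def _null_calibration(
    ref: RamaReference, class_counts: tuple[tuple[str, int], ...],
    n_samples: int, seed: int,
) -> tuple[float, float]:
    """Mean/sd of the mean log-score under the reference distribution itself."""
    key = (id(ref), class_counts, n_samples, seed)
    if key not in _calibration_cache:
        rng = np.random.default_rng(seed)
        n_total = sum(c for _, c in class_counts)
        means = np.zeros(n_samples)
        for b in range(n_samples):
            total = 0.0
            for cls_name, count in class_counts:
                pairs = ref.sample(cls_name, count, rng)
                total += sum(ref.log_score(cls_name, phi, psi) for phi, psi in pairs)
            means[b] = total / n_total
        mu, sd = float(means.mean()), float(means.std(ddof=1))
        if sd <= 0:
            raise CalibrationError("degenerate reference: null has zero spread")
        _calibration_cache[key] = (mu, sd)
    return _calibration_cache[key]


def rama_z(
    model: StructureModel,
    ref: RamaReference | None = None,
    n_samples: int = 500,
    seed: int = 0,
) -> RamaZResult | None:
    """Z-score of the backbone dihedral distribution against the reference.

    The observed statistic is the mean per-residue log-probability; its null
    mean and spread are estimated by drawing ``n_samples`` pseudo-models of
    the same size and class composition from the reference itself. Models
    with fewer than 10 scorable residues return ``None`` (value absent).
    """
    ref = ref or RamaReference.default()
    scored = backbone_dihedrals(model)
    if len(scored) < MIN_RAMA_Z_RESIDUES:
        return None
    counts: dict[str, int] = {}
    total = 0.0
    for _, _, cls_name, phi, psi in scored:
        counts[cls_name] = counts.get(cls_name, 0) + 1
        total += ref.log_score(cls_name, phi, psi)
    m_obs = total / len(scored)
    mu, sd = _null_calibration(
        ref, tuple(sorted(counts.items())), n_samples, seed
    )
    z = (m_obs - mu) / sd
    return RamaZResult(z=z, band=rama_z_band(z), n_residues=len(scored),
                       null_mean=mu, null_sd=sd)
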