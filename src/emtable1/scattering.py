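"""Electron scattering factors and van der Waals radii.

Atomic densities are modelled as sums of five isotropic Gaussians using the
Peng (1996) electron form-factor parameterization shipped with gemmi
(International Tables table 4.3.2.2): f(s) = sum_i a_i exp(-b_i s^2 / 4)
with s = 1/d in 1/Angstrom. In real space each term is a normalized Gaussian
whose width combines b_i with the atom's isotropic B factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import gemmi

from .errors import UnknownElementError

#: van der Waals radii (Angstrom) used for clash detection.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31, "ZN": 1.39, "FE": 1.52,
}
DEFAULT_VDW_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class ScatteringTable:
    """Five-term Gaussian electron form factors per element.

    ``fallback_to_carbon`` substitutes carbon coefficients for elements
    missing from the table instead of raising.
    """

    fallback_to_carbon: bool = False
    _cache: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def gaussians(self, element: str) -> tuple[np.ndarray, np.ndarray]:
        """Amplitudes ``a`` and widths ``b`` (Angstrom^2) for an element."""
        key = element.upper()
        if key not in self._cache:
            el = gemmi.Element(key)
            coef = el.c4322
            a = np.asarray(coef.a, dtype=float)
            b = np.asarray(coef.b, dtype=float)
            if el.atomic_number == 0 or not np.any(a):
                if not self.fallback_to_carbon:
                    raise UnknownElementError(
                        f"element {element!r} not in electron scattering table"
                    )
                a, b = self.gaussians("C")
            if np.any(b <= 0):
                raise UnknownElementError(f"element {element!r}: non-positive widths")
            self._cache[key] = (a, b)
        return self._cache[key]

    def covers(self, element: str) -> bool:
        try:
            self.gaussians(element)
            return True
        except UnknownElementError:
            return False
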