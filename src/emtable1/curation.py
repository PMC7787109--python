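"""Admission filters for a map-model bundle.

Before any metric is computed, an entry must pass basic consistency checks:
a model must exist, the resolution stated in model and map metadata must
agree (the agreed value is the "consensus resolution"), half-maps must share
the full map's gridding, the model and map boxes must match, the model must
be a single coordinate set, must not be mostly single-atom (C-alpha/P-only)
residues, and the consensus resolution must be 5 A or better. All filters
are evaluated — a verdict lists every violated condition, not just the
first one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from .errors import MissingResolutionError
from .map_io import DensityMap, MapMetadata
from .structure_io import StructureModel, model_composition

RESOLUTION_TOLERANCE = 0.01  # Angstrom agreement for "the same value"
RESOLUTION_CUTOFF = 5.0  # consensus worse than this is rejected
BOX_LENGTH_TOLERANCE = 0.5  # Angstrom per cell edge
DEGENERATE_CELL_LENGTH = 2.0  # any edge at or below this is nonsensical
SINGLE_ATOM_FRACTION_LIMIT = 0.25


class RejectionCode(str, Enum):
    NO_MODEL = "NO_MODEL"
    RESOLUTION_MISMATCH = "RESOLUTION_MISMATCH"
    HALFMAP_GRID_MISMATCH = "HALFMAP_GRID_MISMATCH"
    BOX_MISMATCH = "BOX_MISMATCH"
    PROCESS_FAILURE = "PROCESS_FAILURE"
    ENSEMBLE_MODEL = "ENSEMBLE_MODEL"
    SINGLE_ATOM_FRACTION = "SINGLE_ATOM_FRACTION"
    RESOLUTION_TOO_LOW = "RESOLUTION_TOO_LOW"


@dataclass
class EntryBundle:
    """A map-model pair with optional half-maps, as admitted for validation."""

    model: StructureModel | None
    map: DensityMap
    map_metadata: MapMetadata
    half_maps: tuple[DensityMap, DensityMap] | None = None
    labels: str = ""
    load_errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.half_maps is not None and len(self.half_maps) != 2:
            raise ValueError("half_maps must be exactly two maps when present")


@dataclass
class CurationVerdict:
    accepted: bool
    rejections: list[RejectionCode]
    consensus_resolution: float | None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accepted": self.accepted,
            "rejections": [r.value for r in self.rejections],
            "consensus_resolution": self.consensus_resolution,
            "notes": self.notes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def consensus_resolution(
    model_res: list[float], map_res: list[float], tol: float = RESOLUTION_TOLERANCE
) -> float | None:
    """The unique resolution value present in both metadata lists.

    Values agree when within ``tol``; returns ``None`` (mismatch) when no
    unique common value exists. Raises :class:`MissingResolutionError` when
    both lists are empty.
    """
    if not model_res and not map_res:
        raise MissingResolutionError("neither model nor map metadata reports a resolution")
    common = []
    for mv in map_res:
        if any(abs(mv - md) <= tol for md in model_res):
            if not any(abs(mv - c) <= tol for c in common):
                common.append(mv)
    if len(common) == 1:
        return float(common[0])
    return None


def curate_entry(bundle: EntryBundle) -> CurationVerdict:
    """Evaluate every admission filter and return the combined verdict."""
    rejections: list[RejectionCode] = []
    notes: list[str] = []
    consensus: float | None = None

    if bundle.load_errors:
        rejections.append(RejectionCode.PROCESS_FAILURE)
        notes.extend(bundle.load_errors)

    model = bundle.model
    if model is None:
        rejections.append(RejectionCode.NO_MODEL)
        notes.append("map has no corresponding model")
    else:
        if model.n_models > 1:
            rejections.append(RejectionCode.ENSEMBLE_MODEL)
            notes.append(f"multi-model file with {model.n_models} coordinate sets")

        comp = model_composition(model)
        if comp.single_atom_residue_fraction > SINGLE_ATOM_FRACTION_LIMIT:
            rejections.append(RejectionCode.SINGLE_ATOM_FRACTION)
            notes.append(
                f"{100 * comp.single_atom_residue_fraction:.0f}% of residues are single-atom"
            )

        try:
            consensus = consensus_resolution(
                model.model_resolutions, bundle.map_metadata.reported_resolutions
            )
        except MissingResolutionError:
            consensus = None
            notes.append("no resolution value in either model or map metadata")
        if consensus is None:
            rejections.append(RejectionCode.RESOLUTION_MISMATCH)
            notes.append(
                f"model reports {model.model_resolutions}, "
                f"map reports {bundle.map_metadata.reported_resolutions}"
            )
        elif consensus > RESOLUTION_CUTOFF:
            rejections.append(RejectionCode.RESOLUTION_TOO_LOW)
            notes.append(f"consensus resolution {consensus:.2f} A worse than 5 A")

        map_cell = bundle.map.cell
        if model.cell is None:
            rejections.append(RejectionCode.BOX_MISMATCH)
            notes.append("model file carries no cell information")
        elif any(length <= DEGENERATE_CELL_LENGTH for length in model.cell[:3]):
            rejections.append(RejectionCode.BOX_MISMATCH)
            notes.append(f"degenerate model cell lengths {model.cell[:3]}")
        elif any(
            abs(a - b) > BOX_LENGTH_TOLERANCE for a, b in zip(model.cell[:3], map_cell[:3])
        ):
            rejections.append(RejectionCode.BOX_MISMATCH)
            notes.append(f"model cell {model.cell[:3]} vs map cell {map_cell[:3]}")

    if bundle.half_maps is not None:
        for i, half in enumerate(bundle.half_maps):
            if not half.same_geometry(bundle.map):
                rejections.append(RejectionCode.HALFMAP_GRID_MISMATCH)
                notes.append(
                    f"half-map {i + 1} gridding {half.grid.shape}/{half.cell[:3]} "
                    f"differs from map {bundle.map.grid.shape}/{bundle.map.cell[:3]}"
                )
                break

    return CurationVerdict(
        accepted=not rejections,
        rejections=rejections,
        consensus_resolution=consensus if RejectionCode.RESOLUTION_MISMATCH not in rejections else None,
        notes=notes,
    )
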