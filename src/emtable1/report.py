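"""Assembly of the cryo-EM "Table 1" report.

The report mirrors the three-section layout used in structural publications
— model quality, data quality, model-versus-data fit — with explicit
"not available" and "not computed" semantics: d_FSC is absent with a reason
when half-maps were not deposited; rotamer outliers, CaBLAM and EMRinger
are not computed by this toolkit (they need large external reference
libraries) and say so; EMRinger additionally only applies to maps better
than 4 A. A rejected entry produces a verdict-only report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any

from .curation import CurationVerdict
from .errors import IncompleteReportError
from .geometry_metrics import GeometrySummary
from .map_metrics import MapModelCC, ResolutionEstimates

NOT_COMPUTED_ROTAMER = "rotamer classification requires an external rotamer library"
NOT_COMPUTED_CABLAM = "CaBLAM requires an external reference library"
NOT_COMPUTED_EMRINGER = (
    "EMRinger requires an external reference library; it is only calculated "
    "when the map resolution is better than 4 A"
)
DFSC_ABSENT_REASON = "half-maps not available"


def _not_computed(reason: str) -> dict:
    return {"status": "not_computed", "reason": reason}


def _absent(reason: str) -> dict:
    return {"status": "absent", "reason": reason}


@dataclass
class Table1Report:
    """The assembled report; ``sections`` preserves publication row order."""

    accepted: bool
    verdict: dict
    model_section: dict[str, Any] = field(default_factory=dict)
    data_section: dict[str, Any] = field(default_factory=dict)
    model_vs_data_section: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "Table1Report":
        return cls(**json.loads(text))

    def to_text(self) -> str:
        """Aligned plain-text rendering in publication row order."""
        lines = []
        if not self.accepted:
            lines.append("Entry rejected by curation:")
            for code in self.verdict.get("rejections", []):
                lines.append(f"  - {code}")
            for note in self.verdict.get("notes", []):
                lines.append(f"    {note}")
            return "\n".join(lines)

        def fmt(value) -> str:
            if isinstance(value, dict):
                return f"({value['status']}: {value['reason']})"
            if value is None:
                return "-"
            if isinstance(value, float):
                return f"{value:.3f}".rstrip("0").rstrip(".")
            return str(value)

        width = 42
        for title, section in (
            ("Model", self.model_section),
            ("Data", self.data_section),
            ("Model versus data", self.model_vs_data_section),
        ):
            lines.append(title)
            for key, value in section.items():
                lines.append(f"  {key:<{width}}{fmt(value)}")
        return "\n".join(lines)


def assemble_table1(
    verdict: CurationVerdict,
    res: ResolutionEstimates | None = None,
    cc: MapModelCC | None = None,
    geom: GeometrySummary | None = None,
    provenance: dict | None = None,
) -> Table1Report:
    """Combine the stage results into the final report.

    A rejected verdict yields a verdict-only report; an accepted one
    requires every stage result and raises :class:`IncompleteReportError`
    naming the first missing stage otherwise.
    """
    if not verdict.accepted:
        return Table1Report(accepted=False, verdict=verdict.to_dict(),
                            provenance=provenance or {})
    for stage, value in (("resolution estimates", res), ("map-model CC", cc),
                         ("geometry summary", geom)):
        if value is None:
            raise IncompleteReportError(f"missing upstream result: {stage}")

    model_section = {
        "Clashscore": geom.clashscore,
        "R.m.s.d. bonds (A)": geom.rmsd_bonds,
        "R.m.s.d. angles (deg)": geom.rmsd_angles,
        "Cbeta deviations (count)": geom.n_cbeta_dev,
        "Rotamer outliers (%)": _not_computed(NOT_COMPUTED_ROTAMER),
        "Minimum nonbonded distance (A)": geom.min_nonbonded,
        "CaBLAM outliers (%)": _not_computed(NOT_COMPUTED_CABLAM),
        "Ramachandran outliers (%)": geom.rama_outliers,
        "Ramachandran allowed (%)": geom.rama_allowed,
        "Ramachandran favored (%)": geom.rama_favored,
        "Rama-Z score": geom.rama_z,
        "Rama-Z band": geom.rama_z_band,
    }
    data_section = {
        "d_FSC (A)": res.d_fsc if res.d_fsc is not None else _absent(DFSC_ABSENT_REASON),
        "d_FSC at 0.5 (A)": (
            res.d_fsc_05 if res.d_fsc_05 is not None else _absent(DFSC_ABSENT_REASON)
        ),
        "Consensus resolution (A)": res.consensus,
        "d_model (A)": res.d_model,
        "d_99 (A)": res.d_99,
    }
    if not res.d_model_reliable:
        data_section["d_model note"] = (
            "unreliable: CC_mask at the optimum is below 0.2 (model may not fit the map)"
        )
    mvd_section = {
        "CC_box": cc.cc_box,
        "CC_mask": cc.cc_mask,
        "EMRinger": _not_computed(NOT_COMPUTED_EMRINGER),
    }
    return Table1Report(
        accepted=True,
        verdict=verdict.to_dict(),
        model_section=model_section,
        data_section=data_section,
        model_vs_data_section=mvd_section,
        provenance=provenance or {},
    )
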