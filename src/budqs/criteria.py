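"""Intercellular-signalling and quorum-sensing criteria evaluation.

A candidate molecule qualifies as an *intercellular signalling molecule*
only if it is extracellular and chemically identified, acts through a
specific signalling mechanism, reproduces the response at physiological
concentrations, and is adaptive at the community level.  It additionally
qualifies as a *quorum-sensing molecule* only if its concentration is
proportional to cell density and the response is triggered at a critical
threshold.  The evidence values themselves are scientific judgements
supplied as input; this module only encodes the conjunction logic.
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "QSEvidence",
    "QSVerdict",
    "SIGNALLING_CRITERIA",
    "QS_CRITERIA",
    "evaluate_criteria",
]

SIGNALLING_CRITERIA = (
    "extracellular_identified",
    "specific_mechanism",
    "reproducible_at_physiological_conc",
    "adaptive_community_level",
)

QS_CRITERIA = (
    "proportional_to_cell_density",
    "critical_threshold_trigger",
)

#: human-readable checklist labels, in report order
CRITERION_LABELS = {
    "extracellular_identified": "Extracellular and identified",
    "specific_mechanism": "Specific signalling mechanism",
    "reproducible_at_physiological_conc": "Reproducible response",
    "adaptive_community_level": "Adaptive at community level",
    "proportional_to_cell_density": "Proportional to cell density",
    "critical_threshold_trigger": "Critical threshold trigger",
}


class QSEvidence(BaseModel):
    """Boolean evidence for the six criteria; every flag must be set."""

    model_config = ConfigDict(frozen=True)

    extracellular_identified: bool
    specific_mechanism: bool
    reproducible_at_physiological_conc: bool
    adaptive_community_level: bool
    proportional_to_cell_density: bool
    critical_threshold_trigger: bool
    notes: dict[str, str] = Field(default_factory=dict)

    def flag(self, criterion: str) -> bool:
        if criterion not in SIGNALLING_CRITERIA + QS_CRITERIA:
            raise KeyError(f"unknown criterion {criterion!r}")
        return bool(getattr(self, criterion))


@dataclass(frozen=True)
class QSVerdict:
    """Two-tier verdict: quorum sensing implies intercellular signalling."""

    molecule: str
    is_intercellular_signalling_molecule: bool
    is_quorum_sensing_molecule: bool
    failing: tuple[str, ...]


def evaluate_criteria(evidence: QSEvidence, molecule: str = "") -> QSVerdict:
    """Apply the conjunction logic to one molecule's evidence."""
    failing = tuple(
        c for c in SIGNALLING_CRITERIA + QS_CRITERIA if not evidence.flag(c)
    )
    signalling = all(evidence.flag(c) for c in SIGNALLING_CRITERIA)
    quorum = signalling and all(evidence.flag(c) for c in QS_CRITERIA)
    return QSVerdict(
        molecule=molecule,
        is_intercellular_signalling_molecule=signalling,
        is_quorum_sensing_molecule=quorum,
        failing=failing,
    )
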