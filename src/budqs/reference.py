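"""Published study values used as fixed inputs to the worked analyses.

All concentrations are in µM.  The critical-window ranges are the
physiological concentration brackets reported for metabolites that were
not raw-media nutrients and increased during growth, spanning the 10-20 h
window in which unipolar budding rose significantly.  Ranges are printed
sorted (min-max); under low nitrogen every listed metabolite peaked at
20 h, so the 20 h value is the upper endpoint.  Under high nitrogen,
tyrosol and fumarate reached their within-window maximum at 10 h, so their
20 h values are the *lower* endpoints — the reading consistent with the
reported between-condition percent differences (tyrosol 63% and fumarate
73% lower under high nitrogen).
"""

from __future__ import annotations

from .criteria import QSEvidence
from .density import WellGeometry

__all__ = [
    "LOW_N_CRITICAL_RANGES",
    "HIGH_N_CRITICAL_RANGES",
    "LOW_N_CONC_20H",
    "HIGH_N_CONC_20H",
    "NITROGEN_COMPARISON_METABOLITES",
    "PHENYLETHANOL_DOSE_UM",
    "PHENYLETHANOL_CRITICAL_WINDOW_MAX_UM",
    "PHENYLETHANOL_OVERALL_MAX_UM",
    "CRITICAL_LOCAL_CD_LOW_N",
    "CRITICAL_LOCAL_CD_HIGH_N",
    "STUDY_GEOMETRY",
    "PHENYLETHANOL_EVIDENCE",
]

#: (min, max) µM across the 10-20 h critical window, low nitrogen (SLAD)
LOW_N_CRITICAL_RANGES: dict[str, tuple[float, float]] = {
    "1-propanol": (1.4, 3.7),
    "2-hydroxyisovalerate": (0.7, 1.3),
    "2-oxoglutarate": (4.4, 9.3),
    "2-phenylethanol": (0.7, 1.5),
    "acetaldehyde": (2.3, 19.2),
    "acetate": (17.0, 160.0),
    "acetoin": (6.7, 8.0),
    "ethanol": (369.0, 5403.0),
    "fumarate": (0.5, 1.1),
    "isoamylol": (0.6, 1.0),
    "isopropanol": (0.4, 2.1),
    "lactate": (29.0, 224.0),
    "malate": (2.9, 6.8),
    "pyruvate": (5.0, 30.6),
    "succinate": (2.5, 12.0),
    "tyrosol": (0.3, 0.8),
}

#: (min, max) µM across the 10-20 h critical window, high nitrogen (SAD)
HIGH_N_CRITICAL_RANGES: dict[str, tuple[float, float]] = {
    "1-propanol": (1.4, 3.4),
    "2-hydroxyisovalerate": (0.4, 0.5),
    "2-oxoglutarate": (1.5, 2.0),
    "2-phenylethanol": (0.4, 0.6),
    "acetaldehyde": (2.0, 18.0),
    "acetate": (27.0, 186.0),
    "acetoin": (1.0, 5.6),
    "ethanol": (472.0, 4972.0),
    "fumarate": (0.3, 0.4),
    "isoamylol": (0.7, 0.9),
    "isopropanol": (0.3, 2.9),
    "lactate": (33.0, 231.0),
    "malate": (2.1, 2.2),
    "pyruvate": (11.5, 38.8),
    "succinate": (0.9, 1.6),
    "tyrosol": (0.3, 0.6),
}

#: 20 h concentrations, low nitrogen (all metabolites peaked at 20 h)
LOW_N_CONC_20H: dict[str, float] = {
    m: hi for m, (_, hi) in LOW_N_CRITICAL_RANGES.items()
}

#: metabolites whose high-nitrogen within-window maximum fell at 10 h
_HIGH_N_PEAK_AT_10H = ("tyrosol", "fumarate")

#: 20 h concentrations, high nitrogen (see module docstring on endpoints)
HIGH_N_CONC_20H: dict[str, float] = {
    m: (lo if m in _HIGH_N_PEAK_AT_10H else hi)
    for m, (lo, hi) in HIGH_N_CRITICAL_RANGES.items()
}

#: metabolites whose low-vs-high-nitrogen 20 h differences were reported
NITROGEN_COMPARISON_METABOLITES = (
    "2-phenylethanol",
    "tyrosol",
    "2-hydroxyisovalerate",
    "2-oxoglutarate",
    "fumarate",
    "malate",
    "succinate",
    "acetate",
    "pyruvate",
)

#: exogenous 2-phenylethanol dose used to force unipolar budding
PHENYLETHANOL_DOSE_UM = 20.0
#: 2-phenylethanol maximum within the low-nitrogen critical window
PHENYLETHANOL_CRITICAL_WINDOW_MAX_UM = 1.5
#: 2-phenylethanol maximum over the whole low-nitrogen experiment (30 h)
PHENYLETHANOL_OVERALL_MAX_UM = 4.3

#: local cell densities (cells/ml) bracketing the unipolar increase
CRITICAL_LOCAL_CD_LOW_N = (4.8e6, 5.3e7)
CRITICAL_LOCAL_CD_HIGH_N = (5.2e6, 8.2e7)

#: 12-well plate monolayer geometry used throughout the study
STUDY_GEOMETRY = WellGeometry(
    bottom_area_cm2=3.85, cell_diameter_um=10.0, v_sample_ml=1.0
)

#: checklist evidence for 2-phenylethanol from the study's experiments
PHENYLETHANOL_EVIDENCE = QSEvidence(
    extracellular_identified=True,
    specific_mechanism=True,
    reproducible_at_physiological_conc=False,
    adaptive_community_level=True,
    proportional_to_cell_density=True,
    critical_threshold_trigger=False,
    notes={
        "reproducible_at_physiological_conc": (
            "response only observed at 20 µM, far above the physiological "
            "0.7-1.5 µM produced in the critical window"
        ),
        "critical_threshold_trigger": (
            "induction only at high concentration suggests a toxicity or "
            "stress response rather than a threshold-triggered switch"
        ),
    },
)
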