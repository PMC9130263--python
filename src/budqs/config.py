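"""Configuration models for the synthetic budding / quorum-sensing study.

A :class:`SimulationConfig` fully determines one synthetic experiment:
per-window budding-program mixtures, monolayer growth kinetics, and the
extracellular metabolite trajectories whose NMR peak areas the generator
emits.  Identical config + seed produces byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: canonical ordering of budding patterns / latent programs everywhere
PATTERN_ORDER = ("axial", "bipolar", "unipolar")

_SIMPLEX_TOL = 1e-9


class MetaboliteSpec(BaseModel):
    """True concentration trajectory of one extracellular compound.

    ``producer`` compounds are excreted by the cells and follow a monotone
    trajectory from ``c_start_um`` (at inoculation) to ``c_end_um`` (at the
    end of the experiment).  ``nutrient`` compounds are present in the raw
    media and are flat or consumed (``c_end_um <= c_start_um``).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    role: Literal["producer", "nutrient"]
    c_start_um: float = Field(ge=0.0)
    c_end_um: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _nutrients_do_not_increase(self) -> "MetaboliteSpec":
        if self.role == "nutrient" and self.c_end_um > self.c_start_um:
            raise ValueError(
                f"nutrient {self.name!r} must be flat or decreasing "
                f"(c_start={self.c_start_um}, c_end={self.c_end_um})"
            )
        return self


def _default_metabolites() -> tuple[MetaboliteSpec, ...]:
    # Trajectories chosen so the noise-free concentrations at 10/20 h land on
    # the published low-nitrogen critical-window ranges (geometric growth of
    # fermentation products; glucose consumed).  Units: µM.
    producers = [
        ("ethanol", 25.0, 80000.0),
        ("2-phenylethanol", 0.33, 3.2),
        ("tyrosol", 0.11, 2.1),
        ("acetate", 1.8, 1500.0),
        ("succinate", 0.52, 57.6),
        ("lactate", 3.8, 1700.0),
    ]
    specs = [
        MetaboliteSpec(name=n, role="producer", c_start_um=a, c_end_um=b)
        for n, a, b in producers
    ]
    specs.append(
        MetaboliteSpec(
            name="glucose", role="nutrient", c_start_um=111000.0, c_end_um=5000.0
        )
    )
    return tuple(specs)


def _default_program_weights() -> tuple[tuple[float, float, float], ...]:
    # Per-window (axial, bipolar, unipolar) mixture.  Unipolar weights back out
    # the published two-site unipolar percentages (72% -> 91%) through the
    # bipolar program's all-opposite probability 0.7 * 0.5 = 0.35:
    # w_uni = (obs - 0.35) / 0.65.
    w0 = (0.72 - 0.35) / 0.65
    w1 = (0.91 - 0.35) / 0.65
    return (
        (0.0, 1.0 - w0, w0),
        (0.0, 1.0 - w1, w1),
        (0.0, 1.0 - w1, w1),
    )


class SimulationConfig(BaseModel):
    """Every knob of the synthetic study, with study-condition defaults."""

    model_config = ConfigDict(frozen=True)

    seed: int = Field(ge=0)
    condition: str = "low_nitrogen"

    # --- budding-pattern scoring ---------------------------------------
    n_windows: int = Field(default=3, ge=1)
    window_hours: float = Field(default=10.0, gt=0.0)
    cells_per_window: int = Field(default=250, ge=1)
    frac_three_sites: tuple[float, ...] = (0.4, 0.4, 0.0)
    program_weights: tuple[tuple[float, float, float], ...] = Field(
        default_factory=_default_program_weights
    )
    first_bud_opposite_bias: float = Field(default=0.7, ge=0.0, le=1.0)
    subsequent_bud_opposite_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    angle_noise_sd_deg: float = Field(default=20.0, ge=0.0)

    # --- growth ---------------------------------------------------------
    cd0: float = Field(default=1e3, gt=0.0)
    doubling_time_h: float = Field(default=2.6, gt=0.0)
    decline_rate_after_20h: float = Field(default=1.25, ge=0.0)
    replicates: int = Field(default=3, ge=1)
    count_noise_cv: float = Field(default=0.10, ge=0.0)

    # --- NMR peak areas -------------------------------------------------
    metabolite_specs: tuple[MetaboliteSpec, ...] = Field(
        default_factory=_default_metabolites
    )
    area_noise_cv: float = Field(default=0.05, ge=0.0)
    glucose_raw_media_conc: float = Field(default=111000.0, gt=0.0)
    tsp_true_conc: float = Field(default=100.0, gt=0.0)
    n_raw_media_samples: int = Field(default=3, ge=1)

    @model_validator(mode="after")
    def _check_windows(self) -> "SimulationConfig":
        if len(self.frac_three_sites) != self.n_windows:
            raise ValueError(
                f"frac_three_sites has {len(self.frac_three_sites)} entries "
                f"for {self.n_windows} windows"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.frac_three_sites):
            raise ValueError("frac_three_sites entries must lie in [0, 1]")
        if len(self.program_weights) != self.n_windows:
            raise ValueError(
                f"program_weights has {len(self.program_weights)} rows "
                f"for {self.n_windows} windows"
            )
        for i, row in enumerate(self.program_weights):
            if len(row) != 3:
                raise ValueError(f"program_weights[{i}] must have 3 entries")
            if any(not 0.0 <= w <= 1.0 for w in row):
                raise ValueError(f"program_weights[{i}] entries must lie in [0, 1]")
            if abs(sum(row) - 1.0) > _SIMPLEX_TOL:
                raise ValueError(
                    f"program_weights[{i}] sums to {sum(row)!r}, not 1"
                )
        names = [m.name for m in self.metabolite_specs]
        if len(set(names)) != len(names):
            raise ValueError("metabolite_specs names must be unique")
        return self

    def window_label(self, window: int) -> str:
        t0 = window * self.window_hours
        t1 = (window + 1) * self.window_hours
        return f"{t0:g}-{t1:g} h"

    def sample_times(self) -> list[float]:
        """Hemocytometer / media-collection times (window boundaries)."""
        return [i * self.window_hours for i in range(self.n_windows + 1)]

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a JSON or YAML document."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return SimulationConfig(**data)
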