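"""Local cell density for cells immobilised on a well bottom.

Hemocytometer counts measure cells per ml of the sampled culture volume,
but immobilised cells experience the density of the thin monolayer slab at
the well bottom.  With a bottom surface area A (cm²) and a cell diameter d
(µm), that slab has volume

    V_bottom = A x d        (d converted to cm),

and the density the cells experience is

    local CD = measured CD x V_sample / V_bottom.

With the default 12-well geometry (A = 3.85 cm², d = 10 µm, V_sample =
1 ml) the slab is 3.85 x 10^-3 cm³ and the amplification factor is
1 / 3.85e-3 ≈ 259.74.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fisher import Transition

__all__ = [
    "WellGeometry",
    "CriticalWindow",
    "v_bottom",
    "to_local",
    "summarize_growth",
    "critical_window",
]

_UM_PER_CM = 1e4


@dataclass(frozen=True)
class WellGeometry:
    """Monolayer geometry; defaults match a C-treated 12-well plate."""

    bottom_area_cm2: float = 3.85
    cell_diameter_um: float = 10.0
    v_sample_ml: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bottom_area_cm2", "cell_diameter_um", "v_sample_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def v_bottom(geometry: WellGeometry) -> float:
    """Volume (cm³) of the cell monolayer slab at the well bottom."""
    return geometry.bottom_area_cm2 * (geometry.cell_diameter_um / _UM_PER_CM)


def to_local(measured_cd, geometry: WellGeometry = WellGeometry()):
    """Convert measured cells/ml to the local density at the well bottom.

    Accepts scalars or arrays; 1 ml and 1 cm³ are the same volume, so the
    conversion factor v_sample / v_bottom is dimensionless.
    """
    arr = np.asarray(measured_cd, dtype=float)
    if np.any(arr < 0):
        raise ValueError("measured cell density must be non-negative")
    out = arr * geometry.v_sample_ml / v_bottom(geometry)
    return float(out) if np.isscalar(measured_cd) else out


def summarize_growth(
    records: pd.DataFrame, geometry: WellGeometry = WellGeometry()
) -> pd.DataFrame:
    """Per-time mean and sample SD of measured and local cell density.

    ``records`` needs columns ``time_h``, ``replicate``, ``measured_cd``.
    SD uses n-1 degrees of freedom and is NaN at times with one replicate.
    """
    required = {"time_h", "replicate", "measured_cd"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"growth table missing columns {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("growth table is empty")
    df = records.copy()
    df["local_cd"] = to_local(df["measured_cd"].to_numpy(), geometry)
    grp = df.groupby("time_h", sort=True)
    out = grp.agg(
        n=("measured_cd", "size"),
        measured_mean=("measured_cd", "mean"),
        measured_sd=("measured_cd", lambda s: s.std(ddof=1)),
        local_mean=("local_cd", "mean"),
        local_sd=("local_cd", lambda s: s.std(ddof=1)),
    ).reset_index()
    return out


@dataclass(frozen=True)
class CriticalWindow:
    """Local-density bracket around the first significant unipolar increase."""

    window_pair: tuple[object, object]
    t_start_h: float
    t_end_h: float
    local_cd_start: float
    local_cd_end: float
    p_value: float
    secondary: tuple[Transition, ...] = field(default=())


def _mean_local_at(growth_summary: pd.DataFrame, t: float) -> float:
    hit = growth_summary[np.isclose(growth_summary["time_h"], t)]
    if len(hit) == 0:
        raise ValueError(f"no density summary at t = {t:g} h")
    return float(hit["local_mean"].iloc[0])


def critical_window(
    transitions: Sequence[Transition],
    growth_summary: pd.DataFrame,
    window_hours: float = 10.0,
) -> CriticalWindow | None:
    """Bracket the first significant unipolar increase with local densities.

    For a transition from window i to window i+1 the bracketing densities
    are the mean local CDs at the *boundaries* of window i+1 (the paper's
    10-20 h switch is bracketed by the 10 h and 20 h counts).  Returns
    ``None`` when no transition was detected ("no switch detected").
    Later transitions, if any, are carried along as ``secondary``.
    """
    if not transitions:
        return None
    ordered = sorted(transitions, key=lambda tr: float(tr.window_to))
    first, rest = ordered[0], tuple(ordered[1:])
    w = float(first.window_to)
    t_start, t_end = w * window_hours, (w + 1) * window_hours
    cd_start = _mean_local_at(growth_summary, t_start)
    cd_end = _mean_local_at(growth_summary, t_end)
    if cd_start > cd_end:
        warnings.warn(
            f"local CD decreases across the critical window "
            f"({cd_start:.3g} -> {cd_end:.3g} cells/ml): culture not growing?",
            stacklevel=2,
        )
    return CriticalWindow(
        window_pair=(first.window_from, first.window_to),
        t_start_h=t_start,
        t_end_h=t_end,
        local_cd_start=cd_start,
        local_cd_end=cd_end,
        p_value=first.result.p_value,
        secondary=rest,
    )
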