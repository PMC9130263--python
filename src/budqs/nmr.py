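"""Absolute metabolite quantification from aligned 1H-NMR peak areas.

Quantification uses the internal-standard equation

    C(X) = Area(X) / Area(Ref) * H(Ref) * C(Ref) / H(X)

where Ref is TSP (9 equivalent protons) and H the number of protons giving
rise to the integrated signal.  Because short recycle delays make direct
absolute TSP quantification unreliable, calibration is two-step: the known
glucose concentration of the raw (uninoculated) media first yields a
per-sample estimate of the TSP concentration; the average of those
estimates then serves as C(Ref) for every culture sample.  Concentrations
produced this way are estimates of absolute concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteInfo",
    "MetaboliteRegistry",
    "CalibrationResult",
    "PhysiologicalRange",
    "estimate_cref",
    "quantify",
    "summarize_concentrations",
    "filter_candidates",
    "physiological_range",
    "percent_change",
    "fold_difference",
    "round_half_away",
]

REFERENCE_NAME = "TSP"
REFERENCE_PROTONS = 9


@dataclass(frozen=True)
class MetaboliteInfo:
    name: str
    n_protons: int
    in_raw_media: bool

    def __post_init__(self) -> None:
        if int(self.n_protons) < 1:
            raise ValueError(f"{self.name}: n_protons must be >= 1")


class MetaboliteRegistry:
    """Proton counts and raw-media membership per metabolite."""

    def __init__(self, entries: Iterable[MetaboliteInfo]):
        self._by_name: dict[str, MetaboliteInfo] = {}
        for e in entries:
            if e.name in self._by_name:
                raise ValueError(f"duplicate registry entry {e.name!r}")
            self._by_name[e.name] = e

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def names(self) -> list[str]:
        return sorted(self._by_name)

    def get(self, name: str) -> MetaboliteInfo:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"metabolite {name!r} not in registry") from None

    def protons(self, name: str) -> int:
        return self.get(name).n_protons

    def in_raw_media(self, name: str) -> bool:
        return self.get(name).in_raw_media

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetaboliteRegistry":
        required = {"metabolite", "n_protons", "in_raw_media"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"registry table missing columns {sorted(missing)}")
        entries = [
            MetaboliteInfo(
                name=str(r.metabolite),
                n_protons=int(r.n_protons),
                in_raw_media=bool(r.in_raw_media),
            )
            for r in df.itertuples()
        ]
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetaboliteRegistry":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metabolite": e.name,
                    "n_protons": e.n_protons,
                    "in_raw_media": e.in_raw_media,
                }
                for e in (self._by_name[n] for n in self.names())
            ]
        )


@dataclass(frozen=True)
class CalibrationResult:
    """Per-raw-media-sample TSP estimates and their average (µM)."""

    per_sample: Mapping[str, float]
    c_ref: float
    n_samples: int


def _require_columns(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{what} missing columns {sorted(missing)}")


def estimate_cref(
    areas: pd.DataFrame,
    known_glucose_conc: float,
    registry: MetaboliteRegistry,
    reference: str = REFERENCE_NAME,
    glucose: str = "glucose",
) -> CalibrationResult:
    """Estimate the TSP concentration from raw-media glucose signals.

    Solves the quantification equation for C(Ref) in each raw-media sample:
    C(Ref) = C(glc) * Area(Ref) * H(glc) / (Area(glc) * H(Ref)), then
    averages over samples.
    """
    _require_columns(areas, {"sample_id", "metabolite", "area"}, "peak-area table")
    if known_glucose_conc <= 0:
        raise ValueError("known glucose concentration must be positive")
    if "sample_role" in areas.columns:
        raw = areas[areas["sample_role"] == "raw_media"]
    else:
        raw = areas
    if len(raw) == 0:
        raise ValueError("no raw-media samples available for calibration")
    h_glc = registry.protons(glucose)
    h_ref = registry.protons(reference)
    estimates: dict[str, float] = {}
    for sid, grp in raw.groupby("sample_id", sort=True):
        by_met = grp.set_index("metabolite")["area"]
        if glucose not in by_met.index or reference not in by_met.index:
            raise ValueError(
                f"raw-media sample {sid!r} lacks a {glucose!r} or {reference!r} area"
            )
        a_glc, a_ref = float(by_met[glucose]), float(by_met[reference])
        if a_glc <= 0 or a_ref <= 0:
            raise ValueError(
                f"raw-media sample {sid!r} has non-positive {glucose}/{reference} area"
            )
        estimates[sid] = known_glucose_conc * a_ref * h_glc / (a_glc * h_ref)
    return CalibrationResult(
        per_sample=estimates,
        c_ref=float(np.mean(list(estimates.values()))),
        n_samples=len(estimates),
    )


def quantify(
    areas: pd.DataFrame,
    c_ref: float,
    registry: MetaboliteRegistry,
    reference: str = REFERENCE_NAME,
) -> pd.DataFrame:
    """Per-sample absolute concentrations (µM) via the internal standard.

    Operates on culture samples (``sample_role == 'culture'`` when the
    column is present); every sample must carry a positive reference area.
    Returns one row per (sample, metabolite) with a ``conc_um`` column.
    """
    _require_columns(
        areas, {"sample_id", "metabolite", "area"}, "peak-area table"
    )
    if c_ref <= 0:
        raise ValueError("reference concentration must be positive")
    df = areas
    if "sample_role" in df.columns:
        df = df[df["sample_role"] == "culture"]
    unknown = sorted(set(df["metabolite"]) - set(registry.names()))
    if unknown:
        raise KeyError(f"metabolite(s) not in registry: {unknown}")
    h_ref = registry.protons(reference)
    out_rows = []
    for sid, grp in df.groupby("sample_id", sort=True):
        ref_rows = grp[grp["metabolite"] == reference]
        if len(ref_rows) == 0 or float(ref_rows["area"].iloc[0]) <= 0:
            raise ValueError(f"sample {sid!r} lacks a positive {reference!r} area")
        a_ref = float(ref_rows["area"].iloc[0])
        for row in grp.itertuples():
            if row.metabolite == reference:
                continue
            h_x = registry.protons(row.metabolite)
            conc = float(row.area) / a_ref * h_ref * c_ref / h_x
            rec = {c: getattr(row, c) for c in grp.columns if c != "area"}
            rec["conc_um"] = conc
            out_rows.append(rec)
    return pd.DataFrame(out_rows)


def summarize_concentrations(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD concentration per (condition, time, metabolite).

    SD needs at least two biological replicates and is NaN otherwise.
    """
    _require_columns(
        per_sample,
        {"condition", "time_h", "metabolite", "conc_um"},
        "per-sample concentration table",
    )
    grp = per_sample.groupby(["condition", "time_h", "metabolite"], sort=True)
    out = grp.agg(
        mean_um=("conc_um", "mean"),
        sd_um=("conc_um", lambda s: s.std(ddof=1) if len(s) >= 2 else np.nan),
        n=("conc_um", "size"),
    ).reset_index()
    return out


def _mean_at(
    conc: pd.DataFrame, metabolite: str, time_h: float, condition: str | None
) -> float:
    df = conc
    if condition is not None:
        df = df[df["condition"] == condition]
    elif df["condition"].nunique() > 1:
        raise ValueError("multiple conditions present: pass condition explicitly")
    hit = df[(df["metabolite"] == metabolite) & np.isclose(df["time_h"], time_h)]
    if len(hit) == 0:
        raise ValueError(f"no concentration for {metabolite!r} at t = {time_h:g} h")
    return float(hit["mean_um"].iloc[0])


def filter_candidates(
    conc: pd.DataFrame,
    registry: MetaboliteRegistry,
    window_end: float,
    min_fold: float = 1.0,
    condition: str | None = None,
) -> list[str]:
    """Metabolites plausibly linked to the switch: excreted and increasing.

    Keeps metabolites that are not raw-media nutrients and whose mean
    concentration at ``window_end`` strictly exceeds ``min_fold`` times the
    baseline (earliest-time) mean.  Output is sorted; may be empty.
    """
    _require_columns(
        conc, {"condition", "time_h", "metabolite", "mean_um"}, "concentration table"
    )
    baseline_t = float(conc["time_h"].min())
    kept = []
    for met in sorted(conc["metabolite"].unique()):
        if met not in registry or registry.in_raw_media(met):
            continue
        try:
            c0 = _mean_at(conc, met, baseline_t, condition)
            c1 = _mean_at(conc, met, window_end, condition)
        except ValueError:
            continue  # metabolite absent at an endpoint: cannot assess
        if c1 > c0 * min_fold:
            kept.append(met)
    return kept


@dataclass(frozen=True)
class PhysiologicalRange:
    """Concentration bracket of one metabolite across a time window (µM)."""

    metabolite: str
    t_start_h: float
    t_end_h: float
    c_low_um: float
    c_high_um: float


def physiological_range(
    conc: pd.DataFrame,
    metabolite: str,
    window: tuple[float, float],
    condition: str | None = None,
) -> PhysiologicalRange:
    """Mean concentrations at the two boundaries of a time window."""
    t_start, t_end = float(window[0]), float(window[1])
    if t_start == t_end:
        raise ValueError("window start and end must differ")
    c_low = _mean_at(conc, metabolite, t_start, condition)
    c_high = _mean_at(conc, metabolite, t_end, condition)
    return PhysiologicalRange(
        metabolite=metabolite,
        t_start_h=t_start,
        t_end_h=t_end,
        c_low_um=c_low,
        c_high_um=c_high,
    )


def percent_change(c_reference_condition: float, c_other: float) -> float:
    """Signed percent difference of ``c_other`` relative to the reference.

    Full precision is returned; use :func:`round_half_away` when reporting
    to integer percent.
    """
    if c_reference_condition <= 0:
        raise ValueError("reference concentration must be positive")
    return 100.0 * (c_other - c_reference_condition) / c_reference_condition


def fold_difference(dose: float, physiological_max: float) -> float:
    """How many times an exogenous dose exceeds the physiological maximum."""
    if physiological_max <= 0:
        raise ValueError("physiological maximum must be positive")
    return dose / physiological_max


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero (-62.5 -> -63)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))
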