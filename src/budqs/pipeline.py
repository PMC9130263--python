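"""End-to-end orchestration and structured reporting.

``run_pipeline`` composes the analysis: (optional) simulation -> bud-site
classification and tabulation -> Fisher comparisons across consecutive
windows -> local-density summary and critical-window bracketing -> NMR
calibration, quantification, candidate filtering and physiological ranges
over the critical window -> quorum-sensing checklist verdicts.  Partial
inputs produce partial bundles with the absent sections set to ``None``.
Reports are deterministic for a fixed seed and config: provenance embeds
the config hash and seed, and no timestamp unless one is supplied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import PATTERN_ORDER, SimulationConfig
from .criteria import CRITERION_LABELS, QS_CRITERIA, SIGNALLING_CRITERIA, QSEvidence, QSVerdict, evaluate_criteria
from .density import CriticalWindow, WellGeometry, critical_window, summarize_growth
from .fisher import Transition, compare_groups, significant_transitions
from .nmr import (
    MetaboliteRegistry,
    estimate_cref,
    filter_candidates,
    physiological_range,
    quantify,
    summarize_concentrations,
)
from .patterns import classify_records, tabulate, tallies_to_frame
from .simulate import default_registry, gen_bud_records, gen_growth_series, gen_peak_area_table

__all__ = ["ReportBundle", "run_pipeline", "write_report", "read_report"]

SCHEMA_VERSION = "1.0"


@dataclass
class ReportBundle:
    """Everything one pipeline run produced; absent sections are ``None``."""

    provenance: dict
    tallies: pd.DataFrame | None = None
    comparisons: pd.DataFrame | None = None
    transitions: list[Transition] | None = None
    growth_summary: pd.DataFrame | None = None
    critical_window: CriticalWindow | None = None
    calibration_c_ref: float | None = None
    concentrations: pd.DataFrame | None = None
    candidates: list[str] | None = None
    ranges: pd.DataFrame | None = None
    verdicts: dict[str, QSVerdict] | None = None
    evidence: dict[str, QSEvidence] | None = None
    warnings: list[str] = dataclasses.field(default_factory=list)


def _comparison_frame(tallies_by_group: dict, alpha: float) -> pd.DataFrame:
    rows = []
    for (cond, n_sites), ordered in sorted(tallies_by_group.items()):
        for t1, t2 in zip(ordered, ordered[1:]):
            if t1.total == 0 or t2.total == 0:
                continue
            for pat in PATTERN_ORDER:
                res = compare_groups(t1, t2, pat, alpha=alpha)
                a, b, c, d = res.table
                rows.append(
                    {
                        "condition": cond,
                        "n_sites": n_sites,
                        "pattern": pat,
                        "group_1": res.groups[0],
                        "group_2": res.groups[1],
                        "a": a, "b": b, "c": c, "d": d,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(
    config: SimulationConfig | None = None,
    *,
    bud_records: pd.DataFrame | None = None,
    growth: pd.DataFrame | None = None,
    peak_areas: pd.DataFrame | None = None,
    registry: MetaboliteRegistry | None = None,
    evidence: Mapping[str, QSEvidence] | None = None,
    geometry: WellGeometry = WellGeometry(),
    alpha: float = 0.05,
    threshold_deg: float = 90.0,
    known_glucose_conc: float | None = None,
    bonferroni: bool = False,
) -> ReportBundle:
    """Run the full analysis; any missing input yields a partial bundle."""
    warnings_list: list[str] = []
    if config is not None:
        if bud_records is None:
            bud_records = gen_bud_records(config)
        if growth is None:
            growth = gen_growth_series(config)
        if peak_areas is None:
            peak_areas = gen_peak_area_table(config, registry)
        if registry is None:
            registry = default_registry(config)
        if known_glucose_conc is None:
            known_glucose_conc = config.glucose_raw_media_conc

    provenance = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed if config is not None else None,
        "config_hash": config.config_hash() if config is not None else None,
        "alpha": alpha,
        "threshold_deg": threshold_deg,
    }
    bundle = ReportBundle(provenance=provenance, warnings=warnings_list)

    window_hours = config.window_hours if config is not None else 10.0
    transitions: list[Transition] = []
    if bud_records is not None:
        classified = classify_records(bud_records, threshold_deg=threshold_deg)
        tallies = tabulate(classified)
        bundle.tallies = tallies_to_frame(tallies)
        by_group: dict[tuple, list] = {}
        for t in tallies:
            by_group.setdefault((t.condition, t.n_sites), []).append(t)
        for key in by_group:
            by_group[key].sort(key=lambda t: t.window)
        bundle.comparisons = _comparison_frame(by_group, alpha)
        # two-site data drive the switch call: they remain observable in
        # every window, while late windows can lack three-site cells
        for (cond, n_sites), ordered in sorted(by_group.items()):
            if n_sites != 2 or len(ordered) < 2:
                continue
            transitions.extend(
                significant_transitions(ordered, alpha=alpha, bonferroni=bonferroni)
            )
        bundle.transitions = transitions
    else:
        warnings_list.append("no bud records: budding-pattern section absent")

    if growth is not None:
        bundle.growth_summary = summarize_growth(growth, geometry)
        if bundle.transitions is not None:
            bundle.critical_window = critical_window(
                transitions, bundle.growth_summary, window_hours=window_hours
            )
            if bundle.critical_window is None:
                warnings_list.append("no switch detected")
    else:
        warnings_list.append("no growth table: cell-density section absent")

    if peak_areas is not None and registry is not None:
        if known_glucose_conc is None:
            raise ValueError("known_glucose_conc required to calibrate NMR data")
        cal = estimate_cref(peak_areas, known_glucose_conc, registry)
        bundle.calibration_c_ref = cal.c_ref
        per_sample = quantify(peak_areas, cal.c_ref, registry)
        conc = summarize_concentrations(per_sample)
        bundle.concentrations = conc
        if bundle.critical_window is not None:
            win = (bundle.critical_window.t_start_h, bundle.critical_window.t_end_h)
        else:
            times = sorted(conc["time_h"].unique())
            win = (times[0], times[-1]) if len(times) > 1 else None
        if win is not None:
            bundle.candidates = filter_candidates(conc, registry, window_end=win[1])
            rng_rows = []
            for met in bundle.candidates:
                r = physiological_range(conc, met, win)
                rng_rows.append(
                    {
                        "metabolite": r.metabolite,
                        "t_start_h": r.t_start_h,
                        "t_end_h": r.t_end_h,
                        "c_low_um": r.c_low_um,
                        "c_high_um": r.c_high_um,
                    }
                )
            bundle.ranges = pd.DataFrame(rng_rows)
    else:
        warnings_list.append("no peak areas: NMR section absent")

    if evidence:
        bundle.evidence = dict(evidence)
        bundle.verdicts = {
            mol: evaluate_criteria(ev, molecule=mol) for mol, ev in evidence.items()
        }
    return bundle


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        return None if np.isnan(obj) else obj
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, pd.DataFrame):
        return [_jsonify(rec) for rec in obj.to_dict(orient="records")]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, QSEvidence):
        return _jsonify(obj.model_dump())
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in obj]
    return str(obj)


def bundle_to_dict(bundle: ReportBundle) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "provenance": _jsonify(bundle.provenance),
        "tallies": _jsonify(bundle.tallies),
        "comparisons": _jsonify(bundle.comparisons),
        "transitions": _jsonify(bundle.transitions),
        "growth_summary": _jsonify(bundle.growth_summary),
        "critical_window": _jsonify(bundle.critical_window),
        "calibration_c_ref": _jsonify(bundle.calibration_c_ref),
        "concentrations": _jsonify(bundle.concentrations),
        "candidates": _jsonify(bundle.candidates),
        "ranges": _jsonify(bundle.ranges),
        "evidence": _jsonify(bundle.evidence),
        "verdicts": _jsonify(bundle.verdicts),
        "warnings": _jsonify(bundle.warnings),
    }


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    if df is None or len(df) == 0:
        return "_no data_\n"
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = []
        for v in row:
            if isinstance(v, float):
                cells.append("" if np.isnan(v) else floatfmt.format(v))
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def _render_markdown(bundle: ReportBundle, timestamp: str | None) -> str:
    parts = ["# Budding-pattern / quorum-sensing report\n"]
    prov = dict(bundle.provenance)
    if timestamp:
        prov["timestamp"] = timestamp
    parts.append(
        "Provenance: "
        + ", ".join(f"{k}={v}" for k, v in sorted(prov.items()))
        + "\n"
    )
    parts.append("\n## Budding-pattern tallies\n\n" + _md_table(bundle.tallies))
    parts.append("\n## Window comparisons (Fisher exact)\n\n"
                 + _md_table(bundle.comparisons))
    parts.append("\n## Growth / local cell density\n\n"
                 + _md_table(bundle.growth_summary))
    parts.append("\n## Critical window\n\n")
    cw = bundle.critical_window
    if cw is None:
        parts.append("No switch detected.\n")
    else:
        parts.append(
            f"Significant unipolar increase between windows "
            f"{cw.window_pair[0]} and {cw.window_pair[1]} "
            f"({cw.t_start_h:g}-{cw.t_end_h:g} h), local cell density "
            f"{cw.local_cd_start:.3g} -> {cw.local_cd_end:.3g} cells/ml "
            f"(p = {cw.p_value:.3g}).\n"
        )
    parts.append("\n## Metabolite concentrations (µM)\n\n")
    if bundle.concentrations is not None and len(bundle.concentrations):
        grid = bundle.concentrations.pivot_table(
            index="metabolite", columns="time_h", values="mean_um"
        ).reset_index()
        grid.columns = [
            c if isinstance(c, str) else f"{c:g} h" for c in grid.columns
        ]
        parts.append(_md_table(grid))
    else:
        parts.append("_no data_\n")
    parts.append("\n## Candidate metabolites\n\n")
    parts.append(
        (", ".join(bundle.candidates) + "\n") if bundle.candidates else "_none_\n"
    )
    parts.append("\n## Physiological ranges over the critical window\n\n"
                 + _md_table(bundle.ranges))
    parts.append("\n## Signalling / quorum-sensing checklist\n\n")
    if bundle.verdicts:
        for mol, verdict in sorted(bundle.verdicts.items()):
            ev = (bundle.evidence or {}).get(mol)
            parts.append(f"### {mol}\n\n")
            parts.append("| criterion | met |\n| --- | --- |\n")
            for crit in SIGNALLING_CRITERIA + QS_CRITERIA:
                mark = "Y" if (ev is not None and ev.flag(crit)) else "N"
                parts.append(f"| {CRITERION_LABELS[crit]} | {mark} |\n")
            parts.append(
                f"\nIntercellular signalling molecule: "
                f"**{verdict.is_intercellular_signalling_molecule}** — "
                f"quorum sensing molecule: "
                f"**{verdict.is_quorum_sensing_molecule}**\n\n"
            )
    else:
        parts.append("_no molecules assessed_\n")
    if bundle.warnings:
        parts.append("\n## Warnings\n\n")
        parts.extend(f"- {w}\n" for w in bundle.warnings)
    return "".join(parts)


def write_report(
    bundle: ReportBundle, out_dir: str | Path, timestamp: str | None = None
) -> tuple[Path, Path]:
    """Write ``report.json`` and ``report.md``; deterministic by default."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = bundle_to_dict(bundle)
    if timestamp:
        doc["provenance"]["timestamp"] = timestamp
    json_path = out / "report.json"
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    md_path = out / "report.md"
    md_path.write_text(_render_markdown(bundle, timestamp))
    return json_path, md_path


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema {doc.get('schema_version')!r}"
        )
    return doc
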