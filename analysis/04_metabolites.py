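#!/usr/bin/env python
"""Quantify metabolites from NMR peak areas (two-step TSP calibration),
filter switch candidates, extract physiological ranges over the critical
window, and recompute the published low- vs high-nitrogen 20 h comparisons.

Reads results/synthetic/{peak_areas,registry}.tsv and
results/critical_window.json; writes results/nmr/* and
results/nitrogen_comparisons.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from budqs import MetaboliteRegistry, estimate_cref, filter_candidates, physiological_range, quantify, summarize_concentrations
from budqs.io import read_peak_areas, write_table
from budqs.nmr import fold_difference, percent_change, round_half_away
from budqs.reference import (
    HIGH_N_CONC_20H,
    LOW_N_CONC_20H,
    NITROGEN_COMPARISON_METABOLITES,
    PHENYLETHANOL_CRITICAL_WINDOW_MAX_UM,
    PHENYLETHANOL_DOSE_UM,
    PHENYLETHANOL_OVERALL_MAX_UM,
)

ROOT = Path(__file__).resolve().parents[1]
KNOWN_GLUCOSE_UM = 111000.0  # 2 g/100 ml in the defined media


def main() -> None:
    out = ROOT / "results" / "nmr"
    areas = read_peak_areas(ROOT / "results" / "synthetic" / "peak_areas.tsv")
    registry = MetaboliteRegistry.from_tsv(
        ROOT / "results" / "synthetic" / "registry.tsv"
    )

    cal = estimate_cref(areas, KNOWN_GLUCOSE_UM, registry)
    print(f"TSP estimate: {cal.c_ref:.4g} µM "
          f"(average of {cal.n_samples} raw-media samples)")
    conc = summarize_concentrations(quantify(areas, cal.c_ref, registry))
    write_table(conc, out / "concentrations.tsv")

    cw = json.loads((ROOT / "results" / "critical_window.json").read_text())
    window = (cw["t_start_h"], cw["t_end_h"]) if cw["switch_detected"] else (10.0, 20.0)
    cands = filter_candidates(conc, registry, window_end=window[1])
    (out / "candidates.txt").write_text("\n".join(cands) + "\n")
    print(f"candidate metabolites (excreted, increasing): {', '.join(cands)}")

    ranges = pd.DataFrame(
        [
            {"metabolite": r.metabolite, "t_start_h": r.t_start_h,
             "t_end_h": r.t_end_h, "c_low_um": r.c_low_um,
             "c_high_um": r.c_high_um}
            for r in (physiological_range(conc, m, window) for m in cands)
        ]
    )
    write_table(ranges, out / "ranges.tsv")
    print(ranges.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    # published 20 h concentrations: how the metabolome differs with nitrogen
    rows = []
    for met in NITROGEN_COMPARISON_METABOLITES:
        pct = percent_change(LOW_N_CONC_20H[met], HIGH_N_CONC_20H[met])
        rows.append(
            {"metabolite": met, "c_low_n_um": LOW_N_CONC_20H[met],
             "c_high_n_um": HIGH_N_CONC_20H[met],
             "percent_change": round_half_away(pct)}
        )
    comp = pd.DataFrame(rows)
    write_table(comp, ROOT / "results" / "nitrogen_comparisons.tsv")
    print(comp.to_string(index=False))

    fold_window = fold_difference(PHENYLETHANOL_DOSE_UM,
                                  PHENYLETHANOL_CRITICAL_WINDOW_MAX_UM)
    fold_overall = fold_difference(PHENYLETHANOL_DOSE_UM,
                                   PHENYLETHANOL_OVERALL_MAX_UM)
    print(
        f"exogenous 2-phenylethanol ({PHENYLETHANOL_DOSE_UM:g} µM) is "
        f"{round_half_away(fold_window)}x the critical-window peak "
        f"({PHENYLETHANOL_CRITICAL_WINDOW_MAX_UM:g} µM) and "
        f"{fold_overall:.1f}x the 30 h maximum "
        f"({PHENYLETHANOL_OVERALL_MAX_UM:g} µM)"
    )


if __name__ == "__main__":
    main()
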