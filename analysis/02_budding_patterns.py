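#!/usr/bin/env python
"""Classify bud-site sequences, tabulate pattern percentages per window, and
test consecutive windows for a significant unipolar increase (Fisher exact,
alpha 0.05).

Reads results/synthetic/bud_records.tsv; writes results/tallies.tsv and
results/comparisons.tsv.
"""

from pathlib import Path

import pandas as pd

from budqs import classify_records, significant_transitions, tabulate, tallies_to_frame
from budqs.fisher import compare_groups
from budqs.io import read_bud_records, write_table

ROOT = Path(__file__).resolve().parents[1]
ALPHA = 0.05


def main() -> None:
    records = read_bud_records(ROOT / "results" / "synthetic" / "bud_records.tsv")
    tallies = tabulate(classify_records(records))
    frame = tallies_to_frame(tallies)
    write_table(frame, ROOT / "results" / "tallies.tsv")
    print(frame.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

    rows = []
    by_depth = {}
    for t in tallies:
        by_depth.setdefault(t.n_sites, []).append(t)
    for depth, ordered in sorted(by_depth.items()):
        ordered.sort(key=lambda t: t.window)
        for t1, t2 in zip(ordered, ordered[1:]):
            for pattern in ("axial", "bipolar", "unipolar"):
                res = compare_groups(t1, t2, pattern, alpha=ALPHA)
                a, b, c, d = res.table
                rows.append(
                    {"n_sites": depth, "pattern": pattern,
                     "windows": f"{t1.window}->{t2.window}",
                     "a": a, "b": b, "c": c, "d": d,
                     "p_value": res.p_value, "significant": res.significant}
                )
        found = significant_transitions(ordered, alpha=ALPHA)
        for tr in found:
            print(
                f"{depth}-site cells: unipolar budding rose "
                f"{tr.percent_from:.0f}% -> {tr.percent_to:.0f}% between "
                f"windows {tr.window_from} and {tr.window_to} "
                f"(p = {tr.result.p_value:.2e})"
            )
        if not found:
            print(f"{depth}-site cells: no significant unipolar increase")
    write_table(pd.DataFrame(rows), ROOT / "results" / "comparisons.tsv")


if __name__ == "__main__":
    main()
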