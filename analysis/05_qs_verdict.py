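#!/usr/bin/env python
"""Evaluate the intercellular-signalling / quorum-sensing checklist for
2-phenylethanol and write the full structured report for the synthetic study.

Writes results/report/{report.json,report.md}.
"""

from pathlib import Path

from budqs import SimulationConfig, evaluate_criteria
from budqs.criteria import CRITERION_LABELS, QS_CRITERIA, SIGNALLING_CRITERIA
from budqs.pipeline import run_pipeline, write_report
from budqs.reference import PHENYLETHANOL_EVIDENCE

ROOT = Path(__file__).resolve().parents[1]
SEED = 1278


def main() -> None:
    verdict = evaluate_criteria(PHENYLETHANOL_EVIDENCE, molecule="2-phenylethanol")
    print("2-phenylethanol checklist:")
    for crit in SIGNALLING_CRITERIA + QS_CRITERIA:
        mark = "Y" if PHENYLETHANOL_EVIDENCE.flag(crit) else "N"
        print(f"  {CRITERION_LABELS[crit]:<32} {mark}")
    print(f"  intercellular signalling molecule: "
          f"{verdict.is_intercellular_signalling_molecule}")
    print(f"  quorum sensing molecule:           "
          f"{verdict.is_quorum_sensing_molecule}")
    print(f"  failing criteria: {', '.join(verdict.failing)}")

    cfg = SimulationConfig(seed=SEED)
    bundle = run_pipeline(
        cfg, evidence={"2-phenylethanol": PHENYLETHANOL_EVIDENCE}
    )
    json_path, md_path = write_report(bundle, ROOT / "results" / "report")
    print(f"wrote {json_path} and {md_path}")


if __name__ == "__main__":
    main()
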