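#!/usr/bin/env python
"""Evaluate the classifier and CA125 on the held-out validation cohorts.

Computes, per cohort and pooled: AUC with DeLong 95% CI and the DeLong
comparison against CA125, the full confusion-matrix metric panel at the 0.5
cut-off, sensitivity at 90% specificity, a permutation-null p-value,
calibration bins, decision curves and the clinical subgroup contrasts.
Writes diagnostic_report.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tepdx.config import PipelineConfig
from tepdx.pipeline import run

config = PipelineConfig(seed=1)
run_dir = run(config, "evaluate", Path(__file__).resolve().parents[1] / "results" / "runs")
report = json.loads((run_dir / "diagnostic_report.json").read_text())
for cohort, entry in report.items():
    if cohort == "subgroups":
        continue
    tep = entry["markers"]["tep"]
    print(
        f"{cohort:15s} AUC={tep['auc']:.3f} ({tep['auc_ci'][0]:.3f}-{tep['auc_ci'][1]:.3f})  "
        f"ACC={100 * tep['acc']:.1f}%  perm p={entry['tep_permutation_p']:.4f}"
    )
print(f"full report: {run_dir / 'diagnostic_report.json'}")
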