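#!/usr/bin/env python
"""Emit the human-readable diagnostic table (one row per cohort x marker).

Mirrors the conventional diagnostic-study table layout: AUC (95% CI), ACC,
SN, SP, PPV, NPV, Kappa, F1 and the DeLong p-value against CA125.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from tepdx.config import PipelineConfig
from tepdx.pipeline import run

config = PipelineConfig(seed=1)
run_dir = run(config, "report", Path(__file__).resolve().parents[1] / "results" / "runs")
table = pd.read_csv(run_dir / "diagnostic_report.tsv", sep="\t")
print(table.round(3).to_string(index=False))
print(f"\ntable written to {run_dir / 'diagnostic_report.tsv'}")
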