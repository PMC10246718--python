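#!/usr/bin/env python
"""QC, normalization and confounder correction for every cohort.

Applies the total-read sample filter (5e6), the low-count / hypervariable
gene filters (10 reads in >10% of samples; CV > 3), median-of-ratios size
factors, the shifted-log variance-flattening transform, surrogate-variable
estimation and nuisance regression (age, log total reads, batch, SVs).
Writes corrected expression matrices under the run directory.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tepdx.config import PipelineConfig
from tepdx.pipeline import run

config = PipelineConfig(seed=1)
run_dir = run(config, "preprocess", Path(__file__).resolve().parents[1] / "results" / "runs")
manifest = json.loads((run_dir / "manifest_preprocess.json").read_text())
print(f"preprocessed expression written to {run_dir} ({manifest['elapsed_s']} s)")
for expr in sorted(run_dir.glob("*_expr.tsv")):
    header = expr.read_text().splitlines()[0]
    n_samples = len(header.split("\t")) - 1
    n_genes = sum(1 for _ in open(expr)) - 1
    print(f"  {expr.name}: {n_genes} genes x {n_samples} samples after QC")
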