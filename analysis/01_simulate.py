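#!/usr/bin/env python
"""Generate the synthetic four-cohort platelet-transcriptome study.

Writes per-cohort count matrices (TSV), clinical metadata (CSV) and the
generative ground truth (JSON) under results/runs/<config digest>/data/, and
prints the cohort composition table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tepdx.config import PipelineConfig
from tepdx.io import read_metadata
from tepdx.pipeline import run

config = PipelineConfig(seed=1)
run_dir = run(config, "simulate", Path(__file__).resolve().parents[1] / "results" / "runs")
print(f"simulated study in {run_dir}/data")
for meta_path in sorted((run_dir / "data").glob("*_meta.csv")):
    meta = read_metadata(meta_path)
    n = len(meta)
    n_oc = int((meta["class"] == "OC").sum())
    missing = int(meta["ca125"].isna().sum())
    print(
        f"  {meta_path.stem.removesuffix('_meta'):9s} n={n:4d}  OC={n_oc:3d} ({n_oc / n:.1%})  "
        f"median age={meta['age'].median():.0f}  CA125 missing={missing}"
    )
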