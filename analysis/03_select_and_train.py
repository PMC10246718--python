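#!/usr/bin/env python
"""Select the platelet gene panel (MRGF cascade) and train the classifier.

Runs the minimum-redundant-gene-filtering cascade on the training cohort —
abundance re-filter, correlation pruning, cross-validated LASSO, mRMR
ranking, incremental CV-SVM selection — then tunes (cost, sigma) by random
search, trains the RBF SVM with Platt scaling, and fits the CA125
combination model. Writes panel.tsv, model.json and combiner.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tepdx.config import PipelineConfig
from tepdx.pipeline import run

config = PipelineConfig(seed=1)
run_dir = run(config, "train", Path(__file__).resolve().parents[1] / "results" / "runs")
prov = json.loads((run_dir / "panel_provenance.json").read_text())
print("MRGF cascade stage sizes:")
for stage, size in prov["stage_sizes"].items():
    print(f"  {stage:18s} {size}")
hp = prov["hyperparams"]
print(f"tuned SVM: cost={hp['cost']:.4g} sigma={hp['sigma']:.4g}")
print(f"panel written to {run_dir / 'panel.tsv'}")
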