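"""Run the end-to-end pipeline: simulate two maturity groups, score them,
compare regeneration ratios, and write a reproducible result bundle.

Equivalent to `axoregen run-all --config cfg.yaml`.
"""

import json
from pathlib import Path

from axoregen.pipeline import AnalysisConfig, run_full_analysis

config = AnalysisConfig(
    seed=1, out_dir="scratch/example_run",
    stages={"axotomy": {"grouping": ["div"], "groups": [
        {"name": "immature", "div": 4, "n_cells": 50,
         "outcome_fractions": {"death": 0.1, "branch_loss": 0.1,
                               "regeneration": 0.55, "ectopic": 0.05,
                               "no_regeneration": 0.2}},
        {"name": "mature", "div": 24, "n_cells": 50,
         "outcome_fractions": {"death": 0.1, "branch_loss": 0.1,
                               "regeneration": 0.05, "ectopic": 0.03,
                               "no_regeneration": 0.72}}]}})

manifest = run_full_analysis(config)
out = Path(config.out_dir)
tests = json.loads((out / "axotomy" / "cohort_tests.json").read_text())
print("outputs:", sorted(manifest["stages"]["axotomy"]["outputs"]))
print("regeneration-ratio Fisher p:",
      f"{tests['regeneration_ratio'][0]['p']:.2e}")
print("re-running with the same seed reproduces byte-identical files;"
      " the manifest records each output's SHA-256.")
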