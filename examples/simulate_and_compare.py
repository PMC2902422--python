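"""Run the full comparison pipeline on a synthetic cohort.

Simulates a 500-death cohort with known true causes, interprets it with
the Bayesian engine, codes it with the noisy three-physician panel, and
prints the stratified agreement report (percent agreement and kappa).
"""

import tempfile
from pathlib import Path

from vacompare import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(out_dir=tmp, seed=42, n_cases=500, exclude_indeterminate=True)
    results = run_pipeline(cfg)
    print(Path(results["report_path"]).read_text())

overall = results["strata"]["overall"]
print(
    f"Model recovered the true CSMF with accuracy "
    f"{overall['model_vs_truth_accuracy']:.3f}; the physician panel reached "
    f"{overall['physician_vs_truth_accuracy']:.3f}."
)
print(
    "Reading: each row shows cases where the panel's final cause and the\n"
    "engine's most probable cause fall in the same broad group; kappa\n"
    "corrects that percentage for chance agreement. The sensitivity row\n"
    "drops cases either method left indeterminate."
)
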