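"""Validate a fitted policy: concordance, MPR, and outcome curves.

Runs the full pipeline in one call and reads back the evaluation
reports: state-wise concordance with the doctors' modal prescriptions,
per-tier medication possession ratios of model-concordant prescriptions,
and mean complication occurrence per concordance bucket.
"""

import tempfile
from pathlib import Path

import pandas as pd

from htndtr.io import PipelineConfig, run_pipeline
from htndtr.policy_learning import LearnParams
from htndtr.synthetic_cohort import SimulationConfig

config = PipelineConfig(
    seed=7,
    simulation=SimulationConfig(n_patients=20000, horizon=8, seed=8),
    learning=LearnParams(seed=9, max_sweeps=120),
)
out = Path(tempfile.mkdtemp()) / "report"
manifest = run_pipeline(config, out)

print("concordance (percent of the 108 states where the policies agree):")
print(pd.read_csv(out / "concordance.csv").to_string(index=False))
print()
print("MPR of model-concordant prescriptions, by therapy tier:")
print(pd.read_csv(out / "mpr_summary.csv").round(2).to_string(index=False))
print()
curves = pd.read_csv(out / "bucket_curves.csv")
comp = curves[curves["outcome"] == "complication_occurrence"]
print("complication occurrence by patient-concordance bucket:")
print(comp[["bucket", "mean_outcome", "n_patients"]].to_string(index=False))
print()
print("Interpretation: Q-learning tracks both the doctors' modal choices"
      " and the planted optimum; higher concordance with the model goes"
      " with fewer incident complications, and adherence (MPR) sits"
      " inside the simulated 25-90% range.")
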