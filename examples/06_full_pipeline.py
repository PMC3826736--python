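"""The full workflow in one call: simulate, score, map, compare, survive.

Generates a small cohort, runs every pipeline stage and prints the files
the run manifest records. Rerunning with the same seed and configuration
reproduces every table byte-for-byte.
"""

import tempfile
from pathlib import Path

import pandas as pd

from adps.io import RunConfig, run_pipeline
from adps.synthetic import EffectBlock, SyntheticCohortSpec, generate_cohort

spec = SyntheticCohortSpec(
    group_sizes=(12, 12, 12, 12),
    grid_shape=(8, 8, 8),
    effect_regions={
        "GM": (EffectBlock((1, 1, 1), (3, 3, 3), 0.25),),
        "WM": (EffectBlock((4, 4, 4), (3, 3, 3), 0.18),),
        "CSF": (EffectBlock((1, 4, 4), (3, 3, 3), 0.15),),
    },
    seed=5,
)
cohort = generate_cohort(spec)

out = Path(tempfile.mkdtemp()) / "run"
config = RunConfig(K1=3, K2=3, repetitions=3, seed=9, map_repetitions=3)
results = run_pipeline(cohort, config, out)

print("manifest files:")
for name in sorted(results["manifest"]["files"]):
    print(f"  {name}")

perf = pd.read_csv(out / "performance.csv")
print("\nmedian nested-CV accuracy per modality (%):")
print(perf.groupby("modality")["accuracy"].median().to_string())

surv = pd.read_csv(out / "survival_results.csv")
print("\nhazard ratios per 1 SD of each metric:")
print(surv[["metric", "hazard_ratio_per_sd", "p_value"]].to_string(index=False))

# The manifest records the seed and a configuration hash; running this
# script again produces identical CSV bytes for every table.
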