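"""Bootstrap confidence bands around the percentile curves (scaled down).

Resamples the dataset with replacement, reruns the pipeline per replicate
and forms the central 95% band per (age, percentile) cell, expanded where
needed to contain the point estimate.  B = 100 is the production default;
B = 8 and a reduced age range keep the example to a couple of minutes.
"""

import numpy as np

import refcurve as rc
from refcurve.synthetic_data import alp_like, generate_dataset

scenario = alp_like(n_total=8_000, seed=5, pathological_fraction=0.10,
                    max_age_days=2000)
ms, _ = generate_dataset(scenario)

config = rc.PipelineConfig(rng_seed=5, bootstrap_B=8, families=("BCCG",),
                           max_age_days=2000)
ages = np.array([7, 30, 100, 365, 1000, 1500, 1900])
point = rc.fit_pipeline(ms, config, age_grid=ages)

boot = rc.bootstrap_percentile_ci(ms, config, point.percentile_table,
                                  point_model=point.model)
lo, hi = rc.expand_ci_to_include(boot.ci_lower, boot.ci_upper,
                                 point.percentile_table.values)

j = point.percentile_table.probs.index(0.975)
print(f"replicates: {boot.n_success}/{boot.n_requested} succeeded")
print("97.5th percentile with 95% CI:")
for i, a in enumerate(ages):
    est = point.percentile_table.values[i, j]
    print(f"  day {a:>4}: {est:6.1f}  [{lo[i, j]:6.1f}, {hi[i, j]:6.1f}]")

# Bands are widest where the curves change fastest (neonatal period,
# pubertal peak) - more data per unit of change means less uncertainty.
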