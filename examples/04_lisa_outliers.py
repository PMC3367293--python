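"""Local Moran's I cluster/outlier mapping and recovery of injected
pollution point sources.

Injects +4 SD point outliers into low-valued neighbourhoods of a
weak-structure field and checks that local Moran's I flags them as
significant High-low spatial outliers.
"""

import warnings

import numpy as np

from morankrig import (
    AnomalySpec,
    FieldSpec,
    build_distance_band_weights,
    inject_anomalies,
    local_moran,
    simulate_field,
    summarize_categories,
)

warnings.simplefilter("ignore")

spec = FieldSpec(n_sites=400, extent=100.0, log_mean=4.0, nugget=0.06,
                 structures=((0.12, 20.0),), seed=7)
samples, truth = simulate_field(spec)
samples, truth = inject_anomalies(
    samples, truth,
    AnomalySpec(n_outliers=6, outlier_sd=4.0, outlier_neighborhood=10.0, seed=8),
)

weights = build_distance_band_weights(samples, 10.0)
res = local_moran(np.log(samples.values["metal"]), weights, seed=9)

print(summarize_categories(res).round(3).to_string(index=False))
injected = truth["outlier_idx"]
recovered = np.sum(res.category[injected] == "High-low")
print(f"\ninjected outliers recovered as significant High-low: "
      f"{recovered}/{len(injected)}")
print("High-low sites are hot points in cold regions — the pollution point "
      "sources\na variogram-only analysis would treat as noise.")
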