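"""The headline workflow: correlogram-guided variogram models vs the
traditional half-maximum-lag model, compared by leave-one-out
cross-validation and pollution-status agreement.
"""

import warnings

from morankrig import AnalyteConfig, WorkflowConfig, inject_anomalies, run_workflow, simulate_field
from morankrig.simulate import survey_anomalies, survey_spec

warnings.simplefilter("ignore")

samples, truth = simulate_field(survey_spec(seed=0))
samples, truth = inject_anomalies(samples, truth, survey_anomalies(seed=1000))

analyte = AnalyteConfig("metal", critical_value=250.0, background_value=30.0)
cfg = WorkflowConfig(analytes=[analyte], roster=("d1", "d2", "d5", "nested"), seed=0)
result = run_workflow(samples, cfg)["results"]["metal"]

print("characteristic distances:",
      {k: None if v is None else round(v, 1) for k, v in result.distances.to_dict().items()})
print("\ncross-validation (concentration scale, mg/kg):")
print(result.cv_table.round(3).to_string(index=False))
print("\nmodel ranking (ME closest to 0, then RMSSE closest to 1):", result.ranking)
print("\npollution-status agreement, nested model (percent of samples):")
print(result.agreement["nested"].round(2))
print("\nd5 is the traditional model; the nested d1+d2 model resolves the "
      "short-range\nstructure the half-maximum active lag cannot, which "
      "lowers its CV errors and\nkeeps more genuinely polluted samples "
      "classified as polluted.")
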