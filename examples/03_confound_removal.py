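"""Remove age/sex variance from features with a control-fitted GP.

The regression is estimated on control subjects only, so disease effects
are never absorbed into the confound model; its fitted mean is then
subtracted from every subject.
"""

import numpy as np

from connectoclass import (
    CohortSpec,
    fc_feature_table,
    generate_cohort,
    residualize_confounds,
)

spec = CohortSpec(n_regions=20, n_timepoints=150, n_patients_per_site=40,
                  n_controls_per_site=40, n_sites=1,
                  confound_slopes=(0.08, 0.02), seed=4)
table = fc_feature_table(generate_cohort(spec))
ages = table.subjects["age"].to_numpy()

def mean_abs_age_corr(features):
    rs = [abs(np.corrcoef(features[:, j], ages)[0, 1])
          for j in range(features.shape[1])]
    return float(np.mean(rs))

before = mean_abs_age_corr(table.features)
resid = residualize_confounds(table, fit_scope="all_controls", seed=0)
after = mean_abs_age_corr(resid.features)
print(f"mean |corr(feature, age)| before residualization: {before:.3f}")
print(f"mean |corr(feature, age)| after residualization:  {after:.3f}")
print("the drop shows the age-related variance was captured by the "
      "control-sample GP and subtracted from all subjects")
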