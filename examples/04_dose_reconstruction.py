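"""Calibrate the standard curve and reconstruct doses on test data.

Dose = k0 + k1*S + k2*S^4 is fitted on the pooled training sets (the
power structure chosen by AICc, coefficients by ordinary and by Huber
robust regression) and applied to two independent test sets, one from the
same platform and one emulating a platform change.
"""

import numpy as np

from radrecon import PipelineConfig, SimulationConfig, generate_study, summarize_by_dose
from radrecon.pipeline import run_study_analysis

datasets, truth = generate_study(SimulationConfig(), seed=42)
result = run_study_analysis(datasets, PipelineConfig(seed=42))

print(f"signature: {len(result.signature)} genes; "
      f"normalizers: {len(result.normalizers)} genes")
print(f"train Spearman(S, dose) = {result.train_spearman_s_dose:.3f}")
print(f"selected powers {result.model_ols.powers}; "
      f"ols k = {np.round(result.model_ols.params, 2).tolist()}, "
      f"robust k = {np.round(result.model_robust.params, 2).tolist()}")

for name, label in (("test1", "same platform"), ("test2", "different platform")):
    recon = result.reconstructions[name]["robust"]
    print(f"\n{name} ({label}): R2 = {recon.r2:.3f}, RMSE = {recon.rmse:.2f} Gy")
    print(summarize_by_dose(recon).round(2).to_string(index=False))

print("\nReconstruction is tight on the same-platform test set and degrades "
      "on the platform-shifted one — the residual gene-specific shifts that "
      "normalizers cannot remove grow with the platform change.")
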