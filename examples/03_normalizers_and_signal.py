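"""Select normalizer genes and build the normalized signal S.

Normalizer genes track the signature group's median in unirradiated
controls but have no dose response of their own. Subtracting their median
yields S = median(signature) - median(normalizers), which is immune to
array-wide shifts and largely immune to cross-study baseline drift.
"""

from scipy import stats

from radrecon import (
    SimulationConfig,
    build_signature,
    compute_normalized_signal,
    generate_study,
    median_signature_signal,
    merge_datasets,
    preprocess,
    score_normalizer_candidates,
    select_normalizers,
)

datasets, truth = generate_study(SimulationConfig(n_genes=2000), seed=42)
prep = {k: preprocess(v) for k, v in datasets.items()}

signature, _ = build_signature(prep["train1"], seed=42)
pooled = merge_datasets([prep["train1"], prep["train2"]])

scores = score_normalizer_candidates(pooled, signature)
normalizers = select_normalizers(scores, target_size=len(signature))
hit = len(set(normalizers.gene_ids) & set(truth.normalizers))
print(f"selected {len(normalizers)} normalizers, {hit} of them planted")

signal = compute_normalized_signal(pooled, signature, normalizers)
dose = pooled.dose_gy.to_numpy()
rho_s = stats.spearmanr(signal.s.to_numpy(), dose).statistic
rho_raw = stats.spearmanr(
    median_signature_signal(pooled, signature.gene_ids).to_numpy(), dose
).statistic
print(f"pooled Spearman with dose: S = {rho_s:.3f}, "
      f"raw signature median = {rho_raw:.3f}")
print("\nThe raw median is corrupted by the between-study baseline shift; "
      "subtracting the normalizer median restores a clean dose relation.")
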