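"""Separate scaling from persistent GxE with the log transformation.

Data are generated in multiplicative mode: on the log scale there is no
slope variance at all, so every apparent environmental-sensitivity
effect on the observed scale is pure scaling (spread changes across
environments, no re-ranking).  Running the observed-scale and log-scale
pipelines on the same discovery/validation split classifies each tested
SNP; a planted intercept QTL should be validated for ES on the observed
scale only, i.e. its GxE effect is removable by the transformation.
"""

import sirenorm as sn

config = sn.SimulationConfig.multiplicative(
    n_sires=240, daughters_per_sire=60, n_htd=250, n_snps=60, n_qtl=1,
    qtl_var_fraction=0.7, b_fixed=0.15, seed=41,
)
genotypes, pedigree, truth, records = sn.simulate_dataset(config)
ids = sorted(records["sire_id"].unique())
relationship = sn.build_numerator_relationship(pedigree, ids)
split = sn.split_sires(ids, n_validation=60, seed=41)

comparison = sn.run_scale_comparison(records, genotypes, relationship, split)

print("planted intercept QTL:", truth.qtl_effects["snp_id"].iloc[0])
print(comparison.table[["snp_id", "validated_obs_es", "validated_log_es", "classification"]]
      .to_string(index=False))
print(f"observed-scale intercept-slope correlation: {comparison.fit_observed.rho_s0s1:.2f} "
      "(near 1: slopes proportional to intercepts under pure scaling)")
print(f"log-scale sire slope variance: {comparison.fit_log.sigma_s1_sq:.2e}; "
      f"LRT against zero: p = {comparison.log_slope_lrt['p_value']:.3f} "
      "(non-significant: the transformation removed the interaction)")
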