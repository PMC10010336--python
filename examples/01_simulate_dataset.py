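"""Generate a synthetic proteome dataset with planted coexpression modules.

Builds a 600-protein x 60-sample log2 abundance matrix with five planted
modules, three tissue groups, TMT-batch offsets, and survival times whose
hazard follows module 2's latent factor.
"""

from coexmod import SimulationConfig, SurvivalConfig, generate_dataset

config = SimulationConfig(
    n_proteins=600,
    n_samples=60,
    module_sizes=[150, 120, 100, 80, 60],
    kme_target=0.85,          # target protein-factor correlation
    survival=SurvivalConfig(linked_module=2, log_hazard_per_unit=1.2,
                            baseline_scale=24.0, censor_rate=0.2),
    seed=7,
)
matrix, clinical, truth = generate_dataset(config)

print(f"abundance matrix: {matrix.shape[0]} proteins x {matrix.shape[1]} samples")
print("planted module sizes:",
      truth.module_of_protein.value_counts().sort_index().to_dict())
print(clinical.head().to_string(index=False))
print(f"censored fraction: {1 - clinical['os_event'].mean():.2f}")
# Label 0 marks background proteins that belong to no module; os_months /
# os_event are exponential survival times with independent uniform censoring.
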