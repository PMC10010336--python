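"""Build the signed coexpression network and detect protein modules.

Runs the full network stage on simulated data: biweight midcorrelation,
soft-threshold selection by scale-free fit, topological overlap, tree cut,
and kME-based membership cleanup — then compares with the planted truth.
"""

from sklearn.metrics import adjusted_rand_score

from coexmod import SimulationConfig, generate_dataset
from coexmod.network import detect_modules

config = SimulationConfig(n_proteins=600, n_samples=60,
                          module_sizes=[150, 120, 100, 80, 60],
                          kme_target=0.85, seed=7)
matrix, clinical, truth = generate_dataset(config)

labels, scan = detect_modules(matrix)  # auto-beta from the scale-free scan

print(scan.table[["beta", "r_squared", "mean_connectivity"]]
      .round(3).to_string(index=False))
print(f"chosen beta: {scan.chosen_beta}")
sizes = labels[labels != 0].value_counts().sort_index()
print("detected module sizes:", {f"M{m}": int(c) for m, c in sizes.items()})
print(f"unassigned (M0): {int((labels == 0).sum())}")
ari = adjusted_rand_score(truth.module_of_protein.values, labels.values)
print(f"adjusted Rand index vs planted truth: {ari:.3f}")
# An ARI near 1 means the detected modules coincide with the planted factor
# structure; unassigned proteins are background noise by construction.
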