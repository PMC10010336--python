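# coexmod

Signed weighted coexpression-module analysis for quantitative proteomics.

`coexmod` takes a proteins × samples matrix of log2 TMT abundance ratios and
carries out the full module workflow used in tumor-proteome studies (the
motivating application is pancreatic ductal adenocarcinoma): normalization
and variance filtering, a signed weighted coexpression network with
topological-overlap module detection, module eigenproteins / kME / hub
characterization, subsampled k-means consensus clustering of samples on
module signatures, and survival stratification of the resulting subgroups.
A synthetic-data generator with planted ground truth makes every stage
verifiable at desk scale.

It is written for computational biologists who want the module workflow as a
plain Python library (pandas in, pandas out) with a thin command-line
wrapper for TSV-file pipelines.

## The model in brief

- **Network**: from robust pairwise correlations (biweight midcorrelation),
  the signed adjacency is `a_ij = ((1 + cor_ij)/2)^beta` with the soft
  threshold `beta` chosen so the connectivity distribution approximates
  scale-free topology. The topological overlap matrix
  `TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` measures shared
  neighborhoods, and proteins are clustered on `1 − TOM` with a dynamic-style
  tree cut (minimum module size 50; unassigned proteins form M0).
- **Modules**: the module eigenprotein (ME) is the first principal component
  of the standardized member submatrix; kME is each protein's Pearson
  correlation with an ME, and high-kME members are the intramodular hubs.
- **Stratification**: samples are consensus-clustered (1,000 subsampled
  k-means iterations, 80% of items and features each) on a module's top-50
  kME signature; the two clusters are named high/low by signature abundance.
- **Survival**: Kaplan–Meier curves, the k-group log-rank test and Cox
  proportional-hazards regression (Efron ties) compare the arms, plus
  Wilcoxon differential expression with Benjamini–Hochberg control and
  hypergeometric gene-set over-representation.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

```python
from coexmod import SimulationConfig, SurvivalConfig, generate_dataset
from coexmod.network import detect_modules
from coexmod.modules import build_module_set
from coexmod.consensus import stratify_module_signature
from coexmod.survival import km_estimate, logrank_test

cfg = SimulationConfig(
    n_proteins=600, n_samples=60, module_sizes=[150, 120, 100, 80, 60],
    kme_target=0.85,
    survival=SurvivalConfig(linked_module=2, log_hazard_per_unit=1.2,
                            baseline_scale=24.0, censor_rate=0.2),
    seed=7)
matrix, clinical, truth = generate_dataset(cfg)

labels, scan = detect_modules(matrix)           # auto soft threshold
mset = build_module_set(matrix, labels)
arm, signature, _ = stratify_module_signature(matrix, mset, module=2,
                                              n_top=50, k=2,
                                              iterations=500, seed=1)
clin = clinical.set_index("sample_id")
res = logrank_test(clin.os_months, clin.os_event, arm.to_numpy())
print(scan.chosen_beta, mset.sizes.to_dict(), round(res.p_value, 5))
```

Typical output (seed 7):

```
18 {'M1': 154, 'M2': 122, 'M3': 100, 'M4': 81, 'M5': 60} 9e-05
```

Five modules close to the planted sizes (150/120/100/80/60; the remainder is
unassigned background), soft threshold 18 from the scale-free scan, and a
log-rank p ≈ 1e-04 for the high-vs-low split on module 2's hub signature —
the module whose latent factor drives the simulated hazard. The KM medians
behind that p-value (see `examples/05_survival_analysis.py`) are ≈ 6 months
for the high arm vs ≈ 21 months for the low arm: high signature abundance,
shorter survival, matching the positive planted log-hazard.

The `examples/` directory holds one short narrative script per capability
(simulation, network and modules, eigenproteins and hubs, consensus
stratification, survival, enrichment); each prints the numbers it computes
and a line on what they mean.

## Command line

Every stage is also a subcommand over the TSV dialects documented in the
module docstrings of `coexmod.io`:

```sh
coexmod simulate --config sim.yaml --out-dir data --seed 7
coexmod network --abundance data/abundance.tsv --fraction 1.0 --out-dir net
coexmod consensus --abundance data/abundance.tsv --modules net/modules.tsv \
        --module 2 --n-top 50 --k 2 --iterations 1000 --seed 1 --out-dir cons
coexmod survival --clinical data/clinical.tsv \
        --labels cons/signature_labels.tsv --out-dir surv
coexmod pipeline --abundance data/abundance.tsv --clinical data/clinical.tsv \
        --out-dir run --seed 1     # end to end, writes report.json
```

`report.json` validates against the JSON schema shipped as
`coexmod/report_schema.json`.

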