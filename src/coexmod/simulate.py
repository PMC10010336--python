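"""Synthetic abundance matrices with planted coexpression modules.

Emulates the statistical structure the downstream analysis assumes: a complete
(no missing values) log2-ratio matrix in which each planted module is driven by
one latent per-sample factor, sample groups shift those factors, TMT batches add
constant offsets, and survival time depends on one module's factor through an
exponential proportional-hazards model with independent uniform censoring.

Model
-----
For protein i in module m and sample s:

    x_is = f_m(s) + eps_is,   eps_is ~ N(0, sigma_m^2)

with ``sigma_m = sqrt(1/kme_target^2 - 1)`` so that the population Pearson
correlation of x_i with f_m equals ``kme_target`` exactly.  Background proteins
are pure N(0, noise_sd^2) noise.  Group structure enters as per-group,
per-module mean shifts of the factors; batch structure as per-protein,
per-batch N(0, batch_sd^2) offsets constant across the samples of a batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._rng import stream
from .datatypes import AbundanceMatrix, InputContractError

__all__ = [
    "SurvivalConfig",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_survival",
]


@dataclass
class SurvivalConfig:
    """Exponential survival linked to one module's latent factor.

    linked_module is a 1-based module index; log_hazard_per_unit is the log
    hazard ratio per unit of the factor; baseline_scale is the mean survival
    (months) at factor 0; censor_rate is the target fraction censored.
    """

    linked_module: int = 1
    log_hazard_per_unit: float = 1.0
    baseline_scale: float = 24.0
    censor_rate: float = 0.2


@dataclass
class SimulationConfig:
    """Ground-truth generative settings for one synthetic dataset.

    Defaults emulate the study's data shape scaled to desk size: ~60 samples
    in three tissue groups, five modules, one TMT batch structure.  Shifts are
    on the log2 scale.
    """

    n_proteins: int = 600
    n_samples: int = 60
    module_sizes: list[int] = field(default_factory=lambda: [150, 120, 100, 80, 60])
    kme_target: float = 0.8
    group_labels: list[str] = field(default_factory=lambda: ["tumor", "fibrous", "normal"])
    # group_shifts[g][m] = mean shift of module-(m+1) factor in group g
    group_shifts: list[list[float]] | None = None
    n_batches: int = 3
    batch_sd: float = 0.3
    noise_sd: float = 1.0
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    @property
    def background_count(self) -> int:
        return self.n_proteins - sum(self.module_sizes)

    def validate(self) -> None:
        if any(s < 1 for s in self.module_sizes):
            raise InputContractError("module_sizes: every module size must be >= 1")
        if self.background_count < 0:
            raise InputContractError(
                "module_sizes: sum(module_sizes) exceeds n_proteins "
                f"({sum(self.module_sizes)} > {self.n_proteins})"
            )
        if not 0.0 < self.kme_target < 1.0:
            raise InputContractError("kme_target: must be strictly between 0 and 1")
        if self.n_samples < 2:
            raise InputContractError("n_samples: need at least 2 samples")
        if self.n_batches < 1:
            raise InputContractError("n_batches: need at least 1 batch")
        if not 0.0 <= self.survival.censor_rate < 1.0:
            raise InputContractError("survival.censor_rate: must lie in [0, 1)")
        shifts = self.resolved_group_shifts()
        if len(shifts) != len(self.group_labels):
            raise InputContractError("group_shifts: one row per group label required")
        for row in shifts:
            if len(row) != len(self.module_sizes):
                raise InputContractError("group_shifts: one column per module required")

    def resolved_group_shifts(self) -> list[list[float]]:
        if self.group_shifts is not None:
            return self.group_shifts
        # default: spread groups +1.5 / 0 / -1.5 ... on the first module only,
        # a moderate log2-scale separation between tissue groups
        n_g, n_m = len(self.group_labels), len(self.module_sizes)
        base = np.linspace(1.5, -1.5, n_g) if n_g > 1 else np.zeros(1)
        shifts = np.zeros((n_g, n_m))
        if n_m:
            shifts[:, 0] = base
        return shifts.tolist()


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset (module labels are 1-based; 0 = background)."""

    module_of_protein: pd.Series  # protein_id -> int label
    factor_matrix: pd.DataFrame  # modules x samples latent factors (index M1..Mk)
    group_of_sample: pd.Series  # sample_id -> group label
    survival_link: tuple[int, float]  # (module index, log hazard per factor unit)


def _noise_sd_for_kme(kme_target: float) -> float:
    # cor(f + eps, f) = 1/sqrt(1 + sigma^2)  =>  sigma = sqrt(1/k^2 - 1)
    return math.sqrt(1.0 / kme_target**2 - 1.0)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate (abundance, clinical, truth) for one configuration.

    Deterministic for a fixed ``config.seed``; the matrix, survival and batch
    draws come from independent named streams so stages do not interact.
    """
    config.validate()
    n_p, n_s = config.n_proteins, config.n_samples
    n_mod = len(config.module_sizes)

    protein_ids = pd.Index([f"P{i + 1:05d}" for i in range(n_p)], name="protein_id")
    sample_ids = pd.Index([f"S{j + 1:03d}" for j in range(n_s)], name="sample_id")

    # sample -> group (contiguous blocks, as balanced as possible)
    n_g = len(config.group_labels)
    group_idx = np.array_split(np.arange(n_s), n_g)
    group_of_sample = pd.Series(index=sample_ids, dtype=object)
    for g, idx in enumerate(group_idx):
        group_of_sample.iloc[idx] = config.group_labels[g]

    rng = stream(config.seed, "matrix")
    shifts = np.asarray(config.resolved_group_shifts())  # groups x modules

    factors = rng.standard_normal((n_mod, n_s))
    for g, idx in enumerate(group_idx):
        factors[:, idx] += shifts[g][:, None]

    labels = np.zeros(n_p, dtype=int)
    x = np.empty((n_p, n_s))
    row = 0
    for m, size in enumerate(config.module_sizes):
        sigma = _noise_sd_for_kme(config.kme_target)
        x[row : row + size] = factors[m] + sigma * rng.standard_normal((size, n_s))
        labels[row : row + size] = m + 1
        row += size
    n_bg = n_p - row
    if n_bg:
        x[row:] = config.noise_sd * rng.standard_normal((n_bg, n_s))

    # batch structure: contiguous sample blocks; per-protein x per-batch offsets
    batch_idx = np.array_split(np.arange(n_s), config.n_batches)
    batch_of_sample = pd.Series(index=sample_ids, dtype=object)
    rng_batch = stream(config.seed, "batch")
    for b, idx in enumerate(batch_idx):
        batch_of_sample.iloc[idx] = f"B{b + 1}"
        if config.batch_sd > 0 and len(idx):
            x[:, idx] += config.batch_sd * rng_batch.standard_normal((n_p, 1))

    matrix = AbundanceMatrix(
        pd.DataFrame(x, index=protein_ids, columns=sample_ids), batch_of_sample
    )
    truth = SyntheticTruth(
        module_of_protein=pd.Series(labels, index=protein_ids),
        factor_matrix=pd.DataFrame(
            factors, index=[f"M{m + 1}" for m in range(n_mod)], columns=sample_ids
        ),
        group_of_sample=group_of_sample,
        survival_link=(config.survival.linked_module, config.survival.log_hazard_per_unit),
    )

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group_of_sample.values,
            "batch": batch_of_sample.values,
        }
    ).set_index("sample_id")
    surv = generate_survival(truth, config)
    clinical = clinical.join(surv)
    return matrix, clinical.reset_index(), truth


def _solve_censor_bound(rates: np.ndarray, target: float, tol: float = 1e-3) -> float:
    """Upper bound c of the Uniform(0, c) censoring law hitting `target`.

    P(censored) = mean_s (1 - exp(-lambda_s c)) / (lambda_s c), strictly
    decreasing in c from 1 to 0; solved by bisection to `tol`.
    """

    def p_cens(c: float) -> float:
        lc = rates * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-9, 1.0
    while p_cens(hi) > target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological rates
            break
    return float(brentq(lambda c: p_cens(c) - target, lo, hi, xtol=tol))


def generate_survival(truth: SyntheticTruth, config: SimulationConfig) -> pd.DataFrame:
    """Exponential survival times linked to one module factor.

    Hazard for sample s is ``(1/baseline_scale) * exp(beta * f_linked(s))``;
    censoring times are Uniform(0, c) with c solved so the expected censored
    fraction equals ``censor_rate`` (solver tolerance 1e-3).  Returns a frame
    indexed by sample id with columns os_months, os_event.
    """
    sc = config.survival
    if not 0.0 <= sc.censor_rate < 1.0:
        raise InputContractError("survival.censor_rate: must lie in [0, 1)")
    if not 1 <= sc.linked_module <= truth.factor_matrix.shape[0]:
        raise InputContractError(
            f"survival.linked_module: module {sc.linked_module} not in truth "
            f"(have {truth.factor_matrix.shape[0]} modules)"
        )
    f = truth.factor_matrix.iloc[sc.linked_module - 1].to_numpy()
    rates = np.exp(sc.log_hazard_per_unit * f) / sc.baseline_scale

    rng = stream(config.seed, "survival")
    t_event = rng.exponential(1.0 / rates)
    if sc.censor_rate == 0.0:
        os_months, os_event = t_event, np.ones_like(t_event, dtype=int)
    else:
        c = _solve_censor_bound(rates, sc.censor_rate)
        t_cens = rng.uniform(0.0, c, size=t_event.shape)
        os_event = (t_event <= t_cens).astype(int)
        os_months = np.minimum(t_event, t_cens)
    return pd.DataFrame(
        {"os_months": os_months, "os_event": os_event},
        index=truth.factor_matrix.columns,
    )
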